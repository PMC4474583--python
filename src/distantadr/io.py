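"""Readers and writers for the pipeline's plain-text interchange formats.

Messages travel as JSON-lines, gazetteers and knowledge bases as TSV (or
JSON for the KB), relation instances and predictions as JSON-lines, gold
annotations as BRAT-style standoff (.txt + .ann), and evaluation reports
as JSON plus a one-line TSV with the conventional column order
(TP, FP, FN, Precision, Recall, F1).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .candidates import FeatureBundle, RelationInstance
from .kernel import KernelConfig
from .model import EvalReport, TrainedModel
from .synthetic import SyntheticCorpus
from .text import EntityMention, Gazetteer, LexiconEntry, Message, build_gazetteer

from .kb import load_kb, save_kb_json, save_kb_tsv  # noqa: F401  (re-exported)


# --- messages ---------------------------------------------------------------

def read_messages(path: str | Path) -> list[Message]:
    """JSON-lines, one object per line with keys "id" and "text"."""
    messages = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                messages.append(Message(id=str(obj["id"]), text=obj["text"]))
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: bad message record ({exc})") from exc
    return messages


def write_messages(messages: Iterable[Message], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in messages:
            fh.write(json.dumps({"id": m.id, "text": m.text}, ensure_ascii=False) + "\n")


# --- gazetteer --------------------------------------------------------------

def read_gazetteer(path: str | Path) -> Gazetteer:
    """TSV with columns term, entity_type, canonical_id; '#' comments."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            entries.append(LexiconEntry(term=parts[0], entity_type=parts[1], canonical_id=parts[2]))
    return build_gazetteer(entries)


def write_gazetteer(gazetteer: Gazetteer, path: str | Path) -> None:
    lines = ["# term\tentity_type\tcanonical_id"]
    for e in gazetteer.entries:
        lines.append(f"{e.term}\t{e.entity_type}\t{e.canonical_id}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --- mentions ---------------------------------------------------------------

def write_mentions(mentions: Iterable[EntityMention], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(json.dumps(dataclasses.asdict(m), ensure_ascii=False) + "\n")


def read_mentions(path: str | Path) -> list[EntityMention]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(EntityMention(**json.loads(line)))
    return out


# --- relation instances -----------------------------------------------------

def _bundle_to_list(b: FeatureBundle) -> list[str]:
    return [b.surface, b.lemma, b.pos_tag, b.stem]


def write_instances(instances: Iterable[RelationInstance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            obj = {
                "id": inst.id,
                "message_id": inst.message_id,
                "drug": dataclasses.asdict(inst.drug),
                "effect": dataclasses.asdict(inst.effect),
                "fb": list(inst.fb),
                "b": list(inst.b),
                "ba": list(inst.ba),
                "left_local": [_bundle_to_list(b) for b in inst.left_local],
                "right_local": [_bundle_to_list(b) for b in inst.right_local],
                "label": inst.label,
                "label_source": inst.label_source,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_instances(path: str | Path) -> list[RelationInstance]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                RelationInstance(
                    id=obj["id"],
                    message_id=obj["message_id"],
                    drug=EntityMention(**obj["drug"]),
                    effect=EntityMention(**obj["effect"]),
                    fb=tuple(obj["fb"]),
                    b=tuple(obj["b"]),
                    ba=tuple(obj["ba"]),
                    left_local=tuple(FeatureBundle(*b) for b in obj["left_local"]),
                    right_local=tuple(FeatureBundle(*b) for b in obj["right_local"]),
                    label=obj["label"],
                    label_source=obj["label_source"],
                )
            )
    return out


# --- evaluation report ------------------------------------------------------

def write_report_json(report: EvalReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report.as_dict(), indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def write_report_tsv(report: EvalReport, path: str | Path) -> None:
    """One data line mirroring the conventional column order, 2 d.p. display."""
    header = "TP\tFP\tFN\tPrecision\tRecall\tF1"
    row = (
        f"{report.tp}\t{report.fp}\t{report.fn}\t"
        f"{report.precision:.2f}\t{report.recall:.2f}\t{report.f1:.2f}"
    )
    Path(path).write_text(header + "\n" + row + "\n", encoding="utf-8")


# --- BRAT-style standoff ----------------------------------------------------

def write_standoff(
    message: Message,
    mentions: Sequence[EntityMention],
    relations: Sequence[tuple[int, int]],
    directory: str | Path,
) -> None:
    """Write <id>.txt and <id>.ann; relations index into ``mentions``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / f"{message.id}.txt").write_text(message.text, encoding="utf-8")
    lines = []
    for i, m in enumerate(mentions, start=1):
        lines.append(f"T{i}\t{m.entity_type} {m.char_start} {m.char_end}\t{m.surface}")
    for j, (a, b) in enumerate(relations, start=1):
        lines.append(f"R{j}\tRELATED Arg1:T{a + 1} Arg2:T{b + 1}")
    (directory / f"{message.id}.ann").write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_standoff(directory: str | Path) -> list[tuple[Message, list[EntityMention], list[tuple[int, int]]]]:
    """Read all .txt/.ann pairs in a directory.

    Returns (message, mentions, relations) triples; relations are pairs of
    0-based indices into the mention list. Unparseable lines raise with
    file and line number.
    """
    directory = Path(directory)
    out = []
    for txt in sorted(directory.glob("*.txt")):
        msg_id = txt.stem
        text = txt.read_text(encoding="utf-8")
        ann = directory / f"{msg_id}.ann"
        mentions: list[EntityMention] = []
        t_index: dict[str, int] = {}
        relations: list[tuple[int, int]] = []
        if ann.exists():
            for lineno, line in enumerate(ann.read_text(encoding="utf-8").splitlines(), start=1):
                if not line.strip():
                    continue
                try:
                    if line.startswith("T"):
                        tid, spec, surface = line.split("\t")
                        etype, start, end = spec.split()
                        t_index[tid] = len(mentions)
                        mentions.append(
                            EntityMention(
                                message_id=msg_id,
                                entity_type=etype,
                                token_start=-1,
                                token_end=-1,
                                char_start=int(start),
                                char_end=int(end),
                                canonical_id="",
                                surface=surface,
                            )
                        )
                    elif line.startswith("R"):
                        _, spec = line.split("\t")
                        _, arg1, arg2 = spec.split()
                        relations.append(
                            (t_index[arg1.split(":")[1]], t_index[arg2.split(":")[1]])
                        )
                    else:
                        raise ValueError(f"unknown standoff line type {line[:1]!r}")
                except (ValueError, KeyError) as exc:
                    raise ValueError(f"{ann}:{lineno}: bad standoff line ({exc})") from exc
        out.append((Message(id=msg_id, text=text), mentions, relations))
    return out


# --- trained model ----------------------------------------------------------

def write_model(model: TrainedModel, path: str | Path) -> None:
    tmp = Path(str(path) + ".support.jsonl")
    write_instances(model.support_instances, tmp)
    support_lines = tmp.read_text(encoding="utf-8")
    tmp.unlink()
    obj = {
        "dual_coefficients": model.dual_coefficients.tolist(),
        "bias": model.bias,
        "cfg": dataclasses.asdict(model.cfg),
        "regularization_c": model.regularization_c,
        "class_weights": model.class_weights
        if isinstance(model.class_weights, (str, type(None)))
        else dict(model.class_weights),
        "support_instances_jsonl": support_lines,
    }
    Path(path).write_text(json.dumps(obj, ensure_ascii=False), encoding="utf-8")


def read_model(path: str | Path) -> TrainedModel:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    tmp = Path(str(path) + ".support.jsonl")
    tmp.write_text(obj["support_instances_jsonl"], encoding="utf-8")
    support = read_instances(tmp)
    tmp.unlink()
    return TrainedModel(
        support_instances=support,
        dual_coefficients=np.asarray(obj["dual_coefficients"]),
        bias=obj["bias"],
        cfg=KernelConfig(**obj["cfg"]),
        regularization_c=obj["regularization_c"],
        class_weights=obj["class_weights"],
    )


# --- synthetic corpus persistence -------------------------------------------

def save_corpus(corpus: SyntheticCorpus, directory: str | Path) -> None:
    """Persist a synthetic corpus in the same formats the pipeline reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_messages(corpus.messages, directory / "messages.jsonl")
    write_gazetteer(corpus.gazetteer, directory / "gazetteer.tsv")
    save_kb_tsv(corpus.kb, directory / "kb.tsv")
    gold_dir = directory / "gold"
    for message in corpus.messages:
        mentions = corpus.gold_mentions[message.id]
        idx = {(m.char_start, m.char_end): i for i, m in enumerate(mentions)}
        rels = []
        for msg_id, did, eid in sorted(corpus.gold_relations):
            if msg_id != message.id:
                continue
            d = next(i for i, m in enumerate(mentions) if m.canonical_id == did)
            e = next(i for i, m in enumerate(mentions) if m.canonical_id == eid)
            rels.append((d, e))
        write_standoff(message, mentions, rels, gold_dir)
    with open(directory / "bookkeeping.json", "w", encoding="utf-8") as fh:
        json.dump(corpus.bookkeeping, fh, ensure_ascii=False, indent=1, sort_keys=True)
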