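"""End-to-end orchestration: NER → candidates → distant labels → SVM → metrics.

The pipeline mirrors the distant-supervision recipe: recognize drug and
effect mentions with the gazetteer, pair them within a 250-token window,
label each pair by knowledge-base lookup, split messages 75/25, train the
SL-kernel SVM on the training instances and evaluate on the held-out
ones. Every stage persists its artifact so runs are inspectable and
bit-reproducible (a manifest records the config hash and seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as dio
from .candidates import (
    DEFAULT_FLANK_CAP,
    DEFAULT_LOCAL_WINDOW,
    DEFAULT_WINDOW_TOKENS,
    GOLD,
    NEGATIVE,
    POSITIVE,
    RelationInstance,
    build_instances,
    distant_label,
)
from .kb import KnowledgeBase
from .kernel import KernelConfig
from .model import (
    EvalReport,
    TrainedModel,
    evaluate,
    label_predictions,
    profile_corpus,
    profile_percentages,
    split_corpus,
    train,
)
from .text import EntityMention, Gazetteer, Message, analyze_message, match_entities

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One run's inputs and hyperparameters.

    Defaults follow the reference setting: a 250-token candidate window
    and a 75/25 train/test split of messages.
    """

    messages_path: str = ""
    gazetteer_path: str = ""
    kb_path: str = ""
    gold_dir: str = ""
    output_dir: str = "out"
    window_tokens: int = DEFAULT_WINDOW_TOKENS
    local_window: int = DEFAULT_LOCAL_WINDOW
    flank_cap: int = DEFAULT_FLANK_CAP
    kernel: KernelConfig = field(default_factory=KernelConfig)
    regularization_c: float = 1.0
    train_fraction: float = 0.75
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        kernel = data.pop("kernel", None)
        cfg = cls(**data)
        if kernel:
            cfg.kernel = KernelConfig(**kernel)
        return cfg

    def manifest(self) -> dict:
        payload = dataclasses.asdict(self)
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode("utf-8")
        ).hexdigest()
        return {"config": payload, "config_hash": digest, "seed": self.seed}


def run_ner(
    messages: list[Message], gazetteer: Gazetteer
) -> tuple[list[Message], dict[str, list[EntityMention]]]:
    """Tokenize, analyze morphology and match gazetteer entities."""
    analyzed = [analyze_message(m) for m in messages]
    mentions = {m.id: match_entities(m, gazetteer) for m in analyzed}
    n_drug = sum(1 for ms in mentions.values() for m in ms if m.entity_type == "DRUG")
    n_effect = sum(1 for ms in mentions.values() for m in ms if m.entity_type == "EFFECT")
    logger.info("NER: %d messages, %d drug mentions, %d effect mentions", len(messages), n_drug, n_effect)
    return analyzed, mentions


def run_candidates(
    analyzed: list[Message],
    mentions: dict[str, list[EntityMention]],
    config: PipelineConfig,
) -> list[RelationInstance]:
    instances: list[RelationInstance] = []
    for message in analyzed:
        instances.extend(
            build_instances(
                message,
                mentions[message.id],
                window_tokens=config.window_tokens,
                local_window=config.local_window,
                flank_cap=config.flank_cap,
            )
        )
    logger.info("candidates: %d relation instances", len(instances))
    return instances


def run_pipeline(config: PipelineConfig) -> EvalReport:
    """Execute all stages and persist artifacts under the output dir.

    The held-out evaluation compares the classifier's predictions on test
    instances against their own distant labels, the automatic evaluation
    regime the training data defines.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    messages = dio.read_messages(config.messages_path)
    gazetteer = dio.read_gazetteer(config.gazetteer_path)
    kb = dio.load_kb(config.kb_path)

    analyzed, mentions = run_ner(messages, gazetteer)
    dio.write_mentions((m for ms in mentions.values() for m in ms), out / "mentions.jsonl")

    counts = profile_corpus(analyzed, mentions)
    (out / "corpus_profile.json").write_text(
        json.dumps({"counts": counts, "percentages": profile_percentages(counts)}, indent=1, sort_keys=True),
        encoding="utf-8",
    )

    instances = run_candidates(analyzed, mentions, config)
    labeled = [distant_label(inst, kb) for inst in instances]
    dio.write_instances(labeled, out / "instances.jsonl")
    n_pos = sum(1 for i in labeled if i.label == POSITIVE)
    logger.info("distant labels: %d positive / %d total", n_pos, len(labeled))

    train_ids, test_ids = split_corpus(
        [m.id for m in messages], train_fraction=config.train_fraction, seed=config.seed
    )
    logger.info("split: %d train / %d test messages", len(train_ids), len(test_ids))
    train_set = set(train_ids)
    train_instances = [i for i in labeled if i.message_id in train_set]
    test_instances = [i for i in labeled if i.message_id not in train_set]

    model = train(
        train_instances,
        cfg=config.kernel,
        regularization_c=config.regularization_c,
        seed=config.seed,
    )
    dio.write_model(model, out / "model.json")

    predictions = label_predictions(model, test_instances)
    dio.write_instances(predictions, out / "predictions.jsonl")

    report = evaluate(predictions, test_instances)
    dio.write_report_json(report, out / "report.json")
    dio.write_report_tsv(report, out / "report.tsv")
    (out / "manifest.json").write_text(
        json.dumps(config.manifest(), indent=1, sort_keys=True), encoding="utf-8"
    )
    logger.info(
        "evaluation: TP=%d FP=%d FN=%d P=%.2f R=%.2f F1=%.2f",
        report.tp, report.fp, report.fn, report.precision, report.recall, report.f1,
    )
    return report


def _gold_reference(
    analyzed: list[Message],
    instances: list[RelationInstance],
    gold: list[tuple[Message, list[EntityMention], list[tuple[int, int]]]],
) -> list[RelationInstance]:
    """Reference labels for candidate instances from standoff gold relations.

    A candidate is gold-POSITIVE when a gold relation joins mentions whose
    character spans match the candidate's drug and effect spans.
    """
    gold_pairs: set[tuple[str, tuple[int, int], tuple[int, int]]] = set()
    for message, mentions, relations in gold:
        for a, b in relations:
            ma, mb = mentions[a], mentions[b]
            d, e = (ma, mb) if ma.entity_type == "DRUG" else (mb, ma)
            gold_pairs.add(
                (message.id, (d.char_start, d.char_end), (e.char_start, e.char_end))
            )
    out = []
    for inst in instances:
        key = (
            inst.message_id,
            (inst.drug.char_start, inst.drug.char_end),
            (inst.effect.char_start, inst.effect.char_end),
        )
        out.append(
            dataclasses.replace(
                inst, label=POSITIVE if key in gold_pairs else NEGATIVE, label_source=GOLD
            )
        )
    return out


def run_gold_evaluation(config: PipelineConfig, model: TrainedModel | None = None) -> EvalReport:
    """Train on distant labels, evaluate predictions against gold standoff.

    Candidate instances on the gold texts are aligned to gold relation
    annotations by mention character spans.
    """
    gold = dio.read_standoff(config.gold_dir)
    gazetteer = dio.read_gazetteer(config.gazetteer_path)

    if model is None:
        kb = dio.load_kb(config.kb_path)
        messages = dio.read_messages(config.messages_path)
        analyzed, mentions = run_ner(messages, gazetteer)
        labeled = [
            distant_label(i, kb) for i in run_candidates(analyzed, mentions, config)
        ]
        model = train(
            labeled,
            cfg=config.kernel,
            regularization_c=config.regularization_c,
            seed=config.seed,
        )

    gold_messages = [m for m, _, _ in gold]
    analyzed_gold, gold_ner = run_ner(gold_messages, gazetteer)
    candidates = run_candidates(analyzed_gold, gold_ner, config)
    predictions = label_predictions(model, candidates)
    reference = _gold_reference(analyzed_gold, candidates, gold)
    report = evaluate(predictions, reference)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dio.write_report_json(report, out / "gold_report.json")
    dio.write_report_tsv(report, out / "gold_report.tsv")
    return report
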