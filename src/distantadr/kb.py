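"""Drug-effect knowledge base: the supervision source for distant labeling.

The KB stores (drug, effect, relation-type) triples where the type is
either an adverse drug reaction (ADR) or an indication. The classifier
label downstream is binary (related / not related); relation type is
carried as metadata only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .text import EntityMention, normalize_term

logger = logging.getLogger(__name__)

ADR = "ADR"
INDICATION = "INDICATION"
RELATION_TYPES = (ADR, INDICATION)


@dataclass(frozen=True)
class DrugEffectRelation:
    drug_id: str
    effect_id: str
    relation_type: str  # ADR | INDICATION


@dataclass(frozen=True)
class LookupResult:
    related: bool
    types: frozenset[str]


@dataclass
class KnowledgeBase:
    """Drugs, effects, their relations, and a normalized-name index."""

    drugs: dict[str, str] = field(default_factory=dict)  # canonical_id -> preferred name
    effects: dict[str, str] = field(default_factory=dict)
    relations: set[DrugEffectRelation] = field(default_factory=set)
    name_index: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name_index:
            self.rebuild_name_index()
        self._pairs: set[tuple[str, str]] | None = None

    def rebuild_name_index(self) -> None:
        self.name_index = {
            "DRUG": {normalize_term(name): cid for cid, name in self.drugs.items()},
            "EFFECT": {normalize_term(name): cid for cid, name in self.effects.items()},
        }

    def resolve(self, mention: EntityMention) -> str | None:
        """Resolve a mention to a KB identifier.

        The gazetteer canonical_id is preferred; the normalized surface is
        the fallback (gazetteer and KB may disagree on preferred names).
        """
        pool = self.drugs if mention.entity_type == "DRUG" else self.effects
        if mention.canonical_id in pool:
            return mention.canonical_id
        return self.name_index.get(mention.entity_type, {}).get(normalize_term(mention.surface))


def kb_lookup(
    kb: KnowledgeBase, drug_mention: EntityMention, effect_mention: EntityMention
) -> LookupResult:
    """Total lookup: is this (drug, effect) pair related, and how?

    Unresolvable names yield ``related=False``.
    """
    did = kb.resolve(drug_mention)
    eid = kb.resolve(effect_mention)
    if did is None or eid is None:
        return LookupResult(False, frozenset())
    types = frozenset(
        r.relation_type for r in kb.relations if r.drug_id == did and r.effect_id == eid
    )
    return LookupResult(bool(types), types)


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load a KB from TSV (drug_name, effect_name, relation_type) or JSON.

    Names are normalized to build the name index; duplicate triples
    collapse. Unknown relation types raise with the offending line; an
    empty file is an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _load_kb_json(path)
    kb = KnowledgeBase()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
            drug_name, effect_name, rel_type = (p.strip() for p in parts)
            rel_type = rel_type.upper()
            if rel_type not in RELATION_TYPES:
                raise ValueError(
                    f"{path}:{lineno}: unknown relation_type {parts[2]!r} (expected ADR or INDICATION)"
                )
            did = "drug:" + normalize_term(drug_name)
            eid = "effect:" + normalize_term(effect_name)
            kb.drugs.setdefault(did, drug_name)
            kb.effects.setdefault(eid, effect_name)
            kb.relations.add(DrugEffectRelation(did, eid, rel_type))
            n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: knowledge base file is empty")
    kb.rebuild_name_index()
    logger.info(
        "loaded KB: %d drugs, %d effects, %d relations (%d rows)",
        len(kb.drugs), len(kb.effects), len(kb.relations), n_rows,
    )
    return kb


def _load_kb_json(path: Path) -> KnowledgeBase:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    kb = KnowledgeBase(
        drugs={d["id"]: d["name"] for d in data["drugs"]},
        effects={e["id"]: e["name"] for e in data["effects"]},
    )
    for i, rel in enumerate(data["relations"]):
        rel_type = rel["relation_type"].upper()
        if rel_type not in RELATION_TYPES:
            raise ValueError(f"{path}: relation {i}: unknown relation_type {rel['relation_type']!r}")
        if rel["drug_id"] not in kb.drugs or rel["effect_id"] not in kb.effects:
            raise ValueError(f"{path}: relation {i} references unknown drug or effect id")
        kb.relations.add(DrugEffectRelation(rel["drug_id"], rel["effect_id"], rel_type))
    if not kb.relations:
        raise ValueError(f"{path}: knowledge base has no relations")
    kb.rebuild_name_index()
    return kb


def save_kb_json(kb: KnowledgeBase, path: str | Path) -> None:
    data = {
        "drugs": [{"id": cid, "name": name} for cid, name in sorted(kb.drugs.items())],
        "effects": [{"id": cid, "name": name} for cid, name in sorted(kb.effects.items())],
        "relations": [
            {"drug_id": r.drug_id, "effect_id": r.effect_id, "relation_type": r.relation_type}
            for r in sorted(kb.relations, key=lambda r: (r.drug_id, r.effect_id, r.relation_type))
        ],
    }
    Path(path).write_text(json.dumps(data, ensure_ascii=False, indent=1), encoding="utf-8")


def save_kb_tsv(kb: KnowledgeBase, path: str | Path) -> None:
    lines = ["# drug_name\teffect_name\trelation_type"]
    for r in sorted(kb.relations, key=lambda r: (r.drug_id, r.effect_id, r.relation_type)):
        lines.append(f"{kb.drugs[r.drug_id]}\t{kb.effects[r.effect_id]}\t{r.relation_type}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def subsample_kb(kb: KnowledgeBase, keep_fraction: float, seed: int) -> KnowledgeBase:
    """Emulate KB incompleteness: keep each relation independently.

    Entities are always retained; deterministic for a fixed seed. The
    per-relation uniform draws follow a stable sort order so results do
    not depend on set iteration order.
    """
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in [0, 1], got {keep_fraction}")
    rng = np.random.default_rng(seed)
    ordered = sorted(kb.relations, key=lambda r: (r.drug_id, r.effect_id, r.relation_type))
    draws = rng.random(len(ordered))
    kept = {r for r, u in zip(ordered, draws) if u < keep_fraction}
    return KnowledgeBase(drugs=dict(kb.drugs), effects=dict(kb.effects), relations=kept)
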