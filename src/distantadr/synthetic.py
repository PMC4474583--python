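"""Seeded generator of forum-like Spanish message corpora.

Emulates the data this pipeline was designed for — short informal
messages from a Spanish patient forum mentioning drugs and effects — with
full ground truth: gold mentions with exact offsets, gold relations, a
matching knowledge base and gazetteer, per-message category bookkeeping,
and controllable misspelling noise. Everything is deterministic per seed.

The default category mix (55% messages with neither entity, 27% with
effects only, 5% with drugs only, 13% with both) mirrors the profile of
real patient-forum traffic, where most posts are not about treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .kb import ADR, INDICATION, DrugEffectRelation, KnowledgeBase
from .text import (
    DRUG,
    EFFECT,
    EntityMention,
    Gazetteer,
    LexiconEntry,
    Message,
    build_gazetteer,
    normalize_term,
    tokenize,
)

# Positive-cue templates: lay phrasings that assert a drug caused / treats
# an effect. Negative templates talk about both entities without relating
# them; two are negated variants, exercising the known false-positive mode
# of context-blind pairing without implementing negation handling.
POSITIVE_CUE_TEMPLATES = (
    "tomo DRUG y me dio EFFECT a los pocos dias",
    "desde que empece con DRUG tengo EFFECT casi a diario",
    "el DRUG me provoca EFFECT , lo note enseguida",
    "me recetaron DRUG y ahora sufro EFFECT por su culpa",
)

NEGATIVE_TEMPLATES = (
    "hablo de DRUG porque mi vecina comenta EFFECT a veces",
    "vi DRUG en la receta y lei sobre EFFECT en otro foro",
    "no tengo EFFECT aunque llevo meses con DRUG",
    "dejaron el DRUG en la mesa mientras charlabamos de EFFECT",
)

DRUG_ONLY_TEMPLATES = (
    "estoy tomando DRUG desde hace unas semanas",
    "el medico me receto DRUG ayer por la tarde",
    "alguien mas toma DRUG por aqui ?",
)

EFFECT_ONLY_TEMPLATES = (
    "llevo varios dias con EFFECT y no mejora",
    "mi madre sufre EFFECT desde hace tiempo",
    "vuelvo a tener EFFECT , que pesadilla",
)

FILLER_WORDS = (
    "hola", "pues", "bueno", "la", "verdad", "es", "que", "hoy", "me",
    "siento", "un", "poco", "mejor", "gracias", "a", "todos", "por",
    "vuestros", "animos", "y", "espero", "contaros", "algo", "pronto",
    "saludos", "desde", "el", "foro", ".", ",",
)

_ALL_TEMPLATES = (
    POSITIVE_CUE_TEMPLATES + NEGATIVE_TEMPLATES + DRUG_ONLY_TEMPLATES + EFFECT_ONLY_TEMPLATES
)
# Words generated names must avoid so template/filler text never contains
# an accidental gazetteer hit.
_RESERVED_WORDS = frozenset(
    normalize_term(w)
    for tpl in _ALL_TEMPLATES
    for w in tpl.split()
    if w not in ("DRUG", "EFFECT")
) | frozenset(normalize_term(w) for w in FILLER_WORDS) | frozenset({"de"})

_ACCENT = {"a": "á", "e": "é", "i": "í", "o": "ó", "u": "ú"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    n_drugs: int = 25
    n_effects: int = 50
    relation_density: float = 0.3
    n_messages: int = 400
    positive_cue_templates: tuple[str, ...] = POSITIVE_CUE_TEMPLATES
    negative_templates: tuple[str, ...] = NEGATIVE_TEMPLATES
    misspelling_rate: float = 0.1
    both_entity_rate: float = 0.13
    drug_only_rate: float = 0.05
    effect_only_rate: float = 0.27
    neither_rate: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.both_entity_rate,
            self.drug_only_rate,
            self.effect_only_rate,
            self.neither_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates + (self.relation_density, self.misspelling_rate)):
            raise ValueError("all rates must be in [0, 1]")
        if abs(sum(rates) - 1.0) > 1e-9:
            raise ValueError(f"category rates must sum to 1, got {sum(rates)}")
        for tpl in self.positive_cue_templates + self.negative_templates:
            if "DRUG" not in tpl.split() or "EFFECT" not in tpl.split():
                raise ValueError(f"template {tpl!r} must contain both DRUG and EFFECT slots")


@dataclass
class SyntheticCorpus:
    """A generated corpus with complete ground truth."""

    messages: list[Message]
    gold_mentions: dict[str, list[EntityMention]]
    gold_relations: set[tuple[str, str, str]]  # (message_id, drug_id, effect_id)
    kb: KnowledgeBase
    gazetteer: Gazetteer
    truth_pairs: set[tuple[str, str]]  # all truly related (drug_id, effect_id)
    bookkeeping: dict[str, dict]
    config: GeneratorConfig | None = None


_ONSETS = (
    "b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t", "v", "z",
    "br", "cl", "cr", "dr", "fl", "gr", "pl", "pr", "tr",
)
_VOWELS = ("a", "e", "i", "o", "u")
_DRUG_SUFFIXES = ("ol", "ina", "azol", "ex", "il", "an", "ona")
_EFFECT_SUFFIXES = ("or", "ismo", "itis", "ez", "ura", "azon")


def _syllable_word(rng: np.random.Generator, n_syllables: int, suffixes: Sequence[str]) -> str:
    word = "".join(
        _ONSETS[rng.integers(len(_ONSETS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )
    return word + suffixes[rng.integers(len(suffixes))]


def _maybe_accent(rng: np.random.Generator, word: str) -> str:
    if rng.random() >= 0.3:
        return word
    positions = [i for i, c in enumerate(word) if i >= 1 and c in _ACCENT]
    if not positions:
        return word
    i = positions[rng.integers(len(positions))]
    return word[:i] + _ACCENT[word[i]] + word[i + 1 :]


def generate_names(
    n: int, kind: str, seed: int, reserved: frozenset[str] = frozenset()
) -> list[str]:
    """Pronounceable pseudo-Spanish names, unique after normalization.

    Drugs are capitalized single words with nomenclature-like suffixes
    (-ol, -ina, -azol, ...); effects are 1-3-word lay phrases. Some names
    carry an accented vowel so accent-insensitive matching is exercised.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    taken = set(reserved) | _RESERVED_WORDS
    names: list[str] = []
    while len(names) < n:
        if kind == DRUG:
            word = _syllable_word(rng, int(rng.integers(2, 4)), _DRUG_SUFFIXES)
            name = _maybe_accent(rng, word).capitalize()
        else:
            shape = rng.integers(3)
            w1 = _maybe_accent(rng, _syllable_word(rng, int(rng.integers(1, 3)), _EFFECT_SUFFIXES))
            if shape == 0:
                name = w1
            elif shape == 1:
                w2 = _syllable_word(rng, int(rng.integers(1, 3)), _EFFECT_SUFFIXES)
                name = f"{w1} {w2}"
            else:
                w2 = _syllable_word(rng, int(rng.integers(1, 3)), _EFFECT_SUFFIXES)
                name = f"{w1} de {w2}"
        norm = normalize_term(name)
        parts = norm.split()
        if norm in taken or any(p in taken and p != "de" for p in parts):
            continue
        taken.add(norm)
        taken.update(p for p in parts if p != "de")
        names.append(name)
    return names


def generate_kb_and_gazetteer(
    cfg: GeneratorConfig,
) -> tuple[KnowledgeBase, Gazetteer, set[tuple[str, str]]]:
    """Names, truth table, knowledge base and gazetteer for one corpus.

    Each (drug, effect) pair is truly related with probability
    ``relation_density``; relation types default to a 0.92/0.08 ADR vs
    INDICATION mix, echoing how heavily real drug-effect resources skew
    toward adverse reactions. The returned KB contains exactly the truth
    table (a complete KB; use :func:`distantadr.kb.subsample_kb` to study
    incompleteness).
    """
    drug_names = generate_names(cfg.n_drugs, DRUG, cfg.seed)
    effect_names = generate_names(
        cfg.n_effects, EFFECT, cfg.seed + 1,
        reserved=frozenset(normalize_term(n) for n in drug_names),
    )
    drugs = {f"D{i:04d}": name for i, name in enumerate(drug_names)}
    effects = {f"E{i:04d}": name for i, name in enumerate(effect_names)}
    rng = np.random.default_rng(cfg.seed + 2)
    truth: set[tuple[str, str]] = set()
    relations: set[DrugEffectRelation] = set()
    for did in sorted(drugs):
        for eid in sorted(effects):
            if rng.random() < cfg.relation_density:
                rel_type = ADR if rng.random() < 0.92 else INDICATION
                truth.add((did, eid))
                relations.add(DrugEffectRelation(did, eid, rel_type))
    kb = KnowledgeBase(drugs=dict(drugs), effects=dict(effects), relations=relations)
    entries = [LexiconEntry(term=name, entity_type=DRUG, canonical_id=cid) for cid, name in drugs.items()]
    entries += [LexiconEntry(term=name, entity_type=EFFECT, canonical_id=cid) for cid, name in effects.items()]
    gazetteer = build_gazetteer(entries)
    return kb, gazetteer, truth


def _render(
    msg_id: str,
    words: Sequence[str],
    drug: tuple[str, str] | None,
    effect: tuple[str, str] | None,
) -> tuple[Message, list[EntityMention]]:
    """Join words with single spaces, substituting DRUG/EFFECT slots.

    Returns the message and its gold mentions with exact character and
    token offsets.
    """
    parts: list[str] = []
    spans: list[tuple[int, int, str, str, str]] = []  # start, end, type, cid, surface
    pos = 0
    for w in words:
        if w == "DRUG" and drug is not None:
            cid, surface = drug
            spans.append((pos, pos + len(surface), DRUG, cid, surface))
            parts.append(surface)
        elif w == "EFFECT" and effect is not None:
            cid, surface = effect
            spans.append((pos, pos + len(surface), EFFECT, cid, surface))
            parts.append(surface)
        else:
            parts.append(w)
        pos += len(parts[-1]) + 1
    text = " ".join(parts)
    tokens = tokenize(text)
    mentions = [
        EntityMention(
            message_id=msg_id,
            entity_type=etype,
            token_start=_first_token(tokens, start),
            token_end=_last_token(tokens, end),
            char_start=start,
            char_end=end,
            canonical_id=cid,
            surface=surface,
        )
        for start, end, etype, cid, surface in spans
    ]
    return Message(id=msg_id, text=text), mentions


def _first_token(tokens, char_start: int) -> int:
    return next(t.index for t in tokens if t.char_start >= char_start)


def _last_token(tokens, char_end: int) -> int:
    return max(t.index for t in tokens if t.char_end <= char_end) + 1


def generate_messages(
    cfg: GeneratorConfig,
    kb: KnowledgeBase,
    gazetteer: Gazetteer,
    truth: set[tuple[str, str]],
) -> SyntheticCorpus:
    """Draw messages into categories and fill templates with entity names.

    Messages in the "both" category embed a drug and an effect: a
    positive-cue template when the sampled pair is truly related,
    otherwise a neutral/negated template. Filler words (stop-words and
    punctuation included) surround the template. Gold bookkeeping records
    category, template and the sampled pair per message.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    drug_ids = sorted(kb.drugs)
    effect_ids = sorted(kb.effects)
    probs = [cfg.neither_rate, cfg.drug_only_rate, cfg.effect_only_rate, cfg.both_entity_rate]
    categories = ("no_drug_no_effect", "drug_only", "effect_only", "both")

    messages: list[Message] = []
    gold_mentions: dict[str, list[EntityMention]] = {}
    gold_relations: set[tuple[str, str, str]] = set()
    bookkeeping: dict[str, dict] = {}

    for i in range(cfg.n_messages):
        msg_id = f"m{i:06d}"
        cat = categories[rng.choice(4, p=probs)]
        prefix = [FILLER_WORDS[j] for j in rng.integers(0, len(FILLER_WORDS), rng.integers(2, 7))]
        suffix = [FILLER_WORDS[j] for j in rng.integers(0, len(FILLER_WORDS), rng.integers(2, 7))]
        drug = effect = None
        template = ""
        related = False
        if cat == "both":
            did = drug_ids[rng.integers(len(drug_ids))]
            eid = effect_ids[rng.integers(len(effect_ids))]
            related = (did, eid) in truth
            pool = cfg.positive_cue_templates if related else cfg.negative_templates
            template = pool[rng.integers(len(pool))]
            drug, effect = (did, kb.drugs[did]), (eid, kb.effects[eid])
            if related:
                gold_relations.add((msg_id, did, eid))
        elif cat == "drug_only":
            did = drug_ids[rng.integers(len(drug_ids))]
            template = DRUG_ONLY_TEMPLATES[rng.integers(len(DRUG_ONLY_TEMPLATES))]
            drug = (did, kb.drugs[did])
        elif cat == "effect_only":
            eid = effect_ids[rng.integers(len(effect_ids))]
            template = EFFECT_ONLY_TEMPLATES[rng.integers(len(EFFECT_ONLY_TEMPLATES))]
            effect = (eid, kb.effects[eid])
        words = prefix + (template.split() if template else []) + suffix
        message, mentions = _render(msg_id, words, drug, effect)
        messages.append(message)
        gold_mentions[msg_id] = mentions
        bookkeeping[msg_id] = {
            "category": cat,
            "template": template,
            "related": related,
            "pair": (drug[0] if drug else None, effect[0] if effect else None),
        }
    return SyntheticCorpus(
        messages=messages,
        gold_mentions=gold_mentions,
        gold_relations=gold_relations,
        kb=kb,
        gazetteer=gazetteer,
        truth_pairs=truth,
        bookkeeping=bookkeeping,
        config=cfg,
    )


def _edit_surface(surface: str, draws: tuple[float, float, int]) -> str:
    """Apply one character edit at Levenshtein distance 1, sparing char 0."""
    kind_u, pos_u, letter_i = draws
    letters = "aeiourstnlmcd"
    if len(surface) < 2:
        return surface + surface[-1]
    accented = [i for i, c in enumerate(surface) if i >= 1 and c in "áéíóúü"]
    kinds = ["substitute", "duplicate"]
    if len(surface) >= 3:
        kinds.append("drop")
    if accented:
        kinds.append("deaccent")
    kind = kinds[int(kind_u * len(kinds)) % len(kinds)]
    pos = 1 + int(pos_u * (len(surface) - 1)) % (len(surface) - 1)
    if kind == "substitute":
        current = surface[pos]
        repl = letters[letter_i % len(letters)]
        if repl == current:
            repl = letters[(letter_i + 1) % len(letters)]
        return surface[:pos] + repl + surface[pos + 1 :]
    if kind == "duplicate":
        return surface[:pos] + surface[pos] + surface[pos:]
    if kind == "drop":
        return surface[:pos] + surface[pos + 1 :]
    i = accented[pos % len(accented)]
    fold = {"á": "a", "é": "e", "í": "i", "ó": "o", "ú": "u", "ü": "u"}
    return surface[:i] + fold[surface[i]] + surface[i + 1 :]


def inject_noise(corpus: SyntheticCorpus, misspelling_rate: float, seed: int) -> SyntheticCorpus:
    """Misspell mention surfaces in the text with the given probability.

    Each affected mention receives one seeded character edit (substitute /
    drop / duplicate a character, or strip an accent), never touching the
    first character. Bookkeeping retains both the original and the noisy
    surface; canonical ids are untouched, so gold labels stay valid.

    The per-mention random draws are consumed in a fixed order regardless
    of the rate, so for a fixed seed the set of edited mentions at a lower
    rate is a subset of the set at any higher rate (with identical edits),
    making downstream recall monotone in the rate.
    """
    if not 0.0 <= misspelling_rate <= 1.0:
        raise ValueError(f"misspelling_rate must be in [0, 1], got {misspelling_rate}")
    rng = np.random.default_rng(seed)
    new_messages: list[Message] = []
    new_mentions: dict[str, list[EntityMention]] = {}
    bookkeeping = {k: dict(v) for k, v in corpus.bookkeeping.items()}
    for message in corpus.messages:
        mentions = sorted(corpus.gold_mentions[message.id], key=lambda m: m.char_start)
        text = message.text
        delta = 0
        edited: list[EntityMention] = []
        noise_log: list[dict] = []
        for m in mentions:
            u = rng.random()
            draws = (rng.random(), rng.random(), int(rng.integers(1 << 30)))
            start, end = m.char_start + delta, m.char_end + delta
            surface = text[start:end]
            if u < misspelling_rate:
                noisy = _edit_surface(surface, draws)
                text = text[:start] + noisy + text[end:]
                noise_log.append({"char_start": start, "original": surface, "noisy": noisy})
                edited.append(replace(m, char_start=start, char_end=start + len(noisy), surface=noisy))
                delta += len(noisy) - len(surface)
            else:
                edited.append(replace(m, char_start=start, char_end=end))
        tokens = tokenize(text)
        final = [
            replace(
                m,
                token_start=_first_token(tokens, m.char_start),
                token_end=_last_token(tokens, m.char_end),
            )
            for m in edited
        ]
        new_messages.append(Message(id=message.id, text=text))
        new_mentions[message.id] = final
        if noise_log:
            bookkeeping[message.id]["noise"] = noise_log
    return SyntheticCorpus(
        messages=new_messages,
        gold_mentions=new_mentions,
        gold_relations=set(corpus.gold_relations),
        kb=corpus.kb,
        gazetteer=corpus.gazetteer,
        truth_pairs=set(corpus.truth_pairs),
        bookkeeping=bookkeeping,
        config=corpus.config,
    )


def generate_corpus(cfg: GeneratorConfig) -> SyntheticCorpus:
    """Full generation: names -> KB/gazetteer -> messages -> noise."""
    kb, gazetteer, truth = generate_kb_and_gazetteer(cfg)
    corpus = generate_messages(cfg, kb, gazetteer, truth)
    if cfg.misspelling_rate > 0:
        corpus = inject_noise(corpus, cfg.misspelling_rate, cfg.seed + 4)
    return corpus
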