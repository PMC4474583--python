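"""Tokenization, normalization and dictionary-based entity recognition.

Informal Spanish forum text defeats trained sentence segmenters and
taggers, so the pipeline relies on a deliberately simple, fully
deterministic layer: whitespace + punctuation tokenization, case/accent
normalization, a rule-based suffix-stripping stemmer with a small
closed-class PoS table, and leftmost-longest gazetteer matching.
Richer morphology can be plugged in through :class:`MorphologyProvider`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Protocol, Sequence

logger = logging.getLogger(__name__)

DRUG = "DRUG"
EFFECT = "EFFECT"
ENTITY_TYPES = (DRUG, EFFECT)

# Accent folding applied after lowercasing: a/e/i/o/u acute plus diaeresis u.
# The n-tilde is a distinct letter in Spanish and is preserved.
_ACCENT_FOLD = str.maketrans("áéíóúü", "aeiouu")

# A token is a maximal run of word characters, or a single non-word
# non-space character (punctuation, inverted marks, symbols). Nothing but
# whitespace is dropped.
_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def normalize_term(s: str) -> str:
    """Lowercase, fold accents (á→a ... ü→u, ñ kept) and collapse whitespace.

    Idempotent; the empty string maps to itself.
    """
    folded = s.lower().translate(_ACCENT_FOLD)
    return " ".join(folded.split())


@dataclass(frozen=True)
class Token:
    """One tokenized unit with character offsets and optional morphology."""

    surface: str
    char_start: int  # 0-based inclusive
    char_end: int  # 0-based exclusive
    index: int  # position in the message's token sequence
    lemma: str = ""
    pos_tag: str = ""
    stem: str = ""


@dataclass(frozen=True)
class Message:
    """A forum post: stable id, raw text and its token sequence."""

    id: str
    text: str
    tokens: tuple[Token, ...] = ()


@dataclass(frozen=True)
class EntityMention:
    """A DRUG or EFFECT span, normalized to a canonical lexicon identifier.

    Token and character spans are 0-based half-open.
    """

    message_id: str
    entity_type: str
    token_start: int
    token_end: int
    char_start: int
    char_end: int
    canonical_id: str
    surface: str


def tokenize(text: str) -> list[Token]:
    """Split ``text`` on whitespace, separating punctuation into own tokens.

    Offsets are 0-based half-open into the original text; only whitespace
    is discarded. Empty text yields an empty list.
    """
    tokens: list[Token] = []
    for i, m in enumerate(_TOKEN_RE.finditer(text)):
        tokens.append(Token(surface=m.group(), char_start=m.start(), char_end=m.end(), index=i))
    return tokens


# --- default morphology -----------------------------------------------------

class MorphologyProvider(Protocol):
    """Contract for morphological analysis of a single token surface."""

    def analyze(self, surface: str) -> tuple[str, str, str]:
        """Return ``(lemma, pos_tag, stem)`` for a token surface."""
        ...


# Closed-class function words with coarse tags. Lemma is the normalized
# surface itself for these.
_CLOSED_CLASS: dict[str, str] = {}
for _pos, _words in {
    "DET": "el la los las un una unos unas este esta estos estas",
    "ADP": "a de en con por para sin sobre desde hasta entre tras",
    "CONJ": "y o pero ni aunque porque pues mientras",
    "PRON": "yo tu ella me te se le lo nos os les mi su quien",
    "ADV": "no muy mas ya tambien luego ahora siempre nunca bien mal",
    "SCONJ": "que si cuando como",
}.items():
    for _w in _words.split():
        _CLOSED_CLASS.setdefault(_w, _pos)

# Suffix-stripping rules, longest first; a rule applies only when at least
# three characters remain. Input is assumed normalized (lowercase, folded).
_STEM_SUFFIXES = sorted(
    [
        "amientos", "imientos", "aciones", "uciones", "amiento", "imiento",
        "adoras", "adores", "ancias", "encias", "acion", "ucion", "adora",
        "ancia", "encia", "mente", "ables", "ibles", "istas", "ismos",
        "ador", "able", "ible", "ista", "ismo", "osos", "osas", "ando",
        "iendo", "idos", "idas", "ados", "adas", "oso", "osa", "ado", "ido",
        "ar", "er", "ir", "as", "es", "os", "an", "en", "a", "e", "o", "s",
    ],
    key=len,
    reverse=True,
)


def spanish_stem(word: str) -> str:
    """Deterministic rule-based Spanish stemmer (suffix stripping).

    Strips the longest matching suffix that leaves a stem of at least
    three characters; otherwise returns the word unchanged.
    """
    for suf in _STEM_SUFFIXES:
        if word.endswith(suf) and len(word) - len(suf) >= 3:
            return word[: -len(suf)]
    return word


_VERB_ENDINGS = ("ar", "er", "ir", "ando", "iendo", "aba", "aron", "ieron", "aria")


class RuleBasedSpanishAnalyzer:
    """Zero-dependency default morphology provider.

    Closed-class words come from a shipped table; open-class words get
    ``lemma = stem`` from the suffix stripper and a coarse heuristic PoS.
    """

    def analyze(self, surface: str) -> tuple[str, str, str]:
        norm = normalize_term(surface)
        if not norm or not any(c.isalnum() for c in norm):
            return surface, "PUNCT", surface
        if norm.isdigit():
            return norm, "NUM", norm
        pos = _CLOSED_CLASS.get(norm)
        if pos is not None:
            return norm, pos, norm
        stem = spanish_stem(norm)
        if norm.endswith("mente"):
            pos = "ADV"
        elif norm.endswith(_VERB_ENDINGS):
            pos = "VERB"
        else:
            pos = "NOUN"
        return stem, pos, stem


_DEFAULT_ANALYZER = RuleBasedSpanishAnalyzer()


def analyze_morphology(
    tokens: Sequence[Token], analyzer: MorphologyProvider | None = None
) -> list[Token]:
    """Fill lemma / pos_tag / stem on each token.

    A provider failure on a token falls back to ``lemma = stem =``
    normalized surface with pos_tag ``"X"``.
    """
    analyzer = analyzer or _DEFAULT_ANALYZER
    out: list[Token] = []
    for tok in tokens:
        try:
            lemma, pos, stem = analyzer.analyze(tok.surface)
        except Exception:  # pragma: no cover - provider contract fallback
            norm = normalize_term(tok.surface)
            lemma, pos, stem = norm, "X", norm
        out.append(replace(tok, lemma=lemma, pos_tag=pos, stem=stem))
    return out


def analyze_message(message: Message, analyzer: MorphologyProvider | None = None) -> Message:
    """Tokenize (if needed) and morphologically analyze a message."""
    tokens = message.tokens or tuple(tokenize(message.text))
    return replace(message, tokens=tuple(analyze_morphology(tokens, analyzer)))


# --- gazetteer --------------------------------------------------------------

@dataclass(frozen=True)
class LexiconEntry:
    """A gazetteer row: a (possibly multiword) term with type and identifier."""

    term: str
    entity_type: str
    canonical_id: str


def term_key(term: str) -> tuple[str, ...]:
    """Normalized token-sequence key under which a term is indexed."""
    return tuple(normalize_term(t.surface) for t in tokenize(term))


@dataclass
class Gazetteer:
    """Normalized-token-sequence index over lexicon entries."""

    entries: list[LexiconEntry] = field(default_factory=list)
    index: dict[tuple[str, ...], dict[str, LexiconEntry]] = field(default_factory=dict)
    max_term_tokens: int = 0

    @property
    def size(self) -> int:
        return sum(len(by_type) for by_type in self.index.values())

    def lookup(self, key: tuple[str, ...]) -> dict[str, LexiconEntry]:
        return self.index.get(key, {})


def build_gazetteer(entries: Iterable[LexiconEntry]) -> Gazetteer:
    """Index entries by the normalized token sequence of their terms.

    Duplicate normalized ``(term, type)`` pairs collapse to one entry, the
    first canonical_id winning (a warning is logged). Empty terms are
    rejected.
    """
    gaz = Gazetteer()
    for row, entry in enumerate(entries):
        if not entry.term or not entry.term.strip():
            raise ValueError(f"gazetteer entry {row} has an empty term (id={entry.canonical_id!r})")
        if entry.entity_type not in ENTITY_TYPES:
            raise ValueError(
                f"gazetteer entry {row} ({entry.term!r}) has unknown entity_type {entry.entity_type!r}"
            )
        key = term_key(entry.term)
        by_type = gaz.index.setdefault(key, {})
        if entry.entity_type in by_type:
            logger.warning(
                "duplicate gazetteer term %r/%s collapsed (kept id=%s, dropped id=%s)",
                entry.term, entry.entity_type,
                by_type[entry.entity_type].canonical_id, entry.canonical_id,
            )
            continue
        by_type[entry.entity_type] = entry
        gaz.entries.append(entry)
        gaz.max_term_tokens = max(gaz.max_term_tokens, len(key))
    return gaz


def match_entities(message: Message, gazetteer: Gazetteer) -> list[EntityMention]:
    """Leftmost-longest, non-overlapping gazetteer matching over a message.

    Matching is case/accent-insensitive through :func:`normalize_term`.
    When DRUG and EFFECT entries cover the same span, DRUG wins (drugs are
    a closed nomenclature; the tie is logged).
    """
    tokens = message.tokens or tuple(tokenize(message.text))
    norms = [normalize_term(t.surface) for t in tokens]
    mentions: list[EntityMention] = []
    i, n = 0, len(tokens)
    while i < n:
        hit: EntityMention | None = None
        for length in range(min(gazetteer.max_term_tokens, n - i), 0, -1):
            by_type = gazetteer.lookup(tuple(norms[i : i + length]))
            if not by_type:
                continue
            if DRUG in by_type and EFFECT in by_type:
                logger.debug(
                    "DRUG/EFFECT tie at tokens %d..%d in message %s resolved DRUG-first",
                    i, i + length, message.id,
                )
            entry = by_type.get(DRUG) or by_type[EFFECT]
            start, end = tokens[i].char_start, tokens[i + length - 1].char_end
            hit = EntityMention(
                message_id=message.id,
                entity_type=entry.entity_type,
                token_start=i,
                token_end=i + length,
                char_start=start,
                char_end=end,
                canonical_id=entry.canonical_id,
                surface=message.text[start:end],
            )
            i += length
            break
        if hit is not None:
            mentions.append(hit)
        else:
            i += 1
    return mentions
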