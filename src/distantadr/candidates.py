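"""Candidate relation instances: windowed pairing, contexts, distant labels.

Every (drug mention, effect mention) pair within a token window of one
message becomes a candidate relation instance. Each instance carries the
global contexts used by the n-gram kernels — Fore-Between (FB), Between
(B) and Between-After (BA) — and two local contexts of morphological
feature bundles centered on the candidate entities. The knowledge base
then supplies the distant label: POSITIVE iff the pair is in the KB.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .kb import KnowledgeBase, kb_lookup
from .text import DRUG, EntityMention, Message, normalize_term

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
UNLABELED = "UNLABELED"

DISTANT = "DISTANT"
GOLD = "GOLD"
PREDICTED = "PREDICTED"

CAND_DRUG = "CAND_DRUG"
CAND_EFFECT = "CAND_EFFECT"
PAD_VALUE = "⊥"

DEFAULT_WINDOW_TOKENS = 250
DEFAULT_LOCAL_WINDOW = 2
DEFAULT_FLANK_CAP = 10


@dataclass(frozen=True)
class FeatureBundle:
    """Surface, lemma, PoS and stem of one local-context position."""

    surface: str
    lemma: str
    pos_tag: str
    stem: str


PAD_BUNDLE = FeatureBundle(PAD_VALUE, PAD_VALUE, PAD_VALUE, PAD_VALUE)


@dataclass(frozen=True)
class RelationInstance:
    """One (drug, effect) candidate with its contexts and label."""

    id: str
    message_id: str
    drug: EntityMention
    effect: EntityMention
    fb: tuple[str, ...] = ()
    b: tuple[str, ...] = ()
    ba: tuple[str, ...] = ()
    left_local: tuple[FeatureBundle, ...] = ()
    right_local: tuple[FeatureBundle, ...] = ()
    label: str = UNLABELED
    label_source: str = ""


def token_gap(a: EntityMention, b: EntityMention) -> int:
    """Tokens strictly between the nearer boundaries of two mentions."""
    first, second = (a, b) if a.token_start <= b.token_start else (b, a)
    return max(0, second.token_start - first.token_end)


def generate_candidates(
    message: Message,
    mentions: Sequence[EntityMention],
    window_tokens: int = DEFAULT_WINDOW_TOKENS,
) -> list[RelationInstance]:
    """Pair every DRUG with every EFFECT mention within the token window.

    The gap is counted strictly between the nearer mention boundaries.
    Instance ids are deterministic functions of the message id and spans.
    """
    if window_tokens < 1:
        raise ValueError(f"window_tokens must be positive, got {window_tokens}")
    drugs = [m for m in mentions if m.entity_type == DRUG]
    effects = [m for m in mentions if m.entity_type != DRUG]
    out: list[RelationInstance] = []
    for d in drugs:
        for e in effects:
            if token_gap(d, e) > window_tokens:
                continue
            iid = f"{message.id}:d{d.token_start}-{d.token_end}:e{e.token_start}-{e.token_end}"
            out.append(RelationInstance(id=iid, message_id=message.id, drug=d, effect=e))
    return out


def _ctx_token(token) -> str:
    norm = normalize_term(token.surface)
    return norm if norm else token.surface


def _bundle(token) -> FeatureBundle:
    return FeatureBundle(
        surface=_ctx_token(token),
        lemma=token.lemma or _ctx_token(token),
        pos_tag=token.pos_tag or "X",
        stem=token.stem or _ctx_token(token),
    )


def _placeholder_bundle(tag: str) -> FeatureBundle:
    return FeatureBundle(tag, tag, tag, tag)


def extract_contexts(
    message: Message,
    instance: RelationInstance,
    local_window: int = DEFAULT_LOCAL_WINDOW,
    flank_cap: int = DEFAULT_FLANK_CAP,
) -> RelationInstance:
    """Fill FB/B/BA global contexts and left/right local contexts.

    The candidate entities are replaced by the placeholders CAND_DRUG /
    CAND_EFFECT so the classifier learns from context rather than from
    memorized names. Stop-words and punctuation are retained: they are
    informative for relation detection. Local contexts are
    ``2*local_window + 1`` feature bundles centered on the first / second
    entity placeholder, PAD-padded at message edges.
    """
    if local_window < 1 or flank_cap < 1:
        raise ValueError("local_window and flank_cap must be positive")
    tokens = message.tokens
    d, e = instance.drug, instance.effect
    first, second = (d, e) if d.token_start <= e.token_start else (e, d)
    tag_first = CAND_DRUG if first.entity_type == DRUG else CAND_EFFECT
    tag_second = CAND_DRUG if second.entity_type == DRUG else CAND_EFFECT

    pre = tokens[: first.token_start]
    mid = tokens[first.token_end : second.token_start]
    post = tokens[second.token_end :]

    b = tuple(_ctx_token(t) for t in mid)
    fb = tuple(_ctx_token(t) for t in pre[-flank_cap:]) + (tag_first,) + b
    ba = b + (tag_second,) + tuple(_ctx_token(t) for t in post[:flank_cap])

    # Collapsed bundle sequence: each mention becomes one placeholder bundle.
    seq = (
        [_bundle(t) for t in pre]
        + [_placeholder_bundle(tag_first)]
        + [_bundle(t) for t in mid]
        + [_placeholder_bundle(tag_second)]
        + [_bundle(t) for t in post]
    )
    i_first = len(pre)
    i_second = len(pre) + 1 + len(mid)

    def window(center: int) -> tuple[FeatureBundle, ...]:
        out = []
        for j in range(center - local_window, center + local_window + 1):
            out.append(seq[j] if 0 <= j < len(seq) else PAD_BUNDLE)
        return tuple(out)

    return replace(
        instance,
        fb=fb,
        b=b,
        ba=ba,
        left_local=window(i_first),
        right_local=window(i_second),
    )


def distant_label(instance: RelationInstance, kb: KnowledgeBase) -> RelationInstance:
    """Label by KB lookup: POSITIVE iff the pair is related in the KB."""
    result = kb_lookup(kb, instance.drug, instance.effect)
    return replace(instance, label=POSITIVE if result.related else NEGATIVE, label_source=DISTANT)


def build_instances(
    message: Message,
    mentions: Sequence[EntityMention],
    window_tokens: int = DEFAULT_WINDOW_TOKENS,
    local_window: int = DEFAULT_LOCAL_WINDOW,
    flank_cap: int = DEFAULT_FLANK_CAP,
) -> list[RelationInstance]:
    """Candidate generation + context extraction for one analyzed message."""
    return [
        extract_contexts(message, inst, local_window=local_window, flank_cap=flank_cap)
        for inst in generate_candidates(message, mentions, window_tokens=window_tokens)
    ]
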