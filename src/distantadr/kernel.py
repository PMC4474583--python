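"""Shallow Linguistic (SL) kernel over relation instances.

The SL kernel is a linear combination of a *global context* kernel and a
*local context* kernel.

Global: for each of the three contexts FB, B, BA, an n-gram kernel counts
the contiguous n-grams (n = 1..ngram_max) the two instances share:
``K_ctx(x, y) = sum_n <phi_n(x_ctx), phi_n(y_ctx)>``. The global kernel is
the (unit-weight) sum of the three, each cosine-normalized first.

Local: for each side (left context of the first entity, right context of
the second), aligned positions contribute the number of feature values —
surface, lemma, PoS tag, stem — the two bundles share; PAD matches only
PAD. Sides are normalized then summed.

Both component families are explicit inner products, so every kernel here
is positive semi-definite by construction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from .candidates import FeatureBundle, RelationInstance

_FIELDS = ("surface", "lemma", "pos_tag", "stem")


@dataclass(frozen=True)
class KernelConfig:
    """SL kernel hyperparameters.

    ngram_max bounds the n-gram order of the global kernels; local_window
    sets the local-context half-width (contexts have 2*local_window + 1
    positions); normalize applies per-component cosine normalization;
    weight_global / weight_local set the linear combination.
    """

    ngram_max: int = 3
    local_window: int = 2
    normalize: bool = True
    weight_global: float = 1.0
    weight_local: float = 1.0

    def __post_init__(self) -> None:
        if self.ngram_max < 1:
            raise ValueError(f"ngram_max must be >= 1, got {self.ngram_max}")
        if self.local_window < 1:
            raise ValueError(f"local_window must be >= 1, got {self.local_window}")
        if self.weight_global < 0 or self.weight_local < 0:
            raise ValueError("kernel weights must be non-negative")
        if self.weight_global + self.weight_local <= 0:
            raise ValueError("weight_global + weight_local must be > 0")


def _ngram_counts(seq: Sequence[str], ngram_max: int) -> Counter:
    counts: Counter = Counter()
    L = len(seq)
    for n in range(1, ngram_max + 1):
        for i in range(L - n + 1):
            counts[tuple(seq[i : i + n])] += 1
    return counts


def _dot(a: Counter, b: Counter) -> float:
    if len(b) < len(a):
        a, b = b, a
    return float(sum(c * b[g] for g, c in a.items() if g in b))


def ngram_kernel(a: Sequence[str], b: Sequence[str], ngram_max: int) -> float:
    """Count the contiguous n-grams (orders 1..ngram_max) shared by a and b.

    An empty sequence yields 0 against anything.
    """
    if ngram_max < 1:
        raise ValueError(f"ngram_max must be >= 1, got {ngram_max}")
    if not a or not b:
        return 0.0
    return _dot(_ngram_counts(a, ngram_max), _ngram_counts(b, ngram_max))


def _normalized(kxy: float, kxx: float, kyy: float) -> float:
    if kxx <= 0.0 or kyy <= 0.0:
        return 0.0
    return kxy / math.sqrt(kxx * kyy)


def global_kernel(x: RelationInstance, y: RelationInstance, cfg: KernelConfig) -> float:
    """Sum of the FB, B and BA n-gram kernels (each normalized if configured)."""
    total = 0.0
    for ctx in ("fb", "b", "ba"):
        cx, cy = getattr(x, ctx), getattr(y, ctx)
        k = ngram_kernel(cx, cy, cfg.ngram_max)
        if cfg.normalize:
            k = _normalized(
                k,
                ngram_kernel(cx, cx, cfg.ngram_max),
                ngram_kernel(cy, cy, cfg.ngram_max),
            )
        total += k
    return total


def _side_kernel(a: Sequence[FeatureBundle], b: Sequence[FeatureBundle]) -> float:
    return float(
        sum(
            sum(1 for f in _FIELDS if getattr(pa, f) == getattr(pb, f))
            for pa, pb in zip(a, b)
        )
    )


def local_kernel(x: RelationInstance, y: RelationInstance, cfg: KernelConfig) -> float:
    """Sum of the left and right local-context kernels (each normalized)."""
    expected = 2 * cfg.local_window + 1
    for inst in (x, y):
        for side in (inst.left_local, inst.right_local):
            if len(side) != expected:
                raise ValueError(
                    f"local context of length {len(side)} does not match "
                    f"2*local_window+1 = {expected}; instances were featurized "
                    "under a different configuration"
                )
    total = 0.0
    for side in ("left_local", "right_local"):
        sx, sy = getattr(x, side), getattr(y, side)
        k = _side_kernel(sx, sy)
        if cfg.normalize:
            k = _normalized(k, _side_kernel(sx, sx), _side_kernel(sy, sy))
        total += k
    return total


def sl_kernel(x: RelationInstance, y: RelationInstance, cfg: KernelConfig | None = None) -> float:
    """weight_global * K_global + weight_local * K_local; symmetric."""
    cfg = cfg or KernelConfig()
    return cfg.weight_global * global_kernel(x, y, cfg) + cfg.weight_local * local_kernel(x, y, cfg)


# --- vectorized Gram computation -------------------------------------------
#
# Each component kernel has an explicit finite feature map, so the Gram
# matrix is computed channel-by-channel as a sparse count-matrix product.
# Tests verify this path entry-by-entry against the pairwise sl_kernel.

def _global_channel(ctx: str, cfg: KernelConfig) -> Callable[[RelationInstance], Counter]:
    def feats(inst: RelationInstance) -> Counter:
        return _ngram_counts(getattr(inst, ctx), cfg.ngram_max)

    return feats


def _local_channel(side: str) -> Callable[[RelationInstance], Counter]:
    def feats(inst: RelationInstance) -> Counter:
        counts: Counter = Counter()
        for i, bundle in enumerate(getattr(inst, side)):
            for f in _FIELDS:
                counts[(i, f, getattr(bundle, f))] += 1
        return counts

    return feats


def _count_matrix(counts: list[Counter], vocab: dict) -> sp.csr_matrix:
    data, indices, indptr = [], [], [0]
    for c in counts:
        for feat, v in c.items():
            indices.append(vocab[feat])
            data.append(v)
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), indices, indptr),
        shape=(len(counts), len(vocab) or 1),
    )


def gram_matrix(
    instances_a: Sequence[RelationInstance],
    instances_b: Sequence[RelationInstance],
    cfg: KernelConfig | None = None,
) -> np.ndarray:
    """Dense Gram matrix with entry (i, j) = sl_kernel(a_i, b_j).

    Symmetric when the two sequences are the same objects; empty inputs
    yield an empty matrix.
    """
    cfg = cfg or KernelConfig()
    na, nb = len(instances_a), len(instances_b)
    K = np.zeros((na, nb))
    if na == 0 or nb == 0:
        return K
    same = instances_a is instances_b
    channels = [
        (_global_channel("fb", cfg), cfg.weight_global),
        (_global_channel("b", cfg), cfg.weight_global),
        (_global_channel("ba", cfg), cfg.weight_global),
        (_local_channel("left_local"), cfg.weight_local),
        (_local_channel("right_local"), cfg.weight_local),
    ]
    for feats, weight in channels:
        if weight == 0.0:
            continue
        counts_a = [feats(x) for x in instances_a]
        counts_b = counts_a if same else [feats(y) for y in instances_b]
        vocab: dict = {}
        for c in counts_a:
            for g in c:
                vocab.setdefault(g, len(vocab))
        for c in counts_b:
            for g in c:
                vocab.setdefault(g, len(vocab))
        Xa = _count_matrix(counts_a, vocab)
        Xb = Xa if same else _count_matrix(counts_b, vocab)
        raw = np.asarray((Xa @ Xb.T).todense())
        if cfg.normalize:
            norm_a = np.sqrt(np.asarray(Xa.multiply(Xa).sum(axis=1)).ravel())
            norm_b = norm_a if same else np.sqrt(np.asarray(Xb.multiply(Xb).sum(axis=1)).ravel())
            denom = np.outer(norm_a, norm_b)
            with np.errstate(invalid="ignore", divide="ignore"):
                raw = np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
        K += weight * raw
    if same:
        K = (K + K.T) / 2.0  # remove float round-off asymmetry
    return K
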