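"""SL kernel components: n-gram kernels, local kernels, Gram matrices."""

import dataclasses
import math

import numpy as np
import pytest

import distantadr as d
from distantadr.candidates import FeatureBundle
from distantadr.kernel import (
    KernelConfig,
    global_kernel,
    gram_matrix,
    local_kernel,
    ngram_kernel,
    sl_kernel,
)

from tests.conftest import toy_instance


def brute_force_ngram(a, b, nmax):
    """Independent oracle: enumerate every n-gram of a and count matches in b."""
    total = 0
    for n in range(1, nmax + 1):
        grams_a = [tuple(a[i : i + n]) for i in range(len(a) - n + 1)]
        grams_b = [tuple(b[i : i + n]) for i in range(len(b) - n + 1)]
        for g in set(grams_a):
            total += grams_a.count(g) * grams_b.count(g)
    return total


class TestNgramKernel:
    def test_self_dot_abc(self):
        assert ngram_kernel(["a", "b", "c"], ["a", "b", "c"], 2) == 5

    def test_disjoint_vocabularies(self):
        assert ngram_kernel(["a", "b"], ["x", "y"], 3) == 0

    def test_aba_bab(self):
        assert ngram_kernel(["a", "b", "a"], ["b", "a", "b"], 2) == 6

    def test_empty_sequence_is_zero(self):
        assert ngram_kernel([], ["a"], 2) == 0
        assert ngram_kernel([], [], 2) == 0

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            ngram_kernel(["a"], ["a"], 0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        vocab = [f"t{i}" for i in range(6)]
        for _ in range(300):
            a = [vocab[i] for i in rng.integers(0, 6, rng.integers(0, 9))]
            b = [vocab[i] for i in rng.integers(0, 6, rng.integers(0, 9))]
            nmax = int(rng.integers(1, 5))
            assert ngram_kernel(a, b, nmax) == brute_force_ngram(a, b, nmax)


def _pair():
    x = toy_instance(["tomo", "DRUGX", "y", "me", "dio", "EFFECTY", "luego"], (1, 2), (5, 6))
    y = toy_instance(["ayer", "DRUGZ", "y", "me", "dio", "EFFECTW", "fatal"], (1, 2), (5, 6))
    return x, y


class TestGlobalKernel:
    def test_self_similarity_is_three(self):
        x, _ = _pair()
        assert global_kernel(x, x, KernelConfig()) == pytest.approx(3.0)

    def test_nothing_shared_is_zero(self):
        x = toy_instance(["aa", "DRUGX", "bb", "EFFECTY", "cc"], (1, 2), (3, 4))
        y = toy_instance(["dd", "DRUGZ", "ee", "EFFECTW", "ff"], (1, 2), (3, 4))
        # placeholders are shared by construction; strip them out to build
        # genuinely disjoint contexts
        y = dataclasses.replace(
            y,
            fb=("dd", "PH1", "ee"), b=("ee",), ba=("ee", "PH2", "ff"),
        )
        x = dataclasses.replace(
            x,
            fb=("aa", "PH3", "bb"), b=("bb",), ba=("bb", "PH4", "cc"),
        )
        assert global_kernel(x, y, KernelConfig()) == 0.0

    def test_shared_between_context_only(self):
        """When only B overlaps, the kernel equals the normalized B term."""
        x, y = _pair()
        # hand-built contexts: FB and BA are fully disjoint between the two
        # instances, so any kernel mass must come from the shared B
        x = dataclasses.replace(x, fb=("aa", "PH1"), ba=("PH2", "bb"))
        y = dataclasses.replace(y, fb=("cc", "PH3"), ba=("PH4", "dd"))
        cfg = KernelConfig()
        kb_raw = brute_force_ngram(list(x.b), list(y.b), cfg.ngram_max)
        kb_norm = kb_raw / math.sqrt(
            brute_force_ngram(list(x.b), list(x.b), cfg.ngram_max)
            * brute_force_ngram(list(y.b), list(y.b), cfg.ngram_max)
        )
        assert global_kernel(x, y, cfg) == pytest.approx(kb_norm)

    def test_empty_between_contributes_zero_not_nan(self):
        x = toy_instance(["a", "DRUGX", "EFFECTY", "b"], (1, 2), (2, 3))
        k = global_kernel(x, x, KernelConfig())
        assert not math.isnan(k)
        assert k == pytest.approx(2.0)  # FB and BA self-terms only


class TestLocalKernel:
    def test_identical_contexts_normalize_to_two(self):
        x, _ = _pair()
        assert local_kernel(x, x, KernelConfig()) == pytest.approx(2.0)

    def test_fully_disjoint_features(self):
        x, y = _pair()
        blank = tuple(
            FeatureBundle(f"q{i}", f"r{i}", f"s{i}", f"t{i}") for i in range(5)
        )
        other = tuple(
            FeatureBundle(f"u{i}", f"v{i}", f"w{i}", f"x{i}") for i in range(5)
        )
        x = dataclasses.replace(x, left_local=blank, right_local=blank)
        y = dataclasses.replace(y, left_local=other, right_local=other)
        assert local_kernel(x, y, KernelConfig()) == 0.0

    def test_pos_only_agreement_counts_positions(self):
        """Agreement in pos_tag alone at every position gives raw = 2w+1."""
        x, y = _pair()
        left_x = tuple(FeatureBundle(f"a{i}", f"b{i}", "NOUN", f"c{i}") for i in range(5))
        left_y = tuple(FeatureBundle(f"d{i}", f"e{i}", "NOUN", f"f{i}") for i in range(5))
        far = tuple(FeatureBundle(f"g{i}", f"h{i}", f"i{i}", f"j{i}") for i in range(5))
        far2 = tuple(FeatureBundle(f"k{i}", f"l{i}", f"m{i}", f"n{i}") for i in range(5))
        x = dataclasses.replace(x, left_local=left_x, right_local=far)
        y = dataclasses.replace(y, left_local=left_y, right_local=far2)
        raw = local_kernel(x, y, KernelConfig(normalize=False))
        assert raw == 5.0

    def test_length_mismatch_raises(self):
        x, y = _pair()
        y = dataclasses.replace(y, left_local=y.left_local[:3])
        with pytest.raises(ValueError, match="local_window"):
            local_kernel(x, y, KernelConfig())


class TestSlKernel:
    def test_self_similarity_with_defaults(self):
        x, _ = _pair()
        assert sl_kernel(x, x) == pytest.approx(5.0)

    def test_zero_local_weight_degenerates_to_global(self):
        x, y = _pair()
        cfg = KernelConfig(weight_local=0.0)
        assert sl_kernel(x, y, cfg) == pytest.approx(global_kernel(x, y, cfg))

    def test_symmetry(self):
        x, y = _pair()
        assert sl_kernel(x, y) == pytest.approx(sl_kernel(y, x))

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            KernelConfig(weight_global=0.0, weight_local=0.0)

    def test_stopword_retention_changes_values(self):
        """Stripping stop-words from contexts must change the kernel:

        they are kept deliberately because function words carry relational
        cues in this kernel family.
        """
        x = toy_instance(["uno", "DRUGX", "y", "me", "dio", "EFFECTY"], (1, 2), (5, 6))
        y = toy_instance(["dos", "DRUGZ", "y", "me", "vio", "EFFECTW"], (1, 2), (5, 6))
        stop = {"y", "me", "de", "la", "el"}
        strip = lambda seq: tuple(t for t in seq if t not in stop)
        x_stripped = dataclasses.replace(x, fb=strip(x.fb), b=strip(x.b), ba=strip(x.ba))
        y_stripped = dataclasses.replace(y, fb=strip(y.fb), b=strip(y.b), ba=strip(y.ba))
        assert sl_kernel(x, y) != sl_kernel(x_stripped, y_stripped)


class TestGramMatrix:
    def test_matches_pairwise_kernel(self, clean_instances):
        insts = clean_instances[:15]
        cfg = KernelConfig()
        K = gram_matrix(insts, insts, cfg)
        for i, x in enumerate(insts):
            for j, y in enumerate(insts):
                assert K[i, j] == pytest.approx(sl_kernel(x, y, cfg), abs=1e-9)

    def test_unnormalized_matches_pairwise(self, clean_instances):
        insts = clean_instances[:8]
        cfg = KernelConfig(normalize=False)
        K = gram_matrix(insts, insts, cfg)
        for i, x in enumerate(insts):
            for j, y in enumerate(insts):
                assert K[i, j] == pytest.approx(sl_kernel(x, y, cfg), abs=1e-9)

    def test_symmetry_exact(self, clean_instances):
        K = gram_matrix(clean_instances[:10], clean_instances[:10])
        assert np.max(np.abs(K - K.T)) == 0.0

    def test_psd(self, clean_instances):
        K = gram_matrix(clean_instances[:30], clean_instances[:30])
        eig = np.linalg.eigvalsh(K)
        assert eig.min() >= -1e-8 * max(eig.max(), 1.0)

    def test_cross_disjoint_vocabulary_zero(self):
        a = [toy_instance(["aa", "DRUGX", "bb", "EFFECTY"], (1, 2), (3, 4))]
        a = [
            dataclasses.replace(
                a[0],
                fb=("aa", "P1", "bb"), b=("bb",), ba=("bb", "P2"),
                left_local=tuple(FeatureBundle(*(f"a{i}{k}" for k in range(4))) for i in range(5)),
                right_local=tuple(FeatureBundle(*(f"b{i}{k}" for k in range(4))) for i in range(5)),
            )
        ]
        b = [
            dataclasses.replace(
                a[0],
                fb=("cc", "P3", "dd"), b=("dd",), ba=("dd", "P4"),
                left_local=tuple(FeatureBundle(*(f"c{i}{k}" for k in range(4))) for i in range(5)),
                right_local=tuple(FeatureBundle(*(f"d{i}{k}" for k in range(4))) for i in range(5)),
            )
        ]
        assert np.all(gram_matrix(a, b) == 0.0)

    def test_empty_inputs(self):
        assert gram_matrix([], []).shape == (0, 0)

    def test_normalization_bound(self, clean_instances):
        """0 <= K(x,y) <= K(x,x) = 3 + 2 when all contexts are non-empty."""
        insts = [i for i in clean_instances if i.b][:20]
        K = gram_matrix(insts, insts)
        assert K.min() >= 0.0
        assert K.max() <= 5.0 + 1e-9
        for i in range(len(insts)):
            assert K[i, i] == pytest.approx(5.0)
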