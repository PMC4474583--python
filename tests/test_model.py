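"""Corpus splitting, SVM training/prediction and evaluation metrics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import distantadr as d
from distantadr.candidates import NEGATIVE, POSITIVE
from distantadr.model import EvalReport, profile_corpus, profile_percentages
from distantadr.text import EntityMention, Message

from tests.conftest import toy_instance


class TestSplitCorpus:
    def test_reference_sizes(self):
        ids = [f"m{i}" for i in range(84_090)]
        train, test = d.split_corpus(ids, train_fraction=0.75, seed=1)
        assert (len(train), len(test)) == (63_067, 21_023)

    def test_floor_rule_small(self):
        train, test = d.split_corpus(["a", "b", "c", "d"], train_fraction=0.75, seed=0)
        assert (len(train), len(test)) == (3, 1)

    def test_deterministic_per_seed(self):
        ids = [f"m{i}" for i in range(100)]
        assert d.split_corpus(ids, seed=5) == d.split_corpus(ids, seed=5)
        assert d.split_corpus(ids, seed=5) != d.split_corpus(ids, seed=6)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            d.split_corpus(["a", "a", "b"])

    @given(st.integers(2, 500), st.integers(0, 2**16))
    @settings(max_examples=60, derandomize=True)
    def test_exact_partition(self, n, seed):
        ids = [f"m{i}" for i in range(n)]
        train, test = d.split_corpus(ids, seed=seed)
        assert len(train) == int(np.floor(0.75 * n))
        assert sorted(train + test) == sorted(ids)
        assert not set(train) & set(test)


def separable_instances(n_pos=10, n_neg=10):
    """Positives contain the cue token 'provoca' in B; negatives never do."""
    out = []
    for i in range(n_pos):
        inst = toy_instance(
            [f"x{i}", "DRUGX", "me", "provoca", "mucho", "EFFECTY", f"y{i}"],
            (1, 2), (5, 6), msg_id=f"p{i}",
        )
        out.append(dataclasses.replace(inst, label=POSITIVE, label_source="DISTANT"))
    for i in range(n_neg):
        inst = toy_instance(
            [f"x{i}", "DRUGX", "hablamos", "sobre", "otro", "EFFECTY", f"y{i}"],
            (1, 2), (5, 6), msg_id=f"n{i}",
        )
        out.append(dataclasses.replace(inst, label=NEGATIVE, label_source="DISTANT"))
    return out


class TestTrainPredict:
    def test_separable_training_accuracy(self):
        insts = separable_instances()
        model = d.train(insts)
        labels, _ = d.predict(model, insts)
        assert labels == [i.label for i in insts]

    def test_training_determinism(self):
        insts = separable_instances()
        probe = separable_instances(3, 3)
        v1 = d.train(insts).decision_values(probe)
        v2 = d.train(list(insts)).decision_values(probe)
        assert np.array_equal(v1, v2)

    def test_upweighting_positive_class_is_monotone(self):
        insts = separable_instances(4, 16)
        probe = separable_instances(8, 8)
        base = d.predict(d.train(insts, class_weights=None), probe)[0]
        heavy = d.predict(
            d.train(insts, class_weights={POSITIVE: 2.0, NEGATIVE: 1.0}), probe
        )[0]
        assert heavy.count(POSITIVE) >= base.count(POSITIVE)

    def test_single_class_raises(self):
        insts = separable_instances(5, 0)
        with pytest.raises(ValueError, match="single class"):
            d.train(insts)

    def test_empty_prediction(self):
        model = d.train(separable_instances())
        labels, values = d.predict(model, [])
        assert labels == [] and values.shape == (0,)

    def test_config_mismatch_raises(self):
        model = d.train(separable_instances())
        bad = toy_instance(["a", "DRUGX", "b", "EFFECTY"], (1, 2), (3, 4))
        bad = dataclasses.replace(bad, left_local=bad.left_local[:3])
        with pytest.raises(ValueError, match="local_window"):
            d.predict(model, [bad])


class TestEvalReport:
    @pytest.mark.parametrize(
        "tp,fp,fn,p,r,f1",
        [
            (1_755, 1_926, 1_224, 0.48, 0.59, 0.53),
            (41, 27, 123, 0.60, 0.25, 0.35),
            (0, 0, 0, 0.0, 0.0, 0.0),
        ],
    )
    def test_metric_arithmetic(self, tp, fp, fn, p, r, f1):
        rep = EvalReport(tp=tp, fp=fp, fn=fn)
        assert round(rep.precision, 2) == p
        assert round(rep.recall, 2) == r
        assert round(rep.f1, 2) == f1

    @given(st.integers(0, 10_000), st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=300, derandomize=True)
    def test_metric_algebra(self, tp, fp, fn):
        rep = EvalReport(tp=tp, fp=fp, fn=fn)
        assert 0.0 <= rep.precision <= 1.0
        assert 0.0 <= rep.recall <= 1.0
        assert 0.0 <= rep.f1 <= min(2 * rep.precision, 2 * rep.recall) + 1e-12


class TestEvaluate:
    def _inst(self, iid, label):
        inst = toy_instance(["a", "DRUGX", "b", "EFFECTY"], (1, 2), (3, 4), msg_id=iid)
        return dataclasses.replace(inst, id=iid, label=label)

    def test_confusion_counts(self):
        ref = [self._inst("1", POSITIVE), self._inst("2", POSITIVE),
               self._inst("3", NEGATIVE), self._inst("4", NEGATIVE)]
        pred = [self._inst("1", POSITIVE), self._inst("2", NEGATIVE),
                self._inst("3", POSITIVE), self._inst("4", NEGATIVE)]
        rep = d.evaluate(pred, ref)
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 1)

    def test_id_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatched ids"):
            d.evaluate([self._inst("1", POSITIVE)], [self._inst("2", POSITIVE)])


class TestProfileCorpus:
    def _mention(self, msg_id, etype):
        return EntityMention(
            message_id=msg_id, entity_type=etype, token_start=0, token_end=1,
            char_start=0, char_end=1, canonical_id="x", surface="x",
        )

    def test_one_message_per_category(self):
        msgs = [Message(id=f"m{i}", text="t") for i in range(4)]
        mentions = {
            "m0": [],
            "m1": [self._mention("m1", "DRUG")],
            "m2": [self._mention("m2", "EFFECT")],
            "m3": [self._mention("m3", "DRUG"), self._mention("m3", "EFFECT")],
        }
        counts = profile_corpus(msgs, mentions)
        assert counts == {
            "no_drug_no_effect": 1, "drug_only": 1, "effect_only": 1, "both": 1,
        }

    def test_all_empty(self):
        msgs = [Message(id=f"m{i}", text="t") for i in range(5)]
        counts = profile_corpus(msgs, {m.id: [] for m in msgs})
        assert counts["no_drug_no_effect"] == 5
        assert profile_percentages(counts)["no_drug_no_effect"] == 100.0

    def test_matches_generator_bookkeeping(self, clean_corpus):
        """On a noise-free corpus the profile equals the generator's record."""
        from tests.conftest import corpus_instances

        msgs, mentions, _ = corpus_instances(clean_corpus, label=False)
        counts = profile_corpus(msgs, mentions)
        expected = {c: 0 for c in counts}
        for record in clean_corpus.bookkeeping.values():
            expected[record["category"]] += 1
        assert counts == expected
        assert sum(counts.values()) == len(msgs)
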