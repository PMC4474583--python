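"""Classifier training, prediction and evaluation on SL-kernel Gram matrices.

Training solves the soft-margin SVM dual on a precomputed Gram matrix
(scikit-learn's libsvm backend); the trained model keeps only its support
instances and dual coefficients so prediction is
``sum_i coef_i * K(s_i, x) + bias``. Distant labels are heavily skewed
toward NEGATIVE, so inverse-frequency ("balanced") class weighting is the
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .candidates import NEGATIVE, POSITIVE, PREDICTED, RelationInstance
from .kernel import KernelConfig, gram_matrix

_LABEL_TO_INT = {NEGATIVE: 0, POSITIVE: 1}


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts with derived precision / recall / F1.

    Metrics follow the usual conventions with 0 for empty denominators;
    values are kept at full precision and rounded only for display.
    """

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class TrainedModel:
    """Kernel SVM in dual form over its support relation instances."""

    support_instances: list[RelationInstance]
    dual_coefficients: np.ndarray
    bias: float
    cfg: KernelConfig
    regularization_c: float
    class_weights: Mapping[str, float] | str | None = "balanced"

    def decision_values(self, instances: Sequence[RelationInstance]) -> np.ndarray:
        if not instances:
            return np.zeros(0)
        _check_featurized(instances, self.cfg)
        K = gram_matrix(list(instances), self.support_instances, self.cfg)
        return K @ self.dual_coefficients + self.bias


def _check_featurized(instances: Sequence[RelationInstance], cfg: KernelConfig) -> None:
    expected = 2 * cfg.local_window + 1
    for inst in instances:
        if len(inst.left_local) != expected or len(inst.right_local) != expected:
            raise ValueError(
                f"instance {inst.id} was featurized with a different local_window "
                f"(expected contexts of length {expected})"
            )


def split_corpus(
    message_ids: Sequence[str], train_fraction: float = 0.75, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Shuffled exact partition: floor(train_fraction * N) ids for training.

    Deterministic per seed; duplicate ids are rejected.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    ids = list(message_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("message ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = math.floor(train_fraction * len(ids))
    shuffled = [ids[i] for i in order]
    return shuffled[:n_train], shuffled[n_train:]


def train(
    instances: Sequence[RelationInstance],
    cfg: KernelConfig | None = None,
    regularization_c: float = 1.0,
    class_weights: Mapping[str, float] | str | None = "balanced",
    seed: int = 0,
) -> TrainedModel:
    """Fit the soft-margin dual SVM on the precomputed SL Gram matrix.

    Requires at least one instance of each label. ``class_weights`` maps
    label names to positive weights, or "balanced" for inverse-frequency
    weighting.
    """
    cfg = cfg or KernelConfig()
    if regularization_c <= 0:
        raise ValueError(f"regularization_c must be positive, got {regularization_c}")
    instances = list(instances)
    _check_featurized(instances, cfg)
    y = np.array([_LABEL_TO_INT.get(inst.label, -1) for inst in instances])
    if np.any(y < 0):
        bad = next(i for i in instances if i.label not in _LABEL_TO_INT)
        raise ValueError(f"instance {bad.id} has label {bad.label!r}; train needs POSITIVE/NEGATIVE")
    if len(np.unique(y)) < 2:
        raise ValueError(
            "training set contains a single class; distant labels collapsed — "
            "adjust the knowledge base or the corpus generator so both related "
            "and unrelated pairs occur"
        )
    if isinstance(class_weights, Mapping):
        cw: Mapping[int, float] | str | None = {
            _LABEL_TO_INT[k]: v for k, v in class_weights.items()
        }
    else:
        cw = class_weights
    K = gram_matrix(instances, instances, cfg)
    svc = SVC(kernel="precomputed", C=regularization_c, class_weight=cw, random_state=seed)
    svc.fit(K, y)
    support = [instances[i] for i in svc.support_]
    return TrainedModel(
        support_instances=support,
        dual_coefficients=np.asarray(svc.dual_coef_).ravel().copy(),
        bias=float(svc.intercept_[0]),
        cfg=cfg,
        regularization_c=regularization_c,
        class_weights=class_weights,
    )


def predict(
    model: TrainedModel, instances: Sequence[RelationInstance]
) -> tuple[list[str], np.ndarray]:
    """Label POSITIVE iff the decision value is strictly > 0.

    Returns both labels and raw decision values; empty input yields empty
    output.
    """
    values = model.decision_values(instances)
    labels = [POSITIVE if v > 0 else NEGATIVE for v in values]
    return labels, values


def label_predictions(
    model: TrainedModel, instances: Sequence[RelationInstance]
) -> list[RelationInstance]:
    """Convenience: return copies of ``instances`` carrying predicted labels."""
    from dataclasses import replace

    labels, _ = predict(model, instances)
    return [
        replace(inst, label=lab, label_source=PREDICTED)
        for inst, lab in zip(instances, labels)
    ]


def evaluate(
    predicted: Sequence[RelationInstance], reference: Sequence[RelationInstance]
) -> EvalReport:
    """Instance-level confusion counts of predicted vs reference labels.

    Instances align 1:1 by id; missing or extra ids are an error.
    """
    pred_by_id = {inst.id: inst for inst in predicted}
    ref_by_id = {inst.id: inst for inst in reference}
    missing = sorted(set(ref_by_id) ^ set(pred_by_id))
    if missing:
        raise ValueError(f"predicted/reference instance ids do not align; mismatched ids: {missing[:10]}")
    tp = fp = fn = 0
    for iid, ref in ref_by_id.items():
        pred = pred_by_id[iid]
        if pred.label == POSITIVE and ref.label == POSITIVE:
            tp += 1
        elif pred.label == POSITIVE and ref.label != POSITIVE:
            fp += 1
        elif pred.label != POSITIVE and ref.label == POSITIVE:
            fn += 1
    return EvalReport(tp=tp, fp=fp, fn=fn)


CATEGORIES = ("no_drug_no_effect", "drug_only", "effect_only", "both")


def profile_corpus(
    messages: Sequence, mentions_by_message: Mapping[str, Sequence]
) -> dict[str, int]:
    """Categorize messages by which entity types they mention.

    Every message falls in exactly one of: no_drug_no_effect, drug_only,
    effect_only, both; counts sum to the number of messages.
    """
    counts = {c: 0 for c in CATEGORIES}
    for msg in messages:
        mentions = mentions_by_message.get(msg.id, ())
        has_drug = any(m.entity_type == "DRUG" for m in mentions)
        has_effect = any(m.entity_type == "EFFECT" for m in mentions)
        if has_drug and has_effect:
            counts["both"] += 1
        elif has_drug:
            counts["drug_only"] += 1
        elif has_effect:
            counts["effect_only"] += 1
        else:
            counts["no_drug_no_effect"] += 1
    return counts


def profile_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Category percentages at one-decimal reporting precision."""
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in counts}
    return {c: round(100.0 * v / total, 1) for c, v in counts.items()}
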