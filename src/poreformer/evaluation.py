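"""Evaluation harness: stratified 80:20 splits, ROC/AUC, holdout detection.

The protocol mirrors standard practice for binary sequence classifiers:
repeated randomized 80:20 train/test splits (stratified by label),
per-epoch accuracy/loss histories, per-class ROC curves (alpha vs
negatives, beta vs negatives, negatives as detection target on inverted
scores, and their macro average on a fixed FPR grid), plus a held-out
family experiment: how many members of a family absent from training are
called pore formers at the decision threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import train_test_split

from .encoding import EncodingConfig, encode_batch, stack_tensors
from .io import Label, SequenceRecord
from .model import (
    ModelConfig,
    TrainedClassifier,
    TrainingHistory,
    build_model,
    train,
)

FPR_GRID = np.linspace(0.0, 1.0, 101)  # macro-average grid


@dataclass
class SplitSpec:
    train_fraction: float = 0.80
    seed: int = 0
    n_trials: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    class_label: str


@dataclass
class EvalReport:
    histories: list[TrainingHistory] = field(default_factory=list)
    roc_curves: list[dict[str, ROCCurve]] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    holdout_detection: dict[str, tuple[int, int]] = field(default_factory=dict)
    holdout_scores: dict[str, list[float]] = field(default_factory=dict)

    def summary(self) -> dict:
        out: dict = {
            "n_trials": len(self.histories),
            "test_accuracy_mean": float(np.mean(self.test_accuracy)),
            "test_accuracy_std": float(np.std(self.test_accuracy)),
            "auc": {},
            "holdout": {
                fam: {"detected": d, "total": t}
                for fam, (d, t) in self.holdout_detection.items()
            },
        }
        if self.roc_curves:
            for label in self.roc_curves[0]:
                vals = [c[label].auc for c in self.roc_curves if label in c]
                out["auc"][label] = {"mean": float(np.mean(vals)),
                                     "std": float(np.std(vals))}
        return out

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def split_dataset(
    records: Sequence[SequenceRecord],
    spec: SplitSpec,
    trial: int = 0,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """One stratified train/test partition, reproducible per (seed, trial).

    |train| = round(train_fraction * n); stratification is by label so both
    classes appear on each side.
    """
    records = list(records)
    labels = [r.label.value for r in records]
    if len(set(labels)) < 2 or min(labels.count(l) for l in set(labels)) < 2:
        raise ValueError("need at least 2 records of each class to split")
    n_train = int(round(spec.train_fraction * len(records)))
    try:
        train_recs, test_recs = train_test_split(
            records,
            train_size=n_train,
            random_state=(spec.seed + trial) % (2**31),
            stratify=labels,
        )
    except ValueError as exc:
        raise ValueError(
            f"stratified split failed ({exc}); use a larger dataset"
        ) from exc
    for side, part in (("train", train_recs), ("test", test_recs)):
        if len({r.label for r in part}) < 2:
            raise ValueError(
                f"a class is absent from the {side} side; use a larger dataset"
            )
    return list(train_recs), list(test_recs)


def compute_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    class_label: str = "positive",
) -> ROCCurve:
    """ROC from sweeping all distinct score thresholds; AUC by trapezoid.

    Equal scores collapse into a single threshold step, which makes the AUC
    identical to the tie-corrected Mann-Whitney pair statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both a positive and a negative label")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc, class_label=class_label)


def _macro_average(curves: Sequence[ROCCurve]) -> ROCCurve:
    tprs = [np.interp(FPR_GRID, c.fpr, c.tpr) for c in curves]
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return ROCCurve(FPR_GRID.copy(), mean_tpr,
                    float(np.trapezoid(mean_tpr, FPR_GRID)), "average")


def per_class_roc_from_scores(
    scores: np.ndarray,
    records: Sequence[SequenceRecord],
) -> dict[str, ROCCurve]:
    """Per-class ROC set from already-computed scores (aligned to records).

    alpha / beta (and any other positive family tag): that family's
    positives vs all negatives. "negative": negatives as the detection
    target, scored with 1 - score against all positives. "average": macro
    mean TPR over the fixed FPR grid.
    """
    scores = np.asarray(scores, dtype=float)
    is_neg = np.array([r.label == Label.NEGATIVE for r in records])
    families = sorted({r.family for r in records
                       if r.label == Label.POSITIVE and r.family})
    curves: dict[str, ROCCurve] = {}
    for fam in families:
        in_fam = np.array([r.family == fam and r.label == Label.POSITIVE
                           for r in records])
        mask = in_fam | is_neg
        if in_fam.sum() == 0 or is_neg.sum() == 0:
            warnings.warn(f"class {fam!r} or negatives missing; curve omitted")
            continue
        curves[fam] = compute_roc(scores[mask], in_fam[mask].astype(int), fam)
    is_pos = np.array([r.label == Label.POSITIVE for r in records])
    if is_neg.any() and is_pos.any():
        curves["negative"] = compute_roc(1.0 - scores, is_neg.astype(int), "negative")
    else:
        warnings.warn("positives or negatives missing; negative curve omitted")
    if curves:
        curves["average"] = _macro_average(list(curves.values()))
    return curves


def per_class_roc(
    classifier: TrainedClassifier,
    records: Sequence[SequenceRecord],
    encoding: EncodingConfig,
) -> dict[str, ROCCurve]:
    """Encode and score *records*, then build the per-class ROC set."""
    tensors, _ = encode_batch(records, encoding)
    scores = classifier.predict(stack_tensors(tensors))
    return per_class_roc_from_scores(scores, records)


def holdout_family_eval(
    classifier: TrainedClassifier,
    holdout: Sequence[SequenceRecord],
    training: Sequence[SequenceRecord],
    encoding: EncodingConfig,
    threshold: float = 0.5,
) -> tuple[int, int, np.ndarray]:
    """Score a family never seen in training; count calls at *threshold*.

    Refuses to run if any holdout id also appears in the training set (a
    protocol violation that would inflate the generalization claim).
    """
    overlap = {r.id for r in holdout} & {r.id for r in training}
    if overlap:
        raise ValueError(
            f"holdout/training overlap detected (protocol violation): "
            f"{sorted(overlap)[:5]}"
        )
    tensors, _ = encode_batch(holdout, encoding)
    scores = classifier.predict(stack_tensors(tensors))
    detected = int(np.sum(scores >= threshold))
    return detected, len(holdout), scores


def run_benchmark(
    records: Sequence[SequenceRecord],
    holdout_families: dict[str, Sequence[SequenceRecord]],
    model_config: ModelConfig,
    split_spec: SplitSpec,
    encoding: EncodingConfig,
    threshold: float = 0.5,
) -> EvalReport:
    """Full protocol: per trial, split/train/evaluate; then score holdouts.

    Holdout detection uses the final trial's classifier; per-trial
    accuracies and ROC sets are all retained for aggregation.
    """
    report = EvalReport()
    classifier: Optional[TrainedClassifier] = None
    last_train: list[SequenceRecord] = []
    for trial in range(split_spec.n_trials):
        try:
            train_recs, test_recs = split_dataset(records, split_spec, trial)
            train_t, train_y = encode_batch(train_recs, encoding)
            test_t, test_y = encode_batch(test_recs, encoding)
            x_train, x_test = stack_tensors(train_t), stack_tensors(test_t)
            trial_config = ModelConfig(**{**model_config.__dict__,
                                          "seed": model_config.seed + trial})
            classifier = build_model(trial_config, x_train.shape[1:],
                                     scheme=encoding.scheme)
            classifier, history = train(classifier, x_train, train_y,
                                        x_test, test_y, trial_config)
            scores = classifier.predict(x_test)
            report.histories.append(history)
            report.test_accuracy.append(
                float(np.mean((scores >= threshold) == (test_y == 1))))
            report.roc_curves.append(per_class_roc_from_scores(scores, test_recs))
            last_train = train_recs
        except Exception as exc:
            raise RuntimeError(f"benchmark trial {trial} failed: {exc}") from exc
    assert classifier is not None
    for name, fam_records in holdout_families.items():
        detected, total, scores = holdout_family_eval(
            classifier, fam_records, last_train, encoding, threshold)
        report.holdout_detection[name] = (detected, total)
        report.holdout_scores[name] = [float(s) for s in scores]
    return report
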