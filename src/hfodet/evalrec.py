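"""Cross-validated evaluation: detection metrics and per-patient top-N precision.

Two protocols are implemented. *Detection* pools all patients' segments and
uses stratified 10-fold cross-validation (90/10 train/test); confusion counts
are pooled over folds before computing accuracy, recall, precision and
F-score (micro-averaging; per-fold metrics are also reported). *Recommendation*
holds complete patients out (18 train / 2 test per fold with the default
cohort), ranks each held-out patient's segments by predicted HFO probability,
and scores P@N = TP@N / N for N in {1, 3, 5}, averaged over patients within a
fold and then over folds (the patient-first grand mean is reported as well).

Segment-level stratification deliberately allows the same patient on both
sides of a detection split (that is how the pooled protocol is defined);
``mode="patient_holdout"`` gives the strict alternative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from hfodet.core import HFO, ConfigError, LabeledSegment
from hfodet.attnmodel import DetectionResult, ModelSpec, build_model, predict, train

P_AT_N_VALUES = (1, 3, 5)
DECISION_THRESHOLD = 0.5


@dataclass
class FoldSplit:
    fold_id: int
    train_ids: list[str]
    test_ids: list[str]
    mode: str  # "segment_stratified" | "patient_holdout"


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ConfigError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )


@dataclass
class Metrics:
    """Accuracy, recall, precision, F-score; undefined ratios are None, not 0."""

    accuracy: float
    recall: float | None
    precision: float | None
    f_score: float | None


@dataclass
class EvaluationReport:
    mode: str
    fold_counts: list[ConfusionCounts] = field(default_factory=list)
    pooled: ConfusionCounts | None = None
    metrics: Metrics | None = None
    per_fold_metrics: list[Metrics] = field(default_factory=list)
    p_at_n: dict[int, float] = field(default_factory=dict)  # mean over patients, then folds
    p_at_n_patient_mean: dict[int, float] = field(default_factory=dict)  # grand mean over patients
    n_segments: int = 0
    n_folds: int = 0

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (ConfusionCounts, Metrics)):
                return vars(o)
            raise TypeError(type(o))

        return json.dumps(vars(self), default=enc, indent=2)

    def per_fold_frame(self) -> pd.DataFrame:
        rows = []
        for i, (c, m) in enumerate(zip(self.fold_counts, self.per_fold_metrics)):
            rows.append(
                {
                    "fold": i,
                    "TP": c.TP,
                    "FP": c.FP,
                    "TN": c.TN,
                    "FN": c.FN,
                    "accuracy": m.accuracy,
                    "recall": m.recall,
                    "precision": m.precision,
                    "f_score": m.f_score,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


def _segment_ids(dataset: list[LabeledSegment]) -> list[str]:
    ids = [s.segment_id or f"idx{i:06d}" for i, s in enumerate(dataset)]
    if len(set(ids)) != len(ids):
        raise ConfigError("segment ids must be unique")
    return ids


def make_folds(
    dataset: list[LabeledSegment],
    mode: str = "segment_stratified",
    n_folds: int = 10,
    seed: int = 0,
) -> list[FoldSplit]:
    """Deterministic cross-validation splits.

    ``segment_stratified``: class proportions preserved within +-1 segment per
    fold. ``patient_holdout``: patients are shuffled once and partitioned
    across folds (exactly 2 test patients per fold when the cohort has
    2 x n_folds patients); no patient appears on both sides of a fold.
    """
    if not dataset:
        raise ConfigError("dataset is empty")
    if n_folds < 2:
        raise ConfigError("need at least two folds")
    ids = np.array(_segment_ids(dataset))
    if mode == "segment_stratified":
        y = np.array([s.y for s in dataset])
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return [
            FoldSplit(i, ids[tr].tolist(), ids[te].tolist(), mode)
            for i, (tr, te) in enumerate(skf.split(np.zeros(len(dataset)), y))
        ]
    if mode == "patient_holdout":
        patients = sorted({s.patient_id for s in dataset})
        if len(patients) < n_folds:
            raise ConfigError(
                f"patient_holdout needs at least {n_folds} patients, got {len(patients)}"
            )
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(patients))
        groups = np.array_split(np.array(patients, dtype=object)[order], n_folds)
        by_patient = np.array([s.patient_id for s in dataset])
        folds = []
        for i, grp in enumerate(groups):
            test_mask = np.isin(by_patient, list(grp))
            folds.append(FoldSplit(i, ids[~test_mask].tolist(), ids[test_mask].tolist(), mode))
        return folds
    raise ConfigError(f"unknown fold mode {mode!r}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def confusion(labels, predictions) -> ConfusionCounts:
    """2x2 confusion counts from binary labels and binary predictions."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ConfigError(f"labels length {y.size} != predictions length {p.size}")
    if y.size and (not set(np.unique(y)) <= {0, 1} or not set(np.unique(p)) <= {0, 1}):
        raise ConfigError("labels and predictions must be binary")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        FP=int(np.sum((y == 0) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def detection_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, recall, precision and F-score from confusion counts.

    Ratios with zero denominators (e.g. precision with no positive
    predictions) come back as None rather than a silent 0.
    """
    if c.total == 0:
        raise ConfigError("cannot compute metrics from all-zero counts")
    accuracy = (c.TP + c.TN) / c.total
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    f = f_score(precision, recall) if (precision is not None and recall is not None) else None
    return Metrics(accuracy=accuracy, recall=recall, precision=precision, f_score=f)


def rank_segments(results: list[DetectionResult]) -> list[DetectionResult]:
    """Descending by probability; ties broken by ascending segment id (stable)."""
    return sorted(results, key=lambda r: (-r.probability, r.segment_id))


def precision_at_n(ranked_labels, n: int) -> float:
    """Fraction of true HFOs among the top n of a ranking."""
    labels = list(ranked_labels)
    if n < 1:
        raise ConfigError("N must be >= 1")
    if len(labels) < n:
        raise ConfigError(f"ranking has {len(labels)} entries, fewer than N={n}")
    return float(sum(int(v) for v in labels[:n]) / n)


# ---------------------------------------------------------------------------
# End-to-end evaluation
# ---------------------------------------------------------------------------


def default_classifier(spec: ModelSpec):
    """Train-and-predict closure over the attention detector (pluggable)."""

    def fit_predict(train_segments, test_segments, seed):
        fold_spec = ModelSpec(**{**vars(spec), "seed": seed})
        model = train(build_model(fold_spec), train_segments)
        return np.array([r.probability for r in predict(model, test_segments)])

    return fit_predict


def evaluate(
    dataset: list[LabeledSegment],
    spec: ModelSpec,
    task: str = "detection",
    seed: int = 0,
    n_folds: int = 10,
    classifier=None,
) -> EvaluationReport:
    """Cross-validated detection or per-patient recommendation evaluation.

    ``classifier`` may override the model: a callable
    ``(train_segments, test_segments, seed) -> probabilities`` (used for the
    delegated RF/SVM baselines); by default the spec's network is trained
    per fold with a fold-derived seed.
    """
    if task not in ("detection", "recommendation"):
        raise ConfigError(f"unknown task {task!r}")
    fit_predict = classifier or default_classifier(spec)
    ids = _segment_ids(dataset)
    by_id = dict(zip(ids, dataset))
    mode = "segment_stratified" if task == "detection" else "patient_holdout"
    if task == "recommendation" and len({s.patient_id for s in dataset}) < 2:
        raise ConfigError("recommendation needs at least two patients")
    folds = make_folds(dataset, mode=mode, n_folds=n_folds, seed=seed)

    report = EvaluationReport(mode=mode, n_segments=len(dataset), n_folds=len(folds))
    patient_p: dict[int, list[float]] = {n: [] for n in P_AT_N_VALUES}
    fold_p: dict[int, list[float]] = {n: [] for n in P_AT_N_VALUES}

    for fold in folds:
        train_segs = [by_id[i] for i in fold.train_ids]
        test_segs = [by_id[i] for i in fold.test_ids]
        assert not (set(fold.train_ids) & set(fold.test_ids))
        if mode == "patient_holdout":
            leak = {s.patient_id for s in train_segs} & {s.patient_id for s in test_segs}
            assert not leak, f"patient leakage across fold {fold.fold_id}: {leak}"
        fold_seed = (seed * 1000 + fold.fold_id) % (2**31 - 1)
        probs = np.asarray(fit_predict(train_segs, test_segs, fold_seed), dtype=float)
        if probs.shape != (len(test_segs),):
            raise ConfigError("classifier returned wrong number of probabilities")

        if task == "detection":
            y = [s.y for s in test_segs]
            c = confusion(y, (probs >= DECISION_THRESHOLD).astype(int))
            report.fold_counts.append(c)
            report.per_fold_metrics.append(detection_metrics(c))
        else:
            results = [
                DetectionResult(
                    segment_id=s.segment_id,
                    patient_id=s.patient_id,
                    channel_id=s.channel_id,
                    start_s=s.start_s,
                    probability=float(p),
                    label=s.label,
                )
                for s, p in zip(test_segs, probs)
            ]
            per_patient: dict[str, list[DetectionResult]] = {}
            for r in results:
                per_patient.setdefault(r.patient_id, []).append(r)
            fold_vals: dict[int, list[float]] = {n: [] for n in P_AT_N_VALUES}
            for patient, rs in sorted(per_patient.items()):
                ranked = rank_segments(rs)
                labels = [1 if r.label == HFO else 0 for r in ranked]
                for n in P_AT_N_VALUES:
                    if len(labels) >= n:
                        v = precision_at_n(labels, n)
                        fold_vals[n].append(v)
                        patient_p[n].append(v)
            for n in P_AT_N_VALUES:
                if fold_vals[n]:
                    fold_p[n].append(float(np.mean(fold_vals[n])))

    if task == "detection":
        report.pooled = sum(report.fold_counts, ConfusionCounts())
        report.metrics = detection_metrics(report.pooled)
    else:
        report.p_at_n = {n: float(np.mean(v)) for n, v in fold_p.items() if v}
        report.p_at_n_patient_mean = {n: float(np.mean(v)) for n, v in patient_p.items() if v}
    return report
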