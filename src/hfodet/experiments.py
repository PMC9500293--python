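"""Experiment runner: baseline comparison, head-count sweep, and ablation.

Each experiment evaluates one or more detector configurations on a simulated
gold-standard set with both protocols (stratified detection folds and
patient-holdout recommendation folds) and returns one tidy DataFrame row per
configuration: accuracy / recall / precision / F-score and P@{1,3,5}.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import pandas as pd

from hfodet.attnmodel import ABLATION_VARIANTS, ModelSpec
from hfodet.baselines import BASELINE_FACTORIES
from hfodet.core import LabeledSegment
from hfodet.evalrec import evaluate

logger = logging.getLogger("hfodet.experiments")

HEAD_SWEEP = (2, 4, 8, 16)
EXPERIMENTS = ("baselines", "head_sweep", "ablation")


def _evaluate_both(
    dataset: list[LabeledSegment],
    spec: ModelSpec,
    seed: int,
    n_folds: int,
    classifier=None,
) -> dict:
    det = evaluate(dataset, spec, task="detection", seed=seed, n_folds=n_folds, classifier=classifier)
    rec = evaluate(dataset, spec, task="recommendation", seed=seed, n_folds=n_folds, classifier=classifier)
    return {
        "accuracy": det.metrics.accuracy,
        "recall": det.metrics.recall,
        "precision": det.metrics.precision,
        "f_score": det.metrics.f_score,
        "p_at_1": rec.p_at_n.get(1),
        "p_at_3": rec.p_at_n.get(3),
        "p_at_5": rec.p_at_n.get(5),
    }


def run_baselines(
    dataset: list[LabeledSegment],
    spec: ModelSpec,
    seed: int = 0,
    n_folds: int = 10,
    include_delegated: bool = True,
) -> pd.DataFrame:
    """Compare RF / SVM / the plain DNN (smo) / the attention detector."""
    rows = []
    if include_delegated:
        for name, factory in BASELINE_FACTORIES.items():
            logger.info("baseline %s", name)
            rows.append({"method": name, **_evaluate_both(dataset, spec, seed, n_folds, factory(spec))})
    for variant in ("smo", "msadr"):
        logger.info("baseline %s", variant)
        vspec = replace(spec, variant=variant)
        rows.append({"method": variant, **_evaluate_both(dataset, vspec, seed, n_folds)})
    return pd.DataFrame(rows)


def run_head_sweep(
    dataset: list[LabeledSegment],
    spec: ModelSpec,
    seed: int = 0,
    n_folds: int = 10,
    heads: tuple[int, ...] = HEAD_SWEEP,
) -> pd.DataFrame:
    """The attention detector at k in {2, 4, 8, 16} heads."""
    rows = []
    for k in heads:
        logger.info("head sweep k=%d", k)
        vspec = replace(spec, variant="msadr", heads=k)
        rows.append({"heads": k, **_evaluate_both(dataset, vspec, seed, n_folds)})
    return pd.DataFrame(rows)


def run_ablation(
    dataset: list[LabeledSegment],
    spec: ModelSpec,
    seed: int = 0,
    n_folds: int = 10,
) -> pd.DataFrame:
    """raw (no attention) / attn_1 (multi-head only) / attn_2 (single only) / both."""
    rows = []
    for variant in ABLATION_VARIANTS:
        logger.info("ablation %s", variant)
        vspec = replace(spec, variant=variant)
        rows.append({"variant": variant, **_evaluate_both(dataset, vspec, seed, n_folds)})
    return pd.DataFrame(rows)


def run_experiment(
    name: str,
    dataset: list[LabeledSegment],
    spec: ModelSpec,
    seed: int = 0,
    n_folds: int = 10,
) -> pd.DataFrame:
    if name == "baselines":
        return run_baselines(dataset, spec, seed=seed, n_folds=n_folds)
    if name == "head_sweep":
        return run_head_sweep(dataset, spec, seed=seed, n_folds=n_folds)
    if name == "ablation":
        return run_ablation(dataset, spec, seed=seed, n_folds=n_folds)
    raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
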