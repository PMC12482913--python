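"""Discrimination and calibration metrics with bootstrap uncertainty.

AUC uses the Mann-Whitney formulation (ties count one half; delegated to
scikit-learn's tie-corrected implementation), confidence intervals come
from a seeded subject-level percentile bootstrap, calibration curves
compare predicted probabilities with observed event frequencies on
equal-width bins, and the Brier score is the mean squared probability
error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class MetricReport:
    metric: str
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    replicates: int
    seed: int
    n_redrawn: int = 0  # degenerate resamples (one class) that were redrawn

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must contain the point estimate")


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    return scores, labels


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; requires both classes present."""
    scores, labels = _check(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def brier(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Mean squared error of predicted probabilities against 0/1 outcomes."""
    probs, labels = _check(probs, labels)
    if len(probs) == 0:
        raise ValueError("empty input")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((probs - labels) ** 2))


def calibration_curve(
    probs: Sequence[float], labels: Sequence[int], n_bins: int = 10
) -> pd.DataFrame:
    """Per-bin (mean predicted, observed frequency, count) on equal-width bins.

    Empty bins are omitted.  Well-calibrated predictions put the observed
    frequency within binomial noise of the mean prediction in every bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    probs, labels = _check(probs, labels)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    bins = np.clip((probs * n_bins).astype(int), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = bins == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin": b,
                "mean_predicted": float(probs[mask].mean()),
                "observed_frequency": float(labels[mask].mean()),
                "count": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    scores: Sequence[float],
    labels: Sequence[int],
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MetricReport:
    """Percentile bootstrap CI with subject-level resampling.

    Resamples on which the metric is undefined (e.g. a single class for
    AUC) are redrawn and the redraw count logged; more than 50% undefined
    resamples raises.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    scores, labels = _check(scores, labels)
    n = len(scores)
    point = metric(scores, labels)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB007)))
    values = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        for _attempt in range(200):
            idx = rng.integers(0, n, size=n)
            try:
                values[b] = metric(scores[idx], labels[idx])
                break
            except ValueError:
                n_redrawn += 1
        else:
            raise ValueError("metric undefined on most resamples")
    if n_redrawn > B // 2:
        raise ValueError("metric undefined on more than half of the resamples")
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    name = getattr(metric, "__name__", "metric")
    return MetricReport(
        metric=name,
        estimate=float(point),
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        n=n,
        replicates=B,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def subgroup_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    groups: Sequence[str],
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC with bootstrap CI per subgroup (plus 'overall'); thin reporting helper."""
    scores, labels = _check(scores, labels)
    groups = np.asarray(groups)
    rows = []
    for g in ["overall", *sorted(set(groups))]:
        mask = np.ones(len(scores), bool) if g == "overall" else groups == g
        if len(np.unique(labels[mask])) < 2:
            continue
        rep = bootstrap_ci(auc, scores[mask], labels[mask], B=B, seed=seed)
        rows.append(
            {"group": g, "auc": rep.estimate, "ci_low": rep.ci_low,
             "ci_high": rep.ci_high, "n": rep.n}
        )
    return pd.DataFrame(rows)
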