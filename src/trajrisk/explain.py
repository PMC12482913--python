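"""Token-resolved risk trajectories and per-token risk attribution.

Monte-Carlo estimation can be started not only from the most recent token
but from any prefix of the patient's history.  Re-running the estimator
at successive context truncations turns the risk estimate into a time
series over token positions, showing how each clinical event moved the
risk; ranking positions by the signed change in the estimate identifies
the tokens that drove it.

Because every position reuses the same per-trajectory seed streams, the
final-position estimate is bit-identical to a standalone estimate on the
full context, and recomputation with the same seed reproduces the whole
trajectory exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mc_inference import (
    MCProbabilityEstimate,
    StopSpec,
    estimate_probability,
)
from .sequence_model import NextTokenModel
from .tokenizer import PatientHealthTimeline, Vocabulary, decode_token


@dataclass
class RiskTrajectory:
    """Per-position risk estimates for one subject and task."""

    subject_id: str
    task: str
    positions: np.ndarray  # strictly increasing token indices
    estimates: list[MCProbabilityEstimate]
    token_labels: list[str]

    @property
    def p_hat(self) -> np.ndarray:
        return np.array([e.p_hat for e in self.estimates])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "task": self.task,
                "position": self.positions,
                "token": self.token_labels,
                "N": [e.n for e in self.estimates],
                "M": [e.m for e in self.estimates],
                "p_hat": self.p_hat,
                "ci_low": [e.ci_low for e in self.estimates],
                "ci_high": [e.ci_high for e in self.estimates],
                "risk_level": [e.risk_level for e in self.estimates],
            }
        )


def default_positions(n_tokens: int, window: int = 256, stride: int = 1) -> np.ndarray:
    """Every stride-th token within the final ``window`` tokens."""
    start = max(1, n_tokens - window)
    pos = np.arange(start, n_tokens, stride, dtype=np.int64)
    if len(pos) == 0 or pos[-1] != n_tokens - 1:
        pos = np.append(pos, n_tokens - 1)
    return pos


def risk_trajectory(
    model: NextTokenModel,
    timeline: PatientHealthTimeline,
    tasks: Mapping[str, StopSpec],
    positions: Sequence[int],
    n_sims: int = 100,
    seed: int = 0,
    token_minutes: np.ndarray | None = None,
    vocabulary: Vocabulary | None = None,
) -> dict[str, RiskTrajectory]:
    """Risk time series: the estimate at position j uses tokens [0, j].

    All positions share the per-trajectory seed streams, so the estimate at
    the last position equals ``estimate_probability`` on the full context
    with the same seed, exactly.
    """
    positions = np.asarray(sorted(set(int(p) for p in positions)), dtype=np.int64)
    if len(positions) == 0:
        raise ValueError("empty position set")
    if positions[0] < 0 or positions[-1] >= len(timeline.tokens):
        raise ValueError("positions outside the timeline")

    per_task: dict[str, list[MCProbabilityEstimate]] = {name: [] for name in tasks}
    for pos in positions:
        context = timeline.tokens[: pos + 1]
        for name, spec in tasks.items():
            est, _ = estimate_probability(
                model, context, spec, n_sims=n_sims, seed=seed,
                token_minutes=token_minutes,
            )
            per_task[name].append(est[name] if name in est else next(iter(est.values())))

    labels = [
        decode_token(vocabulary.token(int(timeline.tokens[p]))) if vocabulary else str(int(timeline.tokens[p]))
        for p in positions
    ]
    return {
        name: RiskTrajectory(
            subject_id=timeline.subject_id,
            task=name,
            positions=positions.copy(),
            estimates=ests,
            token_labels=list(labels),
        )
        for name, ests in per_task.items()
    }


@dataclass(frozen=True)
class Contributor:
    position: int
    delta: float  # p_hat(j) - p_hat(j-1)
    token_label: str
    significant: bool  # consecutive 95% CIs disjoint


def top_contributors(trajectory: RiskTrajectory, k: int) -> list[Contributor]:
    """Top-k positions by absolute risk change; ties go to the later position.

    A change is flagged significant only when the consecutive Clopper-
    Pearson intervals are disjoint, so Monte-Carlo noise on a flat
    trajectory rarely produces highlighted tokens.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(trajectory.positions) < 2:
        raise ValueError("trajectory needs at least 2 positions")
    items = []
    keys = []
    for j in range(1, len(trajectory.positions)):
        prev, cur = trajectory.estimates[j - 1], trajectory.estimates[j]
        # exact rational delta (M/N counts) so equal steps tie exactly
        delta = Fraction(cur.m, cur.n) - Fraction(prev.m, prev.n)
        disjoint = cur.ci_low > prev.ci_high or cur.ci_high < prev.ci_low
        items.append(
            Contributor(
                position=int(trajectory.positions[j]),
                delta=float(delta),
                token_label=trajectory.token_labels[j],
                significant=bool(disjoint),
            )
        )
        keys.append((abs(delta), int(trajectory.positions[j])))
    order = sorted(range(len(items)), key=lambda i: keys[i], reverse=True)
    return [items[i] for i in order[:k]]


def plot_risk_bands(trajectories: Mapping[str, RiskTrajectory], path=None):
    """Risk trajectories with CI bands and the 5-level color scale underneath."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    level_colors = ["#2c7bb6", "#abd9e9", "#ffffbf", "#fdae61", "#d7191c"]
    fig, (ax, axband) = plt.subplots(
        2, 1, figsize=(10, 5), sharex=True, height_ratios=[4, 1]
    )
    for name, tr in trajectories.items():
        p = tr.p_hat
        lo = np.array([e.ci_low for e in tr.estimates])
        hi = np.array([e.ci_high for e in tr.estimates])
        ax.plot(tr.positions, p, label=name)
        ax.fill_between(tr.positions, lo, hi, alpha=0.2)
    ax.set_ylabel("estimated probability")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)

    first = next(iter(trajectories.values()))
    levels = np.array([e.risk_level for e in first.estimates])
    for j in range(len(first.positions) - 1):
        axband.axvspan(
            first.positions[j], first.positions[j + 1],
            color=level_colors[levels[j] - 1],
        )
    axband.set_yticks([])
    axband.set_xlabel("token position")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
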