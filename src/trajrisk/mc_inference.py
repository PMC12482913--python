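"""Monte-Carlo risk estimation from simulated future timelines.

Given a patient's tokenized context, a next-token model is sampled N times
to produce future patient health timelines (fPHTs).  If M of the N
trajectories contain a tracked event, the event probability estimate is
M/N, with a 95% Clopper-Pearson interval from the Binomial(N, p) model of
the positive count, and an ordinal risk level on the five 0.2-wide
probability bands.  Competing risks are handled implicitly: all tracked
events share the same trajectories, so a sampled death terminates the
course and removes any later ICU admission or prolonged stay from that
trajectory.

Simulated clocks advance by the representative duration of each generated
interval token; horizons and length-of-stay thresholds are evaluated
against that clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_model import NextTokenModel, _sample_from
from .tokenizer import (
    Vocabulary,
    interval_representative_minutes,
    token_class,
)

DEFAULT_N_SIMS = 100  # default trajectory count per estimate
DEFAULT_MAX_TOKENS = 2048

RISK_EDGES = (0.2, 0.4, 0.6, 0.8)  # five ordinal levels


def risk_level(p_hat: float) -> int:
    """Ordinal risk category 1..5: [0,.2) -> 1, [.2,.4) -> 2, ..., [.8,1] -> 5."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"probability {p_hat} outside [0, 1]")
    return min(int(np.searchsorted(RISK_EDGES, p_hat, side="right")) + 1, 5)


def clopper_pearson(m: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial 95% CI; valid at the m = 0 and m = n boundaries."""
    if not 0 <= m <= n or n < 1:
        raise ValueError("require 0 <= m <= n, n >= 1")
    lo = 0.0 if m == 0 else float(stats.beta.ppf(alpha / 2, m, n - m + 1))
    hi = 1.0 if m == n else float(stats.beta.ppf(1 - alpha / 2, m + 1, n - m))
    return lo, hi


@dataclass(frozen=True)
class MCProbabilityEstimate:
    """Monte-Carlo estimate of one event probability from N trajectories."""

    n: int
    m: int
    p_hat: float
    ci_low: float
    ci_high: float
    risk_level: int
    n_censored: int = 0

    @classmethod
    def from_counts(cls, m: int, n: int, n_censored: int = 0) -> "MCProbabilityEstimate":
        lo, hi = clopper_pearson(m, n)
        p = m / n
        return cls(n=n, m=m, p_hat=p, ci_low=lo, ci_high=hi,
                   risk_level=risk_level(p), n_censored=n_censored)


@dataclass(frozen=True)
class StopSpec:
    """When to stop generating and what counts as a positive trajectory.

    ``targets`` maps event names to token-id sets: positive if a member
    appears before any terminal token (and within the horizon).
    ``time_targets`` maps names to minute thresholds: positive once the
    simulated clock exceeds the threshold before a terminal token
    (length-of-stay style events; a terminal before the threshold —
    e.g. death — renders them negative).
    """

    targets: Mapping[str, frozenset[int]] = field(default_factory=dict)
    terminal: frozenset[int] = frozenset()
    time_targets: Mapping[str, float] = field(default_factory=dict)
    horizon_min: float | None = None
    max_tokens: int = DEFAULT_MAX_TOKENS

    def __post_init__(self) -> None:
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be >= 1")
        if self.horizon_min is not None and self.horizon_min <= 0:
            raise ValueError("horizon must be positive when present")
        for thr in self.time_targets.values():
            if thr <= 0:
                raise ValueError("time targets must be positive")

    @property
    def event_names(self) -> list[str]:
        return list(self.targets) + list(self.time_targets)


def interval_clock(vocabulary: Vocabulary) -> np.ndarray:
    """Per-token representative duration in minutes (0 for non-interval tokens)."""
    mins = np.zeros(len(vocabulary))
    for tid in range(len(vocabulary)):
        tok = vocabulary.token(tid)
        if token_class(tok) == "interval":
            mins[tid] = interval_representative_minutes(int(tok.split("/I")[1]))
    return mins


@dataclass
class Trajectory:
    """One simulated fPHT with its outcome flags."""

    tokens: np.ndarray
    flags: dict[str, bool]
    elapsed_min: float
    censored: bool  # token cap reached with no terminal; counts negative


class _TrajState:
    __slots__ = ("context", "generated", "elapsed", "flags", "done", "censored", "rng")

    def __init__(self, context, names, rng):
        self.context = list(context)
        self.generated: list[int] = []
        self.elapsed = 0.0
        self.flags = {name: False for name in names}
        self.done = False
        self.censored = False
        self.rng = rng

    def step(self, tok: int, spec: StopSpec, token_minutes: np.ndarray) -> None:
        self.generated.append(tok)
        self.context.append(tok)
        self.elapsed += float(token_minutes[tok])
        if spec.horizon_min is not None and self.elapsed > spec.horizon_min:
            self.done = True
            return
        for name, thr in spec.time_targets.items():
            if self.elapsed > thr:
                self.flags[name] = True
        # flag before the terminal check: a token that is both a tracked
        # event and a terminal (e.g. death) counts positive, then stops
        for name, toks in spec.targets.items():
            if tok in toks:
                self.flags[name] = True
        if tok in spec.terminal:
            self.done = True
            return
        if self.flags and all(self.flags.values()):
            self.done = True
        if len(self.generated) >= spec.max_tokens:
            self.done = True
            self.censored = True


def _run_group_generic(
    model: NextTokenModel,
    context: Sequence[int],
    stop_spec: StopSpec,
    rngs: list[np.random.Generator],
    mins: np.ndarray,
) -> list[_TrajState]:
    """Ensemble stepping via (batched) full-context evaluation."""
    names = stop_spec.event_names
    states = [_TrajState(context, names, rng) for rng in rngs]
    batched = hasattr(model, "next_distribution_batch")
    while True:
        active = [s for s in states if not s.done]
        if not active:
            break
        if batched:
            ctxs = [np.asarray(s.context[-model.context_length:], dtype=np.int64)
                    for s in active]
            dists = model.next_distribution_batch(ctxs)
            for s, dist in zip(active, dists):
                s.step(_sample_from(dist, s.rng), stop_spec, mins)
        else:
            for s in active:
                s.step(model.sample(s.context, s.rng), stop_spec, mins)
    return states


def _finish_sequential(model, state: _TrajState, spec: StopSpec, mins: np.ndarray) -> None:
    while not state.done:
        state.step(model.sample(state.context, state.rng), spec, mins)


def _run_groups_kv(
    model,
    groups: list[tuple[Sequence[int], list[np.random.Generator]]],
    spec: StopSpec,
    mins: np.ndarray,
    max_batch: int = 1024,
) -> list[list[_TrajState]]:
    """Ensemble stepping with per-layer key/value caching.

    Each group (one context, many trajectory streams) is prefilled once;
    all trajectories across groups then advance one token per pass.
    Finished rows stay in the batch (their outputs are discarded) and the
    batch is compacted when mostly idle; a trajectory that outgrows the
    model window finishes by windowed recompute.
    """
    names = spec.event_names
    cfg = model.config
    nh, dh = cfg.n_heads, cfg.d_model // cfg.n_heads
    t_cap = model.context_length
    results: dict[int, list[_TrajState]] = {}

    # chunk groups so a pass stays within max_batch trajectories
    chunks: list[list[int]] = [[]]
    count = 0
    for gi, (_, rngs) in enumerate(groups):
        if count and count + len(rngs) > max_batch:
            chunks.append([])
            count = 0
        chunks[-1].append(gi)
        count += len(rngs)

    for chunk in chunks:
        states: list[_TrajState] = []
        ctx_lens: list[int] = []
        prefill_kv: list = []
        for gi in chunk:
            context, rngs = groups[gi]
            ctx = np.asarray(context, dtype=np.int64)[-t_cap:]
            group_states = []
            if len(ctx) >= t_cap:  # no room to append: windowed recompute
                for rng in rngs:
                    st = _TrajState(context, names, rng)
                    _finish_sequential(model, st, spec, mins)
                    group_states.append(st)
                results[gi] = group_states
                continue
            kv, dist = model.prefill(ctx)
            for rng in rngs:
                st = _TrajState(context, names, rng)
                st.step(_sample_from(dist, st.rng), spec, mins)
                group_states.append(st)
                states.append(st)
                ctx_lens.append(len(ctx))
                prefill_kv.append(kv)
            results[gi] = group_states

        if not states:
            continue
        B = len(states)
        lens = np.asarray(ctx_lens, dtype=np.int64)
        K = [np.zeros((B, nh, t_cap, dh), dtype=np.float32) for _ in range(cfg.n_layers)]
        V = [np.zeros((B, nh, t_cap, dh), dtype=np.float32) for _ in range(cfg.n_layers)]
        for b, kv in enumerate(prefill_kv):
            for i, (k_l, v_l) in enumerate(kv):
                K[i][b, :, : lens[b]] = k_l
                V[i][b, :, : lens[b]] = v_l

        overflow = np.zeros(B, dtype=bool)
        while True:
            active = np.array(
                [not s.done and not overflow[b] for b, s in enumerate(states)]
            )
            for b in np.flatnonzero(active):
                if lens[b] >= t_cap:
                    overflow[b] = True
                    active[b] = False
                    _finish_sequential(model, states[b], spec, mins)
            if not active.any():
                break
            if active.mean() < 0.25:
                keep = np.flatnonzero(active)  # finished/overflow rows are never read again
                states = [states[b] for b in keep]
                lens = lens[keep]
                overflow = overflow[keep]
                K = [k[keep].copy() for k in K]
                V = [v[keep].copy() for v in V]
                B = len(states)
                active = np.ones(B, dtype=bool)
            tokens = np.zeros(B, dtype=np.int64)
            step_lens = np.zeros(B, dtype=np.int64)
            for b in np.flatnonzero(active):
                tokens[b] = states[b].generated[-1]
                step_lens[b] = lens[b]
            dists = model.step_kv(K, V, step_lens, tokens)
            for b in np.flatnonzero(active):
                lens[b] += 1
                states[b].step(_sample_from(dists[b], states[b].rng), spec, mins)

    return [results[gi] for gi in range(len(groups))]


def _run_groups(
    model: NextTokenModel,
    groups: list[tuple[Sequence[int], list[np.random.Generator]]],
    stop_spec: StopSpec,
    token_minutes: np.ndarray | None,
) -> list[list[_TrajState]]:
    for context, _ in groups:
        if len(context) == 0:
            raise ValueError("context must be non-empty")
    mins = token_minutes if token_minutes is not None else np.zeros(model.vocab_size)
    if hasattr(model, "prefill") and hasattr(model, "step_kv"):
        return _run_groups_kv(model, groups, stop_spec, mins)
    return [
        _run_group_generic(model, context, stop_spec, rngs, mins)
        for context, rngs in groups
    ]


def generate_fpht(
    model: NextTokenModel,
    context: Sequence[int],
    stop_spec: StopSpec,
    rng: np.random.Generator,
    token_minutes: np.ndarray | None = None,
) -> Trajectory:
    """Sample one future timeline until a stopping condition is met.

    Stops at the first terminal token, when the simulated clock passes the
    horizon, once every tracked event has occurred, or at the token cap
    (censored; all unresolved events count negative).
    """
    ((state,),) = _run_groups(model, [(context, [rng])], stop_spec, token_minutes)
    return Trajectory(
        tokens=np.asarray(state.generated, dtype=np.int64),
        flags=dict(state.flags),
        elapsed_min=state.elapsed,
        censored=state.censored,
    )


def estimate_probability(
    model: NextTokenModel,
    context: Sequence[int],
    stop_spec: StopSpec,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    token_minutes: np.ndarray | None = None,
) -> tuple[dict[str, MCProbabilityEstimate], dict[str, np.ndarray]]:
    """Estimate every tracked event's probability from n_sims trajectories.

    Trajectory i draws from an independent stream derived from
    ``(seed, i)``, so results are reproducible and order-independent; the
    same seed yields bit-identical estimates on the same context.  Returns
    the per-event estimates and the per-trajectory flag arrays (the raw
    material for composite endpoints, which must share trajectories to
    inherit outcome dependencies).
    """
    (result,) = estimate_probability_many(
        model, [(context, seed)], stop_spec, n_sims=n_sims, token_minutes=token_minutes
    )
    return result


def estimate_probability_many(
    model: NextTokenModel,
    contexts_and_seeds: Sequence[tuple[Sequence[int], int]],
    stop_spec: StopSpec,
    n_sims: int = DEFAULT_N_SIMS,
    token_minutes: np.ndarray | None = None,
) -> list[tuple[dict[str, MCProbabilityEstimate], dict[str, np.ndarray]]]:
    """Vectorized :func:`estimate_probability` over many (context, seed) pairs.

    Results are identical to calling ``estimate_probability`` per pair;
    trajectories from different contexts are interleaved into shared model
    passes for throughput.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    groups = [
        (context, [np.random.default_rng(np.random.SeedSequence((seed, i)))
                   for i in range(n_sims)])
        for context, seed in contexts_and_seeds
    ]
    out = []
    for states in _run_groups(model, groups, stop_spec, token_minutes):
        n_censored = sum(s.censored for s in states)
        flags = {
            name: np.array([s.flags[name] for s in states], dtype=bool)
            for name in stop_spec.event_names
        }
        estimates = {
            name: MCProbabilityEstimate.from_counts(int(f.sum()), n_sims, n_censored)
            for name, f in flags.items()
        }
        out.append((estimates, flags))
    return out


def composite_estimate(
    flags: Mapping[str, np.ndarray], components: Sequence[str]
) -> MCProbabilityEstimate:
    """Union of component events on the shared trajectory ensemble.

    A trajectory is composite-positive iff any component flagged positive;
    because the components share trajectories, their dependencies (e.g.
    death precluding a later prolonged stay) are inherited, not assumed
    independent.
    """
    arrays = [np.asarray(flags[c], dtype=bool) for c in components]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("component flag arrays come from different ensembles")
    union = np.logical_or.reduce(arrays)
    return MCProbabilityEstimate.from_counts(int(union.sum()), len(union))


def estimates_to_frame(
    estimates: Mapping[str, MCProbabilityEstimate],
    subject_id: str = "",
    context_position: int = -1,
) -> pd.DataFrame:
    """Tidy serialization: one row per (subject, task) estimate."""
    rows = [
        {
            "subject_id": subject_id,
            "task": name,
            "N": e.n,
            "M": e.m,
            "p_hat": e.p_hat,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "risk_level": e.risk_level,
            "context_position": context_position,
        }
        for name, e in estimates.items()
    ]
    return pd.DataFrame(rows)
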