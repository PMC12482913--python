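"""Synthetic MEDS-format cohorts from a semi-Markov hospital course.

Each subject follows a continuous-time course ED triage -> ward -> ICU ->
death/discharge (ED discharge is a competing exit at triage), driven by
per-state competing exponential hazards that depend on a latent severity
covariate (low/high mixture).  State residence time is exponential with
rate equal to the summed outgoing hazards; the destination is drawn
proportionally to the hazards — so scaling one hazard (e.g. quadrupling
death) reshapes the competing outcomes exactly as in a cause-specific
competing-risks model.

Severity is observable through laboratory values: lab means are shifted
far apart between severity classes, so the tokenized timeline carries the
information a sequence model needs to recover per-subject risk.

Every outcome probability (death before discharge, ICU admission, length
of stay above a threshold, composites, ED re-presentation) is computable
exactly by path enumeration; length-of-stay tail probabilities convolve
the per-state exponential residence distributions on an hourly grid.
This gives analytic ground truth for parameter-recovery tests without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .meds_io import EventRecord, SubjectStatics

ED_TRIAGE = "ED_TRIAGE"
WARD = "WARD"
ICU = "ICU"
DEATH = "DEATH"
DISCHARGE = "DISCHARGE"
ED_OUT = "ED_OUT"

ABSORBING = frozenset({DEATH, DISCHARGE, ED_OUT})

_STATE_EVENT = {
    WARD: "ADMIT/HOSPITAL",
    ICU: "ICU_ADMIT/ICU",
    DEATH: "DEATH/DEATH",
    DISCHARGE: "DISCHARGE/HOSPITAL",
    ED_OUT: "ED_OUT/ED",
}

_T0 = datetime(2024, 1, 1, 8, 0, tzinfo=timezone.utc)


def _hazards(mean_residence_min: float, probs: Mapping[str, float]) -> dict[str, float]:
    """Competing hazards (per minute) with given total mean residence and branch probabilities."""
    total = 1.0 / mean_residence_min
    return {s: total * p for s, p in probs.items()}


@dataclass
class CohortConfig:
    """Generator parameters; defaults define the study conditions used in tests.

    ``hazards[severity][state]`` maps destination state to a per-minute
    hazard.  ``lab_mean``/``lab_sd`` give the severity-conditional normal
    distribution of lab values; ``n_ed_labs``/``n_ward_labs`` the number of
    timed lab draws emitted in each phase.
    """

    n_subjects: int = 1000
    seed: int = 0
    p_high_severity: float = 0.3
    hazards: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            "low": {
                ED_TRIAGE: _hazards(240.0, {WARD: 0.30, ED_OUT: 0.70}),
                WARD: _hazards(4320.0, {ICU: 0.08, DEATH: 0.01, DISCHARGE: 0.91}),
                ICU: _hazards(2880.0, {DEATH: 0.10, DISCHARGE: 0.90}),
            },
            "high": {
                ED_TRIAGE: _hazards(240.0, {WARD: 0.85, ED_OUT: 0.15}),
                WARD: _hazards(2880.0, {ICU: 0.45, DEATH: 0.12, DISCHARGE: 0.43}),
                ICU: _hazards(4320.0, {DEATH: 0.35, DISCHARGE: 0.65}),
            },
        }
    )
    lab_code: str = "LAB/lactate"
    lab_mean: dict[str, float] = field(default_factory=lambda: {"low": 1.5, "high": 5.0})
    lab_sd: dict[str, float] = field(default_factory=lambda: {"low": 0.8, "high": 0.8})
    n_ed_labs: int = 3
    n_ward_labs: int = 2
    p_represent: dict[str, float] = field(default_factory=lambda: {"low": 0.10, "high": 0.25})
    represent_mean_min: float = 2880.0
    los_threshold_min: float = 10 * 1440.0  # 10-day prolonged-stay reference

    def scaled_death_hazard(self, factor: float) -> "CohortConfig":
        """Config with every death hazard multiplied by ``factor`` (competing risks knob)."""
        new = {
            sev: {
                st: {dst: h * (factor if dst == DEATH else 1.0) for dst, h in hs.items()}
                for st, hs in states.items()
            }
            for sev, states in self.hazards.items()
        }
        return replace(self, hazards=new)

    def validate(self) -> None:
        for sev, states in self.hazards.items():
            for st, hs in states.items():
                if st in ABSORBING:
                    raise ValueError(f"absorbing state {st} must have no outgoing hazards")
                if any(h < 0 for h in hs.values()) or sum(hs.values()) <= 0:
                    raise ValueError(f"invalid hazards for {sev}/{st}")


# ---------------------------------------------------------------------------
# exact probabilities


def _transition_probs(config: CohortConfig, severity: str, state: str) -> dict[str, float]:
    hs = config.hazards[severity][state]
    total = sum(hs.values())
    return {s: h / total for s, h in hs.items()}


def _enumerate_paths(
    config: CohortConfig, severity: str, start_state: str, tol: float = 1e-12
):
    """Yield (states, probability) for every course from start to absorption."""
    stack = [((start_state,), 1.0)]
    max_depth = 64
    while stack:
        path, p = stack.pop()
        state = path[-1]
        if state in ABSORBING:
            yield path, p
            continue
        if len(path) > max_depth:
            raise RuntimeError("chain does not absorb within depth limit")
        for nxt, q in sorted(_transition_probs(config, severity, state).items()):
            pq = p * q
            if pq >= tol:
                stack.append((path + (nxt,), pq))


def _los_tail_given_path(
    config: CohortConfig, severity: str, path: Sequence[str], threshold_min: float
) -> float:
    """P(total in-hospital residence > threshold | path) on a 1-hour grid.

    Residence of each transient state from admission onward is exponential
    with its total outgoing hazard; the sum is hypoexponential, evaluated by
    discrete convolution (documented tolerance ~1e-3).
    """
    rates = []
    in_hospital = False
    for st in path:
        if st == WARD:
            in_hospital = True
        if in_hospital and st not in ABSORBING:
            rates.append(sum(config.hazards[severity][st].values()))
    if not rates:
        return 0.0
    grid_h = 60.0  # minutes per cell
    n = int(max(threshold_min / grid_h * 4, 64))
    t = (np.arange(n) + 0.5) * grid_h
    pdf = None
    for r in rates:
        comp = r * np.exp(-r * t) * grid_h
        pdf = comp if pdf is None else np.convolve(pdf, comp)[:n]
    cdf_at_thr = float(np.sum(pdf[t[: len(pdf)] <= threshold_min]))
    return max(0.0, min(1.0, 1.0 - cdf_at_thr))


def exact_event_probability(
    config: CohortConfig,
    severity: str,
    event_query: str | tuple,
    start_state: str = WARD,
) -> float:
    """Exact outcome probability from ``start_state`` by path enumeration.

    Queries: ``"death"`` (death before discharge), ``"icu"`` (ICU entry
    before absorption), ``("los_gt", minutes)`` (time to absorption after
    admission exceeds the threshold; dying earlier renders it negative —
    competing-risks semantics), ``("composite", minutes)`` (union of the
    three on shared courses), ``"admit"`` (hospital admission).
    """
    config.validate()

    def query_prob(path: tuple[str, ...]) -> float:
        death = path[-1] == DEATH
        icu = ICU in path
        if event_query == "death":
            return 1.0 if death else 0.0
        if event_query == "icu":
            return 1.0 if icu else 0.0
        if event_query == "admit":
            return 1.0 if WARD in path else 0.0
        kind, thr = event_query
        los = _los_tail_given_path(config, severity, path, thr) if WARD in path else 0.0
        if kind == "los_gt":
            return los
        if kind == "composite":
            return 1.0 if (death or icu) else los
        raise ValueError(f"unknown query {event_query!r}")

    total = 0.0
    mass = 0.0
    for path, p in _enumerate_paths(config, severity, start_state):
        total += p * query_prob(path)
        mass += p
    if mass < 1 - 1e-9:
        raise RuntimeError(f"path enumeration lost mass: {1 - mass:.2e}")
    return total / mass


#: Token ids of the reduced state alphabet used by the tabulated-Markov bridge.
STATE_TOKENS = (ED_TRIAGE, WARD, ICU, DEATH, DISCHARGE, ED_OUT)


def markov_table_from_config(config: CohortConfig, severity: str) -> np.ndarray:
    """Token-level order-1 transition table over the hospital-course states.

    Bridges the generator to the tabulated-Markov sequence model: row i is
    the jump distribution of state token i (absorbing states self-loop), so
    Monte-Carlo estimates on the resulting model can be compared with
    :func:`exact_event_probability` directly.
    """
    config.validate()
    n = len(STATE_TOKENS)
    idx = {s: i for i, s in enumerate(STATE_TOKENS)}
    table = np.zeros((n, n))
    for st in STATE_TOKENS:
        if st in ABSORBING:
            table[idx[st], idx[st]] = 1.0
        else:
            for dst, p in _transition_probs(config, severity, st).items():
                table[idx[st], idx[dst]] = p
    return table


# ---------------------------------------------------------------------------
# cohort simulation


def _simulate_course(config, severity: str, rng: np.random.Generator):
    """One subject's state path with residence times (minutes)."""
    state = ED_TRIAGE
    path = [(state, 0.0)]
    t = 0.0
    while state not in ABSORBING:
        hs = config.hazards[severity][state]
        total = sum(hs.values())
        t += rng.exponential(1.0 / total)
        dests = sorted(hs)
        probs = np.array([hs[d] for d in dests]) / total
        state = dests[rng.choice(len(dests), p=probs)]
        path.append((state, t))
    return path


def simulate_cohort(
    config: CohortConfig,
) -> tuple[dict[str, list[EventRecord]], dict[str, SubjectStatics], pd.DataFrame]:
    """Simulate a cohort; returns (events by subject, statics, ground truth).

    Fully reproducible: subject i draws from a stream derived from
    ``(config.seed, i)``.  Ground truth holds each subject's severity and
    exact conditional-on-admission outcome probabilities at the config's
    length-of-stay threshold, plus the triage-anchored admission and
    72-hour re-presentation probabilities.
    """
    config.validate()
    events: dict[str, list[EventRecord]] = {}
    statics: dict[str, SubjectStatics] = {}

    # per-severity exact probabilities, computed once
    gt_cols = {}
    for sev in ("low", "high"):
        gt_cols[sev] = {
            "p_admit": exact_event_probability(config, sev, "admit", start_state=ED_TRIAGE),
            "p_death": exact_event_probability(config, sev, "death"),
            "p_icu": exact_event_probability(config, sev, "icu"),
            "p_los": exact_event_probability(config, sev, ("los_gt", config.los_threshold_min)),
            "p_composite": exact_event_probability(
                config, sev, ("composite", config.los_threshold_min)
            ),
            "p_represent": config.p_represent[sev]
            * float(1 - np.exp(-72 * 60.0 / config.represent_mean_min)),
        }

    genders = ["female", "male"]
    maritals = ["single", "married", "widowed", "divorced", "unknown"]
    races = ["asian", "black", "hispanic", "white", "other", "unknown"]
    rows = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, i)))
        sid = f"S{i:06d}"
        sev = "high" if rng.random() < config.p_high_severity else "low"

        statics[sid] = SubjectStatics(
            subject_id=sid,
            gender=genders[rng.choice(2)],
            marital_status=maritals[rng.choice(5, p=[0.3, 0.45, 0.1, 0.1, 0.05])],
            race=races[rng.choice(6, p=[0.08, 0.18, 0.12, 0.5, 0.07, 0.05])],
            bmi=float(np.clip(rng.normal(27, 5), 14, 55)),
            age_at_start=int(np.clip(rng.normal(58, 18), 0, 99)),
        )

        evs: list[EventRecord] = []

        def emit(code: str, t_min: float, value: float | None = None) -> None:
            evs.append(EventRecord(sid, _T0 + timedelta(minutes=float(t_min)), code, value))

        def emit_labs(n: int, t_lo: float, t_hi: float) -> None:
            for t in np.sort(rng.uniform(t_lo, t_hi, size=n)):
                emit(config.lab_code, t, float(rng.normal(config.lab_mean[sev], config.lab_sd[sev])))

        emit("ED_REG/ED", 0.0)
        course = _simulate_course(config, sev, rng)
        ed_end = course[1][1]
        emit_labs(config.n_ed_labs, 1.0, max(ed_end - 1.0, 2.0))
        for state, t in course[1:]:
            emit(_STATE_EVENT[state], t)
            if state == WARD:
                nxt_t = course[[s for s, _ in course].index(WARD) + 1][1]
                emit_labs(config.n_ward_labs, t + 1.0, max(nxt_t - 1.0, t + 2.0))
        if course[-1][0] == ED_OUT and rng.random() < config.p_represent[sev]:
            emit("ED_REG/ED", course[-1][1] + rng.exponential(config.represent_mean_min))

        evs.sort(key=lambda e: e.time)
        events[sid] = evs
        rows.append({"subject_id": sid, "severity": sev, **gt_cols[sev]})

    ground_truth = pd.DataFrame(rows)
    return events, statics, ground_truth
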