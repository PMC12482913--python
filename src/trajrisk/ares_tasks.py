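"""Clinician-defined critical-event tasks over tokenized timelines.

A task is a declarative token-set specification: which tokens make a
trajectory positive, which terminate it, an optional horizon, and an
anchor rule fixing the context position at which predictions are issued
(hospital admission, ED triage, or ED discharge).  Because tasks are pure
token-set definitions evaluated on simulated trajectories, new events can
be added without retraining the sequence model.

Built-in tasks: hospital mortality (HM, death before discharge), ICU
admission (IA, ICU before discharge), prolonged stay (PS, length of stay
above the training cohort's 90th percentile), their composite (HM-IA-PS),
and the ED benchmarks — hospitalization at triage, critical outcome
(death or ICU within 12 h of triage), and ED re-presentation within 72 h
of ED discharge.

The module also extracts ground-truth labels from observed held-out
timelines (wall-clock times, not representative bin durations) and
implements the dynamic component logic of a running risk monitor: ICU
risk is dropped once the patient is in the ICU, mortality risk after
death/discharge, and the prolonged-stay component is re-targeted up a
threshold ladder (10 d -> 15 d -> 20 d by default) as the observed stay
overtakes it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .mc_inference import StopSpec
from .tokenizer import PatientHealthTimeline, Vocabulary

_D = 1440.0  # minutes per day

HM = "HM"
IA = "IA"
PS = "PS"
COMPOSITE = "HM-IA-PS"
ED_HOSP = "ED-hospitalization"
ED_CRITICAL = "ED-critical-12h"
ED_REPRESENT = "ED-re-presentation-72h"

#: Prolonged-stay recalibration ladder (minutes); extended beyond the last
#: rung by +5 days per step.
DEFAULT_PS_LADDER = (10 * _D, 15 * _D, 20 * _D)


def _scheme_ids(vocab: Vocabulary, scheme: str) -> frozenset[int]:
    return frozenset(vocab.ids_matching(lambda t: t.split("/", 1)[0] == scheme))


@dataclass(frozen=True)
class TaskSpec:
    """One critical-event definition.

    ``anchor`` names the token scheme at whose (first) occurrence the
    prediction is issued; ``threshold_min`` is set for length-of-stay
    style tasks and replaces ``positive`` token matching by a simulated-
    clock comparison.
    """

    name: str
    positive: frozenset[int]
    terminal: frozenset[int]
    anchor: str  # "ADMIT" | "ED_REG" | "ED_OUT"
    horizon_min: float | None = None
    threshold_min: float | None = None
    components: tuple[str, ...] = ()  # non-empty for composite tasks

    def __post_init__(self) -> None:
        if self.positive & self.terminal:
            raise ValueError("positive and terminal token sets must be disjoint")

    def stop_spec(self, max_tokens: int = 2048) -> StopSpec:
        if self.threshold_min is not None:
            return StopSpec(
                targets={},
                time_targets={self.name: self.threshold_min},
                terminal=self.terminal,
                horizon_min=self.horizon_min,
                max_tokens=max_tokens,
            )
        return StopSpec(
            targets={self.name: self.positive},
            terminal=self.terminal,
            horizon_min=self.horizon_min,
            max_tokens=max_tokens,
        )


def merged_stop_spec(tasks: Sequence[TaskSpec], max_tokens: int = 2048) -> StopSpec:
    """One StopSpec tracking several same-anchor tasks on shared trajectories."""
    targets: dict[str, frozenset[int]] = {}
    time_targets: dict[str, float] = {}
    terminal: frozenset[int] = frozenset()
    horizons = set()
    for t in tasks:
        if t.components:
            continue
        if t.threshold_min is not None:
            time_targets[t.name] = t.threshold_min
        else:
            targets[t.name] = t.positive
        terminal |= t.terminal
        horizons.add(t.horizon_min)
    horizon = None if horizons == {None} else max(h for h in horizons if h is not None)
    # terminal tokens that are positive for some tracked task stay targets
    terminal -= frozenset().union(*targets.values()) if targets else frozenset()
    return StopSpec(
        targets=targets,
        time_targets=time_targets,
        terminal=terminal,
        horizon_min=horizon,
        max_tokens=max_tokens,
    )


def training_los_percentile(
    timelines: Sequence[PatientHealthTimeline],
    vocab: Vocabulary,
    q: float = 0.9,
) -> float:
    """Empirical q-quantile of wall-clock length of stay (admission to
    death/discharge) over the training timelines."""
    admit = _scheme_ids(vocab, "ADMIT")
    out = _scheme_ids(vocab, "DISCHARGE") | _scheme_ids(vocab, "DEATH")
    los = []
    for tl in timelines:
        t_admit = t_out = None
        for tok, t in zip(tl.tokens, tl.time_min):
            if t_admit is None and tok in admit:
                t_admit = t
            elif t_admit is not None and tok in out:
                t_out = t
                break
        if t_admit is not None and t_out is not None:
            los.append(t_out - t_admit)
    if not los:
        raise ValueError("no completed admissions in training data; LOS threshold undefined")
    return float(np.quantile(np.asarray(los), q))


def builtin_tasks(
    training_timelines: Sequence[PatientHealthTimeline],
    vocab: Vocabulary,
    ps_quantile: float = 0.9,
) -> dict[str, TaskSpec]:
    """The built-in task collection, with the PS threshold fitted on training data."""
    death = _scheme_ids(vocab, "DEATH")
    discharge = _scheme_ids(vocab, "DISCHARGE")
    icu = _scheme_ids(vocab, "ICU_ADMIT")
    admit = _scheme_ids(vocab, "ADMIT")
    ed_reg = _scheme_ids(vocab, "ED_REG")
    ed_out = _scheme_ids(vocab, "ED_OUT")
    end = _scheme_ids(vocab, "META")
    ps_thr = training_los_percentile(training_timelines, vocab, ps_quantile)
    return {
        HM: TaskSpec(HM, positive=death, terminal=discharge | end, anchor="ADMIT"),
        IA: TaskSpec(IA, positive=icu, terminal=death | discharge | end, anchor="ADMIT"),
        PS: TaskSpec(PS, positive=frozenset(), terminal=death | discharge | end,
                     anchor="ADMIT", threshold_min=ps_thr),
        COMPOSITE: TaskSpec(COMPOSITE, positive=frozenset(),
                            terminal=death | discharge | end, anchor="ADMIT",
                            components=(HM, IA, PS)),
        ED_HOSP: TaskSpec(ED_HOSP, positive=admit, terminal=ed_out | death | end,
                          anchor="ED_REG"),
        ED_CRITICAL: TaskSpec(ED_CRITICAL, positive=death | icu,
                              terminal=discharge | ed_out | end, anchor="ED_REG",
                              horizon_min=12 * 60.0),
        ED_REPRESENT: TaskSpec(ED_REPRESENT, positive=ed_reg, terminal=death | end,
                               anchor="ED_OUT", horizon_min=72 * 60.0),
    }


# ---------------------------------------------------------------------------
# label extraction from observed timelines


def anchor_position(timeline: PatientHealthTimeline, task: TaskSpec,
                    vocab: Vocabulary) -> int | None:
    """Index of the first anchor token, or None when the anchor rule fails."""
    ids = _scheme_ids(vocab, task.anchor)
    for j, tok in enumerate(timeline.tokens):
        if tok in ids:
            return j
    return None


def extract_label(
    timeline: PatientHealthTimeline,
    task: TaskSpec,
    anchor_pos: int,
    all_tasks: Mapping[str, TaskSpec] | None = None,
) -> int | None:
    """{0,1} label from the observed future after the anchor, or None (n/a).

    Uses wall-clock event times; deterministic and idempotent.  For
    composite tasks the component labels are extracted and OR-ed.
    """
    if task.components:
        assert all_tasks is not None, "composite labels need the component specs"
        labels = [extract_label(timeline, all_tasks[c], anchor_pos) for c in task.components]
        if any(lb is None for lb in labels):
            return None
        return int(any(labels))

    if not 0 <= anchor_pos < len(timeline.tokens):
        return None
    t_anchor = timeline.time_min[anchor_pos]
    for j in range(anchor_pos + 1, len(timeline.tokens)):
        tok = int(timeline.tokens[j])
        dt = timeline.time_min[j] - t_anchor
        within = task.horizon_min is None or dt <= task.horizon_min
        if task.threshold_min is not None and tok in task.terminal:
            return int(dt > task.threshold_min)
        if tok in task.positive and within:
            return 1
        if tok in task.terminal:
            return 0
        if task.horizon_min is not None and dt > task.horizon_min:
            return 0
    # timeline ends without resolution
    if task.threshold_min is not None:
        return int(timeline.time_min[-1] - t_anchor > task.threshold_min)
    return 0


def extract_labels(
    timelines: Sequence[PatientHealthTimeline],
    tasks: Mapping[str, TaskSpec],
    vocab: Vocabulary,
):
    """Label table over a cohort: dict task -> {subject_id: label} (n/a omitted)."""
    out: dict[str, dict[str, int]] = {name: {} for name in tasks}
    for tl in timelines:
        for name, task in tasks.items():
            pos = anchor_position(tl, task, vocab)
            if pos is None:
                continue
            label = extract_label(tl, task, pos, all_tasks=tasks)
            if label is not None:
                out[name][tl.subject_id] = label
    return out


# ---------------------------------------------------------------------------
# dynamic component activation (running-monitor logic)


def update_active_components(
    context: PatientHealthTimeline,
    tasks: Mapping[str, TaskSpec],
    vocab: Vocabulary,
    ps_ladder: Sequence[float] = DEFAULT_PS_LADDER,
) -> dict[str, TaskSpec]:
    """Active task set given the observed context (an admitted patient).

    * IA is deactivated once an ICU-admission token has been observed.
    * HM is deactivated after an observed death or discharge.
    * When the observed stay exceeds the current PS threshold, PS is
      replaced by the next rung of the threshold ladder (10 d -> 15 d ->
      20 d, then +5 d per rung).
    """
    icu = _scheme_ids(vocab, "ICU_ADMIT")
    admit = _scheme_ids(vocab, "ADMIT")
    out = _scheme_ids(vocab, "DISCHARGE") | _scheme_ids(vocab, "DEATH")

    seen_icu = seen_out = False
    t_admit = None
    for tok, t in zip(context.tokens, context.time_min):
        tok = int(tok)
        if t_admit is None and tok in admit:
            t_admit = t
        if tok in icu:
            seen_icu = True
        if t_admit is not None and tok in out:
            seen_out = True
    if t_admit is None:
        raise ValueError("context contains no admission anchor")
    observed_los = context.time_min[-1] - t_admit

    active: dict[str, TaskSpec] = {}
    for name, task in tasks.items():
        if task.anchor != "ADMIT":
            continue
        if name == IA and seen_icu:
            continue
        if name in (HM, IA) and seen_out:
            continue
        if name == PS and task.threshold_min is not None:
            thr = task.threshold_min
            rung = 0
            ladder = list(ps_ladder)
            while observed_los > thr:
                rung += 1
                thr = ladder[rung] if rung < len(ladder) else thr + 5 * _D
            if thr != task.threshold_min:
                task = replace(task, name=f"{PS}>{thr / _D:.0f}d", threshold_min=thr)
            if seen_out:
                continue
        active[task.name] = task
    return active
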