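"""Task definitions, observed-label extraction, and dynamic components."""

import numpy as np
import pytest

from trajrisk.ares_tasks import (
    COMPOSITE,
    HM,
    IA,
    PS,
    ED_CRITICAL,
    ED_HOSP,
    ED_REPRESENT,
    TaskSpec,
    anchor_position,
    builtin_tasks,
    extract_label,
    extract_labels,
    training_los_percentile,
    update_active_components,
)
from trajrisk.mc_inference import estimate_probability_many
from trajrisk.sequence_model import TabulatedMarkovModel
from trajrisk.synthetic_ehr import (
    CohortConfig,
    markov_table_from_config,
    simulate_cohort,
)
from trajrisk.tokenizer import PatientHealthTimeline, Vocabulary, fit_quantiles, tokenize_corpus

_D = 1440.0

BASE_TOKENS = [
    "Q1", "ADMIT/HOSPITAL", "DISCHARGE/HOSPITAL", "DEATH/DEATH",
    "ICU_ADMIT/ICU", "ED_REG/ED", "ED_OUT/ED", "META/TIMELINE_END", "LAB/x",
]


@pytest.fixture()
def vocab() -> Vocabulary:
    return Vocabulary(BASE_TOKENS)


def _tl(vocab, items, subject="S"):
    """items: (token_string, time_minutes) pairs."""
    toks = [vocab.id(t) for t, _ in items]
    times = [t for _, t in items]
    return PatientHealthTimeline(
        subject_id=subject,
        tokens=np.asarray(toks, dtype=np.int64),
        event_index=np.arange(len(toks), dtype=np.int64),
        time_min=np.asarray(times, dtype=np.float64),
    )


def _admission_tl(vocab, los_days, outcome="DISCHARGE/HOSPITAL"):
    return _tl(vocab, [("ADMIT/HOSPITAL", 0.0), (outcome, los_days * _D)])


def test_ps_threshold_is_training_90th_percentile(vocab):
    timelines = [_admission_tl(vocab, d) for d in range(1, 11)]
    thr = training_los_percentile(timelines, vocab, 0.9)
    assert thr == pytest.approx(float(np.quantile(np.arange(1, 11) * _D, 0.9)))


def test_no_admissions_makes_ps_threshold_undefined(vocab):
    with pytest.raises(ValueError):
        builtin_tasks([_tl(vocab, [("ED_REG/ED", 0.0)])], vocab)


def test_death_before_discharge_labels_hm_positive(vocab):
    tasks = builtin_tasks([_admission_tl(vocab, d) for d in range(1, 11)], vocab)
    tl = _admission_tl(vocab, 3, outcome="DEATH/DEATH")
    pos = anchor_position(tl, tasks[HM], vocab)
    assert extract_label(tl, tasks[HM], pos) == 1
    assert extract_label(tl, tasks[IA], pos) == 0
    assert extract_label(tl, tasks[COMPOSITE], pos, all_tasks=tasks) == 1


def test_timeline_without_admission_is_not_applicable(vocab):
    tasks = builtin_tasks([_admission_tl(vocab, d) for d in range(1, 11)], vocab)
    tl = _tl(vocab, [("ED_REG/ED", 0.0), ("ED_OUT/ED", 60.0)])
    assert anchor_position(tl, tasks[HM], vocab) is None


def test_icu_thirteen_hours_after_triage_fails_12h_horizon(vocab):
    tasks = builtin_tasks([_admission_tl(vocab, d) for d in range(1, 11)], vocab)
    tl = _tl(vocab, [("ED_REG/ED", 0.0), ("ADMIT/HOSPITAL", 60.0),
                     ("ICU_ADMIT/ICU", 13 * 60.0), ("DISCHARGE/HOSPITAL", 5 * _D)])
    pos = anchor_position(tl, tasks[ED_CRITICAL], vocab)
    assert extract_label(tl, tasks[ED_CRITICAL], pos) == 0
    # at 11 h it would be positive
    tl2 = _tl(vocab, [("ED_REG/ED", 0.0), ("ADMIT/HOSPITAL", 60.0),
                      ("ICU_ADMIT/ICU", 11 * 60.0), ("DISCHARGE/HOSPITAL", 5 * _D)])
    assert extract_label(tl2, tasks[ED_CRITICAL], pos) == 1


def test_ed_re_presentation_within_72h_is_positive(vocab):
    tasks = builtin_tasks([_admission_tl(vocab, d) for d in range(1, 11)], vocab)
    tl = _tl(vocab, [("ED_REG/ED", 0.0), ("ED_OUT/ED", 120.0),
                     ("ED_REG/ED", 120.0 + 71 * 60.0)])
    pos = anchor_position(tl, tasks[ED_REPRESENT], vocab)
    assert extract_label(tl, tasks[ED_REPRESENT], pos) == 1
    tl2 = _tl(vocab, [("ED_REG/ED", 0.0), ("ED_OUT/ED", 120.0),
                      ("ED_REG/ED", 120.0 + 80 * 60.0)])
    assert extract_label(tl2, tasks[ED_REPRESENT], pos) == 0


def test_prolonged_stay_label_uses_wall_clock_and_competing_death(vocab):
    timelines = [_admission_tl(vocab, d) for d in range(1, 11)]
    tasks = builtin_tasks(timelines, vocab)
    thr_days = tasks[PS].threshold_min / _D
    assert extract_label(_admission_tl(vocab, thr_days + 1), tasks[PS], 0) == 1
    # death before the threshold renders a prolonged stay impossible
    assert extract_label(
        _admission_tl(vocab, thr_days - 1, outcome="DEATH/DEATH"), tasks[PS], 0
    ) == 0
    # death after the threshold still means the stay exceeded it
    assert extract_label(
        _admission_tl(vocab, thr_days + 2, outcome="DEATH/DEATH"), tasks[PS], 0
    ) == 1


def test_labels_are_idempotent(vocab):
    tasks = builtin_tasks([_admission_tl(vocab, d) for d in range(1, 11)], vocab)
    tl = _admission_tl(vocab, 4, outcome="DEATH/DEATH")
    first = [extract_label(tl, tasks[HM], 0) for _ in range(3)]
    assert first == [1, 1, 1]


def test_hospitalization_at_triage_label(vocab):
    tasks = builtin_tasks([_admission_tl(vocab, d) for d in range(1, 11)], vocab)
    tl = _tl(vocab, [("ED_REG/ED", 0.0), ("ADMIT/HOSPITAL", 240.0),
                     ("DISCHARGE/HOSPITAL", 3 * _D)])
    pos = anchor_position(tl, tasks[ED_HOSP], vocab)
    assert extract_label(tl, tasks[ED_HOSP], pos) == 1


def test_extracted_hm_prevalence_matches_generator_probability():
    config = CohortConfig(n_subjects=2000, seed=77)
    events, statics, truth = simulate_cohort(config)
    qm = fit_quantiles(ev for evs in events.values() for ev in evs)
    timelines, vocab, _ = tokenize_corpus(events, statics, qm)
    tasks = builtin_tasks(timelines, vocab)
    labels = extract_labels(timelines, tasks, vocab)[HM]
    truth = truth.set_index("subject_id")
    p = np.array([truth.loc[s, "p_death"] for s in labels])
    y = np.array([labels[s] for s in labels])
    se = np.sqrt(np.mean(p * (1 - p)) / len(y))
    assert abs(y.mean() - p.mean()) <= 3 * se


def test_oracle_scores_reach_bayes_auc_on_synthetic_cohort():
    """Scores from the exact chain (true severity) track the Bayes-optimal AUC."""
    from trajrisk.evaluation import auc
    from trajrisk.mc_inference import StopSpec

    config = CohortConfig(n_subjects=1000, seed=31)
    events, statics, truth = simulate_cohort(config)
    qm = fit_quantiles(ev for evs in events.values() for ev in evs)
    timelines, vocab, _ = tokenize_corpus(events, statics, qm)
    tasks = builtin_tasks(timelines, vocab)
    labels = extract_labels(timelines, tasks, vocab)[HM]
    truth = truth.set_index("subject_id")

    spec = StopSpec(targets={"death": frozenset({3})}, terminal=frozenset({4}))
    models = {
        sev: TabulatedMarkovModel(markov_table_from_config(config, sev))
        for sev in ("low", "high")
    }
    sids = sorted(labels)
    items = [(np.array([1]), 50_000 + i) for i, _ in enumerate(sids)]
    by_sev = {sev: estimate_probability_many(
        models[sev], [it for it, s in zip(items, sids) if truth.loc[s, "severity"] == sev],
        spec, n_sims=100) for sev in ("low", "high")}
    scores = {}
    for sev in ("low", "high"):
        sev_sids = [s for s in sids if truth.loc[s, "severity"] == sev]
        for s, (est, _) in zip(sev_sids, by_sev[sev]):
            scores[s] = est["death"].p_hat
    y = np.array([labels[s] for s in sids])
    mc = np.array([scores[s] for s in sids])
    bayes = np.array([truth.loc[s, "p_death"] for s in sids])
    assert abs(auc(mc, y) - auc(bayes, y)) <= 0.05


# ---------------------------------------------------------------------------
# dynamic component logic


def test_all_components_active_just_after_admission(vocab):
    tasks = builtin_tasks([_admission_tl(vocab, d) for d in range(1, 11)], vocab)
    context = _tl(vocab, [("ADMIT/HOSPITAL", 0.0), ("LAB/x", 60.0)])
    active = update_active_components(context, tasks, vocab)
    assert {HM, IA, PS} <= set(active)


def test_icu_admission_deactivates_icu_component(vocab):
    tasks = builtin_tasks([_admission_tl(vocab, d) for d in range(1, 11)], vocab)
    context = _tl(vocab, [("ADMIT/HOSPITAL", 0.0), ("ICU_ADMIT/ICU", 2 * _D)])
    active = update_active_components(context, tasks, vocab)
    assert IA not in active and HM in active


def test_observed_los_over_10d_retargets_ps_to_15d(vocab):
    timelines = [_admission_tl(vocab, d) for d in range(1, 11)]
    tasks = builtin_tasks(timelines, vocab)
    tasks[PS] = TaskSpec(PS, positive=frozenset(), terminal=tasks[PS].terminal,
                         anchor="ADMIT", threshold_min=10 * _D)
    context = _tl(vocab, [("ADMIT/HOSPITAL", 0.0), ("LAB/x", 11 * _D)])
    active = update_active_components(context, tasks, vocab)
    ps_like = [t for t in active.values() if t.threshold_min is not None]
    assert len(ps_like) == 1 and ps_like[0].threshold_min == 15 * _D


def test_discharge_deactivates_mortality_component(vocab):
    tasks = builtin_tasks([_admission_tl(vocab, d) for d in range(1, 11)], vocab)
    context = _admission_tl(vocab, 3)
    active = update_active_components(context, tasks, vocab)
    assert HM not in active and IA not in active


def test_context_without_admission_anchor_rejected(vocab):
    tasks = builtin_tasks([_admission_tl(vocab, d) for d in range(1, 11)], vocab)
    with pytest.raises(ValueError):
        update_active_components(_tl(vocab, [("ED_REG/ED", 0.0)]), tasks, vocab)


def test_task_spec_requires_disjoint_positive_and_terminal():
    with pytest.raises(ValueError):
        TaskSpec("bad", positive=frozenset({1}), terminal=frozenset({1}), anchor="ADMIT")
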