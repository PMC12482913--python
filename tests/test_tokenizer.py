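"""Tokenization rules: interval bins, quantiles, code hierarchy, statics."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajrisk.meds_io import EventRecord, SubjectStatics
from trajrisk.tokenizer import (
    INTERVAL_EDGES_MIN,
    N_INTERVAL_BINS,
    N_QUANTILES,
    Vocabulary,
    build_timeline,
    decode,
    decode_token,
    decompose_code,
    encode_statics,
    encode_value,
    fit_quantiles,
    interval_representative_minutes,
    interval_token,
    load_timelines,
    save_timelines,
    tokenize_corpus,
)

T0 = datetime(2024, 1, 1, 8, 0, tzinfo=timezone.utc)


def _lab_events(values, code="LAB/x", step_min=10):
    return [
        EventRecord("A", T0 + timedelta(minutes=i * step_min), code, float(v))
        for i, v in enumerate(values)
    ]


# ---------------------------------------------------------------------------
# intervals


def test_interval_bin_count_is_19_partitioning_from_5_minutes():
    assert N_INTERVAL_BINS == 19
    assert INTERVAL_EDGES_MIN[0] == 5


@pytest.mark.parametrize("gap,expected", [(0, None), (4, None), (4.99, None)])
def test_gaps_under_five_minutes_emit_no_token(gap, expected):
    assert interval_token(gap) is expected


def test_three_day_gap_lands_in_two_to_four_day_bin():
    tok = interval_token(3 * 1440)
    assert tok == "INTERVAL/I9"
    assert decode_token(tok).endswith("2d-4d")


def test_negative_gap_is_an_ordering_error():
    with pytest.raises(ValueError):
        interval_token(-1)


@given(st.floats(min_value=5, max_value=10 * 525600, allow_nan=False))
@settings(max_examples=200, deadline=None)
def test_interval_bins_partition_with_no_gaps_or_overlaps(gap):
    tok = interval_token(gap)
    k = int(tok.split("/I")[1])
    lo = INTERVAL_EDGES_MIN[k - 1]
    hi = INTERVAL_EDGES_MIN[k] if k < N_INTERVAL_BINS else np.inf
    assert lo <= gap < hi


def test_representative_duration_lies_inside_its_bin():
    for k in range(1, N_INTERVAL_BINS):
        rep = interval_representative_minutes(k)
        assert INTERVAL_EDGES_MIN[k - 1] <= rep < INTERVAL_EDGES_MIN[k]
    assert interval_representative_minutes(N_INTERVAL_BINS) >= INTERVAL_EDGES_MIN[-1]


# ---------------------------------------------------------------------------
# quantiles


def test_ten_quantiles_and_85th_percentile_encodes_to_q9():
    qm = fit_quantiles(_lab_events(range(1, 1001)))
    assert len(qm.edges["LAB/x"]) == N_QUANTILES - 1
    value_85 = float(np.quantile(np.arange(1, 1001), 0.85))
    assert encode_value("LAB/x", value_85, qm) == "Q9"
    assert decode_token("Q9") == "Q9: 80th–90th percentile"


def test_values_outside_training_range_clamp_to_q1_q10():
    qm = fit_quantiles(_lab_events(range(1, 1001)))
    assert encode_value("LAB/x", -10.0, qm) == "Q1"
    assert encode_value("LAB/x", 1e9, qm) == "Q10"


def test_constant_code_maps_everything_to_q1():
    qm = fit_quantiles(_lab_events([7.0] * 50))
    assert encode_value("LAB/x", 7.0, qm) == "Q1"


def test_one_value_per_decile_maps_to_distinct_tokens():
    # oracle: empirical CDF puts each of 10 spread values in its own decile
    vals = np.arange(10) * 10.0
    qm = fit_quantiles(_lab_events(np.repeat(vals, 10)))
    toks = {encode_value("LAB/x", v, qm) for v in vals}
    assert len(toks) == 10


def test_training_data_spreads_about_ten_percent_per_decile():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=2000)
    qm = fit_quantiles(_lab_events(vals))
    counts = np.zeros(10)
    for v in vals:
        counts[int(encode_value("LAB/x", v, qm)[1:]) - 1] += 1
    assert np.all(np.abs(counts / len(vals) - 0.1) <= 0.02)


def test_scarce_code_falls_back_to_scheme_level_edges():
    events = _lab_events(range(1, 101), code="LAB/common") + _lab_events(
        [5.0] * 3, code="LAB/rare"
    )
    qm = fit_quantiles(events, fit_min=20)
    assert "LAB/rare" not in qm.edges
    assert qm.edges_for("LAB/rare") is not None  # scheme fallback
    assert encode_value("LAB/rare", 200.0, qm) == "Q10"


def test_nan_value_emits_no_token():
    qm = fit_quantiles(_lab_events(range(1, 101)))
    assert encode_value("LAB/x", float("nan"), qm) is None


def test_quantile_model_round_trips(tmp_path):
    qm = fit_quantiles(_lab_events(range(1, 101)))
    qm.save(tmp_path / "q.json")
    back = type(qm).load(tmp_path / "q.json")
    np.testing.assert_allclose(back.edges["LAB/x"], qm.edges["LAB/x"])


# ---------------------------------------------------------------------------
# code decomposition


@pytest.mark.parametrize(
    "code,n_tokens",
    [
        ("ICD10PCS/0BH17EZ", 7),  # procedures: one token per character
        ("ICD10CM/I21", 1),  # bare 3-character category
        ("ICD10CM/S72001", 4),  # category + 3 extension characters
        ("ATC/C03CA01", 5),  # all five hierarchy levels
        ("ATC/C03", 2),
        ("LAB/lactate", 1),
        ("DEATH/DEATH", 1),
    ],
)
def test_hierarchical_decomposition_token_counts(code, n_tokens):
    toks = decompose_code(code)
    assert len(toks) == n_tokens
    assert 1 <= len(toks) <= 7


def test_pcs_tokens_are_positional():
    toks = decompose_code("ICD10PCS/0BH17EZ")
    assert toks[0] == "ICD10PCS/p1=0" and toks[2] == "ICD10PCS/p3=H"


def test_atc_tokens_are_cumulative_prefixes():
    assert decompose_code("ATC/C03CA01") == [
        "ATC/C", "ATC/C03", "ATC/C03C", "ATC/C03CA", "ATC/C03CA01"
    ]


def test_unknown_scheme_kept_opaque_with_warning():
    with pytest.warns(UserWarning):
        assert decompose_code("SNOMED/12345") == ["SNOMED/12345"]


# ---------------------------------------------------------------------------
# statics


@pytest.mark.parametrize("age,tens,units", [(46, "Q5", "Q7"), (0, "Q1", "Q1"), (99, "Q10", "Q10")])
def test_age_digits_reuse_quantile_tokens(age, tens, units):
    toks = encode_statics(SubjectStatics("A", age_at_start=age))
    assert toks[:2] == [tens, units]


def test_static_block_order_is_fixed():
    toks = encode_statics(
        SubjectStatics("A", gender="female", marital_status="married",
                       race="asian", bmi=31.0, age_at_start=30)
    )
    assert toks == ["Q4", "Q1", "STATIC/GENDER=female", "STATIC/MARITAL=married",
                    "STATIC/RACE=asian", "STATIC/BMI=obese"]


def test_missing_bmi_uses_unknown_token():
    toks = encode_statics(SubjectStatics("A", age_at_start=5))
    assert toks[-1] == "STATIC/BMI=unknown"


# ---------------------------------------------------------------------------
# timelines


def _toy_subject():
    events = [
        EventRecord("A", T0, "ADMIT/HOSPITAL"),
        EventRecord("A", T0 + timedelta(minutes=10), "LAB/x", 55.0),
    ]
    statics = SubjectStatics("A", age_at_start=46)
    return events, statics


def test_build_timeline_composes_statics_interval_code_quantile():
    events, statics = _toy_subject()
    qm = fit_quantiles(_lab_events(range(1, 101)))
    vocab = Vocabulary()
    tl = build_timeline(events, statics, vocab, qm)
    toks = [vocab.token(t) for t in tl.tokens]
    assert toks[:2] == ["Q5", "Q7"]
    assert toks[6:] == ["ADMIT/HOSPITAL", "INTERVAL/I1", "LAB/x", "Q6", "META/TIMELINE_END"]
    # metadata links tokens to events and wall clock
    assert tl.event_index[6] == 0 and tl.event_index[8] == 1
    assert tl.time_min[8] == 10.0


def test_events_three_minutes_apart_emit_no_interval_token():
    events = [
        EventRecord("A", T0, "ADMIT/HOSPITAL"),
        EventRecord("A", T0 + timedelta(minutes=3), "DISCHARGE/HOSPITAL"),
    ]
    vocab = Vocabulary()
    tl = build_timeline(events, SubjectStatics("A", age_at_start=20), vocab, fit_quantiles([]))
    toks = [vocab.token(t) for t in tl.tokens]
    assert not any(t.startswith("INTERVAL") for t in toks)


def test_subject_with_no_events_excluded_and_counted():
    statics = {"A": SubjectStatics("A", age_at_start=20)}
    timelines, _, n_excluded = tokenize_corpus({}, statics, fit_quantiles([]))
    assert timelines == [] and n_excluded == 1


def test_timeline_build_is_deterministic(small_cohort):
    _, events, statics, _ = small_cohort
    qm = fit_quantiles(ev for evs in events.values() for ev in evs)
    t1, v1, _ = tokenize_corpus(events, statics, qm)
    t2, v2, _ = tokenize_corpus(events, statics, qm)
    assert len(v1) == len(v2)
    for a, b in zip(t1, t2):
        np.testing.assert_array_equal(a.tokens, b.tokens)


def test_corpus_tokens_per_event_between_1_and_7(small_tokenized):
    timelines, _, _, _ = small_tokenized
    for tl in timelines:
        idx = tl.event_index[tl.event_index >= 0]
        _, counts = np.unique(idx, return_counts=True)
        assert counts.min() >= 1 and counts.max() <= 7


def test_event_times_non_decreasing_along_sequence(small_tokenized):
    timelines, _, _, _ = small_tokenized
    for tl in timelines:
        assert np.all(np.diff(tl.time_min) >= 0)


def test_decode_covers_every_token_class(small_tokenized):
    timelines, vocab, _, _ = small_tokenized
    lines = decode(timelines[0].tokens, vocab)
    assert len(lines) == len(timelines[0].tokens)
    assert all(":" in line for line in lines)


def test_vocabulary_and_timelines_round_trip(tmp_path, small_tokenized):
    timelines, vocab, _, _ = small_tokenized
    vocab.save(tmp_path / "vocab.tsv")
    back = Vocabulary.load(tmp_path / "vocab.tsv")
    assert all(back.token(i) == vocab.token(i) for i in range(len(vocab)))
    save_timelines(timelines[:5], tmp_path / "tl.jsonl")
    loaded = load_timelines(tmp_path / "tl.jsonl")
    for a, b in zip(timelines[:5], loaded):
        assert a.subject_id == b.subject_id
        np.testing.assert_array_equal(a.tokens, b.tokens)
        np.testing.assert_allclose(a.time_min, b.time_min)
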