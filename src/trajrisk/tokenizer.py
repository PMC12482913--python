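"""Patient health timeline (PHT) construction.

A PHT renders a patient's entire record as one chronological token
sequence: a static-attribute block (age digits, gender, marital status,
race, BMI class), then for each clinical event an optional time-interval
token followed by the event's code tokens and, for numeric codes, a decile
(quantile) token.

Encoding rules
--------------
* Elapsed time between consecutive events is tokenized into 19 interval
  bins on a geometric ladder from 5 minutes to 5+ years; gaps under
  5 minutes emit no token.
* Continuous values are encoded against per-code empirical deciles into
  ten quantile tokens Q1..Q10 (Q9 = 80th-90th percentile).
* Diagnostic/procedural codes are decomposed hierarchically: ICD-10-PCS
  one token per character (7), ICD-10-CM category + extension characters
  (1-5), ATC one token per level (1-5).  No event yields more than 7
  code/value tokens.
* Ages 0-99 reuse quantile tokens digit-wise: digit d -> Q(d+1), so a
  46-year-old encodes as Q5 then Q7.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .meds_io import UNKNOWN, EventRecord, SubjectStatics

# ---------------------------------------------------------------------------
# interval bins

_MIN, _H, _D, _W = 1, 60, 1440, 10080
_MO, _Y = 30 * _D, 365 * _D

#: Lower edges (minutes) of the 19 interval bins; the last bin is open-ended.
INTERVAL_EDGES_MIN: tuple[float, ...] = (
    5, 15, 45, 90, 3 * _H, 6 * _H, 12 * _H, _D, 2 * _D, 4 * _D, _W,
    2 * _W, _MO, 2 * _MO, 3 * _MO, 6 * _MO, _Y, 2 * _Y, 5 * _Y,
)
N_INTERVAL_BINS = len(INTERVAL_EDGES_MIN)  # 19
MIN_INTERVAL_MIN = INTERVAL_EDGES_MIN[0]  # 5-minute floor

_INTERVAL_LABELS = (
    "5m-15m", "15m-45m", "45m-1.5h", "1.5h-3h", "3h-6h", "6h-12h", "12h-1d",
    "1d-2d", "2d-4d", "4d-1w", "1w-2w", "2w-1mo", "1mo-2mo", "2mo-3mo",
    "3mo-6mo", "6mo-1y", "1y-2y", "2y-5y", ">=5y",
)

N_QUANTILES = 10
MAX_TOKENS_PER_EVENT = 7

#: Schemes whose events carry a numeric value encoded as a quantile token.
NUMERIC_SCHEMES = frozenset({"LAB", "VITAL"})
#: Single-token special events (admissions, transfers, registrations ...).
SPECIAL_SCHEMES = frozenset(
    {"ADMIT", "DISCHARGE", "ICU_ADMIT", "DEATH", "ED_REG", "ED_OUT"}
)

TIMELINE_END = "META/TIMELINE_END"

_BMI_EDGES = (18.5, 25.0, 30.0)
_BMI_LABELS = ("underweight", "normal", "overweight", "obese")


def interval_token(elapsed_minutes: float) -> str | None:
    """Map a non-negative gap to its interval token, or None under 5 minutes."""
    if elapsed_minutes < 0:
        raise ValueError("negative elapsed time: events out of order")
    if elapsed_minutes < MIN_INTERVAL_MIN:
        return None
    k = int(np.searchsorted(INTERVAL_EDGES_MIN, elapsed_minutes, side="right"))
    return f"INTERVAL/I{k}"


def interval_bin_range(k: int) -> str:
    """Human-readable range of interval bin k (1-based)."""
    return _INTERVAL_LABELS[k - 1]


def interval_representative_minutes(k: int) -> float:
    """Representative duration of bin k: geometric midpoint of its edges.

    The open-ended top bin uses twice its lower edge.  Simulation clocks sum
    these representatives over generated interval tokens.
    """
    lo = INTERVAL_EDGES_MIN[k - 1]
    hi = INTERVAL_EDGES_MIN[k] if k < N_INTERVAL_BINS else 4 * lo
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# quantile model


@dataclass
class QuantileModel:
    """Per-code empirical decile edges fitted on the training split.

    ``edges[code]`` holds 9 non-decreasing cut points; codes with fewer than
    ``fit_min`` training observations fall back to pooled edges for their
    scheme (code class), recorded in ``fallback_edges``.
    """

    edges: dict[str, np.ndarray] = field(default_factory=dict)
    fallback_edges: dict[str, np.ndarray] = field(default_factory=dict)
    n_obs: dict[str, int] = field(default_factory=dict)
    fit_min: int = 20

    def edges_for(self, code: str) -> np.ndarray | None:
        e = self.edges.get(code)
        if e is not None:
            return e
        return self.fallback_edges.get(code.split("/", 1)[0])

    def save(self, path: str | Path) -> None:
        payload = {
            "fit_min": self.fit_min,
            "edges": {c: e.tolist() for c, e in self.edges.items()},
            "fallback_edges": {c: e.tolist() for c, e in self.fallback_edges.items()},
            "n_obs": self.n_obs,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "QuantileModel":
        d = json.loads(Path(path).read_text())
        return cls(
            edges={c: np.asarray(e) for c, e in d["edges"].items()},
            fallback_edges={c: np.asarray(e) for c, e in d["fallback_edges"].items()},
            n_obs={c: int(n) for c, n in d["n_obs"].items()},
            fit_min=int(d["fit_min"]),
        )


def fit_quantiles(
    training_events: Iterable[EventRecord], fit_min: int = 20
) -> QuantileModel:
    """Fit per-code decile edges (empirical CDF, linear interpolation).

    Only the training split may be passed here; applying edges fitted on test
    data would leak outcome information into the encoding.
    """
    by_code: dict[str, list[float]] = {}
    for ev in training_events:
        if ev.numeric_value is not None and np.isfinite(ev.numeric_value):
            by_code.setdefault(ev.code, []).append(float(ev.numeric_value))

    q = np.arange(1, N_QUANTILES) / N_QUANTILES
    model = QuantileModel(fit_min=fit_min)
    by_scheme: dict[str, list[float]] = {}
    for code, vals in sorted(by_code.items()):
        model.n_obs[code] = len(vals)
        by_scheme.setdefault(code.split("/", 1)[0], []).extend(vals)
        if len(vals) >= fit_min:
            model.edges[code] = np.quantile(np.asarray(vals), q)
    for scheme, vals in sorted(by_scheme.items()):
        if vals:
            model.fallback_edges[scheme] = np.quantile(np.asarray(vals), q)
    return model


def encode_value(code: str, value: float, model: QuantileModel) -> str | None:
    """Decile token for ``value`` under ``code``'s training edges.

    A value equal to an edge goes to the upper bin; values outside the
    training range clamp to Q1/Q10; a degenerate (constant) training
    distribution maps everything to Q1.  NaN emits no token.
    """
    if value is None or not np.isfinite(value):
        return None
    edges = model.edges_for(code)
    if edges is None:
        return None
    if edges[0] == edges[-1]:  # constant training distribution
        return "Q1"
    k = 1 + int(np.searchsorted(edges, value, side="right"))
    return f"Q{min(max(k, 1), N_QUANTILES)}"


# ---------------------------------------------------------------------------
# code decomposition


def decompose_code(code: str) -> list[str]:
    """Break an event code into 1..7 hierarchical code tokens.

    ICD-10-PCS: positional, one token per character (7).  ICD-10-CM:
    3-character category token then one token per extension character.
    ATC: one cumulative token per hierarchy level (1/3/4/5/7 characters).
    Lab/vital/special codes: a single token.  Unrecognized schemes fall back
    to a single opaque token with a warning.
    """
    scheme, _, rest = code.partition("/")
    rest = rest.strip()
    if scheme in SPECIAL_SCHEMES or scheme in NUMERIC_SCHEMES or scheme == "META":
        return [code]
    if scheme == "ICD10PCS":
        if len(rest) != 7:
            warnings.warn(f"malformed ICD-10-PCS code {code!r}; kept opaque")
            return [code]
        return [f"ICD10PCS/p{i + 1}={ch}" for i, ch in enumerate(rest)]
    if scheme == "ICD10CM":
        cat, ext = rest[:3], rest[3:].replace(".", "")
        toks = [f"ICD10CM/{cat}"]
        toks += [f"ICD10CM/x{i + 4}={ch}" for i, ch in enumerate(ext[:4])]
        return toks
    if scheme == "ATC":
        # hierarchy levels end at character counts 1, 3, 4, 5, 7
        toks = [f"ATC/{rest[:n]}" for n in (1, 3, 4, 5, 7) if len(rest) >= n]
        return toks or [code]
    warnings.warn(f"unknown code scheme {scheme!r}; kept opaque")
    return [code]


# ---------------------------------------------------------------------------
# statics


def encode_statics(statics: SubjectStatics) -> list[str]:
    """Fixed-order static block: [age-tens, age-units, gender, marital, race, bmi].

    Age digits reuse quantile tokens (digit d -> Q(d+1)); BMI is classed into
    standard clinical categories; missing attributes use their 'unknown' token.
    """
    age = statics.age_at_start
    if not 0 <= age <= 99:
        raise ValueError(f"age {age} outside [0, 99]")
    tokens = [f"Q{age // 10 + 1}", f"Q{age % 10 + 1}"]
    tokens.append(f"STATIC/GENDER={statics.gender}")
    tokens.append(f"STATIC/MARITAL={statics.marital_status}")
    tokens.append(f"STATIC/RACE={statics.race}")
    if statics.bmi is None or not np.isfinite(statics.bmi):
        tokens.append(f"STATIC/BMI={UNKNOWN}")
    else:
        b = int(np.searchsorted(_BMI_EDGES, statics.bmi, side="right"))
        tokens.append(f"STATIC/BMI={_BMI_LABELS[b]}")
    return tokens


# ---------------------------------------------------------------------------
# vocabulary


class Vocabulary:
    """Bijection between token strings and dense integer ids in [0, V)."""

    def __init__(self, tokens: Sequence[str] = ()) -> None:
        self._id_of: dict[str, int] = {}
        self._tok_of: list[str] = []
        for t in tokens:
            self.add(t)

    def add(self, token: str) -> int:
        tid = self._id_of.get(token)
        if tid is None:
            tid = len(self._tok_of)
            self._id_of[token] = tid
            self._tok_of.append(token)
        return tid

    def id(self, token: str) -> int:
        return self._id_of[token]

    def token(self, tid: int) -> str:
        return self._tok_of[tid]

    def __contains__(self, token: str) -> bool:
        return token in self._id_of

    def __len__(self) -> int:
        return len(self._tok_of)

    def ids(self, tokens: Iterable[str]) -> list[int]:
        return [self._id_of[t] for t in tokens]

    def ids_matching(self, predicate) -> set[int]:
        return {i for i, t in enumerate(self._tok_of) if predicate(t)}

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, t in enumerate(self._tok_of):
                fh.write(f"{t}\t{i}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        vocab = cls()
        with open(path) as fh:
            for line in fh:
                tok, tid = line.rstrip("\n").split("\t")
                assert vocab.add(tok) == int(tid), "vocabulary ids must be dense"
        return vocab


def token_class(token: str) -> str:
    """Token class: quantile, interval, static, special, code or meta."""
    if token.startswith("Q") and token[1:].isdigit():
        return "quantile"
    scheme = token.split("/", 1)[0]
    if scheme == "INTERVAL":
        return "interval"
    if scheme == "STATIC":
        return "static"
    if scheme in SPECIAL_SCHEMES:
        return "special"
    if scheme == "META":
        return "meta"
    return "code"


# ---------------------------------------------------------------------------
# timelines


@dataclass
class PatientHealthTimeline:
    """A subject's record as one chronological token-id sequence.

    ``event_index[j]`` is the index (into the subject's event list) of the
    event that emitted token j, or -1 for static/meta tokens; ``time_min[j]``
    is that event's wall clock in minutes since the first event.
    """

    subject_id: str
    tokens: np.ndarray  # int64 ids
    event_index: np.ndarray  # int64
    time_min: np.ndarray  # float64, minutes since first event

    def __len__(self) -> int:
        return len(self.tokens)


def build_timeline(
    subject_events: Sequence[EventRecord],
    statics: SubjectStatics,
    vocabulary: Vocabulary,
    quantile_model: QuantileModel,
    *,
    freeze_vocabulary: bool = False,
    append_end_token: bool = True,
) -> PatientHealthTimeline | None:
    """Tokenize one subject: statics block, then interval/code/quantile tokens.

    Returns None when the subject has no tokenizable events (the caller
    counts exclusions).  With ``freeze_vocabulary`` unseen tokens raise
    instead of growing the vocabulary (inference mode).
    """
    toks: list[str] = []
    ev_idx: list[int] = []
    times: list[float] = []

    for t in encode_statics(statics):
        toks.append(t)
        ev_idx.append(-1)
        times.append(0.0)

    n_event_tokens = 0
    prev_time: float | None = None
    t0 = subject_events[0].time if subject_events else None
    for i, ev in enumerate(subject_events):
        code_tokens = decompose_code(ev.code)
        t_min = (ev.time - t0).total_seconds() / 60.0
        emitted: list[str] = []
        if prev_time is not None:
            gap = interval_token(t_min - prev_time)
            if gap is not None:
                emitted.append(gap)
        emitted.extend(code_tokens)
        scheme = ev.code.split("/", 1)[0]
        if scheme in NUMERIC_SCHEMES and ev.numeric_value is not None:
            q = encode_value(ev.code, ev.numeric_value, quantile_model)
            if q is not None:
                emitted.append(q)
        for t in emitted:
            toks.append(t)
            ev_idx.append(i)
            times.append(t_min)
        n_event_tokens += len(emitted)
        prev_time = t_min

    if n_event_tokens == 0:
        return None

    if append_end_token:
        toks.append(TIMELINE_END)
        ev_idx.append(-1)
        times.append(times[-1])

    if freeze_vocabulary:
        ids = [vocabulary.id(t) for t in toks]
    else:
        ids = [vocabulary.add(t) for t in toks]
    return PatientHealthTimeline(
        subject_id=statics.subject_id,
        tokens=np.asarray(ids, dtype=np.int64),
        event_index=np.asarray(ev_idx, dtype=np.int64),
        time_min=np.asarray(times, dtype=np.float64),
    )


def tokenize_corpus(
    events_by_subject: Mapping[str, Sequence[EventRecord]],
    statics_by_subject: Mapping[str, SubjectStatics],
    quantile_model: QuantileModel,
    vocabulary: Vocabulary | None = None,
    *,
    freeze_vocabulary: bool = False,
    on_unseen: str = "error",
) -> tuple[list[PatientHealthTimeline], Vocabulary, int]:
    """Tokenize a cohort; returns (timelines, vocabulary, n_excluded).

    Subjects with no usable data after tokenization are excluded and
    counted.  With a frozen vocabulary, a subject whose timeline contains a
    token unseen in training raises (``on_unseen='error'``) or is excluded
    and counted (``on_unseen='exclude'``).
    """
    vocab = vocabulary if vocabulary is not None else Vocabulary()
    timelines: list[PatientHealthTimeline] = []
    n_excluded = 0
    for sid in sorted(statics_by_subject):
        try:
            pht = build_timeline(
                events_by_subject.get(sid, []),
                statics_by_subject[sid],
                vocab,
                quantile_model,
                freeze_vocabulary=freeze_vocabulary,
            )
        except KeyError:
            if on_unseen == "exclude":
                n_excluded += 1
                continue
            raise
        if pht is None:
            n_excluded += 1
        else:
            timelines.append(pht)
    return timelines, vocab, n_excluded


# ---------------------------------------------------------------------------
# decoding


def decode_token(token: str) -> str:
    """Human-readable description of one token string."""
    cls = token_class(token)
    if cls == "quantile":
        k = int(token[1:])
        return f"{token}: {(k - 1) * 10}th–{k * 10}th percentile"
    if cls == "interval":
        k = int(token.split("/I")[1])
        return f"{token}: time gap {interval_bin_range(k)}"
    if cls == "static":
        return f"{token}: static attribute"
    if cls == "special":
        return f"{token}: clinical event"
    if cls == "meta":
        return f"{token}: timeline marker"
    return f"{token}: code token"


def decode(tokens: Sequence[int], vocabulary: Vocabulary) -> list[str]:
    """Render a token-id sequence as one description line per token."""
    return [decode_token(vocabulary.token(int(t))) for t in tokens]


# ---------------------------------------------------------------------------
# timeline serialization (JSON lines; round-trips exactly)


def save_timelines(timelines: Iterable[PatientHealthTimeline], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tl in timelines:
            fh.write(
                json.dumps(
                    {
                        "subject_id": tl.subject_id,
                        "tokens": tl.tokens.tolist(),
                        "event_index": tl.event_index.tolist(),
                        "time_min": tl.time_min.tolist(),
                    }
                )
                + "\n"
            )


def load_timelines(path: str | Path) -> list[PatientHealthTimeline]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(
                PatientHealthTimeline(
                    subject_id=d["subject_id"],
                    tokens=np.asarray(d["tokens"], dtype=np.int64),
                    event_index=np.asarray(d["event_index"], dtype=np.int64),
                    time_min=np.asarray(d["time_min"], dtype=np.float64),
                )
            )
    return out
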