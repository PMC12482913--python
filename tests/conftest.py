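"""Shared fixtures: tiny synthetic cohorts and the tabulated-Markov oracle."""

from __future__ import annotations

import numpy as np
import pytest

from trajrisk.sequence_model import TabulatedMarkovModel
from trajrisk.synthetic_ehr import CohortConfig, simulate_cohort
from trajrisk.tokenizer import fit_quantiles, tokenize_corpus

# reduced state alphabet for the hand-built oracle chains
CTX, WARD_T, ICU_T, DEATH_T, DISCH_T = 0, 1, 2, 3, 4


def example_chain() -> np.ndarray:
    """Ward -> death 0.2 / ICU 0.3 / discharge 0.5; ICU -> death 0.5 /
    discharge 0.5.  By path enumeration P(death) = 0.2 + 0.3 * 0.5 = 0.35
    and P(ICU) = 0.3."""
    table = np.zeros((5, 5))
    table[CTX, WARD_T] = 1.0
    table[WARD_T, [DEATH_T, ICU_T, DISCH_T]] = [0.2, 0.3, 0.5]
    table[ICU_T, [DEATH_T, DISCH_T]] = [0.5, 0.5]
    table[DEATH_T, DEATH_T] = 1.0
    table[DISCH_T, DISCH_T] = 1.0
    return table


@pytest.fixture(scope="session")
def oracle_model() -> TabulatedMarkovModel:
    return TabulatedMarkovModel(example_chain())


@pytest.fixture(scope="session")
def small_cohort():
    """300-subject synthetic cohort with ground truth (session-cached)."""
    config = CohortConfig(n_subjects=300, seed=42)
    events, statics, truth = simulate_cohort(config)
    return config, events, statics, truth


@pytest.fixture(scope="session")
def small_tokenized(small_cohort):
    config, events, statics, truth = small_cohort
    qm = fit_quantiles(ev for evs in events.values() for ev in evs)
    timelines, vocab, n_excluded = tokenize_corpus(events, statics, qm)
    return timelines, vocab, qm, n_excluded
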