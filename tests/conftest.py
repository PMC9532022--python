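"""Shared fixtures: synthetic cohorts at the study's default conditions.

The heavyweight session fixture builds ten processed default cohorts (200
subjects x 5 templates each); tests that only need a small cohort use
``small_processed``.
"""

from __future__ import annotations

import numpy as np
import pytest

from crowdtrace.preprocess import process_cohort
from crowdtrace.synthetic import SyntheticConfig, generate_cohort

N_DEFAULT_SEEDS = 10


@pytest.fixture(scope="session")
def default_processed():
    """Processed default cohorts for seeds 0..9 (raw traces discarded)."""
    out = {}
    for seed in range(N_DEFAULT_SEEDS):
        cohort = generate_cohort(SyntheticConfig(seed=seed))
        out[seed] = process_cohort(cohort)
        del cohort
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects, two templates — cheap cohort for unit tests."""
    cfg = SyntheticConfig(
        n_subjects=30, seed=42, templates=("ellipse", "three_petal")
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    return process_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
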