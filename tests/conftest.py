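"""Shared fixtures: synthetic voices and a session-wide study cohort.

The cohort (40 HC + 40 PD at the generator defaults) and its feature
tables are expensive, so they are computed once per session and shared by
the evaluation and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from pdvoice import synth
from pdvoice.pipeline import cohort_feature_tables
from pdvoice.synth import PhonationParams

STANDARD_FORMANTS = (700.0, 1220.0, 2600.0, 3400.0)
STANDARD_BANDWIDTHS = (80.0, 100.0, 120.0, 150.0)


def make_params(
    f0_mean=120.0,
    f0_sd=1.0,
    jitter_pct=1.0,
    shimmer_pct=3.0,
    hnr_target=25.0,
    duration=2.0,
    formant_freqs=STANDARD_FORMANTS,
    formant_bandwidths=STANDARD_BANDWIDTHS,
) -> PhonationParams:
    return PhonationParams(
        f0_mean=f0_mean,
        f0_sd=f0_sd,
        jitter_pct=jitter_pct,
        shimmer_pct=shimmer_pct,
        hnr_target=hnr_target,
        formant_freqs=formant_freqs,
        formant_bandwidths=formant_bandwidths,
        duration=duration,
    )


def make_voice(seed=0, telephone=True, **kwargs):
    return synth.synthesize_vowel(make_params(**kwargs), rng_seed=seed, telephone=telephone)


@pytest.fixture(scope="session")
def study_cohort():
    """40 + 40 synthetic subjects at the generator defaults."""
    return synth.generate_cohort(40, 40, rng_seed=2024)


@pytest.fixture(scope="session")
def cohort_tables(study_cohort):
    """(acoustic table, spectral matrices, spectrograms) of the cohort."""
    return cohort_feature_tables(study_cohort)


@pytest.fixture(scope="session")
def cohort_labels(cohort_tables):
    table, _, _ = cohort_tables
    return (table["group"] == "PD").astype(int).to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
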