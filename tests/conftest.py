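import numpy as np
import pytest

import eegslope as es

#: Compact montage for fast end-to-end tests: the 9 high-priority
#: electrodes (covering all three block-validation groups) plus a few
#: non-visual electrodes so the common-bad 10% rule has an "other" set,
#: plus two frontal electrodes as blink targets.
SMALL_MONTAGE = es.ELECTRODE_GROUPS["high_priority"] + (
    "P4", "P5", "P6", "P7", "CP1", "CP2", "Pz", "Fp1", "Fp2",
)


@pytest.fixture(scope="session")
def small_montage():
    return SMALL_MONTAGE


@pytest.fixture(scope="session")
def clean_cohort_config():
    return es.CohortConfig(n_trials=48, subject_chi_sd=0.0)


@pytest.fixture(scope="session")
def clean_subject(clean_cohort_config, small_montage):
    """One artifact-free eyes-open subject at age 70."""
    return es.simulate_subject(
        70.0,
        "eyes_open",
        clean_cohort_config,
        es.ArtifactConfig.clean(),
        small_montage,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_subject_analysis(clean_subject):
    return es.analyze_subject(clean_subject, profile_method="line")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
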