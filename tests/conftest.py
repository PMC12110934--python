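import numpy as np
import pandas as pd
import pytest

import mrdflow as mf


@pytest.fixture(scope="session")
def profiles():
    return mf.load_table1_fixture()


@pytest.fixture(scope="session")
def thresholds():
    return mf.ThresholdConfig()


@pytest.fixture(scope="session")
def pt8(profiles):
    """Pt#8: three LAIPs (CD25 67 / CD7 63 / CD4 54), partial expression."""
    return profiles[7]


@pytest.fixture(scope="session")
def pt8_diagnosis(pt8):
    events, truth = mf.simulate_diagnosis_from_profile(pt8, n_events=80_000, seed=8)
    return mf.preprocess(events), truth


@pytest.fixture(scope="session")
def pt8_template(pt8, pt8_diagnosis):
    events, _ = pt8_diagnosis
    laip = mf.classify_patient(pt8)
    return mf.fit_template(events, pt8, tracking_marker=laip.tracking_marker)


@pytest.fixture(scope="session")
def cohort():
    """The full-size synthetic study: 25 patients x 5 follow-up samples."""
    return mf.simulate_cohort(
        n_patients=25, samples_per_patient=5, seed=20_260_920,
        n_events=120_000, diagnosis_n_events=80_000,
    )


@pytest.fixture(scope="session")
def cohort_results(cohort):
    return mf.run_cohort(cohort)
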