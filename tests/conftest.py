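import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_profiles() -> pd.DataFrame:
    """Quantified profiles of one default synthetic cohort (36 vs 31)."""
    from sfpanel import SimulationConfig, quantify_profiles, simulate_ct_dataset

    return quantify_profiles(simulate_ct_dataset(SimulationConfig(seed=1)))


@pytest.fixture(scope="session")
def patient_records():
    """The bundled 31-patient clinical table."""
    from sfpanel import load_patient_table

    return load_patient_table()
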