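import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gdrecon import GeneratorConfig, generate_cohort

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config synthetic cohort (n=49), shared across tests."""
    return generate_cohort(GeneratorConfig(), seed=1)


@pytest.fixture()
def tiny_panel():
    """Three timepoints for one patient, hand-checkable ratios."""
    return pd.DataFrame({
        "patient_id": ["P1"] * 3,
        "day": ["15", "30", "60"],
        "ab_t": [100.0, 100.0, 100.0],
        "vd2": [100.0, 100.0, 400.0],
        "gd_t": [100.0, 100.0, 400.0],
        "vd1": [0.0, 0.0, 0.0],
    })


def make_survival_frame(rows):
    """rows: list of (time, status) tuples -> arrays."""
    t = np.array([r[0] for r in rows], dtype=float)
    s = np.array([r[1] for r in rows], dtype=int)
    return t, s
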