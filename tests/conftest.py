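import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_wells_frame():
    """Two models, two drugs, duplicate wells plus vehicle controls."""
    rows = []
    for model, flux in (("mA", 1.0e7), ("mB", 2.0e7)):
        for rep in (1, 2):
            rows.append((model, "DMSO", 0.0, rep, flux, "vehicle"))
        for drug, viab in (("d1", 50.0), ("d2", 150.0)):
            for rep in (1, 2):
                rows.append((model, drug, 10.0, rep, flux * viab / 100.0, "treated"))
    return pd.DataFrame(
        rows, columns=["model", "drug", "dose_uM", "replicate", "signal", "role"]
    )


@pytest.fixture
def seven_doses():
    return (0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0)
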