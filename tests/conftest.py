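import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_wells():
    """Two tiny plates with a known structure: one inhibitor, one control."""
    rows = []
    for plate, scale in (("P1", 1.0), ("P2", 3.0)):
        for i, (cdna, ratio) in enumerate(
            [("GFP", 1.0), ("GFP", 1.0), ("A", 0.5), ("B", 1.0), ("C", 1.0), ("D", 1.0)]
        ):
            for col in range(1, 9):
                rows.append(
                    {
                        "plate": plate,
                        "row": i + 1,
                        "col": col,
                        "cdna": cdna,
                        "treatment": "SAG",
                        "fluc": ratio * scale * 100.0,
                        "rluc": 100.0,
                    }
                )
    return pd.DataFrame(rows)
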