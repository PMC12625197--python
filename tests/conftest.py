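import numpy as np
import pandas as pd
import pytest

from nulisapipe import AnalyteMatrix, CohortConfig, generate_cohort


@pytest.fixture()
def small_cohort():
    """A seeded 5x50 cohort with modest planted AD effects on two analytes."""
    em = np.zeros((12, 4))
    em[0, 0] = 1.0  # P000 up in AD
    em[1, 0] = -0.8  # P001 down in AD
    cfg = CohortConfig(
        n_per_group=50,
        n_analytes=12,
        effect_matrix=em,
        missing_rate=0.02,
        outlier_rate=0.0,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def tiny_matrix():
    vals = pd.DataFrame(
        np.arange(12, dtype=float).reshape(4, 3) + 1.0,
        index=[f"s{i}" for i in range(4)],
        columns=["a", "b", "c"],
    )
    return AnalyteMatrix(vals, scale="log2_npq")
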