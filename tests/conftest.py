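import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mpascore as mp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel_matrix():
    """3 signature + 2 housekeeping + 2 negative-control genes, 4 samples."""
    rng = np.random.default_rng(0)
    genes = ["DUSP6", "SPRY2", "ETV4", "MLH1", "CLTC", "NEG_A", "NEG_B"]
    data = pd.DataFrame(
        np.vstack([
            rng.integers(20, 400, size=(5, 4)),  # expressed genes
            rng.integers(2, 9, size=(2, 4)),     # negative-control probes
        ]).astype(float),
        index=genes,
        columns=[f"S{i}" for i in range(4)],
    )
    return mp.ExpressionMatrix(data=data, platform="panel", state="raw")


@pytest.fixture
def zscored_matrix(rng):
    """Random 12-gene x 8-sample matrix taken through the rnaseq chain."""
    genes = list(mp.MPAS_GENES) + ["MLH1", "CLTC"]
    data = pd.DataFrame(
        rng.lognormal(3, 1, size=(12, 8)), index=genes, columns=[f"S{i}" for i in range(8)]
    )
    m = mp.ExpressionMatrix(data=data, platform="rnaseq", state="raw")
    return mp.zscore_genes(mp.log_transform(m))


@pytest.fixture
def default_cohort():
    return mp.simulate_cohort(mp.CohortConfig(n_samples=200), seed=1, with_clinical=False)
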