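import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tamtil import synthetic as syn

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A modest cohort shared by read-only tests (80 samples, 1,000 CpGs)."""
    cfg = syn.CohortConfig(
        n_samples=80, n_cpgs=1000, n_markers_per_type=(50, 20), seed=11
    )
    refs, beta, clinical, truth = syn.simulate_study(cfg)
    return {"config": cfg, "refs": refs, "beta": beta,
            "clinical": clinical, "truth": truth}


def make_beta(values, cpgs=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    cpgs = cpgs or [f"cg{i:07d}" for i in range(m)]
    samples = samples or [f"S{j}" for j in range(n)]
    return pd.DataFrame(values, index=pd.Index(cpgs, name="cpg_id"), columns=samples)
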