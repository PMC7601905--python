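import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from saspsurv import SimulationConfig, generate_cohorts  # noqa: E402


@pytest.fixture(scope="session")
def default_cohorts():
    """Default three-cohort draw (seed 11): shared read-only fixture."""
    return generate_cohorts(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def null_cohorts():
    """Cohorts with no analyte loadings and no latent hazard effect."""
    return generate_cohorts(SimulationConfig(seed=12).null())


@pytest.fixture(scope="session")
def rtbt2(default_cohorts):
    return default_cohorts[0]


def tiny_instances(n_instances=40, max_n=8, seed=20):
    """Seeded random small survival instances with ties and censoring."""
    import numpy as np
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_instances):
        n = int(rng.integers(5, max_n + 1))
        # half-year rounding induces ties
        t = np.round(rng.exponential(2.0, n) * 2) / 2 + 0.5
        e = (rng.random(n) < 0.7).astype(int)
        if e.sum() < 2:
            e[rng.permutation(n)[:2]] = 1
        x = (rng.integers(0, 2, n).astype(float) if rng.random() < 0.3
             else np.round(rng.standard_normal(n), 2))
        if np.ptp(x) == 0:
            x[0] += 1.0
        out.append((t, e, x))
    return out
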