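import numpy as np
import pytest

import imputeqc as iq
from imputeqc.simulate import SIM_PAR_BOUNDARY
from imputeqc.vcf_io import RegionConfig


@pytest.fixture(scope="session")
def sim_region_config() -> RegionConfig:
    """Region rules matching the simulator's desk-scale coordinates."""
    return RegionConfig(par_boundary=SIM_PAR_BOUNDARY)


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic truth/imputed pair at study scale."""
    cfg = iq.SimulationConfig(seed=42, n_variants=1200)
    truth, panel = iq.simulate_truth(cfg)
    imputed = iq.simulate_imputation(truth, cfg)
    return cfg, truth, imputed


@pytest.fixture(scope="session")
def small_stats(small_sim):
    _, truth, imputed = small_sim
    return iq.compute_stats(truth, imputed)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def brute_force_pearson(x, y):
    """Independent textbook Pearson r: explicit sums, no numpy statistics."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return None
    return sxy / (sxx * syy) ** 0.5
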