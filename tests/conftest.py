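import numpy as np
import pytest

from sympmix.synthetic import GeneratorConfig, generate, simulate_cohort


@pytest.fixture(scope="session")
def single_factor_data():
    """Single-factor data with common loading 0.7, n = 5,000."""
    cfg = GeneratorConfig(n_subjects=5000, loadings=np.full(12, 0.7), seed=42)
    data, theta = generate(cfg)
    return data


@pytest.fixture(scope="session")
def independent_items_data():
    """Zero-loading (mutually independent) items, n = 2,000."""
    cfg = GeneratorConfig(n_subjects=2000, loadings=np.zeros(12), seed=43)
    data, _ = generate(cfg)
    return data


@pytest.fixture(scope="session")
def cohort_6000():
    """A study-scale cohort: n = 6,000, heterogeneous loadings 0.5-0.8,
    ~6% prevalence by calibrated sum-score cutoff."""
    cfg = GeneratorConfig(n_subjects=6000, target_prevalence=0.06, seed=11)
    return simulate_cohort(cfg)


def quintile_thresholds(n_items: int = 12) -> np.ndarray:
    """Standard-normal quintile cutpoints, identical across items."""
    from scipy.special import ndtri

    tau = ndtri(np.array([0.2, 0.4, 0.6, 0.8]))
    return np.tile(tau, (n_items, 1))
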