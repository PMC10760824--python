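import numpy as np
import pytest

from eptx import LinkSpec, PolymerSpec, RateSet


@pytest.fixture
def unit_theta_spec() -> PolymerSpec:
    """Chain whose stationary E-P distance scale is exactly 1:
    k_eff = 1/4 + 3/4 = 1 with D = gamma = 1."""
    return PolymerSpec(N=23, k_NN=1.0, k_EP=0.75, E=10, P=14)


@pytest.fixture
def free_chain_spec() -> PolymerSpec:
    """Same chain without the E-P spring (theta^2 = 4)."""
    return PolymerSpec(N=23, k_NN=1.0, k_EP=0.0, E=10, P=14)


@pytest.fixture
def fig2c_rates() -> RateSet:
    """Frozen-chromatin telegraph rates: scaled (3, 5, 10)."""
    return RateSet(alpha=0.30, beta=0.50, mu=1.0, delta=0.1)


@pytest.fixture
def timescale_link() -> LinkSpec:
    """Distance-modulated rates used in the timescale-regime comparisons."""
    return LinkSpec(
        alpha_min=0.30, alpha_max=0.60, mu_min=0.1, mu_max=3.0, beta=0.50,
        delta=0.1, mode="hill", n_h=2.0, d0=1.0,
    )


def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two pmfs on possibly different supports."""
    n = max(p.size, q.size)
    a = np.zeros(n)
    a[: p.size] = p
    b = np.zeros(n)
    b[: q.size] = q
    return 0.5 * float(np.abs(a - b).sum())


@pytest.fixture
def tv():
    return tv_distance
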