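"""Canonical study conditions used by the validation suite and examples.

These bundle the literature-anchored regime parameters (switching/transcription rates,
friction, E-P interaction strengths) with the package's fixed chain and link
constants, so every consumer (tests, reproduction script, examples) states
them once.  Rationale for the chosen constants is in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import PolymerSpec
from .link import LinkSpec

__all__ = [
    "TimescaleRegime",
    "FAST_REGIME",
    "SLOW_REGIME",
    "INTERMEDIATE_REGIME",
    "timescale_link",
    "modality_sweep_conditions",
    "trend_conditions",
]


def timescale_link() -> LinkSpec:
    """Distance-modulated rates of the timescale-regime comparisons:
    alpha in [0.30, 0.60], beta = 0.50, mu in [0.1, 3], delta = 0.1."""
    return LinkSpec(
        alpha_min=0.30, alpha_max=0.60, mu_min=0.1, mu_max=3.0, beta=0.50,
        delta=0.1, mode="hill", n_h=2.0, d0=1.0,
    )


@dataclass(frozen=True)
class TimescaleRegime:
    """One fast/slow/intermediate chromatin regime."""

    name: str
    gamma: float
    k_EP: float
    limit: str          # which analytic law the simulation should match
    tv_tolerance: float
    t_end: float

    def spec(self, compact: bool = True) -> PolymerSpec:
        """d_G = 4 chain; ``compact`` uses 2-monomer flanks (N = 9), which
        leaves the distance law unchanged and speeds the ensemble up."""
        return PolymerSpec.from_genomic_distance(
            4, k_NN=1.0, k_EP=self.k_EP, D=1.0, gamma=self.gamma, b=1.0,
            flank=2 if compact else 9,
        )


FAST_REGIME = TimescaleRegime("fast", gamma=0.1, k_EP=0.3, limit="fast",
                              tv_tolerance=0.05, t_end=60.0)
SLOW_REGIME = TimescaleRegime("slow", gamma=100.0, k_EP=0.1, limit="slow",
                              tv_tolerance=0.05, t_end=80.0)
INTERMEDIATE_REGIME = TimescaleRegime("intermediate", gamma=5.0, k_EP=0.3,
                                      limit="mixture", tv_tolerance=0.07,
                                      t_end=80.0)


def modality_sweep_conditions() -> tuple[PolymerSpec, LinkSpec, np.ndarray]:
    """Conditions of the k_EP modality sweep at d_G = 70: rates
    alpha in [0.06, 2], beta = 0.10, mu in [3, 9], delta = 0.1, gamma = 50,
    with the reconciled link constants n_h = 7, d0 = 18, d0_mu = 10 and
    encounter distance b = 1."""
    link = LinkSpec(
        alpha_min=0.06, alpha_max=2.0, mu_min=3.0, mu_max=9.0, beta=0.10,
        delta=0.1, mode="hill", n_h=7.0, d0=18.0, d0_mu=10.0,
    )
    spec = PolymerSpec.from_genomic_distance(
        70, k_NN=1.0, k_EP=0.001, D=1.0, gamma=50.0, b=1.0
    )
    return spec, link, np.geomspace(1e-3, 10.0, 60)


def trend_conditions() -> tuple[PolymerSpec, LinkSpec, list, list]:
    """Conditions of the mean/CV trend scans: rates alpha_min = 0.06,
    beta = 0.20, mu_max = 3, delta = 0.1, gamma = 50 completed with
    alpha_max = 2, mu_min = 0.3 and a gentle link (n_h = 2, d0 = 25);
    the d_G sweep holds k_EP = 0.001, the k_EP sweep holds d_G = 10."""
    link = LinkSpec(
        alpha_min=0.06, alpha_max=2.0, mu_min=0.3, mu_max=3.0, beta=0.20,
        delta=0.1, mode="hill", n_h=2.0, d0=25.0,
    )
    spec = PolymerSpec.from_genomic_distance(
        10, k_NN=1.0, k_EP=0.001, D=1.0, gamma=50.0, b=1.0
    )
    d_g_grid = [10, 20, 40, 80, 160]
    k_ep_grid = [0.1, 0.5, 2.5, 12.5, 62.5]
    return spec, link, d_g_grid, k_ep_grid
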