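"""Analytic stationary mRNA distributions under chromatin-gene coupling.

Timescale separation gives two solvable limits and an interpolation:

* fast chromatin (``p_fast``): the gene sees only the Maxwell-Boltzmann
  *average* of the distance-modulated rates, so the stationary law is
  Poisson-Beta at (<alpha~>, beta~, <mu~>);
* slow chromatin (``p_slow``): each cell's E-P distance is effectively
  frozen, so the stationary law is the Maxwell-Boltzmann mixture of
  conditional Poisson-Beta laws, integrated over d_S;
* intermediate (``p_stationary``): the convex mixture
  P = P_fast / (1 + omega) + omega P_slow / (1 + omega), where the scaling
  factor omega is the ratio of the smallest distance-variable transition
  rate to the maximum chromatin velocity
  V = (k_NN/d_G + k_EP) d_99 / (b gamma), with d_99 the 0.99 quantile of
  the distance law.

The module also provides moment/peak summaries (skewness, kurtosis, the
bimodality coefficient BC = 1/(K - S^2), origin/non-origin peak
classification) and parameter-plane scans of the modality classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain import PolymerSpec, contact_probability, ep_equilibrium
from .errors import InputError
from .link import LinkSpec, averaged_rates
from .telegraph import Pmf, default_x_max, poisson_beta_pmf, poisson_beta_pmf_batch

__all__ = [
    "MixtureWeights",
    "SummaryStats",
    "PhaseDiagram",
    "omega",
    "p_fast",
    "p_slow",
    "p_stationary",
    "summarize_pmf",
    "phase_diagram",
    "mode_sequence",
    "scan_expression",
]


@dataclass(frozen=True)
class MixtureWeights:
    """Fast/slow interpolation weights.

    ``weight_fast`` = 1/(1+omega) multiplies the fast-limit law and
    ``weight_slow`` = omega/(1+omega) the slow-limit law.
    """

    omega: float
    v_max: float
    d_s99: float

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise InputError("omega must be non-negative")

    @property
    def weight_fast(self) -> float:
        return 1.0 / (1.0 + self.omega)

    @property
    def weight_slow(self) -> float:
        return self.omega / (1.0 + self.omega)


def omega(spec: PolymerSpec, link: LinkSpec) -> MixtureWeights:
    """Timescale-separation scaling factor for the mixture law."""
    law = ep_equilibrium(spec)
    d99 = law.quantile(0.99)
    v_max = spec.k_eff * d99 / (spec.b * spec.gamma)
    om = min(link.alpha_min, link.mu_min) / v_max
    return MixtureWeights(omega=om, v_max=v_max, d_s99=d99)


def _auto_x_max(link: LinkSpec) -> int:
    return default_x_max(link.mu_max / link.delta)


def p_fast(spec: PolymerSpec, link: LinkSpec, x_max: int | None = None) -> Pmf:
    """Fast-chromatin limit: Poisson-Beta at the distance-averaged rates."""
    if x_max is None:
        x_max = _auto_x_max(link)
    law = ep_equilibrium(spec)
    rates = averaged_rates(link, law)
    return poisson_beta_pmf(rates, x_max)


def p_slow(
    spec: PolymerSpec,
    link: LinkSpec,
    x_max: int | None = None,
    n_nodes: int = 96,
) -> Pmf:
    """Slow-chromatin limit: Maxwell-Boltzmann mixture of conditional
    Poisson-Beta laws, by fixed-node Gauss-Legendre quadrature over d_S.
    """
    if n_nodes < 8:
        raise InputError("n_nodes must be >= 8")
    if x_max is None:
        x_max = _auto_x_max(link)
    law = ep_equilibrium(spec)
    upper = law.quantile(1.0 - 1e-8)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    d = 0.5 * upper * (nodes + 1.0)
    w = 0.5 * upper * weights * law.pdf(d)
    w = w / w.sum()  # absorb the 1e-8 truncation so the mixture is proper
    alpha = np.asarray(link.alpha(d)) / link.delta
    mu = np.asarray(link.mu(d)) / link.delta
    P = poisson_beta_pmf_batch(alpha, link.beta / link.delta, mu, x_max)
    return Pmf(w @ P)


def p_stationary(
    spec: PolymerSpec,
    link: LinkSpec,
    x_max: int | None = None,
    n_nodes: int = 96,
) -> tuple[Pmf, MixtureWeights]:
    """Interpolated stationary law: convex fast/slow mixture with weights
    set by the omega scaling factor."""
    if x_max is None:
        x_max = _auto_x_max(link)
    mw = omega(spec, link)
    pf = p_fast(spec, link, x_max)
    ps = p_slow(spec, link, x_max, n_nodes)
    return Pmf(mw.weight_fast * pf.p + mw.weight_slow * ps.p), mw


@dataclass(frozen=True)
class SummaryStats:
    """Moment and modality summary of an mRNA pmf.

    ``peaks`` is a list of (location, height, kind) with kind 'OP' for the
    origin peak (x = 0) and 'NOP' otherwise; ``mode_class`` is 'U', 'B',
    'T' or 'higher' by peak count, or 'degenerate' for zero variance.
    """

    mean: float
    cv: float | None
    nu2: float
    nu3: float
    nu4: float
    skewness: float | None
    kurtosis: float | None
    bc: float | None
    peaks: tuple[tuple[int, float, str], ...]
    mode_class: str

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_nop(self) -> int:
        return sum(1 for _, _, kind in self.peaks if kind == "NOP")


#: peaks with probability below this are not counted: no population of
#: ~1e4 cells could observe a mode this rare, and exact analytic tails
#: otherwise carry vanishing-mass local maxima with no physical content.
MIN_PEAK_HEIGHT = 1e-4


def _find_peaks(p: np.ndarray, min_height: float = MIN_PEAK_HEIGHT) -> list[tuple[int, float, str]]:
    """Local maxima of a pmf.

    An interior peak at x > 0 requires p(x) > p(x-1) (strict rise) and
    p(x) >= p(x+1) (non-strict fall), so plateaus collapse to their left
    edge; an origin peak requires p(0) > p(1).  Maxima with height below
    ``min_height`` are ignored.
    """
    q = np.concatenate([p, [0.0]])
    peaks: list[tuple[int, float, str]] = []
    if (p.size == 1 or p[0] > p[1]) and p[0] >= min_height:
        peaks.append((0, float(p[0]), "OP"))
    for x in range(1, p.size):
        if q[x] > q[x - 1] and q[x] >= q[x + 1] and q[x] >= min_height:
            peaks.append((x, float(q[x]), "NOP"))
    return peaks


def summarize_pmf(
    pmf: Pmf,
    smooth_window: int | None = None,
    min_peak_height: float = MIN_PEAK_HEIGHT,
) -> SummaryStats:
    """Moments, skewness/kurtosis, bimodality coefficient and peak census.

    ``smooth_window`` (odd, e.g. 3) applies a moving average before peak
    counting -- useful for simulated histograms; analytic pmfs need none.
    """
    p = pmf.p
    mean = pmf.mean()
    nu2 = pmf.central_moment(2)
    if nu2 <= 0:
        return SummaryStats(
            mean=mean, cv=None, nu2=nu2, nu3=0.0, nu4=0.0, skewness=None,
            kurtosis=None, bc=None, peaks=(), mode_class="degenerate",
        )
    nu3 = pmf.central_moment(3)
    nu4 = pmf.central_moment(4)
    skew = nu3 / nu2**1.5
    kurt = nu4 / nu2**2
    bc = 1.0 / (kurt - skew**2)
    cv = float(np.sqrt(nu2) / mean) if mean > 0 else None
    if smooth_window:
        if smooth_window % 2 != 1:
            raise InputError("smooth_window must be odd")
        kernel = np.ones(smooth_window) / smooth_window
        p = np.convolve(p, kernel, mode="same")
    peaks = _find_peaks(p, min_peak_height)
    mode_class = {1: "U", 2: "B", 3: "T"}.get(len(peaks), "higher")
    return SummaryStats(
        mean=mean, cv=cv, nu2=nu2, nu3=nu3, nu4=nu4, skewness=skew,
        kurtosis=kurt, bc=bc, peaks=tuple(peaks), mode_class=mode_class,
    )


@dataclass
class PhaseDiagram:
    """Modality classes over a (d_G, k_EP) grid.

    ``classes[i, j]`` is the mode label at d_G_grid[i], k_EP_grid[j]; the
    boundaries are reported as pairs of adjacent grid cells whose class
    differs (no sub-grid refinement).
    """

    d_G_grid: np.ndarray
    k_EP_grid: np.ndarray
    classes: np.ndarray
    bc: np.ndarray
    n_peaks: np.ndarray
    stats: list[list[SummaryStats]]

    @property
    def boundaries(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        edges = []
        ni, nj = self.classes.shape
        for i in range(ni):
            for j in range(nj):
                if j + 1 < nj and self.classes[i, j] != self.classes[i, j + 1]:
                    edges.append(((i, j), (i, j + 1)))
                if i + 1 < ni and self.classes[i, j] != self.classes[i + 1, j]:
                    edges.append(((i, j), (i + 1, j)))
        return edges

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, dg in enumerate(self.d_G_grid):
            for j, kep in enumerate(self.k_EP_grid):
                s = self.stats[i][j]
                rows.append(
                    dict(
                        d_G=int(dg), k_EP=float(kep), mode_class=self.classes[i, j],
                        n_peaks=int(self.n_peaks[i, j]), bc=self.bc[i, j],
                        mean=s.mean, cv=s.cv,
                    )
                )
        return pd.DataFrame(rows)


def _spec_at(template: PolymerSpec, d_G: int, k_EP: float) -> PolymerSpec:
    return PolymerSpec.from_genomic_distance(
        int(d_G), k_NN=template.k_NN, k_EP=float(k_EP), D=template.D,
        gamma=template.gamma, b=template.b, monomer_kb=template.monomer_kb,
    )


def phase_diagram(
    spec_template: PolymerSpec,
    link: LinkSpec,
    k_EP_grid,
    d_G_grid=None,
    x_max: int | None = None,
    n_nodes: int = 96,
) -> PhaseDiagram:
    """Classify the stationary law over a (d_G, k_EP) grid."""
    k_EP_grid = np.asarray(k_EP_grid, dtype=float)
    if d_G_grid is None:
        d_G_grid = np.array([spec_template.d_G])
    d_G_grid = np.asarray(d_G_grid)
    if np.any(k_EP_grid < 0) or np.any(np.asarray(d_G_grid) < 1):
        raise InputError("grids must be positive (d_G >= 1, k_EP >= 0)")
    if np.any(np.diff(k_EP_grid) <= 0) or np.any(np.diff(d_G_grid) < 0):
        raise InputError("grids must be sorted increasing")
    if x_max is None:
        x_max = _auto_x_max(link)
    classes = np.empty((d_G_grid.size, k_EP_grid.size), dtype=object)
    bc = np.full(classes.shape, np.nan)
    n_peaks = np.zeros(classes.shape, dtype=int)
    stats_grid: list[list[SummaryStats]] = []
    for i, dg in enumerate(d_G_grid):
        row = []
        for j, kep in enumerate(k_EP_grid):
            spec = _spec_at(spec_template, int(dg), float(kep))
            pmf, _ = p_stationary(spec, link, x_max, n_nodes)
            s = summarize_pmf(pmf)
            classes[i, j] = s.mode_class
            bc[i, j] = np.nan if s.bc is None else s.bc
            n_peaks[i, j] = s.n_peaks
            row.append(s)
        stats_grid.append(row)
    return PhaseDiagram(
        d_G_grid=np.asarray(d_G_grid), k_EP_grid=k_EP_grid, classes=classes,
        bc=bc, n_peaks=n_peaks, stats=stats_grid,
    )


def mode_sequence(stats: list[SummaryStats]) -> list[str]:
    """Collapse an ordered list of summaries into the run-length sequence of
    modality labels, annotating bimodal phases by their peak composition
    ('B:OP+NOP' vs 'B:2NOP') and unimodal ones by peak kind."""
    labels = []
    for s in stats:
        if s.mode_class == "U":
            lab = f"U:{s.peaks[0][2]}"
        elif s.mode_class == "B":
            lab = "B:2NOP" if s.n_nop == 2 else "B:OP+NOP"
        else:
            lab = s.mode_class
        labels.append(lab)
    seq = [labels[0]]
    for lab in labels[1:]:
        if lab != seq[-1]:
            seq.append(lab)
    return seq


def scan_expression(
    spec_template: PolymerSpec,
    link: LinkSpec,
    variable: str,
    grid,
    x_max: int | None = None,
    n_nodes: int = 96,
) -> pd.DataFrame:
    """Mean, CV and contact probability of the stationary law along a
    one-parameter sweep of ``d_G`` or ``k_EP``.

    The returned frame also carries log10 columns for power-law inspection.
    """
    if variable not in ("d_G", "k_EP"):
        raise InputError("variable must be 'd_G' or 'k_EP'")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise InputError("grid must be sorted increasing")
    if x_max is None:
        x_max = _auto_x_max(link)
    rows = []
    for val in grid:
        if variable == "d_G":
            spec = _spec_at(spec_template, int(val), spec_template.k_EP)
        else:
            spec = _spec_at(spec_template, spec_template.d_G, float(val))
        pmf, mw = p_stationary(spec, link, x_max, n_nodes)
        law = ep_equilibrium(spec)
        rows.append(
            dict(
                **{variable: val},
                mean=pmf.mean(), cv=pmf.cv(),
                contact_probability=contact_probability(law, spec.b),
                theta=spec.theta, omega=mw.omega,
            )
        )
    out = pd.DataFrame(rows)
    out["log10_" + variable] = np.log10(out[variable])
    out["log10_mean"] = np.log10(out["mean"])
    out["log10_contact"] = np.log10(out["contact_probability"])
    return out
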