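"""Frozen-chromatin transcription machinery: the telegraph model.

For a fixed E-P topology the gene follows the two-state (telegraph) model
with rates (alpha, beta, mu, delta).  Its stationary mRNA copy-number law
is Poisson-Beta: a Poisson whose intensity is mu~ * T with T ~
Beta(alpha~, beta~), where the tilde marks rates in units of delta:

    P(x) = integral_0^1 Poisson(x; mu~ t) Beta(t; alpha~, beta~) dt.

Two evaluation routes are provided: a log-space confluent-hypergeometric
closed form (`poisson_beta_pmf`) and a vectorized backward three-term
recurrence (`poisson_beta_pmf_batch`) used in quadrature/fitting hot paths.
A frozen-rate exact stochastic simulator (`frozen_telegraph_ssa`) serves as
the independent oracle for both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, hyp1f1

from .errors import InputError, NumericalError
from .link import RateSet

__all__ = [
    "Pmf",
    "default_x_max",
    "poisson_beta_pmf",
    "poisson_beta_pmf_batch",
    "poisson_beta_moments",
    "frozen_telegraph_ssa",
]


@dataclass(frozen=True)
class Pmf:
    """Probability mass function over mRNA counts 0..x_max."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise InputError("pmf must be a non-empty 1D array")
        if np.any(p < -1e-12):
            raise InputError("pmf entries must be non-negative")
        p = np.maximum(p, 0.0)
        total = p.sum()
        if not (1.0 - 1e-6 <= total <= 1.0 + 1e-9):
            raise InputError(f"pmf mass {total} outside [1-1e-6, 1]")
        object.__setattr__(self, "p", np.minimum(p, 1.0))

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.p.size)

    @property
    def x_max(self) -> int:
        return self.p.size - 1

    def mean(self) -> float:
        return float(self.p @ self.x)

    def variance(self) -> float:
        m = self.mean()
        return float(self.p @ (self.x - m) ** 2)

    def cv(self) -> float:
        m = self.mean()
        if m == 0:
            raise InputError("CV undefined for zero-mean distribution")
        return float(np.sqrt(self.variance()) / m)

    def central_moment(self, k: int) -> float:
        return float(self.p @ (self.x - self.mean()) ** k)

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.p)


def default_x_max(mu_tilde: float) -> int:
    """Support cap: smallest m with Poisson(mu~) tail < 1e-9 beyond it, doubled.

    The Poisson-Beta law is stochastically dominated by Poisson(mu~), so this
    truncation leaves negligible (< 1e-8 worth of) tail mass.
    """
    if mu_tilde <= 0:
        return 1
    m = int(stats.poisson.isf(1e-9, mu_tilde))
    return max(2 * m, 10)


def _check_rates(rates: RateSet) -> tuple[float, float, float]:
    a, b, m = rates.alpha_tilde, rates.beta_tilde, rates.mu_tilde
    if a <= 0 or b < 0 or m < 0:
        raise InputError(
            f"Poisson-Beta needs alpha~ > 0 and beta~, mu~ >= 0, got "
            f"({a}, {b}, {m})"
        )
    return a, b, m


def poisson_beta_pmf(rates: RateSet, x_max: int | None = None) -> Pmf:
    """Poisson-Beta pmf by the log-space confluent-hypergeometric form.

    P(x) = exp(logC(x)) * 1F1(a + x; a + b + x; -mu) with
    logC(x) = ln G(a+x) - ln G(a) - ln x! + ln G(a+b) - ln G(a+b+x) + x ln mu,
    where (a, b, mu) are the delta-scaled rates.
    """
    a, b, m = _check_rates(rates)
    if x_max is None:
        x_max = default_x_max(m)
    x = np.arange(x_max + 1)
    if m == 0:
        p = np.zeros(x_max + 1)
        p[0] = 1.0
        return Pmf(p)
    if b == 0:  # gene never switches off: plain Poisson(mu~)
        return Pmf(stats.poisson.pmf(x, m))
    logc = (
        gammaln(a + x) - gammaln(a) - gammaln(x + 1.0)
        + gammaln(a + b) - gammaln(a + b + x) + x * np.log(m)
    )
    with np.errstate(over="ignore", invalid="ignore"):
        h = hyp1f1(a + x, a + b + x, -m)
        p = np.exp(logc) * h
    if not np.all(np.isfinite(p)):
        # extreme rate corners (very large mu~) overflow the closed form;
        # the backward recurrence stays stable there
        p = poisson_beta_pmf_batch(np.asarray(a), b, np.asarray(m), x_max)
    p = np.maximum(p, 0.0)
    if p.sum() < 1.0 - 1e-6:
        raise NumericalError(
            f"truncated pmf mass {p.sum():.8f} < 1 - 1e-6; increase x_max"
        )
    return Pmf(p)


def poisson_beta_pmf_batch(
    alpha: np.ndarray, beta: float, mu: np.ndarray, x_max: int
) -> np.ndarray:
    """Poisson-Beta pmfs for many (alpha, mu) pairs sharing one beta.

    Uses the backward (Miller-type) three-term recurrence satisfied by
    Q_x = mu^x J_x / x! with J_x = int_0^1 e^{-mu t} t^{a+x-1}(1-t)^{b-1} dt:

        Q_x = [(mu+a+b+x)(x+1) Q_{x+1} - (x+2)(x+1) Q_{x+2}] / (mu (a+x)).

    The Poisson-Beta pmf is the minimal solution, so downward recursion from
    a tail-safe start index is stable; total probability fixes the
    normalization.  Inputs are delta-scaled rates; output has shape
    broadcast(alpha, mu) + (x_max + 1,).
    """
    a = np.asarray(alpha, dtype=float)
    m = np.asarray(mu, dtype=float)
    shape = np.broadcast_shapes(a.shape, m.shape)
    a = np.broadcast_to(a, shape).copy()
    m = np.broadcast_to(m, shape).copy()
    if np.any(a <= 0) or beta < 0 or np.any(m < 0):
        raise InputError("need alpha~ > 0, beta~ >= 0, mu~ >= 0")
    mu_max = float(m.max(initial=0.0))
    if mu_max == 0.0:
        out = np.zeros(shape + (x_max + 1,))
        out[..., 0] = 1.0
        return out
    x_top = int(max(x_max, stats.poisson.isf(1e-12, mu_max))) + 60
    safe_m = np.where(m > 0, m, 1.0)
    Q = np.zeros(shape + (x_top + 3,))
    Q[..., x_top + 1] = 1e-280
    for x in range(x_top, -1, -1):
        Q[..., x] = (
            (safe_m + a + beta + x) * (x + 1) * Q[..., x + 1]
            - (x + 2.0) * (x + 1.0) * Q[..., x + 2]
        ) / (safe_m * (a + x))
        # per-row rescale: rows grow at very different backward rates, and a
        # global rescale would underflow slow-growing rows to zero
        big = Q[..., x] > 1e250
        if np.any(big):
            Q[big] *= 1e-250
    Q = Q[..., : x_top + 1]
    total = Q.sum(axis=-1, keepdims=True)
    if np.any(~np.isfinite(total)) or np.any(total <= 0):
        raise NumericalError("backward recurrence produced a non-normalizable pmf")
    Q /= total
    out = Q[..., : x_max + 1]
    if np.any(m == 0):
        point = np.zeros(x_max + 1)
        point[0] = 1.0
        out = np.where((m == 0)[..., None], point, out)
    return np.maximum(out, 0.0)


def poisson_beta_moments(rates: RateSet) -> tuple[float, float, float]:
    """Closed-form (mean, variance, CV) of the Poisson-Beta law.

    mean = mu~ a / (a + b),
    var  = mean + mu~^2 a b / ((a + b)^2 (a + b + 1)).
    """
    a, b, m = _check_rates(rates)
    mean = m * a / (a + b)
    var = mean + m**2 * a * b / ((a + b) ** 2 * (a + b + 1.0))
    if mean == 0:
        raise InputError("CV undefined: mean expression is zero")
    return mean, var, float(np.sqrt(var) / mean)


def frozen_telegraph_ssa(
    rates: RateSet,
    t_end: float | None = None,
    n_cells: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Exact stochastic simulation (Gillespie direct method) of the frozen
    telegraph model; returns the mRNA copy number of each cell at ``t_end``.

    Time is measured in units of the mRNA lifetime (rates are delta-scaled).
    All cells are advanced synchronously with per-cell exponential waiting
    times, which is statistically identical to independent runs.  Default
    ``t_end`` is 20 / min(alpha~, beta~, 1), long enough for stationarity.
    """
    a, b, m = rates.alpha_tilde, rates.beta_tilde, rates.mu_tilde
    if n_cells < 1:
        raise InputError("n_cells must be >= 1")
    if t_end is None:
        positive = [v for v in (a, b, 1.0) if v > 0]
        t_end = 20.0 / min(positive)
    rng = np.random.default_rng(seed)
    gene = np.zeros(n_cells, dtype=bool)  # start OFF
    mrna = np.zeros(n_cells, dtype=np.int64)
    t = np.zeros(n_cells)
    active = np.ones(n_cells, dtype=bool)
    while np.any(active):
        on = gene[active]
        mr = mrna[active]
        prop = np.empty((4, on.size))
        prop[0] = a * (~on)          # OFF -> ON
        prop[1] = b * on             # ON -> OFF
        prop[2] = m * on             # transcription
        prop[3] = mr.astype(float)   # degradation (rate 1 per molecule)
        total = prop.sum(axis=0)
        # cells with zero propensity can never change again
        stuck = total <= 0
        tau = np.full(on.size, np.inf)
        tau[~stuck] = rng.exponential(1.0 / total[~stuck])
        t_new = t[active] + tau
        fired = t_new <= t_end
        u = rng.random(on.size) * total
        cum = np.cumsum(prop, axis=0)
        channel = (u[None, :] >= cum).sum(axis=0)
        idx = np.flatnonzero(active)
        fired_idx = idx[fired]
        ch = channel[fired]
        gene[fired_idx[ch == 0]] = True
        gene[fired_idx[ch == 1]] = False
        mrna[fired_idx[ch == 2]] += 1
        mrna[fired_idx[ch == 3]] -= 1
        t[fired_idx] = t_new[fired]
        active[idx[~fired]] = False
    return mrna
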