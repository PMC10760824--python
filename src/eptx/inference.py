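"""Cross-entropy inference of chromatin and transcription parameters.

Observed data are per-cell-line mRNA-count histograms Q_k plus each line's
E-P genomic distance (kb, coarse-grained to monomers; NaN marks a
promoter-only line with no enhancer).  The model predicts each line's
stationary mRNA law P_k from a shared parameter set

    Gamma = (k_NN, k_EP, gamma, alpha_min, alpha_max, beta, mu_min, mu_max),

the lines differing only through d_G.  Fitting minimizes the total cross
entropy  H(Gamma) = -sum_k sum_i Q_k(x_i) log P_k(x_i; Gamma), which is
maximum-likelihood estimation up to the constant empirical entropies.
Model variants restrict which rates respond to the E-P distance:
``var_alpha`` (only alpha varies), ``var_mu`` (only mu), ``var_alpha_mu``
(both), and ``fixed_per_line`` (an independent plain telegraph model per
line, no chromatin layer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

import numpy.polynomial.legendre as _leg
from scipy import stats as _stats

from .chain import PolymerSpec
from .errors import FitError, InputError
from .link import LinkSpec, RateSet
from .stationary import p_stationary
from .telegraph import Pmf, default_x_max, poisson_beta_pmf, poisson_beta_pmf_batch

__all__ = [
    "CellLine",
    "CellLinePanel",
    "ParameterSet",
    "FitResult",
    "VARIANTS",
    "coarse_grain_distance",
    "cross_entropy",
    "entropy",
    "ks_distance",
    "line_model_pmf",
    "total_objective",
    "fit",
    "select_model",
]

VARIANTS = ("fixed_per_line", "var_alpha", "var_mu", "var_alpha_mu")

_P_FLOOR = 1e-12


def coarse_grain_distance(kb: float, monomer_kb: float = 5.0):
    """Genomic distance in kb -> integer monomer count.

    Rounds half away from zero and floors the result at one monomer; a NaN
    (no-enhancer sentinel) passes through unchanged.
    """
    if monomer_kb <= 0:
        raise InputError(f"monomer_kb must be positive, got {monomer_kb}")
    if kb is None or (isinstance(kb, float) and math.isnan(kb)):
        return float("nan")
    if kb <= 0:
        raise InputError(f"genomic distance must be positive, got {kb}")
    return max(1, math.floor(kb / monomer_kb + 0.5))


@dataclass(frozen=True)
class CellLine:
    """One cell line: label, E-P genomic distance and observed histogram.

    ``q`` is the normalized histogram over counts 0..len(q)-1;
    ``distance_kb`` is NaN for the promoter-only (no enhancer) line, in
    which case ``d_G`` is None.
    """

    label: str
    distance_kb: float
    d_G: int | None
    q: np.ndarray
    n_cells: int | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or q.size == 0:
            raise InputError(f"line {self.label}: histogram must be 1D, non-empty")
        if np.any(q < 0):
            raise InputError(f"line {self.label}: negative histogram entries")
        if abs(q.sum() - 1.0) > 1e-6:
            raise InputError(
                f"line {self.label}: histogram sums to {q.sum():.8f}, not 1"
            )
        object.__setattr__(self, "q", q)
        has_enh = not math.isnan(self.distance_kb)
        if has_enh and (self.d_G is None or self.d_G < 1):
            raise InputError(f"line {self.label}: d_G must be >= 1 with an enhancer")
        if not has_enh and self.d_G is not None:
            raise InputError(f"line {self.label}: promoter-only line cannot have d_G")

    @property
    def n_bins(self) -> int:
        return self.q.size

    @classmethod
    def from_kb(
        cls, label: str, distance_kb: float, q, monomer_kb: float = 5.0,
        n_cells: int | None = None,
    ) -> "CellLine":
        dg = coarse_grain_distance(distance_kb, monomer_kb)
        dg = None if isinstance(dg, float) and math.isnan(dg) else int(dg)
        return cls(label=label, distance_kb=float(distance_kb), d_G=dg, q=q,
                   n_cells=n_cells)


@dataclass(frozen=True)
class CellLinePanel:
    """The multi-line inference input."""

    lines: tuple[CellLine, ...]
    monomer_kb: float = 5.0

    def __post_init__(self) -> None:
        if not self.lines:
            raise InputError("panel needs at least one line")
        object.__setattr__(self, "lines", tuple(self.lines))

    def __iter__(self):
        return iter(self.lines)

    def __len__(self) -> int:
        return len(self.lines)


@dataclass(frozen=True)
class ParameterSet:
    """Shared model parameters Gamma plus fixed context.

    The fitted vector is (k_NN, k_EP, gamma, alpha_min, alpha_max, beta,
    mu_min, mu_max); D, b, monomer_kb, delta and the link-shape constants
    are fixed configuration, never fitted: the distributions depend on the
    chain only through Theta(d_G) and omega, so D and b are not separately
    identifiable from count histograms.
    """

    k_NN: float
    k_EP: float
    gamma: float
    alpha_min: float
    alpha_max: float
    beta: float
    mu_min: float
    mu_max: float
    D: float = 1.0
    b: float = 1.0
    monomer_kb: float = 5.0
    delta: float = 1.0
    link_mode: str = "hill"
    n_h: float = 2.0
    d0: float | None = None
    d0_mu: float | None = None
    d_lin: float | None = None

    def __post_init__(self) -> None:
        if self.alpha_min > self.alpha_max or self.mu_min > self.mu_max:
            raise InputError("rate ranges must satisfy min <= max")
        for name in ("k_NN", "gamma", "alpha_min", "beta", "mu_min", "D", "b", "delta"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.k_EP < 0:
            raise InputError("k_EP must be non-negative")
        if self.d0 is None:
            object.__setattr__(self, "d0", self.b)

    def link(self) -> LinkSpec:
        return LinkSpec(
            alpha_min=self.alpha_min, alpha_max=self.alpha_max,
            mu_min=self.mu_min, mu_max=self.mu_max, beta=self.beta,
            delta=self.delta, mode=self.link_mode, n_h=self.n_h,
            d0=self.d0, d0_mu=self.d0_mu, d_lin=self.d_lin,
        )

    def polymer(self, d_G: int, flank: int = 0) -> PolymerSpec:
        return PolymerSpec.from_genomic_distance(
            d_G, k_NN=self.k_NN, k_EP=self.k_EP, D=self.D, gamma=self.gamma,
            b=self.b, monomer_kb=self.monomer_kb, flank=flank,
        )

    def theta(self, d_G: int) -> float:
        return math.sqrt(self.D * self.gamma / (self.k_NN / d_G + self.k_EP))

    def detached_rates(self) -> RateSet:
        return RateSet(alpha=self.alpha_min, beta=self.beta, mu=self.mu_min,
                       delta=self.delta)

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


def entropy(q: np.ndarray) -> float:
    """Shannon entropy of a histogram (natural log)."""
    q = np.asarray(q, dtype=float)
    nz = q[q > 0]
    return float(-(nz * np.log(nz)).sum())


def cross_entropy(model, observed) -> float:
    """-sum_i Q(x_i) log P(x_i), model floored at 1e-12 before the log.

    ``model`` may be a Pmf or a plain probability array; it is truncated or
    zero-extended to the observed support.
    """
    p = model.p if isinstance(model, Pmf) else np.asarray(model, dtype=float)
    q = np.asarray(observed, dtype=float)
    if abs(q.sum() - 1.0) > 1e-6:
        raise InputError(f"observed histogram sums to {q.sum():.8f}, not 1")
    if p.size < q.size:
        p = np.concatenate([p, np.zeros(q.size - p.size)])
    p = np.maximum(p[: q.size], _P_FLOOR)
    return float(-(q * np.log(p)).sum())


def ks_distance(model, observed) -> float:
    """Kolmogorov-Smirnov distance: sup_x |CDF_model(x) - CDF_observed(x)|."""
    p = model.p if isinstance(model, Pmf) else np.asarray(model, dtype=float)
    q = np.asarray(observed, dtype=float)
    n = max(p.size, q.size)
    cp = np.cumsum(np.concatenate([p, np.zeros(n - p.size)]))
    cq = np.cumsum(np.concatenate([q, np.zeros(n - q.size)]))
    return float(np.abs(cp - cq).max())


def line_model_pmf(
    params: ParameterSet, d_G: int | None, x_max: int, n_nodes: int = 64
) -> Pmf:
    """Stationary model law for one line.

    With an enhancer: the fast/slow mixture at that line's d_G.  The
    promoter-only line is the detached (d_S -> infinity) limit: a plain
    Poisson-Beta at (alpha_min, beta, mu_min).
    """
    if d_G is None:
        return poisson_beta_pmf(params.detached_rates(), x_max)
    pmf, _ = p_stationary(params.polymer(d_G), params.link(), x_max, n_nodes)
    return pmf


# chi(3 dof) quantile constants of the distance law (d = theta * z)
_Z99 = float(_stats.chi(3).ppf(0.99))
_ZTAIL = float(_stats.chi(3).ppf(1.0 - 1e-8))


def _panel_pmfs(
    params: ParameterSet, d_gs: list[int | None], x_max: int, n_nodes: int = 64
) -> np.ndarray:
    """Stationary model pmfs for all panel lines in one vectorized pass.

    Mathematically identical to `line_model_pmf` per line (the fast-limit
    rate averages use the same fixed Gauss-Legendre rule as the slow-limit
    mixture instead of adaptive quadrature; the integrand is smooth and the
    two agree to ~1e-10).  Used by the fitting hot path.
    """
    link = params.link()
    nodes, weights = _leg.leggauss(n_nodes)
    out = np.empty((len(d_gs), x_max + 1))
    with_dg = [i for i, dg in enumerate(d_gs) if dg is not None]
    for i, dg in enumerate(d_gs):
        if dg is None:
            out[i] = poisson_beta_pmf_batch(
                np.asarray(params.alpha_min / params.delta),
                params.beta / params.delta,
                np.asarray(params.mu_min / params.delta),
                x_max,
            )
    if not with_dg:
        return out
    thetas = np.array([params.theta(d_gs[i]) for i in with_dg])
    uppers = thetas * _ZTAIL
    d = 0.5 * uppers[:, None] * (nodes[None, :] + 1.0)          # (L, n)
    law_pdf = np.sqrt(2.0 / np.pi) / thetas[:, None] ** 3 * d**2 * np.exp(
        -0.5 * (d / thetas[:, None]) ** 2
    )
    w = 0.5 * uppers[:, None] * weights[None, :] * law_pdf
    w /= w.sum(axis=1, keepdims=True)
    alpha = link.alpha(d) / params.delta                         # (L, n)
    mu = link.mu(d) / params.delta
    beta_t = params.beta / params.delta
    P = poisson_beta_pmf_batch(alpha, beta_t, mu, x_max)         # (L, n, X)
    slow = np.einsum("ln,lnx->lx", w, P)
    a_avg = (w * alpha).sum(axis=1)
    m_avg = (w * mu).sum(axis=1)
    fast = poisson_beta_pmf_batch(a_avg, beta_t, m_avg, x_max)   # (L, X)
    k_eff = np.array([params.k_NN / d_gs[i] + params.k_EP for i in with_dg])
    v_max = k_eff * thetas * _Z99 / (params.b * params.gamma)
    om = min(params.alpha_min, params.mu_min) / v_max
    wf = (1.0 / (1.0 + om))[:, None]
    mix = wf * fast + (1.0 - wf) * slow
    for j, i in enumerate(with_dg):
        out[i] = mix[j]
    return out


def _variant_params(params: ParameterSet, variant: str) -> ParameterSet:
    if variant == "var_alpha":
        return params.replace(mu_max=params.mu_min)
    if variant == "var_mu":
        return params.replace(alpha_max=params.alpha_min)
    if variant == "var_alpha_mu":
        return params
    raise InputError(f"unknown variant {variant!r}")


def _panel_x_max(panel: CellLinePanel, params: ParameterSet | None = None) -> int:
    xm = max(line.n_bins - 1 for line in panel)
    if params is not None:
        xm = max(xm, default_x_max(params.mu_max / params.delta))
    return xm


def total_objective(
    params: ParameterSet, panel: CellLinePanel, variant: str = "var_alpha_mu",
    n_nodes: int = 64,
) -> float:
    """Total cross entropy of the panel under one parameter set."""
    if variant == "fixed_per_line":
        raise InputError(
            "fixed_per_line has independent per-line parameters; use fit()"
        )
    eff = _variant_params(params, variant)
    x_max = _panel_x_max(panel, eff)
    pmfs = _panel_pmfs(eff, [line.d_G for line in panel], x_max, n_nodes)
    return float(sum(
        cross_entropy(pmfs[i], line.q) for i, line in enumerate(panel)
    ))


@dataclass
class FitResult:
    """Best-fit parameters and goodness of fit."""

    params: ParameterSet | list[RateSet]
    variant: str
    per_line_cross_entropy: dict[str, float]
    total_cross_entropy: float
    per_line_ks: dict[str, float]
    per_line_pmf: dict[str, Pmf]
    n_starts: int
    seed: int
    converged: bool
    trace: list[dict] = field(default_factory=list)

    def validate(self, panel: CellLinePanel) -> None:
        """Gibbs inequality: each line's cross entropy is at least the
        empirical entropy of its histogram."""
        tol = 1e-9
        for line in panel:
            hk = self.per_line_cross_entropy[line.label]
            if hk < entropy(line.q) - tol:
                raise FitError(
                    f"line {line.label}: cross entropy {hk} below empirical entropy"
                )
        total = sum(self.per_line_cross_entropy.values())
        if abs(total - self.total_cross_entropy) > 1e-6:
            raise FitError("per-line cross entropies do not sum to the total")


# fit-vector layout per variant: names of log-scale coordinates; ratio
# coordinates are log(max/min) >= 0 so the ordering constraint is a bound.
_FREE = {
    "var_alpha_mu": ("k_NN", "k_EP", "gamma", "alpha_min", "log_ratio_alpha",
                      "beta", "mu_min", "log_ratio_mu"),
    "var_alpha": ("k_NN", "k_EP", "gamma", "alpha_min", "log_ratio_alpha",
                   "beta", "mu_min"),
    "var_mu": ("k_NN", "k_EP", "gamma", "alpha_min", "beta", "mu_min",
                "log_ratio_mu"),
}

DEFAULT_BOUNDS = {
    "k_NN": (0.05, 5.0),
    "k_EP": (1e-3, 5.0),
    "gamma": (0.5, 200.0),
    "alpha_min": (0.01, 5.0),
    "ratio_alpha": (1.0, 50.0),
    "beta": (0.05, 20.0),
    "mu_min": (0.5, 60.0),
    "ratio_mu": (1.0, 30.0),
}


def _params_to_vector(params: ParameterSet, variant: str) -> np.ndarray:
    vals = {
        "k_NN": params.k_NN, "k_EP": params.k_EP, "gamma": params.gamma,
        "alpha_min": params.alpha_min, "beta": params.beta,
        "mu_min": params.mu_min,
        "log_ratio_alpha": math.log(max(params.alpha_max / params.alpha_min, 1.0)),
        "log_ratio_mu": math.log(max(params.mu_max / params.mu_min, 1.0)),
    }
    return np.array([
        vals[n] if n.startswith("log_ratio_") else math.log(vals[n])
        for n in _FREE[variant]
    ])


def _vector_to_params(v: np.ndarray, variant: str, context: ParameterSet) -> ParameterSet:
    names = _FREE[variant]
    d = dict(zip(names, v))
    alpha_min = math.exp(d["alpha_min"])
    mu_min = math.exp(d["mu_min"])
    alpha_max = alpha_min * math.exp(d.get("log_ratio_alpha", 0.0))
    mu_max = mu_min * math.exp(d.get("log_ratio_mu", 0.0))
    return context.replace(
        k_NN=math.exp(d["k_NN"]), k_EP=math.exp(d["k_EP"]),
        gamma=math.exp(d["gamma"]), alpha_min=alpha_min, alpha_max=alpha_max,
        beta=math.exp(d["beta"]), mu_min=mu_min, mu_max=mu_max,
    )


def _bounds_for(variant: str, bounds: dict) -> list[tuple[float, float]]:
    out = []
    for name in _FREE[variant]:
        if name.startswith("log_ratio_"):
            lo, hi = bounds["ratio_" + name[len("log_ratio_"):]]
            out.append((math.log(max(lo, 1.0)), math.log(hi)))
        else:
            lo, hi = bounds[name]
            out.append((math.log(lo), math.log(hi)))
    return out


def _fit_shared(
    panel: CellLinePanel, variant: str, bounds: dict, n_starts: int, seed: int,
    context: ParameterSet, n_nodes: int, maxiter: int,
    extra_starts: list[np.ndarray] | None = None,
) -> FitResult:
    box = _bounds_for(variant, bounds)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    rng = np.random.default_rng(seed)
    xm = _panel_x_max(panel)

    d_gs = [line.d_G for line in panel]

    def objective(v: np.ndarray) -> float:
        params = _vector_to_params(v, variant, context)
        eff = _variant_params(params, variant)
        x_max = max(xm, default_x_max(eff.mu_max / eff.delta))
        pmfs = _panel_pmfs(eff, d_gs, x_max, n_nodes)
        return float(sum(
            cross_entropy(pmfs[i], line.q) for i, line in enumerate(panel)
        ))

    starts = [rng.uniform(lo, hi) for _ in range(n_starts)]
    for x0 in extra_starts or []:
        starts.append(np.clip(x0, lo, hi))
    best = None
    trace = []
    for start, x0 in enumerate(starts):
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=box,
            options=dict(maxiter=maxiter, ftol=1e-10),
        )
        trace.append(dict(start=start, fun=float(res.fun), success=bool(res.success),
                          nit=int(res.nit)))
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"all {n_starts} starts failed; trace: {trace}")

    params = _vector_to_params(best.x, variant, context)
    eff = _variant_params(params, variant)
    x_max = max(xm, default_x_max(eff.mu_max / eff.delta))
    per_h, per_ks, per_pmf = {}, {}, {}
    for line in panel:
        pmf = line_model_pmf(eff, line.d_G, x_max, n_nodes)
        per_h[line.label] = cross_entropy(pmf, line.q)
        per_ks[line.label] = ks_distance(pmf, line.q)
        per_pmf[line.label] = pmf
    result = FitResult(
        params=eff, variant=variant, per_line_cross_entropy=per_h,
        total_cross_entropy=sum(per_h.values()), per_line_ks=per_ks,
        per_line_pmf=per_pmf, n_starts=n_starts, seed=seed,
        converged=any(t["success"] for t in trace), trace=trace,
    )
    result.validate(panel)
    return result


def _fit_per_line(
    panel: CellLinePanel, bounds: dict, n_starts: int, seed: int,
    context: ParameterSet, maxiter: int,
) -> FitResult:
    """Independent plain telegraph (alpha, beta, mu) per line, no chromatin."""
    rng = np.random.default_rng(seed)
    lo = np.log([bounds["alpha_min"][0], bounds["beta"][0], bounds["mu_min"][0]])
    hi = np.log([bounds["alpha_min"][1] * bounds["ratio_alpha"][1],
                 bounds["beta"][1],
                 bounds["mu_min"][1] * bounds["ratio_mu"][1]])
    box = list(zip(lo, hi))
    rates_out, per_h, per_ks, per_pmf, trace = [], {}, {}, {}, []
    for line in panel:

        def objective(v: np.ndarray) -> float:
            a, b, m = np.exp(v)
            rates = RateSet(alpha=a, beta=b, mu=m, delta=context.delta)
            x_max = max(line.n_bins - 1, default_x_max(rates.mu_tilde))
            return cross_entropy(poisson_beta_pmf(rates, x_max), line.q)

        best = None
        for start in range(n_starts):
            res = optimize.minimize(
                objective, rng.uniform(lo, hi), method="L-BFGS-B", bounds=box,
                options=dict(maxiter=maxiter, ftol=1e-10),
            )
            trace.append(dict(line=line.label, start=start, fun=float(res.fun),
                              success=bool(res.success)))
            if best is None or res.fun < best.fun:
                best = res
        a, b, m = np.exp(best.x)
        rates = RateSet(alpha=a, beta=b, mu=m, delta=context.delta)
        rates_out.append(rates)
        x_max = max(line.n_bins - 1, default_x_max(rates.mu_tilde))
        pmf = poisson_beta_pmf(rates, x_max)
        per_h[line.label] = cross_entropy(pmf, line.q)
        per_ks[line.label] = ks_distance(pmf, line.q)
        per_pmf[line.label] = pmf
    result = FitResult(
        params=rates_out, variant="fixed_per_line", per_line_cross_entropy=per_h,
        total_cross_entropy=sum(per_h.values()), per_line_ks=per_ks,
        per_line_pmf=per_pmf, n_starts=n_starts, seed=seed,
        converged=any(t["success"] for t in trace), trace=trace,
    )
    result.validate(panel)
    return result


def fit(
    panel: CellLinePanel,
    variant: str = "var_alpha_mu",
    bounds: dict | None = None,
    n_starts: int = 20,
    seed: int = 0,
    context: ParameterSet | None = None,
    n_nodes: int = 64,
    maxiter: int = 200,
    extra_starts: list[np.ndarray] | None = None,
) -> FitResult:
    """Multi-start bounded quasi-Newton minimization of the total cross
    entropy.  Starts are sampled log-uniformly within the bounds; ties are
    broken by the lowest objective then the earliest start.  The same seed
    and panel give an identical FitResult.
    """
    if variant not in VARIANTS:
        raise InputError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if n_starts < 1:
        raise InputError("n_starts must be >= 1")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    if context is None:
        context = ParameterSet(
            k_NN=1.0, k_EP=0.1, gamma=1.0, alpha_min=1.0, alpha_max=1.0,
            beta=1.0, mu_min=1.0, mu_max=1.0, monomer_kb=panel.monomer_kb,
        )
    if variant == "fixed_per_line":
        return _fit_per_line(panel, b, n_starts, seed, context, maxiter)
    return _fit_shared(panel, variant, b, n_starts, seed, context, n_nodes, maxiter,
                       extra_starts)


def select_model(
    panel: CellLinePanel,
    variants: tuple[str, ...] = ("var_alpha", "var_mu", "var_alpha_mu"),
    **fit_kwargs,
) -> list[FitResult]:
    """Fit each variant and rank by total cross entropy (best first).

    The headline ranking uses the raw cross entropy, without a complexity
    penalty; each FitResult retains its per-line breakdown.  Solutions of
    restricted variants are re-used as warm starts for the variants that
    nest them, so a nested variant can never rank worse than a restriction
    merely through multi-start luck.
    """
    if len(variants) < 1:
        raise InputError("need at least one variant")
    results = []
    solved: list[FitResult] = []
    for v in variants:
        kwargs = dict(fit_kwargs)
        if v in _FREE:
            warm = [
                _params_to_vector(r.params, v)
                for r in solved
                if isinstance(r.params, ParameterSet) and _nests(v, r.variant)
            ]
            if warm:
                kwargs["extra_starts"] = warm
        res = fit(panel, variant=v, **kwargs)
        results.append(res)
        solved.append(res)
    return sorted(results, key=lambda r: r.total_cross_entropy)


def _nests(outer: str, inner: str) -> bool:
    """outer's parameter space contains inner's."""
    if outer == "var_alpha_mu":
        return inner in ("var_alpha", "var_mu")
    return False
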