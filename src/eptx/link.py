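"""Distance-to-rate link functions.

The E-P spatial distance d_S modulates the telegraph (two-state) gene: the
promoter activation rate alpha and the transcription initiation rate mu
decrease monotonically from their contact values (alpha_max, mu_max) at
d_S = 0 to their detached values (alpha_min, mu_min) as d_S grows, while
the inactivation rate beta and the mRNA degradation rate delta are
distance-independent.  Two response shapes are supported:

* ``hill``:   rate(d) = r_min + (r_max - r_min) * d0^n / (d0^n + d^n)
  (a decreasing Hill curve with half-response distance d0 and exponent n);
* ``linear``: rate(d) = clamp(r_max - (r_max - r_min) * d / d_lin),
  a straight-line decrease over [0, d_lin], clamped outside.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate

from .chain import EPDistanceLaw
from .errors import InputError, NumericalError

__all__ = ["RateSet", "LinkSpec", "link_rates", "averaged_rates"]


@dataclass(frozen=True)
class RateSet:
    """Telegraph-model rate vector (alpha, beta, mu, delta).

    ``alpha``: OFF->ON switching; ``beta``: ON->OFF switching; ``mu``:
    transcription while ON; ``delta``: mRNA degradation.  The tilde forms
    are the rates expressed in units of the degradation rate.
    """

    alpha: float
    beta: float
    mu: float
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "mu"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.delta <= 0:
            raise InputError(f"delta must be positive, got {self.delta}")

    @property
    def alpha_tilde(self) -> float:
        return self.alpha / self.delta

    @property
    def beta_tilde(self) -> float:
        return self.beta / self.delta

    @property
    def mu_tilde(self) -> float:
        return self.mu / self.delta


@dataclass(frozen=True)
class LinkSpec:
    """Shape and range of the distance-to-rate response curves.

    The link is a vector of response functions: activation (alpha) and
    initiation (mu) may switch at different spatial scales, so ``d0`` is
    alpha's half-response distance and ``d0_mu`` (default: same as ``d0``)
    is mu's.
    """

    alpha_min: float
    alpha_max: float
    mu_min: float
    mu_max: float
    beta: float
    delta: float = 1.0
    mode: str = "hill"
    n_h: float = 2.0
    d0: float = 1.0
    d0_mu: float | None = None
    d_lin: float | None = None

    def __post_init__(self) -> None:
        if self.alpha_min < 0 or self.mu_min < 0 or self.beta < 0:
            raise InputError("rates must be non-negative")
        if self.alpha_min > self.alpha_max:
            raise InputError(
                f"alpha_min={self.alpha_min} exceeds alpha_max={self.alpha_max}"
            )
        if self.mu_min > self.mu_max:
            raise InputError(f"mu_min={self.mu_min} exceeds mu_max={self.mu_max}")
        if self.delta <= 0:
            raise InputError("delta must be positive")
        if self.mode not in ("hill", "linear"):
            raise InputError(f"unknown link mode {self.mode!r}")
        if self.n_h <= 0 or self.d0 <= 0:
            raise InputError("n_h and d0 must be positive")
        if self.d0_mu is None:
            object.__setattr__(self, "d0_mu", self.d0)
        elif self.d0_mu <= 0:
            raise InputError("d0_mu must be positive")
        if self.d_lin is None:
            object.__setattr__(self, "d_lin", 2.0 * self.d0)
        elif self.d_lin <= 0:
            raise InputError("d_lin must be positive")

    def _response(self, d_S: np.ndarray, d0: float) -> np.ndarray:
        """Dimensionless response in [0, 1]: 1 at contact, 0 when detached."""
        if self.mode == "hill":
            dn = d0 ** self.n_h
            return dn / (dn + np.asarray(d_S, float) ** self.n_h)
        frac = 1.0 - np.asarray(d_S, float) / self.d_lin
        return np.clip(frac, 0.0, 1.0)

    def alpha(self, d_S) -> np.ndarray | float:
        out = self.alpha_min + (self.alpha_max - self.alpha_min) * self._response(
            d_S, self.d0
        )
        return float(out) if np.ndim(out) == 0 else out

    def mu(self, d_S) -> np.ndarray | float:
        out = self.mu_min + (self.mu_max - self.mu_min) * self._response(
            d_S, self.d0_mu
        )
        return float(out) if np.ndim(out) == 0 else out

    def replace(self, **kwargs) -> "LinkSpec":
        return replace(self, **kwargs)


def link_rates(d_S: float, link: LinkSpec) -> RateSet:
    """Instantaneous telegraph rates at E-P spatial distance ``d_S``."""
    if d_S < 0:
        raise InputError(f"d_S must be non-negative, got {d_S}")
    return RateSet(
        alpha=link.alpha(d_S), beta=link.beta, mu=link.mu(d_S), delta=link.delta
    )


def averaged_rates(
    link: LinkSpec, law: EPDistanceLaw, rtol: float = 1e-10
) -> RateSet:
    """Maxwell-Boltzmann averages <alpha(d_S)> and <mu(d_S)>.

    Adaptive quadrature of H(d_S) p(d_S) over [0, quantile(1 - 1e-8)];
    beta and delta are distance-independent and pass through unchanged.
    """
    upper = law.quantile(1.0 - 1e-8)

    def _avg(f) -> float:
        val, err = integrate.quad(
            lambda d: f(d) * law.pdf(d), 0.0, upper, epsrel=rtol, epsabs=1e-13, limit=200
        )
        if not np.isfinite(val) or err > 1e-6 * max(1.0, abs(val)):
            raise NumericalError(
                f"rate-average quadrature did not converge (estimate {val}, error {err})"
            )
        return val

    mass = _avg(lambda d: 1.0)  # ~1 - 1e-8; renormalize away truncation
    a = _avg(link.alpha) / mass
    m = _avg(link.mu) / mass
    # clip float dust so averages respect the configured range
    a = min(max(a, link.alpha_min), link.alpha_max)
    m = min(max(m, link.mu_min), link.mu_max)
    return RateSet(alpha=a, beta=link.beta, mu=m, delta=link.delta)
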