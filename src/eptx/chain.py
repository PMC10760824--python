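"""Bead-spring chromatin chain with an enhancer-promoter (E-P) spring.

The chain is a generalized Rouse polymer: ``N`` monomers connected by
harmonic springs of stiffness ``k_NN``, plus one extra harmonic spring of
stiffness ``k_EP`` between the enhancer monomer ``E`` and the promoter
monomer ``P``.  Monomers move by overdamped Langevin dynamics

    dr = -(1/gamma) * grad U(r) dt + sqrt(2 D) dB(t),

in unbounded 3D space.  Because the potential is quadratic, the stationary
E-P spatial distance d_S = ||r_E - r_P|| follows a Maxwell-Boltzmann law:
the norm of an isotropic 3D Gaussian with per-axis standard deviation

    Theta = sqrt(D * gamma / (k_NN / d_G + k_EP)),

where d_G = |E - P| is the genomic (along-the-chain) distance.  The
effective stiffness k_NN/d_G + k_EP is the d_G chain springs in series,
in parallel with the direct E-P spring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
from scipy import special, stats

from .errors import ConfigurationError, InputError

_CHI3 = stats.chi(3)  # module-level frozen dist; per-call construction is slow

__all__ = [
    "PolymerSpec",
    "Conformation",
    "EPDistanceLaw",
    "ChainTrajectory",
    "chain_potential",
    "simulate_chain",
    "ep_equilibrium",
    "ep_pdf",
    "ep_cdf",
    "ep_quantile",
    "sample_ep",
    "contact_probability",
]


@dataclass(frozen=True)
class PolymerSpec:
    """Parameters of the coarse-grained chromatin chain.

    Monomer indices ``E`` and ``P`` are 1-based, matching the usual
    polymer-model numbering; one monomer represents ``monomer_kb``
    kilobases of DNA (default 5 kb).
    """

    N: int
    k_NN: float
    k_EP: float
    E: int
    P: int
    D: float = 1.0
    gamma: float = 1.0
    b: float = 1.0
    monomer_kb: float = 5.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise InputError(f"chain needs at least 2 monomers, got N={self.N}")
        if not (1 <= self.E <= self.N and 1 <= self.P <= self.N):
            raise InputError(
                f"monomer indices E={self.E}, P={self.P} must lie in [1, {self.N}]"
            )
        if self.E == self.P:
            raise InputError("enhancer and promoter must occupy distinct monomers")
        for name in ("k_NN", "D", "gamma", "b", "monomer_kb"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive, got {getattr(self, name)}")
        if self.k_EP < 0:
            raise InputError(f"k_EP must be non-negative, got {self.k_EP}")

    @property
    def d_G(self) -> int:
        """E-P genomic distance in monomers."""
        return abs(self.E - self.P)

    @property
    def k_eff(self) -> float:
        """Effective E-P stiffness: d_G springs in series, parallel to k_EP."""
        return self.k_NN / self.d_G + self.k_EP

    @property
    def theta(self) -> float:
        """Scale of the stationary E-P distance law."""
        return math.sqrt(self.D * self.gamma / self.k_eff)

    def spring_matrix(self) -> np.ndarray:
        """Symmetric PSD stiffness matrix K such that U = (1/2) sum_axis r.K.r."""
        K = np.zeros((self.N, self.N))
        for j in range(self.N - 1):
            K[j, j] += self.k_NN
            K[j + 1, j + 1] += self.k_NN
            K[j, j + 1] -= self.k_NN
            K[j + 1, j] -= self.k_NN
        e, p = self.E - 1, self.P - 1
        K[e, e] += self.k_EP
        K[p, p] += self.k_EP
        K[e, p] -= self.k_EP
        K[p, e] -= self.k_EP
        return K

    @cached_property
    def _eig(self) -> tuple[np.ndarray, np.ndarray]:
        lam, vec = np.linalg.eigh(self.spring_matrix())
        return lam, vec

    @property
    def lambda_max(self) -> float:
        """Largest eigen-stiffness; sets the integrator stability limit."""
        return float(self._eig[0][-1])

    @property
    def slowest_relaxation_time(self) -> float:
        """gamma / (k_NN * (2 sin(pi/2N))^2), the slowest internal Rouse mode."""
        return self.gamma / (self.k_NN * (2.0 * math.sin(math.pi / (2 * self.N))) ** 2)

    def replace(self, **kwargs) -> "PolymerSpec":
        return replace(self, **kwargs)

    @classmethod
    def from_genomic_distance(
        cls,
        d_G: int,
        *,
        k_NN: float = 1.0,
        k_EP: float = 0.0,
        D: float = 1.0,
        gamma: float = 1.0,
        b: float = 1.0,
        monomer_kb: float = 5.0,
        flank: int = 0,
    ) -> "PolymerSpec":
        """Build a chain whose E and P monomers are ``d_G`` apart, with
        ``flank`` extra monomers dangling on each side."""
        if d_G < 1:
            raise InputError(f"d_G must be >= 1, got {d_G}")
        N = d_G + 1 + 2 * flank
        return cls(
            N=N, k_NN=k_NN, k_EP=k_EP, E=flank + 1, P=flank + 1 + d_G,
            D=D, gamma=gamma, b=b, monomer_kb=monomer_kb,
        )


@dataclass(frozen=True)
class Conformation:
    """A single chain conformation: N monomer positions in 3D."""

    positions: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise InputError(f"positions must have shape (N, 3), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise InputError("positions must be finite")
        object.__setattr__(self, "positions", pos)

    def d_S(self, spec: PolymerSpec) -> float:
        """E-P spatial distance for this conformation."""
        self._check(spec)
        return float(
            np.linalg.norm(self.positions[spec.E - 1] - self.positions[spec.P - 1])
        )

    def _check(self, spec: PolymerSpec) -> None:
        if self.positions.shape[0] != spec.N:
            raise InputError(
                f"conformation has {self.positions.shape[0]} monomers, spec expects {spec.N}"
            )


def chain_potential(conf: Conformation, spec: PolymerSpec) -> float:
    """Total elastic energy U = U_NN + U_EP of a conformation.

    U_NN = (1/2) k_NN sum_j ||r_j - r_{j+1}||^2 over nearest neighbours and
    U_EP = (1/2) k_EP ||r_E - r_P||^2 for the enhancer-promoter spring.
    """
    conf._check(spec)
    r = conf.positions
    bonds = r[:-1] - r[1:]
    u_nn = 0.5 * spec.k_NN * float(np.sum(bonds * bonds))
    sep = r[spec.E - 1] - r[spec.P - 1]
    u_ep = 0.5 * spec.k_EP * float(sep @ sep)
    return u_nn + u_ep


@dataclass(frozen=True)
class EPDistanceLaw:
    """Stationary Maxwell-Boltzmann law of the E-P spatial distance.

    d_S is the norm of a 3D isotropic Gaussian with per-axis s.d. ``theta``,
    i.e. a chi distribution with 3 degrees of freedom scaled by ``theta``:

        p(d_S) = sqrt(2/pi) theta^-3 d_S^2 exp(-d_S^2 / (2 theta^2)).
    """

    theta: float

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise InputError(f"theta must be positive, got {self.theta}")

    def pdf(self, d_S) -> np.ndarray | float:
        """sqrt(2/pi) theta^-3 d^2 exp(-d^2 / 2 theta^2), evaluated directly
        (closed form; avoids per-call frozen-distribution overhead)."""
        d = np.asarray(d_S, dtype=float)
        if np.any(d < 0):
            raise InputError("d_S must be non-negative")
        z = d / self.theta
        out = math.sqrt(2.0 / math.pi) / self.theta * z * z * np.exp(-0.5 * z * z)
        return float(out) if out.ndim == 0 else out

    def cdf(self, x) -> np.ndarray | float:
        """erf(x / (sqrt(2) theta)) - sqrt(2/pi) (x/theta) exp(-x^2/2 theta^2)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise InputError("x must be non-negative")
        z = x / self.theta
        out = special.erf(z / math.sqrt(2.0)) - math.sqrt(2.0 / math.pi) * z * np.exp(
            -0.5 * z * z
        )
        out = np.clip(out, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def quantile(self, q) -> np.ndarray | float:
        q = np.asarray(q, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise InputError("q must lie in (0, 1)")
        out = self.theta * _CHI3.ppf(q)
        return float(out) if out.ndim == 0 else out

    def sample(self, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
        if n < 1:
            raise InputError(f"n must be >= 1, got {n}")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        return np.linalg.norm(rng.standard_normal((n, 3)) * self.theta, axis=1)

    @property
    def mean(self) -> float:
        return 2.0 * math.sqrt(2.0 / math.pi) * self.theta


def ep_equilibrium(spec: PolymerSpec) -> EPDistanceLaw:
    """Exact stationary E-P distance law of the chain."""
    return EPDistanceLaw(theta=spec.theta)


def ep_pdf(d_S, law: EPDistanceLaw):
    return law.pdf(d_S)


def ep_cdf(x, law: EPDistanceLaw):
    return law.cdf(x)


def ep_quantile(q, law: EPDistanceLaw):
    return law.quantile(q)


def sample_ep(law: EPDistanceLaw, n: int, seed: int = 0) -> np.ndarray:
    """n i.i.d. draws of d_S under the stationary law (seeded)."""
    return law.sample(n, seed)


def contact_probability(law: EPDistanceLaw, b: float) -> float:
    """P(d_S <= b): probability the pair sits within the encounter distance."""
    if b <= 0:
        raise InputError(f"encounter distance b must be positive, got {b}")
    return float(law.cdf(b))


@dataclass
class ChainTrajectory:
    """Sampled output of a chain simulation.

    ``d_s`` has shape (n_replicates, n_samples); ``separations`` holds the
    corresponding r_E - r_P component vectors, shape (n_replicates,
    n_samples, 3).  ``positions`` (optional) holds full conformation
    snapshots, shape (n_samples, n_replicates, N, 3).
    """

    spec: PolymerSpec
    dt: float
    times: np.ndarray
    d_s: np.ndarray
    separations: np.ndarray
    positions: np.ndarray | None
    burn_in_steps: int
    seed: int

    @property
    def d_s_flat(self) -> np.ndarray:
        return self.d_s.reshape(-1)

    def snapshots(self) -> list[Conformation]:
        if self.positions is None:
            return []
        return [Conformation(p) for p in self.positions.reshape(-1, self.spec.N, 3)]


def _stationary_positions(
    spec: PolymerSpec, n_replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw conformations from the exact Gaussian stationary law.

    Per axis the stationary covariance is D*gamma*K^+ (pseudo-inverse over
    the non-zero modes); the zero mode (center of mass) is pinned at 0, which
    is irrelevant for internal distances.
    """
    lam, vec = spec._eig
    keep = lam > 1e-12 * lam[-1]
    sd = np.sqrt(spec.D * spec.gamma / lam[keep])  # (n_modes,)
    xi = rng.standard_normal((n_replicates, 3, int(keep.sum())))
    # positions (R, 3, N) = xi * sd @ V^T
    return (xi * sd) @ vec[:, keep].T


def simulate_chain(
    spec: PolymerSpec,
    dt: float | None = None,
    n_steps: int | None = None,
    seed: int = 0,
    *,
    n_samples: int | None = None,
    n_replicates: int = 1,
    sample_stride: int = 1,
    init: str = "stationary",
    burn_in_steps: int | None = None,
    record_positions: bool = False,
) -> ChainTrajectory:
    """Euler-Maruyama simulation of the chain's Langevin dynamics.

    Either ``n_steps`` (total post-burn-in steps) or ``n_samples`` (number of
    recorded frames, every ``sample_stride`` steps) must be given.  With
    ``init='stationary'`` the ensemble starts from the exact Gaussian
    stationary law and the default burn-in is short (discretization
    re-equilibration only); with ``init='coincident'`` all monomers start at
    the origin and the default burn-in is ten times the slowest Rouse
    relaxation time.

    Stability guard: dt * lambda_max / gamma must stay below 0.5.
    """
    if dt is None:
        dt = min(0.01 * spec.gamma / spec.k_eff, 0.1 * spec.gamma / spec.lambda_max)
    ratio = dt * spec.lambda_max / spec.gamma
    if ratio >= 0.5:
        raise ConfigurationError(
            f"unstable step: dt*lambda_max/gamma = {ratio:.3g} >= 0.5 "
            f"(dt={dt:.3g}, lambda_max={spec.lambda_max:.3g}, gamma={spec.gamma:.3g})"
        )
    if n_samples is None:
        if n_steps is None:
            raise InputError("give n_steps or n_samples")
        n_samples = max(1, n_steps // sample_stride)
    if n_samples < 1:
        raise InputError("need at least one sample")
    if burn_in_steps is None:
        if init == "stationary":
            # only the EM-discretization bias of the stiff modes needs to relax
            burn_in_steps = min(200, 20 * max(1, int(spec.gamma / (spec.lambda_max * dt))))
        else:
            burn_in_steps = math.ceil(10.0 * spec.slowest_relaxation_time / dt)

    rng = np.random.default_rng(seed)
    if init == "stationary" and spec.D > 0:
        pos = _stationary_positions(spec, n_replicates, rng)  # (R, 3, N)
    elif init == "coincident" or spec.D == 0:
        pos = np.zeros((n_replicates, 3, spec.N))
    else:
        raise InputError(f"unknown init mode {init!r}")

    K = spec.spring_matrix()
    noise_scale = math.sqrt(2.0 * spec.D * dt)
    e, p = spec.E - 1, spec.P - 1

    d_s = np.empty((n_replicates, n_samples))
    seps = np.empty((n_replicates, n_samples, 3))
    times = np.empty(n_samples)
    pos_rec = (
        np.empty((n_samples, n_replicates, spec.N, 3)) if record_positions else None
    )

    total_steps = burn_in_steps + n_samples * sample_stride
    isample = 0
    for step in range(1, total_steps + 1):
        drift = -(pos @ K) * (dt / spec.gamma)
        if spec.D > 0:
            pos += drift + noise_scale * rng.standard_normal(pos.shape)
        else:
            pos += drift
        if step > burn_in_steps and (step - burn_in_steps) % sample_stride == 0:
            sep = pos[:, :, e] - pos[:, :, p]  # (R, 3)
            seps[:, isample, :] = sep
            d_s[:, isample] = np.linalg.norm(sep, axis=1)
            times[isample] = step * dt
            if pos_rec is not None:
                pos_rec[isample] = np.transpose(pos, (0, 2, 1))
            isample += 1

    return ChainTrajectory(
        spec=spec, dt=dt, times=times, d_s=d_s, separations=seps,
        positions=pos_rec, burn_in_steps=burn_in_steps, seed=seed,
    )
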