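"""Coupled chromatin-transcription simulator.

Realizes the joint stochastic process: the chain moves by overdamped
Langevin dynamics while the telegraph gene switches and transcribes with
rates modulated, at every instant, by the current E-P spatial distance.
Operator splitting per step: (1) Euler-Maruyama chain update, (2) rate
refresh from the new d_S, (3) advance of the jump process over dt with the
rates frozen within the step (exponential thinning for the two switching
channels, capped at one switch per step; Poisson production; binomial
degradation).  Many independent replicate cells are advanced in one
vectorized ensemble, matching the population-snapshot semantics of
smRNA-FISH: each cell contributes its end-state mRNA count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chain import PolymerSpec, _stationary_positions
from .errors import ConfigurationError, InputError
from .link import LinkSpec
from .telegraph import Pmf

__all__ = ["Trajectory", "CoupledRun", "simulate_coupled", "summarize_trajectory"]


@dataclass
class Trajectory:
    """Recorded per-cell time series of a coupled run."""

    times: np.ndarray          # (T,)
    d_s: np.ndarray            # (T,)
    state: np.ndarray          # (T,) bool, True = ON
    mrna: np.ndarray           # (T,) int
    burn_in_index: int

    def __post_init__(self) -> None:
        n = self.times.size
        if not (self.d_s.size == self.state.size == self.mrna.size == n):
            raise InputError("trajectory series lengths differ")
        if np.any(self.mrna < 0):
            raise InputError("mRNA counts must be non-negative")


@dataclass
class CoupledRun:
    """Ensemble result of `simulate_coupled`."""

    spec: PolymerSpec
    link: LinkSpec
    dt: float
    t_end: float
    seed: int
    counts: np.ndarray         # (n_cells,) end-state mRNA
    d_s_final: np.ndarray      # (n_cells,)
    trajectories: list[Trajectory]

    def histogram(self, x_max: int | None = None) -> Pmf:
        if x_max is None:
            x_max = int(self.counts.max())
        h = np.bincount(self.counts, minlength=x_max + 1).astype(float)
        return Pmf(h / h.sum())


def simulate_coupled(
    spec: PolymerSpec,
    link: LinkSpec,
    t_end: float,
    n_cells: int,
    dt: float | None = None,
    seed: int = 0,
    record_cells: int = 0,
    record_stride: int = 1,
    burn_in_time: float = 0.0,
) -> CoupledRun:
    """Simulate ``n_cells`` independent cells to ``t_end``.

    Cells start with the chain drawn from its exact stationary law, gene
    OFF and zero mRNA; ``t_end`` (in units where the rates are expressed)
    must exceed the transcriptional relaxation time so the end-state
    histogram is stationary.  Guards: the chain step must satisfy
    dt * lambda_max / gamma < 0.5 and the switching rates
    max(alpha_max, beta) * dt < 0.1.  Identical seeds give identical runs.
    """
    if n_cells < 1:
        raise InputError("n_cells must be >= 1")
    if t_end <= 0:
        raise InputError("t_end must be positive")
    rate_cap = max(link.alpha_max, link.beta)
    if dt is None:
        dt = 0.1 * spec.gamma / spec.lambda_max
        if rate_cap > 0:
            dt = min(dt, 0.05 / rate_cap)
    chain_ratio = dt * spec.lambda_max / spec.gamma
    if chain_ratio >= 0.5:
        raise ConfigurationError(
            f"unstable chain step: dt*lambda_max/gamma = {chain_ratio:.3g} >= 0.5"
        )
    if rate_cap * dt >= 0.1:
        raise ConfigurationError(
            f"switching too fast for the step: max(alpha_max, beta)*dt = "
            f"{rate_cap * dt:.3g} >= 0.1"
        )
    record_cells = min(record_cells, n_cells)

    rng = np.random.default_rng(seed)
    pos = _stationary_positions(spec, n_cells, rng)  # (n_cells, 3, N)
    gene = np.zeros(n_cells, dtype=bool)
    mrna = np.zeros(n_cells, dtype=np.int64)

    K = spec.spring_matrix()
    noise_scale = math.sqrt(2.0 * spec.D * dt)
    e, p = spec.E - 1, spec.P - 1
    n_steps = max(1, int(round((burn_in_time + t_end) / dt)))
    burn_steps = int(round(burn_in_time / dt))
    p_deg = -math.expm1(-link.delta * dt)

    rec_t, rec_d, rec_s, rec_m = [], [], [], []
    d_s = np.linalg.norm(pos[:, :, e] - pos[:, :, p], axis=1)
    for step in range(1, n_steps + 1):
        # (1) chain update
        pos += -(pos @ K) * (dt / spec.gamma) + noise_scale * rng.standard_normal(pos.shape)
        d_s = np.linalg.norm(pos[:, :, e] - pos[:, :, p], axis=1)
        # (2) rates from the new distance
        alpha = link.alpha(d_s)
        mu = link.mu(d_s)
        # (3) jump process over dt, rates frozen within the step
        u = rng.random(n_cells)
        switch_on = (~gene) & (u < -np.expm1(-alpha * dt))
        switch_off = gene & (u < -math.expm1(-link.beta * dt))
        gene ^= switch_on | switch_off
        born = rng.poisson(mu * dt * gene)
        mrna += born
        mrna -= rng.binomial(mrna, p_deg)
        if record_cells and step % record_stride == 0:
            rec_t.append(step * dt)
            rec_d.append(d_s[:record_cells].copy())
            rec_s.append(gene[:record_cells].copy())
            rec_m.append(mrna[:record_cells].copy())

    trajectories = []
    if record_cells:
        times = np.asarray(rec_t)
        burn_idx = int(np.searchsorted(times, burn_in_time, side="right"))
        D = np.asarray(rec_d)
        S = np.asarray(rec_s)
        M = np.asarray(rec_m)
        for c in range(record_cells):
            trajectories.append(
                Trajectory(
                    times=times, d_s=D[:, c], state=S[:, c], mrna=M[:, c],
                    burn_in_index=burn_idx,
                )
            )
    return CoupledRun(
        spec=spec, link=link, dt=dt, t_end=t_end, seed=seed,
        counts=mrna.copy(), d_s_final=d_s.copy(), trajectories=trajectories,
    )


def _dwell_means(traj: Trajectory, dt_frame: float) -> tuple[float | None, float | None]:
    """Empirical mean ON and OFF dwell times from a recorded state series.

    Only completed (uncensored) visits count; returns None when a state was
    never exited."""
    s = traj.state[traj.burn_in_index:]
    if s.size < 3:
        return None, None
    change = np.flatnonzero(np.diff(s.astype(np.int8)) != 0) + 1
    if change.size < 2:
        return None, None
    runs = np.diff(change) * dt_frame
    kinds = s[change[:-1]]  # state during each completed run
    on_runs = runs[kinds]
    off_runs = runs[~kinds]
    on = float(on_runs.mean()) if on_runs.size else None
    off = float(off_runs.mean()) if off_runs.size else None
    return on, off


def summarize_trajectory(run: CoupledRun) -> dict:
    """Population summary: end-state mean/CV, histogram, and empirical
    ON/OFF dwell-time means from any recorded cells."""
    counts = run.counts
    if counts.size == 0:
        raise InputError("no post-burn-in samples to summarize")
    hist = run.histogram()
    mean = float(counts.mean())
    sd = float(counts.std())
    cv = sd / mean if mean > 0 else (0.0 if sd == 0 else float("inf"))
    on_means, off_means = [], []
    if run.trajectories:
        dt_frame = float(np.diff(run.trajectories[0].times[:2])[0]) if (
            run.trajectories[0].times.size > 1
        ) else run.dt
        for traj in run.trajectories:
            on, off = _dwell_means(traj, dt_frame)
            if on is not None:
                on_means.append(on)
            if off is not None:
                off_means.append(off)
    return dict(
        mean=mean,
        cv=cv,
        histogram=hist,
        on_dwell_mean=float(np.mean(on_means)) if on_means else None,
        off_dwell_mean=float(np.mean(off_means)) if off_means else None,
        n_cells=int(counts.size),
    )
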