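"""Euler-Maruyama simulation of the coupled network SDE and H-infinity verification.

Each cell *i* carries one scalar Wiener path (intrinsic kinetic fluctuation)
and one scalar extrinsic-noise path, so the Ito step for the full population
reads::

    x_i+ = x_i + [f(x_i) + sum_j c_ij g(x_j) + h v_i] dt
               + [f_W(x_i) + sum_j c_ij g_W(x_j)] dW_i

The extrinsic noise is realized as band-limited white noise: an independent
``Normal(0, sigma_v^2)`` draw per step held constant over ``[t_k, t_k+dt)``,
which keeps the disturbance energy integral finite.  The Wiener increments
are ``Normal(0, dt)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from quorumsync.genetic_network import (
    M_SPECIES,
    CouplingMatrix,
    ExtrinsicNoiseSpec,
    FluctuationAmplitudes,
    RepressilatorParams,
    _drift_raw,
    _noise_field_raw,
)

__all__ = [
    "SimulationConfig",
    "TrajectoryEnsemble",
    "ErrorTrajectory",
    "MonteCarloResult",
    "IntegrationError",
    "euler_maruyama_step",
    "simulate_network",
    "simulate_reference",
    "attractor_segment",
    "phase_jittered_initial",
    "compute_errors",
    "filtering_ratio",
    "monte_carlo_filtering",
]

_OVERFLOW_GUARD = 1e9


class IntegrationError(RuntimeError):
    """Raised when the integration produces non-finite or exploding states."""

    def __init__(self, message: str, step: int | None = None, time: float | None = None):
        super().__init__(message)
        self.step = step
        self.time = time


@dataclass(frozen=True)
class SimulationConfig:
    """Time grid, seeding, population size and initial-condition policy."""

    dt: float = 0.005
    t_final: float = 100.0
    seed: int = 0
    n_cells: int = 10
    Q: float = 0.0
    init: np.ndarray | None = None
    init_mode: str = "uniform"          # "uniform" box | "phase-jitter" on the attractor
    init_low: float = 0.0
    init_high: float = 5.0
    jitter_spread: float = 0.5          # time-unit phase spread for "phase-jitter"
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not np.isfinite(self.t_final) or self.t_final < self.dt:
            raise ValueError(f"t_final must be >= dt, got {self.t_final}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.init is not None:
            init = np.asarray(self.init, dtype=float)
            if init.shape != (self.n_cells, M_SPECIES):
                raise ValueError(
                    f"explicit initial condition must have shape ({self.n_cells}, {M_SPECIES}),"
                    f" got {init.shape}"
                )
            if not np.all(np.isfinite(init)) or np.any(init < 0):
                raise ValueError("explicit initial condition must be finite and nonnegative")
            object.__setattr__(self, "init", init)
        if self.init_high < self.init_low:
            raise ValueError("init_high must be >= init_low")
        if self.init_mode not in ("uniform", "phase-jitter"):
            raise ValueError(f"unknown init_mode: {self.init_mode!r}")
        if self.jitter_spread < 0:
            raise ValueError("jitter_spread must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_final / self.dt))

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class TrajectoryEnsemble:
    """States indexed ``(run, time, cell, species)`` plus the extrinsic-noise record."""

    t: np.ndarray
    states: np.ndarray          # (n_runs, n_t, N, 7)
    v: np.ndarray               # (n_runs, n_t - 1, N), left-endpoint draws
    config: SimulationConfig
    run_seeds: tuple[int, ...]

    def __post_init__(self) -> None:
        n_runs, n_t, n_cells, m = self.states.shape
        if m != M_SPECIES or n_t != self.t.shape[0]:
            raise ValueError("inconsistent ensemble shapes")
        if self.v.shape != (n_runs, n_t - 1, n_cells):
            raise ValueError("extrinsic-noise record shape mismatch")

    @property
    def n_runs(self) -> int:
        return self.states.shape[0]

    @property
    def n_cells(self) -> int:
        return self.states.shape[2]


@dataclass
class ErrorTrajectory:
    """Deviations from a synchronization reference, ``(run, time, cell, species)``."""

    e: np.ndarray
    reference: np.ndarray       # (n_runs, n_t, 7)
    kind: str                   # "population-mean" | "nominal-limit-cycle"
    t: np.ndarray


@dataclass
class MonteCarloResult:
    """Pooled H-infinity energy-ratio estimate with jackknife standard errors."""

    ratio: float
    sqrt_ratio: float
    se: float
    sqrt_se: float
    n_runs: int
    base_seed: int
    numerators: np.ndarray
    denominators: np.ndarray

    def to_dict(self) -> dict:
        return {
            "ratio": float(self.ratio),
            "sqrt_ratio": float(self.sqrt_ratio),
            "se": float(self.se),
            "sqrt_se": float(self.sqrt_se),
            "n_runs": int(self.n_runs),
            "base_seed": int(self.base_seed),
        }


def euler_maruyama_step(
    x: np.ndarray,
    drift: np.ndarray,
    intrinsic: np.ndarray,
    extrinsic: np.ndarray,
    dt: float,
    dW: np.ndarray,
    v: np.ndarray,
    clip_negative: bool = False,
) -> np.ndarray:
    """One Ito Euler step ``x + (drift + v*extrinsic) dt + intrinsic dW``.

    ``x``, ``drift`` and ``intrinsic`` have species on the last axis;
    ``dW`` and ``v`` are per-cell scalars broadcast over species.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x = np.asarray(x, dtype=float)
    dW = np.asarray(dW, dtype=float)
    v = np.asarray(v, dtype=float)
    out = (
        x
        + (np.asarray(drift, dtype=float) + v[..., None] * np.asarray(extrinsic, dtype=float)) * dt
        + np.asarray(intrinsic, dtype=float) * dW[..., None]
    )
    if not np.all(np.isfinite(out)):
        raise IntegrationError("non-finite state after Euler-Maruyama step")
    if clip_negative:
        np.maximum(out, 0.0, out=out)
    return out


_ATTRACTOR_CACHE: dict[tuple, np.ndarray] = {}


def attractor_segment(params: RepressilatorParams, dt: float = 0.005) -> np.ndarray:
    """A settled stretch of the noise-free single-cell trajectory (cached).

    Integrates through the transient and returns the final 100 time units,
    which cover many oscillation periods of the nominal limit cycle.
    """
    key = (tuple(sorted(params.to_dict().items())), round(dt, 12))
    if key not in _ATTRACTOR_CACHE:
        x0 = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 3.0, 0.0])
        n_total = int(round(250.0 / dt))
        traj = simulate_reference(params, x0, dt, n_total)
        _ATTRACTOR_CACHE[key] = traj[int(round(150.0 / dt)):]
    return _ATTRACTOR_CACHE[key]


def phase_jittered_initial(
    params: RepressilatorParams,
    n_cells: int,
    spread: float,
    rng: np.random.Generator,
    dt: float = 0.005,
) -> np.ndarray:
    """Cells placed on the nominal attractor at phases offset by ``U(-spread, spread)``.

    An "uncertain initial state" for an oscillating population: every cell
    starts on its oscillatory attractor but at an uncertain phase.
    """
    traj = attractor_segment(params, dt)
    anchor = traj.shape[0] // 2
    offsets = rng.uniform(-spread, spread, n_cells)
    idx = np.clip(anchor + np.round(offsets / dt).astype(int), 0, traj.shape[0] - 1)
    return traj[idx].copy()


def _draw_initial(
    config: SimulationConfig, rng: np.random.Generator, params: RepressilatorParams
) -> np.ndarray:
    if config.init is not None:
        return config.init.copy()
    if config.init_mode == "phase-jitter":
        return phase_jittered_initial(
            params, config.n_cells, config.jitter_spread, rng, config.dt
        )
    return rng.uniform(config.init_low, config.init_high, size=(config.n_cells, M_SPECIES))


def simulate_network(
    params: RepressilatorParams,
    amplitudes: FluctuationAmplitudes,
    coupling: CouplingMatrix,
    noise: ExtrinsicNoiseSpec,
    config: SimulationConfig,
) -> TrajectoryEnsemble:
    """Integrate one seeded realization of the full population SDE.

    The RNG draw order is fixed (initial condition, then per step: the N
    Wiener increments followed by the N extrinsic draws), so identical
    configurations reproduce bit-identical ensembles.
    """
    if coupling.n_cells != config.n_cells:
        raise ValueError(
            f"coupling matrix is {coupling.n_cells}x{coupling.n_cells} but n_cells={config.n_cells}"
        )
    rng = np.random.default_rng(config.seed)
    n_steps = config.n_steps
    N = config.n_cells

    x = _draw_initial(config, rng, params)
    states = np.empty((1, n_steps + 1, N, M_SPECIES))
    v_record = np.empty((1, n_steps, N))
    states[0, 0] = x

    C = coupling.values
    h = noise.h_cell
    sigma_v = noise.sigma_v
    dt = config.dt
    sqrt_dt = np.sqrt(dt)
    clip = config.clip_negative
    gw_scale = amplitudes.d_eta_s / params.eta_s
    intrinsic_on = not amplitudes.is_zero

    for k in range(n_steps):
        # draw both streams unconditionally so a sigma_v = 0 twin run with the
        # same seed shares the identical Wiener path
        dW = rng.standard_normal(N) * sqrt_dt
        v = rng.standard_normal(N) * sigma_v

        drift = _drift_raw(x, params)
        # diffusive AI exchange; the deviation form C @ (x_S - mean) is exact
        # for zero-row-sum C and keeps the synchronization manifold invariant
        # to the last bit for identical cells
        xs_dev = x[:, 6] - x[:, 6].mean()
        drift[:, 6] += C @ xs_dev
        if sigma_v > 0:
            drift += v[:, None] * h

        if intrinsic_on:
            diffusion = _noise_field_raw(x, params, amplitudes)
            diffusion[:, 6] += gw_scale * (C @ xs_dev)
            x = x + drift * dt + diffusion * dW[:, None]
        else:
            x = x + drift * dt

        if clip:
            np.maximum(x, 0.0, out=x)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > _OVERFLOW_GUARD:
            raise IntegrationError(
                f"integration blew up at step {k + 1} (t = {(k + 1) * dt:.4f})",
                step=k + 1,
                time=(k + 1) * dt,
            )
        states[0, k + 1] = x
        v_record[0, k] = v

    return TrajectoryEnsemble(
        t=config.time_grid(),
        states=states,
        v=v_record,
        config=config,
        run_seeds=(config.seed,),
    )


def simulate_reference(
    params: RepressilatorParams,
    x0: np.ndarray,
    dt: float,
    n_steps: int,
    clip_negative: bool = True,
) -> np.ndarray:
    """Noise-free single-cell trajectory on the same Euler grid, shape ``(n_steps+1, 7)``.

    On the synchronization manifold the diffusive exchange cancels exactly,
    so the reference obeys the isolated-cell dynamics.
    """
    x = np.asarray(x0, dtype=float).copy()
    out = np.empty((n_steps + 1, M_SPECIES))
    out[0] = x
    for k in range(n_steps):
        x = x + _drift_raw(x, params) * dt
        if clip_negative:
            np.maximum(x, 0.0, out=x)
        if not np.all(np.isfinite(x)):
            raise IntegrationError(f"reference integration failed at step {k + 1}", step=k + 1)
        out[k + 1] = x
    return out


def compute_errors(
    ens: TrajectoryEnsemble,
    reference: str = "population-mean",
    params: RepressilatorParams | None = None,
) -> ErrorTrajectory:
    """Synchronization errors ``e_i = x_i - s`` against the chosen reference.

    ``"population-mean"`` uses the instantaneous ensemble mean over cells (the
    centred errors sum to zero at every time); ``"nominal-limit-cycle"``
    integrates the noise-free single-cell dynamics from the mean initial
    condition on the same grid.
    """
    if reference == "population-mean":
        s = ens.states.mean(axis=2)                      # (runs, t, 7)
    elif reference == "nominal-limit-cycle":
        if params is None:
            raise ValueError("nominal reference requires the kinetic parameters")
        n_steps = ens.t.shape[0] - 1
        dt = ens.config.dt
        s = np.empty((ens.n_runs, n_steps + 1, M_SPECIES))
        for r in range(ens.n_runs):
            x0 = ens.states[r, 0].mean(axis=0)
            s[r] = simulate_reference(params, x0, dt, n_steps, ens.config.clip_negative)
    else:
        raise ValueError(f"unknown reference kind: {reference!r}")
    e = ens.states - s[:, :, None, :]
    return ErrorTrajectory(e=e, reference=s, kind=reference, t=ens.t)


def _resolve_R(R, n_cells: int) -> np.ndarray | None:
    """Normalize the error weighting to per-species weights or a full matrix."""
    if R is None:
        return None
    R = np.asarray(R, dtype=float)
    if R.ndim == 0:
        return None if float(R) == 1.0 else np.full(M_SPECIES, float(R))
    if R.shape == (M_SPECIES,):
        return R
    dim = n_cells * M_SPECIES
    if R.shape == (dim, dim):
        if not np.allclose(R, R.T):
            raise ValueError("weighting R must be symmetric")
        return R
    raise ValueError(f"weighting R must be scalar, ({M_SPECIES},) or ({dim},{dim}), got {R.shape}")


def _energy_integrals(
    err: ErrorTrajectory, ens: TrajectoryEnsemble, R
) -> tuple[np.ndarray, np.ndarray]:
    """Per-run left-Riemann integrals of ``e^T R e`` and ``v^T v``."""
    dt = ens.config.dt
    e = err.e[:, :-1]                                    # left endpoints
    Rw = _resolve_R(R, ens.n_cells)
    if Rw is None:
        num = np.einsum("rtcs,rtcs->r", e, e) * dt
    elif Rw.ndim == 1:
        num = np.einsum("rtcs,s,rtcs->r", e, Rw, e) * dt
    else:
        n_runs, n_t = e.shape[0], e.shape[1]
        flat = e.reshape(n_runs, n_t, -1)
        num = np.einsum("rti,ij,rtj->r", flat, Rw, flat) * dt
    den = np.einsum("rtc,rtc->r", ens.v, ens.v) * dt
    return num, den


def filtering_ratio(
    err: ErrorTrajectory,
    ens: TrajectoryEnsemble,
    R=None,
    include_initial: bool = False,
    P: np.ndarray | None = None,
) -> float:
    """Empirical disturbance-attenuation ratio ``E[int e'Re dt] / E[int v'v dt]``.

    Expectations are ensemble means, integrals left Riemann sums.  With
    ``include_initial`` the stored initial-condition energy ``E[e(0)' P e(0)]``
    is subtracted from the numerator (floored at zero).
    """
    num, den = _energy_integrals(err, ens, R)
    denominator = float(den.mean())
    if denominator <= 0:
        raise ValueError(
            "disturbance energy is zero (sigma_v = 0?); the ratio is undefined -- "
            "use deterministic synchronization diagnostics instead"
        )
    numerator = float(num.mean())
    if include_initial:
        if P is None:
            raise ValueError("include_initial requires the certificate matrix P")
        e0 = err.e[:, 0].reshape(err.e.shape[0], -1)
        v0 = float(np.einsum("ri,ij,rj->", e0, P, e0) / e0.shape[0])
        numerator = max(numerator - v0, 0.0)
    return numerator / denominator


def monte_carlo_filtering(
    params: RepressilatorParams,
    amplitudes: FluctuationAmplitudes,
    coupling: CouplingMatrix,
    noise: ExtrinsicNoiseSpec,
    config: SimulationConfig,
    n_runs: int,
    base_seed: int,
    R=None,
    reference: str = "population-mean",
    estimator: str = "direct",
) -> MonteCarloResult:
    """Monte-Carlo estimate of the energy ratio, pooled across seeded runs.

    Run *r* uses seed ``base_seed + r``.  Numerator and denominator energies
    are pooled before dividing (a ratio of expectations, not an expectation
    of ratios); standard errors come from leave-one-run-out jackknife.

    ``estimator="direct"`` measures the raw synchronization-error energy.
    ``estimator="v-twin"`` isolates the extrinsic-noise-induced part: each
    run is paired with a twin sharing the same seed (identical initial state
    and Wiener paths) but with the extrinsic noise switched off, and the
    numerator uses the difference of the two centred error signals.  This
    realizes the disturbance-attenuation ratio for a reference that carries
    the same intrinsic fluctuations as the population, under which intrinsic
    noise acts multiplicatively on the error and is "tolerated" rather than
    counted as disturbance energy.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 for jackknife standard errors")
    if estimator not in ("direct", "v-twin"):
        raise ValueError(f"unknown estimator: {estimator!r}")
    nums = np.empty(n_runs)
    dens = np.empty(n_runs)
    twin_noise = None
    if estimator == "v-twin":
        twin_noise = ExtrinsicNoiseSpec(
            h_cell=noise.h_cell, sigma_v=0.0, h_ref=noise.h_ref
        )
    for r in range(n_runs):
        run_cfg = config.replace(seed=base_seed + r)
        try:
            ens = simulate_network(params, amplitudes, coupling, noise, run_cfg)
        except IntegrationError as exc:
            raise IntegrationError(f"run {r} (seed {base_seed + r}): {exc}") from exc
        err = compute_errors(ens, reference, params=params)
        if estimator == "v-twin":
            twin = simulate_network(params, amplitudes, coupling, twin_noise, run_cfg)
            twin_err = compute_errors(twin, reference, params=params)
            err = ErrorTrajectory(
                e=err.e - twin_err.e, reference=err.reference, kind=err.kind, t=err.t
            )
        num, den = _energy_integrals(err, ens, R)
        nums[r], dens[r] = num[0], den[0]

    total_num, total_den = nums.sum(), dens.sum()
    if total_den <= 0:
        raise ValueError("disturbance energy is zero; the ratio is undefined")
    ratio = total_num / total_den
    loo = (total_num - nums) / (total_den - dens)
    se = float(np.sqrt((n_runs - 1) / n_runs * np.sum((loo - loo.mean()) ** 2)))
    sqrt_loo = np.sqrt(loo)
    sqrt_se = float(np.sqrt((n_runs - 1) / n_runs * np.sum((sqrt_loo - sqrt_loo.mean()) ** 2)))
    return MonteCarloResult(
        ratio=float(ratio),
        sqrt_ratio=float(np.sqrt(ratio)),
        se=se,
        sqrt_se=sqrt_se,
        n_runs=n_runs,
        base_seed=base_seed,
        numerators=nums,
        denominators=dens,
    )
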