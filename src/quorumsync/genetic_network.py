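"""Coupled stochastic repressilator model with quorum-sensing coupling.

State layout (dimension ``M_SPECIES = 7``, fixed ordering)::

    index  0    1    2    3    4    5    6
    name   x_a  x_b  x_c  x_A  x_B  x_C  x_S

``x_a, x_b, x_c`` are the mRNA levels of *tetR*, *cI*, *lacI*; ``x_A, x_B,
x_C`` the corresponding protein levels (TetR, CI, LacI); ``x_S`` is the
intracellular autoinducer (AI) concentration.  The cell-local drift excludes
the diffusive AI exchange; that term is carried by a zero-row-sum coupling
configuration matrix acting on the inner-coupling function ``g(x) =
(0,...,0, x_S)``.

All vector-field functions accept arrays with the species on the last axis,
so a population state of shape ``(N, 7)`` is processed in one call.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "M_SPECIES",
    "SPECIES",
    "RepressilatorParams",
    "FluctuationAmplitudes",
    "ExtrinsicNoiseSpec",
    "CouplingMatrix",
    "drift_single_cell",
    "coupling_function",
    "build_coupling_matrix",
    "intrinsic_noise_field",
    "coupling_noise_function",
    "drift_jacobian",
    "noise_field_jacobian",
]

M_SPECIES = 7
SPECIES = ("x_a", "x_b", "x_c", "x_A", "x_B", "x_C", "x_S")


@dataclass(frozen=True)
class RepressilatorParams:
    """Nominal kinetic constants of one oscillator cell.

    Defaults are the in-silico design example's parameter set.
    """

    alpha_a: float = 216.0
    alpha_b: float = 216.0
    alpha_c: float = 216.0
    alpha_S: float = 20.0
    mu: float = 1.2
    mu_S: float = 1.0
    n: float = 2.0
    beta_A: float = 1.0
    beta_B: float = 1.0
    beta_C: float = 1.0
    beta_s: float = 0.1
    gamma_m: float = 6.9315
    gamma_p: float = 1.1552
    gamma_s: float = 1.0
    eta_s: float = 2.0
    Q_e: float = 0.09

    def __post_init__(self) -> None:
        for name in (
            "alpha_a", "alpha_b", "alpha_c", "alpha_S", "mu", "mu_S",
            "beta_A", "beta_B", "beta_C", "beta_s",
            "gamma_m", "gamma_p", "gamma_s", "eta_s",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name} must be finite and > 0, got {value}")
        if not np.isfinite(self.n) or self.n < 1:
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")
        if not (0.0 <= self.Q_e <= 1.0):
            raise ValueError(f"Q_e must satisfy 0 <= Q_e <= 1, got {self.Q_e}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "RepressilatorParams":
        unknown = set(mapping) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown model keys: {sorted(unknown)}")
        return cls(**mapping)

    def replace(self, **changes) -> "RepressilatorParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class FluctuationAmplitudes:
    """Standard deviations of the stochastic kinetic-parameter fluctuations.

    Each amplitude has the units of its nominal counterpart.  A zero vector
    makes the intrinsic dynamics deterministic.  Defaults follow the design
    example.
    """

    d_alpha_a: float = 2.16
    d_alpha_b: float = 2.16
    d_alpha_c: float = 2.16
    d_alpha_S: float = 0.2
    d_beta_A: float = 0.01
    d_beta_B: float = 0.01
    d_beta_C: float = 0.01
    d_beta_s: float = 0.001
    d_gamma_m: float = 0.06
    d_gamma_p: float = 0.01
    d_gamma_s: float = 0.01
    d_eta_s: float = 0.02

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"amplitude {f.name} must be finite and >= 0, got {value}")

    @property
    def is_zero(self) -> bool:
        return all(getattr(self, f.name) == 0.0 for f in dataclasses.fields(self))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "FluctuationAmplitudes":
        unknown = set(mapping) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown fluctuation keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def zero(cls) -> "FluctuationAmplitudes":
        return cls(**{f.name: 0.0 for f in dataclasses.fields(cls)})

    def scaled(self, factor: float) -> "FluctuationAmplitudes":
        return FluctuationAmplitudes(
            **{f.name: getattr(self, f.name) * factor for f in dataclasses.fields(self)}
        )


def _as_array7(h) -> np.ndarray:
    arr = np.asarray(h, dtype=float)
    if arr.shape != (M_SPECIES,):
        raise ValueError(f"noise-coupling column must have shape ({M_SPECIES},), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("noise-coupling column must be finite")
    return arr


@dataclass(frozen=True)
class ExtrinsicNoiseSpec:
    """Extrinsic environmental-noise coupling.

    One scalar noise source per cell enters the state equations through the
    column ``h_cell``; ``h_ref`` is the coupling of the (by default
    noise-free) synchronization reference.
    """

    h_cell: np.ndarray = field(default_factory=lambda: np.ones(M_SPECIES))
    sigma_v: float = 0.02
    h_ref: np.ndarray = field(default_factory=lambda: np.zeros(M_SPECIES))

    def __post_init__(self) -> None:
        object.__setattr__(self, "h_cell", _as_array7(self.h_cell))
        object.__setattr__(self, "h_ref", _as_array7(self.h_ref))
        if not np.isfinite(self.sigma_v) or self.sigma_v < 0:
            raise ValueError(f"sigma_v must be finite and >= 0, got {self.sigma_v}")

    @property
    def h_effective(self) -> np.ndarray:
        """Per-cell error-equation noise column, ``h_cell - h_ref``."""
        return self.h_cell - self.h_ref

    def to_dict(self) -> dict:
        return {
            "h_cell": list(map(float, self.h_cell)),
            "sigma_v": float(self.sigma_v),
            "h_ref": list(map(float, self.h_ref)),
        }

    @classmethod
    def from_dict(cls, mapping: dict) -> "ExtrinsicNoiseSpec":
        unknown = set(mapping) - {"h_cell", "sigma_v", "h_ref"}
        if unknown:
            raise ValueError(f"unknown extrinsic-noise keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass(frozen=True)
class CouplingMatrix:
    """Zero-row-sum quorum-coupling configuration matrix.

    ``values[i, j]`` weights how strongly the inner-coupling output of cell
    *j* enters the dynamics of cell *i*.  The all-to-all mean-field topology
    is symmetric with equal off-diagonal entries.
    """

    values: np.ndarray
    eta_s: float = float("nan")
    Q_e: float = float("nan")
    Q: float = float("nan")

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"coupling matrix must be square, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("coupling matrix must be finite")
        off = values - np.diag(np.diag(values))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal coupling entries must be >= 0")
        row_sums = values.sum(axis=1)
        if np.max(np.abs(row_sums)) > 1e-9 * max(1.0, np.max(np.abs(values))):
            raise ValueError(f"coupling rows must sum to zero, got {row_sums}")
        object.__setattr__(self, "values", values)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def to_csv(self) -> str:
        buf = io.StringIO()
        n = self.n_cells
        buf.write(",".join(f"cell_{j}" for j in range(n)) + "\n")
        for i in range(n):
            buf.write(",".join(repr(float(v)) for v in self.values[i]) + "\n")
        return buf.getvalue()


def build_coupling_matrix(N: int, eta_s: float, Q_e: float, Q: float = 0.0) -> CouplingMatrix:
    """All-to-all quorum-coupling matrix, optionally with external gain ``Q``.

    Diagonal entries are ``-eta_s (1 - 1/N)(Q_e + Q)`` and off-diagonal
    entries ``eta_s (Q_e + Q) / N``; with ``Q = 0`` this is the uncontrolled
    configuration.  ``N = 1`` degenerates to the 1x1 zero matrix.
    """
    if N < 1:
        raise ValueError(f"population size N must be >= 1, got {N}")
    if eta_s <= 0:
        raise ValueError(f"eta_s must be > 0, got {eta_s}")
    if Q_e + Q < 0:
        raise ValueError(f"total coupling fraction Q_e + Q must be >= 0, got {Q_e + Q}")
    strength = eta_s * (Q_e + Q)
    values = np.full((N, N), strength / N)
    np.fill_diagonal(values, -strength * (1.0 - 1.0 / N))
    return CouplingMatrix(values=values, eta_s=eta_s, Q_e=Q_e, Q=Q)


def _validate_state(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != M_SPECIES:
        raise ValueError(f"state must have {M_SPECIES} species on the last axis, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite values")
    if np.any(x < 0):
        raise ValueError("state contains negative concentrations")
    return x


def _drift_raw(x: np.ndarray, p: RepressilatorParams) -> np.ndarray:
    """Cell-local drift without validation; ``x`` has species on the last axis."""
    xa, xb, xc = x[..., 0], x[..., 1], x[..., 2]
    xA, xB, xC = x[..., 3], x[..., 4], x[..., 5]
    xS = x[..., 6]
    out = np.empty_like(x)
    out[..., 0] = -p.gamma_m * xa + p.alpha_a / (p.mu + xC ** p.n)
    out[..., 1] = -p.gamma_m * xb + p.alpha_b / (p.mu + xA ** p.n)
    out[..., 2] = (
        -p.gamma_m * xc
        + p.alpha_c / (p.mu + xB ** p.n)
        + p.alpha_S * xS / (p.mu_S + xS)
    )
    out[..., 3] = -p.gamma_p * xA + p.beta_A * xa
    out[..., 4] = -p.gamma_p * xB + p.beta_B * xb
    out[..., 5] = -p.gamma_p * xC + p.beta_C * xc
    out[..., 6] = -p.gamma_s * xS + p.beta_s * xA
    return out


def drift_single_cell(x, p: RepressilatorParams) -> np.ndarray:
    """Nominal cell-local drift ``f(x)``, excluding the diffusive AI exchange.

    Three Hill-repressed transcription equations (the *lacI* one additionally
    AI-activated), three linear translation/degradation equations and the AI
    synthesis/decay balance.
    """
    return _drift_raw(_validate_state(x), p)


def coupling_function(x) -> np.ndarray:
    """Inner-coupling output ``g(x) = (0, ..., 0, x_S)``.

    Only the intracellular AI concentration is exchanged between cells; the
    zero-row-sum coupling matrix turns this into diffusive mean-field
    coupling.
    """
    x = _validate_state(x)
    out = np.zeros_like(x)
    out[..., 6] = x[..., 6]
    return out


def _noise_field_raw(x: np.ndarray, p: RepressilatorParams, d: FluctuationAmplitudes) -> np.ndarray:
    xa, xb, xc = x[..., 0], x[..., 1], x[..., 2]
    xA, xB, xC = x[..., 3], x[..., 4], x[..., 5]
    xS = x[..., 6]
    out = np.empty_like(x)
    out[..., 0] = -d.d_gamma_m * xa + d.d_alpha_a / (p.mu + xC ** p.n)
    out[..., 1] = -d.d_gamma_m * xb + d.d_alpha_b / (p.mu + xA ** p.n)
    out[..., 2] = (
        -d.d_gamma_m * xc
        + d.d_alpha_c / (p.mu + xB ** p.n)
        + d.d_alpha_S * xS / (p.mu_S + xS)
    )
    out[..., 3] = -d.d_gamma_p * xA + d.d_beta_A * xa
    out[..., 4] = -d.d_gamma_p * xB + d.d_beta_B * xb
    out[..., 5] = -d.d_gamma_p * xC + d.d_beta_C * xc
    out[..., 6] = -d.d_gamma_s * xS + d.d_beta_s * xA
    return out


def intrinsic_noise_field(x, p: RepressilatorParams, d: FluctuationAmplitudes) -> np.ndarray:
    """Intrinsic-fluctuation field ``f_W(x)``: the cell-local Wiener coefficient.

    Obtained from the drift by substituting each nominal kinetic parameter
    with its fluctuation amplitude (denominator constants ``mu``, ``mu_S``
    and the Hill exponent stay nominal).  The fluctuation of the AI
    diffusion rate is factored through the coupling matrix separately, see
    :func:`coupling_noise_function`.
    """
    return _noise_field_raw(_validate_state(x), p, d)


def coupling_noise_function(x, eta_s: float, d_eta_s: float) -> np.ndarray:
    """Coupling-fluctuation output ``g_W(x) = (d_eta_s / eta_s) * g(x)``.

    Routing the AI-diffusion fluctuation through the same coupling matrix
    (which carries the ``eta_s * (Q_e + Q)`` structure) as a scalar rescaling
    keeps a single configuration matrix in the stacked error system.
    """
    if eta_s == 0:
        raise ValueError("eta_s must be nonzero to scale the coupling fluctuation")
    return (d_eta_s / eta_s) * coupling_function(x)


# --- analytic Jacobians (used for T-S local models) -------------------------

def _hill_derivative(alpha: float, mu: float, n: float, x: float) -> float:
    # d/dx [alpha / (mu + x^n)] = -alpha n x^(n-1) / (mu + x^n)^2
    if x == 0.0 and n < 1.0 + 1e-12 and n > 1.0 - 1e-12:
        return -alpha / mu ** 2
    return -alpha * n * x ** (n - 1.0) / (mu + x ** n) ** 2


def drift_jacobian(x, p: RepressilatorParams) -> np.ndarray:
    """Analytic Jacobian of :func:`drift_single_cell` at a single state."""
    x = _validate_state(np.asarray(x, dtype=float))
    if x.ndim != 1:
        raise ValueError("drift_jacobian expects a single state vector")
    xa, xb, xc, xA, xB, xC, xS = x
    J = np.zeros((M_SPECIES, M_SPECIES))
    J[0, 0] = -p.gamma_m
    J[0, 5] = _hill_derivative(p.alpha_a, p.mu, p.n, xC)
    J[1, 1] = -p.gamma_m
    J[1, 3] = _hill_derivative(p.alpha_b, p.mu, p.n, xA)
    J[2, 2] = -p.gamma_m
    J[2, 4] = _hill_derivative(p.alpha_c, p.mu, p.n, xB)
    J[2, 6] = p.alpha_S * p.mu_S / (p.mu_S + xS) ** 2
    J[3, 0] = p.beta_A
    J[3, 3] = -p.gamma_p
    J[4, 1] = p.beta_B
    J[4, 4] = -p.gamma_p
    J[5, 2] = p.beta_C
    J[5, 5] = -p.gamma_p
    J[6, 3] = p.beta_s
    J[6, 6] = -p.gamma_s
    return J


def noise_field_jacobian(x, p: RepressilatorParams, d: FluctuationAmplitudes) -> np.ndarray:
    """Analytic Jacobian of :func:`intrinsic_noise_field` at a single state."""
    x = _validate_state(np.asarray(x, dtype=float))
    if x.ndim != 1:
        raise ValueError("noise_field_jacobian expects a single state vector")
    xa, xb, xc, xA, xB, xC, xS = x
    J = np.zeros((M_SPECIES, M_SPECIES))
    J[0, 0] = -d.d_gamma_m
    J[0, 5] = _hill_derivative(d.d_alpha_a, p.mu, p.n, xC)
    J[1, 1] = -d.d_gamma_m
    J[1, 3] = _hill_derivative(d.d_alpha_b, p.mu, p.n, xA)
    J[2, 2] = -d.d_gamma_m
    J[2, 4] = _hill_derivative(d.d_alpha_c, p.mu, p.n, xB)
    J[2, 6] = d.d_alpha_S * p.mu_S / (p.mu_S + xS) ** 2
    J[3, 0] = d.d_beta_A
    J[3, 3] = -d.d_gamma_p
    J[4, 1] = d.d_beta_B
    J[4, 4] = -d.d_gamma_p
    J[5, 2] = d.d_beta_C
    J[5, 5] = -d.d_gamma_p
    J[6, 3] = d.d_beta_s
    J[6, 6] = -d.d_gamma_s
    return J
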