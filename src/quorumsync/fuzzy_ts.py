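"""Takagi-Sugeno fuzzy approximation of the synchronization-error dynamics.

Local linear models ``(A_k, B_k, A_Wk, B_Wk)`` are analytic Jacobians of the
cell-local drift, the inner-coupling function and their fluctuation fields at
operating points sampled on the nominal limit cycle.  Normalized products of
triangular memberships over the premise variables interpolate the local
models; the interpolated stacked error drift is
``sum_k mu_k(z) [(I_N (x) A_k + C (x) B_k) e]``.

The premise variables are the states entering the dynamics nonlinearly:
``(x_A, x_B, x_C, x_S)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from quorumsync.genetic_network import (
    M_SPECIES,
    CouplingMatrix,
    FluctuationAmplitudes,
    RepressilatorParams,
    drift_jacobian,
    noise_field_jacobian,
)

__all__ = [
    "DEFAULT_PREMISE_INDICES",
    "OperatingPoint",
    "MembershipSpec",
    "FuzzyModel",
    "linearize_at",
    "select_operating_points",
    "membership_weights",
    "fuzzy_error_drift",
    "build_fuzzy_model",
    "LimitCycleError",
]

DEFAULT_PREMISE_INDICES = (3, 4, 5, 6)  # x_A, x_B, x_C, x_S


class LimitCycleError(RuntimeError):
    """No periodic attractor detected; try the grid method instead."""


@dataclass(frozen=True)
class OperatingPoint:
    """A state on or near the nominal trajectory and its premise coordinates."""

    state: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", np.asarray(self.state, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))


@dataclass(frozen=True)
class MembershipSpec:
    """Triangular membership layout: one peak per rule per premise variable."""

    peaks: np.ndarray                       # (L, g)
    premise_indices: tuple[int, ...] = DEFAULT_PREMISE_INDICES

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float)
        if peaks.ndim != 2:
            raise ValueError("peaks must be a (L, g) array")
        if peaks.shape[1] != len(self.premise_indices):
            raise ValueError("peaks column count must match the premise variables")
        if not np.all(np.isfinite(peaks)):
            raise ValueError("membership peaks must be finite")
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(self, "premise_indices", tuple(int(i) for i in self.premise_indices))

    @property
    def n_rules(self) -> int:
        return self.peaks.shape[0]

    @property
    def n_premise(self) -> int:
        return self.peaks.shape[1]

    def extract_premise(self, x: np.ndarray) -> np.ndarray:
        """Premise coordinates of states given with species on the last axis."""
        return np.asarray(x, dtype=float)[..., list(self.premise_indices)]


@dataclass
class FuzzyModel:
    """L local linearizations with their membership layout and provenance."""

    A: np.ndarray                   # (L, 7, 7)
    B: np.ndarray                   # (L, 7, 7)
    A_W: np.ndarray                 # (L, 7, 7)
    B_W: np.ndarray                 # (L, 7, 7)
    membership: MembershipSpec
    operating_points: list[OperatingPoint] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = self.membership.n_rules
        m = np.asarray(self.A).shape[-1]
        for name in ("A", "B", "A_W", "B_W"):
            block = np.asarray(getattr(self, name), dtype=float)
            if block.shape != (L, m, m):
                raise ValueError(f"{name} must have shape ({L}, {m}, {m})")
            if not np.all(np.isfinite(block)):
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, block)

    @property
    def n_rules(self) -> int:
        return self.membership.n_rules

    @property
    def n_states(self) -> int:
        return self.A.shape[-1]

    def rules(self):
        for k in range(self.n_rules):
            yield self.A[k], self.B[k], self.A_W[k], self.B_W[k]

    def to_json(self) -> str:
        payload = {
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "A_W": self.A_W.tolist(),
            "B_W": self.B_W.tolist(),
            "peaks": self.membership.peaks.tolist(),
            "premise_indices": list(self.membership.premise_indices),
            "operating_points": [op.state.tolist() for op in self.operating_points],
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FuzzyModel":
        payload = json.loads(text)
        spec = MembershipSpec(
            peaks=np.asarray(payload["peaks"]),
            premise_indices=tuple(payload["premise_indices"]),
        )
        ops = [
            OperatingPoint(state=np.asarray(s), z=spec.extract_premise(np.asarray(s)))
            for s in payload.get("operating_points", [])
        ]
        return cls(
            A=np.asarray(payload["A"]),
            B=np.asarray(payload["B"]),
            A_W=np.asarray(payload["A_W"]),
            B_W=np.asarray(payload["B_W"]),
            membership=spec,
            operating_points=ops,
            provenance=payload.get("provenance", {}),
        )


def linearize_at(
    point: OperatingPoint,
    params: RepressilatorParams,
    amplitudes: FluctuationAmplitudes,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Local model blocks at an operating point.

    ``A_k`` and ``A_Wk`` are the analytic Jacobians of the drift and the
    intrinsic-fluctuation field; the coupling functions are linear in
    ``x_S``, so ``B_k`` and ``B_Wk`` are constant elementary matrices.
    """
    A = drift_jacobian(point.state, params)
    A_W = noise_field_jacobian(point.state, params, amplitudes)
    B = np.zeros((M_SPECIES, M_SPECIES))
    B[6, 6] = 1.0
    B_W = np.zeros((M_SPECIES, M_SPECIES))
    B_W[6, 6] = amplitudes.d_eta_s / params.eta_s
    for name, block in (("A", A), ("A_W", A_W)):
        if not np.all(np.isfinite(block)):
            raise ValueError(f"non-finite {name} Jacobian at operating point {point.state}")
    return A, B, A_W, B_W


def _settle_trajectory(
    params: RepressilatorParams,
    dt: float = 0.005,
    t_settle: float = 150.0,
    t_observe: float = 100.0,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    from quorumsync.sde_sim import simulate_reference

    if x0 is None:
        x0 = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 3.0, 0.0])
    n_total = int(round((t_settle + t_observe) / dt))
    traj = simulate_reference(params, x0, dt, n_total)
    return traj[int(round(t_settle / dt)):]


def select_operating_points(
    params: RepressilatorParams,
    L: int,
    method: str = "limit-cycle",
    seed: int = 0,
    premise_indices: tuple[int, ...] = DEFAULT_PREMISE_INDICES,
    dt: float = 0.005,
    peak_tol: float = 0.05,
    arc: float = 1.0,
) -> list[OperatingPoint]:
    """Deterministically choose ``L`` operating points for the local models.

    ``"limit-cycle"`` settles the noise-free single cell onto its attractor,
    detects the period from successive maxima of the first mRNA species and
    samples a fraction ``arc`` of one period at equal time spacing (a short
    arc yields a local rule base).  ``"grid"`` lays a lattice over the
    observed premise ranges and snaps each lattice node to the nearest
    trajectory state.
    """
    if not 0.0 < arc <= 1.0:
        raise ValueError("arc must lie in (0, 1]")
    if L < 2:
        raise ValueError("rule count L must be >= 2")
    traj = _settle_trajectory(params, dt=dt)
    idx = list(premise_indices)

    if method == "limit-cycle":
        xa = traj[:, 0]
        peaks, _ = find_peaks(xa)
        if len(peaks) < 3:
            raise LimitCycleError(
                "fewer than three maxima of x_a on the settled trajectory; "
                "no periodic attractor detected -- use method='grid'"
            )
        peak_vals = xa[peaks]
        rel_spread = np.ptp(peak_vals[-3:]) / max(np.mean(peak_vals[-3:]), 1e-12)
        if rel_spread > peak_tol:
            raise LimitCycleError(
                f"successive x_a maxima differ by {rel_spread:.2%} (> {peak_tol:.0%}); "
                "no periodic attractor detected -- use method='grid'"
            )
        start, stop = peaks[-2], peaks[-1]
        span = max(int(round((stop - start) * arc)), L)
        sample_idx = start + np.floor(
            np.arange(L) * span / L
        ).astype(int)
        states = traj[sample_idx]
    elif method == "grid":
        z = traj[:, idx]
        lo, hi = z.min(axis=0), z.max(axis=0)
        rng = np.random.default_rng(seed)
        # low-discrepancy-ish lattice: stratified uniform nodes per variable
        nodes = lo + (hi - lo) * rng.uniform(size=(L, len(idx)))
        nodes[:, 0] = lo[0] + (hi[0] - lo[0]) * (np.arange(L) + 0.5) / L
        dists = np.linalg.norm(z[None, :, :] - nodes[:, None, :], axis=2)
        states = traj[np.argmin(dists, axis=1)]
    else:
        raise ValueError(f"unknown operating-point method: {method!r}")

    return [OperatingPoint(state=s, z=s[idx]) for s in states]


def _triangle_grid(peaks_1d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-rule (left, peak, right) supports from one variable's peak values."""
    uniq = np.unique(peaks_1d)
    left = np.empty_like(peaks_1d)
    right = np.empty_like(peaks_1d)
    for i, pk in enumerate(peaks_1d):
        pos = np.searchsorted(uniq, pk)
        left[i] = uniq[pos - 1] if pos > 0 else -np.inf
        right[i] = uniq[pos + 1] if pos + 1 < len(uniq) else np.inf
    return left, peaks_1d, right


def membership_weights(z: np.ndarray, spec: MembershipSpec) -> np.ndarray:
    """Normalized fuzzy basis values at premise vector(s) ``z``.

    Accepts shape ``(g,)`` or ``(..., g)``; returns ``(L,)`` or ``(..., L)``.
    Outside the covered range the premise value clamps to the nearest peak,
    so the basis always forms a partition of unity.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("premise values must be finite")
    scalar_input = z.ndim == 1
    zb = z[None, :] if scalar_input else z.reshape(-1, z.shape[-1])
    L, g = spec.peaks.shape
    if zb.shape[-1] != g:
        raise ValueError(f"premise vector must have length {g}, got {zb.shape[-1]}")

    raw = np.ones((zb.shape[0], L))
    for j in range(g):
        pj = spec.peaks[:, j]
        zj = np.clip(zb[:, j], pj.min(), pj.max())
        left, peak, right = _triangle_grid(pj)
        with np.errstate(invalid="ignore"):
            up = np.where(
                np.isfinite(left),
                (zj[:, None] - left) / np.where(peak - left == 0, 1.0, peak - left),
                1.0,
            )
            down = np.where(
                np.isfinite(right),
                (right - zj[:, None]) / np.where(right - peak == 0, 1.0, right - peak),
                1.0,
            )
        tri = np.clip(np.minimum(up, down), 0.0, 1.0)
        # tiny floor: premise combinations off the sampled curve would zero the
        # product basis (per-variable supports only reach adjacent peaks); the
        # floor keeps the normalized basis defined everywhere and is far below
        # any tolerance of interest near the rules themselves
        raw *= np.maximum(tri, 1e-9)

    total = raw.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise RuntimeError("all fuzzy basis products vanished; membership spec is degenerate")
    weights = raw / total
    if scalar_input:
        return weights[0]
    return weights.reshape(*z.shape[:-1], L)


def build_fuzzy_model(
    params: RepressilatorParams,
    amplitudes: FluctuationAmplitudes,
    L: int = 8,
    method: str = "limit-cycle",
    seed: int = 0,
    premise_indices: tuple[int, ...] = DEFAULT_PREMISE_INDICES,
    arc: float = 1.0,
) -> FuzzyModel:
    """Select operating points, linearize, and package the rule base."""
    points = select_operating_points(
        params, L, method=method, seed=seed, premise_indices=premise_indices, arc=arc
    )
    blocks = [linearize_at(op, params, amplitudes) for op in points]
    spec = MembershipSpec(
        peaks=np.stack([op.z for op in points]),
        premise_indices=premise_indices,
    )
    return FuzzyModel(
        A=np.stack([b[0] for b in blocks]),
        B=np.stack([b[1] for b in blocks]),
        A_W=np.stack([b[2] for b in blocks]),
        B_W=np.stack([b[3] for b in blocks]),
        membership=spec,
        operating_points=points,
        provenance={"method": method, "L": L, "seed": seed, "arc": arc},
    )


def fuzzy_error_drift(
    e: np.ndarray,
    z_cells: np.ndarray,
    model: FuzzyModel,
    coupling: CouplingMatrix,
) -> np.ndarray:
    """Interpolated stacked error drift ``sum_k mu_k [(I (x) A_k + C (x) B_k) e]``.

    ``e`` is the stacked error (length ``7 N``); ``z_cells`` holds each
    cell's premise vector, shape ``(N, g)``.  Cell *i* uses its own basis
    values for both the local and the coupling contribution.
    """
    N = coupling.n_cells
    m = model.n_states
    e = np.asarray(e, dtype=float)
    if e.shape != (N * m,):
        raise ValueError(f"stacked error must have length {N * m}, got {e.shape}")
    z_cells = np.asarray(z_cells, dtype=float)
    if z_cells.shape != (N, model.membership.n_premise):
        raise ValueError(
            f"premise array must have shape ({N}, {model.membership.n_premise}), got {z_cells.shape}"
        )
    E = e.reshape(N, m)
    W = membership_weights(z_cells, model.membership)        # (N, L)
    CE = coupling.values @ E                                 # (N, 7)
    local = np.einsum("nk,kij,nj->ni", W, model.A, E)
    coupled = np.einsum("nk,kij,nj->ni", W, model.B, CE)
    return (local + coupled).ravel()


def nonlinear_error_drift(
    x: np.ndarray,
    s: np.ndarray,
    params: RepressilatorParams,
    coupling: CouplingMatrix,
) -> np.ndarray:
    """True stacked error drift ``F(x, s) + (C (x) I) G(x, s)`` for comparison.

    ``x`` has shape ``(N, 7)``; ``s`` is the common reference state.
    """
    from quorumsync.genetic_network import coupling_function, drift_single_cell

    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    F = drift_single_cell(x, params) - drift_single_cell(s, params)
    G = coupling_function(x) - coupling_function(s)
    return (F + coupling.values @ G).ravel()
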