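"""Robust-synchronization certification and external-gain design.

Assembles the per-rule LMI blocks of the fuzzy error system

    [[ R + P Phi_k + Phi_k' P + Psi_k' P Psi_k ,  P H ],
     [               H' P                      , -rho^2 I ]]  <  0,   P > 0

with ``Phi_k = I_N (x) A_k + C (x) B_k`` and ``Psi_k = I_N (x) A_Wk +
C (x) B_Wk``, solves them for a common certificate ``P``, optimizes the
filtering level ``rho`` by bisection (feasibility is monotone in ``rho``),
designs the external coupling gain ``Q`` over a grid, reports the
intrinsic / extrinsic / synchronization robustness decomposition, and
evaluates the Hamilton-Jacobi residual for quadratic storage functions.

For the all-to-all mean-field coupling the stacked problem is solved in the
eigenbasis of ``C``: the permutation symmetry of the constraint set means a
feasible certificate exists iff one of the block-diagonal form
``P = (U (x) I) blkdiag(P_lam) (U' (x) I)`` does, which decouples the 7N-dim
LMIs into 7-dim LMIs per distinct coupling eigenvalue.  Every certificate is
re-verified on the dense stacked matrices by direct eigenvalue computation,
independent of the solver path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from quorumsync.fuzzy_ts import FuzzyModel, build_fuzzy_model
from quorumsync.genetic_network import (
    M_SPECIES,
    CouplingMatrix,
    FluctuationAmplitudes,
    RepressilatorParams,
    build_coupling_matrix,
    coupling_function,
    coupling_noise_function,
    drift_single_cell,
    intrinsic_noise_field,
)
from quorumsync.lmi import LMIBlock, solve_lmi

__all__ = [
    "LMIProblem",
    "FeasibilityResult",
    "DesignResult",
    "assemble_lmi_blocks",
    "solve_feasibility",
    "min_rho",
    "design_Q",
    "robustness_decomposition",
    "hji_residual",
    "tune_kinetic_parameters",
]


@dataclass
class LMIProblem:
    """Assembled per-rule LMI constraints, either dense or eigenmode-decoupled."""

    model: FuzzyModel
    coupling: CouplingMatrix
    H: np.ndarray                       # dense (7N, N*q_cell)
    R: np.ndarray                       # dense (7N, 7N)
    rho: float
    eps: float
    mode: str                           # "dense" | "modal"
    blocks: list[LMIBlock] = field(default_factory=list)          # dense blocks
    modal_groups: list[tuple[float, int, list[LMIBlock]]] = field(default_factory=list)
    modal_basis: np.ndarray | None = None   # eigenvectors U of C (modal mode)
    modal_eigenvalues: np.ndarray | None = None
    include_mean_mode: bool = True      # False: restrict to the sync subspace (sum_i e_i = 0)
    mean_mode_index: int | None = None

    @property
    def dim(self) -> int:
        return self.coupling.n_cells * self.model.n_states


@dataclass
class FeasibilityResult:
    status: str                         # "feasible" | "infeasible" | "solver-inconclusive"
    P: np.ndarray | None
    rule_margins: np.ndarray | None     # dense lambda_max of M_k(P) per rule
    min_eig_P: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        return self.status == "feasible"


@dataclass
class DesignResult:
    Q: float | None
    rho: float
    rho0: float | None
    P: np.ndarray | None
    feasible: bool
    trace: list = field(default_factory=list)
    decomposition: list | None = None

    def to_dict(self) -> dict:
        return {
            "Q": None if self.Q is None else float(self.Q),
            "rho": float(self.rho),
            "rho0": None if self.rho0 is None else float(self.rho0),
            "feasible": bool(self.feasible),
            "trace": self.trace,
        }


def _dense_phi_psi(model: FuzzyModel, C: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    N = C.shape[0]
    eye = np.eye(N)
    Phi = np.kron(eye, model.A[k]) + np.kron(C, model.B[k])
    Psi = np.kron(eye, model.A_W[k]) + np.kron(C, model.B_W[k])
    return Phi, Psi


def _default_H(N: int, h: np.ndarray) -> np.ndarray:
    """Stacked noise coupling ``diag(h, ..., h)`` of shape (7N, N)."""
    return np.kron(np.eye(N), np.asarray(h, dtype=float)[:, None])


def assemble_lmi_blocks(
    model: FuzzyModel,
    coupling: CouplingMatrix,
    H: np.ndarray | None = None,
    R: np.ndarray | None = None,
    rho: float = 1.0,
    eps: float = 1e-6,
    mode: str = "auto",
    h_cell: np.ndarray | None = None,
    include_mean_mode: bool = True,
) -> LMIProblem:
    """Build the per-rule LMI constraints at filtering level ``rho``.

    ``H`` defaults to one scalar noise channel per cell through ``h_cell``.
    ``mode="auto"`` picks the eigenmode-decoupled path when the coupling is
    symmetric, ``R`` is a scalar multiple of identity and ``H`` has the
    per-cell Kronecker structure; otherwise the dense path.

    With ``include_mean_mode=False`` (modal path only) the constraints are
    restricted to the synchronization subspace ``sum_i e_i = 0``: the
    zero-row-sum coupling leaves the population-mean direction untouched by
    any gain, so quantifying over it would make the external-gain design
    vacuous.  Population-mean synchronization errors live entirely in this
    subspace.
    """
    if rho <= 0:
        raise ValueError(f"rho must be > 0, got {rho}")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    N = coupling.n_cells
    m = model.n_states
    dim = N * m
    if h_cell is None and H is None:
        h_cell = np.ones(m)
    if H is None:
        H = _default_H(N, h_cell)
    H = np.asarray(H, dtype=float)
    if H.shape[0] != dim:
        raise ValueError(f"H must have {dim} rows, got {H.shape}")
    if R is None:
        R = np.eye(dim)
    R = np.asarray(R, dtype=float)
    if R.shape != (dim, dim):
        raise ValueError(f"R must be ({dim}, {dim}), got {R.shape}")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    if np.any(np.linalg.eigvalsh(R) < -1e-10):
        raise ValueError("R must be positive semidefinite")

    C = coupling.values
    symmetric_C = np.allclose(C, C.T, atol=1e-12)
    r_scalar = R[0, 0]
    scalar_R = np.allclose(R, r_scalar * np.eye(dim), atol=1e-12)
    kron_H = (
        H.shape[1] % N == 0
        and np.allclose(H, _kron_h_candidate(H, N, m), atol=1e-12)
    )
    use_modal = mode == "modal" or (mode == "auto" and symmetric_C and scalar_R and kron_H)
    if mode == "modal" and not (symmetric_C and scalar_R and kron_H):
        raise ValueError("modal mode requires symmetric C, scalar R and per-cell Kronecker H")
    if not include_mean_mode and not use_modal:
        raise ValueError("sync-subspace restriction requires the modal path")

    prob = LMIProblem(
        model=model, coupling=coupling, H=H, R=R, rho=rho, eps=eps,
        mode="modal" if use_modal else "dense",
        include_mean_mode=include_mean_mode,
    )
    L = model.n_rules
    if use_modal:
        lam, U = np.linalg.eigh(C)
        prob.modal_basis = U
        prob.modal_eigenvalues = lam
        q_cell = H.shape[1] // N
        h = H[:m, :q_cell]
        # the population-mean direction is C's kernel along the ones vector
        ones = np.ones(N) / np.sqrt(N)
        mean_mode_idx = int(np.argmax(np.abs(U.T @ ones)))
        prob.mean_mode_index = mean_mode_idx
        # group numerically identical coupling eigenvalues
        groups: dict[float, int] = {}
        for i, lv in enumerate(lam):
            if not include_mean_mode and i == mean_mode_idx:
                continue
            key = round(float(lv), 9)
            groups[key] = groups.get(key, 0) + 1
        if not groups:
            raise ValueError("excluding the mean mode left no constraints (N = 1?)")
        for lam_value, mult in sorted(groups.items()):
            blocks = [
                LMIBlock(
                    Phi=model.A[k] + lam_value * model.B[k],
                    Psi=model.A_W[k] + lam_value * model.B_W[k],
                    H=h,
                    R=r_scalar * np.eye(m),
                    rho=rho,
                    label=f"rule {k}, coupling eigenvalue {lam_value:g}",
                )
                for k in range(L)
            ]
            prob.modal_groups.append((lam_value, mult, blocks))
    else:
        for k in range(L):
            Phi, Psi = _dense_phi_psi(model, C, k)
            prob.blocks.append(
                LMIBlock(Phi=Phi, Psi=Psi, H=H, R=R, rho=rho, label=f"rule {k}")
            )
    return prob


def _kron_h_candidate(H: np.ndarray, N: int, m: int) -> np.ndarray:
    q = H.shape[1] // N
    return np.kron(np.eye(N), H[:m, :q])


def _dense_rule_margins(prob: LMIProblem, P: np.ndarray) -> tuple[np.ndarray, float]:
    """Independent verification: eigenvalues of the dense stacked M_k(P).

    When the problem is restricted to the synchronization subspace, the
    quadratic forms are projected onto it (columns of C's eigenbasis
    orthogonal to the population-mean direction) before the eigenvalue check.
    """
    C = prob.coupling.values
    T = None
    if not prob.include_mean_mode:
        keep = [i for i in range(C.shape[0]) if i != prob.mean_mode_index]
        T = np.kron(prob.modal_basis[:, keep], np.eye(prob.model.n_states))
    margins = np.empty(prob.model.n_rules)
    for k in range(prob.model.n_rules):
        Phi, Psi = _dense_phi_psi(prob.model, C, k)
        core = P @ Phi
        core = core + core.T + prob.R + Psi.T @ P @ Psi
        PH = P @ prob.H
        if T is not None:
            core = T.T @ core @ T
            PH = T.T @ PH
        n, q = core.shape[0], PH.shape[1]
        M = np.empty((n + q, n + q))
        M[:n, :n] = core
        M[:n, n:] = PH
        M[n:, :n] = PH.T
        M[n:, n:] = -(prob.rho ** 2) * np.eye(q)
        margins[k] = np.linalg.eigvalsh(M)[-1]
    P_eff = P if T is None else T.T @ P @ T
    return margins, float(np.linalg.eigvalsh(P_eff)[0])


def solve_feasibility(
    prob: LMIProblem,
    warm_start: dict | np.ndarray | None = None,
    max_iter: int = 400,
) -> FeasibilityResult:
    """Solve for a common positive-definite certificate and re-verify it.

    Modal problems are solved per distinct coupling eigenvalue (each group
    has its own small certificate; the stacked ``P`` is block-diagonal in the
    coupling eigenbasis).  A "feasible" verdict always passes a direct dense
    eigenvalue re-check of every rule at margin ``-eps/2``.
    """
    diagnostics: dict = {"mode": prob.mode, "solutions": []}
    witness = _unstable_combination_witness(prob)
    if witness is not None:
        diagnostics["provable_infeasibility"] = witness
        return FeasibilityResult("infeasible", None, None, float("nan"), diagnostics)
    if prob.mode == "modal":
        P_small: list[np.ndarray] = []
        statuses: list[str] = []
        for gi, (lam_value, mult, blocks) in enumerate(prob.modal_groups):
            P0 = None
            if isinstance(warm_start, dict):
                P0 = warm_start.get(gi)
            sol = solve_lmi(blocks, prob.model.n_states, eps=prob.eps, P0=P0, max_iter=max_iter)
            statuses.append(sol.status)
            P_small.append(sol.P)
            diagnostics["solutions"].append(
                {"coupling_eigenvalue": lam_value, "multiplicity": mult,
                 "status": sol.status, "margin": float(sol.margin)}
            )
        diagnostics["warm_cache"] = dict(enumerate(P_small))
        if any(s == "infeasible" for s in statuses):
            return FeasibilityResult("infeasible", None, None, float("nan"), diagnostics)
        if any(s != "feasible" for s in statuses):
            return FeasibilityResult("solver-inconclusive", None, None, float("nan"), diagnostics)
        P = _assemble_modal_P(prob, P_small)
    else:
        P0 = warm_start if isinstance(warm_start, np.ndarray) else None
        sol = solve_lmi(prob.blocks, prob.dim, eps=prob.eps, P0=P0, max_iter=max_iter)
        diagnostics["solutions"].append({"status": sol.status, "margin": float(sol.margin)})
        diagnostics["warm_cache"] = sol.P
        if sol.status != "feasible":
            status = "infeasible" if sol.status == "infeasible" else "solver-inconclusive"
            return FeasibilityResult(status, None, None, float("nan"), diagnostics)
        P = sol.P

    margins, min_eig_P = _dense_rule_margins(prob, P)
    diagnostics["dense_rule_margins"] = margins.tolist()
    if margins.max() > -prob.eps / 2 or min_eig_P < prob.eps / 2:
        raise RuntimeError(
            "internal error: solver reported feasible but the dense eigenvalue "
            f"re-check failed (max rule margin {margins.max():.3e}, "
            f"min eig P {min_eig_P:.3e})"
        )
    return FeasibilityResult("feasible", P, margins, min_eig_P, diagnostics)


def _unstable_combination_witness(prob: LMIProblem, grid: int = 21) -> dict | None:
    """Provable-infeasibility certificate from the rule polytope.

    A common ``P`` satisfying every rule's LMI would make every convex
    combination of the drift matrices satisfy a Lyapunov inequality, hence
    Hurwitz.  An unstable pairwise combination therefore certifies
    infeasibility at every ``rho``, independent of the solver.  Checks each
    coupling eigenvalue (modal mode) or the stacked matrices (dense mode).
    """
    model = prob.model
    L = model.n_rules
    mus = np.linspace(0.0, 1.0, grid)

    def scan(mats, context):
        for j in range(L):
            for k in range(j, L):
                for mu in mus:
                    A = mu * mats[j] + (1.0 - mu) * mats[k]
                    growth = float(np.max(np.linalg.eigvals(A).real))
                    if growth > 1e-9:
                        return {
                            "reason": "unstable convex combination of rule drifts",
                            "rules": (j, k),
                            "weight": float(mu),
                            "growth_rate": growth,
                            **context,
                        }
        return None

    if prob.mode == "modal":
        for lam_value, _mult, _blocks in prob.modal_groups:
            mats = [model.A[k] + lam_value * model.B[k] for k in range(L)]
            witness = scan(mats, {"coupling_eigenvalue": float(lam_value)})
            if witness is not None:
                return witness
        return None
    C = prob.coupling.values
    mats = [_dense_phi_psi(model, C, k)[0] for k in range(L)]
    return scan(mats, {})


def _assemble_modal_P(prob: LMIProblem, P_small: list[np.ndarray]) -> np.ndarray:
    lam, U = prob.modal_eigenvalues, prob.modal_basis
    keys = [g[0] for g in prob.modal_groups]
    N = prob.coupling.n_cells
    m = prob.model.n_states
    P = np.zeros((N * m, N * m))
    for i in range(N):
        if not prob.include_mean_mode and i == prob.mean_mode_index:
            continue                      # subspace certificate: zero on the mean direction
        gi = keys.index(round(float(lam[i]), 9))
        u = U[:, i]
        P += np.kron(np.outer(u, u), P_small[gi])
    return P


def min_rho(
    model: FuzzyModel,
    coupling: CouplingMatrix,
    H: np.ndarray | None = None,
    R: np.ndarray | None = None,
    rho_bracket: tuple[float, float] = (1e-3, 10.0),
    tol: float = 1e-3,
    eps: float = 1e-6,
    h_cell: np.ndarray | None = None,
    mode: str = "auto",
    include_mean_mode: bool = True,
) -> DesignResult:
    """Minimal certified filtering level by bisection on ``rho``.

    Feasibility is monotone in ``rho`` (growing ``rho`` only relaxes the
    disturbance block), so bisection is valid.  Returns the level and the
    certificate at the first feasible point within ``tol`` of it.
    """
    lo, hi = rho_bracket
    if tol <= 0:
        raise ValueError("tol must be > 0")

    def attempt(rho, warm):
        prob = assemble_lmi_blocks(model, coupling, H=H, R=R, rho=rho,
                                   eps=eps, mode=mode, h_cell=h_cell,
                                   include_mean_mode=include_mean_mode)
        return solve_feasibility(prob, warm_start=warm)

    trace = []
    res_hi = attempt(hi, None)
    trace.append({"rho": float(hi), "status": res_hi.status})
    if not res_hi.feasible:
        witness = res_hi.diagnostics.get("provable_infeasibility")
        detail = f"; certificate: {witness}" if witness else ""
        raise RuntimeError(
            f"LMIs infeasible even at the upper bracket rho = {hi}: the fuzzy model is "
            f"unsynchronizable under this coupling (robustness criterion violated){detail}"
        )
    best = res_hi
    warm = res_hi.diagnostics.get("warm_cache")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        res = attempt(mid, warm)
        trace.append({"rho": float(mid), "status": res.status})
        if res.feasible:
            hi = mid
            best = res
            warm = res.diagnostics.get("warm_cache")
        else:
            lo = mid
    return DesignResult(
        Q=coupling.Q if np.isfinite(coupling.Q) else None,
        rho=float(hi),
        rho0=float(hi),
        P=best.P,
        feasible=True,
        trace=trace,
    )


def design_Q(
    model_builder,
    rho: float,
    q_grid,
    eps: float = 1e-6,
    refine_rho: bool = False,
    h_cell: np.ndarray | None = None,
    H: np.ndarray | None = None,
    R: np.ndarray | None = None,
    mode: str = "auto",
    include_mean_mode: bool = True,
) -> DesignResult:
    """Smallest grid gain ``Q`` making the LMIs feasible at level ``rho``.

    ``model_builder(Q)`` returns the pair ``(FuzzyModel, CouplingMatrix)``
    for the candidate gain (the operating trajectory of the mean-field
    reference does not depend on ``Q``, but callers may rebuild anyway).
    The grid is scanned in ascending order; with ``refine_rho`` the achieved
    optimal level at the selected gain is also reported.
    """
    q_grid = np.asarray(list(q_grid), dtype=float)
    if q_grid.size < 1:
        raise ValueError("Q grid must be nonempty")
    if np.any(np.diff(q_grid) < 0):
        raise ValueError("Q grid must be ascending")
    trace = []
    warm = None
    for Q in q_grid:
        model, coupling = model_builder(float(Q))
        prob = assemble_lmi_blocks(model, coupling, H=H, R=R, rho=rho,
                                   eps=eps, mode=mode, h_cell=h_cell,
                                   include_mean_mode=include_mean_mode)
        res = solve_feasibility(prob, warm_start=warm)
        warm = res.diagnostics.get("warm_cache", warm)
        entry = {"Q": float(Q), "status": res.status}
        if res.rule_margins is not None:
            entry["max_rule_margin"] = float(res.rule_margins.max())
        trace.append(entry)
        if res.feasible:
            rho0 = None
            if refine_rho:
                refined = min_rho(model, coupling, H=H, R=R,
                                  rho_bracket=(1e-3, rho), eps=eps,
                                  h_cell=h_cell, mode=mode,
                                  include_mean_mode=include_mean_mode)
                rho0 = refined.rho0
            return DesignResult(
                Q=float(Q), rho=float(rho), rho0=rho0, P=res.P,
                feasible=True, trace=trace,
            )
    raise RuntimeError(
        f"no feasible Q on the grid at rho = {rho}; margin trace: {trace}"
    )


def robustness_decomposition(
    P: np.ndarray,
    model: FuzzyModel,
    coupling: CouplingMatrix,
    H: np.ndarray | None = None,
    R: np.ndarray | None = None,
    rho0: float = 1.0,
    h_cell: np.ndarray | None = None,
) -> list[dict]:
    """Per-rule intrinsic / extrinsic / synchronization robustness split.

    Returns, for each rule, the three symmetric matrices ``Psi' P Psi``
    (intrinsic), ``R + rho0^-2 P H H' P`` (extrinsic) and ``-(P Phi +
    Phi' P)`` (synchronization), plus the minimum eigenvalue of
    (synchronization - intrinsic - extrinsic), which is nonnegative up to
    the strictness margin exactly when the criterion holds.
    """
    P = np.asarray(P, dtype=float)
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("certificate P must be symmetric")
    N = coupling.n_cells
    dim = N * model.n_states
    if P.shape != (dim, dim):
        raise ValueError(f"P must be ({dim}, {dim})")
    if H is None:
        H = _default_H(N, np.ones(model.n_states) if h_cell is None else h_cell)
    if R is None:
        R = np.eye(dim)
    C = coupling.values
    PHHP = P @ H @ H.T @ P
    report = []
    for k in range(model.n_rules):
        Phi, Psi = _dense_phi_psi(model, C, k)
        intrinsic = Psi.T @ P @ Psi
        extrinsic = R + PHHP / rho0 ** 2
        sync = -(P @ Phi + Phi.T @ P)
        slack = sync - intrinsic - extrinsic
        report.append(
            {
                "rule": k,
                "intrinsic": intrinsic,
                "extrinsic": extrinsic,
                "synchronization": sync,
                "min_eig_slack": float(np.linalg.eigvalsh(slack)[0]),
            }
        )
    return report


def hji_residual(
    e: np.ndarray,
    x: np.ndarray,
    s: np.ndarray,
    P: np.ndarray,
    params: RepressilatorParams,
    amplitudes: FluctuationAmplitudes,
    coupling: CouplingMatrix,
    H: np.ndarray | None = None,
    R: np.ndarray | None = None,
    rho: float = 1.0,
    h_cell: np.ndarray | None = None,
) -> float:
    """Hamilton-Jacobi residual at a population state for ``V(e) = e' P e``.

    Evaluates ``e'Re + 2 e'P [F + (C (x) I) G] + rho^-2 e'PHH'Pe + w'Pw``
    with ``w = F_W + (C (x) I) G_W`` the stacked intrinsic-fluctuation
    difference; negative values certify the robust-synchronization criterion
    at that state.
    """
    N = coupling.n_cells
    dim = N * M_SPECIES
    e = np.asarray(e, dtype=float).ravel()
    if e.shape != (dim,):
        raise ValueError(f"stacked error must have length {dim}")
    x = np.asarray(x, dtype=float).reshape(N, M_SPECIES)
    s = np.asarray(s, dtype=float).ravel()
    if H is None:
        H = _default_H(N, np.ones(M_SPECIES) if h_cell is None else h_cell)
    C = coupling.values

    F = (drift_single_cell(x, params) - drift_single_cell(s, params))
    G = (coupling_function(x) - coupling_function(s))
    drift_part = (F + C @ G).ravel()
    FW = intrinsic_noise_field(x, params, amplitudes) - intrinsic_noise_field(s, params, amplitudes)
    GW = coupling_noise_function(x, params.eta_s, amplitudes.d_eta_s) - coupling_noise_function(
        s, params.eta_s, amplitudes.d_eta_s
    )
    w = (FW + C @ GW).ravel()

    Pe = P @ e
    if R is None:
        quad_R = float(e @ e)
    else:
        quad_R = float(e @ np.asarray(R, dtype=float) @ e)
    PH = P @ H
    return (
        quad_R
        + 2.0 * float(Pe @ drift_part)
        + float((PH.T @ e) @ (PH.T @ e)) / rho ** 2
        + float(w @ P @ w)
    )


def tune_kinetic_parameters(
    base_params: RepressilatorParams,
    amplitudes: FluctuationAmplitudes,
    grid: dict[str, list[float]],
    n_cells: int = 10,
    Q: float = 0.0,
    L: int = 8,
    rho_bracket: tuple[float, float] = (1e-3, 10.0),
    tol: float = 1e-3,
    h_cell: np.ndarray | None = None,
) -> dict:
    """Grid search over up to three kinetic parameters minimizing ``rho0``.

    Rebuilds the fuzzy rule base per candidate (the operating trajectory
    shifts with the kinetics) and records the full trace, including
    candidates whose limit cycle disappears or whose LMIs stay infeasible.
    """
    if not grid or len(grid) > 3:
        raise ValueError("grid must cover between 1 and 3 parameters")
    names = list(grid)
    trace = []
    best = None
    for combo in itertools.product(*(grid[name] for name in names)):
        candidate = base_params.replace(**dict(zip(names, combo)))
        entry = {"params": dict(zip(names, map(float, combo)))}
        try:
            model = build_fuzzy_model(candidate, amplitudes, L=L)
            coupling = build_coupling_matrix(n_cells, candidate.eta_s, candidate.Q_e, Q)
            result = min_rho(model, coupling, rho_bracket=rho_bracket, tol=tol,
                             h_cell=h_cell)
            entry["rho0"] = float(result.rho0)
            if best is None or result.rho0 < best["rho0"]:
                best = {**entry, "params_obj": candidate, "design": result}
        except Exception as exc:  # noqa: BLE001 - candidates may fail legitimately
            entry["error"] = str(exc)
        trace.append(entry)
    if best is None:
        raise RuntimeError(f"no candidate was synchronizable; trace: {trace}")
    return {"best": best, "trace": trace}
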