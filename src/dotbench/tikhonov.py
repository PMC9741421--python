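"""Iterative Jacobian-based reconstruction with Levenberg-Marquardt-style
Tikhonov damping.

State vector is the stacked nodal update [Delta D | Delta mu_a]; reduced
scattering follows from D = 1/(3(mu_s' + mu_a)) after each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh, NodalCoefficients
from .forward import (
    ProbeGeometry,
    MeasurementSet,
    assemble_fd_system,
    solve_sources,
    read_detectors,
    detector_order,
    _detector_interpolators,
    diffusion_coefficient,
)

log = logging.getLogger(__name__)

__all__ = [
    "Jacobian",
    "ReconOptions",
    "ReconResult",
    "chi_squared",
    "compute_jacobian",
    "tr_step",
    "reconstruct_tr",
]


@dataclass
class Jacobian:
    """Stacked sensitivity matrix.

    Rows: log-amplitude components then phase-lag components
    (2 * N_s * N_d total).  Columns: [d/dD | d/dmu_a] nodal blocks.
    """

    matrix: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != 2 * self.n_nodes:
            raise ValueError("column count must be 2 * n_nodes")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("Jacobian contains non-finite entries")


@dataclass
class ReconOptions:
    max_iterations: int = 20
    chi2_rel_tol: float = 1e-3
    lambda0: float = 10.0
    lambda_decay: float = 0.5
    lambda_floor: float = 1e-4
    lambda_grow: float = 10.0
    max_retries: int = 4
    mu_a_bounds: tuple[float, float] = (1e-4, 0.1)
    mu_s_bounds: tuple[float, float] = (0.05, 5.0)

    def __post_init__(self) -> None:
        if self.chi2_rel_tol <= 0 or self.lambda0 <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.lambda_decay <= 1):
            raise ValueError("lambda_decay must be in (0, 1]")


@dataclass
class ReconResult:
    coefficients: NodalCoefficients
    chi2_history: list[float]
    iterations_run: int
    converged: bool = True
    warning: str | None = None


def chi_squared(calc: MeasurementSet, meas: MeasurementSet) -> float:
    """Data-model misfit: sum of squared differences over all components."""
    if calc.shape != meas.shape:
        raise ValueError(f"shape mismatch: {calc.shape} vs {meas.shape}")
    diff = calc.stacked() - meas.stacked()
    return float(np.dot(diff, diff))


def compute_jacobian(
    mesh: Mesh,
    coeffs: NodalCoefficients,
    probe: ProbeGeometry,
    frequency_MHz: float,
    refractive_index: float = 1.4,
) -> Jacobian:
    """Adjoint-method sensitivities of log amplitude and phase lag.

    For reading Phi_d = v_d^T K^-1 q_s, the sensitivity to a coefficient p is
    -psi_d^T (dK/dp) phi_s with adjoint psi_d = K^-1 v_d (K symmetric).
    Element coefficients are nodal averages, so dK/dp_n spreads 1/3 of each
    adjacent element's unit stiffness (D) or mass (mu_a) block.
    """
    system = assemble_fd_system(mesh, coeffs, frequency_MHz, refractive_index)
    fields = solve_sources(system, probe, mesh)  # (N_s, N)
    V = _detector_interpolators(mesh, probe)  # (N_s fibers, N)
    adjoints = system.solve(V.T.astype(complex)).T  # (N_s fibers, N)

    order = detector_order(probe.n_sources)
    n_s, n_d = probe.n_sources, probe.n_detectors_per_source
    n_meas = n_s * n_d
    ele = mesh.elements
    readings = fields @ V.T  # (N_s, N_s fibers)

    dlog = np.zeros((n_meas, mesh.n_nodes), dtype=complex)  # d lnPhi / dD
    dmua = np.zeros((n_meas, mesh.n_nodes), dtype=complex)  # d lnPhi / dmu_a
    row = 0
    for s in range(n_s):
        phi_e = fields[s][ele]  # (M, 3)
        Kphi = np.einsum("mij,mj->mi", system.element_stiffness, phi_e)
        Mphi = np.einsum("mij,mj->mi", system.element_mass, phi_e)
        for d_idx in range(n_d):
            fib = order[s, d_idx]
            psi_e = adjoints[fib][ele]  # (M, 3)
            a_e = np.einsum("mi,mi->m", psi_e, Kphi)  # stiffness contraction
            b_e = np.einsum("mi,mi->m", psi_e, Mphi)  # mass contraction
            colD = np.zeros(mesh.n_nodes, dtype=complex)
            colA = np.zeros(mesh.n_nodes, dtype=complex)
            np.add.at(colD, ele.ravel(), np.repeat(-a_e / 3.0, 3))
            np.add.at(colA, ele.ravel(), np.repeat(-b_e / 3.0, 3))
            phi_d = readings[s, fib]
            dlog[row] = colD / phi_d
            dmua[row] = colA / phi_d
            row += 1

    # ln Phi = ln|Phi| + i * phase_lag  =>  d ln|Phi| = Re, d lag = Im
    top = np.hstack([dlog.real, dmua.real])
    bot = np.hstack([dlog.imag, dmua.imag])
    return Jacobian(np.vstack([top, bot]), mesh.n_nodes)


def tr_step(J: Jacobian | np.ndarray, residual: np.ndarray, lam: float) -> np.ndarray:
    """One damped normal-equation solve:
    (J^T J + lambda diag(J^T J)) dx = J^T r."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    A = J.matrix if isinstance(J, Jacobian) else np.asarray(J, dtype=float)
    JtJ = A.T @ A
    diag = np.diag(JtJ).copy()
    floor = max(diag.max(), 1.0) * 1e-14
    diag[diag < floor] = floor
    M = JtJ + lam * np.diag(diag)
    rhs = A.T @ residual
    try:
        dx = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"normal equations singular at lambda={lam}; increase lambda"
        ) from exc
    return dx


def reconstruct_tr(
    meas: MeasurementSet,
    mesh: Mesh,
    probe: ProbeGeometry,
    init: NodalCoefficients,
    opts: ReconOptions | None = None,
    refractive_index: float = 1.4,
) -> ReconResult:
    """Iterative damped Gauss-Newton loop on (D, mu_a).

    Accepted steps must not increase chi^2; a rejected step restores the
    previous iterate and retries with a larger damping factor.
    """
    opts = opts or ReconOptions()
    coeffs = init.copy()
    lam = opts.lambda0
    freq = meas.frequency_MHz

    def forward(c: NodalCoefficients) -> MeasurementSet:
        system = assemble_fd_system(mesh, c, freq, refractive_index)
        return read_detectors(solve_sources(system, probe, mesh), probe, mesh, freq)

    calc = forward(coeffs)
    chi2 = chi_squared(calc, meas)
    history = [chi2]
    warning = None
    it = 0
    for it in range(1, opts.max_iterations + 1):
        J = compute_jacobian(mesh, coeffs, probe, freq, refractive_index)
        residual = meas.stacked() - calc.stacked()
        accepted = False
        for _ in range(opts.max_retries + 1):
            dx = tr_step(J, residual, lam)
            dD, dmu_a = dx[: mesh.n_nodes], dx[mesh.n_nodes :]
            D_new = diffusion_coefficient(coeffs.mu_a, coeffs.mu_s) + dD
            D_new = np.clip(D_new, 1e-4, 50.0)
            mu_a_new = np.clip(coeffs.mu_a + dmu_a, *opts.mu_a_bounds)
            mu_s_new = np.clip(1.0 / (3.0 * D_new) - mu_a_new, *opts.mu_s_bounds)
            trial = NodalCoefficients(mu_a_new, mu_s_new)
            calc_trial = forward(trial)
            chi2_trial = chi_squared(calc_trial, meas)
            if chi2_trial <= chi2:
                coeffs, calc = trial, calc_trial
                rel_drop = (chi2 - chi2_trial) / max(chi2, 1e-300)
                chi2 = chi2_trial
                history.append(chi2)
                lam = max(lam * opts.lambda_decay, opts.lambda_floor)
                accepted = True
                break
            lam *= opts.lambda_grow
        if not accepted:
            warning = f"no descent step found at iteration {it}; returning best iterate"
            log.warning(warning)
            break
        if rel_drop < opts.chi2_rel_tol:
            break
    return ReconResult(coeffs, history, it, converged=warning is None, warning=warning)
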