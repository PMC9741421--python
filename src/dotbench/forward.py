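"""Frequency-domain photon diffusion forward solver (linear-triangle FEM).

Solves  -div(D grad Phi) + (mu_a - i w/c) Phi = S  on a disk with the Robin
boundary condition  Phi + 2 A D dPhi/dn = 0, and reads out ring-probe
log-amplitude / phase-lag measurement sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh, NodalCoefficients

__all__ = [
    "ProbeGeometry",
    "ComplexSystem",
    "MeasurementSet",
    "SPEED_OF_LIGHT_MM_NS",
    "diffusion_coefficient",
    "assemble_fd_system",
    "point_load",
    "solve_sources",
    "read_detectors",
    "solve_measurements",
    "analytic_infinite_medium",
    "reciprocity_error",
]

#: vacuum speed of light in mm/ns
SPEED_OF_LIGHT_MM_NS = 299.792458


@dataclass(frozen=True)
class ProbeGeometry:
    """Ring-scanning probe: equally spaced boundary fibers.

    Each fiber acts as a source in turn; the remaining ``n_sources - 1``
    fibers detect.  Sources are modelled as isotropic point loads placed
    ``source_depth_mm`` inside the boundary along the fiber angle.
    """

    n_sources: int = 16
    source_depth_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sources < 2:
            raise ValueError("need at least 2 fibers")
        if self.source_depth_mm < 0:
            raise ValueError("source depth must be nonnegative")

    @property
    def n_detectors_per_source(self) -> int:
        return self.n_sources - 1

    @property
    def fiber_angles_deg(self) -> np.ndarray:
        return 360.0 * np.arange(self.n_sources) / self.n_sources

    def source_points(self, diameter_mm: float) -> np.ndarray:
        """(N_s, 2) interior injection points at the fiber angles."""
        r = diameter_mm / 2.0 - self.source_depth_mm
        if r <= 0:
            raise ValueError("source depth exceeds phantom radius")
        th = np.radians(self.fiber_angles_deg)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    def detector_points(self, diameter_mm: float) -> np.ndarray:
        """(N_s, 2) boundary fiber points (all fibers)."""
        r = diameter_mm / 2.0
        th = np.radians(self.fiber_angles_deg)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    @classmethod
    def for_background(cls, mu_s0: float, n_sources: int = 16) -> "ProbeGeometry":
        """Standard diffusion-theory placement: depth one transport mean free path."""
        return cls(n_sources=n_sources, source_depth_mm=1.0 / mu_s0)


@dataclass
class ComplexSystem:
    """Assembled FEM operator plus the pieces needed for sensitivities."""

    system_matrix: sp.csc_matrix
    mesh: Mesh
    omega_rad_ns: float
    wave_speed_mm_ns: float
    boundary_coefficient: float
    # per-element 3x3 stiffness (unit D) and mass (unit coefficient) blocks
    element_stiffness: np.ndarray  # (M, 3, 3)
    element_mass: np.ndarray  # (M, 3, 3)
    _lu: spla.SuperLU | None = field(default=None, repr=False)

    def factor(self) -> spla.SuperLU:
        if self._lu is None:
            self._lu = spla.splu(self.system_matrix)
        return self._lu

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return self.factor().solve(rhs.astype(complex))


def diffusion_coefficient(mu_a, mu_s_prime):
    """D = 1 / (3 (mu_s' + mu_a)), in mm."""
    total = np.asarray(mu_a, dtype=float) + np.asarray(mu_s_prime, dtype=float)
    if np.any(total <= 0):
        raise ValueError("mu_a + mu_s' must be positive")
    out = 1.0 / (3.0 * total)
    return float(out) if out.ndim == 0 else out


def _element_matrices(mesh: Mesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-coefficient P1 stiffness and mass blocks for every triangle."""
    p = mesh.node_coords[mesh.elements]  # (M, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([x[:, 1] - x[:, 2], x[:, 2] - x[:, 0], x[:, 0] - x[:, 1]], axis=1)
    c = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    area = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    # gradient of basis i is (c_i, -b_i)/(2 area); stiffness = area * grad_i . grad_j
    K = (c[:, :, None] * c[:, None, :] + b[:, :, None] * b[:, None, :]) / (
        4.0 * area[:, None, None]
    )
    Mloc = np.tile(np.array([[2.0, 1, 1], [1, 2, 1], [1, 1, 2]]) / 12.0, (len(area), 1, 1))
    Mloc *= area[:, None, None]
    return K, Mloc, area


def _boundary_mass(mesh: Mesh) -> sp.csr_matrix:
    """Line-element mass matrix over the outer ring (unit coefficient)."""
    nb = mesh.boundary_nodes
    n = mesh.n_nodes
    nxt = np.roll(nb, -1)
    seg = np.linalg.norm(mesh.node_coords[nxt] - mesh.node_coords[nb], axis=1)
    rows = np.concatenate([nb, nxt, nb, nxt])
    cols = np.concatenate([nb, nxt, nxt, nb])
    vals = np.concatenate([seg / 3.0, seg / 3.0, seg / 6.0, seg / 6.0])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def assemble_fd_system(
    mesh: Mesh,
    coeffs: NodalCoefficients,
    frequency_MHz: float,
    refractive_index: float = 1.4,
    boundary_A: float = 1.0,
) -> ComplexSystem:
    """Assemble the complex symmetric FEM system for the diffusion equation.

    Element coefficients (D and mu_a - i w/c) use the element average of the
    nodal values.  The Robin condition adds (1/(2A)) x boundary mass.
    """
    if len(coeffs.mu_a) != mesh.n_nodes:
        raise ValueError(
            f"coefficients ({len(coeffs.mu_a)}) do not match mesh ({mesh.n_nodes} nodes)"
        )
    if frequency_MHz < 0:
        raise ValueError("frequency must be nonnegative")

    Ke, Me, _ = _element_matrices(mesh)
    c_med = SPEED_OF_LIGHT_MM_NS / refractive_index
    omega = 2.0 * math.pi * frequency_MHz * 1e-3  # MHz -> rad/ns

    D_nodes = diffusion_coefficient(coeffs.mu_a, coeffs.mu_s)
    D_e = D_nodes[mesh.elements].mean(axis=1)
    kappa_e = coeffs.mu_a[mesh.elements].mean(axis=1) - 1j * omega / c_med

    blocks = D_e[:, None, None] * Ke + kappa_e[:, None, None] * Me
    rows = np.repeat(mesh.elements, 3, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 3)).ravel()
    A = sp.coo_matrix(
        (blocks.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    A = A + (1.0 / (2.0 * boundary_A)) * _boundary_mass(mesh).astype(complex)
    return ComplexSystem(
        system_matrix=A.tocsc(),
        mesh=mesh,
        omega_rad_ns=omega,
        wave_speed_mm_ns=c_med,
        boundary_coefficient=boundary_A,
        element_stiffness=Ke,
        element_mass=Me,
    )


def _barycentric(mesh: Mesh, point: np.ndarray) -> tuple[int, np.ndarray]:
    """Locate the triangle containing ``point``; return (element, weights).

    Falls back to the element with the least-negative worst barycentric
    coordinate for points marginally outside (boundary round-off).
    """
    p = mesh.node_coords[mesh.elements]
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    d = point[None, :] - p[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    l1 = (d[:, 0] * v1[:, 1] - d[:, 1] * v1[:, 0]) / det
    l2 = (v0[:, 0] * d[:, 1] - v0[:, 1] * d[:, 0]) / det
    l0 = 1.0 - l1 - l2
    lam = np.column_stack([l0, l1, l2])
    worst = lam.min(axis=1)
    e = int(np.argmax(worst))
    w = np.clip(lam[e], 0.0, None)
    return e, w / w.sum()


def point_load(mesh: Mesh, point: np.ndarray) -> np.ndarray:
    """Unit isotropic point source distributed to its containing element."""
    e, w = _barycentric(mesh, np.asarray(point, dtype=float))
    q = np.zeros(mesh.n_nodes)
    q[mesh.elements[e]] = w
    return q


def solve_sources(
    system: ComplexSystem, probe: ProbeGeometry, mesh: Mesh
) -> np.ndarray:
    """Solve the FD system for every source; returns (N_s, N_nodes) complex."""
    pts = probe.source_points(mesh.diameter_mm)
    rhs = np.column_stack([point_load(mesh, p) for p in pts]).astype(complex)
    fields = system.solve(rhs)
    fields = np.atleast_2d(fields.T) if fields.ndim == 1 else fields.T
    if not np.all(np.isfinite(fields)):
        raise RuntimeError("forward solve produced non-finite field values")
    return fields


@dataclass
class MeasurementSet:
    """Ring-probe measurement set: natural-log amplitude and phase lag.

    Shapes are (N_s, N_d) with detectors ordered by increasing angular
    offset from the source fiber (source fiber skipped).
    """

    log_amplitude: np.ndarray
    phase_lag: np.ndarray
    frequency_MHz: float
    diameter_mm: float

    def __post_init__(self) -> None:
        self.log_amplitude = np.asarray(self.log_amplitude, dtype=float)
        self.phase_lag = np.asarray(self.phase_lag, dtype=float)
        if self.log_amplitude.shape != self.phase_lag.shape:
            raise ValueError("log_amplitude and phase_lag shapes differ")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.log_amplitude.shape

    def stacked(self) -> np.ndarray:
        """Flat data vector: log amplitudes then phase lags."""
        return np.concatenate([self.log_amplitude.ravel(), self.phase_lag.ravel()])

    def as_array(self) -> np.ndarray:
        """(N_s, N_d, 2) array: [..., 0] log amplitude, [..., 1] phase lag."""
        return np.stack([self.log_amplitude, self.phase_lag], axis=-1)

    def to_dataframe(self):
        """Long-format per-channel table for inspection/CSV export."""
        import pandas as pd

        n_s, n_d = self.log_amplitude.shape
        src, det = np.meshgrid(np.arange(n_s), np.arange(n_d), indexing="ij")
        return pd.DataFrame(
            {
                "source": src.ravel(),
                "detector_offset": det.ravel() + 1,
                "log_amplitude": self.log_amplitude.ravel(),
                "phase_lag_rad": self.phase_lag.ravel(),
            }
        )


def _detector_interpolators(mesh: Mesh, probe: ProbeGeometry) -> np.ndarray:
    """(N_s, N_nodes) sparse-ish interpolation weights at fiber boundary points."""
    pts = probe.detector_points(mesh.diameter_mm)
    # nudge inward so the point sits inside the outermost element ring
    pts = pts * (1.0 - 1e-9)
    V = np.zeros((probe.n_sources, mesh.n_nodes))
    for i, p in enumerate(pts):
        e, w = _barycentric(mesh, p)
        V[i, mesh.elements[e]] = w
    return V


def detector_order(n_sources: int) -> np.ndarray:
    """(N_s, N_d) fiber indices per source, increasing angular offset."""
    offsets = np.arange(1, n_sources)
    return (np.arange(n_sources)[:, None] + offsets[None, :]) % n_sources


def read_detectors(
    fields: np.ndarray,
    probe: ProbeGeometry,
    mesh: Mesh,
    frequency_MHz: float,
) -> MeasurementSet:
    """Interpolate per-source fields at the detector fibers.

    log_amplitude = ln|Phi|.  Under the exp(-i w t) time convention implied
    by the (mu_a - i w/c) sign of the assembled operator, the detected
    signal is |Phi| cos(w t - arg Phi), so the nonnegative phase lag is
    +arg(Phi), folded to [0, 2 pi); it grows with source-detector distance.
    """
    if fields.shape != (probe.n_sources, mesh.n_nodes):
        raise ValueError("one nodal field per source required")
    V = _detector_interpolators(mesh, probe)
    readings = fields @ V.T  # (N_s sources, N_s fibers)
    order = detector_order(probe.n_sources)
    det = np.take_along_axis(readings, order, axis=1)
    log_amp = np.log(np.abs(det))
    lag = np.mod(np.angle(det), 2.0 * np.pi)
    return MeasurementSet(log_amp, lag, frequency_MHz, mesh.diameter_mm)


def solve_measurements(
    mesh: Mesh,
    coeffs: NodalCoefficients,
    probe: ProbeGeometry,
    frequency_MHz: float,
    refractive_index: float = 1.4,
) -> MeasurementSet:
    """Convenience pipeline: assemble, solve all sources, read detectors."""
    system = assemble_fd_system(mesh, coeffs, frequency_MHz, refractive_index)
    fields = solve_sources(system, probe, mesh)
    return read_detectors(fields, probe, mesh, frequency_MHz)


def analytic_infinite_medium(
    mu_a: float,
    mu_s_prime: float,
    frequency_MHz: float,
    distance_mm: float,
    refractive_index: float = 1.4,
) -> complex:
    """Infinite-medium FD point-source Green's function, 2-D: K0(kr)/(2 pi D).

    Test oracle only, matching the planar FEM away from boundaries;
    k = sqrt((mu_a - i w/c)/D) with Re(k) > 0.  (The 3-D counterpart would
    be exp(-kr)/(4 pi D r).)
    """
    from scipy.special import kv

    if distance_mm <= 0:
        raise ValueError("distance must be positive")
    D = diffusion_coefficient(mu_a, mu_s_prime)
    c_med = SPEED_OF_LIGHT_MM_NS / refractive_index
    omega = 2.0 * math.pi * frequency_MHz * 1e-3
    k = np.sqrt((mu_a - 1j * omega / c_med) / D)
    if k.real < 0:
        k = -k
    return complex(kv(0, k * distance_mm) / (2.0 * np.pi * D))


def reciprocity_error(
    system: ComplexSystem, probe: ProbeGeometry, mesh: Mesh
) -> float:
    """Max relative asymmetry of the source-to-source transfer matrix.

    Injecting at fiber i and sampling with fiber j's injection operator must
    equal the converse exactly for the symmetric discrete system.
    """
    pts = probe.source_points(mesh.diameter_mm)
    Q = np.column_stack([point_load(mesh, p) for p in pts])
    fields = system.solve(Q.astype(complex))  # (N_nodes, N_s)
    T = Q.T @ fields
    denom = np.maximum(np.abs(T), np.abs(T.T))
    off = ~np.eye(len(T), dtype=bool)
    return float(np.max(np.abs(T - T.T)[off] / denom[off]))
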