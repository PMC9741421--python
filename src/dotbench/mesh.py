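"""Structured disk meshes, phantom sampling, and ground-truth rasterization.

The mesh is a concentric-ring ("hexagonal") triangulation of a disk: ring k
carries 6k equally spaced vertices, giving exactly 3*n**2 + 3*n + 1 nodes and
6*n**2 triangles at refinement level n.  Phantoms are circular media with up
to two circular inclusions, sampled uniformly from configurable parameter
ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Inclusion",
    "Phantom",
    "Mesh",
    "NodalCoefficients",
    "ParameterRanges",
    "DEFAULT_RANGES",
    "DEFAULT_PARTITION",
    "CONTAINMENT_MARGIN",
    "build_disk_mesh",
    "allocate_partition",
    "sample_phantom",
    "sample_phantom_batch",
    "nodal_coefficients",
    "rasterize_truth",
    "save_mesh_text",
    "save_mesh_gmsh",
    "phantoms_to_table",
]

#: inclusions must satisfy off_center + radius <= margin * phantom_radius,
#: keeping them clear of the boundary source/detector ring
CONTAINMENT_MARGIN = 0.95


@dataclass(frozen=True)
class Inclusion:
    """A circular inclusion inside the phantom.

    Contrasts are multiplicative relative to the background coefficients.
    """

    radius_mm: float
    off_center_mm: float
    angle_deg: float
    contrast_a: float
    contrast_s: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"inclusion radius must be positive, got {self.radius_mm}")
        if self.off_center_mm < 0:
            raise ValueError("off-center distance must be nonnegative")
        if self.contrast_a < 1 or self.contrast_s < 1:
            raise ValueError("contrasts must be >= 1")

    @property
    def center_mm(self) -> tuple[float, float]:
        th = math.radians(self.angle_deg)
        return (self.off_center_mm * math.cos(th), self.off_center_mm * math.sin(th))


@dataclass(frozen=True)
class Phantom:
    """Circular phantom: geometry, background optics, and 0-2 inclusions."""

    diameter_mm: float
    frequency_MHz: float
    mu_a0: float
    mu_s0: float
    inclusions: tuple[Inclusion, ...] = ()

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")
        if self.frequency_MHz < 0:
            raise ValueError("frequency must be nonnegative")
        if self.mu_a0 <= 0 or self.mu_s0 <= 0:
            raise ValueError("background coefficients must be positive")
        if len(self.inclusions) > 2:
            raise ValueError("at most 2 inclusions supported")
        R = self.diameter_mm / 2.0
        for inc in self.inclusions:
            if inc.off_center_mm + inc.radius_mm > R + 1e-12:
                raise ValueError(
                    f"inclusion (r={inc.radius_mm}, r_oc={inc.off_center_mm}) "
                    f"extends beyond phantom radius {R}"
                )


@dataclass(frozen=True)
class Mesh:
    """Triangulated disk: node coordinates (mm), triangles, boundary ring."""

    node_coords: np.ndarray  # (N, 2)
    elements: np.ndarray  # (M, 3) int
    boundary_nodes: np.ndarray  # indices on the outer ring
    n_rings: int

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def diameter_mm(self) -> float:
        return 2.0 * float(np.max(np.linalg.norm(self.node_coords, axis=1)))

    def element_areas(self) -> np.ndarray:
        """Signed areas of all triangles (positive for CCW orientation)."""
        p = self.node_coords[self.elements]  # (M, 3, 2)
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        return 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])


@dataclass
class NodalCoefficients:
    """Per-node absorption and reduced scattering coefficients (mm^-1)."""

    mu_a: np.ndarray
    mu_s: np.ndarray

    def __post_init__(self) -> None:
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        self.mu_s = np.asarray(self.mu_s, dtype=float)
        if self.mu_a.shape != self.mu_s.shape:
            raise ValueError("mu_a and mu_s must have equal length")
        if np.any(self.mu_a <= 0) or np.any(self.mu_s <= 0):
            raise ValueError("coefficients must be strictly positive")

    def copy(self) -> "NodalCoefficients":
        return NodalCoefficients(self.mu_a.copy(), self.mu_s.copy())


def build_disk_mesh(n_rings: int, diameter_mm: float) -> Mesh:
    """Concentric-ring triangulation of a disk.

    Ring k (k = 1..n) lies at radius k/n * d/2 and carries 6k equally spaced
    vertices; ring 0 is the single center node.  Node count is 3n^2 + 3n + 1
    and element count 6n^2.

    Parameters
    ----------
    n_rings : number of concentric rings (refinement level), >= 1.
    diameter_mm : disk diameter in mm.
    """
    if n_rings < 1 or int(n_rings) != n_rings:
        raise ValueError(f"n_rings must be a positive integer, got {n_rings}")
    if diameter_mm <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_mm}")
    n = int(n_rings)
    R = diameter_mm / 2.0

    coords = [np.zeros((1, 2))]
    ring_start = [0, 1]  # first node index of each ring
    for k in range(1, n + 1):
        ang = 2.0 * np.pi * np.arange(6 * k) / (6 * k)
        r = R * k / n
        coords.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
        ring_start.append(ring_start[-1] + 6 * k)
    node_coords = np.vstack(coords)

    tris: list[tuple[int, int, int]] = []
    for k in range(1, n + 1):
        outer0, n_out = ring_start[k], 6 * k
        inner0, n_in = ring_start[k - 1], max(6 * (k - 1), 1)
        for s in range(6):
            for i in range(k):
                o0 = outer0 + (s * k + i) % n_out
                o1 = outer0 + (s * k + i + 1) % n_out
                iv = inner0 + (s * (k - 1) + i) % n_in
                tris.append((o0, o1, iv))
                if i < k - 1:
                    iv1 = inner0 + (s * (k - 1) + i + 1) % n_in
                    tris.append((o1, iv1, iv))
    elements = np.array(tris, dtype=np.int64)

    # enforce positive (CCW) orientation
    p = node_coords[elements]
    signed = 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0])
    )
    flip = signed < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    boundary = np.arange(ring_start[n], ring_start[n] + 6 * n, dtype=np.int64)
    return Mesh(node_coords, elements, boundary, n)


@dataclass(frozen=True)
class ParameterRanges:
    """Uniform sampling ranges for phantom parameters."""

    diameter_mm: tuple[float, float] = (60.0, 150.0)
    frequency_MHz: tuple[float, float] = (10.0, 100.0)
    mu_a0: tuple[float, float] = (0.005, 0.03)
    mu_s0: tuple[float, float] = (0.5, 3.0)
    contrast: tuple[float, float] = (1.5, 8.0)
    inclusion_radius_mm: tuple[float, float] = (4.0, 17.0)

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"range {name} is not ordered: ({lo}, {hi})")


DEFAULT_RANGES = ParameterRanges()
#: inclusion-count weights for 0, 1 and 2 inclusions
DEFAULT_PARTITION = (0.01, 0.44, 0.55)

_MAX_PLACEMENT_ATTEMPTS = 100


def allocate_partition(n: int, weights: Sequence[float]) -> list[int]:
    """Exact stratified allocation of n samples to the given weights.

    Uses largest-remainder rounding so counts sum to n and the printed
    partition (1% / 44% / 55% of 10,000) is reproduced exactly.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("partition weights must be nonnegative and sum to 1")
    exact = w * n
    counts = np.floor(exact).astype(int)
    rem = n - int(counts.sum())
    order = np.argsort(-(exact - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def _place_inclusions(
    n_inc: int, ranges: ParameterRanges, R: float, rng: np.random.Generator
) -> tuple[Inclusion, ...]:
    r_lo, r_hi = ranges.inclusion_radius_mm
    c_lo, c_hi = ranges.contrast
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        incs = []
        for _ in range(n_inc):
            radius = rng.uniform(r_lo, min(r_hi, CONTAINMENT_MARGIN * R))
            max_oc = CONTAINMENT_MARGIN * R - radius
            incs.append(
                Inclusion(
                    radius_mm=radius,
                    off_center_mm=rng.uniform(0.0, max_oc),
                    angle_deg=rng.uniform(0.0, 360.0),
                    contrast_a=rng.uniform(c_lo, c_hi),
                    contrast_s=rng.uniform(c_lo, c_hi),
                )
            )
        if len(incs) < 2:
            return tuple(incs)
        (x0, y0), (x1, y1) = incs[0].center_mm, incs[1].center_mm
        gap = math.hypot(x1 - x0, y1 - y0) - incs[0].radius_mm - incs[1].radius_mm
        if gap > 0:
            return tuple(incs)
    raise RuntimeError(
        f"could not place {n_inc} disjoint inclusions (radius range "
        f"{ranges.inclusion_radius_mm}) inside phantom of radius {R} after "
        f"{_MAX_PLACEMENT_ATTEMPTS} attempts"
    )


def sample_phantom(
    ranges: ParameterRanges = DEFAULT_RANGES,
    partition: Sequence[float] = DEFAULT_PARTITION,
    rng: np.random.Generator | None = None,
    n_inclusions: int | None = None,
) -> Phantom:
    """Draw one phantom uniformly from the parameter ranges.

    The inclusion count is drawn from ``partition`` unless fixed via
    ``n_inclusions``.  Deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_inclusions is None:
        w = np.asarray(partition, dtype=float)
        if not math.isclose(float(w.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("partition weights must sum to 1")
        n_inclusions = int(rng.choice(len(w), p=w))
    d = rng.uniform(*ranges.diameter_mm)
    f = rng.uniform(*ranges.frequency_MHz)
    mu_a0 = rng.uniform(*ranges.mu_a0)
    mu_s0 = rng.uniform(*ranges.mu_s0)
    incs = _place_inclusions(n_inclusions, ranges, d / 2.0, rng)
    return Phantom(d, f, mu_a0, mu_s0, incs)


def sample_phantom_batch(
    n: int,
    ranges: ParameterRanges = DEFAULT_RANGES,
    partition: Sequence[float] = DEFAULT_PARTITION,
    rng: np.random.Generator | None = None,
    shuffle: bool = True,
) -> list[Phantom]:
    """Sample n phantoms with *exact* stratified inclusion-count allocation."""
    if rng is None:
        rng = np.random.default_rng()
    counts = allocate_partition(n, partition)
    phantoms: list[Phantom] = []
    for n_inc, count in enumerate(counts):
        for _ in range(count):
            phantoms.append(sample_phantom(ranges, partition, rng, n_inclusions=n_inc))
    if shuffle:
        perm = rng.permutation(n)
        phantoms = [phantoms[i] for i in perm]
    return phantoms


def _coefficient_fields(
    phantom: Phantom, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (mu_a, mu_s) at arbitrary points; overlaps take max contrast."""
    ca = np.ones_like(x)
    cs = np.ones_like(x)
    for inc in phantom.inclusions:
        cx, cy = inc.center_mm
        inside = (x - cx) ** 2 + (y - cy) ** 2 <= inc.radius_mm**2
        ca = np.where(inside, np.maximum(ca, inc.contrast_a), ca)
        cs = np.where(inside, np.maximum(cs, inc.contrast_s), cs)
    return phantom.mu_a0 * ca, phantom.mu_s0 * cs


def nodal_coefficients(phantom: Phantom, mesh: Mesh) -> NodalCoefficients:
    """Map the phantom description onto mesh nodes.

    Nodes inside an inclusion disc get background x contrast; overlapping
    inclusions resolve to the maximum contrast.
    """
    if not math.isclose(mesh.diameter_mm, phantom.diameter_mm, rel_tol=1e-9):
        raise ValueError(
            f"mesh diameter {mesh.diameter_mm} != phantom diameter {phantom.diameter_mm}"
        )
    x, y = mesh.node_coords[:, 0], mesh.node_coords[:, 1]
    mu_a, mu_s = _coefficient_fields(phantom, x, y)
    return NodalCoefficients(mu_a, mu_s)


def grid_centers(grid_size: int) -> np.ndarray:
    """Normalized pixel-center coordinates in [-0.5, 0.5], row 0 = minimum y."""
    u = (np.arange(grid_size) + 0.5) / grid_size - 0.5
    return u


def circular_mask(grid_size: int) -> np.ndarray:
    """Boolean mask of pixels whose center lies in the inscribed circle."""
    u = grid_centers(grid_size)
    xx, yy = np.meshgrid(u, u)
    return xx**2 + yy**2 <= 0.25


def rasterize_truth(phantom: Phantom, grid_size: int = 64, kind: str = "absolute"):
    """Rasterize the ground-truth coefficient images on a square grid.

    The grid spans [-d/2, d/2]^2 regardless of diameter; pixels outside the
    inscribed circle are masked out (value 0).  ``kind='contrast'`` returns
    (c - 1)/(c_max - 1) normalized contrast images in [0, 1].
    """
    from .dataset import CoefficientImage, CONTRAST_MAX  # local: avoid cycle

    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    u = grid_centers(grid_size) * phantom.diameter_mm
    xx, yy = np.meshgrid(u, u)
    mask = circular_mask(grid_size)
    mu_a, mu_s = _coefficient_fields(phantom, xx, yy)
    if kind == "absolute":
        a, s = mu_a, mu_s
    elif kind == "contrast":
        a = (mu_a / phantom.mu_a0 - 1.0) / (CONTRAST_MAX - 1.0)
        s = (mu_s / phantom.mu_s0 - 1.0) / (CONTRAST_MAX - 1.0)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    a = np.where(mask, a, 0.0)
    s = np.where(mask, s, 0.0)
    return CoefficientImage(a, s, mask, kind)


def save_mesh_text(mesh: Mesh, prefix: str) -> None:
    """Write node/element tables (<prefix>_nodes.csv, <prefix>_elements.csv)."""
    np.savetxt(
        f"{prefix}_nodes.csv",
        mesh.node_coords,
        delimiter=",",
        header="x_mm,y_mm",
        comments="",
    )
    np.savetxt(
        f"{prefix}_elements.csv",
        mesh.elements,
        fmt="%d",
        delimiter=",",
        header="n0,n1,n2",
        comments="",
    )


def save_mesh_gmsh(mesh: Mesh, path: str) -> None:
    """Export as Gmsh 2.2 ASCII (.msh), readable by standard mesh tools."""
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
        f.write(f"{mesh.n_nodes}\n")
        for i, (x, y) in enumerate(mesh.node_coords, start=1):
            f.write(f"{i} {x:.12g} {y:.12g} 0\n")
        f.write("$EndNodes\n$Elements\n")
        f.write(f"{mesh.n_elements}\n")
        for i, (a, b, c) in enumerate(mesh.elements + 1, start=1):
            f.write(f"{i} 2 2 0 1 {a} {b} {c}\n")
        f.write("$EndElements\n")


def phantoms_to_table(phantoms: Sequence[Phantom]):
    """Phantom parameters as a pandas DataFrame (one row per case)."""
    import pandas as pd

    rows = []
    for i, ph in enumerate(phantoms):
        rows.append(
            {
                "CASE": i,
                "D_mm": ph.diameter_mm,
                "f_MHz": ph.frequency_MHz,
                "mu_a0": ph.mu_a0,
                "mu_s0": ph.mu_s0,
                "r_mm": [inc.radius_mm for inc in ph.inclusions],
                "r_oc_mm": [inc.off_center_mm for inc in ph.inclusions],
                "theta_oc_deg": [inc.angle_deg for inc in ph.inclusions],
                "c_a": [inc.contrast_a for inc in ph.inclusions],
                "c_s": [inc.contrast_s for inc in ph.inclusions],
            }
        )
    return pd.DataFrame(rows)
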