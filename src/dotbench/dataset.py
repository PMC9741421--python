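"""Dataset generation: measurement/truth pairs, noise, grid interpolation,
and homogeneous-reference calibration of experimental data."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .mesh import (
    Mesh,
    Phantom,
    ParameterRanges,
    DEFAULT_RANGES,
    DEFAULT_PARTITION,
    build_disk_mesh,
    sample_phantom,
    sample_phantom_batch,
    nodal_coefficients,
    rasterize_truth,
    circular_mask,
    grid_centers,
)
from .forward import ProbeGeometry, MeasurementSet, solve_measurements

log = logging.getLogger(__name__)

__all__ = [
    "CoefficientImage",
    "NoiseModel",
    "DatasetFile",
    "CONTRAST_MAX",
    "interpolate_to_grid",
    "add_measurement_noise",
    "generate_dataset",
    "calibrate_experimental",
    "save_dataset",
    "load_dataset",
]

#: maximum inclusion-to-background contrast; contrast images are normalized
#: as (c - 1)/(CONTRAST_MAX - 1) so targets lie in [0, 1]
CONTRAST_MAX = 8.0


@dataclass
class CoefficientImage:
    """64x64 (or grid_size^2) coefficient images with a circular validity mask.

    ``kind`` is 'absolute' (mm^-1 values) or 'contrast' (normalized [0, 1]).
    """

    mu_a_grid: np.ndarray
    mu_s_grid: np.ndarray
    mask: np.ndarray
    kind: str = "absolute"

    def __post_init__(self) -> None:
        self.mu_a_grid = np.asarray(self.mu_a_grid, dtype=float)
        self.mu_s_grid = np.asarray(self.mu_s_grid, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.mu_a_grid.shape == self.mu_s_grid.shape == self.mask.shape):
            raise ValueError("grid shapes inconsistent")

    @property
    def grid_size(self) -> int:
        return self.mu_a_grid.shape[0]

    def stacked(self) -> np.ndarray:
        """(H, W, 2) array, channel 0 = mu_a, channel 1 = mu_s'."""
        return np.stack([self.mu_a_grid, self.mu_s_grid], axis=-1)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise: relative amplitude sigma and phase sigma."""

    amplitude_sigma_percent: float = 1.0
    phase_sigma_deg: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_sigma_percent < 0 or self.phase_sigma_deg < 0:
            raise ValueError("noise sigmas must be nonnegative")


@dataclass
class DatasetFile:
    """In-memory dataset: sensor inputs, aux scalars, truths, split labels."""

    inputs: np.ndarray  # (N, N_s, N_d, 2)
    aux: np.ndarray  # (N, 2) = (f MHz, d mm)
    truth_contrast: np.ndarray  # (N, H, W, 2) normalized contrast
    truth_background: np.ndarray  # (N, 2) = (mu_a0, mu_s0)
    split: np.ndarray  # (N,) 0 = train, 1 = validation
    phantoms: list[Phantom] | None = None
    meta: dict | None = None

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]

    @property
    def train_indices(self) -> np.ndarray:
        return np.flatnonzero(self.split == 0)

    @property
    def validation_indices(self) -> np.ndarray:
        return np.flatnonzero(self.split == 1)


def interpolate_to_grid(
    nodal_values: np.ndarray, mesh: Mesh, grid_size: int = 64
) -> np.ndarray:
    """Barycentric-linear interpolation of a nodal field at pixel centers.

    Pixels outside the circular mask are 0; masked pixels falling outside
    every element (boundary round-off) use the nearest element, logged once.
    """
    nodal_values = np.asarray(nodal_values, dtype=float)
    if nodal_values.shape[0] != mesh.n_nodes:
        raise ValueError("nodal_values length does not match mesh")
    d = mesh.diameter_mm
    u = grid_centers(grid_size) * d
    xx, yy = np.meshgrid(u, u)
    mask = circular_mask(grid_size)
    pts = np.column_stack([xx[mask], yy[mask]])

    p = mesh.node_coords[mesh.elements]  # (M, 3, 2)
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]

    dd = pts[:, None, :] - p[None, :, 0, :]  # (P, M, 2)
    l1 = (dd[..., 0] * v1[None, :, 1] - dd[..., 1] * v1[None, :, 0]) / det[None, :]
    l2 = (v0[None, :, 0] * dd[..., 1] - v0[None, :, 1] * dd[..., 0]) / det[None, :]
    l0 = 1.0 - l1 - l2
    lam = np.stack([l0, l1, l2], axis=-1)  # (P, M, 3)
    worst = lam.min(axis=-1)  # (P, M)
    elem = np.argmax(worst, axis=1)
    best = worst[np.arange(len(pts)), elem]
    n_fallback = int(np.sum(best < -1e-12))
    if n_fallback:
        log.debug("interpolate_to_grid: %d pixels used nearest-element fallback", n_fallback)
    w = lam[np.arange(len(pts)), elem]
    w = np.clip(w, 0.0, None)
    w /= w.sum(axis=1, keepdims=True)
    vals = np.einsum("pk,pk->p", w, nodal_values[mesh.elements[elem]])

    out = np.zeros((grid_size, grid_size))
    out[mask] = vals
    return out


def add_measurement_noise(meas: MeasurementSet, noise: NoiseModel) -> MeasurementSet:
    """Multiplicative Gaussian amplitude noise + additive Gaussian phase noise.

    Amplitude noise is applied in linear amplitude then re-logged;
    deterministic under the model's seed.
    """
    rng = np.random.default_rng(noise.seed)
    amp = np.exp(meas.log_amplitude)
    sigma = noise.amplitude_sigma_percent / 100.0
    factor = 1.0 + sigma * rng.standard_normal(amp.shape)
    factor = np.clip(factor, 1e-6, None)
    phase = meas.phase_lag + np.radians(noise.phase_sigma_deg) * rng.standard_normal(
        meas.phase_lag.shape
    )
    return MeasurementSet(
        np.log(amp * factor),
        np.mod(phase, 2.0 * np.pi),
        meas.frequency_MHz,
        meas.diameter_mm,
    )


def generate_dataset(
    n_samples: int,
    ranges: ParameterRanges = DEFAULT_RANGES,
    partition: Sequence[float] = DEFAULT_PARTITION,
    noise: NoiseModel | None = None,
    seed: int = 0,
    n_rings: int = 32,
    grid_size: int = 64,
    n_sources: int = 16,
    train_fraction: float = 0.8,
    skip_forward: bool = False,
) -> DatasetFile:
    """Build a full measurement -> truth-image dataset.

    Per sample: sample phantom, map coefficients to the mesh, forward-solve,
    read detectors, add noise; truth = normalized contrast images plus the
    background coefficient pair.  The train/validation split assigns the
    first ``train_fraction`` of the (already shuffled) samples to training.

    ``skip_forward=True`` fills measurements with zeros (parameter-only
    generation, used for partition accounting at scale).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    phantoms = sample_phantom_batch(n_samples, ranges, partition, rng)
    n_det = n_sources - 1

    inputs = np.zeros((n_samples, n_sources, n_det, 2))
    aux = np.zeros((n_samples, 2))
    truth_contrast = np.zeros((n_samples, grid_size, grid_size, 2))
    truth_background = np.zeros((n_samples, 2))

    mesh_cache: dict[float, Mesh] = {}
    for i, ph in enumerate(phantoms):
        aux[i] = (ph.frequency_MHz, ph.diameter_mm)
        truth_background[i] = (ph.mu_a0, ph.mu_s0)
        ci = rasterize_truth(ph, grid_size, kind="contrast")
        truth_contrast[i] = ci.stacked()
        if skip_forward:
            continue
        for attempt in range(3):
            mesh = mesh_cache.setdefault(
                ph.diameter_mm, build_disk_mesh(n_rings, ph.diameter_mm)
            )
            probe = ProbeGeometry.for_background(ph.mu_s0, n_sources)
            coeffs = nodal_coefficients(ph, mesh)
            try:
                meas = solve_measurements(mesh, coeffs, probe, ph.frequency_MHz)
                break
            except RuntimeError:
                log.warning("forward solve failed for sample %d; resampling", i)
                ph = sample_phantom(ranges, partition, rng, len(ph.inclusions))
                phantoms[i] = ph
                aux[i] = (ph.frequency_MHz, ph.diameter_mm)
                truth_background[i] = (ph.mu_a0, ph.mu_s0)
                truth_contrast[i] = rasterize_truth(ph, grid_size, "contrast").stacked()
        else:
            raise RuntimeError(f"forward solve failed repeatedly for sample {i}")
        if noise is not None:
            meas = add_measurement_noise(
                meas,
                NoiseModel(
                    noise.amplitude_sigma_percent,
                    noise.phase_sigma_deg,
                    seed=noise.seed + i,
                ),
            )
        inputs[i] = meas.as_array()

    n_train = int(round(train_fraction * n_samples))
    split = np.ones(n_samples, dtype=np.int8)
    split[:n_train] = 0

    meta = {
        "n_samples": n_samples,
        "seed": seed,
        "n_rings": n_rings,
        "grid_size": grid_size,
        "n_sources": n_sources,
        "train_fraction": train_fraction,
        "partition": list(partition),
        "ranges": asdict(ranges),
        "noise": asdict(noise) if noise is not None else None,
        "contrast_max": CONTRAST_MAX,
    }
    return DatasetFile(inputs, aux, truth_contrast, truth_background, split, phantoms, meta)


def calibrate_experimental(
    meas_inhomog: MeasurementSet,
    meas_homog: MeasurementSet,
    reference_homog: MeasurementSet,
) -> MeasurementSet:
    """Homogeneous-reference calibration in the log/phase domain.

    calibrated = (inhomogeneous - homogeneous) + simulated reference, which
    cancels per-channel instrument gains (additive in log amplitude and in
    phase) exactly.
    """
    if meas_inhomog.shape != meas_homog.shape or meas_homog.shape != reference_homog.shape:
        raise ValueError("measurement sets must share probe geometry")
    log_amp = (
        meas_inhomog.log_amplitude - meas_homog.log_amplitude + reference_homog.log_amplitude
    )
    phase = meas_inhomog.phase_lag - meas_homog.phase_lag + reference_homog.phase_lag
    return MeasurementSet(
        log_amp,
        np.mod(phase, 2.0 * np.pi),
        reference_homog.frequency_MHz,
        reference_homog.diameter_mm,
    )


def _phantoms_to_json(phantoms: Sequence[Phantom]) -> str:
    from dataclasses import asdict as dc_asdict

    return json.dumps(
        [
            {
                "diameter_mm": ph.diameter_mm,
                "frequency_MHz": ph.frequency_MHz,
                "mu_a0": ph.mu_a0,
                "mu_s0": ph.mu_s0,
                "inclusions": [dc_asdict(inc) for inc in ph.inclusions],
            }
            for ph in phantoms
        ]
    )


def _phantoms_from_json(blob: str) -> list[Phantom]:
    from .mesh import Inclusion

    out = []
    for d in json.loads(blob):
        incs = tuple(Inclusion(**i) for i in d.pop("inclusions"))
        out.append(Phantom(inclusions=incs, **d))
    return out


def save_dataset(ds: DatasetFile, path: str) -> None:
    """Write the dataset to an HDF5 container (phantom params embedded)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=ds.inputs)
        f.create_dataset("aux", data=ds.aux)
        f.create_dataset("truth_contrast", data=ds.truth_contrast)
        f.create_dataset("truth_background", data=ds.truth_background)
        f.create_dataset("split", data=ds.split)
        if ds.meta is not None:
            f.attrs["meta"] = json.dumps(ds.meta)
        if ds.phantoms is not None:
            f.attrs["phantoms"] = _phantoms_to_json(ds.phantoms)


def load_dataset(path: str) -> DatasetFile:
    import h5py

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else None
        phantoms = (
            _phantoms_from_json(f.attrs["phantoms"]) if "phantoms" in f.attrs else None
        )
        return DatasetFile(
            inputs=f["inputs"][...],
            aux=f["aux"][...],
            truth_contrast=f["truth_contrast"][...],
            truth_background=f["truth_background"][...],
            split=f["split"][...],
            phantoms=phantoms,
            meta=meta,
        )
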