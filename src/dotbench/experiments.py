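"""Desk-scale recovery experiments.

These bundle the seeded end-to-end runs used to validate the two
reconstruction routes on a laptop-class budget: Tikhonov localization of a
known inclusion, and scaled-down neural training against a
predict-the-mean baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mesh import (
    Phantom,
    Inclusion,
    ParameterRanges,
    build_disk_mesh,
    nodal_coefficients,
    sample_phantom,
    circular_mask,
    grid_centers,
)
from .forward import ProbeGeometry, solve_measurements
from .tikhonov import ReconOptions, reconstruct_tr
from .dataset import generate_dataset
from .mesh import NodalCoefficients

log = logging.getLogger(__name__)

__all__ = [
    "tr_localization_trial",
    "tr_localization_experiment",
    "image_blob_centroid",
    "nn_scaled_training_experiment",
    "ScaledTrainingResult",
]


def _single_inclusion_phantom(
    seed: int,
    diameter_mm: float = 90.0,
    frequency_MHz: float = 100.0,
    contrast: float = 4.0,
) -> Phantom:
    """Deterministic single-inclusion phantom with r = d/6 at a seeded pose."""
    rng = np.random.default_rng(seed)
    r = diameter_mm / 6.0
    r_oc = rng.uniform(0.25, 0.55) * diameter_mm / 2.0
    angle = rng.uniform(0.0, 360.0)
    return Phantom(
        diameter_mm=diameter_mm,
        frequency_MHz=frequency_MHz,
        mu_a0=0.01,
        mu_s0=1.0,
        inclusions=(
            Inclusion(
                radius_mm=r,
                off_center_mm=r_oc,
                angle_deg=angle,
                contrast_a=contrast,
                contrast_s=contrast / 2.0,
            ),
        ),
    )


def tr_localization_trial(
    seed: int, n_rings: int = 16, max_iterations: int = 8
) -> tuple[float, float]:
    """One TR recovery run on noiseless synthetic data.

    Returns (centroid error in mm, inclusion radius in mm): the centroid of
    the top-10% mu_a perturbation nodes versus the true inclusion center.
    """
    ph = _single_inclusion_phantom(seed)
    mesh = build_disk_mesh(n_rings, ph.diameter_mm)
    probe = ProbeGeometry.for_background(ph.mu_s0)
    truth = nodal_coefficients(ph, mesh)
    meas = solve_measurements(mesh, truth, probe, ph.frequency_MHz)

    init = NodalCoefficients(
        np.full(mesh.n_nodes, ph.mu_a0), np.full(mesh.n_nodes, ph.mu_s0)
    )
    opts = ReconOptions(max_iterations=max_iterations)
    result = reconstruct_tr(meas, mesh, probe, init, opts)

    perturb = result.coefficients.mu_a - ph.mu_a0
    thr = np.percentile(perturb, 90.0)
    sel = perturb >= thr
    centroid = mesh.node_coords[sel].mean(axis=0)
    inc = ph.inclusions[0]
    err = float(np.linalg.norm(centroid - np.asarray(inc.center_mm)))
    return err, inc.radius_mm


def tr_localization_experiment(
    seeds=range(5), n_rings: int = 16, max_iterations: int = 8
) -> list[bool]:
    """Pass/fail per seed: centroid error within one inclusion radius."""
    outcomes = []
    for s in seeds:
        err, radius = tr_localization_trial(s, n_rings, max_iterations)
        log.info("TR localization seed %s: error %.2f mm (radius %.2f mm)", s, err, radius)
        outcomes.append(err <= radius)
    return outcomes


def image_blob_centroid(
    image: np.ndarray, diameter_mm: float, percentile: float = 90.0
) -> np.ndarray:
    """Centroid (mm) of the top-percentile pixels inside the circular mask."""
    grid = image.shape[0]
    mask = circular_mask(grid)
    vals = image[mask]
    thr = np.percentile(vals, percentile)
    u = grid_centers(grid) * diameter_mm
    xx, yy = np.meshgrid(u, u)
    sel = mask & (image >= thr)
    return np.array([xx[sel].mean(), yy[sel].mean()])


@dataclass
class ScaledTrainingResult:
    validation_q: float
    baseline_q: float
    localization_pass: list[bool]
    selected_epoch: int
    history: dict[str, list[float]]

    @property
    def beats_baseline(self) -> bool:
        return self.validation_q < self.baseline_q


def _predict_mean_baseline(ds) -> float:
    """Q of always predicting the training-set mean contrast and background."""
    from .nn.network import LossWeights

    tr, va = ds.train_indices, ds.validation_indices
    mask = circular_mask(ds.truth_contrast.shape[1])
    mean_c = ds.truth_contrast[tr].mean(axis=0)
    mean_b = ds.truth_background[tr].mean(axis=0)
    w = LossWeights()
    dc = (ds.truth_contrast[va] - mean_c) * mask[None, :, :, None]
    n_masked = int(mask.sum())
    mse_c = (dc**2).sum(axis=(1, 2)) / n_masked  # (n_va, 2)
    db = ds.truth_background[va] - mean_b
    q = (
        w.w_ima * mse_c[:, 0]
        + w.w_ims * mse_c[:, 1]
        + w.w_a * db[:, 0] ** 2
        + w.w_s * db[:, 1] ** 2
    )
    return float(q.mean())


def nn_scaled_training_experiment(
    seed: int = 0,
    n_samples: int = 500,
    n_rings: int = 16,
    epochs: int = 40,
    n_test: int = 10,
    learning_rate: float = 2e-3,
    verbose: bool = False,
) -> ScaledTrainingResult:
    """CPU-scale stand-in for the full training run.

    Trains the reduced-width network on ``n_samples`` single-inclusion
    phantoms at fixed geometry (d = 100 mm, f = 100 MHz), then scores (a)
    validation Q against the predict-the-mean baseline and (b) localization
    of ``n_test`` held-out high-contrast (c_a >= 4) inclusions: the
    top-10% mu_a blob centroid must fall within 1.5 inclusion radii of
    truth.
    """
    from .nn import NetworkConfig, TrainingConfig, assemble_network, train_network
    from .nn import reconstruct_nn

    ranges = ParameterRanges(
        diameter_mm=(100.0, 100.0),
        frequency_MHz=(100.0, 100.0),
        contrast=(1.5, 8.0),
        inclusion_radius_mm=(6.0, 17.0),
    )
    ds = generate_dataset(
        n_samples,
        ranges=ranges,
        partition=(0.0, 1.0, 0.0),
        noise=None,
        seed=seed,
        n_rings=n_rings,
    )
    model = assemble_network(NetworkConfig.small(seed=seed))
    tc = TrainingConfig(
        learning_rate=learning_rate, epochs=epochs, batch_size=32, seed=seed
    )
    trained = train_network(model, ds, tc, verbose=verbose)
    baseline_q = _predict_mean_baseline(ds)
    val_q = trained.history["validation"][trained.selected_epoch - 1]

    # held-out high-contrast single-inclusion test cases
    test_ranges = ParameterRanges(
        diameter_mm=(100.0, 100.0),
        frequency_MHz=(100.0, 100.0),
        contrast=(4.0, 8.0),
        inclusion_radius_mm=(10.0, 17.0),
    )
    rng = np.random.default_rng(seed + 10_000)
    mesh = build_disk_mesh(n_rings, 100.0)
    passes = []
    for _ in range(n_test):
        ph = sample_phantom(test_ranges, rng=rng, n_inclusions=1)
        probe = ProbeGeometry.for_background(ph.mu_s0)
        meas = solve_measurements(mesh, nodal_coefficients(ph, mesh), probe, ph.frequency_MHz)
        recon = reconstruct_nn(trained, meas)
        centroid = image_blob_centroid(recon.mu_a_grid, ph.diameter_mm)
        inc = ph.inclusions[0]
        err = float(np.linalg.norm(centroid - np.asarray(inc.center_mm)))
        passes.append(err <= 1.5 * inc.radius_mm)
        log.info("NN localization: error %.1f mm, radius %.1f mm", err, inc.radius_mm)
    return ScaledTrainingResult(
        validation_q=val_q,
        baseline_q=baseline_q,
        localization_pass=passes,
        selected_epoch=trained.selected_epoch,
        history=trained.history,
    )
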