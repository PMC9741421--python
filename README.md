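# dotbench

A frequency-domain diffuse optical tomography (DOT) workbench for circular
breast-like phantoms:

* **`dotbench.mesh`** — structured concentric-ring disk triangulation
  (3169 nodes / 6144 elements at 32 rings), uniform phantom sampling with
  stratified inclusion-count allocation, and ground-truth rasterization to a
  64 × 64 grid with a circular validity mask.
* **`dotbench.forward`** — linear-triangle FEM solver for the
  frequency-domain photon diffusion equation with a Robin boundary
  condition, a 16-fiber ring probe (each fiber sources in turn, the other 15
  detect), and log-amplitude / phase-lag measurement sets. Includes the
  2-D infinite-medium Green's function as an independent test oracle.
* **`dotbench.dataset`** — measurement → truth-image dataset generation
  (HDF5), Gaussian amplitude/phase noise, barycentric interpolation of nodal
  fields to the pixel grid, and homogeneous-reference calibration of
  experimental data.
* **`dotbench.tikhonov`** — iterative inverse solver: adjoint-method
  Jacobian of log amplitude and phase with respect to nodal (D, μa),
  Levenberg–Marquardt-damped Tikhonov steps, and a monotone-χ² update loop.
* **`dotbench.nn`** — the branching sensor-to-image network (background
  predictor + domain-transform encoder/decoder + residual U-net producing
  contrast × background coefficient images), the weighted Q loss, Adam
  training, and inference. Built on a small NumPy reverse-mode autodiff
  engine, so no deep-learning framework is required.
* **`dotbench.metrics`** — contrast / size / contrast-size-detail (CSD)
  resolution analysis with 90th/10th-percentile robustification and the
  signed geometric-mean composition rules.
* **`dotbench.experiments`** — seeded desk-scale recovery experiments used
  by the acceptance suite.

## CLI

```bash
dotbench generate --n 100 --seed 7 --out data/train.h5     # dataset (HDF5 + CSV)
dotbench train --dataset data/train.h5 --seed 7 --epochs 40 --small --out-dir runs/m1
dotbench reconstruct --method tr --dataset data/train.h5 --index 0 --out-dir runs/tr0
dotbench reconstruct --method nn --dataset data/train.h5 --index 0 \
    --model runs/m1 --out-dir runs/nn0
dotbench evaluate --recon runs/tr0 --dataset data/train.h5 --indices 0 \
    --out runs/report.csv
dotbench demo --seed 0                                     # end-to-end smoke run
```

Every command writes a JSON manifest (resolved parameters, seed, version,
timing) next to its outputs.

## Conventions

* Units: mm, mm⁻¹, MHz; ω is converted to rad/ns internally;
  c = 299.792458 mm/ns ÷ refractive index (default 1.4).
* Measurements: natural-log amplitude; phase lag in radians, nonnegative,
  folded to [0, 2π).
* Contrast images are normalized as (c − 1)/(c_max − 1) with c_max = 8, so
  targets lie in [0, 1]; absolute images are contrast × background.
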