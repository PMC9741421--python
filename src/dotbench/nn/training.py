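"""Training loop (Adam on the weighted Q loss) and inference helpers."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np

from ..dataset import DatasetFile, CoefficientImage, CONTRAST_MAX
from ..forward import MeasurementSet
from ..mesh import circular_mask
from .autograd import Tensor, no_grad
from .network import ReconNet, NetworkConfig, LossWeights, assemble_network, loss_Q

log = logging.getLogger(__name__)

__all__ = ["TrainingConfig", "TrainedModel", "Adam", "train_network", "reconstruct_nn",
           "save_model", "load_model"]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.0002
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)


class Adam:
    def __init__(self, params, lr=0.0002, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainedModel:
    model: ReconNet
    config: NetworkConfig
    history: dict[str, list[float]]
    selected_epoch: int

    @property
    def epochs_run(self) -> int:
        return len(self.history["train"])


def _truth_tensors(ds: DatasetFile, idx: np.ndarray):
    tc = ds.truth_contrast[idx].transpose(0, 3, 1, 2)  # (n, 2, H, W)
    tb = ds.truth_background[idx]
    return tc, tb


def _evaluate_split(model, x, a, tc, tb, mask, weights, batch_size=64) -> float:
    total, n = 0.0, 0
    with no_grad():
        for lo in range(0, len(x), batch_size):
            hi = min(lo + batch_size, len(x))
            pc, pb = model(Tensor(x[lo:hi]), Tensor(a[lo:hi]), train=False)
            q = loss_Q(pc, pb, tc[lo:hi], tb[lo:hi], mask, weights)
            total += float(q.data) * (hi - lo)
            n += hi - lo
    return total / n


def train_network(
    model: ReconNet,
    dataset: DatasetFile,
    config: TrainingConfig,
    verbose: bool = False,
) -> TrainedModel:
    """Minimize the Q loss with Adam; select the best-validation epoch.

    Records per-epoch training and validation Q.  Weights of the epoch with
    the lowest validation loss are restored in the returned model.
    """
    tr_idx = dataset.train_indices
    va_idx = dataset.validation_indices
    if len(tr_idx) == 0 or len(va_idx) == 0:
        raise ValueError("dataset must contain both train and validation samples")

    model.fit_normalization(dataset.inputs[tr_idx])
    x_all, a_all = model.prepare_inputs(dataset.inputs, dataset.aux)
    tc_all = dataset.truth_contrast.transpose(0, 3, 1, 2)
    tb_all = dataset.truth_background
    mask = circular_mask(model.config.grid_size)

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), config.learning_rate, config.beta1, config.beta2)
    history: dict[str, list[float]] = {"train": [], "validation": []}
    best = (np.inf, -1, None)

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(tr_idx)
        running, seen = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            pc, pb = model(Tensor(x_all[idx]), Tensor(a_all[idx]), train=True)
            q = loss_Q(pc, pb, tc_all[idx], tb_all[idx], mask, config.weights)
            if not np.isfinite(q.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (batch starting {lo}); "
                    "lower the learning rate"
                )
            opt.zero_grad()
            q.backward()
            opt.step()
            running += float(q.data) * len(idx)
            seen += len(idx)
        train_q = running / seen
        val_q = _evaluate_split(
            model, x_all[va_idx], a_all[va_idx], tc_all[va_idx], tb_all[va_idx],
            mask, config.weights,
        )
        history["train"].append(train_q)
        history["validation"].append(val_q)
        if val_q < best[0]:
            state = {k: v.copy() for k, v in model.state_arrays().items()}
            best = (val_q, epoch, (model.get_weights(), state))
        if verbose:
            log.info("epoch %d: train Q=%.5g val Q=%.5g", epoch, train_q, val_q)

    if best[2] is not None:
        weights, state = best[2]
        model.set_weights(weights)
        live_state = model.state_arrays()
        for k, v in state.items():
            live_state[k][...] = v
    return TrainedModel(model, model.config, history, selected_epoch=best[1])


def reconstruct_nn(
    trained: TrainedModel | ReconNet,
    meas: MeasurementSet | np.ndarray,
    aux: tuple[float, float] | None = None,
) -> CoefficientImage:
    """Reconstruct an absolute-coefficient image from one measurement set."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    cfg = model.config
    if isinstance(meas, MeasurementSet):
        arr = meas.as_array()[None]
        aux_arr = np.array([[meas.frequency_MHz, meas.diameter_mm]])
    else:
        arr = np.asarray(meas)[None]
        if aux is None:
            raise ValueError("aux (frequency, diameter) required for raw arrays")
        aux_arr = np.asarray(aux, dtype=float)[None]
    if arr.shape[1:] != (cfg.n_sources, cfg.n_detectors, 2):
        raise ValueError(
            f"measurement shape {arr.shape[1:]} does not match probe "
            f"({cfg.n_sources}, {cfg.n_detectors}, 2)"
        )
    x, a = model.prepare_inputs(arr, aux_arr)
    with no_grad():
        contrast, background = model(Tensor(x), Tensor(a), train=False)
    c = contrast.data[0]  # (2, H, W)
    bg = background.data[0]  # (2,)
    mask = circular_mask(cfg.grid_size)
    absolute = (c * (CONTRAST_MAX - 1.0) + 1.0) * bg[:, None, None]
    absolute *= mask[None]
    return CoefficientImage(absolute[0], absolute[1], mask, kind="absolute")


def save_model(trained: TrainedModel, weights_path: str, config_path: str) -> None:
    """Weights as .npz, config + history as JSON."""
    model = trained.model
    arrays = {f"param_{i}": w for i, w in enumerate(model.get_weights())}
    for k, v in model.state_arrays().items():
        arrays[f"state_{k}"] = v
    np.savez(weights_path, **arrays)
    with open(config_path, "w") as f:
        json.dump(
            {
                "config": asdict(trained.config),
                "history": trained.history,
                "selected_epoch": trained.selected_epoch,
            },
            f,
            indent=2,
        )


def load_model(weights_path: str, config_path: str) -> TrainedModel:
    with open(config_path) as f:
        blob = json.load(f)
    cfg_dict = blob["config"]
    for key in ("blockB_channels", "blockA_widths", "unet_widths",
                "aux_frequency_range", "aux_diameter_range", "background_init"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = NetworkConfig(**cfg_dict)
    model = assemble_network(config)
    data = np.load(weights_path)
    n_params = len(model.parameters())
    model.set_weights([data[f"param_{i}"] for i in range(n_params)])
    state = model.state_arrays()
    for k in state:
        key = f"state_{k}"
        if key in data:
            state[k][...] = data[key]
    model.input_mean = data["state_input_mean"]
    model.input_std = data["state_input_std"]
    return TrainedModel(model, config, blob["history"], blob["selected_epoch"])
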