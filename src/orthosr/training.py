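"""Plane-selective patch training and full-slice inference.

Training pairs are 2-D slices taken from the HR (thin axial) and LR
(fused) volumes along one anatomical plane — axial, coronal or
sagittal. Each step samples ``batch_size`` random 96×96 patch pairs
cut at identical locations, normalises them from the Hounsfield window
[−1024, 3071] to [0, 1], and minimises L1 or MSE loss with Adam.
After every epoch the model is evaluated by running full-slice
inference on held-out cases; the checkpoint with the best evaluation
PSNR is the one returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import CTVolume
from .models import ArchitectureSpec, Network, build_model
from .nn import Adam, clip_global_norm, l1_loss, mse_loss

__all__ = [
    "PLANES",
    "TrainConfig",
    "TrainedModel",
    "extract_plane_slices",
    "restack_plane_slices",
    "sample_patch_pair",
    "train",
    "infer_volume",
    "TABLE_SETTINGS",
]

PLANES = ("axial", "coronal", "sagittal")

HU_WINDOW = (-1024.0, 3071.0)

#: Published full-scale training settings per architecture:
#: (batches per epoch, total epochs, initial learning rate, loss).
TABLE_SETTINGS: dict[str, tuple[int, int, float, str]] = {
    "EDSR": (7500, 20, 1e-4, "L1"),
    "SRCNN": (1000, 200, 1e-4, "MSE"),
    "VDSR": (1000, 240, 1e-5, "MSE"),
    "SRResNet": (1000, 180, 1e-4, "MSE"),
}


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    patch_size: int = 96
    batch_size: int = 16
    batches_per_epoch: int = 1000
    total_epochs: int = 20
    learning_rate: float = 1e-4
    loss: str = "MSE"
    plane: str = "sagittal"
    seed: int = 0
    grad_clip: float | None = None
    normalization_window: tuple[float, float] = HU_WINDOW

    def __post_init__(self) -> None:
        if self.loss not in ("L1", "MSE"):
            raise ValueError(f"loss must be 'L1' or 'MSE', got {self.loss!r}")
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")

    @property
    def total_patches(self) -> int:
        """Patches consumed by a complete run."""
        return self.batch_size * self.batches_per_epoch * self.total_epochs

    @classmethod
    def published(cls, arch: str, plane: str = "sagittal", seed: int = 0) -> "TrainConfig":
        """The full-scale settings used for each architecture.

        VDSR additionally trains with global-norm gradient clipping
        (bound 1.0 — the clipping constant is not part of the published
        settings table).
        """
        bpe, epochs, lr, loss = TABLE_SETTINGS[arch]
        return cls(
            patch_size=96,
            batch_size=16,
            batches_per_epoch=bpe,
            total_epochs=epochs,
            learning_rate=lr,
            loss=loss,
            plane=plane,
            seed=seed,
            grad_clip=1.0 if arch == "VDSR" else None,
        )


@dataclass
class TrainedModel:
    """A network with its provenance: config, spec, window and log."""

    network: Network
    spec: ArchitectureSpec
    config: TrainConfig
    train_log: list[dict] = field(default_factory=list)
    patch_counter: int = 0

    @property
    def window(self) -> tuple[float, float]:
        return self.config.normalization_window


def extract_plane_slices(vol: CTVolume | np.ndarray, plane: str) -> np.ndarray:
    """Slice a volume along an anatomical plane.

    Returns an (S, H, W) stack: axial → size_z slices of (y, x),
    coronal → size_y slices of (z, x), sagittal → size_x slices of
    (z, y). The same transform applied to HR and LR partners keeps
    their orientations consistent.
    """
    arr = vol.intensities if isinstance(vol, CTVolume) else np.asarray(vol)
    if plane == "axial":
        return arr.transpose(2, 1, 0)
    if plane == "coronal":
        return arr.transpose(1, 2, 0)
    if plane == "sagittal":
        return arr.transpose(0, 2, 1)
    raise ValueError(f"unknown plane {plane!r}")


def restack_plane_slices(stack: np.ndarray, plane: str) -> np.ndarray:
    """Inverse of :func:`extract_plane_slices` (lossless round-trip)."""
    if plane == "axial":
        return stack.transpose(2, 1, 0)
    if plane == "coronal":
        return stack.transpose(2, 0, 1)
    if plane == "sagittal":
        return stack.transpose(0, 2, 1)
    raise ValueError(f"unknown plane {plane!r}")


def normalize_hu(x: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    lo, hi = window
    return (x - lo) / (hi - lo)


def denormalize_hu(x: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    lo, hi = window
    return x * (hi - lo) + lo


def _pad_to(img: np.ndarray, size: int) -> np.ndarray:
    ph = max(size - img.shape[0], 0)
    pw = max(size - img.shape[1], 0)
    if ph == 0 and pw == 0:
        return img
    return np.pad(img, ((0, ph), (0, pw)), mode="reflect")


def sample_patch_pair(
    hr_slice: np.ndarray,
    lr_slice: np.ndarray,
    patch: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut one random patch pair at a shared location.

    Slices smaller than the patch in either dimension are
    reflect-padded first; offsets are uniform over the valid range.
    """
    if hr_slice.shape != lr_slice.shape:
        raise ValueError("HR and LR slices must have the same shape")
    hr_slice = _pad_to(hr_slice, patch)
    lr_slice = _pad_to(lr_slice, patch)
    h, w = hr_slice.shape
    i = int(rng.integers(0, h - patch + 1))
    j = int(rng.integers(0, w - patch + 1))
    return (
        hr_slice[i : i + patch, j : j + patch],
        lr_slice[i : i + patch, j : j + patch],
    )


def _infer_stack(network: Network, stack: np.ndarray) -> np.ndarray:
    """Run every (normalised) slice of a stack through the network."""
    out = np.empty_like(stack)
    for s in range(stack.shape[0]):
        out[s] = network.forward(stack[s][None, None], training=False)[0, 0]
    return out


def _psnr_hu(ref: np.ndarray, test: np.ndarray, data_range: float) -> float:
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0:
        return 100.0
    return float(10.0 * np.log10(data_range**2 / mse))


def evaluate_psnr(
    network: Network,
    cases: list[tuple[CTVolume, CTVolume]],
    plane: str,
    window: tuple[float, float] = HU_WINDOW,
) -> float:
    """Mean full-volume PSNR (HU scale) of SR output over (hr, lr) cases."""
    lo, hi = window
    scores = []
    for hr, lr in cases:
        sr = infer_stack_volume(network, lr, plane, window)
        scores.append(_psnr_hu(hr.intensities, sr.intensities, hi - lo))
    return float(np.mean(scores))


def infer_stack_volume(
    network: Network,
    lr: CTVolume,
    plane: str,
    window: tuple[float, float] = HU_WINDOW,
) -> CTVolume:
    """Slice → network → restack, with HU de-normalisation and clipping."""
    stack = normalize_hu(extract_plane_slices(lr, plane), window)
    out = _infer_stack(network, stack)
    hu = np.clip(denormalize_hu(out, window), window[0], window[1])
    return lr.copy_with(restack_plane_slices(hu, plane))


def train(
    network: Network,
    train_cases: list[tuple[CTVolume, CTVolume]],
    eval_cases: list[tuple[CTVolume, CTVolume]],
    config: TrainConfig,
) -> TrainedModel:
    """Patch-based training with per-epoch held-out model selection.

    ``train_cases`` and ``eval_cases`` are (hr, lr) volume pairs on a
    common grid. Each epoch consumes ``batches_per_epoch`` batches of
    ``batch_size`` patch pairs from the configured plane; the returned
    model carries the weights of the epoch with the best evaluation
    PSNR and a patch counter equal to
    ``batch_size * batches_per_epoch * total_epochs``.
    """
    if not eval_cases:
        raise ValueError("evaluation set must not be empty")
    if not train_cases:
        raise ValueError("training set must not be empty")

    rng = np.random.default_rng(config.seed)
    window = config.normalization_window
    hr_stacks = [
        normalize_hu(extract_plane_slices(hr, config.plane), window)
        for hr, _ in train_cases
    ]
    lr_stacks = [
        normalize_hu(extract_plane_slices(lr, config.plane), window)
        for _, lr in train_cases
    ]
    n_slices = [s.shape[0] for s in hr_stacks]

    loss_fn = l1_loss if config.loss == "L1" else mse_loss
    opt = Adam(network.params(), lr=config.learning_rate)

    model = TrainedModel(network=network, spec=network.spec, config=config)
    best_psnr = -np.inf
    best_state = network.get_state()
    for epoch in range(config.total_epochs):
        epoch_loss = 0.0
        for _ in range(config.batches_per_epoch):
            hr_batch = np.empty((config.batch_size, 1, config.patch_size, config.patch_size))
            lr_batch = np.empty_like(hr_batch)
            for b in range(config.batch_size):
                c = int(rng.integers(len(train_cases)))
                s = int(rng.integers(n_slices[c]))
                hp, lp = sample_patch_pair(
                    hr_stacks[c][s], lr_stacks[c][s], config.patch_size, rng
                )
                hr_batch[b, 0] = hp
                lr_batch[b, 0] = lp
            opt.zero_grad()
            pred = network.forward(lr_batch, training=True)
            loss, grad = loss_fn(pred, hr_batch)
            network.backward(grad)
            if config.grad_clip is not None:
                clip_global_norm(network.params(), config.grad_clip)
            opt.step()
            epoch_loss += loss
            model.patch_counter += config.batch_size
        eval_psnr = evaluate_psnr(network, eval_cases, config.plane, window)
        model.train_log.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / config.batches_per_epoch,
                "eval_psnr": eval_psnr,
            }
        )
        if eval_psnr > best_psnr:
            best_psnr = eval_psnr
            best_state = network.get_state()
    network.set_state(best_state)
    return model


def infer_volume(
    model: TrainedModel, lr: CTVolume, plane: str | None = None
) -> CTVolume:
    """Super-resolve a volume slice-by-slice along ``plane``.

    The networks are fully convolutional, so slices are processed at
    full size regardless of the training patch size. Inferring along a
    plane other than the training plane is a legitimate experiment and
    only warns.
    """
    plane = plane or model.config.plane
    if plane != model.config.plane:
        warnings.warn(
            f"inferring along {plane!r} with a model trained on "
            f"{model.config.plane!r}",
            stacklevel=2,
        )
    return infer_stack_volume(model.network, lr, plane, model.window)


def save_model(model: TrainedModel, path) -> None:
    """Serialise a trained model (weights + spec + config) to .npz."""
    import json

    meta = json.dumps(
        {
            "name": model.spec.name,
            "width": model.spec.width,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in model.config.__dict__.items()
            },
            "train_log": model.train_log,
            "patch_counter": model.patch_counter,
        }
    )
    state = model.network.get_state()
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{f"arr_{i}": a for i, a in enumerate(state)})


def load_model(path) -> TrainedModel:
    """Inverse of :func:`save_model`."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    cfg_dict = meta["config"]
    cfg_dict["normalization_window"] = tuple(cfg_dict["normalization_window"])
    config = TrainConfig(**cfg_dict)
    network = build_model(ArchitectureSpec(meta["name"], width=meta["width"]))
    network.set_state(state)
    return TrainedModel(
        network=network,
        spec=network.spec,
        config=config,
        train_log=meta["train_log"],
        patch_counter=meta["patch_counter"],
    )


# re-export for callers configuring architectures alongside training
__all__ += ["build_model", "ArchitectureSpec", "save_model", "load_model"]
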