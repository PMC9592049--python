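"""Fully convolutional deep denoising autoencoder (DDAE).

The network is a symmetric encoder-decoder with no fully connected layers:
``depth`` encoder stages (k x k convolution with ``m * 2**stage`` filters,
ReLU, 2x average pooling), mirrored decoder stages (2x nearest upsampling,
convolution, ReLU) and a final single-filter linear convolution, so any
input whose sides are divisible by ``2**depth`` maps to an output of
identical size. Training minimizes per-pixel mean-squared error between the
network output for a noisy frame and the frame-averaged low-noise answer,
with early stopping on a held-out validation set (best-epoch weights are
restored).

Inputs are normalized before the forward pass and de-normalized after;
the normalization statistics are estimated from the training answers and
stored on the model so inference inverts them exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .nn import Adam, AvgPool2, Conv2D, ReLU, Sequential, Upsample2

Pair = Tuple[np.ndarray, np.ndarray]  # (noisy frame, answer)


class ShapeError(ValueError):
    """Input spatial dimensions incompatible with the encoder depth."""


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture and training hyperparameters.

    ``m`` is the base filter count (8, 16 or 32 in the standard sweeps),
    ``k`` the spatial filter size and ``depth`` the number of 2x
    downsampling stages. Training defaults: 50 epochs with early-stopping
    patience of 10 epochs, MSE loss, Adam at 1e-3.
    """

    m: int = 16
    k: int = 3
    depth: int = 2
    epochs: int = 50
    patience: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    normalization: str = "unit_range"  # or "zscore"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 3")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.epochs < 1 or self.patience < 1:
            raise ValueError("epochs and patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.normalization not in ("unit_range", "zscore"):
            raise ValueError("normalization must be 'unit_range' or 'zscore'")


@dataclass
class TrainingReport:
    train_losses: List[float]
    val_losses: List[float]
    stopped_epoch: int
    best_epoch: int
    init_val_loss: float
    config: DenoiserConfig

    def __post_init__(self) -> None:
        if self.stopped_epoch > self.config.epochs:
            raise ValueError("stopped_epoch exceeds epoch budget")
        if self.best_epoch > self.stopped_epoch:
            raise ValueError("best_epoch exceeds stopped_epoch")
        if not all(np.isfinite(self.train_losses)) or not all(np.isfinite(self.val_losses)):
            raise ValueError("losses must be finite")

    def to_json_dict(self) -> dict:
        return {
            "train_losses": self.train_losses,
            "val_losses": self.val_losses,
            "stopped_epoch": self.stopped_epoch,
            "best_epoch": self.best_epoch,
            "init_val_loss": self.init_val_loss,
            "config": vars(self.config) | {},
        }


class DDAE:
    """Model handle wrapping the Sequential network and its normalization."""

    def __init__(self, config: DenoiserConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list = []
        c_in = 1
        for s in range(config.depth):
            c_out = config.m * 2**s
            layers += [Conv2D(c_in, c_out, config.k, rng), ReLU(), AvgPool2()]
            c_in = c_out
        for s in reversed(range(config.depth)):
            c_out = config.m * 2**s
            layers += [Upsample2(), Conv2D(c_in, c_out, config.k, rng), ReLU()]
            c_in = c_out
        layers.append(Conv2D(c_in, 1, config.k, rng))
        self.net = Sequential(layers)
        # normalization statistics (identity until fit)
        self.norm_scale: float = 1.0
        self.norm_offset: float = 0.0

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def _check_shape(self, image: np.ndarray) -> None:
        factor = 2**self.config.depth
        h, w = image.shape[-2:]
        if h % factor or w % factor:
            raise ShapeError(
                f"spatial dims {h}x{w} must be divisible by {factor} "
                f"(depth={self.config.depth}); pad to "
                f"{-(-h // factor) * factor}x{-(-w // factor) * factor}"
            )

    def set_normalization(self, answers: Sequence[np.ndarray]) -> None:
        """Estimate normalization statistics from answer images."""
        stacked = np.concatenate([np.asarray(a, dtype=np.float64).ravel() for a in answers])
        if self.config.normalization == "unit_range":
            self.norm_offset = 0.0
            self.norm_scale = float(stacked.max()) or 1.0
        else:
            self.norm_offset = float(stacked.mean())
            self.norm_scale = float(stacked.std()) or 1.0

    def normalize(self, image: np.ndarray) -> np.ndarray:
        return (np.asarray(image, dtype=np.float32) - self.norm_offset) / self.norm_scale

    def denormalize(self, image: np.ndarray) -> np.ndarray:
        return image * self.norm_scale + self.norm_offset

    def forward_batch(self, batch01: np.ndarray) -> np.ndarray:
        """Forward pass on a normalized (N, H, W) batch."""
        self._check_shape(batch01)
        return self.net.forward(batch01[:, None].astype(np.float32))[:, 0]

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        np.savez(
            path,
            **arrays,
            norm=np.array([self.norm_scale, self.norm_offset]),
            config_json=np.array(json.dumps(vars(self.config))),
        )
        return path

    @classmethod
    def load(cls, path: Union[str, Path]) -> "DDAE":
        data = np.load(Path(path), allow_pickle=False)
        cfg = DenoiserConfig(**json.loads(str(data["config_json"])))
        model = cls(cfg)
        n = len(model.net.get_weights())
        model.net.set_weights([data[f"w{i}"] for i in range(n)])
        model.norm_scale, model.norm_offset = (float(x) for x in data["norm"])
        return model


def build_ddae(config: DenoiserConfig) -> DDAE:
    """Construct an untrained DDAE from a validated config."""
    return DDAE(config)


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2))


def train(
    model: DDAE,
    pairs: Sequence[Pair],
    config: Optional[DenoiserConfig] = None,
    val_pairs: Optional[Sequence[Pair]] = None,
) -> TrainingReport:
    """Fit the DDAE on (noisy frame, answer) pairs with early stopping.

    If ``val_pairs`` is not given, a seeded ~20% split (at least one pair)
    of ``pairs`` is held out for validation. Validation loss is evaluated
    after every epoch; training stops at the epoch budget or after
    ``patience`` consecutive epochs without improvement, and the
    best-validation weights are restored.
    """
    config = config or model.config
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no training pairs")
    shapes = {p[0].shape for p in pairs} | {p[1].shape for p in pairs}
    if len(shapes) != 1:
        raise ValueError(f"all pairs must share dimensions, got {shapes}")
    rng = np.random.default_rng(config.seed)
    if val_pairs is None:
        n_val = max(1, int(round(0.2 * len(pairs))))
        if n_val >= len(pairs):
            raise ValueError("need at least 2 pairs to split off validation")
        idx = rng.permutation(len(pairs))
        val_pairs = [pairs[i] for i in idx[:n_val]]
        pairs = [pairs[i] for i in idx[n_val:]]
    val_pairs = list(val_pairs)

    model.set_normalization([p[1] for p in pairs])
    x = np.stack([model.normalize(p[0]) for p in pairs])
    y = np.stack([model.normalize(p[1]) for p in pairs])
    xv = np.stack([model.normalize(p[0]) for p in val_pairs])
    yv = np.stack([model.normalize(p[1]) for p in val_pairs])
    model._check_shape(x)

    opt = Adam(model.net, lr=config.learning_rate)
    init_val_loss = _mse(model.forward_batch(xv), yv)
    best_val = np.inf
    best_epoch = 0
    best_weights = model.net.get_weights()
    train_losses: list[float] = []
    val_losses: list[float] = []
    stopped = 0
    since_best = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x))
        epoch_losses = []
        for start in range(0, len(x), config.batch_size):
            sel = order[start : start + config.batch_size]
            out = model.forward_batch(x[sel])
            diff = out - y[sel]
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"reduce learning_rate (currently {config.learning_rate})"
                )
            grad = (2.0 * diff / diff.size).astype(np.float32)
            model.net.backward(grad[:, None])
            opt.step()
            epoch_losses.append(loss)
        val_loss = _mse(model.forward_batch(xv), yv)
        if not np.isfinite(val_loss):
            raise RuntimeError("non-finite validation loss; reduce learning_rate")
        train_losses.append(float(np.mean(epoch_losses)))
        val_losses.append(val_loss)
        stopped = epoch
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_weights = model.net.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.net.set_weights(best_weights)
    return TrainingReport(
        train_losses=train_losses,
        val_losses=val_losses,
        stopped_epoch=stopped,
        best_epoch=max(best_epoch, 1),
        init_val_loss=init_val_loss,
        config=config,
    )


def denoise(model: DDAE, image: np.ndarray) -> np.ndarray:
    """Denoise one frame: normalize, forward, invert, clip at zero."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("denoise expects a single 2-D frame")
    out = model.forward_batch(model.normalize(image)[None])[0]
    return np.clip(model.denormalize(out.astype(np.float64)), 0.0, None)


def denoise_stack(model: DDAE, frames: np.ndarray) -> np.ndarray:
    """Frame-wise denoising of a 3-D stack (concatenated single-frame calls)."""
    return np.stack([denoise(model, f) for f in np.asarray(frames)])
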