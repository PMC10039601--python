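"""U-net segmentation of the sella turcica on preprocessed radiographs.

The network is the classic U-shaped fully convolutional encoder-decoder:
``depth`` resolution levels of two 3x3 conv + ReLU blocks, 2x2 max pooling
on the way down, 2x2 transposed convolutions on the way up, and skip
connections concatenating mirrored encoder features into the decoder.  A
1x1 head emits one logit per pixel; thresholding the sigmoid at 0.5 gives
the binary mask.

Training minimizes binary cross entropy on logits with RMSprop, reduces
the learning rate when the validation loss plateaus, and keeps the
parameters of the epoch with the best validation dice.  Overlap with a
reference mask is scored by the dice coefficient

    Dice = 2 |A ∩ B| / (|A| + |B|)

where A is the ground-truth foreground pixel set and B the predicted one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .types import as_mask

_DICE_EPS = 1e-6  # smoothing: dice(empty, empty) = 1 (perfect agreement on absence)


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyper-shape.

    ``depth`` down/up-sampling levels with ``base_channels * 2**level``
    feature channels; ``in_size`` must be divisible by ``2**depth``.
    The full-scale profile is (4, 64, 400); a reduced profile (3, 16, 128)
    is first-class for CPU-scale experiments.
    """

    depth: int = 4
    base_channels: int = 64
    in_size: int = 400

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.in_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"in_size {self.in_size} not divisible by 2^depth = {2 ** self.depth}"
            )


REDUCED_UNET = UNetConfig(depth=3, base_channels=16, in_size=128)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the full-scale protocol)."""

    learning_rate: float = 1e-5
    batch_size: int = 8
    epochs: int = 50
    seed: int = 0
    val_fraction: float = 0.1
    # ReduceLROnPlateau on validation loss (mode min).  Monitoring the
    # hard dice instead stalls training: dice sits at 0 while the
    # foreground probabilities ramp toward the 0.5 threshold, and the
    # schedule would decay the rate to nothing before they cross it.
    lr_factor: float = 0.5
    lr_patience: int = 3
    min_lr: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate > 0, batch_size >= 1, epochs >= 1 required")


@dataclass
class TrainHistory:
    """Per-epoch metrics; one record per completed epoch."""

    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    val_soft_dice: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epoch,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_dice": self.train_dice,
                "val_dice": self.val_dice,
                "val_soft_dice": self.val_soft_dice,
                "lr": self.lr,
            }
        )

    @property
    def best_val_dice(self) -> float:
        return max(self.val_dice)


class UNet:
    """Numpy U-net; see module docstring for the architecture."""

    def __init__(self, config: UNetConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        d, base = config.depth, config.base_channels
        ch = [base * 2 ** i for i in range(d + 1)]  # per-level channels

        self.enc: list[list[_nn.Layer]] = []
        c_prev = 1
        for i in range(d):
            self.enc.append(
                [
                    _nn.Conv3x3(c_prev, ch[i], rng), _nn.ReLU(),
                    _nn.Conv3x3(ch[i], ch[i], rng), _nn.ReLU(),
                ]
            )
            c_prev = ch[i]
        self.pools = [_nn.MaxPool2() for _ in range(d)]
        self.bottleneck = [
            _nn.Conv3x3(ch[d - 1], ch[d], rng), _nn.ReLU(),
            _nn.Conv3x3(ch[d], ch[d], rng), _nn.ReLU(),
        ]
        self.ups: list[_nn.UpConv2] = []
        self.dec: list[list[_nn.Layer]] = []
        for i in reversed(range(d)):
            self.ups.append(_nn.UpConv2(ch[i + 1], ch[i], rng))
            self.dec.append(
                [
                    _nn.Conv3x3(2 * ch[i], ch[i], rng), _nn.ReLU(),
                    _nn.Conv3x3(ch[i], ch[i], rng), _nn.ReLU(),
                ]
            )
        self.head = _nn.Conv1x1(ch[0], 1, rng)

    # -- plumbing ---------------------------------------------------------
    def layers(self) -> list[_nn.Layer]:
        out: list[_nn.Layer] = []
        for block in self.enc:
            out.extend(block)
        out.extend(self.bottleneck)
        for up, block in zip(self.ups, self.dec):
            out.append(up)
            out.extend(block)
        out.append(self.head)
        return out

    @staticmethod
    def _run(block: Sequence[_nn.Layer], x: np.ndarray) -> np.ndarray:
        for layer in block:
            x = layer.forward(x)
        return x

    @staticmethod
    def _run_back(block: Sequence[_nn.Layer], g: np.ndarray) -> np.ndarray:
        for layer in reversed(block):
            g = layer.backward(g)
        return g

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, H, W, 1) float32 in [0, 1] -> (N, H, W, 1) logits."""
        if x.shape[1] != self.config.in_size or x.shape[2] != self.config.in_size:
            raise ValueError(
                f"input size {x.shape[1:3]} != model in_size {self.config.in_size}"
            )
        skips = []
        h = x.astype(_nn.F32)
        for block, pool in zip(self.enc, self.pools):
            h = self._run(block, h)
            skips.append(h)
            h = pool.forward(h)
        h = self._run(self.bottleneck, h)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(skip.shape[-1])
            h = self._run(block, np.concatenate([skip, h], axis=-1))
        return self.head.forward(h)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.head.backward(glogits)
        gskips = []  # collected shallowest level first
        for up, block, csk in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            g = self._run_back(block, g)
            gskips.append(g[..., :csk])
            g = up.backward(g[..., csk:])
        g = self._run_back(self.bottleneck, g)
        for block, pool, gskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(gskips)
        ):
            g = pool.backward(g)
            g = g + gskip
            g = self._run_back(block, g)

    # -- persistence ------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers():
            out.extend(layer.params)
        return out

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self.layers():
            for p in layer.params:
                p[...] = next(it)

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez_compressed(
            path,
            depth=self.config.depth,
            base_channels=self.config.base_channels,
            in_size=self.config.in_size,
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with np.load(path) as data:
            cfg = UNetConfig(
                depth=int(data["depth"]),
                base_channels=int(data["base_channels"]),
                in_size=int(data["in_size"]),
            )
            model = cls(cfg, seed=0)
            n = len(model.state_arrays())
            model.load_state_arrays([data[f"p{i}"] for i in range(n)])
        return model


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct a U-net with deterministic parameter initialization."""
    return UNet(config, seed=seed)


# ---------------------------------------------------------------- scoring

def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two equal-shape masks.

    Smoothed so that two empty masks score 1.0 (agreement on absence).
    """
    a = as_mask(a)
    b = as_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    return float((2.0 * inter + _DICE_EPS) / (a.sum() + b.sum() + _DICE_EPS))


# --------------------------------------------------------------- training

def _stack_images(images: Sequence[np.ndarray]) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    return (arr / 255.0).astype(_nn.F32)[..., None]


def _stack_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([as_mask(m) for m in masks]).astype(_nn.F32)[..., None]


def _batch_dice(prob: np.ndarray, target: np.ndarray, threshold: float = 0.5,
                soft: bool = False) -> float:
    """Mean per-image dice of thresholded (or raw, if soft) probabilities."""
    pred = prob if soft else (prob >= threshold).astype(np.float64)
    inter = (pred * target).sum(axis=(1, 2, 3))
    sums = pred.sum(axis=(1, 2, 3)) + target.sum(axis=(1, 2, 3))
    return float(((2.0 * inter + _DICE_EPS) / (sums + _DICE_EPS)).mean())


def _eval_model(model: UNet, x: np.ndarray, y: np.ndarray,
                batch_size: int) -> tuple[float, float, float]:
    """(loss, hard dice, soft dice) over a dataset, in minibatches."""
    losses, dices, softs, weights = [], [], [], []
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward(xb)
        loss, _ = _nn.bce_with_logits(logits, yb)
        prob = _nn.sigmoid(logits)
        losses.append(loss)
        dices.append(_batch_dice(prob, yb))
        softs.append(_batch_dice(prob, yb, soft=True))
        weights.append(len(xb))
    w = np.asarray(weights, dtype=float)
    return (
        float(np.average(losses, weights=w)),
        float(np.average(dices, weights=w)),
        float(np.average(softs, weights=w)),
    )


def train(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    ucfg: UNetConfig,
    tcfg: TrainConfig,
    val_images: Sequence[np.ndarray] | None = None,
    val_masks: Sequence[np.ndarray] | None = None,
) -> tuple[UNet, TrainHistory]:
    """Train a U-net on (image, mask) pairs; return best model and history.

    If no validation pairs are supplied, a seeded random ``val_fraction``
    split (default 10%) is carved out of the training pairs.  The returned
    model carries the parameters of the epoch with the highest validation
    dice coefficient.
    """
    if len(images) != len(masks):
        raise ValueError(f"{len(images)} images vs {len(masks)} masks")
    for im, mk in zip(images, masks):
        if np.asarray(im).shape != np.asarray(mk).shape:
            raise ValueError("image/mask shape mismatch in training pairs")
        if np.asarray(im).shape != (ucfg.in_size, ucfg.in_size):
            raise ValueError(
                f"training raster shape {np.asarray(im).shape} != "
                f"({ucfg.in_size}, {ucfg.in_size})"
            )

    rng = np.random.default_rng(tcfg.seed)
    x = _stack_images(images)
    y = _stack_masks(masks)
    if val_images is None:
        if len(x) < 2:
            raise ValueError("need >= 2 pairs to carve out a validation split")
        n_val = max(1, int(round(tcfg.val_fraction * len(x))))
        perm = rng.permutation(len(x))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        xv, yv = x[val_idx], y[val_idx]
        x, y = x[train_idx], y[train_idx]
    else:
        if len(val_images) != len(val_masks or []):
            raise ValueError("validation images and masks must pair up")
        xv = _stack_images(val_images)
        yv = _stack_masks(val_masks)

    model = build_unet(ucfg, seed=tcfg.seed)
    opt = _nn.RMSprop(model.layers(), lr=tcfg.learning_rate)
    history = TrainHistory()
    best_dice = -1.0
    best_loss = np.inf
    best_state: list[np.ndarray] = []
    plateau = 0

    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(len(x))
        ep_losses, ep_dices, ep_w = [], [], []
        for i in range(0, len(order), tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            xb, yb = x[idx], y[idx]
            opt.zero_grad()
            logits = model.forward(xb)
            loss, grad = _nn.bce_with_logits(logits, yb)
            model.backward(grad)
            opt.step()
            ep_losses.append(loss)
            ep_dices.append(_batch_dice(_nn.sigmoid(logits), yb))
            ep_w.append(len(idx))
        w = np.asarray(ep_w, dtype=float)
        val_loss, val_dice, val_soft = _eval_model(model, xv, yv, tcfg.batch_size)
        history.epoch.append(epoch)
        history.train_loss.append(float(np.average(ep_losses, weights=w)))
        history.train_dice.append(float(np.average(ep_dices, weights=w)))
        history.val_loss.append(val_loss)
        history.val_dice.append(val_dice)
        history.val_soft_dice.append(val_soft)
        history.lr.append(opt.lr)

        if val_dice > best_dice:
            best_dice = val_dice
            best_state = [p.copy() for p in model.state_arrays()]
        if val_loss < best_loss:
            best_loss = val_loss
            plateau = 0
        else:
            plateau += 1
            if plateau > tcfg.lr_patience:
                opt.lr = max(opt.lr * tcfg.lr_factor, tcfg.min_lr)
                plateau = 0

    model.load_state_arrays(best_state)
    return model, history


def predict_mask(model: UNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Segment one preprocessed image; returns a boolean mask.

    Foreground is where ``sigmoid(logit) >= threshold``; with the default
    0.5 this is simply ``logit >= 0``.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.shape != (model.config.in_size, model.config.in_size):
        raise ValueError(
            f"image shape {arr.shape} != model in_size {model.config.in_size}"
        )
    logits = model.forward((arr / 255.0).astype(_nn.F32)[None, ..., None])
    # float64 so sigmoid < 1 strictly for finite logits (threshold 1.0
    # must yield an empty mask)
    prob = _nn.sigmoid(logits[0, :, :, 0].astype(np.float64))
    return prob >= threshold
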