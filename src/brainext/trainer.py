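"""Supervised training and the two transfer baselines.

Training follows the convention used throughout: Adam, Dice loss, batch
size 16, 50 epochs, learning rate 1e-4 in the source domain and 1e-5 in
target domains.  Augmentation draws a random rotation within ±10°, a
random scale within 90–110% and a random translation up to ±10 pixels
per axis, applied identically to a slice and its mask (nearest-neighbour
for the mask, which therefore stays binary).

Splitting for cross-validation is always by volume, never by slice, so
no subject leaks between folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DimensionError
from .nlunet import NLUNet
from .nn import Adam
from .phantoms import PhantomSample
from .volio import (
    MaskVolume,
    VolumeGrid,
    normalize_intensity,
    to_slices,
)

__all__ = [
    "TrainConfig",
    "AugmentSpec",
    "DataSplit",
    "augment_pair",
    "dice_loss",
    "dice_loss_grad",
    "train_supervised",
    "fine_tune",
    "crossval_split",
    "prepare_training_arrays",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    lr_source: float = 1e-4
    lr_target: float = 1e-5
    optimizer: str = "adam"
    loss_smooth: float = 1.0
    l1_weight: float = 0.0  # 0 = pure Dice pretraining; >0 adds the fidelity term
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.lr_source <= 0 or self.lr_target <= 0:
            raise ConfigurationError("learning rates must be positive")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is supported")

    def lr(self, role: str) -> float:
        if role == "source":
            return self.lr_source
        if role == "target":
            return self.lr_target
        raise ConfigurationError(f"unknown domain role {role!r}")


@dataclass(frozen=True)
class AugmentSpec:
    rot_deg: float = 10.0
    scale_range: tuple = (0.9, 1.1)
    translate_px: float = 10.0

    def __post_init__(self):
        if self.rot_deg < 0 or self.translate_px < 0:
            raise ConfigurationError("augmentation bounds must be non-negative")
        lo, hi = self.scale_range
        if not (lo <= 1.0 <= hi):
            raise ConfigurationError("scale_range must contain 1")

    @property
    def is_identity(self) -> bool:
        return (self.rot_deg == 0 and self.translate_px == 0
                and self.scale_range == (1.0, 1.0))


@dataclass
class DataSplit:
    """Volume-level k-fold assignment; folds are disjoint and exhaustive."""

    folds: List[List[int]]
    k: int

    def train_test(self, fold: int) -> Tuple[List[int], List[int]]:
        test = list(self.folds[fold])
        train = [i for f, ids in enumerate(self.folds) if f != fold for i in ids]
        return train, test


def augment_pair(
    slice_2d: np.ndarray,
    mask_2d: np.ndarray,
    spec: AugmentSpec,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Apply one random rigid+scale transform to a slice/mask pair."""
    if slice_2d.shape != mask_2d.shape:
        raise DimensionError("slice and mask shapes differ")
    if spec.is_identity:
        return slice_2d, mask_2d
    angle = np.deg2rad(rng.uniform(-spec.rot_deg, spec.rot_deg))
    scale = rng.uniform(*spec.scale_range)
    shift = rng.uniform(-spec.translate_px, spec.translate_px, size=2)

    c, s = np.cos(angle), np.sin(angle)
    lin = np.array([[c, -s], [s, c]]) / scale  # inverse mapping matrix
    center = (np.asarray(slice_2d.shape) - 1) / 2.0
    offset = center - lin @ (center + shift)
    img = ndimage.affine_transform(slice_2d, lin, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    msk = ndimage.affine_transform(mask_2d.astype(np.float32), lin, offset=offset,
                                   order=0, mode="constant", cval=0.0)
    return img, (msk > 0.5).astype(mask_2d.dtype)


def dice_loss(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss 1 − (2Σpg + s)/(Σp + Σg + s) over the whole batch."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise DimensionError(f"shape mismatch {pred.shape} vs {target.shape}")
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def dice_loss_grad(pred: np.ndarray, target: np.ndarray,
                   smooth: float = 1.0) -> np.ndarray:
    """Analytic gradient of :func:`dice_loss` w.r.t. ``pred``."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    inter = (pred * target).sum()
    denom = pred.sum() + target.sum()
    num = 2.0 * inter + smooth
    den = denom + smooth
    return -(2.0 * target * den - num) / (den * den)


def prepare_training_arrays(
    samples: Sequence,
    size: int,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Normalize each volume and cut volume+mask into size×size slices.

    Accepts ``PhantomSample`` objects or ``(VolumeGrid, MaskVolume)``
    pairs; returns per-volume ``(slices, mask_slices)`` float arrays.
    """
    out = []
    for item in samples:
        if isinstance(item, PhantomSample):
            vol, mask = item.volume, item.mask
        else:
            vol, mask = item
        norm, record = normalize_intensity(vol)
        stack = to_slices(norm, size=size, resize_mode="resize", record=record)
        mask_grid = VolumeGrid(mask.data.astype(np.float64), mask.spacing_mm)
        mask_stack = to_slices(mask_grid, size=size, resize_mode="resize")
        out.append((stack.slices.astype(np.float32),
                    (mask_stack.slices > 0.5).astype(np.float32)))
    return out


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train_supervised(
    model: NLUNet,
    samples: Sequence,
    tcfg: TrainConfig,
    aug: Optional[AugmentSpec] = None,
    role: str = "source",
    epochs: Optional[int] = None,
) -> Tuple[NLUNet, List[float]]:
    """Train in place with Adam on the Dice loss (plus an optional L1
    fidelity term weighted by ``tcfg.l1_weight``); returns the model and
    the per-epoch mean-loss trace."""
    samples = list(samples)
    if not samples:
        raise ConfigurationError("empty training set")
    aug = aug if aug is not None else AugmentSpec()
    n_epochs = tcfg.epochs if epochs is None else epochs
    if n_epochs == 0:
        return model, []

    data = prepare_training_arrays(samples, model.cfg.in_plane_size)
    X = np.concatenate([d[0] for d in data], axis=0)
    Y = np.concatenate([d[1] for d in data], axis=0)

    recalibrate = not any(bn.stats_frozen for bn in model.bn_layers())
    opt = Adam(model.parameters(), lr=tcfg.lr(role))
    rng = np.random.default_rng(tcfg.seed)
    trace: List[float] = []
    for _ in range(n_epochs):
        losses = []
        for idx in _epoch_batches(X.shape[0], tcfg.batch_size, rng):
            xb = np.empty((len(idx),) + X.shape[1:], dtype=np.float32)
            yb = np.empty_like(xb)
            for j, i in enumerate(idx):
                xb[j], yb[j] = augment_pair(X[i], Y[i], aug, rng)
            pred = model.forward(xb[:, None], mode="train", rng=rng)[:, 0]
            loss = dice_loss(pred, yb, tcfg.loss_smooth)
            grad = dice_loss_grad(pred, yb, tcfg.loss_smooth)
            if tcfg.l1_weight > 0:
                loss += tcfg.l1_weight * float(np.abs(pred - yb).mean())
                grad = grad + tcfg.l1_weight * np.sign(pred - yb) / pred.size
            opt.zero_grad()
            model.backward(grad[:, None].astype(model.cfg.np_dtype))
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    if recalibrate:
        # replace the momentum-EMA running statistics (estimated on
        # augmented batches during training) with pooled statistics over
        # the unaugmented training slices — the same estimator the
        # adaptive-normalization transfer uses, so that adaptation on the
        # training domain itself is a fixed point
        from .adabn import adapt as _recalibrate
        _recalibrate(model, X, batch_size=tcfg.batch_size)
    return model, trace


def fine_tune(
    pretrained: NLUNet,
    samples: Sequence,
    tcfg: TrainConfig,
    aug: Optional[AugmentSpec] = None,
    epochs: Optional[int] = None,
) -> Tuple[NLUNet, List[float]]:
    """Baseline transfer: continue training all weights at the target
    learning rate. With zero epochs or zero labels, parameters are
    untouched (evaluation-only path)."""
    model = pretrained.copy()
    n_epochs = tcfg.epochs if epochs is None else epochs
    if n_epochs == 0 or len(list(samples)) == 0:
        return model, []
    # plain baseline semantics: every weight trains and normalization
    # statistics update batch by batch, exactly as ordinary training does
    return train_supervised(model, samples, tcfg, aug, role="target",
                            epochs=n_epochs)


def crossval_split(volume_ids: Sequence, k: int = 5, seed: int = 0) -> DataSplit:
    """Deterministic volume-level k-fold split (e.g. 243 volumes, k=5 →
    first fold trains on 194 and tests on 49)."""
    ids = list(range(len(volume_ids)))
    if len(ids) < k:
        raise ConfigurationError(f"need at least k={k} volumes, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds: List[List[int]] = [[] for _ in range(k)]
    sizes = np.full(k, len(ids) // k)
    sizes[: len(ids) % k] += 1
    pos = 0
    for f in range(k):
        folds[f] = sorted(int(ids[i]) for i in order[pos:pos + sizes[f]])
        pos += sizes[f]
    return DataSplit(folds=folds, k=k)
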