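"""Monte Carlo quality assessment (MCQA) and semi-supervised transfer.

Uncertainty is estimated by keeping dropout active at inference and
collecting T stochastic predictions p_t per pixel.  The decomposition

    aleatoric  = (1/T) Σ p_t (1 − p_t)
    epistemic  = (1/T) Σ (p_t − p̄)²          with  p̄ = (1/T) Σ p_t
    total      = aleatoric + epistemic

separates irreducible data noise from model uncertainty; for binary
probabilities both components are bounded by 1/4.

Volume-level quality screening reduces the total-uncertainty map to a
scalar (mean over the plausible-brain region, p̄ > 0.05), min–max
normalized across the cohort being screened.  The lowest-uncertainty
prediction per minibatch is admitted to the pseudo-label pool as a
frozen snapshot of the previous-epoch model, and the hybrid loss

    (1/N) Σ_i [ ‖f(x_i;θ_t) − y_i‖₁ + λ_Dice·L_dice(f(x_i;θ_t), y_i) ]
      + α(t) · (1/M) Σ_j L_dice(f(x_j;θ_t), label_j)

with the trust schedule α(t) = 0 for t < T_sl and λ_sl afterwards,
mixes the few true labels with the screened pseudo-labels.  Default
constants: T_sl = 20, λ_Dice = 1, λ_sl = 0.5, T_epoch = 50, and T = 10
Monte Carlo samples (7 when matching a panel of seven human raters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, StateError
from .nlunet import NLUNet, forward_mc
from .nn import Adam
from .trainer import (
    AugmentSpec,
    TrainConfig,
    augment_pair,
    dice_loss,
    dice_loss_grad,
    prepare_training_arrays,
)
from . import adabn as _adabn
from .volio import MaskVolume, largest_component, normalize_intensity, to_slices

__all__ = [
    "MCSampleSet",
    "UncertaintyMap",
    "SemiSupConfig",
    "PseudoLabelPool",
    "decompose_uncertainty",
    "volume_uncertainty",
    "normalize_scores",
    "consensus_prediction",
    "alpha_schedule",
    "select_pseudolabels",
    "hybrid_loss",
    "semisup_train",
]


@dataclass
class MCSampleSet:
    """T Monte Carlo probability maps for one volume (or slice stack)."""

    samples: List[np.ndarray]
    master_seed: int = 0

    def __post_init__(self):
        if len(self.samples) < 2:
            raise ConfigurationError("Monte Carlo sampling requires T >= 2")
        shape = np.asarray(self.samples[0]).shape
        for s in self.samples:
            if np.asarray(s).shape != shape:
                raise ConfigurationError("all MC samples must share one shape")

    @property
    def T(self) -> int:
        return len(self.samples)

    def stacked(self) -> np.ndarray:
        return np.stack([np.asarray(s, dtype=np.float64) for s in self.samples])


@dataclass
class UncertaintyMap:
    aleatoric: np.ndarray
    epistemic: np.ndarray
    total: np.ndarray
    mean_prob: np.ndarray
    volume_score: Optional[float] = None


def decompose_uncertainty(mc: MCSampleSet) -> UncertaintyMap:
    """Pixelwise aleatoric/epistemic decomposition of T MC predictions."""
    p = mc.stacked()
    mean = p.mean(axis=0)
    aleatoric = (p * (1.0 - p)).mean(axis=0)
    epistemic = ((p - mean) ** 2).mean(axis=0)
    return UncertaintyMap(
        aleatoric=aleatoric,
        epistemic=epistemic,
        total=aleatoric + epistemic,
        mean_prob=mean,
    )


def volume_uncertainty(
    u: UncertaintyMap, region_threshold: float = 0.05
) -> float:
    """Scalar (un-normalized) uncertainty: mean total uncertainty over the
    plausible-brain region ``mean_prob > region_threshold``; falls back to
    the whole grid when that region is empty."""
    region = u.mean_prob > region_threshold
    if not np.any(region):
        warnings.warn("plausible-brain region empty; using whole-grid mean")
        return float(u.total.mean())
    return float(u.total[region].mean())


def normalize_scores(raw_scores: Sequence[float]) -> np.ndarray:
    """Min-max normalize cohort uncertainty scalars to [0, 1]."""
    arr = np.asarray(list(raw_scores), dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi - lo <= 0:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def consensus_prediction(
    mc: MCSampleSet,
    spacing_mm: Sequence[float] = (1.0, 1.0, 1.0),
    threshold: float = 0.5,
) -> MaskVolume:
    """Binarize the MC mean probability and keep the largest component."""
    mean = mc.stacked().mean(axis=0)
    binary = mean > threshold
    if binary.ndim == 2:
        binary = binary[..., None]
    mask = MaskVolume(binary, spacing_mm)
    if not binary.any():
        return MaskVolume(binary, spacing_mm, warning="empty consensus mask")
    return largest_component(mask)


@dataclass(frozen=True)
class SemiSupConfig:
    T_sl: int = 20
    lambda_sl: float = 0.5
    lambda_dice: float = 1.0
    T_epoch: int = 50
    selection_rule: str = "min_per_batch"  # or "quantile"
    quantile: float = 0.25
    mc_T: int = 10
    region_threshold: float = 0.05

    def __post_init__(self):
        if not 0 <= self.T_sl <= self.T_epoch:
            raise ConfigurationError("require 0 <= T_sl <= T_epoch")
        if self.lambda_sl < 0 or self.lambda_dice < 0:
            raise ConfigurationError("loss weights must be non-negative")
        if self.selection_rule not in ("min_per_batch", "quantile"):
            raise ConfigurationError(f"unknown selection_rule {self.selection_rule!r}")
        if self.mc_T < 2:
            raise ConfigurationError("mc_T must be >= 2")


@dataclass
class PoolEntry:
    volume_id: int
    label: np.ndarray  # frozen soft prediction from the previous epoch
    volume_score: float
    selected: bool = True


@dataclass
class PseudoLabelPool:
    entries: List[PoolEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def clear(self) -> None:
        self.entries = []

    @property
    def volume_ids(self) -> List[int]:
        return [e.volume_id for e in self.entries]


def alpha_schedule(t: int, cfg: SemiSupConfig) -> float:
    """Trust schedule: 0 before epoch T_sl, λ_sl from T_sl onwards."""
    if not 0 <= t <= cfg.T_epoch:
        raise IndexError(f"epoch {t} outside [0, {cfg.T_epoch}]")
    return 0.0 if t < cfg.T_sl else cfg.lambda_sl


def select_pseudolabels(
    batch: Sequence[Tuple[int, np.ndarray, float]],
    cfg: SemiSupConfig,
) -> List[PoolEntry]:
    """Screen one minibatch of (volume_id, prediction, volume_score).

    ``min_per_batch`` admits exactly the argmin-uncertainty member (ties
    broken by lowest volume id); ``quantile`` admits the lowest-q
    fraction (at least one).
    """
    batch = list(batch)
    if not batch:
        raise ConfigurationError("empty screening batch")
    scores = np.asarray([s for _, _, s in batch], dtype=np.float64)
    ids = np.asarray([i for i, _, _ in batch])
    if cfg.selection_rule == "min_per_batch":
        best = np.lexsort((ids, scores))[0]
        chosen = [int(best)]
    else:
        q = float(np.clip(cfg.quantile, 0.0, 1.0))
        n_keep = max(1, int(np.ceil(q * len(batch))))
        chosen = [int(i) for i in np.lexsort((ids, scores))[:n_keep]]
    return [
        PoolEntry(volume_id=int(ids[i]), label=np.asarray(batch[i][1]).copy(),
                  volume_score=float(scores[i]))
        for i in chosen
    ]


def hybrid_loss(
    labeled_pred: np.ndarray,
    labeled_target: np.ndarray,
    pseudo_pred: Optional[np.ndarray],
    pseudo_label: Optional[np.ndarray],
    t: int,
    cfg: SemiSupConfig,
    smooth: float = 1.0,
    return_grads: bool = False,
):
    """Evaluate the semi-supervised hybrid loss (see module docstring).

    ``pseudo_label`` is a frozen snapshot: no gradient flows through it.
    With ``return_grads`` the gradients w.r.t. both prediction arrays are
    returned for backpropagation.
    """
    pred = np.asarray(labeled_pred, dtype=np.float64)
    target = np.asarray(labeled_target, dtype=np.float64)
    l1 = float(np.abs(pred - target).mean())
    ld = dice_loss(pred, target, smooth)
    loss = l1 + cfg.lambda_dice * ld

    alpha = alpha_schedule(t, cfg)
    grad_pseudo = None
    has_pseudo = pseudo_pred is not None and np.size(pseudo_pred) > 0
    if has_pseudo and pseudo_label is None:
        raise StateError("pseudo predictions supplied without frozen snapshots")
    if has_pseudo and alpha > 0:
        pp = np.asarray(pseudo_pred, dtype=np.float64)
        pl = (np.asarray(pseudo_label, dtype=np.float64) > 0.5).astype(np.float64)
        loss += alpha * dice_loss(pp, pl, smooth)
        if return_grads:
            grad_pseudo = alpha * dice_loss_grad(pp, pl, smooth)
    if not return_grads:
        return loss
    grad_labeled = (np.sign(pred - target) / pred.size
                    + cfg.lambda_dice * dice_loss_grad(pred, target, smooth))
    return loss, grad_labeled, grad_pseudo


def _volume_mc_screen(
    model: NLUNet,
    unlabeled: List[np.ndarray],
    cfg: SemiSupConfig,
    seed: int,
    batch_volumes: int,
) -> Tuple[PseudoLabelPool, List[float]]:
    """MC-sample every unlabeled volume with the (frozen) model, score it,
    and admit the per-minibatch minimum-uncertainty predictions.

    The admitted pseudo-label is the snapshot's deterministic prediction;
    the Monte Carlo samples serve only to rank volumes by uncertainty."""
    preds, raw = [], []
    for v, slices in enumerate(unlabeled):
        samples = forward_mc(model, slices, T=cfg.mc_T, seed=seed + 7919 * v)
        mc = MCSampleSet(samples=samples, master_seed=seed + 7919 * v)
        u = decompose_uncertainty(mc)
        det = np.concatenate([
            model.forward(slices[i:i + 16][:, None], mode="eval")[:, 0]
            for i in range(0, slices.shape[0], 16)
        ])
        preds.append(det)
        raw.append(volume_uncertainty(u, cfg.region_threshold))
    norm = normalize_scores(raw)
    pool = PseudoLabelPool()
    for s in range(0, len(unlabeled), batch_volumes):
        batch = [(i, preds[i], float(norm[i]))
                 for i in range(s, min(s + batch_volumes, len(unlabeled)))]
        pool.entries.extend(select_pseudolabels(batch, cfg))
    return pool, list(map(float, norm))


def semisup_train(
    pretrained: NLUNet,
    labeled_samples: Sequence,
    unlabeled_samples: Sequence,
    cfg: SemiSupConfig,
    tcfg: TrainConfig,
    aug: Optional[AugmentSpec] = None,
    adapt_first: bool = True,
    screen_batch_volumes: int = 8,
) -> Tuple[NLUNet, Dict]:
    """Semi-supervised transfer with uncertainty-screened pseudo-labels.

    Per epoch t: train on the labeled target volumes with the supervised
    part of the hybrid loss; from epoch T_sl, additionally MC-sample the
    unlabeled volumes with the previous-epoch snapshot, screen by volume
    uncertainty, and add the admitted frozen predictions as pseudo-label
    Dice terms.  Normalization statistics are adapted once before epoch 0.
    With no unlabeled data this degrades to fine-tuning with the
    supervised composite loss.
    """
    labeled_samples = list(labeled_samples)
    unlabeled_samples = list(unlabeled_samples)
    if not labeled_samples:
        raise ConfigurationError("semi-supervised training requires >= 1 label")
    aug = aug if aug is not None else AugmentSpec()
    model = pretrained.copy()
    size = model.cfg.in_plane_size

    labeled = prepare_training_arrays(labeled_samples, size)
    X = np.concatenate([d[0] for d in labeled], axis=0)
    Y = np.concatenate([d[1] for d in labeled], axis=0)
    unlabeled = []
    for u in unlabeled_samples:
        vol = u.volume if hasattr(u, "volume") else (u[0] if isinstance(u, tuple) else u)
        norm, record = normalize_intensity(vol)
        stack = to_slices(norm, size=size, record=record)
        unlabeled.append(stack.slices.astype(np.float32))

    history: Dict = {"loss": [], "pool_size": [], "pool_ids": [],
                     "uncertainty": [], "adapted": False}
    if adapt_first and unlabeled:
        stack = np.concatenate(unlabeled, axis=0)
        _adabn.adapt(model, stack)
        history["adapted"] = True

    opt = Adam(model.parameters(), lr=tcfg.lr("target"))
    rng = np.random.default_rng(tcfg.seed)
    # statistics are owned by the adaptation step above; training on a few
    # target volumes must not churn them
    model.freeze_bn_stats(True)
    snapshot = model.copy()  # θ_{t−1}

    for t in range(cfg.T_epoch):
        pool = PseudoLabelPool()
        if unlabeled and alpha_schedule(t, cfg) > 0:
            pool, scores = _volume_mc_screen(
                snapshot, unlabeled, cfg, seed=tcfg.seed + 104729 * (t + 1),
                batch_volumes=screen_batch_volumes)
            history["uncertainty"].append(scores)
        losses = []
        order = rng.permutation(X.shape[0])
        for i0 in range(0, X.shape[0], tcfg.batch_size):
            idx = order[i0:i0 + tcfg.batch_size]
            xb = np.empty((len(idx), size, size), dtype=np.float32)
            yb = np.empty_like(xb)
            for j, i in enumerate(idx):
                xb[j], yb[j] = augment_pair(X[i], Y[i], aug, rng)
            pred = model.forward(xb[:, None], mode="train", rng=rng)[:, 0]

            pseudo_pred = pseudo_label = None
            if len(pool) > 0:
                entry = pool.entries[int(rng.integers(len(pool)))]
                slices_u = unlabeled[entry.volume_id]
                # a random slice sub-batch of the pseudo-labeled volume
                sub = rng.choice(slices_u.shape[0],
                                 size=min(tcfg.batch_size, slices_u.shape[0]),
                                 replace=False)
                pseudo_pred = model.forward(slices_u[sub][:, None], mode="train",
                                            rng=rng)[:, 0]
                pseudo_label = entry.label[sub]
                # keep caches of the labeled pass: recompute below
            if pseudo_pred is not None:
                loss, g_lab, g_pse = hybrid_loss(
                    pred, yb, pseudo_pred, pseudo_label, t, cfg,
                    smooth=tcfg.loss_smooth, return_grads=True)
                # pseudo pass was the last forward; backprop it first
                opt.zero_grad()
                model.backward(g_pse[:, None].astype(model.cfg.np_dtype))
                pseudo_grads = [p.grad.copy() for p in model.parameters()]
                pred = model.forward(xb[:, None], mode="train", rng=rng)[:, 0]
                loss, g_lab, _ = hybrid_loss(
                    pred, yb, None, None, t, cfg,
                    smooth=tcfg.loss_smooth, return_grads=True)
                model.backward(g_lab[:, None].astype(model.cfg.np_dtype))
                for p, g in zip(model.parameters(), pseudo_grads):
                    p.grad = p.grad + g
                loss += alpha_schedule(t, cfg) * dice_loss(
                    pseudo_pred, (np.asarray(pseudo_label) > 0.5).astype(float),
                    tcfg.loss_smooth)
            else:
                loss, g_lab, _ = hybrid_loss(
                    pred, yb, None, None, t, cfg,
                    smooth=tcfg.loss_smooth, return_grads=True)
                opt.zero_grad()
                model.backward(g_lab[:, None].astype(model.cfg.np_dtype))
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        history["pool_size"].append(len(pool))
        history["pool_ids"].append(pool.volume_ids)
        snapshot = model.copy()
    model.freeze_bn_stats(False)
    return model, history
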