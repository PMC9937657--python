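"""Adaptive batch normalization (AdaBN) domain transfer.

Zero-label adaptation: all learned weights are frozen and unlabeled
target-domain slices are forward-propagated so the normalization layers
can re-estimate their running mean/variance under the target intensity
distribution.  Two estimator policies:

* ``recompute`` (default) — pool the per-batch statistics over the whole
  adaptation set and overwrite the running statistics (one pass over the
  target set);
* ``ema`` — exponential moving average with the layer momentum, which
  converges geometrically under repeated passes.

Dropout is inactive during adaptation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .nlunet import NLUNet

__all__ = ["AdaBNReport", "adapt", "weight_checksum"]


@dataclass
class AdaBNReport:
    """Quantifies what adaptation changed: per-layer L2 norms of the
    running-statistic shifts and a checksum over all non-normalization
    weights, which must be identical before and after."""

    mean_deltas: dict
    var_deltas: dict
    n_batches: int
    checksum_before: str
    checksum_after: str

    @property
    def frozen_weights_intact(self) -> bool:
        return self.checksum_before == self.checksum_after

    @property
    def max_delta(self) -> float:
        deltas = list(self.mean_deltas.values()) + list(self.var_deltas.values())
        return max(deltas) if deltas else 0.0


def weight_checksum(model: NLUNet) -> str:
    """SHA-256 over every trainable parameter (BN scale/shift included:
    AdaBN must not touch them either)."""
    h = hashlib.sha256()
    for p in sorted(model.parameters(), key=lambda q: q.name):
        h.update(p.name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def adapt(
    model: NLUNet,
    target_slices: np.ndarray,
    batch_size: int = 16,
    n_batches: Optional[int] = None,
    policy: str = "recompute",
) -> AdaBNReport:
    """Refresh normalization statistics on unlabeled target slices, in place.

    ``target_slices`` is a (n, size, size) stack of normalized slices; no
    labels are consumed. ``n_batches`` limits the number of adaptation
    batches (default: one pass over the whole set).
    """
    if policy not in ("recompute", "ema"):
        raise ConfigurationError(f"unknown policy {policy!r}")
    slices = np.asarray(target_slices)
    if slices.ndim != 3 or slices.shape[0] == 0:
        raise ConfigurationError("adaptation requires a non-empty slice stack")
    starts = list(range(0, slices.shape[0], batch_size))
    if n_batches is not None:
        if n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")
        starts = starts[:n_batches]

    bns = model.bn_layers()
    before_mean = {bn.name: bn.running_mean.copy() for bn in bns}
    before_var = {bn.name: bn.running_var.copy() for bn in bns}
    checksum_before = weight_checksum(model)

    for bn in bns:
        bn.adapt_stats = []
    for s in starts:
        model.forward(slices[s:s + batch_size][:, None], mode="adapt")

    for bn in bns:
        stats = bn.adapt_stats
        counts = np.array([c for _, _, c in stats], dtype=np.float64)
        w = counts / counts.sum()
        mus = np.stack([m for m, _, _ in stats])
        vars_ = np.stack([v for _, v, _ in stats])
        pooled_mean = (w[:, None] * mus).sum(axis=0)
        # law of total variance across batches
        pooled_var = (w[:, None] * (vars_ + (mus - pooled_mean) ** 2)).sum(axis=0)
        if policy == "recompute":
            bn.running_mean = pooled_mean.astype(bn.running_mean.dtype)
            bn.running_var = pooled_var.astype(bn.running_var.dtype)
        else:
            m = bn.momentum
            bn.running_mean = ((1 - m) * bn.running_mean + m * pooled_mean).astype(
                bn.running_mean.dtype)
            bn.running_var = ((1 - m) * bn.running_var + m * pooled_var).astype(
                bn.running_var.dtype)
        bn.adapt_stats = []

    report = AdaBNReport(
        mean_deltas={
            bn.name: float(np.linalg.norm(bn.running_mean - before_mean[bn.name]))
            for bn in bns
        },
        var_deltas={
            bn.name: float(np.linalg.norm(bn.running_var - before_var[bn.name]))
            for bn in bns
        },
        n_batches=len(starts),
        checksum_before=checksum_before,
        checksum_after=weight_checksum(model),
    )
    return report
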