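"""End-to-end single-volume inference.

preprocess (timepoint, bias, percentile normalization) → slice →
forward (deterministic or Monte Carlo) → consensus/threshold →
reconstruct the 3D mask → largest connected component, with optional
uncertainty and attention-saliency volumes on the original grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .mcqa import MCSampleSet, decompose_uncertainty, volume_uncertainty
from .nlunet import NLUNet, forward_mc, get_attention_map
from .volio import (
    MaskVolume,
    VolumeGrid,
    correct_bias,
    from_slices,
    largest_component,
    normalize_intensity,
    select_timepoint,
    to_slices,
)

__all__ = ["PredictResult", "predict_volume"]


@dataclass
class PredictResult:
    mask: MaskVolume
    probability: np.ndarray  # per-slice mean probability (n, size, size)
    uncertainty: Optional[np.ndarray] = None  # total uncertainty, original grid
    attention: Optional[np.ndarray] = None  # saliency, original grid
    volume_uncertainty_raw: Optional[float] = None


def _slices_to_grid(slices: np.ndarray, record, spacing) -> np.ndarray:
    """Map per-slice float maps back onto the original grid (values, not masks)."""
    from skimage.transform import resize as _resize

    orig = tuple(record.original_shape)
    axis = record.slice_axis % 3
    in_plane = tuple(s for i, s in enumerate(orig) if i != axis)
    restored = np.stack([
        _resize(s, in_plane, order=1, mode="edge", anti_aliasing=False,
                preserve_range=True)
        for s in slices
    ])
    return np.moveaxis(restored, 0, axis)


def predict_volume(
    model: NLUNet,
    volume: VolumeGrid,
    mc_T: int = 10,
    seed: int = 0,
    timepoint: Optional[int] = None,
    bias_mode: str = "off",
    slice_axis: int = -1,
    resize_mode: str = "resize",
    threshold: float = 0.5,
    with_uncertainty: bool = False,
    with_attention: bool = False,
    batch_size: int = 16,
) -> PredictResult:
    """Segment one volume; ``mc_T=1`` runs a single deterministic pass,
    ``mc_T>=2`` averages Monte Carlo dropout samples (required when
    ``with_uncertainty`` is set)."""
    if volume.is_4d:
        volume = select_timepoint(volume, timepoint)
    volume = correct_bias(volume, mode=bias_mode)
    norm, record = normalize_intensity(volume)
    stack = to_slices(norm, size=model.cfg.in_plane_size, slice_axis=slice_axis,
                      resize_mode=resize_mode, record=record)
    slices = stack.slices.astype(np.float32)

    unc_grid = None
    raw_unc = None
    if mc_T >= 2:
        samples = forward_mc(model, slices, T=mc_T, seed=seed,
                             batch_size=batch_size)
        mc = MCSampleSet(samples=samples, master_seed=seed)
        u = decompose_uncertainty(mc)
        prob = u.mean_prob
        if with_uncertainty:
            unc_grid = _slices_to_grid(u.total, record, volume.spacing_mm)
            raw_unc = volume_uncertainty(u)
    else:
        if with_uncertainty:
            raise ConfigurationError("uncertainty output requires mc_T >= 2")
        parts = [model.forward(slices[i:i + batch_size][:, None], mode="eval")[:, 0]
                 for i in range(0, slices.shape[0], batch_size)]
        prob = np.concatenate(parts, axis=0)

    mask = from_slices(prob, record, volume.spacing_mm, threshold=threshold)
    if mask.data.any():
        mask = largest_component(mask)

    att_grid = None
    if with_attention:
        sal = np.concatenate([
            get_attention_map(model, slices[i:i + batch_size])
            for i in range(0, slices.shape[0], batch_size)
        ])
        att_grid = _slices_to_grid(sal, record, volume.spacing_mm)

    return PredictResult(
        mask=mask,
        probability=prob,
        uncertainty=unc_grid,
        attention=att_grid,
        volume_uncertainty_raw=raw_unc,
    )
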