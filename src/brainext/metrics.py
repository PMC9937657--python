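"""Segmentation evaluation: Dice overlap, 95% Hausdorff distance in
physical units, brain volume, and predicted-vs-annotated volume agreement
(regression slope and Bland-Altman statistics).

Conventions
-----------
* Dice is computed on whole 3D volumes, 2|S∩G| / (|S|+|G|).
* HD95 is the maximum of the two directed 95th-percentile boundary-to-
  boundary Euclidean distances.  The boundary of a mask is the set of
  foreground voxels with at least one 6-connected background neighbour
  (volume faces count as background); distances are in mm via the voxel
  spacing and percentiles use linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .errors import ConfigurationError, DimensionError
from .volio import MaskVolume

__all__ = [
    "MetricReport",
    "AgreementReport",
    "dice_score",
    "hd95",
    "brain_volume",
    "volume_agreement",
    "evaluate_pair",
]

MaskLike = Union[MaskVolume, np.ndarray]


def _as_bool(m: MaskLike) -> np.ndarray:
    if isinstance(m, MaskVolume):
        return m.data
    return np.asarray(m).astype(bool)


@dataclass
class MetricReport:
    dice: float
    hd95_mm: float
    pred_volume_mm3: float
    true_volume_mm3: float
    volume_id: Optional[str] = None


@dataclass
class AgreementReport:
    """Volume agreement between predicted and annotated brain volumes.

    ``lrc`` is the least-squares slope of predicted on annotated volume;
    ``bias`` the mean difference (predicted minus annotated); ``loa`` the
    Bland-Altman 95% limits of agreement, bias ± 1.96·SD(differences).
    """

    lrc: float
    bias: float
    loa: tuple
    n: int


def dice_score(S: MaskLike, G: MaskLike) -> float:
    """Overlap 2|S∩G| / (|S|+|G|); two empty masks score 1 with a warning."""
    s, g = _as_bool(S), _as_bool(G)
    if s.shape != g.shape:
        raise DimensionError(f"mask shapes differ: {s.shape} vs {g.shape}")
    denom = int(s.sum()) + int(g.sum())
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1 by convention")
        return 1.0
    return 2.0 * int(np.logical_and(s, g).sum()) / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels 6-adjacent to background (or the volume edge)."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def _directed_d95(src_pts: np.ndarray, dst_pts: np.ndarray) -> float:
    d, _ = cKDTree(dst_pts).query(src_pts, k=1)
    return float(np.percentile(d, 95.0))


def hd95(S: MaskLike, G: MaskLike, spacing_mm: Optional[Sequence[float]] = None) -> float:
    """Symmetric 95th-percentile Hausdorff distance between mask boundaries, in mm."""
    s, g = _as_bool(S), _as_bool(G)
    if s.shape != g.shape:
        raise DimensionError(f"mask shapes differ: {s.shape} vs {g.shape}")
    if spacing_mm is None:
        for m in (S, G):
            if isinstance(m, MaskVolume):
                spacing_mm = m.spacing_mm
                break
        else:
            spacing_mm = (1.0,) * s.ndim
    spacing = np.asarray(spacing_mm, dtype=np.float64)[: s.ndim]
    if not s.any() or not g.any():
        raise ConfigurationError("HD95 undefined for an empty mask")
    bs = np.argwhere(_boundary(s)) * spacing
    bg = np.argwhere(_boundary(g)) * spacing
    return max(_directed_d95(bs, bg), _directed_d95(bg, bs))


def brain_volume(m: MaskLike, spacing_mm: Optional[Sequence[float]] = None) -> float:
    """Mask volume in mm³: voxel count × voxel volume."""
    data = _as_bool(m)
    if spacing_mm is None:
        spacing_mm = m.spacing_mm if isinstance(m, MaskVolume) else (1.0,) * data.ndim
    voxel = float(np.prod(np.asarray(spacing_mm, dtype=np.float64)))
    return float(data.sum()) * voxel


def volume_agreement(pairs: Sequence[tuple]) -> AgreementReport:
    """Regression and Bland-Altman agreement over (predicted, annotated) volumes."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ConfigurationError("volume agreement requires at least 3 pairs")
    pred = np.asarray([p for p, _ in pairs], dtype=np.float64)
    true = np.asarray([t for _, t in pairs], dtype=np.float64)
    if np.ptp(true) == 0:
        slope = 1.0 if np.allclose(pred, true) else float("nan")
    else:
        slope = float(linregress(true, pred).slope)
    diff = pred - true
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementReport(
        lrc=slope, bias=bias, loa=(bias - 1.96 * sd, bias + 1.96 * sd), n=len(pairs)
    )


def evaluate_pair(
    pred: MaskVolume, truth: MaskVolume, volume_id: Optional[str] = None
) -> MetricReport:
    return MetricReport(
        dice=dice_score(pred, truth),
        hd95_mm=hd95(pred, truth, pred.spacing_mm),
        pred_volume_mm3=brain_volume(pred),
        true_volume_mm3=brain_volume(truth),
        volume_id=volume_id,
    )
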