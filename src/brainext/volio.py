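"""Volume I/O, preprocessing and postprocessing.

Handles NIfTI-1 reading/writing, timepoint selection for functional
series, multiplicative bias-field correction, percentile intensity
normalization, slicing a 3D volume into the fixed in-plane size the
segmentation network consumes, reassembling per-slice masks into the
original grid, and largest-connected-component cleanup.

Intensity normalization maps a volume V to

    V_norm = (V - V_p1) / (V_p99 - V_p1)

where V_p1 / V_p99 are the 1st / 99th intensity percentiles over the
whole volume; the 2% tails are clipped to [0, 1].  Percentiles are
computed per volume (not per slice) so that slices share one intensity
frame of reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import nibabel as nib
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    DimensionError,
    FormatError,
)

__all__ = [
    "VolumeGrid",
    "MaskVolume",
    "PreprocessRecord",
    "SliceStack",
    "read_volume",
    "write_volume",
    "write_mask",
    "select_timepoint",
    "correct_bias",
    "normalize_intensity",
    "to_slices",
    "from_slices",
    "largest_component",
]

#: 0-based frame used for functional (4D) series: the fifth timepoint.
DEFAULT_TIMEPOINT = 4

ResizeMode = Literal["resize", "crop", "pad"]


@dataclass
class VolumeGrid:
    """A 3D (or 4D time-series) intensity grid with voxel spacing in mm."""

    data: np.ndarray
    spacing_mm: tuple
    axis_order: str = "xyz"
    source_path: Optional[str] = None
    warning: Optional[str] = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise DimensionError(
                f"VolumeGrid requires 3D or 4D data, got {self.data.ndim}D"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3:
            raise DimensionError("spacing_mm must have 3 entries")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def is_4d(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3] if self.is_4d else 1


@dataclass
class MaskVolume:
    """Binary 3D brain mask sharing the geometry of its parent volume."""

    data: np.ndarray
    spacing_mm: tuple
    warning: Optional[str] = None

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise DimensionError(f"MaskVolume requires 3D data, got {arr.ndim}D")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ConfigurationError("mask values must be binary (0/1)")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("spacing must be positive")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class PreprocessRecord:
    """Everything needed to undo preprocessing geometry.

    ``p1``/``p99`` anchor the percentile normalization; the remaining
    fields let :func:`from_slices` restore the original grid exactly for
    crop/pad and to within interpolation for resize.
    """

    p1: float
    p99: float
    resize_mode: ResizeMode = "resize"
    original_shape: tuple = ()
    slice_axis: int = -1
    size: int = 256
    timepoint_used: Optional[int] = None

    def __post_init__(self):
        if self.p99 <= self.p1:
            raise DegenerateInputError(
                f"p99 ({self.p99}) must exceed p1 ({self.p1})"
            )


@dataclass
class SliceStack:
    """Ordered 2D slices of fixed in-plane size plus the inversion record."""

    slices: np.ndarray  # (n_slices, size, size)
    record: PreprocessRecord

    def __post_init__(self):
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise DimensionError("SliceStack.slices must be (n, size, size)")
        if not np.all(np.isfinite(self.slices)):
            raise DegenerateInputError("slice stack contains non-finite values")

    def __len__(self) -> int:
        return self.slices.shape[0]


# ---------------------------------------------------------------------------
# NIfTI-1 I/O


def _spacing_from_header(img) -> tuple:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI-1 volume (``.nii``/``.nii.gz``) with its voxel spacing."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several distinct types
        raise FormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        raise DimensionError(f"{path}: 2D image; a 3D or 4D volume is required")
    if data.ndim > 4:
        raise DimensionError(f"{path}: {data.ndim}D image not supported")
    return VolumeGrid(
        data=np.asarray(data),
        spacing_mm=_spacing_from_header(img),
        source_path=str(path),
    )


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_volume(v: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data), _affine(v.spacing_mm))
    zooms = v.spacing_mm + ((1.0,) if v.is_4d else ())
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def write_mask(m: MaskVolume, path) -> None:
    """Masks are stored as unsigned 8-bit 0/1 volumes."""
    img = nib.Nifti1Image(m.data.astype(np.uint8), _affine(m.spacing_mm))
    nib.save(img, str(path))


def read_mask(path) -> MaskVolume:
    v = read_volume(path)
    return MaskVolume(data=v.data > 0.5, spacing_mm=v.spacing_mm)


# ---------------------------------------------------------------------------
# Timepoint selection


def select_timepoint(v: VolumeGrid, t: Optional[int] = None) -> VolumeGrid:
    """Extract one 3D frame from a functional series.

    The default frame is the fifth timepoint (0-based index 4), the
    convention used when reporting metrics on functional scans.
    """
    if not v.is_4d:
        if t is None or t == DEFAULT_TIMEPOINT:
            return v
        raise DimensionError("timepoint selection on a 3D volume")
    if t is None:
        t = min(DEFAULT_TIMEPOINT, v.n_timepoints - 1)
    if not (0 <= t < v.n_timepoints):
        raise IndexError(
            f"timepoint {t} out of range for series of length {v.n_timepoints}"
        )
    return VolumeGrid(
        data=np.ascontiguousarray(v.data[..., t]),
        spacing_mm=v.spacing_mm,
        axis_order=v.axis_order,
        source_path=v.source_path,
    )


# ---------------------------------------------------------------------------
# Bias-field correction


def _class_conditional_field(data: np.ndarray, n_classes: int, sigma_frac: float):
    """Estimate a smooth multiplicative field as the Gaussian-smoothed
    log-residual around per-class intensity means.

    Voxels are grouped into ``n_classes`` intensity classes (1D k-means on
    log intensity); the residual of each voxel's log intensity around its
    class mean isolates the bias from genuine tissue contrast, and heavy
    Gaussian smoothing keeps only its low-frequency component.
    """
    eps = 1e-6 * float(np.max(data)) if np.max(data) > 0 else 1e-12
    logd = np.log(data + eps)
    flat = logd.ravel()

    # 1D k-means, initialized at evenly spaced quantiles
    centers = np.quantile(flat, np.linspace(0.1, 0.9, n_classes))
    for _ in range(12):
        assign = np.argmin(np.abs(flat[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [flat[assign == k].mean() if np.any(assign == k) else centers[k]
             for k in range(n_classes)]
        )
        if np.allclose(new, centers, atol=1e-8):
            centers = new
            break
        centers = new
    assign = np.argmin(np.abs(flat[:, None] - centers[None, :]), axis=1)
    residual = (flat - centers[assign]).reshape(data.shape)

    sigma = [max(1.0, sigma_frac * s) for s in data.shape]
    log_field = ndimage.gaussian_filter(residual, sigma=sigma, mode="nearest")
    log_field -= log_field.mean()
    return np.exp(log_field)


def correct_bias(
    v: VolumeGrid,
    mode: Literal["homomorphic", "external_n4", "off"] = "homomorphic",
    n_classes: int = 3,
    sigma_frac: float = 0.25,
) -> VolumeGrid:
    """Remove a smooth multiplicative intensity inhomogeneity.

    ``homomorphic`` is the built-in estimator (class-conditional
    log-residual smoothing); ``external_n4`` delegates to SimpleITK's N4
    implementation when that package is importable; ``off`` is identity.
    The mean intensity of the volume is preserved.
    """
    if mode == "off":
        return v
    data = np.asarray(v.data, dtype=np.float64)
    if data.ndim != 3:
        raise DimensionError("bias correction expects a 3D volume")
    if np.min(data) < 0:
        # magnitude images are non-negative; tolerate a noise tail below zero
        # but reject images that are negative in the bulk
        if np.mean(data < 0) > 0.25:
            raise ConfigurationError(
                "bias correction requires (close to) non-negative intensities"
            )
        data = np.clip(data, 0.0, None)
    if not np.any(data > 0):
        return replace(v, warning="all-zero volume; bias correction skipped")

    if mode == "external_n4":
        try:
            import SimpleITK as sitk
        except ImportError:
            warnings.warn("SimpleITK not available; falling back to homomorphic")
            mode = "homomorphic"
        else:
            img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
            img.SetSpacing(tuple(v.spacing_mm))
            corrected = sitk.N4BiasFieldCorrection(sitk.Cast(img, sitk.sitkFloat32))
            out = np.asarray(sitk.GetArrayFromImage(corrected)).T.astype(np.float64)
            out *= data.mean() / max(out.mean(), 1e-30)
            return VolumeGrid(out, v.spacing_mm, v.axis_order, v.source_path)

    field = _class_conditional_field(data, n_classes=n_classes, sigma_frac=sigma_frac)
    out = data / field
    out *= data.mean() / out.mean()
    return VolumeGrid(out, v.spacing_mm, v.axis_order, v.source_path)


# ---------------------------------------------------------------------------
# Intensity normalization


def normalize_intensity(
    v: VolumeGrid, record_kwargs: Optional[dict] = None
) -> tuple[VolumeGrid, PreprocessRecord]:
    """Percentile normalization with tail clipping (see module docstring)."""
    data = np.asarray(v.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise DegenerateInputError("volume contains non-finite intensities")
    p1, p99 = np.percentile(data, [1.0, 99.0])
    if p99 - p1 < 1e-12 * max(1.0, abs(p99)):
        raise DegenerateInputError(
            "intensity range between 1st and 99th percentile is zero"
        )
    out = np.clip((data - p1) / (p99 - p1), 0.0, 1.0)
    record = PreprocessRecord(p1=float(p1), p99=float(p99), **(record_kwargs or {}))
    normalized = VolumeGrid(out, v.spacing_mm, v.axis_order, v.source_path)
    return normalized, record


# ---------------------------------------------------------------------------
# Slicing / reassembly


def _crop_pad_2d(img: np.ndarray, size: int, pad_value: float = 0.0) -> np.ndarray:
    """Center-crop each axis larger than ``size``; center-pad smaller axes."""
    out = img
    for ax in (0, 1):
        n = out.shape[ax]
        if n > size:
            lo = (n - size) // 2
            out = out.take(range(lo, lo + size), axis=ax)
        elif n < size:
            lo = (size - n) // 2
            pad = [(0, 0), (0, 0)]
            pad[ax] = (lo, size - n - lo)
            out = np.pad(out, pad, constant_values=pad_value)
    return out


def _uncrop_unpad_2d(img: np.ndarray, orig: tuple) -> np.ndarray:
    out = img
    for ax in (0, 1):
        n, size = orig[ax], out.shape[ax]
        if n < size:  # was padded
            lo = (size - n) // 2
            out = out.take(range(lo, lo + n), axis=ax)
        elif n > size:  # was cropped: re-embed in zeros
            lo = (n - size) // 2
            pad = [(0, 0), (0, 0)]
            pad[ax] = (lo, n - size - lo)
            out = np.pad(out, pad, constant_values=0.0)
    return out


def to_slices(
    v: VolumeGrid,
    size: int = 256,
    slice_axis: int = -1,
    resize_mode: ResizeMode = "resize",
    record: Optional[PreprocessRecord] = None,
) -> SliceStack:
    """Cut a normalized 3D volume into 2D slices of ``size``×``size``.

    Slices are taken along ``slice_axis`` (default: last stored axis) and
    brought to the network's in-plane size by bilinear resize or by center
    crop/pad.  If a normalization ``record`` is supplied its geometry
    fields are filled in; otherwise a unit record is created.
    """
    data = np.asarray(v.data, dtype=np.float64)
    if data.ndim != 3:
        raise DimensionError("to_slices expects a 3D volume")
    axis = slice_axis % 3
    if data.shape[axis] == 0:
        raise DimensionError("slice axis has length 0")
    moved = np.moveaxis(data, axis, 0)  # (n_slices, H, W)

    if resize_mode == "resize":
        slices = np.stack(
            [
                _sk_resize(
                    s, (size, size), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True,
                )
                for s in moved
            ]
        )
    elif resize_mode in ("crop", "pad"):
        slices = np.stack([_crop_pad_2d(s, size) for s in moved])
    else:
        raise ConfigurationError(f"unknown resize_mode {resize_mode!r}")

    if record is None:
        record = PreprocessRecord(p1=0.0, p99=1.0)
    record.resize_mode = resize_mode
    record.original_shape = tuple(data.shape)
    record.slice_axis = axis
    record.size = size
    return SliceStack(slices=slices.astype(np.float64), record=record)


def from_slices(
    slices: np.ndarray,
    record: PreprocessRecord,
    spacing_mm: Sequence[float],
    threshold: float = 0.5,
) -> MaskVolume:
    """Reassemble per-slice masks (binary or soft) into the original 3D grid."""
    slices = np.asarray(slices, dtype=np.float64)
    if slices.ndim != 3:
        raise DimensionError("expected a (n_slices, size, size) stack")
    orig = tuple(record.original_shape)
    axis = record.slice_axis % 3
    n_expected = orig[axis]
    if slices.shape[0] != n_expected:
        raise DimensionError(
            f"slice count {slices.shape[0]} != original axis length {n_expected}"
        )
    in_plane = tuple(s for i, s in enumerate(orig) if i != axis)

    if record.resize_mode == "resize":
        restored = np.stack(
            [
                _sk_resize(
                    s, in_plane, order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True,
                )
                for s in slices
            ]
        )
    else:
        restored = np.stack([_uncrop_unpad_2d(s, in_plane) for s in slices])

    vol = np.moveaxis(restored, 0, axis) > threshold
    return MaskVolume(data=vol, spacing_mm=tuple(spacing_mm))


# ---------------------------------------------------------------------------
# Largest connected component


def largest_component(m: MaskVolume, connectivity: int = 26) -> MaskVolume:
    """Keep only the largest connected foreground component.

    ``connectivity`` is 6 (faces) or 26 (faces+edges+corners); ties between
    equal-sized components are broken in favour of the component containing
    the lowest raster-order voxel (the labelling order of the scan).
    """
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ConfigurationError("connectivity must be 6 or 26")
    if not m.data.any():
        return MaskVolume(m.data.copy(), m.spacing_mm, warning="empty mask")
    labels, n = ndimage.label(m.data, structure=structure)
    if n == 1:
        return MaskVolume(m.data.copy(), m.spacing_mm)
    counts = np.bincount(labels.ravel())[1:]
    # np.argmax returns the first maximum; scipy labels components in raster
    # order, so this is exactly the lowest-voxel-index tie-break.
    keep = int(np.argmax(counts)) + 1
    return MaskVolume(labels == keep, m.spacing_mm)
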