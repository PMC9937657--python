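"""Parametric head phantoms with ground-truth brain masks.

Each phantom is a piecewise-constant "head": a brain ellipsoid (with an
optional low-order sinusoidal surface wobble), a surrounding shell
(skull/scalp analogue, a dilated ellipsoid minus the brain), and
background.  Region means are gamma-mapped, modulated by a smooth
multiplicative bias field built from low-frequency cosine modes, and
corrupted with Gaussian noise.

Domains differ along three axes mirroring the ways real cohorts shift:

* ``scanner``  — noise level, bias-field amplitude and gamma (field
  strength / hardware);
* ``modality`` — contrast polarity and region-mean remapping (imaging
  sequence);
* ``species``  — brain geometry (semi-axes and shell thickness).

Geometry randomness (center jitter, wobble and bias-field phases) is
derived from a stable hash of the spec itself, so the ground-truth mask
is a function of the spec alone; the ``seed`` argument drives only the
noise realization.  ``make_phantom`` is bit-reproducible under
``(spec, seed)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .volio import MaskVolume, VolumeGrid

__all__ = ["DomainSpec", "PhantomSample", "make_phantom", "shift_domain", "degrade"]

ShiftKind = Literal["scanner", "modality", "species"]

#: Default grid and anisotropic spacing: in-plane 0.1 mm, through-plane
#: 0.4 mm, the anisotropy typical of rodent 2D multislice acquisitions.
DEFAULT_GRID = (64, 64, 32)
DEFAULT_SPACING = (0.1, 0.1, 0.4)


@dataclass(frozen=True)
class DomainSpec:
    """Parametric description of one phantom domain."""

    name: str = "source"
    brain_semiaxes: tuple = (20.0, 16.0, 10.0)
    brain_center_jitter: float = 2.0
    shell_thickness: float = 3.0
    brain_mean: float = 1.0
    shell_mean: float = 0.55
    background_mean: float = 0.10
    contrast_polarity: Literal["normal", "inverted"] = "normal"
    gamma: float = 1.0
    noise_sd: float = 0.05
    bias_amplitude: float = 0.0
    surface_wobble: float = 0.0
    grid_shape: tuple = DEFAULT_GRID
    spacing_mm: tuple = DEFAULT_SPACING

    def __post_init__(self):
        object.__setattr__(self, "brain_semiaxes", tuple(float(a) for a in self.brain_semiaxes))
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        self.validate()

    def validate(self) -> None:
        if len(self.brain_semiaxes) != 3 or any(a <= 0 for a in self.brain_semiaxes):
            raise ConfigurationError("brain_semiaxes must be 3 positive lengths")
        if any(n <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ConfigurationError("grid_shape must be 3 positive integers")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("spacing_mm must be strictly positive")
        if self.brain_center_jitter < 0:
            raise ConfigurationError("brain_center_jitter must be non-negative")
        if self.shell_thickness < 0:
            raise ConfigurationError("shell_thickness must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.bias_amplitude < 0:
            raise ConfigurationError("bias_amplitude must be non-negative")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")
        if self.contrast_polarity not in ("normal", "inverted"):
            raise ConfigurationError(f"unknown contrast_polarity {self.contrast_polarity!r}")
        margin = self.shell_thickness + self.brain_center_jitter + self.surface_wobble * max(self.brain_semiaxes)
        for a, n in zip(self.brain_semiaxes, self.grid_shape):
            if a + margin > n / 2:
                raise ConfigurationError(
                    f"semiaxis {a} + shell {self.shell_thickness} + jitter "
                    f"{self.brain_center_jitter} exceeds half grid extent {n / 2}"
                )
        means = (self.brain_mean, self.shell_mean, self.background_mean)
        if self.noise_sd == 0 and len(set(means)) != 3:
            raise ConfigurationError("region means must be distinct when noise_sd = 0")

    def geometry_seed(self) -> int:
        """Stable spec-derived seed for geometry draws (mask independent of ``seed``)."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return int.from_bytes(hashlib.sha256(payload).digest()[:4], "little") % (2**31)


@dataclass
class PhantomSample:
    volume: VolumeGrid
    mask: MaskVolume
    spec: DomainSpec
    seed: int


def _ellipsoid_mask(spec: DomainSpec, semiaxes, center, wobble_phases) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx) - center[0],
        np.arange(ny) - center[1],
        np.arange(nz) - center[2],
        indexing="ij",
    )
    a, b, c = semiaxes
    r = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    if spec.surface_wobble > 0:
        # low-order angular perturbation of the surface radius
        theta = np.arctan2(np.sqrt(x**2 + y**2), z + 1e-12)
        phi = np.arctan2(y, x)
        wob = 1.0 + spec.surface_wobble * (
            0.6 * np.sin(2 * phi + wobble_phases[0]) * np.sin(theta)
            + 0.4 * np.cos(3 * theta + wobble_phases[1])
        )
        return r <= wob
    return r <= 1.0


def _bias_field(spec: DomainSpec, phases) -> np.ndarray:
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape)
    nx, ny, nz = spec.grid_shape
    gx = np.cos(np.pi * np.arange(nx) / nx + phases[0])[:, None, None]
    gy = np.cos(np.pi * np.arange(ny) / ny + phases[1])[None, :, None]
    gz = np.cos(np.pi * np.arange(nz) / nz + phases[2])[None, None, :]
    field = 1.0 + spec.bias_amplitude * gx * gy * gz
    return field / field.mean()


def _effective_means(spec: DomainSpec) -> tuple:
    means = (spec.brain_mean, spec.shell_mean, spec.background_mean)
    if spec.contrast_polarity == "inverted":
        lo, hi = min(means), max(means)
        means = tuple(hi + lo - m for m in means)
    return means


def make_phantom(spec: DomainSpec, seed: int) -> PhantomSample:
    """Render one phantom volume and its ground-truth brain mask."""
    spec.validate()
    geom_rng = np.random.default_rng(spec.geometry_seed())
    noise_rng = np.random.default_rng(seed)

    center = np.array(spec.grid_shape, dtype=float) / 2.0 - 0.5
    if spec.brain_center_jitter > 0:
        center = center + geom_rng.uniform(
            -spec.brain_center_jitter, spec.brain_center_jitter, size=3
        )
    wobble_phases = geom_rng.uniform(0, 2 * np.pi, size=2)
    bias_phases = geom_rng.uniform(-0.6, 0.6, size=3)

    brain = _ellipsoid_mask(spec, spec.brain_semiaxes, center, wobble_phases)
    outer_axes = tuple(a + spec.shell_thickness for a in spec.brain_semiaxes)
    outer = _ellipsoid_mask(spec, outer_axes, center, wobble_phases)
    shell = outer & ~brain

    b_mean, s_mean, bg_mean = _effective_means(spec)
    img = np.full(spec.grid_shape, bg_mean, dtype=np.float64)
    img[shell] = s_mean
    img[brain] = b_mean

    if spec.gamma != 1.0:
        scale = max(abs(b_mean), abs(s_mean), abs(bg_mean), 1e-12)
        img = np.power(np.clip(img / scale, 0.0, None), spec.gamma) * scale

    img *= _bias_field(spec, bias_phases)
    if spec.noise_sd > 0:
        img = img + noise_rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    return PhantomSample(
        volume=VolumeGrid(img, spec.spacing_mm, source_path=None),
        mask=MaskVolume(brain, spec.spacing_mm),
        spec=spec,
        seed=int(seed),
    )


def shift_domain(base: DomainSpec, kind: ShiftKind, magnitude: float) -> DomainSpec:
    """Derive a shifted domain along one axis of variation.

    ``magnitude`` in [0, 1] interpolates from the base domain (0) to the
    full shift (1).  ``scanner`` touches only noise_sd, bias_amplitude
    and gamma; ``modality`` only contrast polarity and region means;
    ``species`` only semi-axes and shell thickness.
    """
    if not 0.0 <= magnitude <= 1.0:
        raise ConfigurationError("magnitude must lie in [0, 1]")
    if magnitude == 0.0:
        return base
    m = float(magnitude)
    if kind == "scanner":
        return replace(
            base,
            name=f"{base.name}-scanner{m:g}",
            noise_sd=base.noise_sd + 0.15 * m,
            bias_amplitude=base.bias_amplitude + 0.35 * m,
            gamma=base.gamma * (1.0 + 0.8 * m),
        )
    if kind == "modality":
        polarity = "inverted" if base.contrast_polarity == "normal" else "normal"
        return replace(
            base,
            name=f"{base.name}-modality{m:g}",
            contrast_polarity=polarity,
            # texture remap: shell drifts toward the brain level
            shell_mean=base.shell_mean + m * 0.5 * (base.brain_mean - base.shell_mean),
        )
    if kind == "species":
        # a species change reshapes the brain (elongation, flattening,
        # thicker shell) at a roughly preserved brain/FOV volume fraction,
        # mirroring how the field of view is chosen per species
        a, b, c = base.brain_semiaxes
        return replace(
            base,
            name=f"{base.name}-species{m:g}",
            brain_semiaxes=(
                a * (1.0 + 0.20 * m),
                b * (1.0 - 0.25 * m),
                c * (1.0 - 0.20 * m),
            ),
            shell_thickness=base.shell_thickness * (1.0 + 0.3 * m),
        )
    raise ConfigurationError(f"unknown shift kind {kind!r}")


def degrade(sample: PhantomSample, level: float, seed: int) -> PhantomSample:
    """Blur and re-noise a phantom while leaving its mask untouched.

    ``level`` in [0, 1] scales both the Gaussian blur width (up to 2
    voxels in-plane) and the added noise SD (up to 0.25); ``level=0`` is
    the identity.  Used to manufacture graded segmentation difficulty for
    uncertainty-vs-quality experiments.
    """
    if not 0.0 <= level <= 1.0:
        raise ConfigurationError("level must lie in [0, 1]")
    if level == 0.0:
        return sample
    rng = np.random.default_rng(seed)
    data = np.asarray(sample.volume.data, dtype=np.float64)
    blurred = ndimage.gaussian_filter(data, sigma=2.0 * level)
    noisy = blurred + rng.normal(0.0, 0.25 * level, size=data.shape)
    return PhantomSample(
        volume=VolumeGrid(noisy, sample.volume.spacing_mm),
        mask=sample.mask,
        spec=sample.spec,
        seed=sample.seed,
    )
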