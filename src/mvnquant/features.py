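"""Per-pixel feature bank for the vessel pixel classifier.

The bank mirrors the trainable-segmentation feature families used for the
chip images: Gaussian blur, Sobel gradient magnitude, Hessian eigenvalues,
difference of Gaussians and membrane projections, computed on a geometric
ladder of scales.  Defaults are the settings used for the vessel classifier:
membrane thickness 1, patch size 19, sigma 1.0–16.0, all five families.

All filters use reflect padding so that vessel probability is not biased by
dark borders at the chip edge; every plane is translation-equivariant away
from the image border and bit-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, signal

from .imaging import CalibratedImage, ValidationError

__all__ = [
    "FEATURE_FAMILIES",
    "FeatureConfig",
    "FeatureStack",
    "scale_set",
    "gaussian_blur",
    "sobel_magnitude",
    "difference_of_gaussians",
    "hessian_eigenimages",
    "membrane_kernels",
    "membrane_projections",
    "compute_feature_stack",
]

FEATURE_FAMILIES = (
    "gaussian_blur",
    "sobel",
    "hessian",
    "difference_of_gaussians",
    "membrane_projections",
)

#: fixed order of the six membrane-projection reductions
MEMBRANE_REDUCTIONS = ("sum", "mean", "std", "median", "max", "min")


@dataclass(frozen=True)
class FeatureConfig:
    """Configuration of the feature bank.

    Attributes
    ----------
    membrane_thickness:
        Width in pixels of the line kernels (default 1).
    membrane_patch_size:
        Side of the (odd) square line kernels (default 19).
    sigma_min, sigma_max:
        Bounds of the powers-of-two scale ladder (defaults 1.0 and 16.0).
    families:
        Enabled feature families, a subset of :data:`FEATURE_FAMILIES`.
    n_membrane_rotations:
        Number of rotated line kernels (default 30, i.e. 6° steps).
    """

    membrane_thickness: int = 1
    membrane_patch_size: int = 19
    sigma_min: float = 1.0
    sigma_max: float = 16.0
    families: tuple[str, ...] = FEATURE_FAMILIES
    n_membrane_rotations: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.sigma_min <= self.sigma_max):
            raise ValidationError(
                f"require 0 < sigma_min <= sigma_max, got "
                f"({self.sigma_min}, {self.sigma_max})"
            )
        if self.membrane_patch_size < 3 or self.membrane_patch_size % 2 == 0:
            raise ValidationError(
                f"membrane_patch_size must be odd and >= 3, got {self.membrane_patch_size}"
            )
        if self.membrane_thickness < 1:
            raise ValidationError("membrane_thickness must be >= 1")
        if not self.families:
            raise ValidationError("families must be non-empty")
        unknown = set(self.families) - set(FEATURE_FAMILIES)
        if unknown:
            raise ValidationError(f"unknown feature families: {sorted(unknown)}")
        if self.n_membrane_rotations < 1:
            raise ValidationError("n_membrane_rotations must be >= 1")
        object.__setattr__(self, "families", tuple(self.families))

    def to_dict(self) -> dict:
        return {
            "membrane_thickness": self.membrane_thickness,
            "membrane_patch_size": self.membrane_patch_size,
            "sigma_min": self.sigma_min,
            "sigma_max": self.sigma_max,
            "families": list(self.families),
            "n_membrane_rotations": self.n_membrane_rotations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        if "families" in d:
            d["families"] = tuple(d["families"])
        return cls(**d)


@dataclass
class FeatureStack:
    """Stack of named per-pixel feature planes (n_features × H × W)."""

    features: np.ndarray
    names: list[str]
    source_channels: list[str]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 3:
            raise ValidationError("features must be (n_features, H, W)")
        if len(self.names) != self.features.shape[0]:
            raise ValidationError("one name per feature plane required")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.features.shape[1:]  # type: ignore[return-value]

    def as_samples(self) -> np.ndarray:
        """(H·W, n_features) matrix for the classifier."""
        return self.features.reshape(self.n_features, -1).T

    def samples_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.features[:, rows, cols].T

    def reordered(self, names: Sequence[str]) -> "FeatureStack":
        """Planes permuted to match ``names`` (error if sets differ)."""
        if set(names) != set(self.names):
            raise ValidationError("feature name sets differ; stacks incompatible")
        idx = [self.names.index(n) for n in names]
        return FeatureStack(
            self.features[idx], list(names), list(self.source_channels),
            self.pixel_size_um,
        )


def scale_set(config: FeatureConfig) -> list[float]:
    """Powers-of-two scale ladder ``sigma_min · 2^k`` up to ``sigma_max``."""
    sigmas = []
    s = float(config.sigma_min)
    while s <= float(config.sigma_max) * (1 + 1e-12):
        sigmas.append(s)
        s *= 2.0
    return sigmas


def _as_float(img: CalibratedImage | np.ndarray) -> np.ndarray:
    a = img.pixels if isinstance(img, CalibratedImage) else img
    return np.asarray(a, dtype=np.float64)


def gaussian_blur(img: CalibratedImage | np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    return ndimage.gaussian_filter(_as_float(img), sigma, mode="reflect")


def sobel_magnitude(img: CalibratedImage | np.ndarray, sigma: float) -> np.ndarray:
    """Gradient magnitude of the Gaussian-smoothed image at scale ``sigma``."""
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    a = _as_float(img)
    gy = ndimage.gaussian_filter(a, sigma, order=(1, 0), mode="reflect")
    gx = ndimage.gaussian_filter(a, sigma, order=(0, 1), mode="reflect")
    return np.hypot(gx, gy)


def difference_of_gaussians(
    img: CalibratedImage | np.ndarray, sigma_a: float, sigma_b: float
) -> np.ndarray:
    """blur(min σ) − blur(max σ); the orientation is fixed by convention."""
    if sigma_a <= 0 or sigma_b <= 0:
        raise ValidationError(f"sigmas must be > 0, got ({sigma_a}, {sigma_b})")
    lo, hi = min(sigma_a, sigma_b), max(sigma_a, sigma_b)
    a = _as_float(img)
    return ndimage.gaussian_filter(a, lo, mode="reflect") - ndimage.gaussian_filter(
        a, hi, mode="reflect"
    )


def hessian_eigenimages(
    img: CalibratedImage | np.ndarray, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the Gaussian-smoothed Hessian, largest first.

    The smallest eigenvalue is strongly negative along bright ridges (vessel
    centrelines), which is what makes this family useful for tubes.
    """
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    a = _as_float(img)
    hrr = ndimage.gaussian_filter(a, sigma, order=(2, 0), mode="reflect")
    hcc = ndimage.gaussian_filter(a, sigma, order=(0, 2), mode="reflect")
    hrc = ndimage.gaussian_filter(a, sigma, order=(1, 1), mode="reflect")
    mean = 0.5 * (hrr + hcc)
    root = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc**2, 0.0))
    return mean + root, mean - root


def membrane_kernels(config: FeatureConfig) -> np.ndarray:
    """Rotated line kernels (n_rotations × patch × patch).

    Each kernel is a digital straight line of length ``patch_size`` and width
    ``membrane_thickness`` through the patch centre, built by stepping along
    the dominant axis so a thickness-1 kernel has exactly ``patch_size``
    nonzero pixels at every rotation.
    """
    p = config.membrane_patch_size
    half = p // 2
    kernels = np.zeros((config.n_membrane_rotations, p, p), dtype=np.float64)
    for k in range(config.n_membrane_rotations):
        angle = np.pi * k / config.n_membrane_rotations
        dr, dc = -np.sin(angle), np.cos(angle)  # image rows grow downward
        dominant_c = abs(dc) >= abs(dr)
        for t in range(-half, half + 1):
            if dominant_c:
                c = t
                r = int(round(t * dr / dc)) if dc != 0 else 0
            else:
                r = t
                c = int(round(t * dc / dr))
            for w in range(config.membrane_thickness):
                # thicken perpendicular to the dominant axis
                off = w - (config.membrane_thickness - 1) // 2
                rr = r + (off if dominant_c else 0)
                cc = c + (0 if dominant_c else off)
                if -half <= rr <= half and -half <= cc <= half:
                    kernels[k, rr + half, cc + half] = 1.0
    return kernels


def membrane_projections(
    img: CalibratedImage | np.ndarray, config: FeatureConfig
) -> np.ndarray:
    """Six reduction planes (sum, mean, std, median, max, min) over the
    responses to all rotated line kernels."""
    a = _as_float(img)
    kernels = membrane_kernels(config)
    half = config.membrane_patch_size // 2
    padded = np.pad(a, half, mode="reflect")
    responses = np.empty((kernels.shape[0],) + a.shape, dtype=np.float64)
    for i, k in enumerate(kernels):
        # correlation == convolution with the point-symmetric line kernel
        responses[i] = signal.fftconvolve(padded, k[::-1, ::-1], mode="valid")
    out = np.empty((6,) + a.shape, dtype=np.float64)
    out[0] = responses.sum(axis=0)
    out[1] = responses.mean(axis=0)
    out[2] = responses.std(axis=0)
    out[3] = np.median(responses, axis=0)
    out[4] = responses.max(axis=0)
    out[5] = responses.min(axis=0)
    return out


def _channel_planes(
    img: CalibratedImage, prefix: str, config: FeatureConfig
) -> tuple[list[np.ndarray], list[str]]:
    planes: list[np.ndarray] = [_as_float(img)]
    names: list[str] = [f"{prefix}|raw"]
    sigmas = scale_set(config)
    blurs = {s: gaussian_blur(img, s) for s in sigmas} if (
        {"gaussian_blur", "difference_of_gaussians"} & set(config.families)
    ) else {}
    if "gaussian_blur" in config.families:
        for s in sigmas:
            planes.append(blurs[s])
            names.append(f"{prefix}|gaussian_blur|s={s:g}")
    if "sobel" in config.families:
        for s in sigmas:
            planes.append(sobel_magnitude(img, s))
            names.append(f"{prefix}|sobel|s={s:g}")
    if "hessian" in config.families:
        for s in sigmas:
            hi, lo = hessian_eigenimages(img, s)
            planes += [hi, lo]
            names += [f"{prefix}|hessian_max|s={s:g}", f"{prefix}|hessian_min|s={s:g}"]
    if "difference_of_gaussians" in config.families:
        for i, si in enumerate(sigmas):
            for sj in sigmas[i + 1:]:
                planes.append(blurs[si] - blurs[sj])
                names.append(f"{prefix}|dog|s={si:g}-{sj:g}")
    if "membrane_projections" in config.families:
        mp = membrane_projections(img, config)
        for red, plane in zip(MEMBRANE_REDUCTIONS, mp):
            planes.append(plane)
            names.append(f"{prefix}|membrane_{red}|p={config.membrane_patch_size}")
    return planes, names


def compute_feature_stack(
    channels: Iterable[CalibratedImage], config: FeatureConfig | None = None
) -> FeatureStack:
    """Concatenate, per channel, the raw plane plus every enabled family at
    every scale of :func:`scale_set`."""
    config = config or FeatureConfig()
    channels = list(channels)
    if not channels:
        raise ValidationError("at least one channel required")
    shape = channels[0].shape
    if any(ch.shape != shape for ch in channels):
        raise ValidationError(
            f"all channels must share one shape, got "
            f"{[ch.shape for ch in channels]}"
        )
    planes: list[np.ndarray] = []
    names: list[str] = []
    roles: list[str] = []
    for i, ch in enumerate(channels):
        role = ch.channel_role.value
        prefix = f"ch{i}:{role}"
        p, n = _channel_planes(ch, prefix, config)
        planes += p
        names += n
        roles.append(role)
    return FeatureStack(np.stack(planes), names, roles, channels[0].pixel_size_um)
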