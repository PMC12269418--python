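"""Calibrated image I/O.

Everything downstream of this module is calibration-aware: areas and lengths
are always converted through ``pixel_size_um`` attached here.  Conventions
used throughout the package: row-major arrays, origin at the top-left,
0-based indices, half-open window bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ChannelRole",
    "CalibratedImage",
    "BinaryMask",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "area_um2",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class ChannelRole(str, Enum):
    """Role of a microscopy channel in the intravasation assay."""

    PHASE = "phase"   # phase contrast
    GFP = "gfp"       # GFP-labelled endothelium (HUVEC)
    CANCER = "cancer"  # red-labelled cancer cells / spheroid
    OTHER = "other"

    @classmethod
    def coerce(cls, value: "ChannelRole | str") -> "ChannelRole":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ValidationError(
                f"unknown channel role {value!r}; expected one of "
                f"{[r.value for r in cls]}"
            ) from exc


@dataclass
class CalibratedImage:
    """A 2D intensity image with physical pixel calibration.

    Parameters
    ----------
    pixels:
        Non-negative 2D intensity array.  Kept in its native dtype — no
        silent 8-bit conversion, so thresholds computed here match the
        acquisition scale.
    channel_role:
        One of :class:`ChannelRole` (or its string value).
    pixel_size_um:
        Physical side of one pixel in micrometres; must be positive.
    frame_index:
        Optional time-lapse frame number.
    metadata:
        Free-form provenance.
    """

    pixels: np.ndarray
    channel_role: ChannelRole | str
    pixel_size_um: float
    frame_index: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError(
                f"pixels must be a non-empty 2D array, got shape {self.pixels.shape}"
            )
        if not np.issubdtype(self.pixels.dtype, np.number):
            raise ValidationError(f"pixels must be numeric, got {self.pixels.dtype}")
        if np.nanmin(self.pixels) < 0:
            raise ValidationError("intensities must be non-negative")
        if not (float(self.pixel_size_um) > 0):
            raise ValidationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        self.pixel_size_um = float(self.pixel_size_um)
        self.channel_role = ChannelRole.coerce(self.channel_role)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def crop(self, top: int, left: int, bottom: int, right: int) -> "CalibratedImage":
        """Return a view-free crop with calibration propagated (half-open bounds)."""
        sub = np.array(self.pixels[top:bottom, left:right])
        return CalibratedImage(
            sub, self.channel_role, self.pixel_size_um, self.frame_index,
            dict(self.metadata, crop=(int(top), int(left), int(bottom), int(right))),
        )


@dataclass
class BinaryMask:
    """A boolean mask sharing geometry and calibration with its source image."""

    pixels: np.ndarray
    pixel_size_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError(
                f"mask must be a non-empty 2D array, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != bool:
            self.pixels = self.pixels.astype(bool)
        if not (float(self.pixel_size_um) > 0):
            raise ValidationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        self.pixel_size_um = float(self.pixel_size_um)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def area_um2(self) -> float:
        """Foreground area in μm²."""
        return area_um2(int(self.pixels.sum()), self.pixel_size_um)

    def crop(self, top: int, left: int, bottom: int, right: int) -> "BinaryMask":
        sub = np.array(self.pixels[top:bottom, left:right])
        return BinaryMask(sub, self.pixel_size_um, provenance=self.provenance)


def area_um2(pixel_count: int, pixel_size_um: float) -> float:
    """Convert a pixel count to a physical area.

    ``area = pixel_count × pixel_size_um²`` — linear in the count, quadratic
    in the calibration.
    """
    if pixel_count < 0:
        raise ValidationError(f"pixel_count must be >= 0, got {pixel_count}")
    if not (float(pixel_size_um) > 0):
        raise ValidationError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return float(pixel_count) * float(pixel_size_um) ** 2


def _read_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in {".tif", ".tiff"}:
            return tifffile.imread(path)
        # PNG (and friends) fallback
        import imageio.v3 as iio

        return np.asarray(iio.imread(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoding failure
        raise OSError(f"could not decode image file {path}") from exc


def _tiff_pixel_size_um(path: Path) -> float | None:
    """Pixel size from TIFF resolution tags, if present and in known units."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None:
                return None
            num, den = xres.value
            if num == 0:
                return None
            px_per_unit = num / den
            unit_val = getattr(unit, "value", None)
            unit_name = getattr(unit_val, "name", str(unit_val)).upper()
            if "CENTIMETER" in unit_name:
                return 1e4 / px_per_unit
            if "INCH" in unit_name:
                return 25400.0 / px_per_unit
            return None
    except Exception:
        return None


def load_image(
    path: str | Path,
    channel_role: ChannelRole | str | Sequence[ChannelRole | str],
    pixel_size_um: float | None = None,
) -> CalibratedImage | list[CalibratedImage]:
    """Load a calibrated image (TIFF primary, PNG fallback).

    For a multi-page/multi-channel file pass one role per page and a list of
    :class:`CalibratedImage` is returned.  ``pixel_size_um`` from the caller
    always wins; if omitted, TIFF resolution tags are consulted and an error
    is raised when neither source provides a calibration.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"image file not found: {path}")
    if pixel_size_um is None:
        pixel_size_um = _tiff_pixel_size_um(path)
        if pixel_size_um is None:
            raise ValidationError(
                f"no pixel_size_um given and none recoverable from {path}"
            )
    if not (float(pixel_size_um) > 0):
        raise ValidationError(f"pixel_size_um must be > 0, got {pixel_size_um}")

    arr = _read_raster(path)
    single = isinstance(channel_role, (str, ChannelRole))
    roles = [channel_role] if single else list(channel_role)

    if arr.ndim == 2:
        planes = [arr]
    elif arr.ndim == 3:
        # pages-first (tifffile) or channels-last (PNG RGB)
        if arr.shape[0] == len(roles):
            planes = [arr[i] for i in range(arr.shape[0])]
        elif arr.shape[-1] == len(roles):
            planes = [arr[..., i] for i in range(arr.shape[-1])]
        elif len(roles) == 1 and arr.shape[0] == 1:
            planes = [arr[0]]
        else:
            raise ValidationError(
                f"{path} has {arr.shape} planes but {len(roles)} roles were given"
            )
    else:
        raise ValidationError(f"unsupported raster dimensionality {arr.ndim} in {path}")

    if len(planes) != len(roles):
        raise ValidationError(
            f"{path}: {len(planes)} planes but {len(roles)} channel roles"
        )
    images = [
        CalibratedImage(p, r, pixel_size_um, metadata={"source": str(path)})
        for p, r in zip(planes, roles)
    ]
    return images[0] if single else images


def save_image(images: CalibratedImage | Sequence[CalibratedImage], path: str | Path) -> None:
    """Write one or more calibrated images to a (multi-page) TIFF.

    Pixel values are written unchanged; calibration goes into the TIFF
    resolution tags (pixels per centimetre) and the roles into the image
    description.
    """
    path = Path(path)
    imgs = [images] if isinstance(images, CalibratedImage) else list(images)
    if not imgs:
        raise ValidationError("nothing to save")
    px = imgs[0].pixel_size_um
    if any(i.pixel_size_um != px for i in imgs):
        raise ValidationError("all pages must share one calibration")
    data = np.stack([i.pixels for i in imgs]) if len(imgs) > 1 else imgs[0].pixels
    ppcm = 1e4 / px
    desc = json.dumps({"channel_roles": [i.channel_role.value for i in imgs],
                       "pixel_size_um": px})
    tifffile.imwrite(
        path, data, resolution=(ppcm, ppcm), resolutionunit="CENTIMETER",
        description=desc, photometric="minisblack",
    )


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit {0, 255} TIFF with calibration tags."""
    ppcm = 1e4 / mask.pixel_size_um
    tifffile.imwrite(
        Path(path), (mask.pixels.astype(np.uint8) * 255),
        resolution=(ppcm, ppcm), resolutionunit="CENTIMETER",
        description=json.dumps({"provenance": mask.provenance,
                                "pixel_size_um": mask.pixel_size_um}),
    )


def load_mask(path: str | Path, pixel_size_um: float | None = None) -> BinaryMask:
    """Read a mask written by :func:`save_mask` (foreground = any nonzero)."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"mask file not found: {path}")
    arr = _read_raster(path)
    provenance = ""
    try:
        with tifffile.TiffFile(path) as tif:
            desc = tif.pages[0].tags.get("ImageDescription")
            if desc is not None:
                meta = json.loads(desc.value)
                provenance = meta.get("provenance", "")
                if pixel_size_um is None:
                    pixel_size_um = meta.get("pixel_size_um")
    except Exception:
        pass
    if pixel_size_um is None:
        pixel_size_um = _tiff_pixel_size_um(path)
    if pixel_size_um is None:
        raise ValidationError(f"no pixel_size_um given and none recoverable from {path}")
    return BinaryMask(arr > 0, float(pixel_size_um), provenance=provenance)
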