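"""2D assay quantifications: circularity, CTCF, scratch gap area, spheroid
invasion ratio and cytokine-array log₂ fold change.

These are the simple calibrated measurements used alongside the chip
experiments.  The reference path for the scratch assay is a manually drawn
gap mask; :func:`detect_gap_mask` is an automatic convenience based on the
observation that cell-free regions have low local intensity variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, CalibratedImage, ValidationError, area_um2
from .roi import region_circularity

__all__ = [
    "RegionMeasurement",
    "measure_region",
    "circularity",
    "ctcf",
    "gap_area_fraction",
    "invasion_ratio",
    "cytokine_log2fc",
    "duplicate_spot_mean",
    "detect_gap_mask",
]


@dataclass
class RegionMeasurement:
    """Calibrated measurements of one region (a traced cell, a spot, ...)."""

    area_um2: float
    perimeter_um: float
    integrated_density: float  # sum of intensities over the region
    mean_intensity: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.area_um2 < 0:
            raise ValidationError("area must be >= 0")


def measure_region(
    img: CalibratedImage, mask: BinaryMask, label: str = ""
) -> RegionMeasurement:
    """Measure a region of a calibrated image through a boolean mask."""
    from skimage.measure import perimeter_crofton

    if img.shape != mask.shape:
        raise ValidationError("image and mask shapes differ")
    px = img.pixel_size_um
    sel = np.asarray(img.pixels, dtype=float)[mask.pixels]
    if sel.size == 0:
        raise ValidationError("empty region")
    return RegionMeasurement(
        area_um2=area_um2(int(mask.pixels.sum()), px),
        perimeter_um=float(perimeter_crofton(mask.pixels, directions=4)) * px,
        integrated_density=float(sel.sum()),
        mean_intensity=float(sel.mean()),
        label=label,
    )


def circularity(region: RegionMeasurement) -> float:
    """Shape descriptor 4π·area/perimeter², clipped at 1.0.

    1.0 is a perfect circle; values approaching 0 indicate elongated
    morphology (the mesenchymal phenotype in the EMT readout).
    """
    return region_circularity(region.area_um2, region.perimeter_um)


def ctcf(integrated_density: float, cell_area: float, mean_background: float) -> float:
    """Corrected total cell fluorescence:

    ``CTCF = integrated density − (area of selected cell × mean background
    fluorescence intensity)``.  May legitimately be negative (a cell dimmer
    than background) and is reported unfloored.
    """
    if cell_area <= 0:
        raise ValidationError(f"cell_area must be > 0, got {cell_area}")
    if mean_background < 0:
        raise ValidationError("mean_background must be >= 0")
    return float(integrated_density - cell_area * mean_background)


def gap_area_fraction(gap_mask_t: BinaryMask, gap_mask_0: BinaryMask) -> float:
    """Percent of the initial scratch gap still free of cells at time t:
    ``100 × area(gap_t) / area(gap_0)``."""
    if gap_mask_t.shape != gap_mask_0.shape:
        raise ValidationError("gap masks must share geometry")
    if gap_mask_t.pixel_size_um != gap_mask_0.pixel_size_um:
        raise ValidationError("gap masks must share calibration")
    a0 = gap_mask_0.area_um2()
    if a0 == 0:
        raise ValidationError("initial gap mask is empty")
    return 100.0 * gap_mask_t.area_um2() / a0


def invasion_ratio(
    invasion_area_um2: float,
    initial_spheroid_area_um2: float,
    control_mean: float | None = None,
) -> float:
    """Invaded area divided by the initial spheroid area; optionally
    normalized so the control-group mean maps to 1.0."""
    if initial_spheroid_area_um2 <= 0:
        raise ValidationError("initial spheroid area must be > 0")
    ratio = invasion_area_um2 / initial_spheroid_area_um2
    if control_mean is not None:
        if control_mean <= 0:
            raise ValidationError("control mean must be > 0")
        ratio /= control_mean
    return float(ratio)


def duplicate_spot_mean(intensities) -> float:
    """Average pixel intensity of an array-spot duplicate pair (or more)."""
    arr = np.asarray(intensities, dtype=float)
    if arr.size == 0:
        raise ValidationError("no spot intensities given")
    return float(arr.mean())


def cytokine_log2fc(
    mean_spot_intensity_cm: float,
    mean_spot_intensity_control: float,
    pseudocount: float = 0.0,
) -> float:
    """log₂ fold change of conditioned-medium spot intensity over control.

    ``pseudocount`` (default 0 — no background handling) is added to both
    intensities before the ratio for arrays with near-zero control spots.
    """
    cm = mean_spot_intensity_cm + pseudocount
    ctl = mean_spot_intensity_control + pseudocount
    if ctl <= 0 or cm <= 0:
        raise ValidationError(
            f"spot intensities must be positive after pseudocount, got "
            f"({cm}, {ctl})"
        )
    return float(np.log2(cm / ctl))


def detect_gap_mask(
    img: CalibratedImage, window_px: int = 15, keep_largest: bool = True
) -> BinaryMask:
    """Automatic scratch-gap detector (convenience; manual masks are the
    reference path).

    Cell-free regions are smooth, so the gap is the low-local-variance side
    of an Otsu split of the local standard deviation image.
    """
    from skimage.filters import threshold_otsu

    a = np.asarray(img.pixels, dtype=float)
    mean = ndimage.uniform_filter(a, window_px)
    sq = ndimage.uniform_filter(a * a, window_px)
    local_sd = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    if float(local_sd.min()) == float(local_sd.max()):
        raise ValidationError("texture-free image; cannot locate a gap")
    gap = local_sd <= threshold_otsu(local_sd)
    gap = ndimage.binary_opening(gap, ndimage.generate_binary_structure(2, 1),
                                 iterations=2)
    if keep_largest and gap.any():
        from skimage.measure import label as sk_label

        lbl = sk_label(gap, connectivity=2)
        counts = np.bincount(lbl.ravel())
        counts[0] = 0
        gap = lbl == int(counts.argmax())
    return BinaryMask(gap, img.pixel_size_um, provenance="detect_gap_mask")
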