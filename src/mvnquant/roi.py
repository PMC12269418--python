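"""Spheroid ROIs, vessel ROIs and intravasation-event counting.

The quantification proxy: each spheroid gets a square analysis window (tROI)
whose side is 115 % of the major axis of the ellipse fitted to the spheroid;
the vessel mask restricted to that window (vROI) is the co-localization
domain; red-labelled cancer particles found inside the vROI after Otsu
thresholding and passing the size (≥ 50 μm²) and circularity ([0.5, 1.0])
filters are counted as intravasation events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label
from skimage.measure import perimeter_crofton, regionprops

from .imaging import BinaryMask, CalibratedImage, ValidationError, area_um2

__all__ = [
    "TROI_SCALE",
    "MIN_AREA_UM2",
    "CIRC_RANGE",
    "SpheroidROI",
    "VesselROI",
    "Particle",
    "EventCount",
    "extract_spheroid_rois",
    "build_vessel_roi",
    "otsu_threshold",
    "count_intravasation_events",
    "summarize_events",
    "events_long_table",
    "region_circularity",
]

#: tROI side as a fraction of the fitted major axis
TROI_SCALE = 1.15
#: particle filters used for event counting
MIN_AREA_UM2 = 50.0
CIRC_RANGE = (0.5, 1.0)


def region_circularity(area: float, perimeter: float) -> float:
    """4π·area/perimeter², clipped at 1.0 (digital circles can exceed 1)."""
    if perimeter <= 0:
        raise ValidationError("perimeter must be > 0")
    return float(min(4.0 * np.pi * area / perimeter**2, 1.0))


@dataclass
class SpheroidROI:
    """Fitted spheroid ellipse and the derived square analysis window (tROI).

    ``bounds`` are the clipped half-open window bounds (top, left, bottom,
    right); ``side_px`` is the unclipped side, ``round(TROI_SCALE × major
    axis / pixel size)``.
    """

    spheroid_id: int
    center: tuple[float, float]           # row, col in px
    major_axis_um: float
    minor_axis_um: float
    orientation_rad: float
    side_px: int
    bounds: tuple[int, int, int, int]
    clipped: bool
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if not (self.major_axis_um >= self.minor_axis_um > 0):
            raise ValidationError(
                f"require major >= minor > 0, got "
                f"({self.major_axis_um}, {self.minor_axis_um})"
            )

    @property
    def window_shape(self) -> tuple[int, int]:
        t, l, b, r = self.bounds
        return (b - t, r - l)


@dataclass
class VesselROI:
    """Vessel mask restricted to a tROI — the event-counting domain."""

    spheroid_id: int
    mask: BinaryMask
    vessel_area_um2: float = field(init=False)

    def __post_init__(self) -> None:
        self.vessel_area_um2 = self.mask.area_um2()


@dataclass
class Particle:
    """One segmented cancer particle inside a vROI."""

    area_um2: float
    perimeter_um: float
    circularity: float
    centroid: tuple[float, float]  # row, col within the tROI window
    spheroid_id: int

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValidationError("particle area must be > 0")
        if not (0 < self.circularity <= 1.0):
            raise ValidationError("circularity must be in (0, 1]")


@dataclass
class EventCount:
    """Intravasation events for one spheroid (= filtered particle count)."""

    spheroid_id: int
    particles: list[Particle]
    condition_label: str = ""
    candidates_rejected: int = 0

    @property
    def n_events(self) -> int:
        return len(self.particles)


def extract_spheroid_rois(
    spheroid_mask: BinaryMask,
    min_spheroid_area_um2: float = 2000.0,
    troi_scale: float = TROI_SCALE,
) -> list[SpheroidROI]:
    """Locate spheroids as connected components and derive their tROIs.

    An ellipse is fitted to each sufficiently large component by second image
    moments; the axis-aligned square window of side ``troi_scale × major
    axis`` is centred on the ellipse centre and clipped to the image.
    An empty mask yields an empty list.
    """
    px = spheroid_mask.pixel_size_um
    labeled = sk_label(spheroid_mask.pixels, connectivity=2)
    h, w = spheroid_mask.shape
    rois: list[SpheroidROI] = []
    for prop in regionprops(labeled):
        if area_um2(prop.area, px) < min_spheroid_area_um2:
            continue
        major_px = float(prop.axis_major_length)
        minor_px = float(prop.axis_minor_length)
        if major_px <= 0 or minor_px <= 0:
            continue
        cr, cc = prop.centroid
        side = int(round(troi_scale * major_px))
        top = int(round(cr - side / 2))
        left = int(round(cc - side / 2))
        bottom, right = top + side, left + side
        ct, cl = max(top, 0), max(left, 0)
        cb, cr_ = min(bottom, h), min(right, w)
        rois.append(
            SpheroidROI(
                spheroid_id=int(prop.label),
                center=(float(cr), float(cc)),
                major_axis_um=major_px * px,
                minor_axis_um=minor_px * px,
                orientation_rad=float(prop.orientation),
                side_px=side,
                bounds=(ct, cl, cb, cr_),
                clipped=(ct, cl, cb, cr_) != (top, left, bottom, right),
                pixel_size_um=px,
            )
        )
    return rois


def build_vessel_roi(vessel_mask: BinaryMask, troi: SpheroidROI) -> VesselROI:
    """Crop the full-image vessel mask to the tROI window."""
    if vessel_mask.pixel_size_um != troi.pixel_size_um:
        raise ValidationError("vessel mask and tROI calibrations differ")
    t, l, b, r = troi.bounds
    h, w = vessel_mask.shape
    if not (0 <= t <= b <= h and 0 <= l <= r <= w):
        raise ValidationError("tROI bounds outside the vessel-mask geometry")
    return VesselROI(troi.spheroid_id, vessel_mask.crop(t, l, b, r))


def otsu_threshold(window: CalibratedImage | np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold of a window: maximizes the between-class variance over
    an ``n_bins`` histogram.

    Foreground is *strictly above* the returned value, so the threshold is
    placed at the upper edge of the last background bin — every value that
    Otsu's criterion assigns to the background class stays background (a
    bin-centre convention would leak the top background bin into the
    foreground).
    """
    values = window.pixels if isinstance(window, CalibratedImage) else np.asarray(window)
    values = np.asarray(values, dtype=float).ravel()
    if float(values.min()) == float(values.max()):
        raise ValidationError("cannot Otsu-threshold a constant window")
    hist, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(hist)[:-1].astype(float)
    w1 = values.size - w0
    csum = np.cumsum(hist * centers)[:-1]
    mu0 = csum / np.where(w0 > 0, w0, 1)
    mu1 = (np.sum(hist * centers) - csum) / np.where(w1 > 0, w1, 1)
    var = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(var))
    return float(edges[k + 1])


def _measure_particles(
    fg: np.ndarray, pixel_size_um: float, spheroid_id: int
) -> list[tuple[Particle, bool]]:
    """Measure all 8-connected components; second element marks filter passage
    candidates are classified later so rejected counts can be reported."""
    labeled = sk_label(fg, connectivity=2)
    out = []
    for prop in regionprops(labeled):
        a = area_um2(prop.area, pixel_size_um)
        perim_px = perimeter_crofton(labeled == prop.label, directions=4)
        if perim_px <= 0:  # single-pixel degenerate shapes
            continue
        p_um = float(perim_px) * pixel_size_um
        circ = region_circularity(a, p_um)
        out.append(
            (
                Particle(a, p_um, circ, tuple(map(float, prop.centroid)), spheroid_id),
                True,
            )
        )
    return out


def count_intravasation_events(
    cancer_img: CalibratedImage,
    vroi: VesselROI,
    min_area_um2: float = MIN_AREA_UM2,
    circ_min: float = CIRC_RANGE[0],
    circ_max: float = CIRC_RANGE[1],
    condition_label: str = "",
) -> EventCount:
    """Count filtered cancer particles inside the vROI.

    The stated order of operations: (1) cancer signal outside the vROI is
    zeroed, (2) the masked window is Otsu-thresholded, (3) 8-connected
    components are labelled, (4) components with area ≥ ``min_area_um2`` and
    circularity within [``circ_min``, ``circ_max``] are kept.  The result is
    therefore invariant to any repainting of cancer pixels outside the vessel
    mask.
    """
    if cancer_img.shape != vroi.mask.shape:
        raise ValidationError(
            f"cancer window {cancer_img.shape} does not match vROI "
            f"{vroi.mask.shape}"
        )
    if cancer_img.pixel_size_um != vroi.mask.pixel_size_um:
        raise ValidationError("cancer window and vROI calibrations differ")
    px = cancer_img.pixel_size_um
    masked = np.where(vroi.mask.pixels, np.asarray(cancer_img.pixels, dtype=float), 0.0)
    if float(masked.min()) == float(masked.max()):
        warnings.warn(
            "count_intravasation_events: constant masked window, no particles",
            stacklevel=2,
        )
        return EventCount(vroi.spheroid_id, [], condition_label)
    t = otsu_threshold(masked)
    fg = masked > t
    particles: list[Particle] = []
    rejected = 0
    for particle, _ in _measure_particles(fg, px, vroi.spheroid_id):
        if particle.area_um2 >= min_area_um2 and circ_min <= particle.circularity <= circ_max:
            particles.append(particle)
        else:
            rejected += 1
    return EventCount(vroi.spheroid_id, particles, condition_label, rejected)


def events_long_table(counts: list[EventCount]) -> pd.DataFrame:
    """Tidy per-spheroid table for external statistics software."""
    return pd.DataFrame(
        {
            "condition": [c.condition_label for c in counts],
            "spheroid_id": [c.spheroid_id for c in counts],
            "n_events": [c.n_events for c in counts],
            "candidates_rejected": [c.candidates_rejected for c in counts],
        }
    )


def summarize_events(counts: list[EventCount]) -> pd.DataFrame:
    """Per-condition descriptive summary of events per spheroid.

    Columns: n spheroids, mean, SD (sample SD; missing for n = 1) and median
    events/spheroid.  Inferential statistics are deliberately left to
    external software.
    """
    if not counts:
        raise ValidationError("no event counts to summarize")
    long = events_long_table(counts)
    rows = []
    for cond, grp in long.groupby("condition", sort=True):
        n = len(grp)
        if n == 0:
            warnings.warn(f"empty group {cond!r} omitted", stacklevel=2)
            continue
        rows.append(
            {
                "condition": cond,
                "n_spheroids": n,
                "mean_events": float(grp.n_events.mean()),
                "sd_events": float(grp.n_events.std(ddof=1)) if n > 1 else np.nan,
                "median_events": float(grp.n_events.median()),
            }
        )
    return pd.DataFrame(rows)
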