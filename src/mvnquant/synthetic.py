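"""Synthetic microscopy scenes with machine-readable ground truth.

Every pipeline stage is testable without downloads: this module renders the
three-channel imaging setting of the intravasation assay — a GFP-labelled
microvascular network with partially decayed fluorescence, a dense spheroid
mass and discrete cancer particles of controlled area and elongation planted
inside or outside vessels — plus dye-efflux time series and skeleton
phantoms with combinatorial truth.

Geometry of a scene: an elliptical spheroid sits at the image centre; two
sinuous "corridor" vessels run horizontally through the bands between the
spheroid edge and the edge of its square analysis window (115 % of the major
axis), so intravascular particle placement is always feasible, and further
random-walk vessels with widths drawn from the configured range complete the
network.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import perimeter_crofton

from .imaging import BinaryMask, CalibratedImage, ChannelRole, ValidationError
from .roi import CIRC_RANGE, MIN_AREA_UM2, region_circularity

__all__ = [
    "GenerationError",
    "SceneSpec",
    "ParticleRecord",
    "SceneTruth",
    "SyntheticScene",
    "generate_scene",
    "generate_condition_batch",
    "generate_permeability_series",
    "generate_skeleton_phantom",
]


class GenerationError(RuntimeError):
    """Raised when a particle plan cannot be realized after bounded retries."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults are the study conditions exercised by the test suite: 1 μm/px
    calibration, a 110 × 50 μm spheroid, vessel widths spanning the 10–40 μm
    range, GFP dropout emulating decayed endothelial expression, and a
    particle plan whose filter-passing intravascular disks (60–150 μm²,
    circular) sit on either side of the 50 μm² / circularity-0.5 filters
    together with deliberate distractors.
    """

    image_size: int = 192
    pixel_size_um: float = 1.0
    seed: int = 0
    # vessels
    n_random_vessels: int = 3
    vessel_width_um: tuple[float, float] = (10.0, 40.0)
    corridor_width_um: tuple[float, float] = (18.0, 22.0)
    tortuosity: float = 0.5          # SD of lateral wander per axial step (px)
    # GFP channel
    gfp_intensity: float = 150.0
    gfp_background: float = 5.0
    gfp_noise_sd: float = 8.0
    gfp_dropout_fraction: float = 0.25
    # spheroid (axis-aligned ellipse; major axis horizontal)
    spheroid_major_um: float = 110.0
    spheroid_minor_um: float = 50.0
    spheroid_intensity: float = 180.0
    # cancer particles
    n_intravascular: int = 3
    n_extravascular: int = 2
    n_small_distractors: int = 1
    n_elongated_distractors: int = 1
    particle_area_um2: tuple[float, float] = (60.0, 150.0)
    extravascular_area_um2: tuple[float, float] = (60.0, 90.0)
    small_area_um2: float = 49.0
    elongated_shape_px: tuple[int, int] = (3, 30)
    particle_intensity: float = 200.0
    cancer_background: float = 2.0   # fluorescence background is near-black
    cancer_noise_sd: float = 3.0
    # phase contrast (stylized edge-enhanced rendering)
    phase_background: float = 100.0
    phase_vessel_delta: float = -20.0
    phase_spheroid_delta: float = -30.0
    phase_edge_gain: float = 40.0
    phase_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in ("n_random_vessels", "n_intravascular", "n_extravascular",
                     "n_small_distractors", "n_elongated_distractors"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.vessel_width_um
        if not (0 < lo <= hi <= 100):
            raise ValidationError("vessel widths must lie in (0, 100] μm")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.image_size < 64:
            raise ValidationError("image_size must be >= 64 px")


@dataclass
class ParticleRecord:
    """Ground truth for one planted cancer particle."""

    particle_id: int
    kind: str                 # intravascular / extravascular / small / elongated
    centroid: tuple[float, float]
    area_um2: float
    perimeter_um: float
    circularity: float
    inside_vessel: bool
    passes_filters: bool


@dataclass
class SceneTruth:
    vessel_mask: BinaryMask
    spheroid_mask: BinaryMask
    particles: list[ParticleRecord]
    particle_labels: np.ndarray   # int image; particle_id at each particle pixel

    @property
    def n_true_events(self) -> int:
        """Planted filter-passing intravascular particles."""
        return sum(p.inside_vessel and p.passes_filters for p in self.particles)


@dataclass
class SyntheticScene:
    channels: dict[str, CalibratedImage]
    truth: SceneTruth
    spec: SceneSpec


def _dilate_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask
    L = np.arange(-radius, radius + 1)
    footprint = (L[:, None] ** 2 + L[None, :] ** 2) <= radius**2
    return ndimage.binary_dilation(mask, structure=footprint)


def _erode_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask
    L = np.arange(-radius, radius + 1)
    footprint = (L[:, None] ** 2 + L[None, :] ** 2) <= radius**2
    return ndimage.binary_erosion(mask, structure=footprint)


def _wandering_line(
    n: int, start: float, rng: np.random.Generator, wander_sd: float,
    lo: float, hi: float,
) -> np.ndarray:
    """Lateral coordinate of a random-walk centreline, reflected into [lo, hi]."""
    steps = rng.normal(0.0, wander_sd, size=n)
    y = start + np.cumsum(steps)
    # reflect into the admissible band
    span = hi - lo
    y = lo + np.abs((y - lo) % (2 * span) - span) if span > 0 else np.full(n, lo)
    return y


def _render_vessels(spec: SceneSpec, rng: np.random.Generator,
                    spheroid: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Vessel mask (spheroid carved out) and the corridor centrelines."""
    N = spec.image_size
    px = spec.pixel_size_um
    cy = cx = N // 2
    minor_r = spec.spheroid_minor_um / 2 / px
    major_px = spec.spheroid_major_um / px
    safe_half = 0.55 * major_px
    band_lo = minor_r + 4
    band_hi = safe_half + 4
    band_center = 0.5 * (band_lo + band_hi)

    mask = np.zeros((N, N), dtype=bool)
    centerlines: list[np.ndarray] = []
    xs = np.arange(N)
    for sign in (-1.0, +1.0):
        width = rng.uniform(*spec.corridor_width_um) / px
        y0 = cy + sign * band_center
        y = _wandering_line(N, y0, rng, spec.tortuosity * 0.3,
                            y0 - 2.0, y0 + 2.0)
        rows = np.clip(np.round(y).astype(int), 0, N - 1)
        line = np.zeros((N, N), dtype=bool)
        line[rows, xs] = True
        mask |= _dilate_disk(line, int(round(width / 2)))
        centerlines.append(np.column_stack([rows, xs]))

    for _ in range(spec.n_random_vessels):
        width = rng.uniform(*spec.vessel_width_um) / px
        horizontal = rng.random() < 0.5
        start = rng.uniform(0.15 * N, 0.85 * N)
        y = _wandering_line(N, start, rng, spec.tortuosity, 2, N - 3)
        rows = np.clip(np.round(y).astype(int), 0, N - 1)
        line = np.zeros((N, N), dtype=bool)
        if horizontal:
            line[rows, xs] = True
        else:
            line[xs, rows] = True
        mask |= _dilate_disk(line, int(round(width / 2)))

    mask &= ~ndimage.binary_dilation(
        spheroid, ndimage.generate_binary_structure(2, 1), iterations=2
    )
    return mask, centerlines


def _disk_footprint(center: tuple[int, int], area_um2: float,
                    px: float, shape: tuple[int, int]) -> np.ndarray:
    radius = float(np.sqrt(area_um2 / np.pi)) / px
    rr, cc = draw_disk(center, radius, shape=shape)
    fp = np.zeros(shape, dtype=bool)
    fp[rr, cc] = True
    return fp


def _measure_footprint(fp: np.ndarray, px: float) -> tuple[float, float, float]:
    area = float(fp.sum()) * px**2
    perim = float(perimeter_crofton(fp, directions=4)) * px
    circ = region_circularity(area, perim) if perim > 0 else 0.0
    return area, perim, circ


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one calibrated three-channel scene plus its ground truth.

    Raises :class:`GenerationError` if the particle plan cannot be placed
    (no room inside vessels) after bounded retries.
    """
    last_err: Exception | None = None
    for attempt in range(5):
        try:
            return _generate_scene_once(replace(spec, seed=spec.seed), attempt)
        except GenerationError as err:
            last_err = err
    raise GenerationError(
        f"particle plan infeasible for spec seed {spec.seed}: {last_err}"
    )


def _generate_scene_once(spec: SceneSpec, attempt: int) -> SyntheticScene:
    # the attempt index perturbs only the geometry stream, keeping the
    # (spec, seed) → scene mapping deterministic
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
    N = spec.image_size
    px = spec.pixel_size_um
    cy = cx = N // 2

    spheroid = np.zeros((N, N), dtype=bool)
    rr, cc = draw_ellipse(
        cy, cx, spec.spheroid_minor_um / 2 / px, spec.spheroid_major_um / 2 / px,
        shape=(N, N),
    )
    spheroid[rr, cc] = True

    vessels, corridor_centerlines = _render_vessels(spec, rng, spheroid)

    major_px = spec.spheroid_major_um / px
    safe_half = int(round(0.55 * major_px))
    safe = np.zeros((N, N), dtype=bool)
    safe[max(cy - safe_half, 0): cy + safe_half, max(cx - safe_half, 0): cx + safe_half] = True

    spheroid_clearance = _dilate_disk(spheroid, 3)
    occupied = np.zeros((N, N), dtype=bool)
    particle_labels = np.zeros((N, N), dtype=int)
    records: list[ParticleRecord] = []
    pid = 0

    def stamp(fp: np.ndarray, kind: str, inside: bool) -> None:
        nonlocal pid
        pid += 1
        particle_labels[fp] = pid
        occupied[:] |= _dilate_disk(fp, 3)
        area, perim, circ = _measure_footprint(fp, px)
        com = ndimage.center_of_mass(fp)
        records.append(
            ParticleRecord(
                particle_id=pid, kind=kind, centroid=(float(com[0]), float(com[1])),
                area_um2=area, perimeter_um=perim, circularity=circ,
                inside_vessel=inside,
                passes_filters=(area >= MIN_AREA_UM2
                                and CIRC_RANGE[0] <= circ <= CIRC_RANGE[1]),
            )
        )

    def place_disks(n: int, area_range: tuple[float, float], kind: str,
                    inside: bool) -> None:
        for _ in range(n):
            placed = False
            for _try in range(300):
                area = rng.uniform(*area_range)
                r = int(np.ceil(np.sqrt(area / np.pi) / px))
                if inside:
                    region = _erode_disk(vessels, r + 2) & safe
                else:
                    region = (safe & ~_dilate_disk(vessels, r + 3)
                              & ~_dilate_disk(spheroid_clearance, r))
                region &= ~occupied
                sites = np.argwhere(region)
                if sites.size == 0:
                    continue
                center = tuple(sites[rng.integers(len(sites))])
                fp = _disk_footprint(center, area, px, (N, N))
                if occupied[fp].any() or (inside and not vessels[fp].all()):
                    continue
                stamp(fp, kind, inside)
                placed = True
                break
            if not placed:
                raise GenerationError(f"could not place a {kind} particle")

    place_disks(spec.n_intravascular, spec.particle_area_um2, "intravascular", True)
    place_disks(spec.n_extravascular, spec.extravascular_area_um2,
                "extravascular", False)
    place_disks(spec.n_small_distractors,
                (spec.small_area_um2, spec.small_area_um2), "small", True)

    # elongated intravascular distractors ride along a corridor centreline
    h_px, l_px = spec.elongated_shape_px
    for _ in range(spec.n_elongated_distractors):
        placed = False
        for _try in range(300):
            line = corridor_centerlines[rng.integers(len(corridor_centerlines))]
            x0 = int(rng.integers(cx - safe_half + 1, cx + safe_half - l_px - 1))
            seg = line[(line[:, 1] >= x0) & (line[:, 1] < x0 + l_px)]
            if len(seg) < l_px:
                continue
            row = int(round(seg[:, 0].mean()))
            fp = np.zeros((N, N), dtype=bool)
            fp[row - h_px // 2: row - h_px // 2 + h_px, x0: x0 + l_px] = True
            if occupied[fp].any() or not vessels[fp].all() or not safe[fp].all():
                continue
            stamp(fp, "elongated", True)
            placed = True
            break
        if not placed:
            raise GenerationError("could not place an elongated distractor")

    particle_fg = particle_labels > 0

    # --- channels -----------------------------------------------------------
    cancer = np.full((N, N), spec.cancer_background, dtype=float)
    cancer[spheroid] = spec.spheroid_intensity
    cancer[particle_fg] = spec.particle_intensity
    cancer += rng.normal(0.0, spec.cancer_noise_sd, (N, N))

    gfp = np.full((N, N), spec.gfp_background, dtype=float)
    gfp[vessels] = spec.gfp_intensity
    if spec.gfp_dropout_fraction > 0 and vessels.any():
        field_ = ndimage.gaussian_filter(rng.normal(size=(N, N)), 8.0)
        thr = np.quantile(field_[vessels], spec.gfp_dropout_fraction)
        dropout = vessels & (field_ <= thr)
        gfp[dropout] = spec.gfp_background + 0.08 * spec.gfp_intensity
    gfp += rng.normal(0.0, spec.gfp_noise_sd, (N, N))

    edges = ndimage.gaussian_gradient_magnitude(vessels.astype(float), 1.5)
    phase = np.full((N, N), spec.phase_background, dtype=float)
    phase[vessels] += spec.phase_vessel_delta
    phase[spheroid] += spec.phase_spheroid_delta
    phase += spec.phase_edge_gain * edges
    phase += rng.normal(0.0, spec.phase_noise_sd, (N, N))

    def ch(arr: np.ndarray, role: ChannelRole) -> CalibratedImage:
        return CalibratedImage(np.clip(arr, 0, None), role, px,
                               metadata={"synthetic": True, "seed": spec.seed})

    truth = SceneTruth(
        vessel_mask=BinaryMask(vessels, px, provenance="synthetic truth"),
        spheroid_mask=BinaryMask(spheroid, px, provenance="synthetic truth"),
        particles=records,
        particle_labels=particle_labels,
    )
    return SyntheticScene(
        channels={
            "phase": ch(phase, ChannelRole.PHASE),
            "gfp": ch(gfp, ChannelRole.GFP),
            "cancer": ch(cancer, ChannelRole.CANCER),
        },
        truth=truth,
        spec=spec,
    )


def generate_condition_batch(
    n_spheroids: int,
    mean_events: float,
    spec_template: SceneSpec | None = None,
    seed: int = 0,
) -> tuple[list[SyntheticScene], np.ndarray]:
    """One scene per spheroid with Poisson-distributed true event counts.

    Emulates a condition regime (e.g. control-like mean 1 vs EMT-like mean 3
    events per spheroid).  Returns the scenes and the drawn truth counts.
    """
    if mean_events < 0:
        raise ValidationError("mean_events must be >= 0")
    template = spec_template or SceneSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA7C4]))
    counts = rng.poisson(mean_events, size=n_spheroids)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_spheroids)
    scenes = [
        generate_scene(replace(template, n_intravascular=int(k), seed=int(s)))
        for k, s in zip(counts, scene_seeds)
    ]
    return scenes, counts


def generate_permeability_series(
    P_true_cm_per_s: float,
    d_um: float = 40.0,
    I_i: float = 200.0,
    I_b: float = 100.0,
    n_frames: int = 61,
    frame_interval_s: float = 15.0,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
    window_shape: tuple[int, int] = (80, 120),
    pixel_size_um: float = 1.0,
) -> tuple[list[CalibratedImage], BinaryMask, dict]:
    """Dye-efflux window time series built as the exact forward model of the
    endpoint estimator.

    The window mean rises linearly at rate ``(I_i − I_b) · P · 4/d`` (d in
    cm): lumen intensity stays constant while the perivascular gel intensity
    increases to match, honouring the efflux-equals-accumulation assumption.
    Per-pixel multiplicative noise of relative SD ``noise_sd_frac`` is then
    applied.  The vessel strip width is rounded to an even pixel count and
    the realized diameter recorded as truth.

    Defaults follow the acquisition protocol: 61 frames every 15 s, i.e. a
    15-minute lapse (Δt = 900 s).
    """
    if P_true_cm_per_s < 0:
        raise ValidationError("P_true must be >= 0")
    if d_um <= 0:
        raise ValidationError("d_um must be > 0")
    if n_frames < 2:
        raise ValidationError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    H, W = window_shape
    px = pixel_size_um
    w_px = max(2, int(round(d_um / px / 2.0)) * 2)
    if w_px >= H - 4:
        raise ValidationError("vessel diameter does not fit the window")
    d_actual_um = w_px * px
    top = (H - w_px) // 2
    vessel = np.zeros((H, W), dtype=bool)
    vessel[top: top + w_px, :] = True

    A = H * W
    A_v = int(vessel.sum())
    A_g = A - A_v
    lumen = (I_i * A - A_g * I_b) / A_v
    if lumen <= 0:
        raise ValidationError("infeasible intensity configuration (lumen <= 0)")

    d_cm = d_actual_um / 1e4
    slope = (I_i - I_b) * P_true_cm_per_s * 4.0 / d_cm  # intensity / s
    frames: list[CalibratedImage] = []
    for i in range(n_frames):
        t = i * frame_interval_s
        target_mean = I_i + slope * t
        gel = (target_mean * A - A_v * lumen) / A_g
        img = np.where(vessel, lumen, gel)
        if noise_sd_frac > 0:
            img = img * (1.0 + rng.normal(0.0, noise_sd_frac, (H, W)))
        frames.append(
            CalibratedImage(np.clip(img, 0, None), ChannelRole.OTHER, px,
                            frame_index=i, metadata={"synthetic": True})
        )
    truth = {
        "P_true_cm_per_s": float(P_true_cm_per_s),
        "d_um": float(d_actual_um),
        "delta_t_s": float((n_frames - 1) * frame_interval_s),
        "I_i": float(I_i),
        "I_b": float(I_b),
    }
    return frames, BinaryMask(vessel, px, provenance="synthetic vessel strip"), truth


def _draw_arm(canvas: np.ndarray, center: tuple[int, int], direction: tuple[int, int],
              n_steps: int) -> float:
    """Draw an arm along an axial/diagonal direction; return its geodesic length
    in pixels (axial steps 1, diagonal steps √2)."""
    r, c = center
    dr, dc = direction
    for _ in range(n_steps):
        r += dr
        c += dc
        canvas[r, c] = True
    return n_steps * (np.sqrt(2.0) if dr != 0 and dc != 0 else 1.0)


def generate_skeleton_phantom(
    kind: str,
    arm_length_um: float = 50.0,
    width_um: float | None = None,
    pixel_size_um: float = 1.0,
) -> tuple[BinaryMask, dict]:
    """Skeleton phantom (bar / Y / cross / lattice) with combinatorial truth.

    Arm directions are restricted to multiples of 45° so the rasterized
    geodesic length equals the Euclidean one; the truth dictionary records
    the junction count and the total drawn length computed from the step
    counts, independent of any measurement code.
    """
    px = pixel_size_um
    n = int(round(arm_length_um / px))
    nd = int(round(arm_length_um / px / np.sqrt(2.0)))
    if n < 2:
        raise ValidationError("arm too short for the requested calibration")

    if kind == "bar":
        size = n + 11
        canvas = np.zeros((size, size), dtype=bool)
        r0, c0 = size // 2, 5
        canvas[r0, c0: c0 + n + 1] = True
        truth = {"junctions": 0, "total_length_um": n * px}
    elif kind == "Y":
        size = 2 * n + 11
        canvas = np.zeros((size, size), dtype=bool)
        center = (size // 2, size // 2)
        canvas[center] = True
        total = _draw_arm(canvas, center, (-1, 0), n)        # up
        total += _draw_arm(canvas, center, (1, -1), nd)      # down-left
        total += _draw_arm(canvas, center, (1, 1), nd)       # down-right
        truth = {"junctions": 1, "total_length_um": total * px}
    elif kind == "cross":
        size = 2 * n + 11
        canvas = np.zeros((size, size), dtype=bool)
        center = (size // 2, size // 2)
        canvas[center] = True
        total = 0.0
        for d in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            total += _draw_arm(canvas, center, d, n)
        truth = {"junctions": 1, "total_length_um": total * px}
    elif kind == "lattice":
        size = 2 * n + 11
        canvas = np.zeros((size, size), dtype=bool)
        off = size // 2
        positions = [off - n, off, off + n]
        for p in positions:
            canvas[p, off - n: off + n + 1] = True
            canvas[off - n: off + n + 1, p] = True
        # 3×3 line grid: 4 T-nodes (degree 3) + 1 cross-node (degree 4);
        # corners have degree 2 and are not junctions
        truth = {"junctions": 5, "total_length_um": 6 * 2 * n * px}
    else:
        raise ValidationError(f"unknown phantom kind {kind!r}")

    if width_um is not None and width_um > px:
        canvas = _dilate_disk(canvas, int(round(width_um / 2 / px)))
    return BinaryMask(canvas, px, provenance=f"phantom:{kind}"), truth
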