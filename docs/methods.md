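# Methods

`mvnquant` quantifies cancer-cell intravasation into self-assembled
microvascular networks (MVNs) in microfluidic chips from calibrated
multi-channel 2D microscopy, together with the surrounding assay
measurements: vascular architecture, vessel permeability, and the usual 2D
readouts (circularity, CTCF, scratch gap closure, invasion ratio, cytokine
log₂ fold change). This note documents the models, the parameters that
matter, the numerical conventions, and what the bundled synthetic benchmark
does and does not show.

## Intravasation quantification

The proxy for intravasation is co-localization: a red-labelled cancer
particle lying inside the segmented vessel area counts as one event. The
pipeline runs per image:

1. **Spheroid location.** The cancer channel is thresholded with the
   iterative-intermeans ("default"/IsoData) algorithm, opened (1 erosion +
   1 dilation, 3×3 cross), and connected components above
   `min_spheroid_area_um2` (default 2000 μm²) are kept. An ellipse is fitted
   to each component by second image moments.
2. **tROI.** Each spheroid gets an axis-aligned square analysis window of
   side 115 % of its fitted major axis, centred on the ellipse centre and
   clipped to the image. The square is axis-aligned; event counts are
   per-spheroid, and overlapping windows of neighbouring spheroids are
   processed independently.
3. **Vessel segmentation (per tROI).** The GFP endothelial channel is
   binarized with the same intermeans threshold; a random forest
   (200 trees, fixed seed, majority vote, probability ties resolved to
   background) classifies each pixel of the window as vessel vs
   everything-else using a joint feature bank over the phase-contrast crop
   and the {0,1} binarized-GFP crop. The dual-channel input is what keeps
   segmentation reliable when GFP expression has partially decayed. The
   predicted mask is opened once to suppress speckle; restricted to the
   window it is the vROI.
4. **Event counting.** Cancer-channel signal outside the vROI is zeroed
   first, then the masked window is Otsu-thresholded, components are
   labelled with 8-connectivity, and components with area ≥ 50 μm² and
   circularity in [0.5, 1.0] are counted. Because masking precedes
   thresholding, the count is provably invariant to anything outside the
   vessel mask; particles straddling the vessel boundary contribute only
   their in-vROI portion.

Descriptive per-condition summaries (n, mean, SD, median events/spheroid)
are exported along with tidy per-spheroid tables; inferential statistics are
deliberately left to external software.

### Feature bank

Families: Gaussian blur, Sobel gradient magnitude (of the smoothed image),
Hessian eigenvalues (largest/smallest — the smallest is strongly negative on
bright tubes), difference of Gaussians (all ordered scale pairs, min-σ minus
max-σ), and membrane projections (30 line kernels at 6° steps, patch 19,
thickness 1, reduced across rotations by sum/mean/std/median/max/min).
Scales form the powers-of-two ladder from σ = 1.0 to σ = 16.0 px. All
convolutions use reflect padding so chip borders do not bias vessel
probability. Line kernels are built by stepping along the dominant axis, so
a thickness-1 kernel has exactly 19 nonzero pixels at every rotation.

## Numerical conventions

- **Thresholds.** Foreground is strictly above the threshold everywhere.
  The Otsu implementation returns the *upper edge* of the last background
  bin rather than its centre: with a bin-centre convention, values in the
  winning background bin can leak into the foreground (observed concretely
  with a uniform background exactly at a bin centre). Intermeans iterates
  `t ← (μ_below + μ_above)/2` on a 256-bin histogram to its fixed point.
  Both are verified against exhaustive brute-force optimization of their
  criteria; when empty histogram bins create exact variance ties, agreement
  is asserted on the induced partition.
- **Perimeter and circularity.** Circularity is 4π·area/perimeter², clipped
  at 1.0 (digital circles can exceed 1). Perimeters use the Crofton
  four-direction estimator: on a rasterized disk of radius 200 px it yields
  circularity 1.003, whereas the classical weighted pixel-count estimator
  gives 0.906 and would make the printed filter range [0.5, 1.0]
  systematically biased against large round particles.
- **Coordinates.** Row-major, origin top-left, 0-based, half-open window
  bounds, 8-connectivity for components (ImageJ Analyze Particles
  convention).
- **Classifier.** Probability tie (exactly 0.5) → background, keeping
  vessel calls conservative; stacks are matched to the model by feature
  *names*, so plane order is irrelevant; a prediction-batching batch size of
  100 is recorded as provenance only.

## Vascular network metrics

Phase-contrast or GFP network images are auto-thresholded and opened, then
topologically thinned to a 1-px skeleton. A junction is a skeleton pixel
with ≥ 3 8-connected neighbours; a tubule is a skeleton path bounded by two
junctions or a junction and an endpoint. Lengths accumulate 1 px per axial
step and √2 px per diagonal step, converted through the calibration.
Adjacent junction pixels (an artefact of thinning at thick crossings) are
merged into a single node at their centroid, and each incident segment adds
the Euclidean leg from that centroid to its first traced pixel — without
this, every arm of a thick crossing loses about one pixel and a 4-arm
crossing undercounts length by ~2 %. A configurable spur-pruning length is
exposed (default 0: no pruning). Only junction count and total tubule
length per field of view are produced; the full angiogenesis-plugin feature
set (meshes, master junctions, isolated elements) is out of scope.

## Permeability

The coefficient follows the standard efflux model for a cylindrical vessel
perfused with dye, under the assumptions of constant intravascular
intensity and efflux balanced by accumulation in the perivascular gel:

    P (cm/s) = 1/(I_i − I_b) · (I_f − I_i)/Δt · d/4

with I_i, I_f the mean intensities of the whole analysis window (lumen +
gel) at the first and last frames, I_b a background level from a
vessel-free region or supplied directly, Δt the elapsed time (61 frames
every 15 s → 900 s), and d the mean vessel diameter, converted from μm to
cm exactly once inside the formula. Diameter is measured as twice the mean
Euclidean distance-to-background along the vessel centreline — exact for
even pixel widths, ±1 px for odd. Windows with d ≥ 50 μm are refused (the
cylindrical-cross-section assumption fails) unless explicitly overridden;
negative P (bleaching-dominated) is returned with a QC flag, never clipped.
An optional regression estimator (least-squares slope over all frames) is
provided as a robustness variant beyond the endpoint form. There is a known
tension between the constant-intravascular-intensity assumption and using
the whole-window endpoint difference; the formula is implemented as printed.

## Synthetic benchmark: what it emulates, and what it does not

The generator renders 192×192 px scenes at 1 μm/px: an elliptical spheroid
(110 × 50 μm) at the centre, a vessel network of random-walk tubes with
widths uniform in 10–40 μm plus two guaranteed "corridor" vessels
(18–22 μm) running through the bands between spheroid edge and tROI edge
(so any particle plan up to ~10 events is feasible), GFP = vessel ×
intensity with smooth dropout patches emulating decayed endothelial
expression (default fraction 0.25; the stress tests use 0.5), a stylized
edge-enhanced phase-contrast rendering, and a near-black cancer channel with
the spheroid disk and planted particles. Particles comprise filter-passing
intravascular disks (60–150 μm²), extravascular disks, 49 μm²
sub-threshold disks, and 3×30 px elongated bars (circularity ≈ 0.3) riding
inside corridors. Truth records each particle's rasterized area, Crofton
circularity, containment flag, and filter verdict. Condition batches draw
per-spheroid event counts from a Poisson (the two reference regimes: mean 1
control-like, mean 3 EMT-like) — Poisson is the simplest count model
consistent with reported means. Dye-efflux series are the exact forward
model of the endpoint estimator (lumen constant, gel rising so the window
mean follows the model rate), with per-pixel multiplicative noise; window
averaging is what makes endpoint estimation robust to that noise, so the
benchmark does not probe frame-wide illumination flicker, to which the
endpoint estimator is genuinely sensitive. The vessel strip width rounds to
an even pixel count and the realized diameter is recorded as truth.

Passing these benchmarks shows the machinery is self-consistent and
recovers known ground truth under the modelled imaging physics; it does
**not** validate performance on real chip images, whose optics (PSF, shot
noise, debris, uneven illumination, out-of-focus light) are deliberately
not simulated. Classifier training in the benchmark scribbles on truth
masks; on real data, scribble quality is a further variable.

## Problem sizes and determinism

Everything is a pure function of explicit seeds: scene generation,
batching, training, and prediction are bit-reproducible. The bundled
recovery studies use 100 scenes per seeded run for counting recovery, 100
scenes per condition (×5 repetitions) for the condition-mean study, 10
seeds for the dropout segmentation stress test, and 50 seeds for noisy
permeability recovery — sizes chosen so each study's sampling error is well
below the effect it measures while the whole suite stays desk-scale.

## Known limitations

- The tROI square is axis-aligned, not rotated with the spheroid ellipse.
- The event proxy cannot distinguish wall-adherent from fully lumenized
  cells; that verification requires orthogonal confocal views and is out of
  scope.
- Particles clipped by an imperfect vessel mask at the boundary can fall
  below the 50 μm² filter; this is the dominant (rare) error mode of the
  full pipeline relative to planted truth.
- Absolute areas depend entirely on the supplied μm/px calibration; TIFF
  resolution tags are honoured but explicit configuration wins.
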