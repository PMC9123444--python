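# Methods

## Problem and scope

`colonytrack` analyses time-lapse images of bacterial colonies growing on
agar plates recorded by a flatbed scanner inside an incubator. Inputs are
a timed series of raster frames — either a full scan bed (an A4-class
216 mm × 297 mm area holding up to six 3-inch dishes) or single
pre-cropped plates — plus a small config (dpi, scan cadence or filename
timestamp pattern, plate positions or auto-detection). Outputs are
per-colony area trajectories, emergence (lag) times, logistic growth-fit
parameters, and per-plate CFU counts with the 25–250 validity rule.
Driving the scanner hardware, live folder watching, and interactive
editing are out of scope: the package operates on already-saved images,
and the manual de-selection step of GUI-based tools is replaced by
automated flagging plus config overrides.

## Geometry and physical scale

The pixel grid is 0-based with x = column and y = row; centroids and
circle centres are sub-pixel floats. Physical scale is
`pixel_size_mm = 25.4 / dpi`; areas are reported both in px² and mm²
(`area_mm2 = area_px2 * pixel_size_mm²`). RGB frames are reduced to
intensity by standard luminance weighting before any processing, and
intensities are normalised to [0, 1] by the image dtype range.

Plate layout is planned as axis-aligned grid packing: `floor(w/(d+m))`
columns × `floor(h/(d+m))` rows of plates of diameter `d` with margin
`m`, centred on the bed — deterministic, and it reproduces the standard
2 × 3 arrangement of six 3-inch dishes on the A4-class bed. Optimal
circle packing is deliberately not attempted. Plate auto-detection uses a
Canny-edge circular Hough transform over radii within a configurable
tolerance of the expected radius; an accumulator peak below threshold
yields "not found" and the caller falls back to the configured position.
Splitting crops each plate's bounding square (side = 2·radius, rounded
up) and masks pixels outside the circle as NaN; masked pixels are
excluded from every downstream statistic, so the plate rim and
inter-plate bed never contaminate background estimates. Whether crops
should be rectangles or masked circles was an open choice; masked
bounding squares keep raster shapes while making the exclusion explicit.

## Background model and segmentation

Two background modes are provided. `region_mean` mirrors the classic
cursor-picked reference patch: the mean of a user-chosen rectangle (at
least 25 unmasked pixels). `surface` (default) fits a quadratic 2-D
polynomial to all in-mask pixels with three iterations of ±2.5 σ outlier
rejection (σ from the median absolute deviation), so colonies — bright
outliers — do not pull the fit; the polynomial captures the generator's
linear ramp exactly and real scanner shading approximately.

Subtraction rectifies the signed difference so colony pixels are
positive. Default polarity is `bright` (colonies scatter more light on a
flatbed scan); `auto` picks the sign whose rectified residual carries
more total mass.

Thresholding is Otsu's method on in-mask residual values with a floor of
3× the estimated noise σ. Because the rectified residual of an empty
plate is a zero-clipped Gaussian, its median absolute deviation collapses
to zero; the noise σ is therefore estimated as the residual's 84.1st
percentile, which equals σ for the clipped half-normal and stays robust
to a small bright colony tail. Without this floor an empty plate would be
carved into hundreds of noise blobs. Connected components (8-adjacency by
default) smaller than `min_area_px2` (default 5 px²) are removed;
survivors are relabelled 1..n in raster order of their first pixel for
determinism. Features per detection: centroid, area, equivalent diameter
`2·sqrt(A/π)`, perimeter, circularity `4πA/P²` clipped to ≤ 1 (set to 1
for degenerate zero-perimeter components).

Fused and rim-adjacent candidates are flagged, never deleted. A component
is flagged touching when its circularity falls below 0.6 (a waisted
two-colony blob at contact has circularity ≈ 0.5) or it carries more than
one regional intensity maximum after 1-px Gaussian smoothing. Maxima are
counted per component with an h-maxima transform at 30 % of the
component's peak: plain local-maximum counting misfires on the flat top
of a saturated colony, where pixel noise creates spurious peaks, whereas
prominence gating only counts genuinely separated domes. `touches_edge`
is set when any component pixel lies within an edge margin (default 2 %
of the plate radius) of the rim.

## Tracking

Colonies are effectively stationary, so linking is greedy
nearest-centroid assignment between consecutive frames, processing
candidate pairs in ascending distance with ties broken by lower
(track id, detection label); pairs beyond the displacement gate are
unassigned. The gate defaults to 0.5× the median equivalent diameter of
the previous frame's detections (growth shifts centroids slightly), with
a 2 px minimum so sub-pixel colonies remain linkable. Unmatched
detections seed new tracks (colonies emerge mid-series); a track
unmatched for more than 2 consecutive frames is marked lost. Greedy
matching is near-optimal here because inter-colony distances dwarf
centroid jitter; the test suite cross-checks it against a global
optimal-assignment oracle on jittered scenes.

Merges are censored, not split: when two tracks map onto one connected
component (directly, or via a vanished track's last centroid falling
inside a neighbour's component), all involved tracks get status `merged`
and their points from the contact frame onward are removed, keeping only
the unambiguous pre-merge history for kinetics. A lone track whose
component newly *gains* the fused-blob flag (it merged with an untracked
late emerger) is censored the same way; components flagged from birth are
not, since a pair fused from its first appearance is one candidate, not a
detected merge. Tracks whose detections ever touch the rim get status
`edge`. Watershed separation of merged colonies is a known possible
extension; censoring matches the de-selection semantics of manual
workflows.

## Kinetics

The growth law is logistic, `A(t) = K / (1 + exp(−mu·(t − t50)))`:
exponential at early times with rate `mu` (per hour), saturating at
carrying capacity `K` (area units). Fits are least squares
(trust-region-reflective with analytic Jacobian), initialised with
`K₀ = max area`, `t50₀` from the interpolated half-max crossing, and
`mu₀` from the slope of log A over early points between 5 % and 80 % of
`K₀`. Box constraints `K ≤ 10× max area` and `mu ≤ 50/h` guard runaway
fits; a fit pressed to within 0.1 % of a bound, or an optimiser failure,
returns best-effort parameters with `converged=False`, distinct from the
`InsufficientDataError` raised for fewer than 5 points or fewer than 3
distinct positive areas. Pre-emergence frames contribute zero-area points
by default (they anchor the lag phase); a fit-from-emergence mode is
available via `fit_track(..., pad_zeros=False)`.

Emergence (lag) time is the first sustained detection: the `time_h` of
the earliest recorded point from which the area stays at or above
`area_min_px2` for `persist_frames` (default 2) consecutive points. The
default area floor is the larger of the segmentation minimum (5 px²) and
the area of a 0.3-mm disk at the configured dpi — colonies below ~0.3 mm
are not reliably resolvable on a flatbed scan. The fitted `t50` and `mu`
are reported separately; "lag" in the output tables always means the
emergence time.

A plate's CFU count is the number of tracks with a defined emergence
time, excluding merged and edge tracks unless `include_flagged` is set
(merged colonies then count as their distinct pre-merge tracks, each
having arisen from a separate founder). Validity is the inclusive
interval 25 ≤ CFU ≤ 250 — "between 25 and 250" read inclusively, matching
plate-count conventions — and is config-overridable.

## Synthetic scenes and what they do (not) show

The generator renders the study conditions end to end: plates on a bed
(base intensity 0.45, a small linear shading ramp, a quadratic radial
vignette, darker bed outside the plates), colonies as radially symmetric
disks with a soft Gaussian edge (σ = 0.5 px) and uniform interior
contrast 0.35, additive Gaussian pixel noise (σ = 0.02), and per-colony
logistic growth. Defaults mirror a typical run: six 3-inch plates or a
single plate, ~50 colonies per plate (mid-range plating density, inside
the 25–250 validity window), scans every 15 min for 20 h, lag times
uniform on 5–8 h, rates 0.8–1.5 /h, saturation areas 3–12 mm². Each
colony's `t50` is placed so its analytic area equals the detection-limit
area (2 px², deliberately below the 5 px² emergence floor) exactly at its
lag time; before the lag it is not rendered and its true area is 0.
Placement is uniform over the plate disk minus an edge keep-out band,
rejection-sampled to a minimum centre spacing; a touching-scenario switch
instead places one pair closer than their final radii sum to exercise
merge handling. Identical seeds give bit-identical frames and truth.

The synthetic resolution defaults to 100 dpi — far below the 2400+ dpi of
real scanners — preserving geometry and statistics at image sizes the
test suite can afford; dpi is a free parameter throughout. Not modelled:
colony domes and halos, dust, scanner streaks, condensation, illumination
flicker, plate rim reflections, and non-Gaussian sensor noise. Passing
benchmarks therefore demonstrate the pipeline's correctness under
idealised contrast and noise, not robustness to every real-scan artefact;
the configurable thresholds (polarity, fixed thresholds, circularity,
margins) exist precisely because real plates will need them.

## Benchmarks and problem sizes

`colonytrack.evaluation` backs both the acceptance tests and
`scripts/acceptance.py` with identical code: the 6-plate layout capacity;
an exhaustive sweep of the validity rule over counts 0–10 000; count
exactness on 100 seeded scenes of 10–40 separated colonies scored at a
late frame; tracking identity on 50 series of 20–200 slow-growing
colonies at ≥ 10 px spacing over 17 half-hour frames; lag recovery for
100 colonies (two 50-colony plates at 15-min cadence over 12 h), a colony
counting as recovered when its emergence estimate is within one frame
interval plus its detection-limit delay (the time its rasterised true
area needs to reach the emergence floor — pixel quantisation holds tiny
disks below the floor for several frames, so this delay is read off the
recorded ground truth, not the continuous law); noiseless and σ = 5 px²
noisy logistic recovery on an 81-point grid; and byte-level CSV
determinism of two identical pipeline runs. Problem sizes were chosen so
the whole suite completes in a few minutes on one core while keeping
every per-scene condition (spacing, contrast, cadence) at its stated
value.

## Known limitations

- Merged colonies are censored rather than separated; plates far above
  the validity ceiling will lose many tracks to censoring.
- Greedy linking assumes near-stationary objects; it is not suitable for
  motile organisms on the same hardware.
- The surface background model is quadratic; strongly non-polynomial
  shading (e.g. sharp glare) should use `region_mean` with a clean patch
  or a fixed threshold.
- Animation export writes GIF or multi-page TIFF; these containers were
  chosen for dependency-light portability over MP4-class codecs.
- Timestamp parsing assumes timestamps within one day unless a full
  date-time format is given (clock rollover across midnight is not
  inferred from time-only stamps).
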