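# Methods

This note records the models and procedures implemented in
`dendrotrace`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic validation
does and does not demonstrate.

## Image model

All computation happens on a four-axis intensity record `I(t, c, x, y)`
(time, channel, row, column) with finite, non-negative intensities and
an optional physical pixel size in µm/px. Coordinates are `(row, col)`,
0-based, pixel centres on integer coordinates. Readers must declare the
source axis layout explicitly; a multi-page TIFF is never guessed to be
a time series versus a channel stack. ImageJ `.roi` conversion (polygon
and polyline records, big-endian, 64-byte header) happens only at the
file boundary.

## Medial axis

The centreline of a dendrite between two user-supplied endpoints is a
shortest-path problem. The frame is median-filtered (window
`filter_size`, default 7 px) and thresholded (default: the mean of the
filtered frame) into an admissibility mask. On admissible pixels the
traversal cost is

    step_cost(p) = 1 / (1 + d(p))

with `d` the Euclidean distance transform to the nearest inadmissible
pixel (the image border ring counts as inadmissible, so a fully
admissible frame falls back to border distance). An 8-connected edge
costs its geometric length (1 or √2) times the mean endpoint step cost.
This makes deep-interior pixels cheap while keeping all weights
positive, as Dijkstra requires; the functional form is monotone,
bounded and parameter-free. The search runs on a vectorized sparse
grid graph (`scipy.sparse.csgraph.dijkstra`); construction order is
fixed, so results are bit-stable across runs. Endpoints off the mask are
snapped to the nearest admissible pixel within 10 px, beyond which the
call fails rather than guessing.

When either image dimension exceeds 512 px, the mask is block-mean
pooled by the smallest integer factor `k` with `max(H, W)/k ≤ 512`
(occupancy re-threshold 0.5), the coarse solution is found there, and
the final path is re-solved at full resolution inside a corridor of
half-width `2k + 1` px around the upscaled coarse path — so the
returned path always lies on full-resolution admissible pixels and
stays within a couple of `k` of the unrestricted optimum.

The full-rank pixel chain is compressed to control points with
Douglas–Peucker (default tolerance 2 px): the minimal-deviation
realization of sampling the path at its major turning points. Linear
interpolation plus Bresenham rasterization recovers an 8-connected
chain within the stated tolerance (property-tested on random
polylines).

## Width profile and segmentation

Edges come from Canny applied to the median-filtered frame with
adjustable smoothing scale `gaussian_sigma` (default 2 px) and
hysteresis thresholds set as *quantiles* of the gradient magnitude
(0.90 / 0.98), restricted to a dilated neighbourhood of the
above-threshold region. Two remarks on this choice:

- running Canny on the *hard-thresholded* image would re-introduce the
  very speckle the median filter removed — every salt pixel surviving
  the threshold becomes a closed edge contour — and collapses at low
  SNR; Canny's own Gaussian stage is the principled place for the
  smoothing the threshold was standing in for;
- quantile hysteresis makes the detector invariant to the intensity
  scale and adapts it to the noise level. The defaults (window 7,
  quantiles 0.90/0.98) were chosen by a robustness sweep on the
  synthetic tube across noise levels, balancing low-SNR edge
  reliability against width accuracy on 6-px tubes.

At every full-rank path pixel an ellipse is grown with its semi-minor
axis (preset 2 px) along the local tangent and its semi-major axis
along the normal, iteratively enlarged until the boundary arc —
sampled at ≤ 1 px spacing over ±45° about the normal, separately per
side — touches an edge pixel. The finite arc is what guarantees
termination when the edge chain has small gaps that a single ray would
slip through. A side that reaches the cap (`max_semi_major`, default
30 px) without an edge is treated as a *missing measurement* and takes
the median of the measured points on that side; propagating the cap
value instead lets segmentation failures dominate the mask at low SNR.

Raw half widths are scaled by `width_multiplier` and then pass a
width-continuity condition: a running median over a 25-point window
along the path bounds each point to `median / (1+s) … median · (1+s)`
with `s = smoothing_strength` (default 0.5; `s = ∞` disables it). The
clamp is two-sided — upward excursions come from spines and filopodia,
downward dropouts from missed edges — and the window is deliberately
longer than two spine-head footprints so a spine cannot dominate its
own neighbourhood median. Flags record where the condition intervened.
The segmentation mask is the union of the per-point ellipses (always
containing the rasterized path), and per-(t, c) statistics cover width
in px and µm, luminosity along the axis and total mask luminosity.

Evaluation uses pixel-wise recall, precision and their harmonic mean
F1, with the convention that a zero denominator yields 0 unless both
masks are empty (then 1). The reference baseline is the "straight
dendrite": a chord of 2 µm physical thickness drawn between the
endpoints (a disc of the same radius when they coincide).

## Spine analysis

Spine centres arrive manually, from CSV, or from any detector callable
returning `(centre, confidence)` pairs; a confidence threshold filters
them (manual points carry confidence 1 and always survive). From a
centre `s0`, eight rays step along the cardinal and ordinal unit
vectors (diagonals Euclidean-normalized, so step *i* sits at radius
*i* in every direction). At each step the rules are evaluated on a
3-px-median-filtered view of the frame (a single noisy pixel should
neither halt nor extend a ray):

- luminosity drop-off: intensity below `drop_factor · l0`
  (`drop_factor` default 0.4, `l0` the seed luminosity);
- other-spine: the point is closer to another centre than to its own;
- dendrite: the point lies on the dendrite mask;
- fall-back: the step index exceeds `max_extent` (default 30 px).

Each violated rule increments the ray's counter once per step; the ray
halts when the counter reaches `n` (default 2), and the ROI edge is
the last point *before* the halting step — the reading consistent with
the bisector geometry of the other-spine rule and with the fall-back
rule producing a regular octagon of circumradius exactly `max_extent`.
Counters are independent across rays. The final head ROI is the
vertex-wise mean of five octagons grown from `s0` and its four
one-pixel cardinal perturbations (out-of-bounds or zero-luminosity
seeds are skipped).

In *luminosity mode* one ROI is grown on the per-pixel temporal
maximum projection (the spine's maximal extent over the period); in
*area mode* the ROI is regrown independently at every timepoint.
Backgrounds are placed by an outward spiral search (start 1.5× the
head circumradius, 2 px steps, 50 px limit) for the nearest position
where a translated copy of the head ROI overlaps neither any ROI nor
the dendrite.

Necks reuse the medial-axis machinery on a small crop between the
centre and the nearest dendrite pixel, with gentler Canny quantiles
(0.30/0.70): the faint neck sides must survive next to the much
stronger head and shaft boundaries inside the same crop. The neck
proper is the path portion outside both the head ROI and the dendrite
mask; its ROI excludes head pixels by construction. Failure — centre
already on the dendrite, no admissible path, or a free span shorter
than 3 px — is a reported absence, not an error, and such spines are
classed stubby (NW = 0). Classification uses NW = median width of the
free neck profile and HW = maximal caliper width of the head polygon:
NW = 0 → stubby, NW/HW < 0.5 → mushroom, 0.5 ≤ NW/HW ≤ 1.1 → thin
(boundaries read inclusively), NW/HW > 1.1 → outlier.

## Motion correction

Global drift is estimated per frame against a reference (t = 0 by
default) on one structural channel and undone by translation with zero
fill, integer-rounded unless subpixel resampling is requested; all
channels share the one estimate. The estimator is skimage's
`phase_cross_correlation` run on lightly smoothed frames (Gaussian
σ = 1.5) with the *unnormalized* cross-power spectrum: whitening
(phase normalization) amplifies high-frequency noise and already loses
integer shifts at moderate noise, while the plain spectrum recovers
the exhaustive ±10 px grid exactly at SNR 2 on the validation scenes.

Local correction crops a window (side 3× the head circumradius)
around each spine, flattens dendrite-mask pixels to the crop median —
the shaft's edge is translation-invariant along its own axis but not
across it, and would otherwise anchor the transverse component of the
spine's motion — and registers the crop per timepoint at 1/10 px
precision. Only the ROI (and recorded shift table) moves; pixel data
is never altered, so genuine morphological change stays visible.
User-supplied compensatory offsets (CSV of t, drow, dcol) add to the
local shifts.

## Puncta detection

Spots are scale-normalized Laplacian-of-Gaussian maxima
(`skimage.feature.blob_log`, 10 scales in `[σ_min, σ_max]`, defaults
1–5 px). Each ROI gets the adaptive threshold
`tR = max(ROI pixels) · γ/100`, with separate γ sliders for dendrite
and synapse/soma ROIs; an ROI whose maximum does not exceed the noise
floor (default: mean + 2 SD of the pixels outside all ROIs) is skipped
outright. Candidates outside the polygon are discarded (border centres
count as inside, even-odd rule); maxima sitting on the boundary of the
scale grid are rejected, since a boundary maximum cannot be certified
as a scale-space maximum — this is also what makes the size filter
sharp (a σ = 6 blob is not reported when `σ_max = 3`, even though its
response at σ = 3 can exceed a low threshold). Dendrites are scanned
through consecutive quadrilaterals, one per control-point segment,
spanning the local cross-section (segment-median half widths, mitred
shared edges); duplicates within `max(σ_i, σ_j)` across shared edges
keep the brighter member, and each punctum is annotated with its
arclength along the medial axis. Localization fractions are reported
per channel and compartment and sum to 1; an empty channel reports
undefined fractions rather than 0/0.

## Synthetic fixtures

The generator renders plateau-intensity structures so ground-truth
masks are unambiguous: tubes of known centreline and width (a nominal
width w around a pixel-centred line spans `2⌊w/2⌋+1` pixels; the
recorded truth width is that effective span), disc spine heads,
rectangular necks imaged dim at 0.30× the structure amplitude (thin
stalks are sub-resolution in practice), disc or Gaussian puncta, rigid
per-frame drift plus per-spine wander, then a dark pedestal
(min(0.12 · amplitude, 2 noise SD) — fluorescence backgrounds are
near-dark, and the cap keeps the pedestal below the luminosity
drop-off level), Gaussian noise with SD = amplitude/SNR, and optional
salt-and-pepper corruption. Identical spec + seed renders bit-identical
stacks. Empirical SNR is measured with quantile statistics (median
levels, 84th-minus-50th percentile spread) so floor clipping cannot
bias it.

The canonical gallery holds a straight tube, a curved tube, a
six-spine scene spanning all four classes, a crowded pair 6 px apart,
a soma + dendrite puncta field (8:2 split), a drifting 5-frame series
with one wandering spine, and an SNR ladder at 0.5/1/2/3/5. A separate
grid generator produces N well-separated bright disc puncta
(SNR 20, the bright single-molecule regime) for counting experiments,
and a curved spiny scene serves drift-recovery validation (a straight
tube is nearly translation-invariant along its own axis and cannot pin
the parallel shift component).

What passing on these fixtures shows — and what it does not: plateau
structures with sharp borders are kinder to edge detection than real
point-spread-function-blurred dendrites; Gaussian noise omits photon
shot noise; drift is rigid. Recovery numbers here are therefore upper
bounds on real-data performance, and the noise-robustness sweep
measures degradation trends, not absolute field performance.

## Problem sizes used in the validation suite

Fixtures are 96–220 px per side with single frames or 5-frame series;
the shortest-path oracle comparison uses 200 random 20×20 mazes against
an independent NetworkX Dijkstra; shift recovery sweeps the 25-point
integer grid spanning [−10, 10]²; puncta counting uses fields of 5, 20
and 50 spots. These sizes keep the full suite and the acceptance script
in the seconds-to-minutes range while exercising every code path,
including the > 512 px downsampling branch (via 513–600 px masks).

## Known limitations

- One start/end pair per dendrite; branch points are traced as separate
  paths.
- Neck tracing on noisy images fails (reported, not fatal) more often
  than head ROI generation; class recovery under heavy noise is
  correspondingly weaker than the clean-scene benchmark.
- 2D only; no z-stacks, no rotation/scaling in motion correction, no
  spot deconvolution or sub-pixel Gaussian refinement of puncta.
- The bundled detector interface accepts any external spine detector
  but none is shipped; centres come from the user or from files.
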