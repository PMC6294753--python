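# Methods notes

This note documents the models, parameter choices and numerical
conventions behind `octavld`, and what the synthetic phantoms do and do
not establish about real acquisitions.

## Quantification chain

**Vesselness.** The ridge filter is scale-normalized tubeness:
`V_sigma = sigma^2 * max(-lambda_2, 0)`, with `lambda_2` the
more-negative eigenvalue of the Gaussian-derivative Hessian (reflect
boundary handling). We use the single-eigenvalue form rather than a
two-ratio (Frangi-style) functional because it matches the behavior of
the classical ImageJ tubeness plugin this workflow descends from; the
response is non-negative, zero on constant images, and equivariant
under quarter-turn rotations away from the filter's border support
(~4 sigma). The two smoothing scales are `sigma = 3 px` (capillaries,
~9 um at the canonical 2.93 um/px) and `sigma = 15 px` (wide radial
vessels); both are interpreted as Gaussian sigmas in pixels on the
1024-px frame and are configurable via `PipelineParams`.

**Binarization.** The filter response is min-max rescaled to 8 bits
over valid pixels (mirroring the histogram behavior of 8-bit image
platforms) and thresholded by Otsu's criterion over the 256-bin
histogram: the threshold maximizes between-class variance over all 256
candidates; the foreground is strictly above threshold. When the
criterion plateaus (e.g. two-valued images) the threshold is the
plateau midpoint — this tie rule is part of the contract and is what
the exhaustive-search oracle in the tests applies. A constant image
yields an empty foreground with a logged warning. We threshold the
filter response, not the raw image; thresholding the raw image after
filtering is a plausible alternative reading of the original workflow,
but the response is where the vessel/background separation lives.

**Large-vessel removal.** The `sigma = 15` mask is cleaned by a
"remove outliers" step: each pixel brighter than the median of its
disc-shaped radius-15 neighborhood by more than 50 (on the 0-255
scale) is replaced by that median. Applied to the 0/255 binarized
stage this deletes small bright islands (mesh texture that leaks
through the coarse filter) while leaving wide vessel bands intact; the
result is rebinarized and subtracted from the initial binarized image
by plain set difference (no dilation before subtraction — the
cleaned mask already spans the vessel width, and dilation would eat
adjacent capillaries).

**Skeleton and length.** Thinning uses topology-preserving
skeletonization (connectivity-preserving, 1-px-wide output). Length is
link-based: an axial 8-neighbor link counts 1 px, a diagonal link
sqrt(2) px, each link split half-and-half between its endpoint pixels;
an isolated pixel counts 1 px. Because each pixel's contribution is
computed from the global skeleton and then assigned to the region
containing the pixel, region lengths are exactly additive over a
partition (the quadrant sums reproduce the annulus total to integer
link counts). The (1, sqrt(2)) chain metric systematically
overestimates the Euclidean length of oblique digital lines by up to
~8% (worst at 22.5 degrees); together with junction pixels in a dense
mesh this is the dominant, known bias of skeleton-based VLD and the
reason phantom recovery is validated at the 10% level rather than 1%.

**ROI geometry.** The measurement annulus (diameters 1.5/2.25 mm about
the disc center; 1/3 mm about the image center in repeatability mode)
is rasterized at pixel centers with the half-open radial condition
`r_in <= r < r_out`. Quadrants split the annulus at the 45-degree
diagonals with half-open angular intervals, so the four masks are
pairwise disjoint and union to the annulus exactly. For a right eye
(OD) in standard orientation the image-right sector is nasal; OS
mirrors. At the canonical scale the radii are exactly 256 and 384 px
and the rasterized annulus area is within 0.5% of
`pi * (384^2 - 256^2)`.

**Registration and intensity.** Cross-device registration is a
least-squares similarity transform (affine optional) from >= 4
landmark pairs — four pairs are required to mirror the manual
four-feature matching even though two determine a similarity. Warping
is bilinear for intensities and nearest-neighbor for masks; pixels
mapped from outside the source field are flagged invalid and excluded
from ROI statistics. Mean-intensity equalization is multiplicative to
a common target (default: mean of the input means); a positive scalar
cannot change relative ordering, so histogram-shape-based thresholds
(including Otsu after min-max rescaling) are invariant to it. Additive
equalization is the alternative we rejected: it can push intensities
negative and does change Otsu masks.

## Synthetic phantoms

The generator emulates what the chain needs to be tested end to end:
a dark disc (radius 0.55 mm) inside the 0.75 mm inner measurement
circle; five wide vessels (widths 0.07-0.11 mm, gently wiggling
radial courses) leaving the disc rim; and a capillary mesh modeled as
a square lattice with vertices jittered by ±0.35 spacing. The lattice
spacing is `2 * 1.041 / density`, where 1.041 is the analytic mean
edge elongation under that jitter, so the requested centerline density
(default 22 mm^-1, the middle of the range reported for healthy eyes
on commercial instruments) is realized within a few percent, and the
exact per-region ground truth is computable by clipping the polylines
against annulus/quadrant polygons. Large vessels are rendered with a
parabolic cross-profile (flat-top profiles create spurious
second-derivative edge ridges at the capillary scale that real,
smoothly shaded vessels do not show); capillaries are rendered at
their ~8 um width (3 px). Device profiles add Gaussian PSF blur,
multiplicative gain, additive Gaussian noise, a per-device fraction of
resolved capillaries, and a signal-strength draw; the four named
profiles follow the published per-device signal minima (25/50/50/7)
and the observed device ordering of measured VLD.

What the phantom does **not** model: flow-signal physics (SSADA /
OMAG / OCTARA), 3D slab segmentation and its errors, projection
artifacts, real vascular topology (arterio-venous structure,
capillary-free zones around arteries), or realistic intensity
distributions of OCTA speckle. Passing phantom tests therefore
establishes the correctness of the geometry, filtering, and
bookkeeping of the chain — not clinical accuracy on real images.

**Cohort simulator.** VLD tables follow an additive model:
grand mean + eye effect N(0, sigma_between) + device offset + location
offset + axial-length-group effect + scan noise N(0, sigma_within).
Defaults are n = 39 eyes, device offsets (0, -2, +1, -4) mm^-1 and
location offsets (0, +2.9, 0, +3.5) mm^-1 (temporal ≈ nasal >
superior ≈ inferior), sigma_between = 2, sigma_within = 1 mm^-1, a
grand mean of 20.6 mm^-1 (so the overall simulated mean matches the
~20.9 mm^-1 across-cell mean of the published summaries), and axial
length N(24.8, 1.1) mm, putting roughly 11 of 39 eyes in the >= 25.5 mm
group. The scan-rescan model is i.i.d. Gaussian noise on VLD; at the
defaults the eye-mean scan-rescan ICC is ~0.94, matching the
repeatability regime reported for these devices.

## Statistics

**ICC.** Computed from the two-way ANOVA mean squares
(MSR subjects, MSC raters, MSE residual):
`ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`,
with the McGraw-Wong F-based 95% CI (Satterthwaite df for the
absolute-agreement form). ICC(2,1) is the default because device and
scan comparisons are absolute-agreement questions; ICC(3,1) and the
average-measure forms are selectable. A zero-variance table is
rejected as degenerate rather than reported as 1.

**Repeated-measures GLM.** Implemented by the univariate approach via
orthonormal (Helmert) within-subject contrasts: each within effect
(instrument 3 df, location 3 df, interaction 9 df) is a transform of
the 16 cells; its F compares trace of the hypothesis SSCP for the
effect-coded intercept to trace of the residual SSCP, with
df = r * (N - p). With one between factor this reproduces the
classical split-plot Type III decomposition (verified against a hand
sums-of-squares oracle on balanced designs and against an independent
within-subjects ANOVA implementation), and effect coding keeps the
EMMs unweighted over the unbalanced axial-length groups. No sphericity
correction is applied by default, matching the uncorrected F
presentation typical of this literature. Degenerate fits (zero
residual trace) report F = inf with p = 0 when the effect is nonzero
and F = 0 with p = 1 otherwise. Pairwise EMM comparisons are
per-subject contrast scores tested by t against zero, per-comparison
(LSD-style) without multiplicity correction; Bonferroni can be applied
downstream by the caller.

**Correlations.** Pearson and Spearman are both exposed; analyses of
VLD against axial length default to Pearson in the report layer, but
the choice is the caller's — the literature this implements describes
the plan as Spearman and reports Pearson, a discrepancy we surface
rather than resolve.

**Report-layer rounding.** CVs to integers, VLD to one decimal, ICC to
two decimals; all computation is done in double precision and rounding
happens only at the reporting boundary.

## Problem sizes and determinism

All generators and the pipeline are deterministic for a fixed seed;
renders are bitwise reproducible. The test suite and the acceptance
script run phantoms at the full 1024 x 1024 frame and use 200
simulated-cohort replicates for the power estimate — sizes chosen so
the complete validation executes in a few minutes on one CPU while
keeping Monte-Carlo error on power estimates below ~2 percentage
points. One published summary cell (Spectralis, nasal) prints a CV of
14 where the printed mean/SD pair gives 13.5 -> 13 (presumably computed
from unrounded data); arithmetic-reproduction checks exclude that cell
and the exclusion is recorded in `reference.py`.

## Known limitations

* The chain measures pixel-intensity ridges; non-vascular texture that
  survives filtering is counted as vessel, so VLD is an upper bound in
  noisy images (mirrored in the phantom by noise-dependent recall).
* The chain-code length metric biases VLD upward by a few percent on
  oblique segments (a pure pixel-count mode is available for
  comparison studies).
* Saccade/shadow detectors are heuristics validated only on synthetic
  injections; they are not substitutes for human grading on real data.
* The GLM is the classical sums-of-squares decomposition; no REML
  mixed-model alternative is provided.
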