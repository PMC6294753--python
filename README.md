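# octavld

Quantification of peri-papillary capillaries on en face OCT angiography
(OCTA), and the agreement statistics needed to compare measurements
across instruments and repeated scans.

## The problem

OCTA renders perfused retinal vasculature without dye. Around the optic
disc, the density of the superficial capillary plexus is a biomarker for
glaucoma and other optic neuropathies — but every manufacturer uses its
own flow algorithm and slab segmentation, so measurements from different
devices need not agree. Assessing that requires (a) a common, device-
independent quantification chain applied to exported en face images, and
(b) repeatability/reproducibility statistics over eyes x devices x
scans. This package implements both, plus a ground-truthed synthetic
angiogram generator so the whole chain is testable without patient data.

## The quantification chain

For a disc-centered 3 x 3 mm en face image, resampled to the canonical
1024 x 1024 frame and registered across devices from >= 4 manually
matched landmarks:

1. **Vesselness** — scale-normalized Hessian tubeness
   `V_sigma(x) = sigma^2 * max(-lambda_2(x), 0)`, where `lambda_2` is the
   smaller eigenvalue of the Gaussian-scale Hessian. `sigma = 3 px`
   targets capillaries; `sigma = 15 px` targets the wide radial vessels.
2. **Binarization** — Otsu's threshold on the 8-bit-rescaled response
   (256-bin histogram, between-class variance maximization).
3. **Large-vessel removal** — the `sigma = 15` mask is cleaned with a
   median "remove outliers" filter (disc radius 15 px) and subtracted
   from the initial binarized image, leaving capillaries only.
4. **Skeletonization** — topology-preserving thinning to 1-px
   centerlines.
5. **VLD** — vessel length density, centerline length per unit area
   (mm^-1), computed on the four quadrants (superior / nasal / inferior /
   temporal, split at the 45-degree diagonals) of the annulus between
   the 1.5 and 2.25 mm circles centered on the disc; or on the whole
   ring between the 1 and 3 mm circles for scan-rescan repeatability.

Skeleton length uses link-based accounting: axial neighbor steps count
1 px, diagonal steps sqrt(2) px, each link shared between its endpoint
pixels, so quadrant lengths add exactly to the annulus total.

## The statistics

* **CV** `100 * SD / mean` between subjects, and per-eye between a pair
  of instruments (summarized mean ± SD across eyes);
* **ICC(2,1)** — two-way random-effects, absolute-agreement, single-
  measurement intraclass correlation with F-based 95% CI (ICC(3,1) and
  average-measure forms selectable);
* **repeated-measures GLM** — within-subject factors instrument and
  location, between-subject factor axial-length group (cut at 25.5 mm),
  estimated marginal means and pairwise EMM comparisons;
* **Pearson / Spearman** correlations of VLD with axial length.

Quality screening encodes the eligibility rules (>= 3 saccades or a
dark shadow patch, decentration, signal strength below the per-device
minimum — 25 Spectralis, 50 Optovue, 50 Triton, 7 Cirrus) as a
deterministic rule engine, with optional pixel-based saccade/shadow
detectors validated on synthetic injections.

## Worked example

```python
from octavld import (NetworkConfig, generate_vessel_network, render_angiogram,
                     DEVICE_PROFILES, quantify_eye, CohortSpec, simulate_cohort,
                     rm_glm, icc)
from octavld.synthetic import CAPILLARY, quadrant_geometries

network = generate_vessel_network(seed=1, config=NetworkConfig())
image = render_angiogram(network, DEVICE_PROFILES["Triton"], seed=3)
quads = quadrant_geometries(network.disc_center_mm, 1.5, 2.25, "OD")
for m in quantify_eye(image, eye_id="phantom"):
    gt = network.region_length_mm(quads[m.location], CAPILLARY) / quads[m.location].area
    print(f"{m.location:9s}  VLD = {m.vld:5.2f} mm^-1   (ground truth {gt:5.2f})")
```

```
superior   VLD = 22.41 mm^-1   (ground truth 21.67)
nasal      VLD = 21.55 mm^-1   (ground truth 22.14)
inferior   VLD = 22.95 mm^-1   (ground truth 22.36)
temporal   VLD = 22.75 mm^-1   (ground truth 21.99)
```

The measured quadrant VLD tracks the polyline-clipping ground truth of
the phantom within a few percent, in the range (15-26 mm^-1) reported
for healthy eyes on commercial devices. On a simulated 39-eye cohort
with the default device/location effect structure:

```python
df = simulate_cohort(CohortSpec(n_eyes=39, seed=1))
glm = rm_glm(df[df["scan"] == 1])
print(glm.anova[glm.anova.effect.isin(["instrument", "location"])].to_string(index=False))
```

```
    effect          F  df1  df2            p
instrument 571.148065    3  111 2.734103e-67
  location 357.624033    3  111 7.137512e-57
```

i.e. both the instrument and the location systematically shift VLD,
while the axial-length group does not (p = 0.32 in the same fit).

A console script exposes the same operations
(`octavld simulate image|cohort`, `octavld quantify`, `octavld screen`,
`octavld agree`); see `octavld --help`.

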