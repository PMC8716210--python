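# Methods

## Problem and model

A macular hole is a full-thickness interruption of the neurosensory
retina at the fovea. On a single OCT B-scan (depth × lateral position,
row 0 at the vitreous side) the retina is a bright band between the
inner retinal surface and the outer retinal boundary; the hole is a
hypo-reflective gap inside that band, centred on the foveal
depression. `mhseg` treats segmentation as a fusion of two weak cues:

* **region cue** — multilevel thresholding assigns each pixel to one of
  K+1 reflectivity classes; hole lumen and vitreous share the darkest
  class, and band containment disambiguates them;
* **boundary cue** — Sobel-derivative edges vet each dark component: a
  real hole has walls, so a minimum fraction of its boundary must lie
  near detected edges.

Candidates are scored `area · edge_support · exp(−|c − c_fovea|/(W/8))`.
The exponential encodes the clinical prior that holes arise at the
fovea as a soft preference; `W/8` (28 px at the working width) makes a
candidate a full quarter-width off-fovea pay a factor ≈ `e⁻²` while
leaving genuinely eccentric holes detectable.

## Pipeline stages and parameters

Stage order: standardize → denoise → derive → threshold → band →
fovea → candidates → select → refine. Resizing precedes filtering so
the filter window is scale-consistent. All defaults below are exposed
as config keys / CLI flags.

| parameter | default | units | role |
|---|---|---|---|
| `target_size` | 224×224 | px | standardized working geometry |
| `window` | 5 | px | adaptive-filter window (odd) |
| `noise_variance` | estimated | intensity² | speckle floor `v_n` |
| `rel_threshold` | 0.2 | — | edge map cut, fraction of peak `|∇L|` |
| `k` | 3 | — | thresholds (4 classes: vitreous, inner/outer retina, RPE) |
| `bins` | 256 | — | histogram resolution |
| `min_area` | 25 | px | smallest plausible hole after resize |
| `min_edge_support` | 0.1 | — | boundary fraction within 2 px of an edge |
| `decay_frac` | 8 | — | foveal decay constant = width/8 |
| `connectivity` | 8 | — | component connectivity (4 splits speckled blobs) |

**Denoiser.** Local-statistics adaptive (Lee/Wiener) filter,
`out = m + max(0, v − v_n)/max(v, ε)·(in − m)`, replicate padding
(zero padding draws dark halos at scan borders). It is applied in the
intensity domain by default, keeping the pipeline monotone in
intensity; `log_domain=True` gives log → filter → exp for
multiplicative fidelity. `v_n` is estimated as the mean variance of
the lowest-variance decile of non-overlapping 16×16 tiles —
background-dominated tiles in a B-scan are flat, so their variance is
essentially noise. 16×16 tiles keep the per-tile variance estimate
tight enough (≈9% relative s.d.) that the low-decile selection bias
stays well under the estimate itself.

**Edges.** The 3×3 Sobel pair is applied by *correlation* (no kernel
flip) with replicate padding; magnitude and direction are
flip-invariant, so downstream stages do not depend on the convention.
The erf blurred-step model
`f(x) = (Ir−Iℓ)/2·erf((x−x₀)/(σ√2)) + (Ir+Iℓ)/2` provides sub-pixel
edge localization on scanlines; the transition is reported as
`x₀ ± 2σ` (≈95% of the intensity swing). The fit initializes
`Iℓ`/`Ir` from first/last-quartile means, the centre at the
max-|gradient| sample, `σ = 1`, with `σ` bounded in [0.3, len/2].

**Thresholding.** Default criterion: exhaustive multilevel Otsu
(between-class-variance maximization over all increasing K-tuples of
bin boundaries; vectorized for K ≤ 3, explicit enumeration above).
Ties break to the lexicographically smallest tuple, so results are
deterministic even on histograms with empty gaps. Otsu levels are
reported as bin edges (exact on quantized data); valley levels as bin
centres (the valley is a bin). The valley rule — smooth with a 5-bin
moving average, take the K+1 most prominent peaks, cut at the leftmost
minimum strictly between consecutive peaks — is faithful to classical
practice but brittle on speckled histograms, hence the automatic
fallback to Otsu when too few modes survive.

**Band tracing.** Per column, top/bottom are the first/last
non-background rows, median-filtered over 7 columns. Columns with no
foreground, *or with less than 25% of the median column's foreground
count*, are marked invalid and their band rows linearly interpolated
from valid neighbours. The count rule matters: at a full-thickness
hole's rim, lateral blur bleed from the hyper-reflective RPE leaves a
thin bright sliver that would otherwise anchor the interpolated band
tens of pixels below the true inner surface.

**Fovea.** Thickness (bottom − top) is smoothed over 7 columns and
minimized over valid columns in the central half of the width; ties go
to the column nearest the centre. When the global minimum falls
outside the central half the central-half minimum is still used and
the segmentation is flagged (`fovea_off_center`) in provenance.

**Refinement.** Closing (3×3 cross) bridges speckle pits, hole-filling
removes enclosed background, and opening-by-reconstruction (cross
erosion + geodesic reconstruction) deletes components too thin to
survive erosion while leaving surviving shapes intact — a plain
structural opening would clip convex corners. The result is clipped to
strictly-inside-band.

## Features and metrics

Shape features: area, base width (max per-row extent), minimum
diameter (min per-row extent over strictly interior rows; all rows for
masks under three rows tall), height, aspect, circularity
(`4πA/P²` with the weighted contour-length perimeter — a raw
boundary-pixel count overestimates curved contours), centroid.
Circularity is advisory, never a filter.

Metrics are pixel-wise: accuracy `(TP+TN)/N`, sensitivity
`TP/(TP+FN)`, Jaccard `TP/(TP+FP+FN)`, `DSC = 2TP/(2TP+FP+FN)`.
Sensitivity on an image with an empty truth mask is undefined and
reported as missing — report means exclude it rather than averaging in
zeros. Feature selection is unsupervised (no labelled criterion is
available): drop zero-variance columns, rank by variance of min-max-
scaled values, and greedily keep features whose absolute pairwise
correlation with everything already kept is ≤ 0.95.

## Synthetic phantom

The phantom emulates a standardized fovea-centred B-scan: background
0.05; five sublayers at reflectivities (0.65, 0.45, 0.55, 0.40, 0.90)
between rows 60 and 150 (the last is the RPE); a Gaussian foveal pit
(depth 25 px, σ 12 px) carved into the inner surface; optionally a
full-thickness hole (default 30 columns, centred on the pit) cut to
background and recorded pre-noise as the truth mask; optional vertical
shadow columns (vessel shadowing); multiplicative gamma speckle with
mean 1 and variance 1/looks (the fully-developed-speckle model;
default 8 looks, `None` disables it); then a 1-px Gaussian blur for
the detector PSF, and a clip to [0, 1].

Truth defined pre-noise means the evaluation measures recovery of the
latent object. What the phantom does **not** emulate: physical OCT
forward modelling (coherence, A-scan PSF, depth attenuation), retinal
curvature, cysts, epiretinal membranes, lamellar holes, real vessel
shadow texture. Passing the phantom suite therefore demonstrates that
the pipeline recovers a layered-band-with-gap geometry under speckle,
blur and shadows — not clinical-grade performance on patient scans,
which additionally depends on pathology variety and scanner
characteristics the phantom cannot represent.

## Study sizes and numerical choices

The recovery studies use 30-scan cohorts (hole and hole-free) at the
default conditions and 20-scan cohorts per speckle level for the noise
sweep — large enough for stable medians while keeping a full run of
suite plus acceptance script around a minute on one CPU. Determinism
is end-to-end: every tie-break is specified (leftmost/lexicographic),
the only randomness is the phantom seed, and two runs on the same
input produce bit-identical masks.

Degenerate inputs are contracts, not crashes: constant images are
valid (standardize maps them to zeros; the noise estimate returns 0),
histograms with fewer occupied bins than classes raise a degenerate-
histogram error, an all-background class map raises a no-retina error,
and an empty candidate list is a valid "no hole" outcome, not an
error.

## Known limitations

* Single 2-D B-scans only; no volumetric linkage across slices.
* The darkest-class rule assumes the hole lumen is as dark as the
  vitreous; partially fluid-filled or lamellar defects with
  intermediate reflectivity may be missed.
* The candidate score's weights (edge-support threshold, foveal decay)
  are heuristic and exposed as config; they were chosen for the
  phantom geometry and should be revisited for clinical material.
* Illumination is handled only by global min-max normalization; no
  illumination-field fit or B-scan flattening.
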