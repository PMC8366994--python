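# Methods

This note documents the models, parameters and numerical choices behind
`globquant`, and what the synthetic-data tests do and do not establish.

## Physical calibration and coordinates

All measurements are physical: areas in µm² (globules) or mm² (tissue),
densities per mm².  The single calibration input is `mpp`
(microns per pixel, isotropic), read from the Aperio `MPP` field of the
TIFF ImageDescription, else from TIFF resolution tags, else a
configurable default of 0.50 µm/px (the nominal 20× scan regime) with a
logged warning.  Coordinates are 0-based `(x, y)`, x right, y down,
half-open rectangles, always expressed at pyramid level 0.  Tiled
processing uses a stride of `tile − overlap`; edge tiles are clipped,
never padded.

## Tissue detection

The biopsy must be separated from the near-white slide background
because every burden metric is normalised to the tissue area actually
present.  No single standard exists for this step, so a conventional,
fully parameter-exposed approach is used: the image is downsampled
(default 4×; tissue-scale structure does not need full resolution),
the background white point is estimated as a high percentile of HSV
luminance (default 95th), and tissue is any pixel that is chromatic
(saturation > 0.08) or clearly darker than the background
(< 0.75 × white point).  Morphological closing (20 µm radius), hole
filling and small-object removal (< 0.005 mm²) regularise the mask.
Tissue area is `pixels × (mpp × downsample)² / 10⁶` mm².

Specimen adequacy follows the source cohort's rule (core ≥ 12 mm,
≥ 10 portal tracts): length is measured as the largest component's
major axis; the portal-tract count cannot be computed from the image
and is consumed as optional metadata.  Failing specimens are flagged,
never silently dropped.  Whether area normalisation should exclude
tears/folds is ambiguous on real material; an artifact mask can be
supplied by eroding or editing the exported mask PNG.

## Stain separation

Brightfield staining follows Beer–Lambert: `I = I0·10^(−Mᵀc)` with `M`
rows the unit absorbance vectors of the stains.  `OD = −log10((I+ε)/I0)`
is clipped to [0, 3]; unmixing is the per-pixel 3×3 solve, with 2-stain
matrices completed by the orthogonal residual direction (cross
product).  Negative concentrations — noise or model mismatch — are
clipped to 0, which is tolerable because all downstream decisions
threshold the positive channel.

Default vectors: hematoxylin (0.650, 0.704, 0.286) and DAB
(0.268, 0.570, 0.776) from the classical deconvolution literature; for
PAS-D magenta no canonical vector exists and the default
(0.175, 0.972, 0.155) is the green-absorbing magenta used by the
synthetic renderer (which composites through the same forward model,
guaranteeing invertibility).  For real material whose staining deviates
from these, `estimate_stain_vectors` calibrates a matrix from
user-supplied pure-stain patches as the unit median OD direction over
pixels with total OD > 0.05.

## Inclusion (globule) analysis

The PAS-D channel is thresholded (default OD ≥ 0.25) inside the tissue
mask.  Speckle is removed by opening **by reconstruction** (erosion by
a 1-px disk, then geodesic reconstruction): objects that vanish under
erosion are dropped, while survivors keep their exact pixel sets, so
measured areas carry no boundary-shaving bias.  Touching inclusions are
split by a watershed on the Euclidean distance transform, with markers
from `peak_local_max` (minimum separation = one small-globule radius).
`segment_candidates` returns the basin **label map** rather than a
binary mask: a 1-px watershed line does not disconnect basins under
8-connectivity, and erasing line pixels would bias areas; returning
labels preserves both the split and every pixel.  Unsplit masks are
labeled with 8-connectivity.

Particles are filtered by physical area (default 2–1000 µm²) and
circularity `4πA/P²` computed with the contour-weighted perimeter
estimator and capped at 1.0 (raw pixel-edge perimeters bias small
rasterised objects upward).  Whole-slide runs tile at full resolution
with overlap = one maximum-globule diameter; particles touching an
interior right/bottom tile edge are deferred to the neighbouring tile
that sees them whole, and duplicates from the overlap band are removed
by centroid proximity (closer than the smaller equivalent radius).

Because well-tuned size/circularity cut-offs are lab-specific, five
candidate parameter sets (`alg1`…`alg5`, a grid over minimum area
{1, 2, 4} µm² × minimum circularity {0.3, 0.5}) ship as defaults and
`compare_algorithms` ranks them against observer-averaged manual ROI
measurements by Lin's CCC.  CCC ties are broken toward the candidate
with the wider acceptance window (area range × circularity range), i.e.
the one that rejects least freely.  A pathologist-style P-score
(P0 none / P1 < 5 / P2 5–20 / P3 > 20) can be derived from the globule
count; this counts globules as affected-cell proxies and is documented
as an approximation for cross-walking only.

The reported `%area` sums accepted-particle areas (not raw
suprathreshold pixels); the two differ only by rejected particles and
the choice is recorded here because either convention is defensible.

## IHC quantification

DAB positivity is a fixed OD threshold (default 0.15) on the
deconvolved DAB channel; only the binary positive-area fraction is
reported, never intensity-weighted quantity, because chromogen
deposition is not stoichiometric with protein.  Positive staining that
hugs the tissue boundary is a known artifact of AAT IHC, so the tissue
mask is eroded by a physical margin (default 50 µm) before counting,
and a QC flag is raised when the boundary band's positive fraction
exceeds 2× the interior's.  Specimens excluded by judgement in the
source workflow map to these QC flags plus a manual exclusion list in
the config.  Foci counting (Annexin V) labels DAB-positive components
and keeps those within a physical size band (default 5–2000 µm²),
reported per mm² of tissue.

Total-AAT and polymer fractions are independent measurements; no
per-slide invariant relates them.

## Cohort statistics

* **Lin's CCC** uses population (1/n) moments,
  `ρc = 2s_xy/(s_x²+s_y²+(x̄−ȳ)²)`; the 95% CI applies Lin's asymptotic
  variance to the Fisher z-transform.  Degenerate cases: two constant
  equal vectors → 1; constant vs varying → 0.
* **High accumulators**: linear-interpolation quantiles (numpy default,
  R type 7 — the original statistics program's convention is unknown and
  fence-dependent counts can differ by ±1 subject between conventions);
  upper fence Q3 + 1.5·IQR, flag at ≥ fence.  When IQR = 0 no one is
  flagged (otherwise every subject would be).
* **Group comparisons**: D'Agostino–Pearson per group (reported; needs
  n ≥ 8, NaN below), Mann–Whitney U (two-sided) for 2 groups,
  tie-corrected Kruskal–Wallis with Dunn's z post-hoc for ≥ 3.  Dunn's
  p-values are two-sided normal with no family-wise adjustment by
  default (Bonferroni available), matching common defaults for "Dunn's
  multiple comparisons".  The log10 path excludes zeros with a logged
  count (the convention for the occasional zero-burden subject is
  otherwise undefined) and runs one-way ANOVA with Tukey HSD.
  All-tied inputs return statistic 0, p 1 rather than erroring.
* **Summaries**: median and IQR per stratum, fold change as the ratio
  of adjacent ordered-stratum medians; columns passing normality are
  additionally reported as mean ± SD.

## Synthetic data

The slide renderer emulates a scanned stained biopsy at 0.5 µm/px: a
wobbled-ellipse tissue core (aspect 3:1), hematoxylin with smooth
texture, globules as rasterised disks with log-normal areas (median
10.31 µm², ln-σ 0.45 — the burden regime of the emulated cohort, where
a median-size globule is only ~40 px and deliberately near the
resolution limit), composited through the same Beer–Lambert forward
model the separation module inverts, plus Gaussian sensor noise
(σ = 2 grey levels).  Truth is exact by construction: the manifest
records the *rendered* tissue pixel area, each globule's raster area
and its post-overlap placed area, and the union total.  Placement is
non-touching by default (pairwise gap > √2 px, so rasters are never
8-connected); a configurable fraction can be forced to touch to
exercise watershed splitting, and a clustering factor concentrates
placement.  DAB mode marks a quantile region of a short-correlation
smooth field (so the positive fraction of any large sub-region tracks
the whole-tissue fraction) and/or places foci disks.

The cohort generator draws per-subject measurements log-normally around
stage-wise medians (PAS-D %area defaults 0.004 / 0.011 / 0.019 / 0.056 /
0.28 for F0–F4; polymer 0.5–12%; total-AAT median 19%), with
multiplicative sex (×1.95, applied symmetrically) and degeneration
(×7.5) effects, within-stage spread σ = 0.55 log10, 35% male, and foci
densities of 0.90 vs 0.58 /mm² by degeneration status.  These defaults
are the study conditions the generator emulates, not tuning knobs.

**What passing tests show** — that the measurement chain (masking,
deconvolution, splitting, filtering, physical-unit arithmetic, seam
handling, statistics) is correct against exact truth.  **What they do
not show** — robustness to real-slide phenomena the renderer omits:
nuclei and portal structure, stain gradients and batch variation,
folds, tears, out-of-focus regions, non-disk globule shapes.  Real
deployments should recalibrate stain vectors and re-validate filter
candidates against manual measurements via the `validate` workflow.

## Problem sizes and numerics

Test and acceptance slides are 1150²–2200² px (0.25–1.0 mm² tissue), a
deliberate scale-down from full biopsy scans chosen so the whole
suite exercises every code path, including multi-tile runs, in minutes;
the per-pixel operations are identical at any size.  The acceptance
grid spans globule-area fractions 10⁻⁵–4×10⁻³ of tissue, with low
fractions produced by sparsity (one typical-size globule in a large
tissue area), matching how low-burden biopsies actually present.  The
Mann–Whitney calibration uses 2000 null replicates at n = 30/group.
All simulations are seeded; identical inputs and parameters reproduce
outputs bit-exactly on a given platform.  ε = 10⁻⁶ guards the OD
logarithm; OD is capped at 3; stain vectors must be unit-norm within
10⁻⁶ and pairwise ≥ 1° apart.
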