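# globquant

Whole-slide quantification of alpha-1 antitrypsin (AAT) accumulation in
liver biopsies.

In alpha-1 antitrypsin deficiency (AATD), misfolded PiZ-variant AAT
polymerises in the hepatocyte endoplasmic reticulum and accumulates as
inclusion bodies that stain magenta with Periodic Acid–Schiff after
diastase digestion (PAS-D), and as polymer detectable by
immunohistochemistry (IHC) with the DAB chromogen.  Pathologists grade
this burden on a coarse ordinal scale (P0–P3); `globquant` replaces the
ordinal grade with continuous whole-slide morphometry for researchers
studying the relationship between polymer burden and liver fibrosis:

* **PAS-D inclusion analysis** — tissue is separated from the slide
  background, the PAS-D channel is recovered by color deconvolution
  (Ruifrok–Johnston, Beer–Lambert optical-density model), touching
  inclusions are split by a distance-transform watershed, and particles
  are filtered by physical size and circularity (4πA/P²).  Per-specimen
  outputs: `%area` (globule area as % of tissue area), globules/mm²,
  and globule-size statistics in µm².
* **IHC positive-pixel analysis** — DAB-positive area as % of tissue for
  polymer-specific and total-AAT staining (edge-artifact suppression by
  physical-margin erosion, with QC flags), and stained-foci density per
  mm² (e.g. Annexin V).
* **Validation** — candidate particle-filter parameter sets are ranked
  against manual region-of-interest measurements with Lin's concordance
  correlation coefficient ρc = 2s_xy / (s_x² + s_y² + (x̄−ȳ)²).
* **Cohort statistics** — D'Agostino–Pearson normality gating,
  Mann–Whitney U, Kruskal–Wallis with Dunn's multiple comparisons,
  log10-ANOVA with Tukey HSD, median/IQR summaries with fold changes,
  and "high accumulator" classification by the Tukey upper fence
  (value ≥ Q3 + 1.5·IQR).
* **Synthetic slides** — a forward-model renderer produces
  brightfield-like biopsy images with pixel-exact ground truth (tissue
  area, per-globule sizes, DAB fraction, foci), so every stage of the
  pipeline is testable without patient data.

## Worked example

Render a synthetic PAS-D slide with known truth, then quantify it:

```
$ globquant simulate slide --seed 1 --n-globules 30 --tissue-area-mm2 0.2 --out sim
wrote sim/synthetic_pasd_seed1.tiff (tissue 0.144 mm2, truth pct_area 0.23980%)

$ globquant pasd --slide sim/synthetic_pasd_seed1.tiff --out results.csv
synthetic_pasd_seed1: pct_area=0.23899% n=30 tissue=0.145 mm2
```

The measured burden (0.23899 % of tissue area, 30 globules) recovers the
renderer's truth manifest (0.23980 %, 30 globules) to ~0.3 % relative
error; `results.csv` holds one row per metric (`pct_area`,
`count_per_mm2`, `n_globules`, `median_size_um2`, `tissue_area_mm2`).
The rendered tissue (0.144 mm²) can be smaller than requested when the
elongated core does not fit the canvas; the truth manifest always
records the rendered area.

Cohort-level statistics from a per-subject table (synthetic here; a
real table binds its column names in the YAML config):

```
$ globquant simulate cohort --seed 1 --n-subjects 89 --out cohort.csv
$ globquant cohort --table cohort.csv --out stats
kruskal_wallis: statistic=36.38 p=2.4e-07; 16 high accumulators
```

`stats/` then contains `summary_by_stage.csv` (n, median, IQR, fold
change per METAVIR stage) and `comparisons.json` (stage and sex
comparisons with Dunn post-hoc pairs, and the high-accumulator fence
and membership).

Other subcommands: `globquant ihc --stain polymer|total|annexin` for
IHC quantification and `globquant validate` for the CCC ranking of
candidate algorithms against manual ROI measurements.  Every command
writes its fully resolved parameters as YAML next to its outputs.

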