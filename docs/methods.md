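# Methods

## Assay model

The pipeline quantifies pathway activation of transfected variants through
reporter translocation. One cell's readout is the nuclear-to-cytoplasmic
ratio (NCR) of reporter fluorescence. Aggregation is hierarchical and robust
at the level where outliers live: the **median** NCR over a well's
transfected cells defines the well, the **mean** over the (nominally six)
replicate wells defines the condition. Activity is the affine rescaling of
the condition NCR onto the wild-type (0%) / known-activating-mutation (100%)
scale; the 20% cutoff defines the active call, and the same cutoff applied
across a 6-point log-spaced dose series defines the inhibition call.
Patient-level prediction follows three ordered rules: amplification-based
treatments resolve against a literature table; patients with no active
MTA-targeted variant are negative; otherwise the dose-response outcome of
the patient's full co-transfected variant set decides.

## Synthetic plates

No raw images from the assay are public, so the generator fabricates wells
with known ground truth. It emulates: per-cell NCR sampled from a
condition-specific log-normal (median = condition level, log-sd 0.15),
six replicate wells per condition, partial transfection (default 50%, so the
transfection gate is always exercised), touching cells (minimum centre
separation 1.6 × mean cell radius, i.e. below one diameter), flat background
(100 ADU), additive Gaussian read noise (6 ADU), optical blur (Gaussian,
σ = 0.8 px) and 16-bit clipping. Cells are disks (radius 12 ± 1.5 px) with
concentric half-radius nuclei; the nuclear channel carries a bright nuclear
disk plus an 8% whole-cell body (out-of-focus light) so untransfected cells
remain segmentable; in the reporter channel a transfected cell's nuclear and
cytoplasmic plateaus are set so their ratio equals the sampled NCR exactly
before blur and noise. Optional sub-nuclear debris specks exercise
refinement.

Deliberately not modelled: realistic cell morphology and texture,
illumination vignetting, photobleaching, Poisson shot noise, 3-D optics,
plate-edge effects. Passing recovery tests therefore demonstrates that the
measurement chain is unbiased under the stated geometry and noise, not that
it would segment real adherent-cell images; on real data the morphology
rules and thresholds would need recalibration.

Default well scale in the analysis scripts and recovery tests is 400 cells
in a 768 × 768 px field (≈ 200 transfected cells per well, six wells per
condition) — enough for the well median's sampling error to sit well inside
the 10% recovery tolerance while a 7-condition plate (42 wells) analyses in
about a minute.

## Image analysis

1. **Enhancement** — background field estimated by a large-kernel grey
   opening (min- then max-filter, 96 px window ≈ 8 × cell radius), smoothed,
   subtracted; residual flat offset removed as the image median (valid while
   background pixels are the majority); mild Gaussian denoise (σ = 0.5);
   clamped at zero.
2. **Foreground detection** — Gaussian mixture (default 3 components, full
   covariance) over per-pixel log-intensity vectors of both channels, fitted
   by EM on a 50 000-pixel subsample with k-means initialisation and a fixed
   seed; the dimmest component is background, all brighter components are
   foreground. Three components leave room for the dim untransfected cell
   body between background and bright structures. The mask is opened with a
   2 px disk and hole-filled: the blurred halo at object edges and thin
   bridges to debris otherwise get annexed by the watershed and dilute
   cytoplasm measurements.
3. **Segmentation** — nuclei are nuclear-channel pixels above 0.5 × the
   channel's bright level (99th percentile inside the mask); this relative
   threshold is robust where a per-channel mixture model is not, because the
   nuclear stain's intensity classes vary with plating density. The nuclear
   region is opened with a 3 px disk so noise speckle and sub-nuclear debris
   cannot seed cells. Local maxima of the smoothed nuclear channel
   (min-distance 10 px) seed a watershed over the inverted sum of the
   min-max-normalised smoothed channels ("cross-spectral": both channels
   shape the topography), restricted to the mask. Nucleus labels are the
   nuclear-bright pixels of each cell, making nucleus ⊆ cell structural.
4. **Refinement** — objects violating any morphology bound (cell area
   150–2500 px², nucleus area 30–700 px², eccentricity ≤ 0.95, solidity
   ≥ 0.65, nucleus/cell area ratio 0.05–0.85; all configurable) are removed
   with their nuclei; survivors are relabelled 1..k in raster-scan order.
   The bounds were calibrated once against the generator's default geometry.

## Quantification choices

- Compartment means are taken on the enhanced reporter channel. The nucleus
  is eroded by 2 px and the cytoplasm excludes a 2 px ring around the
  nucleus **and** the outermost 3 px of the cell: blur moves nuclear signal
  outward and the segmented outline rides the intensity edge, so un-eroded
  compartments bias the ratio by 20–30%; with erosion the bias is ≈ 1–2%.
- Cells whose cytoplasm mean is ≤ 1 intensity unit are excluded with a
  reason code rather than capped — unbounded ratios would dominate a mean
  but silently distort even a median.
- Transfection gate: whole-cell mean reporter > background mean + 5 sd
  (background estimated from non-cell pixels). With the default expression
  contrast the gated fraction tracks the simulated transfection rate within
  a few percent.
- Wells need ≥ 50 usable transfected cells (flagged invalid otherwise,
  excluded with a log entry); a condition needs ≥ 3 valid wells (error
  below that, warning between 3 and 6).

## Statistics

- Activity significance: two-sided two-sample t-test over well medians,
  Welch form by default (replicate-well variances need not be equal); the
  pooled-variance form is a config option. The p-value is reported alongside
  the score but does not gate the active call — the printed decision rule is
  the 20% cutoff alone.
- Inhibition: "activity below 20 at any dose" is read on the absolute
  activity scale, the same scale as the activation cutoff. The alternative
  reading — below 20% of the untreated activity — is available as
  ``mode="relative"``.
- Scores are not clamped; values < 0% or > 100% are reported as computed.
- Kruskal–Wallis: mid-ranks with tie correction 1 − Σ(t³−t)/(N³−N), p from
  the χ² approximation with k−1 df (what standard software does even at
  n = 12); an exact two-group permutation p-value is available.
- Kaplan–Meier: product-limit estimator (via lifelines); the packaged cohort
  has no censoring (every patient progressed) but censoring is supported.
- Reported medians are rounded half-up to one decimal. Note: the cohort's
  negative-group PFS values {3.7, 1.3, 3.7, 1.5, 1.1, 1.9, 2.3, 1.6} have
  sample median 1.75, which this convention reports as 1.8; the value 1.7
  sometimes quoted for this group is not reproducible from the one-decimal
  PFS values themselves (it likely reflects medians taken on unrounded
  survival times). The pipeline reports 1.75/1.8 and documents the
  discrepancy instead of forcing agreement.

## Cohort fixture and decision tables

The 12-patient cohort ships as a one-row-per-(patient, variant) CSV with the
per-variant activity calls and treatment basis; amplification-based
treatments (patients 1, 9, 11) carry the amplified-gene alteration used by
the literature lookup. The literature table has the single grounded entry
(ERBB2 amplification + lapatinib/trastuzumab → positive); unmatched
amplification regimens default to negative. The drug → gene-target map
(sorafenib → FLT3/PDGFRA/KIT/RAF; imatinib → KIT/PDGFRA; vemurafenib → BRAF;
lapatinib/trastuzumab → ERBB2(/EGFR); erlotinib → EGFR) is an editable CSV.
Resistance co-mutations (KRAS, NRAS, PIK3CA) are not hard-coded rules: they
act through the dose-response outcome of the co-transfected combination or
through the targeted-variant-activity rule. Dose-response curves for the
four assay-tested combinations are a synthetic fixture encoding only the
qualitative outcomes (three inhibited, lapatinib + ERBB2 T862A/KRAS G12S not
inhibited) as smooth 6-point series.

## Determinism and degenerate inputs

Every stochastic step (simulation, GMM subsample and initialisation) derives
from one global seed; identical config + seed reproduces outputs
bit-for-bit. Degenerate cases return defined results rather than crashing:
constant images yield an empty foreground mask with a warning, no seeds
yield empty label maps, equal anchors (NCR_MT = NCR_WT) raise (the activity
scale is undefined), two zero-variance equal-mean groups give p = 1, and an
empty cohort predicts an empty list.

## Known limitations

- Segmentation quality is only demonstrated on disk-shaped synthetic cells;
  the refinement bounds encode that geometry.
- The transfection gate assumes expressing cells are well separated from
  background in whole-cell reporter intensity; weak expressers would be
  missed.
- The literature table and drug-target map are minimal by design; applying
  the prediction rules to other cohorts requires extending both CSVs.
- Per-plate results are treated independently; replicate experiments would
  be combined by averaging per-plate condition NCRs.
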