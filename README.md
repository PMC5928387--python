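# factpipe

Analysis pipeline for **nuclear-translocation reporter assays** used to
functionally annotate cancer variants and predict targeted-therapy benefit.

In these assays a patient-derived variant is co-transfected into cells with a
fluorescently tagged signalling protein (ERK2, STAT3, RelA or FOXO1) that
moves from cytoplasm to nucleus when its pathway is activated. Plates are
imaged in two channels (nuclear stain + reporter); the readout for one cell is
the **nuclear-to-cytoplasmic ratio**

    NCR = mean reporter intensity in nucleus / mean reporter intensity in cytoplasm.

The median NCR of a well's transfected cells is the well NCR, and the mean
over six replicate wells is the condition NCR. Condition NCRs are rescaled
onto an activity scale anchored by the wild-type gene (0%) and a known
activating mutation (100%):

    score = 100 · (NCR_VUS − NCR_WT) / (NCR_MT − NCR_WT)

A variant with score ≥ 20% is called **active**. Active variants are exposed
to a 6-point log-spaced dose series of the targeted agent; if activity drops
below the same 20-point cutoff at any dose the drug **inhibits** the variant.
A patient's survival prediction is **positive** when the agent they received
inhibits the pathway activated by their variant(s) (or a literature rule for
amplification-based treatment applies), otherwise **negative**. Predictions
are compared against observed progression-free survival (PFS) with group
medians, a tie-corrected Kruskal–Wallis test and Kaplan–Meier curves.

Because no raw microscope data are public, the package ships a ground-truthed
**synthetic imaging module**: wells of disk-shaped cells with concentric
nuclei, per-cell NCR drawn from a condition-specific log-normal, partial
transfection, touching cells, background, read noise and optical blur. The
segmentation chain (background subtraction → Gaussian-mixture multispectral
foreground detection → cross-spectral seeded watershed → rule-based
morphological refinement) and the NCR quantification are validated against
this ground truth.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
their tables to `results/`:

```bash
python analysis/01_simulate_and_quantify.py   # simulate plates, measure NCRs
python analysis/02_score_activity.py          # activity scores + t-tests
python analysis/03_dose_response.py           # inhibition calls
python analysis/04_predict_cohort.py          # patient predictions
python analysis/05_survival_stats.py          # PFS contrast
```

`01` simulates 42 wells (7 conditions × 6 wells, ~400 cells each: anchors at
NCR 1.0 and 3.0 plus five test conditions planted at scores 5–100%) and
recovers the planted signal:

```
detected 16779 cells (99.9% of planted)
  WT       NCR 1.013 (target 1.0, +1.3%)
  MT       NCR 3.027 (target 3.0, +0.9%)
  VUS_50   NCR 2.034 (target 2.0, +1.7%)
```

`02` rescales the measured NCRs — the planted scores come back within ~1
point and the 20% cutoff classifies all five correctly:

```
  VUS_05   score    5.1%  p=5.98e-06  active=False
  VUS_15   score   15.4%  p=2.56e-10  active=False
  VUS_25   score   25.0%  p=1.70e-09  active=True
  VUS_50   score   50.7%  p=2.93e-12  active=True
  VUS_100  score  100.1%  p=1.05e-11  active=True
```

`04`/`05` apply the decision rules to the packaged 12-patient cohort table
(4 positive / 8 negative predictions, positives = patients 3, 4, 5, 9) and
contrast their PFS:

```
  positive n=4  median PFS 5.8 months (unrounded 5.750)
  negative n=8  median PFS 1.8 months (unrounded 1.750)
Kruskal-Wallis H=4.892, p=0.0270
```

The positive-prediction group lives almost three times longer on treatment;
the rank test rejects equality at p < 0.05 despite n = 12.

The same machinery is exposed as a CLI (`factpipe run-all --seed 0 --outdir
runs/demo`, or stage-wise `simulate`/`segment`/`quantify`/`score`/`predict`/
`stats`) configured by a YAML file.

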