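# Methods

This note documents the models, conventions and numerical choices behind
`tmaquant`, and what the synthetic benchmark does and does not establish.

## Synthetic cohort model

Each of `n_patients` (default 104) patients carries clinical covariates,
latent marker intensities, and an overall-survival outcome.

**Marker intensities.** For marker *m* the patient baseline is
`epithelial_location · exp(N(0, between_patient_scale))` (defaults 3000 on
the 16-bit scale, σ between patients 0.35). Tumor and normal epithelium
share this baseline and receive independent `exp(N(0, 0.12))` within-patient
deviations; the tumor epithelium is additionally multiplied by
`tumor_downregulation` (default 0.6). Sharing the baseline makes the
matched tumor/normal design informative: with the default scales,
tumor < normal holds for ≈99.9% of patients, which is the ground truth the
paired-comparison stage must recover. Stromal intensity follows the same
construction around a lower location (1200) and is independent of the
epithelial values. All intensities are clipped to [0, 65535] only at pixel
rendering.

**Ground-truth stratification.** A patient is *m*-low when the latent
tumor-epithelial value lies strictly below the cohort median; the combined
NLRP6/IL-18 profile is `low_low`, `high_high` or `mixed` accordingly. These
noise-free labels drive the outcome model, so recovery experiments are
well-posed.

**Survival.** Exponential event times with hazard
`h_i = baseline_hazard · exp(Σ_g β_g · 1[i ∈ g])` and administrative
censoring at `censoring_time_months`. Defaults: baseline 0.003/month,
censoring at 120 months, and β = log 1.72, log 1.58, log 1.68 for NLRP6-,
caspase-1- and IL-18-low status respectively — the percent mortality
increases the pipeline is meant to detect. Under these defaults the
expected cohort Kaplan–Meier five-year survival is ≈0.66 with roughly half
the cohort censored, a realistic surgical-series regime.

**Stage, infiltrates, checkpoints.** TNM stage and the four ordinal
infiltrate grades (CD3, CD8, CD68, CD163: low/mild/high) are drawn from
categorical distributions conditioned on the profile group: the low/low
profile concentrates in stage IV (probability 0.50 vs 0.05 for high/high)
and has depressed lymphoid (CD3/CD8) but unchanged macrophage infiltrates.
PD-1 positivity is more frequent when epithelial IL-18 is high (0.45 vs
0.20); PD-L1 is 0.30 throughout. Sex, age, grade, MSI/KRAS/BRAF are drawn
from fixed marginals typical of a colorectal surgical series (57.7% male,
age ≈ N(70, 10) clipped to [38, 89], 15.4% MSI). Grade probabilities are
normalized to sum to one.

## Spot images

A spot is a disk of radius `spot_radius_px` (default 80) with a 4 px
margin. The epithelium is drawn as 3–8 random annuli ("crypts", outer
radius 0.4–0.6 of the spot radius, inner/outer ratio 0.1–0.35) clipped to
the disk, accumulated until the epithelial area fraction reaches its target
(default 0.5). Nuclei (default 280 per spot, radius 3 px) are placed by
rejection sampling with minimum center distance twice the nucleus radius —
a Poisson-disk-like layout that keeps nuclei from merging into blobs; the
attempt limit caps the density at what such a hard-core process can
accommodate. Channels are piecewise constant (DAPI 20000 in nuclei,
cytokeratin 15000/800 inside/outside the glands, marker at the patient's
latent compartment values) plus additive Gaussian noise (`noise_sd`,
default 100), clipped to the 16-bit range. Channels stay float64 in
memory; TIFF output rounds to uint16. Per-spot seeds derive from the master
seed through a `SeedSequence` spawned on the (patient, marker, tissue,
spot) counters, so any spot can be regenerated in isolation.

These defaults were fixed as a package design choice so that the default
spots form a well-posed segmentation benchmark (nuclei-count error a few
percent, epithelial-mask Dice ≈0.92–0.96); they are free parameters of the
generator, not claims about any particular instrument or stain.

What the images deliberately omit: autofluorescence, spectral
bleed-through, intensity gradients, texture within compartments, irregular
nucleus shapes, tissue folds and de-arraying artifacts. Passing tests
therefore demonstrate the correctness of the measurement and statistics
machinery under the stated model, not robustness to real-world staining
variation.

## Segmentation

Nuclei: Gaussian smoothing (σ 0.5) → global threshold (Otsu default; Li,
mean or a fixed value selectable) → hole filling → removal of objects
smaller than 15 px → Euclidean distance transform → peak markers (minimum
separation 2 px within each connected blob) → watershed on the negated
distance. Constant images yield an empty label map rather than an error.
Labels are relabelled consecutively from 1.

Cells: each nucleus is expanded outward up to `expansion_radius_px`
(default 6), stopping where two cells meet, with pixels assigned to the
nearest nucleus (`skimage.segmentation.expand_labels`); the pipeline clips
cell regions to the spot's tissue disk so edge cells do not accumulate
empty background. Radius 0 is the identity; the cell label set always
equals the nucleus label set.

Cytokeratin mask: positivity is decided per cell, not per pixel — a cell is
cytokeratin-positive when its mean CK intensity exceeds a spot-level Otsu
threshold over the per-cell means (a fixed threshold can be supplied). If
all cells share one mean, they are all positive iff that mean is nonzero.
The mask is the union of positive cells' pixels and is invariant to
relabeling.

## Quantification

A cell is counted iff its label exists in the nuclei map (DAPI positivity
is the segmentation itself; no second intensity cutoff). The compartment is
epithelial when the majority of the cell's pixels fall in the CK mask, and
the per-cell statistic is the median marker intensity over the cell's
pixels *within its own compartment* — inside the mask for epithelial cells,
outside for stromal. With segmentation-derived masks (unions of whole
cells) this restriction is a no-op; with ground-truth masks that cut across
cells it prevents boundary cells from mixing compartments, which would
otherwise bias the estimate by roughly one noise standard deviation times
the boundary-cell fraction. A nucleus-only pixel set is available via
`region="nucleus"`.

Spot values are arithmetic means of per-cell medians per compartment;
patient values are means over the available tumor spots (≤3) and normal
spots (≤2). Missing compartments and missing spots propagate as NaN with
recorded counts — never as 0. No background subtraction or cross-spot
normalization is applied: the design compares matched cores within
patients, which such global transforms would not improve.

## Statistics

All tests are two-sided at α = 0.05; no multiplicity correction is applied
by default (a Benjamini–Hochberg helper is provided for users who want
one).

- **Paired comparison** (`method="auto"`): Shapiro–Wilk on the differences
  at α = 0.05 chooses the paired t test or the Wilcoxon signed-rank test.
  Wilcoxon drops zero differences, mid-ranks ties, enumerates the exact
  null (dynamic programming over doubled ranks) for n ≤ 25 and otherwise
  uses the tie-corrected normal approximation without continuity
  correction. All-zero differences return p = 1 with a degenerate flag.
- **Mann–Whitney**: exact subset-enumeration null when there are no ties
  and both groups have ≤ 8 observations; tie-corrected normal otherwise.
  **Kruskal–Wallis**: H with tie correction, χ²_{k−1} reference.
- **Contingency tables**: Pearson χ² without continuity correction;
  zero-margin rows/columns are dropped with a warning; 2×2 tables with any
  expected count < 5 switch automatically to the two-sided Fisher exact
  test (hypergeometric enumeration, summing tables no more probable than
  the observed one, with a 1e-9 relative tie guard).
- **ROC cutpoints**: oriented so that *low* values predict death; AUC by
  the mid-rank Mann–Whitney formulation; the cutoff maximizes Youden's J
  over midpoints between adjacent sorted unique values, ties broken toward
  the lower cutoff. Training sensitivity/specificity are stored, and
  re-stratifying the training values reproduces them exactly. The
  stratification rule everywhere is value > cutoff → high, ties low — the
  same convention as the median split, whose all-equal case is flagged
  degenerate.
- **Kaplan–Meier / log-rank**: product-limit estimator with right-continuous
  step evaluation; the two-group log-rank uses the hypergeometric variance
  with the (n−d)/(n−1) tie factor; a zero variance yields the degenerate
  p = 1 result.
- **Cox regression**: Efron tie handling; Newton–Raphson on centered
  covariates with step halving, convergence when the log-likelihood change
  and gradient norm fall below 1e-9 (≤ 50 iterations, else an error);
  standard errors from the inverse observed information; Wald CIs and
  p-values. A coefficient escaping |β| > 20 stops the iteration with a
  "divergent beta" warning — the complete-separation case, which a
  two-subject dataset with the high-covariate subject dying first
  exercises. Stage adjustment encodes TNM stage as categorical dummies
  III and IV against the I–II reference.
- **Profiles**: two concordant high/low labels combine to high/high or
  low/low; discordant pairs are "mixed" and are excluded from the
  two-group profile comparisons (survival, stage, infiltrates) — the
  concordant-only comparison is the stated design. Five-year survival is
  read from the KM curve at t = 60 months.
- **Age tertiles** split at the empirical 1/3 and 2/3 quantiles with ties
  to the lower group; **percentages** are 100·count/total rounded half-up
  to one decimal (so 6.25% prints as 6.3).

Fig-2B-style stromal stratification is ambiguous between median and ROC
cutpoints in the source design; both are supported and ROC is the default
for the stromal compartment (configurable per marker and compartment).

## Pipeline and problem sizes

`run_pipeline` is a pure function of its configuration: cohort generation,
marker-value acquisition (imaging path, ground-truth-mask imaging path, or
the latent fast path), stratification and the seven report tables, plus a
manifest carrying a SHA-256 hash of the canonical YAML of the
configuration, the seed, package/library versions and stage timings
(timings live only in the manifest so table CSVs are byte-stable).

Problem sizes used by the shipped verification runs are chosen to keep the
whole suite fast while leaving the estimators in their asymptotic regime:
cohort-level checks use n = 104 (the reference design) or n = 2,000 for
Cox recovery over 50 seeds; the log-rank calibration uses 1,000 null
replicates of n = 60; the imaging checks use 20 default spots; the
acceptance script pools 250 replicate cohorts of n = 104 and reports
Monte-Carlo means. The Cox-recovery acceptance fit includes all three
injected low-status indicators jointly: the joint model is the correctly
specified one, and hazard ratios are non-collapsible, so univariate fits
would be mildly attenuated by the omitted independent effects.

## Known limitations

- The exponential, constant-HR outcome model and administrative censoring
  are the simplest structure consistent with a Cox analysis; no competing
  risks, time-varying effects or delayed entry.
- Stromal marker values are independent of epithelial values, so stromal
  survival effects exist only if explicitly injected.
- Segmentation quality figures hold for the default synthetic geometry;
  heavily overlapping nuclei or textured backgrounds are out of scope.
- The ROC-Youden cutpoint is trained and applied on the same cohort, as in
  the emulated design; its optimism is inherited, not corrected.
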