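# tmaquant

Epithelial-restricted quantification of immunofluorescence tissue-microarray
(TMA) cohorts, with the full downstream biomarker statistics — exercised on
synthetic images and cohorts that carry their own ground truth.

## The problem

In colorectal cancer, inflammasome components (NLRP1, NLRP3, NLRP6, AIM2,
ASC, caspase-1, IL-1β, IL-18) are expressed both by tumor epithelium and by
stromal immune cells. Bulk measurements mix the two, so epithelium-specific
loss of a marker — a candidate prognostic signal — is invisible without an
image-level analysis. The standard TMA design samples each patient with
three tumor cores and two matched normal-mucosa cores; each core is stained
with DAPI (nuclei), pan-cytokeratin (epithelium) and one marker of
interest. Quantification is restricted to the epithelial compartment by a
*cytokeratin mask*: the union of the pixels of cytokeratin-positive
segmented cells.

`tmaquant` implements that workflow end to end:

1. **simulate** — synthetic cohorts (clinical covariates, ordinal immune
   infiltrates, exponential survival with marker-dependent hazards) and
   synthetic spot images (gland-shaped epithelium, Poisson-disk nuclei,
   lognormal marker intensities with tumor-epithelium downregulation), all
   with ground-truth sidecars;
2. **segment** — Gaussian smoothing → Otsu threshold → hole filling → small
   object removal → distance-transform watershed for nuclei; bounded
   nearest-nucleus expansion for cells; per-cell Otsu on mean cytokeratin
   for the epithelial mask;
3. **quantify** — per-cell median marker intensity of DAPI-positive cells,
   split into epithelial/stromal compartments, averaged per spot and then
   per patient (mean of 3 tumor and of 2 normal cores);
4. **stats** — paired t / Wilcoxon signed-rank comparisons, ROC–Youden and
   median cutpoints, Kaplan–Meier curves, the two-group log-rank test, Cox
   proportional-hazards regression (Efron ties, Newton–Raphson),
   Mann–Whitney / Kruskal–Wallis / χ² / Fisher associations, combined
   two-marker protein profiles, age tertiles and percentage summaries —
   implemented from their definitions and cross-checked against
   independent libraries in the test suite;
5. **pipeline / CLI** — a seeded, deterministic orchestration producing
   seven analysis tables and a run manifest.

## The statistics at the core

For survival, the hazard for patient *i* is modelled as
λ_i(t) = λ₀ exp(βᵀx_i) (proportional hazards); β̂ maximizes the Efron-tied
partial likelihood and HR = exp(β̂) with Wald 95% CI exp(β̂ ± 1.96·SE).
Survival curves use the product-limit estimator Ŝ(t) = Π_{t_i≤t}(1 − d_i/n_i)
and groups are compared with the log-rank statistic U²/V ~ χ²₁.
High/low stratification uses either the sample median or the ROC cutpoint
maximizing Youden's J = sensitivity + specificity − 1 for predicting death
(low values predict death; the decision rule is value > cutoff → "high").
The exact nonparametric tests (Wilcoxon signed-rank, Mann–Whitney, Fisher
2×2) enumerate their null distributions at small n and use tie-corrected
normal/χ² approximations otherwise.

## Worked example

```python
from tmaquant import RunConfig, run_pipeline

config = RunConfig(seed=1, use_images=False)   # latent-value fast path
bundle = run_pipeline(config)

surv = bundle.tables["survival_by_marker"]
row = surv[(surv.marker == "NLRP6") & (surv.compartment == "epithelial")].iloc[0]
print(f"NLRP6 (epithelial): cutoff={row.cutoff:.0f} ({row.cutoff_method}), "
      f"AUC={row.auc:.2f}, HR(low vs high)={row.hr_low_vs_high:.2f} "
      f"[{row.hr_ci_low:.2f}, {row.hr_ci_high:.2f}], log-rank p={row.logrank_p:.3f}")
prof = bundle.tables["profile"].iloc[0]
print(f"profile {prof.marker_pair}: 5-year survival "
      f"high/high={prof.surv_horizon_high_high:.2f} vs low/low={prof.surv_horizon_low_low:.2f}, "
      f"stage chi2 p={prof.stage_p:.2g}")
```

prints

```
NLRP6 (epithelial): cutoff=1820 (roc_youden), AUC=0.57, HR(low vs high)=1.80 [1.03, 3.18], log-rank p=0.038
profile NLRP6/IL18: 5-year survival high/high=0.84 vs low/low=0.67, stage chi2 p=9.5e-06
```

i.e. on a default synthetic cohort of 104 patients the pipeline recovers the
injected structure: patients below the NLRP6 ROC cutpoint die at ~1.8× the
hazard of the rest, and the NLRP6-low/IL-18-low combined profile shows worse
five-year survival and a stage distribution shifted toward metastatic
disease. Set `use_images=True` to run the same analysis through actual spot
rendering, segmentation and per-cell quantification.

The same pipeline is available from the shell:

```bash
tmaquant run-all --seed 1 --outdir report/
tmaquant simulate --seed 1 --outdir sim/ --images --n-image-patients 4
tmaquant segment --indir sim/images --outdir seg/
tmaquant quantify --images sim/images --labels seg/ --outdir quant/
```

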