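# datsbr

Subregional dopamine-transporter (DAT) PET quantification and staging
analysis for the Lewy body disease spectrum.

Nigrostriatal dopaminergic degeneration is the imaging hallmark of dementia
with Lewy bodies (DLB) and its prodromal stage, mild cognitive impairment
with Lewy bodies (MCI-LB). `datsbr` implements the full quantitative chain
used to characterise FP-CIT PET uptake in five regions of interest —
anterior/posterior putamen (AP, PP), anterior/posterior caudate (AC, PC)
and substantia nigra (SN) — and to ask *which* subregion best separates
patients from healthy controls (HC) and *in what order* the regions become
abnormal.

## What it computes

1. **SBR extraction** (`datsbr.imaging`). A standardized uptake value ratio
   (SUVR) map is formed by dividing the PET volume by the mean uptake in an
   occipital white-matter reference mask. Caudate and putamen masks are
   split into anterior/posterior subregions by deterministic k-means on
   voxel world coordinates, eroded by one voxel (6-connectivity), and the
   regional specific binding ratio is the median SUVR in the mask
   (bilateral values pool left + right voxels; the SN is not eroded).

2. **Normative age model** (`datsbr.normative`). Per region, OLS of SBR on
   age in HCs; a subject's age-adjusted z-score is

       zSBR = (SBR − (β₀ + β₁·age)) / RSE,   RSE = √(RSS/(n−2)).

   `NormativeAgeModel(hc_table).fit()` returns a results object with
   per-region estimates, `zscore_table()` and `summary()`.

3. **Diagnostics** (`datsbr.diagnostics`). Univariate logistic models with
   AIC, empirical ROC curves (AUC ≡ Mann–Whitney with ties counted half),
   Youden operating points, and DeLong / paired-bootstrap AUC comparison.

4. **Abnormality ordering** (`datsbr.ordering`). With abnormality defined
   as zSBR < −1.5, the pairwise conditional probability
   P(Y+|X−) = #(Y+∧X−)/#(X−) is tested for asymmetry against P(X+|Y−) by
   the exact McNemar test (doubled smaller binomial tail at p = ½);
   significant asymmetry with b > c yields "Y becomes abnormal before X".

5. **Clinical associations** (`datsbr.associations`). Logistic models for
   core features (RBD, cognitive fluctuation, visual hallucination, modest
   parkinsonism) and standardized-β linear models for motor/cognitive
   scores, adjusted for age, sex and education, with Benjamini–Hochberg
   FDR across the five regional predictors.

6. **Voxel-based morphometry** (`datsbr.vbm`). Voxel-wise GLM of modulated
   gray-matter density on a regional zSBR (covariates: age, sex, education,
   intracranial volume), cluster-forming threshold p < 0.001 two-sided,
   26-connected clusters, and family-wise-error-corrected cluster p-values
   from the Freedman–Lane permutation distribution of the maximum cluster
   size. Effect sizes are reported as r = t/√(t² + dof).

7. **Synthetic data** (`datsbr.synth`). Calibrated cohort and 3D phantom
   generators with the statistical structure the pipeline assumes, so the
   whole chain is testable without clinical data.

## Worked example

```python
from datsbr import synth, diagnostics, ordering
from datsbr.normative import NormativeAgeModel
import numpy as np

subjects, sbr = synth.simulate_cohort(synth.reference_cohort_config(seed=1))
norm = NormativeAgeModel.from_dataframe(sbr).fit()
z = norm.zscore_table(sbr)

hc, dlb = z[z.group == "HC"], z[z.group == "DLB"]
labels = np.r_[np.ones(len(dlb), int), np.zeros(len(hc), int)]
for r in ("SN", "PP"):
    roc = diagnostics.roc_curve(labels, np.r_[dlb[r], hc[r]])
    print(r, round(roc.auc, 2))

pooled = z[z.group.isin(["DLB", "MCI-LB"])]
res = ordering.conditional_matrix(ordering.flag_abnormal(pooled))
for e in ordering.infer_order(res, alpha=0.01):
    if e.before == "SN":
        print(f"SN precedes {e.after}: P(SN+|{e.after}-) = {e.prob:.2f}, "
              f"b={e.b}, c={e.c}, p={e.p_value:.2g}")
```

Output:

```
SN 0.96
PP 0.84
SN precedes AP: P(SN+|AP-) = 0.59, b=30, c=4, p=6.2e-06
SN precedes PP: P(SN+|PP-) = 0.63, b=40, c=2, p=4.1e-10
SN precedes PC: P(SN+|PC-) = 0.65, b=44, c=1, p=2.6e-12
```

Lower zSBR means more severe DAT loss; the nigral region
separates DLB from HC better than the posterior putamen and becomes
abnormal while striatal regions are still normal.

A command-line interface mirrors the library:

```bash
datsbr simulate --seed 1 --out run/
datsbr zscore --sbr run/sbr.csv --out run/z.csv
datsbr order --zsbr run/z.csv --out run/ordering.json
datsbr run --seed 1 --out run/full
```

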