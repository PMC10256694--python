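# Methods

This note documents the statistical models implemented in `datsbr`, the
assumptions behind the synthetic-data generators, and the numerical and
design choices made where the procedure admitted more than one reasonable
reading.

## Quantification model

**SUVR referencing.** The PET volume is divided voxel-wise by the *mean*
uptake over the occipital white-matter mask. Mean rather than median was
chosen as the conventional SUVR reference summary; a `summary="median"`
switch exists because the choice is not forced by the procedure. SUVR is
invariant to global rescaling of the PET image, which the tests assert.

**SBR definition.** The regional specific binding ratio is the *median*
SUVR over the (eroded) ROI, with no −1 subtraction. The conventional
`(target/reference − 1)` variant is available via
`convention="suvr_minus_1"`; the two differ only by an affine shift and
therefore produce identical z-scores downstream.

**Subregion splitting.** Caudate and putamen are split per hemisphere into
anterior/posterior parts by k-means (k = 2) on voxel world coordinates.
Plain Lloyd iteration is made deterministic: centroids are initialised at
the two mask voxels extreme along the anterior–posterior (world y) axis,
assignment ties break toward the anterior centroid, and the cluster whose
centroid has the larger y is labelled anterior. On a symmetric lattice this
reproduces the exhaustive 1D split minimising within-cluster sum of
squares (tested).

**Erosion.** Striatal masks are eroded by one voxel with the 6-connected
structuring element before extraction, to limit partial-volume
contamination. The substantia nigra mask is small and is *not* eroded. An
erosion that empties a mask is a hard error carrying the region name;
falling back to the uneroded mask is the caller's explicit decision, never
silent.

## Normative z-scoring

Per region, SBR is regressed on age by OLS in healthy controls;
`zSBR = (SBR − predicted)/RSE` with `RSE = sqrt(RSS/(n−2))`. Education and
sex are deliberately absent from the normative model (age is the only
systematic predictor modelled). Two exact in-sample identities follow for
the HC group itself and serve as self-diagnostics: the z mean is 0 per
region (residual orthogonality) and the sample SD is `sqrt((n−2)/(n−1))`
(≈ 0.987 for n = 40, printing as 1.0 at one decimal). Bilateral z-scores
are computed from the pooled-voxel bilateral SBR; per-hemisphere z-scores
use per-hemisphere normative fits (each hemisphere is its own reference
population), and the more-affected side is the per-region minimum of the
two.

## Diagnostics

ROC curves are empirical over all unique thresholds with lower zSBR
oriented toward disease; the trapezoid AUC is identical to the
Mann–Whitney estimator with ties counted half (property-tested on random
instances). Operating points maximise Youden's J, with ties resolved
toward the more specific threshold; a fixed-specificity rule
(`min_specificity=0.975`) is also provided since high-specificity
operating points are common in this application. Paired AUC differences
use DeLong's variance of the placement values; a seeded paired bootstrap
is provided as a cross-check and the two agree within Monte-Carlo error in
tests. Logistic fits flag complete/quasi-separation (divergent
coefficient, exploded SE) instead of reporting a spuriously huge odds
ratio.

## Abnormality ordering

Abnormality is `zSBR < −1.5`, strict: a subject exactly at −1.5 is
normal. For an ordered pair (Y, X), `P(Y+|X−) = #(Y+∧X−)/#(X−)`;
when `#(X−) = 0` the entry is *undefined* and rendered as an explicit
null, never 0, distinguishing "no evidence" from "probability zero". The
asymmetry test is the exact McNemar test on the discordant counts:
`p = min(1, 2·P(Bin(b+c, ½) ≤ min(b, c)))`, `p = 1` when `b + c = 0`.
Because the Bin(m, ½) distribution is symmetric, the doubled-tail and
minimum-likelihood two-sided conventions coincide here; the implementation
is cross-checked against an independent exact-McNemar routine in the test
suite. Precedence edges "Y precedes X" require `p < α` (default 0.01) and
`b > c`; no transitive closure is applied. The analysis runs per
diagnostic group and pooled; the pooled patient group is used for the
headline nigral-first property because it roughly doubles the discordant
counts available to the exact test at the calibrated deficit gaps.

## Clinical associations

Binary core features are modelled by maximum-likelihood logistic
regression on one regional zSBR plus age, sex and education (antipsychotic
use optionally added as a sensitivity covariate); the odds ratio is per
1 z-unit. Continuous scores use OLS with the outcome and the zSBR
predictor z-transformed and covariates left on their raw scales, so the
reported coefficient is a standardized β (equal to Pearson's r when no
covariates are present, which the tests verify on a hand dataset).
Standardizing covariates as well would change nothing about the
predictor's t/p and only rescale nuisance coefficients, so the simpler
convention was kept. p-values are corrected per outcome across the five
regional predictors by Benjamini–Hochberg; significance flags in generated
reports use adjusted p < 0.05. "Modest parkinsonism" defaults to
UPDRS-III > 20, with the ≥ 20 variant selectable (`strict=False`) because
both conventions circulate.

## Voxel-based morphometry

Per-voxel OLS of modulated GM density on one regional zSBR with age, sex,
education and intracranial volume as covariates. Cluster forming is
two-sided at p < 0.001 (|t| above the central-t quantile at n − k dof);
positive and negative clusters are labelled separately with
26-connectivity. FWE correction is purely permutation-based: the
Freedman–Lane scheme permutes reduced-model residuals while covariates
stay fixed, the null statistic is the maximum cluster size over both
signs, and corrected p uses the +1 estimator
`(1 + #{perm ≥ obs})/(1 + n_perm)`, which is valid (never anti-
conservative) and never exactly zero. Random-field-theory corrections are
deliberately out of scope; the permutation route is self-contained and
exact under exchangeability. On very small grids cluster sizes are
coarsely discrete, which makes the procedure mildly conservative — the
calibration experiment below quantifies this.

## Synthetic-data generators

**Cohort.** `SBR_r = β₀ᵣ + β₁ᵣ·age + σᵣ·(εᵣ + δ_{r,g})` with
`εᵣ = √ρ·L + √(1−ρ)·eᵣ`: a shared latent severity factor L (ρ = 0.5 of
the unit variance) induces the positive inter-regional correlation real
uptake data show, a modelling choice not validated against any dataset.
Deficits δ are zero for HC by construction. Ages are uniform within
per-group ranges chosen to match the published group means and SDs
(uniform keeps leverage for the age regression). Sex is Bernoulli(0.5),
education truncated normal at 0. Clinical flags are Bernoulli draws from
logistic links on the true regional z-scores with *per-group intercepts*
— needed because core features are essentially absent in controls while
only weakly graded by zSBR within patients; a pure zSBR link cannot
produce both patterns. Continuous scores are linear in the true z-scores,
age and education with Gaussian noise, clipped to instrument ranges.
Hemispheric SBRs are the bilateral value ± a Gaussian asymmetry (SD 0.3 z).

The default calibration (`reference_cohort_config`) encodes a
40/36/51 HC/MCI-LB/DLB cohort with the substantia nigra the most affected
region (deficits −1.5/−2.2 z for MCI-LB/DLB) and striatal deficits between
−0.8 and −1.6 z. Normative slopes and residual SDs were solved jointly so
the HC group SD (age spread plus residual) and the DLB group-mean SBR are
simultaneously consistent — e.g. SN: slope −0.012/yr, residual SD 0.205,
giving HC 1.1 ± 0.23 and DLB mean ≈ 0.5. The published-style summaries are
not perfectly mutually consistent at one-decimal rounding (the MCI-LB
nigral mean lands near 0.66 rather than 0.8); the DLB row and HC SD were
prioritised. What passing tests on these cohorts shows is that the
*pipeline* recovers the structure it assumes; the generator does not
emulate scanner PSF, registration error, longitudinal change, or realistic
inter-score correlation structure, so no claim about real-data effect
sizes follows.

**Phantom.** Axis-aligned box ROIs (bilateral caudate, putamen, SN, an
occipital WM reference block) on a 24³ grid of 2 mm voxels (a 16³ variant
exists for calibration experiments). PET voxels are
`reference_level · true_ratio(label)` plus optional Gaussian noise, so a
noiseless phantom must round-trip through the extraction chain exactly —
the tests assert equality, not approximation. GM maps are a constant
baseline minus `gm_effect · SN-z` inside a designated cluster, plus
smoothed Gaussian noise (6 mm FWHM by default in analysis runs); ICV is
the summed tissue volume with small subject-level jitter.

## Problem sizes and calibration results

The permutation-FWE calibration experiment uses 200 independent fully-null
16³ phantom datasets, 40 subjects each, 500 permutations per dataset — a
size chosen so the binomial 95% band around the nominal 0.05 FWE level is
informative while the whole experiment stays around a minute. Observed
rates sit in the 3–8% range across batches, inside the band, with the mild
conservatism expected from discrete cluster sizes on a small grid. The
headline reproduction test runs 100 cohort seeds and requires the nigral
AUC to exceed the posterior-putamen AUC for both patient contrasts in at
least 95 of them, and nigral-precedes-striatum ordering edges (pooled
patients, α = 0.01) with no reverse edge in at least 90.

## Known limitations

- The cohort generator's per-region z dispersion in patient groups is ~1
  by construction; observed clinical cohorts show 1.2–2.0, so patient-group
  heterogeneity is understated.
- Exact McNemar on n ≈ 50 per group has limited power for deficit gaps
  under ~0.5 z; single-seed runs can legitimately return no edge for a
  true ordering (≈3% of seeds at the default calibration).
- The VBM stage models a single planted cluster and stationary smooth
  noise; it says nothing about non-stationary smoothness, which real GM
  data exhibit.
- No partial-volume correction beyond erosion; no registration or
  segmentation is performed (label masks are inputs).
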