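# Methods

## The problem

After resective surgery for mesial temporal lobe epilepsy (mTLE), a
substantial fraction of patients do not become seizure-free. A candidate
imaging biomarker of surgical prognosis is the degree to which a patient's
grey-matter covariance structure deviates from a healthy norm *outside* the
tissue that surgery removes: patients whose spared network — and in
particular its hemisphere contralateral to the seizure focus — is already
abnormal before surgery are less likely to achieve seizure freedom. This
package implements that analysis chain for region × subject grey-matter
volume tables and provides a synthetic cohort generator so every stage can
be validated against known ground truth.

## Reference network (rSCN)

Given `n` control subjects and `p` atlas regions, each region's volumes are
residualized by ordinary least squares against an intercept plus the
nuisance covariates age, sex (coded F=0/M=1; any consistent binary coding
is equivalent after centering) and total intracranial volume. The reference
structural covariance network is the `p × p` Pearson correlation matrix of
these residuals. This residualize-then-correlate construction is
algebraically identical to the partial correlation of each region pair
given the covariates (the precision-matrix formula), which the test suite
verifies to 1e-8. Partialling is against nuisance covariates only, never
against the other regions — with `n = 78` controls and `p = 246` regions a
full region-wise partialling would be rank-deficient, and the
covariates-only reading is the standard structural-covariance construction.

Degenerate inputs are rejected rather than patched: a rank-deficient
covariate design reports the collinear columns, and a region whose
residual variance is (numerically) zero reports the region. Fewer than
5 controls, or fewer than `4 + n_covariates`, is an error.

## Individual deviation (pSCN and Z)

One patient at a time is appended to the control cohort and the same
construction is re-run on the `n + 1` stacked subjects, giving the
perturbed network pSCN. The covariate regression is refit on the `n + 1`
sample by default; whether the original study refit or reused the control
coefficients is not documented, so the frozen-coefficient variant is
available as `fixed_covariate_fit=True`. The edge-wise deviation is

    Z_ij = (pSCN_ij − rSCN_ij) / ((1 − rSCN_ij²) / (n − 1))

with `n` the control-group size. The scale `(1 − r²)/(n − 1)` is the
first-order sensitivity of a sample correlation to one added observation,
so `Z` measures the patient's perturbation in units of the perturbation a
typical control-like subject would produce. Edges are *abnormal* when
`|Z| > 2`, strictly — ties at exactly 2 are excluded. Edges whose reference
correlation is exactly ±1 have no finite scale; they are flagged invalid
with a warning (they indicate duplicated input rows) and excluded from
abnormal-edge sets instead of being clipped.

Under null patients drawn from the control distribution the supra-threshold
rate is not a nominal 5% tail probability — the statistic's finite-sample
spread depends on the reference correlation — but it is a small, seed-stable
fraction (empirically ~5–8% at `n = 78`), which the calibration tests check
for stability rather than for a fixed level.

## Virtual resection

Surgical nodes are atlas regions whose voxel mask overlaps an individual
resection area by at least 50% (inclusive at the boundary; the choice at
this measure-zero point is stated so it is testable). Right-sided patients'
nodes are flipped to their left homotopic partners, individual sets are
merged by union into a canonical left-lateralized group mask, and the mask
ships in the atlas table's `resected` column — the voxel-overlap path is
provided for users who have masks but is not needed to run the pipeline.
The overlap computation is space-agnostic: the caller supplies voxel index
sets (or co-registered label/mask arrays) on one grid.

Partitioning is exhaustive and exact: the surgery network holds the mask
nodes (mirrored to the right hemisphere for right-focus patients) and every
edge with at least one surgical endpoint; the spared network holds the
remaining nodes and their mutual edges. The counting identity
`|surgery edges| = k(k−1)/2 + k(p−k)` is property-tested over random sizes.

## Abnormality features

For each patient, abnormality strength is the sum of `|Z|` over abnormal
edges:

* **global** — within the surgery and spared subnetworks separately (the
  edge count is reported alongside; the sum of `|Z|` is the primary
  measure, consistent with the regional definition);
* **regional** — for every spared region, over its abnormal spared–spared
  edges, split by the *partner* region's hemisphere into ipsilateral and
  contralateral components (bilateral = ipsi + contra exactly, since the
  atlas is fully lateralized). The alternative seed-hemisphere reading is
  available as `seed_laterality=True`;
* **modular** — regional values summed over the seven anatomical modules,
  with ipsi/contra cells restricted to the module's regions in the
  respective hemisphere.

Right-focus patients' regional features are relabeled through the homotopic
involution so every patient lives in a focus-relative canonical space
(ipsilateral = left); this makes the feature columns comparable across
patients and is why one canonical spared-region index serves the whole
cohort. Two identities are enforced by tests on every run: bilateral =
ipsi + contra per region, and Σ regional bilateral = 2 × global spared
strength (each spared edge counts at both endpoints).

## Outcome model

Features at one laterality level enter a select-then-classify pipeline:
per training fold, standardize, rank by the Fisher criterion
`F(i) = [(m⁺−m)² + (m⁻−m)²] / [s²⁺ + s²⁻]` (unbiased class variances;
zero-variance-separated features rank first, constant features score 0),
keep the top `k`, and fit a linear-kernel SVM (cost 1.0; no inner
hyperparameter search). Folds are stratified 10-fold with seeded shuffling.
Held-out predictions are pooled into accuracy/sensitivity/specificity
(positive class = NSF) and an AUC over pooled decision values. `k` runs
over a grid starting at 20 in steps of 5 up to min(100, #features); the
value with the best pooled accuracy wins, ties to the smaller `k`.
Selection and standardization never see held-out patients; a
`whole_cohort_selection` flag exists only for leakage sensitivity analyses.

Classifier significance is a label-permutation test: the full
cross-validation is re-run per permutation and
`p = (1 + #{perm ≥ observed}) / (B + 1)`, which cannot return zero.
Model interpretation averages `|w|` per region over the folds that selected
it and then per Yeo-7 functional network; regions mapped to `none`
(subcortex, which the cortical Yeo parcellation does not cover) are
excluded from network averages and reported separately. For external
cohorts the final model is refit once on the whole internal cohort at the
CV-chosen `k`, and the frozen standardization/selection/weights are applied
unchanged.

## Group statistics

SF-vs-NSF comparisons use the pooled-variance Student t-test (the classical
two-sample t; Welch via `equal_var=False`), with Benjamini–Hochberg step-up
FDR control across regions/modules at q < 0.05. The global spared-vs-surgery
comparison is reported uncorrected as well as corrected. The display report
of strongest group differences takes the top ⌈1%⌉ of edges by signed t,
ties broken lexicographically for determinism.

## Synthetic cohorts

The generator emulates the statistical skeleton of the study, not its
images. Control residuals follow Σ = LLᵀ + ψI with seeded factor loadings;
homotopic pairs share correlated loadings (ρ = 0.7) so left/right structure
is realistic; Σ is rescaled to a residual SD of 0.5 ml. Volumes add a
per-region baseline (5–10 ml) and linear age/sex/TIV effects; covariates
are drawn as age ~ U(20, 50), sex ~ Bernoulli(0.5), TIV ~ N(1400, 120) ml.

Patients are controls whose residual vector is displaced on chosen
spared–spared pairs with positive reference correlation:
`e_i = +δσ_i, e_j = −δσ_j`. This opposite-signed displacement lies along
the pair's minor axis and attenuates the pair's correlation once the
patient joins the controls; it was chosen over a joint-minor-eigenvector
displacement because it is auditable by hand, and it lives in residual
space so the covariate regression cannot remove it. Defaults: δ = 4
residual SDs; NSF patients receive 40 edges with 80% placed among
contralateral spared–spared pairs, SF patients 15 edges at 30% — a strong,
cleanly detectable group contrast whose magnitudes are calibration choices
(no per-edge effect size is published), chosen so ground-truth recovery is
unambiguous rather than marginal. Injected edges may share nodes;
ground-truth evaluation therefore compares injected edges only against
null edges sharing no node with any injected edge. Everything flows from
the single config seed and reproduces byte-identically.

What the generator does *not* emulate: scanner/site effects, registration
and segmentation error, spatially smooth lesions, non-linear covariate
effects, or outcome-correlated covariate shifts. Passing tests therefore
demonstrate the correctness and calibration of the machinery, not
real-data effect sizes: synthetic classification accuracies sit near
ceiling under the default injection strength, where the published
real-data accuracies are ~80%.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence suites run 50 random toys at 4–12 regions and 20–80
controls. Calibration and recovery experiments keep the study's cohort
sizes (78 controls, 43 SF / 28 NSF) and reduce the spatial scale: 40
regions for null calibration and delta-recovery, 90 regions for the
contralateral-vs-bilateral ordering (20 seeds; the richer feature space
keeps both models off the accuracy ceiling so the ordering is
informative). The acceptance script runs the full default 246-region study
once, with the permutation test scaled to B = 199 and the detection
experiment at 40 regions, 3 cohorts × 3 patients. The strong-contralateral
ordering condition is δ = 6 with contra fractions 0.95 (NSF) vs 0.1 (SF)
and 10 vs 6 edges — a placement-dominated contrast, since a pure edge-count
contrast would let the bilateral model discriminate equally well.

## Known limitations

* Midline/unpaired regions are unsupported: every region must have a
  cross-hemisphere homotopic partner (true of the 246-region parcellation
  the design targets).
* No missing-data support; volumes must be complete and strictly positive.
* No shrinkage or regularized covariance; with fewer controls than ~p/2
  the reference correlations get noisy (the generator warns).
* The group resection mask is shared across patients; individualized masks
  would change the spared-region feature space across patients and are not
  modeled.
* Permutation tests re-run the entire cross-validation per permutation and
  are the dominant cost at B = 5000; scale B down for exploration.
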