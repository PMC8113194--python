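# Methods

## Scope and model

`parkdx` treats differential diagnosis of Parkinsonian syndromes as a
5-class classification problem over six quantitative indices — three from
DAT SPECT (SBR, PCR, AI) and three from cardiac MIBG scintigraphy
(H/M Early, H/M Delay, WR).  The classifier family is a binary
classification tree (CART): recursive partitioning by axis-aligned
thresholds chosen to maximize the decrease in Gini impurity
`G = 1 − Σ_c p_c²`, followed by cost-complexity pruning and
cross-validated subtree selection.  A fixed, published tree over four of
the six indices is also shipped as a deployable classifier.

## Quantification conventions

* **SBR** is `(S − O)/O`: the occipital reference mean is subtracted from
  the striatal mean before dividing.  Some vendor tools report the plain
  ratio `S/O`; the subtracted convention matches the published group means
  (healthy-range SBR ≈ 2, severe loss < 1) and is used everywhere here.
* The per-side striatal mean is the **voxel-weighted union** of the caudate
  and putamen VOIs (a whole-striatum value).  Whether vendor software
  averages sub-region ratios instead is not documented; the union mean is
  the convention chosen here and is applied consistently to phantom truth
  and extraction, so round-trips are exact.
* **Min-of-sides rule**: reported SBR and PCR are the smaller of the two
  per-side values (disease is asymmetric; the worse side is diagnostic).
* **AI** uses the absolute left-right difference over the side mean and is
  a fraction (~0.03–0.10), not a percent.  It is undefined (error for
  direct calls, NaN in phantom truth) when the mean per-side SBR is not
  positive.
* **WR** is reported in percent.  The decay coefficient defaults to
  `k = 2^(−2.75 h / 13.2232 h) ≈ 0.8657` — the physical decay of ¹²³I
  between the standard 15-min and 3-h acquisitions.  Clinical packages do
  not publish their `k`; it is overridable wherever WR is computed.
* ROI/VOI "count density" is the mean pixel/voxel intensity inside the
  label mask.

## CART engine

* **Splits**: exhaustive search over every feature and every midpoint
  between consecutive distinct sorted values; routing is "`≤` goes left".
  Split scores are compared by exact integer cross-multiplication
  (class counts are integers, so the weighted-Gini objective is rational);
  ties break by the fixed feature order
  (H/M Early, H/M Delay, WR, SBR, PCR, AI), then by the smaller threshold.
  Predicted classes break count ties by the fixed label order
  (NPS, PD, DLB, PSP, MSA).  This makes trees bit-reproducible and lets
  tests demand exact agreement with a brute-force oracle.
* **Growth controls** default to `minsplit = 20` (smallest node that may be
  split), `minbucket = 7` (smallest child), `max_depth = 30` — conventional
  recursive-partitioning defaults; all configurable.  Priors are the
  empirical class frequencies; misclassification costs are uniform.
* **Pruning**: weakest-link cost-complexity.  Each step collapses every
  internal node minimizing `g = (R(node) − R(subtree)) / (leaves − 1)`
  (computed with exact rationals), iterating until the weakest remaining
  link exceeds the current alpha, which guarantees strictly increasing
  alphas and the nested optimal-subtree sequence.  Errors are
  misclassification counts relative to the root stump (`rel error`,
  `xerror` conventions), and the reported alpha is likewise scaled by the
  root error (the CP convention), so values are comparable across trees.
* **Cross-validation**: stratified k-fold (default k = 10) with a seeded
  per-class shuffle and round-robin assignment staggered across classes;
  classes smaller than k simply occupy fewer folds.  Each fold tree is
  pruned at the geometric mean of the main path's alpha interval and
  scored on the held-out fold.  `xstd` is the binomial-style standard
  error of the pooled cross-validated misclassification count, on the same
  root-relative scale as `xerror`.
* **Min-1SE selection**: the smallest subtree (largest alpha) whose
  `xerror` does not exceed the minimum `xerror` plus the standard error at
  that minimum.  A `1e-12` guard keeps profiles that sit exactly at the
  boundary in decimal (e.g. 0.40 vs 0.35 + 0.05) on the qualifying side of
  the float comparison.
* **Gini importance**: per-feature sum of node-weighted impurity decreases
  over the selected tree, normalized to sum to one; a stump yields an
  all-zero table and a warning.

## Published fixed tree

The deployable classifier splits on PCR 0.81 (root), WR 44.55 (high-PCR
branch), H/M (Delay) 2.26 and SBR 0.91 (low-PCR branch), with leaves NPS,
DLB, PD, PSP and a residual leaf (PCR ≤ 0.81, H/M (Delay) > 2.26,
SBR > 0.91) assigned PD.  The residual assignment is a reconstruction
choice: the source figure's leaf compositions are not machine-readable, and
PD — by far the largest Parkinsonian group, with only half of PSP cases
captured by the PSP leaf — is the only assignment consistent with the
published per-class denominators.  The topology is therefore overridable
from a tree-JSON file.  Cutoffs are compared verbatim at two decimals with
the same "`≤` left" convention; MSA is never an output.

## Synthetic data

* **Cohorts**: per-group independent truncated Gaussians for the six
  indices, parameterised by the published group means ± SDs and group
  sizes 80/90/21/16/9 (n = 216).  Only marginal moments are published, so
  no covariance is invented; an optional user-supplied correlation matrix
  is applied through a Gaussian copula (latent correlated normals mapped
  through the truncated-normal quantile function, preserving marginals).
  Truncation bounds are physiologic guards only: H/M ∈ [0.5, 6],
  WR ∈ [−30, 100] %, SBR ∈ [−0.5, 8], PCR ∈ [0.05, 2.5], AI ∈ [0, 1.5];
  all published means sit far inside them, so the truncation bias is
  negligible (tests compare sample means against the closed-form
  truncated-normal mean).
* **Phantoms**: the SPECT phantom places ellipsoidal caudate/putamen VOIs
  and a cuboid occipital slab on a fixed 64³ grid at 4.4 mm pitch, with
  the VOI label map generated jointly with the volume — no registration,
  by design: the indices consume only VOI means.  The planar pair uses
  rectangular heart/mediastinum ROIs on 128² images.  Noise is additive
  Gaussian clipped at zero (optional Poisson), and every phantom carries
  analytic truth values; noise-free extraction round-trips truth to
  ≤ 1e-9 relative error.
* **What the generator does not emulate**: between-index correlation,
  non-Gaussian and skewed clinical distributions, scanner physics
  (attenuation, scatter, partial volume), registration error, and
  disease-severity stratification.  Passing recovery tests therefore show
  the estimation machinery is correct under the published marginal
  structure — not that real cohorts would yield the same tree.

## Known limitations and observed behaviour on synthetic cohorts

The most consequential missing ingredient is the joint distribution.  On
independent-marginal cohorts the NPS-versus-rest separation carried by SBR
(NPS mean 2.13 vs 1.0–1.24 in all Parkinsonian groups) produces a larger
root Gini decrease than any PCR split, so fitted trees are SBR-led and the
Gini-importance profile concentrates on SBR, whereas the published
analysis of the real cohort is PCR-led.  The recovered cutoffs for the
shared features nonetheless land near the published ones (PCR ≈ 0.80,
H/M (Delay) ≈ 2.3).  Reproducing the published importance ordering would
require the real per-patient data or invented covariance; the package does
neither.

Other limitations: no surrogate splits or missing-value routing (missing
required features raise), no regression trees or forests, no ROC analysis,
and the post hoc test is Dunn's z-test (with pairwise Mann-Whitney behind
a flag) — the exact procedure behind the source's "Bonferroni post hoc" is
not documented.  For the smallest group (MSA, n = 9) Bonferroni-corrected
pairwise power against NPS is about 0.87 at the published effect size, so
simulation suites assert systematic direction for that pair rather than
near-certain significance.

## Problem sizes used in the test suite

Oracle-equivalence suites run 100 random instances with n ≤ 60 and ≤ 4
features against exhaustive brute force; calibration suites use 200 null
replicates (5 × 50 observations) for the Kruskal-Wallis type-I error and
100 seeded 216-patient cohorts for the post hoc direction pattern;
recovery suites fit 25 seeded 216-patient cohorts.  These sizes give
stable Monte-Carlo margins for every assertion while keeping the default
`pytest` run near fifteen seconds.
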