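# Methods

## Scope and design

The package re-implements, as a reusable and fully tested pipeline, a
multi-stage procedure for inferring the transcriptional architecture of
the tumor matrisome: global landscape classification, per-tumor matrisome
signatures, TF→target module consensus inference, a master-regulator
layer, and survival/druggability consequences. The original study ran on
a pan-cancer compendium (tens of thousands of samples, hundreds of
matrisome genes, external priors and annotation services). Here every
input is emulated by a synthetic generator with planted ground truth, so
the claims the test suite makes are about *method correctness and
recovery under controlled conditions*, not about reproducing cohort-
specific counts.

## Synthetic cohort model

Expression is generated directly on the log2(x+1) scale. Each gene g has
a global mean μ_g ~ N(8, 1.5²) and a per-(gene, tumor) offset
δ_{g,t} ~ N(0, 1²) drawn once from a shared hyper-distribution; sample
values add N(0, 1²) noise and are clipped at zero (the clip is inactive in
practice at these means). The per-tumor offsets make tumors separable by
their matrisome profile without hand-tuning, which is what the landscape
classifiers and the inter-tumor correlation map exploit. Matched healthy
tissues (one per tumor type, 1:1) share the tumor's baseline means, so
*the planted signature shift is the only tumor-vs-healthy signal*; with
`signature_log2_shift = 0` the tumor-vs-healthy comparison is an exact
null, which the calibration tests use.

Planted structure, all recorded in a `GroundTruth` sidecar:

- **Signatures** — disjoint blocks of `signature_genes_per_tumor`
  matrisome genes shifted up by `signature_log2_shift` (default +4 log2
  units, a strong but realistic tumor-specific induction) in the owning
  tumor's tumor samples only.
- **Modules** — TF→target pairs built by the shared-latent construction
  z_target = α·z_TF + √(1−α²)·ε with α = `r_in` (default 0.8) inside the
  owning tumor and α = `r_out` (default 0.1) everywhere else; α equals
  the population Pearson correlation in closed form. Module targets are
  drawn from the owning tumor's signature genes.
- **Masters** — tumor-specific drivers carry mutation frequency
  `driver_freq_specific` (default 0.2, comfortably above the 5% filter);
  one pan-cancer driver is planted as a *common* regulator of the first
  two tumors (frequency 0.15 there vs 0.03 elsewhere, hence above its own
  cross-cohort mean exactly where planted). Masters receive PPI edges to
  30% of the owning tumor's module TFs; the two decoy classes fail
  exactly one filter each (frequency 0.04, or zero edges into the module
  TF set). Master genes are also elevated by +1.5 log2 units in their
  owning *tissue* (tumor and matched healthy alike), giving the
  cluster-level regulator selection a real signal without perturbing the
  tumor-vs-healthy null.
- **Prognostic effects** — survival times are exponential; a sample's
  hazard is multiplied by `hazard_ratio_prognostic` (default 3) once per
  planted prognostic module for which it falls in the at-risk stratum
  (high activity for noxious modules, low for favorable). Censoring is an
  independent exponential calibrated so each sample's censoring
  probability equals `censoring_rate` exactly.
- **Priors** — each of six sources (four "textual" databases plus
  CAGE-style TF presence and TFBS enrichment) reports a true pair with
  probability `prior_coverage` (default 0.8); a structural guarantee then
  enforces what the mining rule needs (≥ 2 sources, ≥ 1 functional) with
  probability 1, not merely in expectation. Decoy pairs — `decoy_rate`
  (default 3) per true pair — target signature genes with random source
  membership, so a realistic fraction of them survives mining and must be
  eliminated by the correlation, Youden, and model-confirmation stages.

Determinism: every stage draws from `default_rng([stage_tag, seed])`, so
one root seed yields bit-identical outputs and regenerating one table
never perturbs the others.

What the generator does *not* emulate: batch effects and platform noise,
library-size artifacts, CAGE read counts, metastatic/recurrent-specific
biology, and correlated confounding between tissue of origin and
signature content. Passing recovery tests therefore demonstrates that the
pipeline's logic is correct and well-calibrated under its stated model,
not that real-cohort numbers would be reproduced.

## Landscape

Per-tumor ranking uses mean expression over non-healthy samples with
lexicographic tie-breaks. The inter-tumor map correlates tumor
mean-profiles over the union of per-tumor top-k lists and clusters them
by average linkage on 1 − r with a configurable cut height (default 0.5)
— a deterministic stand-in for reading blocks off a correlation heatmap.
Classification uses three algorithm families (RBF SVM, a small MLP, a
decision tree — any decision-tree family member satisfies the contract)
over repeated random 80/20 splits (defaults 100×/10×/10×),
standardization fit on training folds only to avoid leakage, per-tumor
recall averaged within and then unweighted across algorithms
(macro-averaging; whether the original recall was macro- or
micro-averaged is not determinable, macro is implemented). Contingency
tests apply the Yates continuity correction on 2×2 tables and plain
Pearson chi-square otherwise; tables with a zero margin or fewer than two
rows/columns are rejected.

## Signatures

Per tumor, each matrisome gene is compared against matched healthy tissue
and against the pooled rest of the cohort (excluding same-cluster tumors,
so related tumors do not mask shared programs) by two-sided Welch t-tests
— Welch because group sizes and variances are unequal by design. BH
adjustment is applied separately within each comparison family (all
matrisome genes × one tumor × one comparison); membership requires
positive mean difference and adjusted P < 0.05 in *both* comparisons.
The rest-of-cohort comparison pools all other tumors into a single group.
Cluster signatures are exact intersections of member signatures. Tumors
without matched healthy tissue are skipped with a logged reason.

## Module consensus

Stage order and contracts are described in the README. Numerical choices:

- `fisher_z` is `atanh`, with a hard domain check at |r| = 1; correlation
  values are clipped to ±0.999999 before transformation only to guard
  against degenerate duplicated-sample inputs.
- The Youden cutpoint scans midpoints between consecutive distinct pooled
  values; sensitivity counts zCor_in strictly above, specificity counts
  zCor_rest at or below. Ties resolve to the smallest maximizing cutpoint
  with a 1e-9 tolerance absorbing float noise (distinct true J values on
  n₁ vs n₂ samples differ by at least 1/(n₁n₂)). The "confidence
  interval = 0.95" phrasing attached to the Youden computation in the
  source procedure is not interpretable as an operation on the cutpoint;
  it is accepted as a config echo and does not alter the threshold.
- Adaptive lasso: γ = 1, initial weights from OLS with a ridge fallback
  (α = 0.01) for rank-deficient designs; exact-duplicate TF columns are
  deduplicated up front keeping the lexicographically first identifier,
  which makes the collinear tie-break deterministic. Penalty by k-fold CV
  (k = min(5, n/10)).
- Models 2 and 3 use 10 random 90% subsamples (the stated "10×
  cross-validation" does not fix a scheme; subsampling-stability is the
  standard reading for structure learning) and a 50% stability threshold,
  both configurable. Model 2 scores candidate parent sets with the
  Gaussian BIC via greedy forward selection — a score-based,
  sparsity-inducing structure search restricted to the model-1 edge set.
  Model 3 performs neighborhood selection with an L1 penalty chosen by
  BIC, which rejects null edges more sharply than prediction-optimal CV.
- Consensus keeps modules in ≥ 2 of 3 models; since models 2–3 are
  restricted to model 1, edges outside model 1 can never qualify.
- PPS = 100 × (#High + #Medium)/#assayed; proteins absent from the
  staining table are "not assayed", a distinct state from PPS = 0, and
  excluded from the validation denominator.

## Master regulators

All three filters are strict inequalities (frequency > 5%, frequency >
own cross-cohort mean, TF coverage > 10%), verified at their exact
boundaries. The remark that the coverage cut corresponds to the top half
of mined drivers is treated as an observation about the original data,
not as a second filter. Cluster-level regulator extraction intersects
member master lists, then trains an L2-penalized linear SVM (the
vendor-specific epsilon/lambda knobs of the original collapse to one
regularization strength, default C = 1) on per-sample expression over 10
random 80/20 splits, reporting mean held-out ROC AUC and normalized
|coefficient| importances. Pathway over-representation is a one-sided
hypergeometric test against a user-supplied (or synthetic) GMT table with
BH FDR across pathways; the universe defaults to all genes in the
expression matrix; a pathway is "mutationally activated" when ≥ 2
cancer-specific masters belong to it.

## Survival and druggability

Module activity is the unweighted mean of the TF and target log2 values;
dichotomization is at the cohort mean with ties assigned to "low".
Strata are compared by the standard log-rank test; direction (noxious vs
favorable) is defined by restricted-mean survival of the fitted KM curves
up to the largest observed time — no Cox model is fit anywhere, so the
sign convention stays nonparametric — and is reported only for
significant modules. Raw per-module P values are the primary calls,
matching the monovariate design; BH-adjusted values are emitted alongside
for transparency. Druggability assigns each mechanism-bearing drug–gene
row to its layer (master > TF > matrisome precedence for the rare
multi-layer gene) and splits FDA cancer drugs into on-label vs off-label
by the tumor's presence in the approval list; mechanism-less rows are
removed at load time and can never enter a report.

## Problem sizes

The default study conditions are 5 tumor types × 200 tumor samples
(+ 50 matched healthy each), 300 genes of which 60 matrisome and 40 TFs,
10 planted modules and 10 signature genes per tumor, r_in = 0.8,
r_out = 0.1, decoy rate 3. Recovery suites run 10 replicate cohorts;
null-calibration suites run 100 replicate survival simulations on a
2-tumor × 100-sample cohort and 3 replicate zero-shift cohorts. These
sizes give the planted effects near-unit power while keeping each full
pipeline run in the seconds range.

## Known limitations

- The generator's correlation structure is pairwise (one latent factor
  per planted pair); it does not emulate dense co-regulation, so the
  adaptive-lasso and conditional-dependence stages face easier collinear
  structure than real data would present.
- Pan-cancer "rest" pooling assumes roughly comparable cohort sizes;
  heavily unbalanced cohorts would weight r_rest toward the large ones.
- The Youden threshold is a single global cutpoint per tumor; when decoy
  contamination of the candidate set is heavy and diffuse, the maximizing
  cutpoint can sit low and defer decoy removal to the model-confirmation
  stages (observed occasionally in the seeded runs; final precision is
  restored downstream).
- Direction assignment by restricted-mean survival can be unstable when
  censoring is extreme (> 80%); the default censoring rate is 30%.
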