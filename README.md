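# matrisome-atlas

A tested re-implementation of an end-to-end pipeline for charting how
tumors rewire their extracellular matrix transcriptionally: per-tumor
**matrisome signatures** (ECM and ECM-associated genes up-regulated versus
both matched healthy tissue and the rest of a pan-tumor cohort), the
**TF→target regulatory modules** controlling those signatures, the
**master-regulator** driver layer physically wired to the module TFs, and
the **prognostic and druggability** consequences of module activity.

Because the original inputs are large controlled-access downloads, the
package ships a first-class synthetic-cohort generator that emulates every
input — log2(x+1)-scale expression with matched healthy samples, a
categorized matrisome catalog, six TF→target prior-evidence sources,
driver mutation frequencies, protein–protein interactions,
immunohistochemistry staining, survival follow-up, and drug–gene
interactions — with *planted, recoverable structure*, so every inference
stage is benchmarked against known ground truth, offline.

## The method

For each tumor *t* with signature gene set *S(t)*:

1. **Mining.** Candidate modules are (TF, g) pairs with g ∈ *S(t)*
   supported by ≥ 2 prior sources, at least one functional
   (CAGE-style TF presence or TF-binding-site enrichment).
2. **Correlation separation.** Pearson r of each pair in-tumor (r_in) and
   over the pooled rest of the cohort (r_rest); pairs with r_in ≤ 0 are
   dropped and both are Fisher-transformed, zCor = atanh(r). The cutpoint
   θ maximizing Youden's J = sensitivity + specificity − 1 between the
   {zCor_in} and {zCor_rest} samples is computed, and a module survives
   iff zCor_in > θ and zCor_in > zCor_rest.
3. **Adaptive lasso pruning.** For each target with > 1 surviving TF, the
   target is regressed on its TFs with weights w_j = 1/|β̂_j| (γ = 1,
   initial fit OLS, ridge if collinear) and a cross-validated L1 penalty;
   un-shrunk TFs form *model 1*.
4. **Confirmation.** Model 2: greedy BIC-scored Gaussian structure search
   restricted to the model-1 edges; model 3: per-target L1 neighborhood
   selection (BIC penalty); both over 10 random 90% subsamples with a
   ≥ 50% stability rule.
5. **Consensus.** Final modules appear in ≥ 2 of the three models
   (equivalently model 1 ∩ (model 2 ∪ model 3)).

Above the modules, drivers become **master regulators** when their
mutation frequency passes a strict filter (tumor-specific: > 5% in-tumor;
pan-cancer: > own cross-cohort mean) *and* they contact > 10% of the
tumor's module TFs in the PPI network. Module **activity** (mean of TF
and target log2 expression) is mean-dichotomized into high/low and
compared by Kaplan–Meier/log-rank; the full architecture (matrisome +
TFs + masters) is mapped to drugs with an on-/off-label partition.

## Worked example

The numbered drivers under `analysis/` run the whole study on one
synthetic cohort (5 tumor types × 200 samples, 10 planted modules each,
r_in = 0.8, r_out = 0.1, 3 decoy prior pairs per true pair):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_landscape.py --seed 1
python analysis/03_signatures.py
python analysis/04_modules.py --seed 1
python analysis/05_masters.py --seed 1
python analysis/06_survival_druggability.py
```

Representative output (seed 1):

```
mean recall 99.9% across 5 tumors; confusion chi-square 11960.1 (P = 0)
TUM01: 10 signature genes (10/10 planted recovered)
TUM02: 31 mined -> 19 after correlation -> 10 after Youden -> 10 model 1 -> 10 final (threshold zCor > 0.69)
recovery vs planted truth: precision 0.980, recall 1.000
staining cross-validation: 81/81 assayed proteins with PPS > 0 (mean PPS 60.6%)
masters per tumor: mean 2.4 total, 2.0 tumor-specific; weighted avg TFs per master 3.17
cluster ['TUM01', 'TUM02']: shared regulators ['G0010'], AUC 0.816
TUM03: 2/10 modules prognostic at P < 0.05; 2/2 planted effects recovered with direction
druggability: 69 drug-gene rows, 7 on-label
```

Reading: the classifier recall shows the synthetic tumors are separable by
matrisome expression alone; the stage counts show the consensus pipeline
shrinking monotonically from mined candidates to final modules; precision
0.98 / recall 1.0 means the pipeline recovered all 50 planted TF→target
modules and admitted one decoy; both planted prognostic modules per tumor
are rediscovered with the correct direction (noxious vs favorable).

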