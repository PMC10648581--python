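# Methods

`mirec` implements a subtype-profiling analysis for bulk miRNA RT-qPCR
panels, modeled on a clinical endometrial-carcinoma design: a 384-well
panel of 352 miRNA assays plus 32 synthetic spike-in controls measured on
119 tumors spanning four histological subtypes (endometrioid, serous,
clear cell, de-differentiated), four TCGA-surrogate molecular subtypes
(MMR-deficient, POLE-mutated, p53 wild type, p53 abnormal; 102 of 119
labelled) and CTNNB1 mutation status (92 sequenced, 19 mutated). This
note records the model, the defaults and why they hold, and what the
synthetic validation does and does not establish.

## Normalization model

Raw quantification cycles Ct(m, s) are converted to log2 relative
expression against the per-sample median spike-in Ct:

    expression(m, s) = median_k Ct(spike_k, s) − Ct(m, s)

One unit equals one PCR cycle, i.e. a two-fold abundance difference, and
higher values mean more abundant. Any technical factor that shifts all
assays of a sample by a constant number of cycles (input amount, RT
efficiency) cancels exactly; this invariance is tested directly.
Commercial panel pipelines use proprietary normalization schemes; the
spike-in median ΔCt used here is the standard transparent stand-in and is
deterministic and testable, which is what the downstream statistics need.

Detection handling: a Ct at or above the detection limit (default 38
cycles) or missing counts as undetected. A miRNA undetected in more than
`max_missing_frac` (default 20%) of samples is dropped; remaining
undetected entries are imputed at the miRNA's minimum observed expression
minus one cycle — a conservative floor just below the weakest observed
detection that keeps the matrix finite without inventing signal. Both
thresholds are exposed as parameters.

## Differential screen

Each subtype level is contrasted one-vs-rest: samples with the level
against all other samples with a *known* value of the same variable.
Samples with unknown labels are excluded from both sides — pooling them
into the control group would contaminate it with unlabelled members of
the target class (only 102 of 119 tumors carry a molecular label).

Per miRNA the screen reports:

* **Fold change** — `2^(mean log2 target − mean log2 rest)`, the ratio of
  geometric means. On this panel's scale the ratio-of-geometric-means
  reading is the one under which the reference MMR-deficient column
  (values 1.24–1.37) has effects "ranging from 0.1 to 0.4", i.e.
  |FC − 1|.
* **Student t** — two-sample pooled-variance t on log2 expression,
  positive when the target group is higher. The log-normal noise model of
  the simulator makes this test correctly specified by construction.
* **Permutation p** — two-sided: group labels are reassigned uniformly at
  random B = 1000 times preserving group sizes, and
  `p = (1 + #{|t_perm| ≥ |t_obs|}) / (B + 1)`. The +1 estimator never
  returns zero and is mildly conservative. When the label-assignment
  space has at most B distinct assignments (e.g. 6 vs 6 gives 924), it is
  enumerated exhaustively and p is the exact proportion; tests verify the
  sampled estimator against brute-force enumeration on every contrast
  shape with ≤ 10 samples.

Significance is `p < 0.05` with no multiple-testing correction (the
screen is a ranking device; the record count is reported so users can
post-correct). A separate effect-size filter keeps `|FC − 1| > 0.5`
strictly — fold change above 1.5 or below 0.5; boundary values are
excluded, the convention under which the shipped reference columns
reproduce their published survivor counts (28/3/13/11 histological, 0 for
MMR-deficient).

Numerical notes: the permutation batch is computed as matrix products
over all labellings at once; rows are mean-centered first (t is
shift-invariant) to limit cancellation, the observed statistic is
computed inside the same batched evaluation so the identity labelling can
never lose to itself by floating-point noise, and a 1e-12 relative buffer
counts mirror-image labellings as ties. Zero pooled variance yields t = 0
for equal means and a signed-infinity sentinel otherwise.

## Synthetic cohorts

The generator emulates the study design in the Ct domain. Spike-in base
Cts cluster around 20 cycles (median exactly 20); each miRNA draws a
baseline log2 level such that raw Cts center on `baseline_ct_mean`
(default 28 ± 2 cycles between miRNAs). Planted effects add
`log2(fold_change)` to every labelled member of the target group.
Within-group biological noise is Gaussian in log2 (default
`noise_sd = 1.0` cycle) — log-normal on the linear scale, the standard
description of qPCR ΔCt spread; the study itself reports no within-group
variance, so this default is a package choice, not a reported value.
Per-sample technical shifts (default SD 1 cycle) move all assays
including spike-ins and must vanish under normalization. Cts at or beyond
the detection limit are emitted as missing, producing realistic censoring
of lowly expressed miRNAs.

Group structure: histology sizes 89/8/13/9; molecular labels 48/8/35/11
assigned to a random 102-sample subset *independently* of histology; 92
random samples carry a CTNNB1 result with 19 mutated, placed
preferentially in endometrioid tumors (17 of 19) to reproduce the known
confounding without modeling biology. Grades split endometrioid tumors
33:33:23 across G1/G2/G3. The default planted-effect catalogue is the
shipped reference fold-change table (94 effects, 0.30×–14.9×), so default
runs produce screen tables on the clinical effect-size scale. Each random
component (labels, baselines, noise, shifts) uses its own child stream of
the seed, so disabling one leaves the others' draws intact; generation is
a pure function of the config.

What the simulator does **not** emulate: correlated miRNA co-expression
(rows are independent given their group), batch/plate structure beyond
the additive shift, heavy-tailed or sample-quality-dependent noise, and
any histology–molecular dependence. Passing recovery tests therefore
demonstrates correctness of the statistics under the design's group sizes
and noise scale, not robustness to those real-data complications.

## Classifier panels

One-vs-rest subtype membership is scored by an L2- (ridge-) penalized
logistic model (penalty weight 1.0) on standardized log2 expression of a
candidate panel. The base classifier, the number of folds, and the
evaluation protocol are package choices — deterministic, stable for
cohorts of ~100 samples with panels of ≤ 10 features, and rank-equivalent
to common linear alternatives on standardized inputs. Standardization
parameters and weights are always learned on training folds only; a
pure-noise guard test confirms the cross-validated AUC of fixed noise
panels stays within the null band.

Cross-validation is stratified 5-fold (the smallest modelled groups — 8
POLE, 11 p53-abnormal — still place at least one positive per fold);
held-out scores of the five folds are pooled and a single Mann–Whitney
AUC is computed on the pool, which avoids the instability of per-fold
AUCs computed on 1–3 positives.

Sequential forward selection starts from the empty panel and at each step
adds the candidate maximizing the cross-validated AUC averaged over
`n_selection_repeats` fold partitions (default 5; partitions are shared
across candidates and steps, so comparisons are paired). Growth stops
when the best improvement falls below `min_improvement = 0.005` AUC or at
`max_features = 10`, the envelope of the 3–10-miRNA panels such models
reach in practice. The first feature is always kept (a model is never
empty; a warning is logged if nothing beats 0.5). Ties break toward the
earlier candidate index. The final AUC is recomputed over `n_repeats =
50` fold partitions whose seeds are disjoint from those used during
selection.

Two caveats are deliberate. First, the selection criterion uses fewer
repeats than the final evaluation: scoring every candidate at every step
over all 50 partitions costs ~10⁵–10⁶ model fits per panel, while 5
paired partitions already rank candidates stably; the reported AUC still
uses the full 50. Second, re-evaluating a greedily selected panel on
fresh fold partitions of the *same cohort* does not remove selection
(winner's-curse) bias — only an external cohort can. The reported AUC
should be read accordingly; the selection trace is emitted so the
step-wise criterion is auditable.

In the orchestrated pipeline, the candidate pool for each subtype panel
is that subtype's screen-significant miRNAs (falling back to the full
panel when fewer than twice `max_features` are significant); the direct
library call accepts any candidate list.

## Pipeline and reproducibility

`run-all` executes simulate/load → normalize → nine screens (four
histological, four molecular, CTNNB1) → three panels (MMR-deficient,
p53-abnormal, CTNNB1-mutated), writing per-contrast screen TSVs with a
parameter sidecar, filtered top tables, a direction-count summary, model
JSONs with selection traces, ROC point TSVs, and a manifest with a
SHA-256 checksum per artifact. One global seed fans out to per-stage
seeds by stable hashing of stage names, so a rerun with the same config
is byte-identical and any stage can be reproduced in isolation.

## Problem sizes used in validation

The validation suite runs the permutation screen at full study scale (352
miRNAs × 119 samples, B = 1000). Effect recovery is assessed over 20
replicate cohorts under one base seed, calling an effect recovered when
it is significant in a majority of replicates and its mean estimated fold
change lies within ±20% of truth: at these group sizes the per-cohort
log2 estimate has SE ≈ 0.21, so single-cohort estimates of the weakest
catalogue effects (FC ≈ 1.5) are coin flips against a ±20% band, while
the 20-replicate average tests systematic recovery. Selection-consistency
checks use 100 replicates of a 51-candidate cohort and one 352-candidate
cohort with the 48 vs 54 molecular split; selection there averages 10
fold partitions per candidate so the criterion noise (≈ 0.003 AUC) stays
well under the 0.005 stopping margin. Panel-level determinism is checked
on a reduced 60-miRNA configuration.

## Known limitations

* The spike-in ΔCt scheme is a stand-in for proprietary panel
  normalization; absolute quantification, efficiency curves and plate
  effects are out of scope.
* No multiple-testing correction and no Welch/nonparametric variants; the
  pooled-variance t matches the simulator's equal-variance noise but real
  cohorts may violate it.
* Reported panel AUCs carry selection bias (see above) and the synthetic
  cohorts' independence assumptions make classification easier than on
  real tissue; cross-cohort validation is a non-goal here.
* Sampled permutation p-values have resolution 1/(B+1); exact enumeration
  engages only when the assignment space is at most B.
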