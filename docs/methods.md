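# Methods

This note documents the models, defaults and design choices behind
`bsgdiag`. It describes what the code computes and why; every number
quoted as an observation here is produced by the test suite or the
worked example, not imported from elsewhere.

## Problem setting

Brainstem gliomas stratify into three molecular subtypes with sharply
different prognoses: H3K27M-mutant (K27M substitution in H3F3A or
HIST1H3B/C; worst outcome), IDH-mutant (IDH1/2; best outcome among
diffuse gliomas) and double-wildtype (DW). Tissue is hard and risky to
obtain from the brainstem, so the analysis targets cerebrospinal-fluid
(CSF) circulating tumor DNA: a targeted panel measures methylation beta
values (fraction methylated, in [0, 1]) at subtype-informative CpG
sites, and a companion gene panel yields mutation calls with variant
allele frequencies (VAF). The package implements the full decision
pipeline over those two data streams.

## Marker discovery

Screening splits the labelled beta matrix into a class-stratified
discovery portion (default 70%) and a held-out remainder. Per class
pair, a CpG is differential when the available-case group-mean
difference satisfies |Δβ| ≥ 0.3 and its Wilcoxon rank-sum p-value,
Benjamini–Hochberg adjusted across sites within the contrast, falls
below α = 0.05. BH is our choice of multiplicity control; with a 0.3
effect-size floor it is essentially a guard against tiny-n flukes.

Candidates from all contrasts are reduced by a three-algorithm
consensus: impurity importance from a 300-tree random forest, aggregate
|weight| from standardized one-vs-rest linear SVMs, and order of first
entry along an L1-regularized multinomial logistic path (30 log-spaced
penalty steps). Each algorithm "selects" its top k; sites selected by
at least two of three survive and are truncated to k by mean rank. The
two-of-three rule and the mean-rank tie-break are package choices — any
single algorithm is noisy at array scale, and the majority vote is
order-invariant and deterministic under the seed.

Retained sites are assigned a marker class from class mean betas with a
margin m (default 0.2, deliberately close to the 0.3 screening delta):

* **H3-specific**: mean(H3K27M) exceeds both mean(IDH) and every other
  class mean by m — sites consistently hypermethylated in H3K27M tumors;
* **IDH-specific**: mean(IDH) exceeds mean(H3K27M) by m while the
  H3K27M mean stays within m of the other classes — sites
  hypermethylated in IDH tumors but low in H3K27M tumors.

Sites matching neither pattern are dropped with a logged count. A panel
with either class empty is an error, because the signature score below
is undefined without both.

The wet-lab reduction of a candidate list to a validated primer panel is
chemistry, not statistics; the package treats the final panel size k as
a parameter (default 76) and does not model primer attrition.

## Methylation Signature Score (MSS)

For a panel with n_H3 H3-specific and n_IDH IDH-specific probes,
N = n_H3 + n_IDH:

    MSS = ( Σ β(H3 sites) + (1 − Σ β(IDH sites)) ) / N

The formula is implemented literally — sums of betas, a single +1,
division by the total probe count. Its attainable range for a given
panel is [(1 − n_IDH)/N, (n_H3 + 1)/N], which always lies inside
[−1, 1]; the interval endpoints themselves are only reached by
degenerate panels. The literal reading reproduces the small magnitudes
characteristic of this score (tissue medians of order 0.1, CSF values
of order 0.01–0.1); a mean-difference variant would not.

Missing probes (common in CSF) are handled by class-proportional
rescaling: each class's observed sum is scaled by n_class /
n_observed_class before applying the formula. Under probes missing
completely at random this is unbiased (verified by simulation in the
test suite). Every result carries observed-probe counts and a coverage
QC flag (default threshold 0.5); a class with zero observed probes is
an error rather than a silent extrapolation.

## Subtype classifier, risk score, and fusion

A 500-tree random forest on panel betas produces the three-class
probability triple (p_H3K27M, p_IDH, p_DW). Hyperparameters come from a
small grid (max_features ∈ {√p, 0.3p} × min_samples_leaf ∈ {1, 3})
chosen by stratified 10-fold cross-validated micro-AUC; the winner is
refit on all training data. The fold count drops with a warning when
the smallest class cannot populate ten folds. Missing probes at predict
time are imputed with training-set class-agnostic medians, which cannot
leak label information. The **Methylation Risk Score (MRS)** is the
forest's H3K27M probability.

Mutation evidence is deterministic: an H3F3A/HIST1H3B/HIST1H3C K27M
call sets the H3K27M probability to 1; an IDH1/2 call sets the IDH
probability to 1; the DW class never receives positive mutation
evidence. H3-gene calls without the K27M substitution (e.g. G34
variants) do not trigger the rule.

The fused diagnosis takes the per-class maximum of the two triples and
calls the argmax, ties broken H3K27M > IDH > DW. Design notes:

* The combined triple is **not renormalized**. The argmax is invariant
  either way, and renormalizing would dilute the certainty a called
  driver conveys.
* The tie-break priority puts the worst-prognosis class first: in this
  disease, trading specificity for H3K27M sensitivity is the clinically
  defensible direction.
* Both drivers called together is biologically anomalous (they are
  mutually exclusive in these tumors); the fusion classifies H3K27M and
  raises a conflict flag rather than dropping evidence silently.
* A below-LOD sample (no mutation library) passes the methylation
  triple through with evidence `methylation_only`.

## Evaluation statistics

Sensitivity/specificity are TPR/TNR with Agresti–Coull intervals
(adjusted counts ñ = n + z², p̃ = (x + z²/2)/ñ, half-width
z·√(p̃(1−p̃)/ñ), truncated to [0, 1]). ROC AUC is the midrank
Mann–Whitney statistic (ties get half credit). Interval estimates for
AUCs use nonparametric bootstrapping, default R = 100 with equi-tailed
percentile intervals; resampling is stratified within each truth class
so small-n resamples cannot lose a class. Three-class performance is
summarized by one-vs-rest AUCs, their unweighted mean (macro-AUC) and
the AUC of the pooled sample × class binary expansion (micro-AUC) —
the standard reading of "micro". The coverage study in the test suite
shows the R = 100 percentile interval covering a true AUC of 0.8 about
91% of the time at n = 200, the familiar slight undercoverage of
small-R percentile bootstraps; R is a parameter if better calibration
is needed.

## Survival stratification

Patients split into high/low risk at an MRS cutoff; the shipped default
is 0.44 with the convention that *strictly greater* is high risk. The
cutoff is treated as an external constant. A separate exploratory tool
scans a grid for the maximally selected log-rank cutoff subject to at
least 15% of patients on each side, and its returned statistic is
documented as selection-inflated — it must not be reported as a
hypothesis test. Kaplan–Meier medians use the product-limit estimate
with a Not-Reached sentinel (infinity) when the curve stays above 0.5.
Cox fits use Efron tie handling, Wald intervals and Harrell
concordance; monotone-likelihood failures are retried with a small
ridge penalty and flagged.

## Longitudinal monitoring and MRD

A patient's series holds (day, timepoint, MSS result, VAF, phase)
points with strictly increasing days. VAF "undetectable" is an explicit
sentinel, never conflated with a measured 0.0. Dynamics are per-interval
and versus-baseline deltas with direction labels (stability band
|Δ| < 0.005). The **minimal-residual-disease flag** is true when the
VAF is undetectable while the MSS exceeds a detection floor; a
QC-failed MSS yields an indeterminate (None) flag, not a negative. The
floor has no published value; the default calibration is the 95th
percentile of MSS in background/DW samples, exposed as
`mss_detection_floor` and documented as a knob, not a constant.

## Synthetic cohort generator

The generator exists so the whole pipeline is testable offline; its
defaults define the study conditions used by the test suite.

**Tissue betas.** Per (subtype × site-class) mean with beta-distributed
noise parameterized by (mean, concentration); concentration defaults to
40 (sd ≈ 0.07 at mean 0.5), and `dispersion=None` switches noise off so
closed-form tests can be exact. Default means:

| subtype | H3 sites | IDH sites | noise sites |
|---------|----------|-----------|-------------|
| H3K27M  | 0.85     | 0.15      | 0.30        |
| IDH     | 0.60     | 0.90      | 0.35        |
| DW      | 0.15     | 0.12      | 0.25        |

The IDH row is hypermethylated at every panel site *relative to DW*
while staying 0.25 below the H3K27M level at H3 sites; with the default
40/36 panel split this makes the three tissue MSS medians come out
ordered and signed like the real assay (H3K27M ≈ 0.39, DW ≈ 0.04,
IDH ≈ −0.10 under defaults) and keeps the 0.2 marker-class margin
recoverable. Every H3K27M patient carries a K27M driver call (90%
H3F3A / 10% HIST1H3B), every IDH patient an IDH1 R132H call, DW none;
TP53/ATRX concurrency is sprinkled in for realism.

**CSF dilution.** β_csf = f·β_tumor + (1−f)·β_background with a
low-methylation background (mean 0.1 at every site) and tumor fraction
f ~ Beta(4, 2). DNA mass is lognormal with the log-mass shifted by
+1.0·f, so ctDNA-poor samples tend to fall under the 5 ng threshold
that gates mutation testing (BLOD: methylation only; ALOD: both). Under
defaults ~45% of samples are BLOD. Probes go missing at rate 0.05.
ALOD driver calls are emitted with sensitivity 0.95 and
VAF = f/2 × lognormal noise (heterozygous driver). No real
tumor-fraction or DNA-mass distributions are published for this
setting; these laws are placeholders chosen once to reproduce the
qualitative structure the analysis assumes (a dilution-sensitive MSS, a
dilution-buffered MRS, a roughly half-and-half LOD split) and are fully
configurable.

**Survival.** Weibull times (shape 1.3) whose scale shrinks with a
latent risk covariate and with H3K27M status as proportional hazards;
administrative censoring at a horizon (default 60 months).

**Longitudinal.** Tumor fraction follows per-phase multipliers of a
baseline f0; the VAF detection floor (default 0.02) sits above the
methylation floor, so post-treatment phases with small residual f show
the MRD pattern — methylation signal without detectable VAF.

**What the generator does not model:** fragment-length effects,
bisulfite/enzymatic conversion error, read-count noise, probe-specific
biases, intratumoral heterogeneity, or clonal evolution. Passing tests
therefore demonstrate that the *pipeline* recovers planted structure
under idealized noise, not that the assay performs at any particular
level on real CSF.

## Problem sizes and determinism

The test suite runs cohorts of 36–135 patients for pipeline checks,
400–500 for survival-law recovery, and 500 replicates for the bootstrap
coverage study; these sizes put Monte-Carlo error comfortably inside
the asserted bands while keeping the suite quick on one CPU. Every
stochastic operation takes an explicit integer seed and is
byte-deterministic under it; operation-specific salts derived from the
seed keep the tissue, CSF, survival and longitudinal draws independent.

## Known limitations

* The real assay's published headline numbers come from a specific
  62–80-patient clinical cohort and cannot be reproduced from synthetic
  data; the suite checks qualitative pattern recovery instead.
* The consensus rule (2-of-3, mean-rank truncation) is one defensible
  reading of "feature selection with RF, SVM and Lasso"; alternatives
  (intersection, union, stability selection) would change the candidate
  list at the margin.
* The attainable MSS range depends on the panel split; scores from
  panels with different n_H3/n_IDH are not directly comparable without
  renormalization.
* Combined fusion probabilities are decision scores, not calibrated
  posteriors.
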