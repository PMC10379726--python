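# Methods

## Dirichlet multinomial mixture community typing

Given genus counts *x*ᵢ with library size *n*ᵢ, component *k* has density
DM(*x*; α*ₖ*) = [*n*!/∏*x*ⱼ!] · Γ(*A*)/Γ(*n*+*A*) · ∏ⱼ Γ(*x*ⱼ+αⱼ)/Γ(αⱼ),
*A* = Σαⱼ. The mixture is fitted by EM: responsibilities from the current
(π, α); mixture weights from mean responsibilities; α by a
responsibility-weighted fixed-point (MM) update,

  αⱼ ← αⱼ · Σᵢ rᵢ[ψ(xᵢⱼ+αⱼ) − ψ(αⱼ)] / (Σᵢ rᵢ[ψ(nᵢ+A) − ψ(A)] + η),

which is an ascent step for the MAP objective under the weak exponential
prior α ~ Exp(η), η = 0.1 (prior mean 10). Inner updates are capped (10 per
M-step, tolerance 1e-3); EM stops when the penalized objective changes by
less than 1e-6 relative (max 200 iterations). Initialization is k-means++ on
centered-log-ratio proportions (pseudocount 0.5); restarts use distinct
seeds derived from the master seed, and the best run by penalized likelihood
wins. Hard assignment is the responsibility argmax, ties to the lowest
component index.

**Model evidence.** K is selected by the minimal Laplace-approximated
negative log evidence: −log Z ≈ f(θ̂) − (d/2)·log 2π + ½·log|H|, where f is
the negative log posterior at the fitted mode, d = K·T (the α parameters in
log space; the K−1 mixture weights contribute O(1) nats per component and
are omitted from the quadratic term), and H is the block-diagonal Hessian of
the responsibility-weighted complete-data negative log posterior, computed
analytically in log-α space (verified against numerical differentiation).
A non-positive-definite block triggers a BIC-style fallback
(−loglik + ½·d·log N) with a warning.

**Degeneracy guard.** Mixture likelihoods admit micro-cluster solutions: a
component that concentrates on a handful of samples is unidentifiable (T
parameters, a few observations), and its near-flat Hessian block spuriously
*inflates* the Laplace integral because the exponential prior is nearly flat
in log-α. EM therefore enforces a minimum effective occupancy per component
(`min_weight`, default 3% of samples, applied after a 2-iteration grace
period); components below it are pruned with a warning and the model's K is
the effective component count. Community types are population-level states,
so a 3% floor is scientifically conservative; it is a fitting constraint,
not a change to the data or the selection rule.

**FCT ordering.** Components are renumbered FCT1..FCTK by ascending mean age
of their member samples (ties: ascending median age, then raw index). Mean
age was chosen over first-appearance age because it is robust to single
early outliers; the rule is a documented switch point if another ordering is
preferred.

## Transition network

Month index = round(age / 30.4375) with half-up rounding (mean Gregorian
month). For each infant, every consecutive sample pair contributes one edge
from its source to its destination age bin — same-bin pairs give self-loops
(visits < 30 d apart), skipped bins give skip edges. Node occupancy is the
fraction of an age column's samples in each FCT (columns sum to 1); edge
fractions are relative to all transitions leaving the source column. Edges
at or below the display threshold (4%) are retained in the data and only
flagged `hidden` for rendering, so occupancies never depend on the
threshold.

## Survival analysis

The event "reached FCT *t* or later" is timed at the age of the earliest
qualifying visit; infants never observed there are right-censored at their
last visit. Infants with fewer than two samples are excluded (generalizing
the exclusion of single-visit infants). Although visit spacing makes the
data interval-censored in principle, the implemented event time is the
explicit earliest-visit rule with right censoring only; interval-censored
likelihoods are out of scope.

The Cox model has a single binary covariate (control = 0, test = 1), Breslow
tie handling, Newton–Raphson with step clipping, and a |β| cap of 15 under
complete separation (flagged in the result). The reported test is the score
test at β = 0, which for a binary covariate without ties equals the
classical log-rank statistic (asserted against a direct 2×2-summation oracle
in the tests); the 95% CI is Wald. lifelines serves as an independent
cross-check of β and its standard error, never as the implementation.

## Rank statistics

`wmw_test` uses exact enumeration (shift algorithm) when the combined sample
size is ≤ 30 without ties, otherwise the tie- and continuity-corrected
normal approximation clipped to [0, 1] (so identical samples give p = 1).
Cliff's delta's 95% CI uses the consistent (unpooled) variance estimator
with normal quantiles, clamped to [−1, 1]. Kendall τ-b is exact for n ≤ 8
without ties, tie-corrected asymptotic otherwise; constant vectors yield
(τ = 0, p = 1) with a warning rather than NaN. Fisher's exact p sums
hypergeometric probabilities ≤ the observed table's. BH adjustment is off by
default for metabolite univariate sweeps (mirroring the exploratory,
unadjusted convention for small metabolomics panels) and on for taxa sweeps,
set enrichment, and all integration analyses. Taxon-set enrichment is a
competitive two-sided WMW on member vs. non-member Cliff's-delta ranks —
a documented stand-in, switchable if another statistic is preferred.

## PLS modelling

NIPALS PLS2 on mean-centered data; X columns unit-variance scaled by default
(Pareto and none available), Y columns unit-variance scaled so a days-scale
age column and a 0/1 treatment coding carry comparable weight. Constant X
columns are dropped with a warning. Per-component explained Y-variance is
the SSY reduction from deflation; VIP follows the weighted sum-of-squares
formula and satisfies Σ VIP² = p to 1e-8 on every fit (tested). p(corr) is
the plain Pearson correlation between a component's scores and each scaled X
column — reported against component 2, where treatment loads in the combined
age+treatment model; the SIMCA-style loading-scaled variant was not chosen
because the plain correlation is reproducible without reference to a
specific vendor convention. Q2Y = 1 − PRESS/SS over 7 venetian-blind folds
assigned by sample order after a seeded shuffle; the permutation p-value
uses the +1-corrected count of permuted refits with Q2 ≥ observed (200
permutations by default). The discriminant rule — VIP > 1 and
|p(corr)| > 0.2 and WMW p < 0.05 — is a pure conjunction, reported sorted by
VIP.

## Bile-acid conjugation ratios

BA/CBA = (CA + CDCA + LCA + DCA) / (TCA + TCDCA + TDCA + GCA + TLCA + GCDCA
+ GDCA); CA/CCA = CA/(GCA + TCA); CDCA/CCDCA = CDCA/(GCDCA + TCDCA);
LCA/CLCA = LCA/(GLCA + TLCA). GLCA is included in the pair-specific
lithocholic denominator even though the total-conjugate sum lists only TLCA,
since the pair ratio is meaningless without both conjugates of its acid.
Zero denominators and missing analytes give an undefined (NaN) ratio, never
infinity. Baseline-shift tests are unpaired two-sided WMW of each follow-up
visit against the same arm's V0 values — unpaired because visit-level group
composition varies with dropout and the rank test tolerates unequal n.

## Omics integration

Features detected (> 0) in fewer than 3 shared samples are removed before
testing; Kendall τ-b and two-sided p are computed for every remaining
KO × metabolite pair, and BH is applied once across the entire matrix with
significance at FDR 10% (a nominal p < 0.05 tier is also flagged for
display). Sidebar associations (treatment by MWU + Cliff's delta; FCT by
Kendall on ordinally encoded labels, FCT1 = 1, FCT2 = 2, ...) are computed
per visit with BH within the visit. Heatmap ordering is agglomerative Ward
linkage (Ward.D2 convention) on Euclidean distances between τ row- and
column-vectors.

## Synthetic cohort generator

The generator defines the study conditions; it is not a tuning dial.

- **Design.** 130 infants, 1:1 randomization, enrollment age uniform on
  14–180 d, stratified EE/LE at 90 d; visits V0 (enrollment), V1 (+30 d),
  V3 (+90 d), V6 (365 d of age); V0 always collected, later visits each
  missing with probability 0.07 (matching observed attrition of roughly
  5–10% per visit).
- **Trajectories.** Forward-only jump process FCT1→…→FCT5 with exponential
  stage waits of mean 60/90/120/150 d, multiplied by the treatment hazard
  ratio 0.56 in the test arm. Regressions are not generated latently (they
  can only arise from observation/assignment noise), matching the treatment
  of regression as rare.
- **Counts.** 30 genera; five alpha vectors with distinct dominant blocks
  (proteobacteria-rich newborn type, bifidobacteria milk-adapted type, early
  clostridia, mixed firmicutes, mature Faecalibacterium-rich type), baseline
  α = 0.05 elsewhere, concentration A ≈ 20–30. Pairwise Bray–Curtis between
  component means is ≥ 0.5 (min 0.80 in the default), keeping the K = 5
  recovery target meaningful. Library size is negative-binomial around
  20,000 reads (dispersion 10, floor 2,000) — far below real shotgun depth,
  since the DMM operates on composition, not absolute depth.
- **Metabolites.** Log-normal with median keyed by (FCT, arm). The
  control-arm 2′-FL trace is 86 nmol/g in FCT1 and 64 in FCT2 — the
  generator keys levels by community state rather than visit, and FCT1/FCT2
  dominate the earliest visits — decaying below 20 afterwards; the test arm
  carries the supplementation signal. Proteolytic (Ehrlich-pathway)
  catabolites rise with later FCTs and are scaled down (×0.25–0.55) in the
  test arm; SCFAs follow maturation with no arm effect. The 43-analyte
  bile-acid panel has large, arm-independent conjugated pools and
  unconjugated primaries that decline with maturation in the control arm
  but are maintained in the test arm.
- **KOs.** 20 KEGG orthologues as per-FCT loadings × log-normal noise,
  row-normalized: Ehrlich-pathway enzymes rise with maturation,
  amine-pathway decarboxylases fall, and choloylglycine hydrolase (BSH)
  peaks in the bifidobacteria-rich type.
- **What it does not emulate.** Strain-level structure, read-level
  sequencing error, household/antibiotic covariates, metabolite missingness
  patterns, inter-metabolite correlation beyond the shared FCT/arm
  dependence, and real phylogeny (the genus tree is a fixed-length
  phylum-block scaffold). Passing tests therefore demonstrate correctness
  of the *methods* under a faithful but idealized data-generating process,
  not performance on real sequencing data.

## Problem sizes and numerical choices

The default cohort (~480–500 samples × 30 genera) with K = 2..10 × 10
repeats completes model selection in about a minute on one CPU; the test
suite's calibration studies use 1,000–2,000 replicates for type-I-error and
FDR checks and n = 400–1,000 for recovery checks — sizes at which binomial
error bands are tight enough to be informative while the suite stays fast.
Parameter-recovery assertions compare fitted component means to generating
values by the mean L1 distance across components (≤ 0.05 at n = 400): at 80
samples per component the *empirical* cluster means already deviate from the
generating values by L1 ≈ 0.05–0.075, so per-component bounds at that level
would measure sampling noise, not estimator quality (the DM fit is closer to
truth than the plug-in empirical means).

Known limitations: evidence values at adjacent K can tie when higher-K
initializations collapse to the same effective model (the selected K is the
effective component count of the evidence-minimizing fit); the Laplace
approximation omits the mixture-weight block; exact WMW/Kendall branches
switch to asymptotics in the presence of any ties; the PLS permutation test
permutes whole Y rows (age and treatment together).
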