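# Methods

## Scope and model

`snpmeta` pools the evidence that candidate-gene association studies publish
for a single SNP: per-study allelic odds ratios for carrying one allele
rather than the other, estimated from whatever each study reported —
genotype counts, allele counts, an odds ratio with a p-value or 95% CI, or
transmitted/non-transmitted counts from parent-offspring trios.  The unit of
analysis is the allelic effect AE = log OR and its standard error seAE; the
pooled quantity is the DerSimonian–Laird (DL) random-effects mean of the
per-study AEs, with the fixed-effect (inverse-variance) pool always reported
alongside.  Strata ("All", "Asian", "Caucasian") are pooled independently,
and a stratum is analysed only when it has at least four usable studies.

The model assumes each study's AE is normally distributed around a
study-specific true effect, and that true effects are exchangeable draws
from Normal(θ, τ²).  τ² is the DL moment estimate truncated at zero;
confidence intervals use the normal 1.96 multiplier throughout (no
Knapp–Hartung adjustment), which matches how the source literature reports
CIs but is known to undercover somewhat when k is small and heterogeneity is
high (see *Calibration*, below).

## Effect extraction

Routes, in priority order (genotype counts > allele counts > statistics,
with CI preferred over p; trios always use transmission counts):

* **Counts.** AE is the Woolf log OR of the allele 2×2 table;
  seAE = sqrt of the summed reciprocal cells.  Genotype payloads are
  collapsed to allele counts (C_A = 2·AA + Aa) first.  When any cell is
  zero, 0.5 is added to every cell (Haldane–Anscombe); the same correction
  applies to zero trio counts.  The 2×2 table is retained on the estimate
  because the Harbord test needs it.
* **CI.** seAE = (log CI_up − log CI_low)/(2·1.96), the log-scale width of a
  95% interval.  A compatibility flag (`ci_se_literal`) reproduces the
  literal mixed-scale form CI_up − OR found in print; it exists for audit
  only and is never the default.
* **p-value.** seAE = |AE| / z(p) with
  z(p) = −0.862 + sqrt(0.743 − 2.404·ln p), a closed-form approximation to
  Φ⁻¹(1 − p/2).  Measured against the exact quantile the approximation is
  within 0.5% for p ∈ [5.4e-4, 0.24] but drifts to +2.1% at p = 1e-8 and
  +2.3% at p = 0.5; the package applies the formula as published and the
  test suite pins this measured accuracy profile.  An OR of exactly 1 with
  this route leaves seAE undefined and raises, so callers can fall back or
  exclude.  The reported p is assumed to be a two-sided allelic-test p.
* **Trios.** AE = log(C_T/C_N); seAE = sqrt(1/C_T + 1/C_N), the
  Kazeem–Farrall large-sample SE of the log relative risk.  A compatibility
  flag (`trio_se_literal`) reproduces the square-root-free form that appears
  in print.

## Harmonization and QC

Every study is aligned to the reference panel's forward strand and oriented
so its AE refers to the reference *minor* allele.  Decision procedure:
matching allele pair → frequency-concordance check; complemented pair →
strand flip, then the same check; palindromic pair (A/T, C/G) → orient by
allele frequency or exclude; anything else → excluded as unresolved.  The
concordance check calls a label switch — and negates AE — when the study's
frequency for the reference minor allele deviates from the reference MAF by
more than `switch_maf_delta` (0.2) *and* matches 1 − MAF within
`switch_match_tol` (0.1).  The two-sided rule separates true label switches
from ordinary subpopulation MAF drift; both thresholds are config keys.
Palindromic SNPs with reference MAF inside [0.4, 0.6] (`palindromic_low/high`)
are excluded as frequency-undecidable, as are palindromic studies reporting
no frequency at all.  Ancestry maps to reference populations via a config
table defaulting to Asian→EAS, Caucasian→EUR; SNPs absent from the panel
pass through unchanged with a warning note.

Control-group Hardy–Weinberg equilibrium is tested exactly (conditional
distribution of the heterozygote count given the allele counts; the p-value
sums configurations no more probable than the observed one).  A chi-square
variant is available by config.  Only genotype payloads are testable.  HWE
violation (p < 0.05) does not remove a study from the primary analysis; it
drives a separate sensitivity re-analysis.

## Diagnostics and sensitivity

All deleted quantities come from true leave-one-out refits with τ²
re-estimated on each k−1 subset.  A study is an outlier when its studentized
deleted residual t_i = (AE_i − pool_(−i)) / sqrt(se_i² + τ²_(−i) + se_(−i)²)
exceeds 1.96 in absolute value; influential when |DFFITS_i| =
|(pool − pool_(−i))/se_(−i)| exceeds 3·sqrt(1/(k−1)) or COVRATIO_i =
var_(−i)/var_full falls below 1 − 3/(k−1).  For this intercept-only model
DFBETAS coincides with DFFITS and is reported as such.  The cutoffs follow
the standard influence-diagnostics literature and are config keys; no
numeric cutoffs exist in the source literature, which speaks only of
"considerable changes".

Two independent re-analyses are reported beside the primary pool: one
excluding outliers and influential studies (a single exclusion set), one
excluding HWE violators.  The *presented* per-SNP result is the
outlier-sensitivity re-pool when exclusions occurred and the stratum stayed
eligible, else the primary.  Exclusions that push a stratum below four
studies mark it ineligible-after-sensitivity rather than re-pooling.

A note on invariances: DFFITS/COVRATIO are exactly invariant under joint
rescaling of all effects and standard errors (a change of units), because Q
is scale-free and τ̂² scales with the squared unit.  They are *not*
invariant under rescaling the standard errors alone, which changes the
relative weight of the re-estimated τ².

## Publication bias

Applied only to strata with at least `bias_min_k` (10) studies.  The Harbord
score test regresses Z_i/√V_i on √V_i with an intercept, where
Z_i = a_i − E[a_i | margins] and V_i is the hypergeometric variance of the
allele 2×2 table; the intercept is t-tested with k−2 df.  Studies that
reported only summary statistics carry no table; if fewer than 10 studies
have tables the test falls back to an Egger-style regression of AE_i/se_i on
1/se_i, and the report records the fallback.  Under the simulated no-bias
null (k = 15) the measured type-I rate is ≈ 0.04–0.05.

When the Harbord p is below `bias_alpha` (0.05), Duval–Tweedie trim-and-fill
runs with the L0 missing-study estimator (R0 available by config): trim the
k0 most extreme effects on the excess side, re-centre on the fixed-effect
pool of the untrimmed set, iterate to convergence (≤ 50 iterations), then
fill mirror-image pseudo-studies and report the DL pool of the filled set.
The trimming side comes from the sign of the Harbord intercept.  Filling
never removes observed studies.  Cross-checked against `metafor::trimfill`
on identical inputs, the implementation matches the reference's k0 and
adjusted estimates up to the expected estimator variants.  Under one-sided
censoring of a true-null effect the adjusted estimate moves toward the null
in ≈ 82–86% of the replicates where the gate fires; forcing adjustment on
every replicate (ignoring the detection gate) drops this to ≈ 70% for this
method regardless of implementation, because undetected funnels mostly yield
k0 = 0.

## Combination with GWAS summaries

SNPs nominally significant (random-effects p < 0.05 in any analysed stratum)
are combined with per-cohort GWAS effects by inverse variance.  The
candidate-gene side enters as its single pooled random-effects estimate —
by default the Asian stratum, since Caucasian candidate samples are assumed
to overlap large Caucasian GWAS panels (`exclude_caucasian_candidates`).
The combined Z is fixed-effects unless I² across inputs exceeds 75%, in
which case the DL random-effects Z is used.  GWAS alleles pass through the
same harmonization procedure, using the cohort's effect-allele frequency
when available; palindromic SNPs without a frequency are excluded.

## Synthetic data

The generator emulates the published candidate-gene literature the pipeline
targets.  Per SNP: a control MAF ~ U(0.05, 0.5); study count 3 + Geometric
(p = 0.4), i.e. at least 4 with median 5 and a right skew; per-study true
effects Normal(θ, τ²) with defaults θ = log 1.2, τ² = 0.05; case/control
arms lognormal with median ≈ 550 subjects each, so a median SNP accumulates
roughly five thousand subjects.  Controls carry the minor allele at the MAF;
cases at logistic(logit(MAF) + θ_i); genotypes are drawn multinomially from
HWE proportions, or with inbreeding coefficient F (default 0.3) for the
configured fraction of contaminated studies.  Trio studies draw
transmissions Binomial(n, e^θ/(1+e^θ)).  A reporting layer then publishes
each study with certainty when its own Wald p < α and with probability γ
otherwise, strips a configured fraction down to (OR, p) summaries, and
injects strand errors (labels complemented) and label switches (labels
swapped, counts untouched).  Each SNP has its own child RNG stream spawned
from the master seed, so per-SNP data are independent of dataset size and
order.

What the generator does *not* emulate: linkage disequilibrium between SNPs,
haplotype effects, covariate confounding and population stratification
within a study, overlapping samples across studies, and genotyping error
mechanisms other than the inbreeding-style HWE distortion.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated sampling model, not robustness to those real-data pathologies.

## Calibration results the suite pins

Problem sizes were chosen to give stable Monte-Carlo estimates in seconds:
200 replicates for recovery/coverage, 1000 for the Harbord null, 400 for
censoring, 500 for the outlier-rate null.

* Pooled log OR bias at true OR 1.2 (k ∈ {10, 50}, τ² ∈ {0, 0.05}):
  < 0.01 in all four cells.
* 95% CI coverage: ≈ 0.95–0.98 except the hardest cell (k = 10, τ² = 0.05,
  I² ≈ 0.9) where DL with normal intervals is known to undercover; measured
  values fluctuate around 0.90–0.96 across seeds there.
* DL τ̂² at τ² = 0.05, k = 100: mean within a few percent of truth.
* Outlier-flag rate under the homogeneous null: ≈ 0.04 against the nominal
  0.05 (the studentized deleted residual is slightly conservative at k = 7).

## Degenerate inputs and tie-breaks

Single-study strata are reported but flagged degenerate, never pooled.
Q = 0 yields I² = 0; τ̂² is truncated at 0.  Zero cells are continuity
corrected; whole-zero arms or all-zero trio counts raise extraction errors.
Validation is total: every malformed input row yields a located diagnostic
(row number + reason) instead of a silent drop.  Fractional counts are
rejected as curation artifacts.  The Bonferroni denominator is the number of
meta-analysed SNPs (configurable), giving 0.05/550 = 9.09e-5 for a
550-SNP family.
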