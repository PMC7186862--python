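# Methods

## Scope and data model

`crossmr` operates entirely on GWAS summary statistics: per-SNP effect
estimates (beta or log-odds), standard errors, P-values, alleles and
optionally effect-allele frequencies (EAF) and sample sizes. Tables are
tab-separated text; readers take an explicit column *dialect* (presets
for GWAS-catalog-, PGC-, GIANT- and SSGAC-style headers) rather than
guessing, because a silently misread effect-allele column corrupts every
downstream sign. Positions are 1-based, loci are closed intervals,
alleles are upper-cased on read, indels and multi-character alleles are
rejected with a logged exclusion, and odds ratios are converted to
log-odds on read (recorded in run metadata). Every reader satisfies the
accounting identity rows_in = records_out + exclusions.

## Look-up pipeline

**Threshold.** The family-wise error rate α is divided by the number of
catalog SNPs (Bonferroni). The correction is across SNPs only, not
across the phenotypes examined — deliberately conservative on SNP count
while leaving the phenotype dimension uncorrected, matching practice
for exploratory cross-trait scans. A stricter SNP × phenotype
correction is available by passing the larger test count.

**Locus clustering.** "A locus" is under-determined by a ±500 kb rule
alone, since clusters can grow beyond 1 Mb. The rule implemented:
within a chromosome, SNPs sorted by position merge greedily into the
current cluster while the candidate lies within the half-window of the
cluster's running midpoint ((min+max)/2, recomputed after each merge);
a cluster exceeding 1 Mb is flagged in logs. Within a positional
cluster, a SNP pair with *known* r² < 0.01 and D′ < 0.01 is in linkage
equilibrium; single-linkage over the complement relation splits the
cluster. Unknown LD counts as linked — loci are split only on
demonstrated equilibrium, never on missing data. The procedure is
deterministic and order-free (tested by permutation and against an
exhaustive oracle).

**Lead SNP.** Per locus: (1) most mental phenotypes with a significant
hit; (2) lowest significant P-value; (3) rsID lexicographic order. Rule
(3) is a determinism tie-break of this package's own and is logged
whenever it decides.

**Directions.** Both effects are aligned to the
anthropometric-trait-increasing allele via the harmonization rules; a
hit is concordant when the mental-phenotype beta is then positive. Loci
are stratified into a BMI stratum (any contributing trait label matches
"body mass index"/"bmi"/"obesity") versus adjusted-only. Zero betas are
flagged indeterminate and excluded from counts. Proxy SNPs are never
substituted for missing ones; absence is reported in a coverage table.

## Harmonization

Outcome records are aligned to the exposure's effect allele by direct
match, allele swap (negate beta), or strand complement (optionally both).
Palindromic pairs ({A,T}, {C,G}) cannot be strand-resolved from alleles:
**strict** mode (default) excludes them; **eaf-infer** mode keeps those
whose EAF is outside [0.42, 0.58] in *both* studies and orients by
frequency agreement (labels are uninformative for palindromes, so only
the frequency side of 0.5 decides), refusing records lacking EAF.
Irreconcilable allele sets are excluded as "ambiguous" and logged
separately from palindromes. Exposure-positive orientation (negating
both betas when the exposure beta is negative) is applied inside the
Egger estimator only; the other estimators are orientation-invariant,
so harmonization does not impose it.

## MR estimators

**IVW.** Weighted mean of Wald ratios with first-order weights
w<sub>j</sub> = β̂²<sub>Xj</sub>/σ²<sub>Yj</sub>, equal to WLS through
the origin (identity tested to 10 significant digits against a generic
WLS solver). Default SE is multiplicative random effects, the fixed SE
inflated by max(1, √(Q/(J−1))); fixed effects by flag. The floor at 1
never deflates below the fixed-effects SE. P-values from the standard
normal.

**MR-Egger.** Weighted regression with intercept, weights 1/σ²<sub>Yj</sub>,
solved from the weighted normal equations; residual variance floored at
1; coefficient tests against t with J−2 df, the field's convention.
The intercept is the average directional pleiotropy; its test is the
pleiotropy diagnostic.

**MR-RAPS.** The profile score in b is solved by a grid scan for a
sign change on b ∈ [−10, 10] followed by Brent's method (tolerance
10⁻¹² on b); if no sign change exists the grid minimizer of |score| is
returned with `converged=False` — non-convergence is a reported state,
never an exception. Overdispersed mode alternates the b-score with the
τ² moment equation (Σ(t²−1) = 0 for l2, floored at 0) to a joint
tolerance of 10⁻⁸. For the Huber loss (c = 1.345) the τ² equation uses
the consistency constant E[ψ(Z)Z] = 2Φ(c)−1. SEs are the empirical
sandwich √(Σψ²)/|dS/db| with the score derivative by central
differences. With all σ<sub>Xj</sub> = 0 and τ² = 0 the score equation
reduces algebraically to IVW fixed effects (tested).

**Wald ratio SE.** First-order σ<sub>Yj</sub>/|β̂<sub>Xj</sub>| by
default — exposure uncertainty is the business of RAPS, not of the
per-SNP ratio; a second-order variant (adding
β̂²<sub>Yj</sub>σ²<sub>Xj</sub>/β̂⁴<sub>Xj</sub>) is behind a flag and
verified against a finite-difference delta-method oracle.

**F statistics.** Two conventions exist in the literature and reports
rarely say which was used, so both are implemented: the mean per-SNP
(β̂<sub>X</sub>/σ<sub>X</sub>)² and the overall-r² form
(n−k−1)/k · r²/(1−r²). Reports print both; neither is privileged.

**Power.** Noncentrality closed form for a binary outcome (see README).
At OR = 1 it returns exactly α. Reported to 2 decimals, matching the
granularity at which such analyses are typically quoted. Note the
closed form at the default design (N = 105,318, cf = 0.386, r² = 0.039)
gives 0.77 at OR = 1.09 — "about 80%" at percent granularity — and
1.00 at OR = 1.28.

## Synthetic data

**MR generator.** Per SNP: MAF ~ U(maf_range); exposure effect
γ<sub>j</sub> ~ N(γ̄, s²); direct effect α<sub>j</sub> ~ N(μ_p, s_p²)
independent of γ (InSIDE holds; an `inside_violated` mode makes α
proportional to γ to demonstrate Egger failure); latent outcome effect
b·γ<sub>j</sub> + α<sub>j</sub>; observed estimates add N(0, se²) noise
with se = 1/√(2·MAF(1−MAF)·N), the standard marginal-regression
approximation, which makes F statistics and power analyses internally
consistent with the configured sample sizes. Binary outcomes use the
normal approximation on the log-odds scale with effective sample size
N·cf(1−cf) — no individual-level logistic sampling, since two-sample MR
consumes only summary statistics. Defaults mirror the forward study
design: 328 SNPs, exposure N = 694,649, outcome N = 105,318 with
cf = 0.386, 9/328 palindromic pairs, MAF ∈ [0.05, 0.5], and
γ̄ = 0.0172, s = 0.0065 chosen so the mean per-SNP F is ≈ 86 under the
SE model (E[γ²]·E[1/σ²<sub>X</sub>] ≈ 86).

**Look-up generator.** Plants n_loci clusters separated by > 1 Mb
(validated), each of `snps_per_locus` members within 100 kb; for an
`overlap_fraction` of loci one designated member gets P = `effect_p` in
one random phenotype with direction set by `concordant_fraction`; all
other pairs are null with P ≥ `null_p_floor`. The truth record carries
planted loci, designated leads and directions.

**What the generators do not emulate.** Realistic LD structure (LD
enters only through user-supplied pair tables), ancestry structure,
sample overlap between exposure and outcome studies, winner's-curse
selection of instruments, and individual-level binary sampling. Tests
passing on synthetic data therefore validate the estimators and
pipeline logic under their stated assumptions, not robustness to those
real-data complications.

## Calibration checks and their regimes

Monte-Carlo checks are run at the regimes where the asserted limit
actually holds: the chi-square mean property of Q (mean ≈ J−1) is
checked with no palindromic loss so exactly J instruments enter; the
Egger intercept-consistency check uses instruments bounded away from
zero effect (γ̄ = 0.03, s = 0.005), because instruments whose observed
exposure effect crosses zero get orientation-flipped, which distorts
the intercept near the origin — a real finite-sample property of
MR-Egger, not an implementation artifact — and pools 6 replicates of
5,000 instruments to keep the check's own Monte-Carlo error small.
Problem sizes used in the test suite (500 replicates of 200
instruments for recovery, 1,000 replicates for type-I error and Q,
200 random instances of ≤ 60 SNPs for clustering) were chosen to keep
Monte-Carlo error well below the asserted tolerances.

## Known limitations

- No MR-PRESSO, weighted-median/mode estimators, multivariable MR, or
  Steiger filtering.
- No remote queries (GWAS Catalog API, LDlink), liftover, or VCF input.
- Strand inference beyond allele complement (e.g., from a reference
  genome) is out of scope; palindromes are dropped or EAF-resolved.
- Trait-term matching against catalog labels is case-insensitive
  substring — a pragmatic choice; curated term lists remain the
  caller's responsibility.
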