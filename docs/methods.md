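# Methods

## Model and inference

All inference is ordinary least squares on the natural log of a strictly
positive trait.  The natural log (rather than log10) is load-bearing for
interpretation: a coefficient β reads as a `100(e^β − 1)` percent change in
the original-scale trait, and predictions are `exp(linear predictor)` with no
retransformation (smearing) correction — predictions are conditional medians
under log-normality, not means.

Per marker, five nested models are built (see README).  Conventions that
matter:

* **Reference category.** EE (two European alleles) is the omitted diplotype
  baseline; the heterogeneous model M4 carries `g × D_c` for *every* present
  category including EE and no unstratified `g` term, so the EE genotype
  effect appears as the EE-stratum slope.
* **Global ancestry.** Exactly two of the three global proportions (Native
  American and African) enter the covariate block; the third is collinear
  with the intercept.  Global ancestry is the chromosome-average of
  local-ancestry allele counts — proportions are count ratios and rows sum
  to 1.
* **Category dropping is per marker.** A diplotype category with no carriers
  at a marker contributes no indicator and no interaction column there, so
  the admixture df is `(#categories present) − 1` and the combined df is the
  sum of the admixture and stratified-slope dfs (e.g. 4 + 5 = 9 when five of
  the six categories are present).  Any residual rank deficiency is resolved
  by greedily dropping later columns (intercept and covariates are listed
  first and therefore protected), with a warning.
* **Variance conventions.** The reported log-likelihood is the Gaussian
  maximum with the MLE variance RSS/n (so LRT = n·log(RSS_red/RSS_full));
  the coefficient covariance uses the unbiased RSS/(n − p), matching standard
  regression software.  Wald tests are referred to χ²(df) by default; an F
  variant (`wald(..., use_f=True)`) is available for finite-sample use.
* **Covariate selection** is forward stepwise on partial-F tests at entry
  level 0.05, run once per trait before the scan, starting from intercept +
  global ancestry; ties break by candidate order.

## The scan kernel

Permutation thresholds require on the order of 10⁶–10⁷ model comparisons
(markers × permutations), so the scan does not refit each model naively.
The marker-side design blocks `Z_j = [D columns | g×D columns]` are fixed
under permutation (only the phenotype-side rows move), so per permutation the
kernel computes one thin QR of the covariate block `C`, residualizes `y` and
all `Z_j` against it (Frisch–Waugh–Lovell), and obtains the four model RSS
values per marker from sub-blocks of one small Gram matrix
(`Z̃'Z̃`, at most 11 × 11), solved in batch across markers that share a
retained-column signature.  Both statistics then follow from RSS pairs:

    LRT  = n · log(RSS_red / RSS_full)
    Wald = (RSS_red − RSS_full) · (n − p_full) / RSS_full

These are exact identities of Gaussian OLS (the Wald form follows from block
inversion of the information matrix), not approximations; the test suite
verifies the kernel against explicit per-marker statsmodels fits to ~1e-12.

Markers where a contrast is undefined (monomorphic dosage → no association
contrast; a single ancestry stratum → no admixture contrast) are emitted
with a skip flag and contribute p = 1 to the scan-wide minimum, a
conservative choice.

## Permutations

The permutation unit is the whole phenotype-side row: (trait, global
ancestry, covariates) are shuffled jointly against the fixed (genotype,
local ancestry) rows, so a trait value never decouples from its own
covariates while the genotype–local-ancestry dependence at each marker is
preserved.  Thresholds are the empirical α-quantile (type 7, linear
interpolation) of the min-p distribution, computed separately for Wald and
LRT from one shared permutation stream.  The deep single-marker estimator is
`p̂ = (r + 1)/(n + 1)` with `r` counting permuted statistics `≥` the observed
one — it can never return 0 and is computed streaming.

The type-I-error harness redraws the trait noise (keeping individuals,
covariates and the genotype side fixed) for each of the replicate datasets,
scans, and compares the min-p of the chosen contrast with the thresholds;
the empirical FWER is reported with its binomial standard error.  At the
default scale (132 × 2,000 markers, 1,000 permutations, 200 replicates) the
threshold's own Monte-Carlo error dominates: the 5% quantile of 1,000 min-p
draws rests on ~50 tail observations, so empirical FWERs scatter roughly
between 0.01 and 0.09 across seeds while averaging at the nominal 0.05.

## The simulator

The generator reproduces the statistical structure the analysis assumes,
not population-genetic history:

* **Ancestry mosaics.** Each haplotype gets `Poisson(T·L/100)` breakpoints
  placed uniformly on `[0, L]`, with segment ancestries i.i.d. from the
  global proportions.  This is the simplest process whose expected *observed*
  diploid switch count reproduces the closed form
  `0.04·T·L·z(1−z)` in 2-way scenarios (2 haplotypes × (T/100)·L breakpoints
  × 2z(1−z) chance a breakpoint changes ancestry); the 3-way analogue
  replaces `2z(1−z)` with `1 − Σ p_i²`.  At marker resolution the per-interval
  change probability is `(1 − e^{−TΔ/100})(1 − Σ p_i²)`, which the tests use
  as the exact discretized oracle.
* **Allele frequencies.** Balding–Nichols draws around a shared ancestral
  frequency `p₀ ~ U(0.1, 0.9)`, with per-population divergence
  F = (E: 0.05, N: 0.05, A: 0.10), giving expected pairwise differentiation
  near 0.10 for E–N and near 0.15 for contrasts involving A.  (A per-pair
  pattern of exactly 0.15/0.10/0.10 is not expressible with additive
  per-population F; the N–A pair lands near 0.15.)  Frequencies are clipped
  to (0.01, 0.99) so no allele is fixed.
* **Traits.** Log-normal: a linear predictor assembled exactly per the named
  generating model on the log scale plus Gaussian noise, exponentiated.
  The null cohort used for error-rate studies has intercept 4.1
  (`e^4.1 ≈ 60`, a diastolic-blood-pressure-like level), sex ~ Bernoulli(0.5)
  with effect 0.05, age ~ Uniform(20, 80) with effect 0.002 per year, and
  residual SD 0.15 on the log scale — distributions and effect sizes chosen
  as plausible for a blood-pressure trait, since only the covariate *names*
  are prescribed.  A zero residual SD is rejected (a constant trait cannot
  be tested or permuted).

What the simulator deliberately omits: recombination-map realism and
coalescent linkage disequilibrium (segment ancestries are independent),
family structure, phasing error, genotyping error, and missingness.
Consequently, passing tests demonstrate the statistical machinery is correct
under the assumed model; they do not certify behaviour under cryptic
relatedness, LD between markers, or local-ancestry miscalls, all of which
real cohorts have.

Default cohort dimensions are 132 individuals × 2,000 markers — the study's
sample size with the marker count scaled down (from ~40k) to desk-scale
runtime; the per-marker category structure, not the marker count, drives the
df patterns under test.

## Ancestry arithmetic

* `expected_switches` evaluates `B = 0.04·T·L·z(1−z)` and `B + 1` blocks
  (switches and blocks are the same partition counted two ways).
* `count_switches` counts changes of the unordered diplotype category along
  the map — the minimum-switch reading of hard-called, phase-free input;
  `count_haplotype_switches` counts per-haplotype changes when simulation
  truth is available.  Both are exposed because phase-free counting loses
  coincident double switches.
* The AIM `f` value is the standard two-population fixation-index estimator
  `f = 1 − [p₁(1−p₁) + p₂(1−p₂)] / [2·p̄(1−p̄)]`, `p̄ = (p₁+p₂)/2` — a
  deliberate, parameter-free choice where several FST variants exist;
  absolute marker counts from any particular historical panel are therefore
  not reproduction targets, but the set-nesting and threshold-monotonicity
  properties hold for any such estimator.  Fixed alleles make f undefined:
  NaN, warned, never selected.

## Numerical choices and edge cases

* Rank decisions use a relative tolerance of 1e-8 on residual column norms.
* RSS values are floored at `1e-12 × RSS_null` before forming ratios.
* Nesting for the LRT is checked by column names, falling back to a numeric
  column-span check (needed for M5-in-M4, where the shared `g` column is the
  sum of the stratified columns rather than one of them).
* The heterogeneity test with a single stratum returns an explicit skip
  (df 0, p = NaN) rather than an error.
* Readers reject missing dosages, dosages outside [0, 2], unsorted bp
  positions, inconsistent IDs and malformed ancestry codes with cell-level
  diagnostics; individuals lacking phenotype rows are dropped with a logged
  count.  "NA" in ancestry TSVs is always the Native-American/African
  category, never a missing value.
* All writers use fixed column order and `%.3e` formatting for statistics
  and p-values so reruns diff cleanly; the pipeline is byte-reproducible
  under a fixed master seed, from which all stage seeds are spawned.

## Known limitations

Single chromosome, unrelated individuals, Gaussian log-scale errors, and
χ² reference distributions (adequate at n = 132 for the df range used, but
the F variant exists for small strata).  No kinship or mixed-model
adjustment, no FDR alternatives, no local-ancestry inference, no liftover —
inputs must share one coordinate system and map.
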