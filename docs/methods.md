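# Methods

## Scope and data model

The package operates entirely on GWAS summary statistics: one record per
variant per trait (identifier, chromosome, 1-based GRCh37 position,
effect/other allele, effect-allele frequency, per-allele beta, SE,
p-value, sample size).  Traits are classed as `taxon`, `protein` or
`disease`; disease effects are log-odds.  Variants are matched across
traits by identifier only, as cross-consortium panels are in practice
merged on shared SNP IDs; a strict chromosome/position cross-check is not
performed.  Pairwise LD is an explicit sparse r² table with unlisted
pairs treated as unlinked — this makes clumping a deterministic function
of its inputs instead of depending on an external reference panel.

Input hygiene: rows with non-positive SE, missing beta, malformed
alleles, out-of-range p-values or missing n are dropped and counted per
reason in a load report (retained + dropped always equals input rows);
p = 0, which occurs in underflowed biobank files, is clamped to the
smallest positive double and flagged rather than rejected.

## Instrument selection

Candidates must pass the class-specific significance threshold — 5×10⁻⁸
for protein pQTLs, the suggestive 5×10⁻⁶ for microbial taxa, whose GWAS
are far smaller (n ≈ 18,000) and rarely yield genome-wide-significant
hits.  Greedy clumping then ranks candidates by p-value (ties broken by
chromosome, position, then identifier, for exact reproducibility), takes
the best remaining variant as an index and removes remaining variants on
the same chromosome within 10 Mb with r² ≥ 0.1 against it.  Different
chromosomes never clump regardless of the LD table.  Per-SNP instrument
strength is the squared Wald statistic F = (β/σ)², the standard
summary-data approximation; variants with F < 10 are dropped (pass
`f_min=0` to keep and merely record them).

## Harmonization and Steiger filtering

Outcome effects are aligned to the exposure's effect allele: identical
alleles pass through, swapped alleles negate the outcome beta, and strand
complements (or complement-swaps) are complemented first, since panels
from different consortia can sit on opposite strands.  Palindromic (A/T,
C/G) variants cannot be resolved from labels; the default policy infers
orientation from allele-frequency concordance when both frequencies lie
outside 0.5 ± 0.08 (a common community default), otherwise drops the
variant.  A `drop` policy is available, and is forced when either
frequency is missing.

Steiger filtering retains variants whose variance explained in the
exposure, r² = t²/(t² + n − 2) with t = β/σ, strictly exceeds that in the
outcome.  The t-statistic form is used for both continuous and log-odds
traits; n is taken as given per row.  Real binary-GWAS files report total
cohort n while their SEs carry the information of the effective sample
size, which makes the outcome r² conservative (smaller) — the synthetic
generator reproduces exactly this convention (below).

## Estimators

All estimators consume the harmonized pairs (β_Xj, β_Yj, σ_Yj).

* **IVW** is the closed-form weighted regression through the origin,
  β̂ = Σ w β_X β_Y / Σ w β_X² with w = 1/σ_Y².  The default
  multiplicative random-effects model scales the fixed-effect SE by
  max(1, √(Q/(J−1))), never reporting less uncertainty than the fixed
  model; p-values are two-sided normal.  One instrument delegates to the
  Wald ratio, whose first-order SE |σ_Y/β_X| ignores exposure-side
  uncertainty (the downstream mediation consumes IVW path estimates, not
  per-ratio SEs; an exact-product option exists where it matters, see
  mediation).
* **Cochran's Q** weights the per-variant ratios b_j = β_Yj/β_Xj by
  w_j = β_Xj²/σ_Yj² around the IVW estimate; variants with β_X = 0 are
  excluded with a warning.  Under homogeneity and conditioning on the
  observed β_X the statistic is exactly χ²_{J−1} — measured exceedance of
  the 5% critical value over 2,000 null replicates is ≈ 0.05.
* **MR-Egger** orients all β_X ≥ 0 (negating both members of a pair,
  which leaves ratios invariant), fits weighted least squares with a free
  intercept via the normal equations, scales both SEs by
  max(1, √(RSS_w/(J−2))) and tests on t_{J−2}.  The lower bound on the
  dispersion scale makes the intercept test deliberately conservative
  when there is no heterogeneity at all (type-I ≈ 0.025); with realistic
  balanced pleiotropy the bound is inactive and the test is calibrated
  (measured ≈ 0.046 at nominal 0.05).  Calibration studies therefore use
  the balanced-pleiotropy null, which is the null the Egger model is
  designed for.
* **Weighted median**: ratios sorted ascending with normalized weights
  w_j = β_Xj²/σ_Yj², cumulative weight S_j = Σ_{k≤j} w_k − w_j/2, and
  linear interpolation at S = 0.5.  The SE is the SD of the estimator
  over 1,000 parametric-bootstrap replicates (each variant's β_X, β_Y
  resampled from normal(estimate, SE)), with a fixed default seed so
  repeated runs are bit-identical.
* **Leave-one-out** refits IVW excluding each variant in turn.

`run_mr` dispatches on instrument count — 1: Wald; 2: IVW; ≥ 3: IVW plus
Egger and weighted median — and tags the IVW/Wald fit `primary`.

## Two-step mediation

For a taxon→protein→disease triplet, β_total (taxon on disease), β1
(taxon on protein) and β2 (protein on disease) are each the primary MR
estimate.  The indirect effect is β12 = β1·β2 with first-order (Sobel)
delta-method SE √(β1²SE2² + β2²SE1²); the exact-product variance (adding
SE1²SE2²) is available but off by default, matching the convention the
Z-test implies.  Significance is Z = β12/SE12 against the two-sided
normal.  The mediated proportion β12/β_total is reported raw: on a
log-odds outcome it is a relative ranking metric, so values outside
[0, 1] are flagged (`proportion_out_of_range`) rather than truncated, and
sign-discordant triplets (β12 opposing β_total — inconsistent mediation)
are set aside in a separate list instead of being ranked.  Screening
retains proportion strictly greater than the 10% floor, sorted
descending; optional nominal-significance filters on β1 and on the
Z-test are exposed but default off.

## Pipeline

The four steps run in order: protein screen against the disease, taxon
screen, pairwise taxon→protein MR over every passed pair (all results
retained regardless of significance; each pair counts as an attempt even
when no shared instruments exist), then mediation over every passed
pair.  Taxon instruments selected for the disease screen are
re-harmonized against each protein panel rather than re-clumped per
outcome.  Steiger filtering applies in every MR step.  No
multiple-testing correction is used anywhere — the screens are an
exploratory prioritization device — but a Benjamini–Hochberg column is
emitted for reference.  The run manifest records the config echo,
per-stage counts and skip lists; with fixed inputs, config and seed the
output tables are byte-identical across runs (floats are written at 10
significant digits).

A screen of truly null exposures passes ≈ 3.5% at nominal α = 0.05
(measured over 2,000 screens): slightly conservative because the
random-effects IVW inflates SEs whenever the heterogeneity estimate
exceeds its null expectation.

## Synthetic data generator

The generator works at the summary level — no individual genotypes —
which is sufficient for every estimator in scope and keeps full studies
at seconds of runtime.  Its defaults emulate the cohorts of the design it
mirrors: taxa at n = 18,340 (consortium microbiome GWAS), proteins at
n = 35,559 (plasma proteomics cohort), disease at n = 456,348 (biobank
binary phecode), instrument panels of 15 variants per exposure trait,
MAFs uniform on (0.05, 0.5], mean per-SNP F of 30.

Each exposure trait receives its own instrument panel: taxon variants
carry true effects γ_j; the protein additionally has pQTL-like variants
with direct effects on its level, exactly as the real design exploits
(the protein→disease path is instrumented by the protein's own strong
pQTLs, not by weakly-inherited taxon variants).  True effects are drawn
zero-centred and scaled so the mean F at the trait's sample size hits the
target.  A planted chain with parameters (θ1, θ2, θ_direct) sets the
protein's true effect at taxon variant j to θ1γ_j + a_j and the
disease's to θ_total·γ_j + θ2·a_j + d_j with θ_total = θ_direct + θ1θ2;
a_j and d_j are horizontal-pleiotropy terms, nonzero for a configurable
fraction of variants with configurable mean (directional) and SD
(balanced).  Observed betas are true effects plus normal noise with
σ_j = (2·n·maf_j(1−maf_j))^(−1/2); p-values are two-sided normal.

For the binary disease trait the noise scale uses the effective sample
size 4·n·φ(1−φ) with case fraction φ (default 0.05, the order of a
common binary phecode), while the n column reports total cohort size —
the convention of real biobank binary-GWAS files.  This matters: with the
continuous-trait scale applied naively, Steiger's exposure/outcome r²
ratio for a protein→disease path collapses to exactly θ2², so any
mediator with |θ2| > 1 would be filtered out by construction, which is an
artifact of the noise model rather than of the biology being emulated.

LD is block-constant (within-block r² constant, between-block zero) —
the simplest structure that makes clumping non-trivial — with one causal
variant per block and tag variants at marginal effect r·γ.  Observed
noise is drawn independently across variants even within blocks; this
under-states the correlation of test statistics inside a block and is
acceptable because clumping reduces every block to its lead variant
before estimation.

What the generator does not emulate: realistic allele-frequency spectra,
population structure or selection, liability-threshold disease genetics,
correlated noise within LD blocks, sample overlap between cohorts, and
winner's-curse-free discovery (instrument selection in the pipeline does
select on observed p-values).  Passing tests therefore demonstrate
correctness of the estimators and pipeline mechanics under the stated
noise model, not robustness to everything real cohorts can do.

## Simulation studies and their design choices

`medmr.studies` packages the seeded studies the tests and the acceptance
script run; problem sizes were chosen to give stable Monte-Carlo
estimates at interactive runtimes.

* **Chain recovery** (500 replicates): θ1 = 0.3, θ2 = −1.0, no direct
  effect, 30 instruments per trait, n = 50,000 everywhere.  Each path is
  estimated by IVW using the exposure's own panel as the instrument set,
  without p-value selection or Steiger filtering: selection adds
  winner's-curse attenuation and, at |θ2| = 1, Steiger sits exactly on
  its decision boundary and selects on noise — both are properties of
  screening, not of the estimators under study.  Bias is assessed against
  the Monte-Carlo SD of the estimator (|mean − truth| ≤ 3 SD): with mean
  F = 30, IVW necessarily carries regression-dilution attenuation of
  order 1/F ≈ 3% (the F > 10 convention tolerates ~10%), so a criterion
  on the standard error of the Monte-Carlo mean would reject every
  consistent finite-strength estimator; measured biases are ≤ 0.9 SD on
  every path.
* **Calibrations** (2,000 replicates each, 20 instruments): Egger
  intercept under the balanced-pleiotropy null; Q under the
  homogeneity null; the full screening stage over 200 repetitions of 10
  null exposures with 40 instruments each.
* **Robustness** (200 replicates): 40% of instruments directionally
  pleiotropic (outcome shift 0.2) with all exposure effects oriented
  positive and strong instruments (mean F = 100) so the invalid set is a
  weight minority with ratios cleanly separated from the valid cluster;
  the weighted median should stay within 3 MC SDs of truth while the IVW
  bias is resolvable against the Monte-Carlo error of its mean and
  larger than the weighted median's.
* **Planted-universe recovery**: one chain (θ1 = 0.3, θ2 = −1.2,
  θ_direct = 0) in a 4-taxa × 5-protein null universe, run through the
  full default pipeline; the planted triplet should rank first by
  mediated proportion.

## Numerical conventions and degenerate inputs

P-values are clamped to (smallest positive double, 1].  Equal-p clumping
ties break lexicographically on (chromosome, position, id).  β_X = 0 rows
are excluded from Q with a warning and are illegal for Wald ratios and
the weighted median.  Zero SE12 with nonzero β12 yields an infinite Z
with the p-value clamp and a `degenerate_se` flag; with zero β12 it
yields Z = 0, p = 1.  A zero total effect makes the proportion undefined
and raises.  Empty intersections, zero surviving instruments, and
all-Steiger-dropped pairs are recorded as skips, never exceptions, so
genome-scale scans are never aborted by a single trait.  Bootstrap
resampling floors |β_X| at the smallest positive normal double to keep
ratios finite.

## Known limitations

Mediation uses marginal two-step decomposition, not multivariable MR: a
protein's β2 is its total effect on disease, so overlapping mediators are
not mutually adjusted.  The Steiger r² approximation on the log-odds
scale has no observed-scale correction for binary traits.  The mediated
proportion on a log-odds outcome is non-collapsible and should be read
as a ranking heuristic.  No proxy-variant lookup, reference-panel LD
computation, liftover, or binary genotype formats.
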