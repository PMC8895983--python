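# Methods

This note records the statistical models implemented in `namqtl`, the
defaults and why they were chosen, what the synthetic data generator does and
does not emulate, and the numerical decisions a maintainer would want to
know. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Mixed-model BLUEs

The plot-level model for one trait is

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 I),  e ~ N(0, R)

with a grand-mean fixed part during variance estimation. Baseline random
terms are family, RIL-within-family, year and field-within-year; candidate
extras are autosampler plate, set, block, family x year and RIL x year
(nested labels are pre-combined, so "set" already encodes
set-in-field-in-year). R is block diagonal: by year for the identity
structure (one variance per year) or by field-within-year for the spatial
structures, where the covariance between two plots of the same field is

    sigma^2 * rho_row^|d_row| * rho_range^|d_range|

— the Kronecker AR1(range) x AR1(row) form evaluated at the occupied grid
cells; pinning one rho at zero yields the AR1 x ID and ID x AR1 variants
exactly (0^0 = 1 on the diagonal dimension).

REML is maximized directly: variance components on the log scale, AR1
correlations through atanh, L-BFGS-B with analytic score equations
(dL/dθ = -1/2 [tr(P V_θ) - y'P V_θ P y]); V is dense, so fits are intended
for field experiments up to a few thousand plots. BIC = -2 logL_REML +
k ln(n) with k the number of free variance parameters and n the non-missing
observations (the conventional REML-BIC bookkeeping; the choice matters only
for comparisons at fixed fixed-effects). Structure selection is two-stage:
minimum BIC over the explicit candidate random-term sets under an identity
residual, then minimum BIC over residual structures given that random
structure, ties broken toward fewer parameters — which also makes the
selection order-invariant.

**DFFITS.** Outliers are flagged on the fixed-effect projection of the final
model (all model terms as dummies), using the standard leave-one-out
identities on the hat matrix. The classical cutoff 2*sqrt(p/n) is the
function default, but in an augmented incomplete-block design with ~2 plots
per line the mean leverage is about 0.5 and that cutoff flags close to a
fifth of clean Gaussian data; the pipeline therefore defaults to the
conservative absolute cutoff |DFFITS| > 3, which flags under 1% of clean
data in simulation. Both are config-exposed. Flagged values are set missing
for that trait only.

**BLUEs.** Lines become fixed effects; the remaining random terms and the
selected residual structure are re-estimated with the line design as the
fixed part, and BLUEs are the GLS coefficients. With no usable random terms
and an identity residual this collapses to per-line means.

**Box-Cox.** The "convenient lambda" is chosen on the grid
{-2, -1.5, ..., 2} by the Box-Cox profile likelihood; traits with
non-positive values receive the shift max(0, -min y) + 0.001 * range(y)
(negative BLUEs do occur for near-zero carotenoid concentrations).

**Heritability.** Line-mean h² = σ²_g / (σ²_g + σ²_ge/ē + σ²_ε/p̄) with ē,
p̄ harmonic means of environments and plots per line; the SE is first-order
delta method on the variance-parameter covariance from the observed REML
information (finite differences of the analytic score, mapped off the log
scale).

## Joint-linkage mapping

Genotypes are coded 0 (common parent) / 1 (alternate parent); projected
dosages are continuous in [0, 1], and missing codes are mean-imputed within
family. The model always contains one intercept per family; a marker
contributes one slope per family in which it segregates, so the partial-F
numerator df equals the number of segregating families. The reported
per-family effect a_f is this slope — the difference between parental
genotype-class means — and the per-allele substitution effect is a_f / 2;
the distortion-aware PVE formula w_f p_f (1 - p_f) a_f² is identical to
p_f (1 - p_f) (2 α_f)² for the per-allele effect α_f.

Scans are vectorized: with Q an orthonormal basis of the current design, the
per-marker added sum of squares is b' C⁻¹ b with C and b assembled from
per-family cross-products, and C (with its pseudo-inverse) is
phenotype-independent — so a thousand within-family permutations cost one
batched einsum. The permutation entry threshold is the floor(alpha*n_perm)-th
smallest of the per-permutation minimum p-values; phenotypes are permuted
within family because the family term is forced, so only the within-family
null must be destroyed. Stepwise search alternates a forward step (smallest
partial-F p <= entry; ties to lower chromosome then lower cM) with backward
elimination (drop-one p > exit = 2 x entry, worst first). Support intervals
are substitution mappings: the contiguous run of markers around a peak whose
substituted partial-F p stays at or below the alpha = 0.01 permutation
threshold. Re-scan substitutes in-interval markers with larger drop-one SS
until a local maximum, moving leftward along exactly flat plateaus, with a
visited-state oscillation guard. Multicollinearity pruning removes, from any
pair with |Pearson r| strictly above 0.8 on the genotype codes, the member
with lower drop-one SS.

## Resampling GWAS

Founder variants are projected per family: the parental-origin probability
at the variant's interpolated cM position (linear between flanking map
markers, nearest marker outside the span) is mapped through the two
founders' alleles, so a variant colinear with a map marker reproduces that
marker's codes exactly, and panel-monomorphic variants are dropped.
Chromosome-specific residuals retain the family term and all JL peaks except
those on the focal chromosome — the focal chromosome keeps its own signal.

The per-trait threshold targets an empirical-null FDR: within-family
permutations of the full-model JL residuals give the null p-value
distribution; the threshold is the largest observed p with expected null
count / observed count <= 0.05, falling back to the alpha-quantile of
per-permutation minima when no observed p qualifies. RMIP then counts, over
100 iterations of forward selection per chromosome on ceil(0.8 N) resampled
RILs, how often each variant enters; RMIP >= 5 is reported.

**Bootstrap vs subsampling.** Sampling with replacement (the default,
honoring the published protocol) duplicates rows; duplicated observations
pseudo-replicate the data and inflate partial-F statistics relative to a
threshold calibrated on unduplicated permutations, so a measurable fraction
of null variants can accumulate RMIP >= 5. Without-replacement subsampling
(`replace=False`) preserves the threshold's calibration — in our
simulations essentially no signal-free variant reaches the reporting
threshold, while a 25%-PVE causal variant reaches RMIP ~100 under either
mode. Users wanting calibrated null behavior should prefer the subsampling
switch; the default remains the literal bootstrap protocol.

## Pleiotropy

Trait A's final model is refit with trait B's transformed BLUEs; paired
(peak, family) effects are correlated per peak and genome-wide, both model
directions reported separately. Effects are standardized by each trait's
BLUE standard deviation before correlation (Box-Cox puts traits on
incomparable scales; correlation is scale-invariant per vector, so this
matters only for pooled interpretation, and it is config-exposed because the
alternative — raw effects — is equally defensible). Monomorphic-family
effects are dropped pairwise; scopes with fewer than 3 pairs or a
zero-variance vector are marked untestable rather than raised. BH-FDR is
applied across the full batch at q <= 0.05.

## Loci resolution

All interval arithmetic is 1-based closed; BED input is converted on read.
Overlapping intervals (>= 1 shared bp) merge by sweep line. The LD profile
computes r² between each focal variant and all variants within 250 kb, with
a null built the same way from up to 50,000 random variants. Gene resolution
requires (i) overlap of the gene span with [variant - 250 kb, variant +
250 kb] for at least one reported association, (ii) overlap (or, optionally,
containment — the strict reading is config-exposed because the source
protocol does not disambiguate) with an individual-trait JL interval of one
of the same traits, and (iii) membership on the a-priori candidate list.

## Color models

OLS comparisons use one-hot family with a reference level; the random forest
receives family as integer codes (a tree can split a categorical integer
code; OLS cannot). Metrics follow the published definitions literally:
Baseline Error is the mean absolute test-set error of the forest, Percent
Accuracy is 100 - 100 |ŷ - y| / y per test observation averaged across
observations (|y| < 1e-6 excluded and counted), both averaged with test R²
over 30 split seeds; impurity importances are seed-averaged and renormalized
to sum to one.

## Synthetic data generator

The generator emulates: ten biparental RIL families sharing a common parent
(default 170 RILs each, matching the study's per-family line counts; tests
and the pipeline scale this down), a regular consensus map, fully inbred
mosaics with Haldane (no-interference) crossovers and RIL map expansion
R = 2r/(1+2r) so realized recombination matches the selfed-RIL expectation,
per-QTL per-family effects with optional cross-trait correlation (negative
values give branchpoint-style antagonistic pleiotropy), viability-selection
segregation distortion that preserves local linkage, a founder variant panel
with arbitrary allele-sharing patterns, and an augmented incomplete-block
design over 2 years / 3 fields with year/field/set/block variance components
and a unit-variance AR1 x AR1 spatial error field. Residual variance is
derived from the target line-mean heritability using the realized
within-family genetic variance, because the forced family term in all
downstream models absorbs between-family genetic differences.

Not emulated: residual heterozygosity (NAM RILs are >= S5; codes are 0/1),
crossover interference, genotyping error, HPLC measurement censoring,
trait-specific error distributions (plot errors are Gaussian), field trends
beyond AR1 x AR1, and real LD structure at the variant level (founder allele
patterns are exchangeable rather than coalescent-shaped). Green tests
therefore certify the statistical machinery under its own assumptions — not
robustness to assay artifacts or model misspecification on real field data.

## Problem sizes and numerical choices

Tests and the acceptance script use 10 families x 100 RILs with three
100 cM chromosomes at 1 cM spacing for linkage-level checks, and
10 x 12-40 RILs for stages that need plot-level REML (dense-matrix REML is
cubic in plot count); these sizes give the calibration checks useful power
while keeping each run in minutes. Other numerical choices: V gets a 1e-8
relative diagonal jitter; QR rank filtering at 1e-9 of the leading diagonal;
stacked per-marker systems use pseudo-inverses (rcond 1e-10) so monomorphic
families drop out of both the estimate and the degrees of freedom; entry-p
order statistics use the floor convention (alpha = 1 gives the largest
minimum); and all random draws flow from explicit integer seeds, making
every pipeline output byte-reproducible.

## Known limitations

- Dense-matrix REML does not scale to tens of thousands of plots; a sparse
  or average-information implementation would be needed.
- The stepwise scan rebuilds the QR basis per forward step (fine at
  10^2-10^4 markers per scan; the published 14,772-marker map is in range,
  but millions of variants are handled only through the per-chromosome
  residual GWAS, which is linear per iteration).
- FDR-from-permutations has no unique definition; ours (expected null count
  over observed count, minima fallback) is one defensible reading and is
  config-exposed.
- The pleiotropy test treats allelic-effect correlation as the estimand; it
  cannot distinguish one pleiotropic gene from two linked genes, matching
  the scope of the original analysis.
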