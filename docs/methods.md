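# Methods

## The analysis this package implements

A multi-cohort eQTL study has one discovery panel and one or more
replication panels, each with genotypes (dosages), array expression, and
donor demographics.  The workflow is: quality-control markers and arrays;
regress demographic covariates and estimated hidden confounders out of
expression; scan residual phenotypes for cis (TSS ± 250 kb) and trans
(other-chromosome) associations by single-SNP Bayesian regression; declare
discoveries at log₁₀ BF > 5; re-test each discovery SNP in every
replication panel and call replication at p < 0.05 with a concordant
coefficient sign; then interrogate the non-replicating remainder with
resampling power baselines, winner's-curse tables, probe-artifact
attribution, and logistic determinant models.  Reporter (luciferase)
assays provide an orthogonal functional check of allelic direction.

## Bayes factor

For phenotype vector *y* and dosage *g* at *n* samples, the single-SNP
model is y = μ1 + a·g + ε with ε ~ N(0, σ²I), a ~ N(0, σₐ²σ²), flat prior
on μ and Jeffreys prior p(σ²) ∝ 1/σ².  Projecting out the intercept and
integrating a and σ² analytically gives, in centred sums,

    BF(σₐ) = (1 + σₐ² sgg)^(-1/2) (syy / S1)^((n-1)/2),
    S1 = syy − σₐ² sgy² / (1 + σₐ² sgg).

Because the effect prior scales with σ, the BF is invariant to affine
transformations of y.  The default prior grid {0.05, 0.2, 0.4} with equal
weights is configurable (`BfPriorSpec`) and is an assumption, not a fit:
the grid any particular legacy software used is not recoverable, so the
package defines its own default and logs it.  log₁₀ is used everywhere.
The closed form is verified in tests against an independent
adaptive-quadrature oracle (explicit intercept projection, multivariate
normal density, numeric σ² integral) to 10⁻⁶.

Best-SNP selection is the log₁₀ BF argmax with a deterministic tie-break:
lowest genomic coordinate, then lexicographic SNP id.

## Covariate adjustment

The full mixed model y ~ m + P + A + C + R + I + W + SV + e (intercept,
protocol batch, age, sex, ancestry, individual and probe random effects,
surrogate variables) is approximated by averaging technical replicates
within individual (I) and centring probes before averaging them into gene
values (W), then per-gene OLS on the fixed terms.  On balanced designs
this preserves fixed-effect estimates; tests assert < 1% relative error
against an explicit random-intercept fit.  Sex is coded male = 1, so
reported sex effects are male − female.  Ancestry covariates are
standardized.

Surrogate variables are estimated by parallel analysis: the
gene-standardized residual matrix is decomposed by SVD and the k leading
components kept while their variance-explained fraction beats its null
distribution from within-gene permutations (default 100 permutations,
α = 0.05, sequential stopping at the first failure).  Scores are
orthogonalized against the known covariates.  This is deliberately the
permutation-thresholded variant rather than the iteratively reweighted
algorithm; planted-confounder recovery (k and score correlation > 0.9) is
what the tests demand of it.

The within-population rank-based inverse-normal transform uses the Blom
offset, Φ⁻¹((r − 3/8)/(n + 1/4)), applied per population when a panel has
more than one population with ≥ 2 members (singleton populations fall back
to a single joint transform).

Storey q-values: π₀(λ) = #{p > λ}/(m(1 − λ)) on λ = 0.05…0.95, smoothed by
a cubic polynomial and evaluated at λ = 0.95, clipped to (0, 1];
q(p₍ᵢ₎) = min over j ≥ i of π₀·m·p₍ⱼ₎/j.  Below 100 p-values the smoother
is unstable and π₀ = 1 is used (the Benjamini–Hochberg limit).

## Quality control

* Marker filters run in a fixed order — call rate (> 10% missing), HWE
  exact test (p < 0.001, hard-call genotypes only; fractional dosages are
  exempt because HWE on dosages is ill-defined), MAF (< 1%) — and each SNP
  is charged to the first filter it fails, so the QC report reconciles
  exactly.  Survivors are mean-imputed per SNP.
* The HWE exact test sums the conditional distribution of the heterozygote
  count (P(h) ∝ n!/(n_AA! n_AB! n_BB!)·2^h over same-parity h) over all h
  at most as probable as the observed one; a 1 + 10⁻¹² relative tolerance
  on the probability comparison makes float ties match exact rational
  enumeration, which the tests sweep fully for n ≤ 50.
* Probes are grouped into probesets per gene by complete-linkage
  hierarchical clustering on 1 − Pearson r, cut at height 0.5; complete
  linkage guarantees within-probeset pairwise r ≥ 0.5, the property the
  cut is meant to enforce.  Probeset expression is the mean of member
  probes.
* Probe–variant overlap uses 0-based half-open probe intervals and VCF
  1-based positions converted on read.  Offsets are measured from the 5′
  end: the leftmost base for + probes, the rightmost (end − 1 in 0-based
  coordinates) for − probes.
* Sex confirmation is 2-means clustering on Y-linked expression means and
  X-linked heterozygosity, with the higher-Y cluster called male;
  degenerate (constant-feature) panels return indeterminate calls rather
  than guesses.
* Dixon's Q (r10) test screens per-array metrics at one-sided α = 0.05 per
  tail, with the classical critical table for n = 3…30; beyond 30 the
  n = 30 value is held, a conservative fallback.  Flags are advisory, not
  auto-removal.

## Replication machinery

Replication re-tests the *same* SNP in the replication panel (no LD-proxy
fallback); absent or monomorphic SNPs are flagged untested and excluded
from rate denominators.  "Either"/"both" rates are computed only over
records tested in all panels so denominators match.  p < 0.05 is strict.
Discoveries with an exactly zero coefficient are indeterminate and
excluded.

The concordance-only adjustment treats direction-discordant effects as
half of all false positives (single panel) or a quarter (either of two):
adjusted = 1 − 2(1 − c), respectively 1 − 4(1 − c), floored at 0.  These
are the exact inverses of the 50%/75% null concordance rates, which the
tests verify on 10⁴ simulated nulls.

Matched resampling draws, for each target individual, one source
individual of the same sex and population with age within ± 3 years,
without replacement within a set and independently across the default 100
sets.  Infeasible targets raise with the row named; partial sets are never
returned.  Resampled coefficients are recomputed on the *fixed* full-panel
covariate residuals — surrogate variables are not re-estimated per subset.

A caution about the resampling null: a subset of the discovery panel is
not an independent panel.  Under the null the subset coefficient
correlates with the full-panel one at ρ = √(m/n) (≈ 0.54 for 60 of 206),
so the baseline "replication" rate for null genes is
2·P(Z_sub > z₀.₀₂₅, Z_full > 0; ρ) ≈ 0.057, not the independent-panel
0.025.  The tests assert the overlap-corrected value.

Winner's-curse tables bin resamples by the full/resampled coefficient
ratio (sign flips binned separately) per BF stratum.  Determinant models
are logistic regressions of replication on standardized candidate terms
(BF, |TSS distance|, expression mean and CV, probe-SNP count and its BF
interaction, MAF, imputation flag) with drop-one likelihood-ratio
p-values; optional forward–backward stepwise selection by AIC; complete
separation is detected and refit with a small ridge penalty and flagged.
Probe-artifact attribution works on the non-replication scale:
(nonrep_with − nonrep_without)/nonrep_with per BF stratum, plus a logistic
probe-SNP × BF interaction test.

## Reporter model

Luminescence per region is modelled as haplotype (fixed) + preparation
(random intercept) + residual, fit by REML profiled over the variance
ratio λ = σ²_prep/σ²_resid; the prep blocks make V = I + λZZ′
block-diagonal with closed-form inverse, so the profile is a cheap
one-dimensional optimization (log-scale bounded search, boundary λ = 0
allowed).  On balanced designs the estimates equal the method-of-moments
ANOVA components, asserted to 10⁻⁶.

The haplotype term is tested by a Wald F on the REML fit with
Satterthwaite denominator degrees of freedom from the REML information
matrix.  The asymptotic χ² likelihood-ratio reference was measured to
reject 3× too often at α = 0.001 on null 3-prep × 4-replicate plates,
so it was rejected in favour of the calibrated F (0 rejections in 10⁴
null plates).  This choice has a consequence worth stating plainly: with
3 preparations per haplotype the effective replication unit is the prep
(six units; the exact balanced F has (1, 4) degrees of freedom, critical
value ≈ 74 at α = 0.001), so *no* correctly calibrated test detects a
3-residual-SD haplotype shift with 90% power at this design — the
calibrated power is roughly 15–30%.  The acceptance suite keeps the 90%
bound as stated and that single assertion fails by design; detecting such
shifts reliably at α = 0.001 requires more preparations, not a different
test.  Single-prep-per-haplotype plates degrade to OLS with a warning.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
not real human genetics.  Per panel it draws HWE hard-call genotypes with
first-order haplotype-copying LD (allele copied from the previous SNP with
probability `ld_decay`, else redrawn at its MAF; the realized allele
frequency follows p*ₖ = ld·p*ₖ₋₁ + (1 − ld)·pₖ and effect sizes are
calibrated against that realized frequency), marks a fraction of SNPs
"imputed" by shrinking dosages toward 2·MAF with a per-SNP quality factor
in [0.7, 1], and builds expression as

    baseline + probe offset + cis + trans + age + sex + ancestry
    + confounders − artifact·dosage + residual + replicate noise.

Each gene's per-sample biological value has unit variance, decomposed into
recorded fractions that sum to 1 (rescaled proportionally if a
configuration over-commits the budget, keeping ≥ 5% residual).
Demographic effects apply to standardized covariates so their variance
fractions are β².  Confounders are per-panel standard-normal factors with
sparse loadings sized from each gene's confounder budget.  Probe maps are
platform-specific; artifact probes are placed directly over a genotyped
SNP and their intensity *decreases* with artifact-allele dosage (a
mismatch lowers hybridization efficiency).

Default study conditions: panels of 206/60/266 donors with 2/2/1
technical replicates, in-probe-polymorphism fractions 0.274/0.191/0.191 by
platform, a minority non-European fraction of 23/206, 5/60 and 0 per
panel, ages N(50, 12) truncated to the donor range [20, 75] (the bounded
range keeps ± 3-year matching feasible), MAF uniform on [0.05, 0.5],
ld_decay 0.8, cis effects on 30% of genes with h² uniform on [0.1, 0.4],
3 confounders per panel absorbing 30% of variance on 40% of genes, and
0.3 log₂ units of replicate noise.  Default run sizes (≈ 100–300 genes,
6–15 SNPs/gene) are chosen so a full three-panel analysis completes in
seconds to minutes on one core; the generator scales linearly if larger
studies are wanted.

What the generator does *not* emulate — realistic LD maps and allele
spectra, genotype–confounder correlation (population stratification in
expression), heavy-tailed batch artifacts, platform normalization quirks —
bounds what passing tests show: parameter recovery, calibration and the
directional benefits of adjustment transfer to real data only insofar as
real confounders resemble genotype-independent low-rank structure.

One consequence is worked out in the tests: with genotype-independent
confounders, surrogate-variable adjustment provably increases discovery
power but leaves the aggregate replication *rate* at a fixed BF threshold
roughly invariant — each arm selects discoveries and re-tests them on its
own variance scale, so marginal discoveries sit at the same relative power
in both arms.  What adjustment strictly increases is the *yield*: true
discoveries at BF > 5 and the number of discoveries that replicate in
either panel.  The SVA-benefit acceptance check therefore compares those
counts, run under a deliberately heavy-confounding scenario (4 confounders
per panel absorbing 55% of variance on 90% of genes, cis h² 0.06–0.30) at
the canonical 206/60/266 sizes.

## Numerical choices and degenerate inputs

* Zero-variance (monomorphic) genotypes are errors in single-SNP
  operations and silently skipped in scans; genes with no eligible SNP
  appear in outputs with missing statistics.
* Constant probes become singleton probesets with a warning; constant
  transform groups map to zeros with a warning.
* OLS p-values are floored at the smallest positive float to keep
  downstream logs finite.
* Aliased design columns are dropped with a warning; n ≤ p is an error.
* Every operation is a pure function of its inputs including the seed;
  pipeline outputs carry a config hash and reproduce bit-for-bit.

## Known limitations

Dosage-level HWE is not tested (hard calls only).  LD-proxy replication,
conditional/secondary signals, dominance models, meta-analysis across
panels, and ancestry estimation from genotypes are out of scope.  The
Dixon table fallback beyond n = 30 is conservative rather than exact.
Stepwise AIC selection inherits the usual instability of stepwise
procedures and is off by default.
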