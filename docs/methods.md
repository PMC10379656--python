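# Methods

## Model and test

The package detects two-locus epistasis on a quantitative trait by comparing,
for every unordered SNP pair, two nested ordinary-least-squares models of the
trait: a main-effects model (intercept, both additive genotype codes, age,
gender, four diagnosis indicators) and the same model plus the product term
g₁·g₂.  The interaction is tested with the partial F statistic

F = (RSS_reduced − RSS_full) / (RSS_full / (n − 10)),  F ~ F(1, 10 … n−10 df),

which for a single added column equals the squared t statistic of the
interaction coefficient.  Genotypes are additively coded as the count of the
bim A1 allele (PLINK convention).  Because F and R² are invariant under
affine transformations of the trait and under allele flipping of either SNP
(only coefficient signs and the intercept change), the test's p-values do not
depend on which allele is counted.

Diagnosis (`cds`) is treated as a five-level categorical covariate with CN as
reference, not as an ordinal score; indicator coding makes no monotonicity
assumption and is recorded in the scan's metadata sidecar.  Missing data are
handled by complete-case analysis per pair: a subject is dropped from a
pair's fit iff either genotype, the trait, or any covariate is missing.  No
imputation is performed; after ≥95 % call-rate QC the per-pair loss is small
and results remain exactly reproducible.

## Quality control

Variant filters are applied in a fixed order with inclusive thresholds:
autosomes only (chromosomes 1–22), SNP call rate ≥ 0.95, minor allele
frequency ≥ 0.05, Hardy–Weinberg exact-test p ≥ 10⁻⁶.  Subject filters run
first (optional externally derived exclusion list, per-subject call rate
≥ 0.90, phenotype present, covariates present) so that MAF and HWE are
computed on the analysis cohort.  Every stage reports
before/removed/after counts, chained, so the provenance of the final panel
is auditable.

The HWE test is the conditional exact (Levene–Haldane) test: given the
allele counts, each feasible heterozygote count h has integer weight
C(n, n_hom1)·C(n − n_hom1, h)·2^h, and the two-sided p sums the
probabilities of all h whose weight does not exceed the observed one.
Weights are exact integers (Python big-ints), so tail membership involves no
floating-point comparison; only the final tail/total ratio is a float.  The
plain exact test is used, not the mid-p variant, matching PLINK's default.

Phenotype normalization is configurable: identity, natural log (default —
CSF P-tau concentrations are positive and right-skewed), or rank-based
inverse-normal scores.  No outlier exclusion is performed; the "one baseline
record per subject" assumption is enforced as a uniqueness check on subject
ids.  The chosen transform is recorded in run metadata.

## Scan implementation

The exhaustive scan evaluates each of the m(m−1)/2 pairs exactly once.  When
neither genotype column has missing calls it uses a blocked
Frisch–Waugh–Lovell path: the covariate block (with intercept) is
QR-factorized once per scan; the trait, all genotype columns and each
block's interaction products are residualized against it; each pair then
reduces to a 3×3 (full) and closed-form 2×2 (reduced) Gram solve, batched
over a configurable block of pairs.  Full-model covariate coefficients are
recovered by triangular back-substitution for reported pairs only.  Pairs
with missing genotypes, a rank-deficient covariate block, or a
near-singular Gram system (relative determinant below 10⁻⁹) fall back to a
per-pair full-design `lstsq` fit, which is also the reference path the
blocked results are tested against (agreement to 10⁻⁸ relative on F).

Numerical conventions: rank-deficient pairs (e.g. perfect LD making the
product collinear) are reported with a `rank_deficient` flag and F = 0,
p = 1 rather than dropped; pairs with ≤ 10 complete cases are flagged
`insufficient_df`; a numerically negative RSS difference is clamped to 0; a
zero full-model RSS yields F = ∞, p = 0.  Block size changes runtime only —
reported statistics are identical across block sizes up to floating-point
associativity of the blocked matrix products (observed ≲ 10⁻¹⁴ relative),
and the pair order of the output is fixed (bim order, i < j) regardless of
blocking.

The significance criterion is configurable; the default is Bonferroni
0.05 / (number of pairs), printed in the metadata sidecar.  A threshold of
1.0 keeps every pair, which the validation suite uses for full dumps.
Single-SNP marginal effects ("GWAS p") use the analogous 8-parameter model
y ~ 1 + g + covariates with a t test on the genotype coefficient.

## Variance partition

For reported pairs, unadjusted R² is computed for three nested models
(covariates; + mains; + interaction) on the pair's complete-case subset, and
successive differences give the components.  Unadjusted R² is used because
at n ≈ 860 the adjustment is negligible for these model sizes and it matches
the convention of standard GLM software output.  Components sum to the
full-model R² by construction; deltas within −10⁻¹² of zero are clamped to 0
(more negative values warn).  Computing R²_cov per pair (rather than once on
the full cohort) can make the covariate component vary slightly across pairs
when missingness differs; with complete data it is constant.

## Gene mapping

A SNP inside one or more gene bodies maps to all of them; an intergenic SNP
maps to the nearest gene whose body boundary lies within 100 kb (inclusive
at exactly 100,000 bp; equidistant ties all kept).  An alternative
`all-in-window` mode maps to every gene in the window, since the positional
offset rule admits both readings.  Coordinates are 1-based inclusive
internally; BED input is converted at the boundary.  SNP pairs expand to the
cross-product of their gene lists; gene pairs are unordered and
deduplicated, accumulating supporting SNP pairs.  Pairs whose two SNPs map
to the same single gene are reported as intragenic and excluded from
gene-pair counts, as are pairs touching an unmapped SNP (reported
separately).  Disease-relatedness is a user-supplied gene list (three-way
categorization: both / one / neither gene in the list); PPI overlap is exact
unordered symbol matching against a user-supplied edge list, invariant to
edge orientation and duplication.  No external databases are queried at run
time.

## Synthetic cohorts

The generator emulates a post-QC quantitative-trait epistasis cohort:

- genotypes i.i.d. Binomial(2, p) per SNP (Hardy–Weinberg proportions), with
  p drawn uniformly from a configurable MAF range, default [0.05, 0.5];
  SNPs independent by default, with an optional Gaussian-copula AR(1)
  block-LD mode used to exercise collinearity handling;
- covariates: age uniform on [55, 90] years, gender Bernoulli(½), diagnosis
  multinomial with proportions (201, 84, 251, 209, 115)/860 across
  CN/SMC/EMCI/LMCI/AD — the composition of the emulated 860-subject cohort;
- a unit-variance latent trait assembled additively; the covariate effect is
  scaled analytically to a target variance share (default 9.3 %), each
  planted main effect to its share via β = √(f / 2p(1−p)), and each planted
  interaction via α₁₂ = √(f / (v_i·v_j)) applied to the doubly centered
  genotype product, which is orthogonal to the mains and therefore plants
  exactly f of *incremental* interaction variance (default scale 5.6 %, the
  magnitude of the strongest pairs the method targets); Gaussian noise
  absorbs the remaining budget;
- stored P-tau is 25·exp(latent) pg/mL, so the cohort file carries realistic
  positive right-skewed concentrations and the default log transform
  recovers the latent trait exactly.

All draws flow from one integer seed through independent named substreams,
so a config reproduces genotypes, cohort, and every downstream output
byte-for-byte.  The generator records the full latent truth (coefficients
and variance components) for recovery tests, and a Monte-Carlo harness
estimates per-pair power and empirical type-I error with binomial standard
errors.

What the simulations do not emulate: linkage disequilibrium with realistic
decay, allele-frequency spectra from reference panels, population structure
or relatedness, genotyping batch effects, covariate–genotype correlation
(diagnosis is simulated independent of genotype), and non-Gaussian trait
noise.  Passing tests therefore demonstrate correctness of the statistics
and calibration under the stated sampling model, not robustness to
confounding in real cohorts — population stratification, in particular, must
be handled upstream (the QC stage accepts an externally derived subject
exclusion list for that purpose).

## Validation problem sizes

The validation suite checks the blocked scan against a naive
normal-equation oracle on a 200×60 panel (all 1,770 pairs, 10⁻⁸ relative on
F), null calibration on 10,000 independent pairs at n = 500
(Kolmogorov–Smirnov at the 1 % level plus a binomial band on the 0.05
exceedance rate), planted-effect recovery at n = 860 over 200 replicates
(mean recovered ΔR²_int within 0.005 of the planted 0.056 — about three
Monte-Carlo standard errors plus the O(1/n) fit bias — and the planted pair
ranked first among 102 SNPs' 5,151 pairs in ≥95 % of replicates), the HWE
test against an exact rational enumeration oracle for every table with
≤ 50 subjects, and empirical power against the analytic noncentral-F value.
These sizes give stable Monte-Carlo estimates while keeping the whole suite
fast enough to run routinely.

## Known limitations

- The scan is O(m²) pairs on one machine; genome-scale panels (~5×10⁵ SNPs)
  are out of reach without distribution — the package targets candidate
  panels and methodological validation at desk scale.
- Only quantitative traits with Gaussian-error regression are supported; no
  logistic (case-control) epistasis, no three-way interactions.
- Complete-case handling can differ from software that computes the
  covariate R² once on the full cohort; see the variance-partition note.
- The exact HWE test's big-integer enumeration is O(n) per SNP and is sized
  for cohorts of hundreds to thousands of subjects, not biobank scale.
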