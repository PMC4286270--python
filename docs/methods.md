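# Methods

## Study design being modelled

The package implements a two-stage genome-wide interaction study (GWIS) of a
quantitative longitudinal phenotype: the annual decline of forced
mid-expiratory flow (FEF₂₅–₇₅%), computed as (follow-up − baseline)/years in
mL/sec per year, regressed SNP-by-SNP on additive minor-allele dosage,
cumulative PM₁₀ exposure, and their product.  Stage one scans all SNPs in a
discovery sample and nominates candidates at a Bonferroni genome-wide level;
stage two refits the identical interaction model for the *k* candidates in
an independent replication sample at level α/k, followed by
covariate-sensitivity refits and genotype-stratified exposure-slope
estimation.

## Exposure assignment

Cumulative exposure is a residence-weighted sum of annual grid means.  Each
calendar year of the follow-up window contributes the day-weighted average
of the annual means of the cells the subject lived in that year, with
weights = days resided / days in the calendar year, so a year spent fully in
one cell contributes exactly that cell-year's mean and partial years at the
window edges contribute proportionally.  Residence intervals are half-open
`[start, end)` in days.  How mid-year moves were prorated is not something
the summed-annual-averages formulation pins down; day-weighting is its
natural refinement, and the implementation is tested against a brute-force
day-by-day summation oracle and for invariance under splitting a residence
period in two.  Unknown cell-years and gapped or overlapping histories are
hard errors, not silent zeros.

The exposure window is a fixed calendar span shared by the whole cohort
(default 1991-01-01 plus 11 whole years), matching a cohort whose follow-up
period is defined by survey waves rather than per-subject anniversaries;
examination dates vary within the boundary years and carry the seasonal
terms.  The "cumulative exposure" is reported in μg/m³ as a sum of annual
means — formally μg/m³·year — keeping the unit convention of the
epidemiological literature this mirrors.

## Regression and tests

Each per-SNP model is ordinary least squares with classical covariance
σ̂²(XᵀX)⁻¹ at n − p residual degrees of freedom.  Wald tests of β_main and
β_int use the normal reference by default (standard for GWAS-scale n; a t
reference is available via `use_t` and is preferable below a few hundred
subjects).  The joint 2-df test is the Wald chi-square b̂ᵀV̂⁻¹b̂ of
(β_main, β_int) with their estimated 2×2 covariance; a likelihood-ratio
version would agree asymptotically.  Exposure and dosage enter uncentered,
so β_int reads directly as "per 1 μg/m³ per allele" and β_main is the
genotype effect at zero exposure.  A consequence worth knowing: with
uncentered exposure the two estimates are strongly negatively correlated
(≈ −0.95 at the default exposure distribution), so the joint statistic can
be far more extreme than either single test when the estimates have the same
sign — the covariance term, not a bug.  Centering is available in principle
by transforming inputs; it changes β_main's meaning, not p_int or p_joint.

The genome scan streams SNP-by-SNP over a pre-factorized covariate block: a
QR decomposition of the covariate-only design residualizes the outcome, the
dosage and the dosage×exposure columns once (Frisch–Waugh), reducing each
SNP to a 2×2 solve.  This is algebraically identical to the naive per-SNP
fit; the `engine="naive"` path exists and a test asserts agreement to 1e-8.
Single fits use a QR solve rather than normal equations because the
uncentered design (raw heights, weights, dosage×exposure products) is too
ill-conditioned for a Cholesky of XᵀX in double precision.  Designs whose R
diagonal ratio falls below 1e-10 (e.g. a constant dosage) are flagged
untestable and excluded from ranking, not fatal to the scan.  Missing
dosages drop subjects per SNP (complete case per test), with `n_used`
recorded.  Ranks are ascending in each p-value with ties broken by
(chromosome, position).  p-values are clipped into (0, 1] at the smallest
positive float.

Genomic-control λ divides the median observed 2-df joint statistic by the
χ²₂ median 2 ln 2 = 1.386294…, held internally at full precision.

## Linkage disequilibrium

Two-locus haplotype frequencies come from the standard EM algorithm over the
double-heterozygote phase ambiguity under Hardy–Weinberg random union of
gametes, initialized at linkage equilibrium (deterministic, no seed),
converged at 1e-10 maximum frequency change or 1000 iterations, with the
multinomial log-likelihood asserted non-decreasing at every iteration.  From
the frequencies: D = p_AB − p_A p_B; D′ = |D| / D_max with
D_max = min(p_A p_b, p_a p_B) for D > 0 and min(p_A p_B, p_a p_b) otherwise;
r² = D²/(p_A p_a p_B p_b).  Monomorphic loci yield flagged, undefined
statistics.  Fractional dosages are rounded to hard calls for LD; entries
farther than 0.1 from an integer are dropped and counted, since the EM
operates on genotype classes.  Strong-LD grouping is greedy in ascending
interaction p-value: a SNP joins the first reference satisfying
r² > threshold and D′ ≥ threshold, else founds a new group.

## Replication and stratified stages

Candidate selection always carries the top interaction SNP, plus further
genome-wide-significant SNPs above a MAF floor whose r² with every
already-selected candidate is below a ceiling (default 0.95).  Replication
reports the interaction coefficient with a 95% CI using the normal
multiplier 1.96 and a pass flag at α/k.  Stratified analysis hard-calls the
SNP, splits major-allele homozygotes from minor-allele carriers, and refits
the covariate model without SNP terms within each stratum, reporting the
cumulative-exposure coefficient; empty strata return flagged rows with
n = 0.  Combined-sample analyses pool discovery and replication with a
sample-indicator covariate to absorb mean differences between samples — the
pooling method is a design choice of this package, made because the two
samples share the model but not necessarily the phenotype level.

## Synthetic-cohort generator

The generator reproduces the statistical structure the analysis assumes, not
any real population:

- **Genotypes.** Finite haplotype pools per block of SNPs (default 10 SNPs,
  16 haplotypes): each subject draws two pool haplotypes independently and
  dosage = alt-allele count.  This yields Hardy–Weinberg genotype pairing,
  within-block LD of order 1/pool-size, and independence across blocks —
  enough to exercise LD-aware logic without coalescent realism.  Per-SNP
  target MAFs are uniform on [maf_min, maf_max] (default [0.05, 0.5],
  emulating a panel already filtered at 5%) and rounded to whole pool
  haplotypes, so small pools give strong LD and exact control of pool
  frequency.  Tiny pools (2–4) are used in tests that need r² near 1.
- **Exposure.** Annual means decline linearly 27.4 → 17.2 μg/m³ over the 11
  follow-up years (mean 22.3, 11-year sum ≈ 245 μg/m³), reconciling a
  baseline annual mean near 27 with a cumulative total near 245 in the
  target scale — consistent with the downward PM₁₀ trend in 1990s central
  Europe.  Cells deviate from the trend by a Normal(0, 7.3 μg/m³) cell
  effect (truncated at zero), putting the cumulative SD near 80.  Subjects
  hold 1–3 residence periods covering the window without gaps.
- **Covariates.** Age ~ N(41, 11) years, 51% female, height ~ N(169.5, 9)
  cm, weight ~ N(68, 12.6) kg, weight change ~ N(5.5, 6) kg, 43%
  never-smokers with gamma-distributed pack-years for smokers, eight study
  centers — scale realism only, no claim of distributional fidelity.
  Follow-up examinations are scheduled with ±90 days of jitter around the
  11-year anniversary; without jitter the two exams' seasonal terms would be
  exactly collinear.
- **Phenotype.** Decline = linear covariate effects + β_main·G +
  β_int·G·E + Normal(0, noise_sd²), noise_sd default 35 mL/sec/yr, default
  covariate effects putting the mean decline near −35 mL/sec/yr with an
  adverse exposure slope of −0.05 per μg/m³.  Baseline FEF values are drawn
  at N(3500, 1100) mL/sec and the follow-up value is reconstructed from the
  decline, so derived variables are internally consistent.

All randomness flows from one seed through four spawned sub-streams
(genotypes, exposure, covariates, noise), so identical seeds reproduce
cohorts bit-for-bit and changing one component's parameters does not perturb
the others' draws.  Haplotype pools can be shared between two samples to
model discovery and replication drawn from one source population.

What the generator does **not** emulate: population structure and
relatedness, imputation uncertainty (dosages are hard calls unless read from
external files), missing-data mechanisms beyond uniform missingness,
spatial autocorrelation of exposure beyond the shared annual trend, and
selection/attrition.  Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under clean conditions, not that real
cohort confounding is handled.

## Calibration experiments and problem sizes

The test suite and `scripts/acceptance.py` run the same experiments: a null
scan of 5,000 SNPs at n = 800 (type-I error at nominal 5%, λ, uniformity of
p_int); recovery of a planted β_int = 0.07 mL/sec/yr per allele per μg/m³ at
n = 3,000 over 200 cohorts (mean estimate, 95% CI coverage, model-vs-
empirical SE); and 40 independent two-stage replicates at discovery n = 800
over 2,000 SNPs with β_int = 0.25 and replication n = 1,200 at α/k
(detection of the planted locus or an r² > 0.85 proxy).  These sizes give
each experiment enough Monte Carlo precision to be informative while keeping
the whole suite in the minutes range.

A property of single-cohort calibration experiments worth flagging: all
SNP-wise tests within one scan share a single phenotype, design and exposure
vector, so the empirical type-I error over one scan is unbiased but
over-dispersed relative to a binomial count (measured SD ≈ 3.8× binomial
across independent scans at the default conditions).  This is the same
conditioning that makes genomic-control λ fluctuate several percent around
1 in real GWIS — the motivation for genomic control in the first place —
and it means single-scan rejection rates should be read with λ, not against
binomial error bars.

## Known limitations

Classical (non-robust) OLS standard errors are by design; no mixed models,
no relatedness, no case–control logic.  The EM LD estimator assumes
Hardy–Weinberg; it is not a phaser and handles exactly two loci.  The VCF
writer emits a minimal v4.2 file (GT + DS) sufficient for round-tripping
dosage panels, not a general-purpose VCF manipulation layer.
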