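# Methods

## The problem

An epigenome-wide association study (EWAS) regresses DNA methylation
(the beta value, a fraction in [0, 1]) at each CpG on a trait of
interest plus covariates. Methylation at a substantial minority of CpGs
is also under local genetic control: a nearby SNP (a *cis*-mQTL) shifts
the CpG's mean level per effect allele. Omitting that genetic term
inflates residual variance at mQTL-matched CpGs, and — if the genotype is
itself correlated with the trait — biases the trait coefficient. The
package builds a per-CpG mQTL database from genotype + methylation
datasets and uses it to fit trait models with and without the matched
genetic covariate, quantifying what changes.

## cis-mQTL scan

For one dataset (one ancestry stratum of one sample set):

* **Window.** Candidate SNPs for a CpG are those on the same chromosome
  within a total 2 Mb span flanking the CpG, i.e. |pos_SNP − pos_CpG| ≤
  1 Mb. Positions are 1-based (array-manifest convention); BED feature
  files stay 0-based half-open with the conversion isolated in
  `io_formats.read_features`.
* **Pre-filters.** CpGs on sex chromosomes and CpGs whose dinucleotide
  (position or position + 1) coincides with a variant of MAF > 0.05 are
  excluded from association testing. Genotypes pass variant QC first:
  missingness > 5%, Hardy–Weinberg exact P < 1e-4 (Levene–Haldane
  conditional distribution on rounded hard calls; dosages with
  fractional part > 0.1 are excluded from the HWE count), MAF < 0.01,
  and — when an imputation-quality column is present — R² ≤ 0.6, applied
  in that order. Remaining missing dosages are mean-imputed per variant
  before regression.
* **Marginal model.** Methylation is regressed on dosage plus the scan
  covariates: sex, methylation batch, and the first five genetic
  principal components. (The EWAS stage uses a different, richer
  covariate set; the two are deliberately kept distinct.) The
  implementation residualizes the phenotype and all window dosages on
  the covariate block once (Frisch–Waugh–Lovell) and then fits simple
  regressions on the residuals with df = n − p_cov − 1; this reproduces
  the full-design estimate, SE and P exactly and makes the window scan a
  single matrix product.
* **Top SNP.** Smallest nominal P wins; ties break to the SNP closest to
  the CpG, then lexicographically by id. Numerically perfect fits report
  P = 0 and are excluded from the beta fit below.
* **Adjusted P.** The window holds many correlated tests, so the null
  distribution of the top SNP's nominal P is estimated by permutation:
  the covariate-residualized phenotype vector is permuted n_perm = 1000
  times (genotypes and covariates fixed, preserving the cis-LD of the
  window), each permuted vector is **re-projected onto the covariate
  orthocomplement**, and the minimum P across the window is recorded.
  The re-projection matters: a permuted residual vector is no longer
  orthogonal to the covariate span, and skipping it shrinks the
  permuted correlations by √((n−p−1)/(n−1)) relative to the observed
  one — a small systematic anti-conservative bias that a 500-CpG
  KS test reliably detects. A Beta(a, b) is fitted to the 1000 minima by
  maximum likelihood (method-of-moments start, two-parameter Newton
  iterations on the digamma score, tolerance 1e-8, ≤ 100 iterations,
  falling back to method-of-moments with a `converged = False` flag),
  and adjusted P = BetaCDF(p_top; a, b). The empirical analogue
  (1 + #{minima ≤ p_top}) / (n_perm + 1) is reported alongside. For K
  independent null SNPs the minimum of K uniforms is Beta(1, K), so the
  fitted shape2 estimates the effective number of independent tests.
* **Seeding.** Each CpG's permutation stream is keyed on
  (global seed, CRC32 of the CpG id), so scan order and parallel
  execution cannot change any result.

A CpG is mQTL-matched in a dataset when its adjusted P < 0.05.

## Database and meta-analysis

Significant (CpG, SNP) pairs from all contributing datasets are unioned.
Effect sizes are first sign-aligned to a single effect allele per pair
(flipped records negate beta; strand-ambiguous A/T and C/G variants with
MAF in [0.4, 0.5] are dropped, as their orientation cannot be resolved).
Pairs observed in ≥ 2 datasets are pooled by inverse-variance
fixed-effects meta-analysis (weights 1/SE²; P from z with the normal
survival function evaluated on the log scale, so values below the float
underflow limit survive as a log10-P column); singleton pairs carry their
one dataset's statistics, with `?` in the direction string for absent
datasets. A pair needs adjusted P < 0.05 in **any one** dataset to enter
(the union convention), not in all of them. Within a CpG, pairs rank by
ascending P, ties broken by distance then SNP id; the rank-1 SNP is the
CpG's assigned mQTL. No heterogeneity statistic is computed
(fixed-effects only).

Cross-dataset concordance over shared CpGs counts identical assigned
SNPs, different SNPs whose dosage r² exceeds 0.5, and their union;
CpGs whose SNPs are missing from the supplied genotype matrix are
"untestable" and leave the denominator.

## EWAS

Per CpG and dataset, ordinary least squares of the beta value on:
birthweight (grams; the coefficient of interest), sex, gestational age
(weeks), batch, case-control selection status, six deconvoluted cell
proportions (CD8T, CD4T, NK, B cells, monocytes, nRBC — granulocytes are
the omitted remainder, avoiding exact collinearity with the intercept),
ten genetic PCs, and (mQTL model only) the assigned mQTL dosage. Only
the top-ranked database SNP per CpG is used; lower-ranked pairs stay in
the database but not in the design. Subjects with gestational age below
30 weeks are excluded before any design matrix is formed, with a logged
count. The sensitivity model adds maternal weight gain, dropping samples
missing it (required present for ≥ 95%).

Model comparison per CpG: relative coefficient change
(β_mqtl − β_plain)/|β_plain| with a >20% flag (undefined and marked when
β_plain = 0), a more-significant-with-mQTL indicator (ties count as
not-more-significant), and the nested partial F-test
F = ((RSS_red − RSS_full)/q)/(RSS_full/df_full), which equals the squared
t of the mQTL coefficient for q = 1. Per-dataset tables are pooled per
platform with the same inverse-variance machinery and
Bonferroni-corrected at 0.05 / (CpGs tested on the platform);
Benjamini–Hochberg adjusted P values are available as an optional column
on the comparison table.

## Enrichment

Two labelled contrasts: (i) a disjoint 2×2 Fisher exact test
(mQTL-matched vs remaining CpGs × inside vs outside a feature), with
fold enrichment (a/(a+b)) / ((a+c)/n) and odds ratio; the two-sided P
sums hypergeometric probabilities of tables at most as likely as the
observed one (scipy's exact implementation; an independent enumeration
oracle checks it exhaustively in the tests for totals ≤ 40). (ii) A
superset proportion contrast per island-relation category — the category
share among mQTL-matched CpGs against the share among **all** CpGs —
using a two-sample chi-squared test without continuity correction
(the "proportion test" flavor was an open choice; chi-squared without
correction is the documented one), star-coded at 0.05/0.01/0.001, plus
a pooled shore-vs-rest row.

## Cell-type deconvolution

A sample's methylation over a reference panel of discriminating CpGs is
modelled as y = Rp with R the CpG × 7 class reference matrix and p on
the probability simplex. The quadratic program min ‖y − Rp‖² s.t.
p ≥ 0, Σp = 1 is solved by nonnegative least squares on a
penalty-augmented system (one extra equation Σp = 1 with weight 1e6)
followed by exact renormalization — deterministic, and exact to
machine precision on noiseless mixtures. Reference-library
*selection* is out of scope: the reference CpG set is an input, and the
synthetic generator emits a matching panel (each reference CpG
high-methylated in a random subset of classes, keeping the columns well
conditioned).

## Synthetic cohorts

The generator defines the study conditions; all strata share one genome
(variant/CpG positions, LD blocks, causal architecture) drawn from the
global seed, while genotypes, covariates and noise are
stratum-specific.

* **Genotypes.** Dosages are sums of two haplotypes from Gaussian-copula
  thresholding: within a block of `ld_block_size` variants the latent
  Gaussians follow an AR(1); `ld_rho` targets the *allele-level*
  adjacent correlation, so the latent correlation is sin(π·ld_rho/2)
  (the inverse of the arcsine attenuation of dichotomized Gaussians,
  exact at frequency ½). Tightly linked variants share a per-block base
  frequency with ±0.05 jitter, clipped to the stratum's MAF range.
  Defaults: 2000 variants on an 80 Mb chromosome, so a 2 Mb window holds
  ~50 SNPs; two strata of 150 ("NLW") and 250 ("LAT") samples — the LAT
  stratum larger, mirroring the power asymmetry such multi-ethnic
  studies show.
* **Phenotypes.** Gestational age ~ N(39, 1.5²) truncated at 30 weeks
  (so the exclusion rule is exercisable); birthweight = 3400 +
  150·(GA − 39) + 120·I(male) + N(0, 400²) grams. Cell proportions are
  Dirichlet with a granulocyte-dominated concentration typical of cord
  blood. `mqtl_bw_effect` (grams/allele, default 0) optionally adds a
  direct genotype → birthweight path at causal SNPs to create the
  confounding scenario.
* **Methylation.** Additive on the raw beta scale with clipping to
  [0, 1] — not M-values — because the trait models regress beta values
  directly: baseline mu from a trimodal mixture (0.1/0.5/0.9 modes),
  plus planted mQTL effects (default N(0, 0.05²) per allele at 20% of
  CpGs, each assigned the nearest variant within the half-window),
  birthweight effects (per-gram scale, default sd 0.02 per 1000 g at 5%
  of CpGs, count exactly round(frac·n)), small batch and sex effects, a
  cell-composition loading at 20% of CpGs, and i.i.d. N(0, 0.02²) noise.
  `mqtl_effect_fixed` / `bw_effect_fixed` plant constant-magnitude
  (random-sign) effects for power studies.
* **What it does not emulate:** admixture LD and local ancestry tracts,
  probe-chemistry (type I/II) artifacts, trans effects, non-additive
  genetic effects, and realistic genome-wide probe density. Passing
  tests therefore demonstrate the statistical machinery — calibration,
  recovery, exactness, determinism — under the stated generative model,
  not performance on real arrays.

## Numerical choices and degenerate inputs

* OLS via thin QR; rank deficiency raises an error naming the aliased
  columns. Residual sums of squares below 1e-20 of the response energy
  are treated as perfect fits (SE = 0, P = 0 for nonzero coefficients).
* Beta-fit inputs are clipped to [1e-12, 1 − 1e-12]; fewer than 10
  nonzero minima fall back to Beta(1, 1) unconverged.
* LD r² is undefined (error) for constant dosage vectors; monomorphic
  cis variants are skipped inside the scan, and a CpG whose window is
  entirely degenerate is skipped with a reason.
* Meta-analysis rejects non-positive SEs; the comparison table marks
  relative changes undefined at β_plain = 0 rather than dividing.

## Problem sizes

Default test and acceptance runs use 500-CpG, ~50-SNPs-per-window,
n = 300 scans at 1000 permutations (a few seconds each on one CPU) and
an end-to-end demonstration at 2 × (60–250) samples. These sizes give
the calibration tests enough resolution (binomial 99% interval around
0.05 at 500 trials; KS at n = 500) while keeping a full suite run under
a minute of compute per heavy fixture.

## Known limitations

* The permutation scheme permutes the residualized phenotype; it assumes
  exchangeability of residuals and does not protect against
  heteroscedastic or family-structured noise.
* Fixed-effects pooling only; between-dataset heterogeneity is neither
  estimated nor down-weighted.
* The database keeps single-dataset discoveries, so its false-positive
  content grows with the number of contributing datasets (by design:
  the union convention).
* Deconvolution assumes the reference spans the sample's true cell
  classes; no reference-free mode is provided.
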