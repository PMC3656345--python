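# Methods

## The statistical question

Genome-wide association signals for complex psychiatric disease leave most
heritability unexplained, and statistical epistasis — a departure of two
loci's joint effect on disease log-odds from additivity — is one candidate
reservoir. Testing all SNP pairs genome-wide is hopeless both
computationally and in multiplicity cost, so this package implements the
candidate-gene strategy: fix an index gene with established association
(the packaged demonstration uses an ANK3-like locus), nominate partner
genes whose protein products have prior biological evidence of interacting
with the index gene's product (a STRING-derived table with interaction
confidence scores ships with the package), and exhaustively test only
index-SNP x partner-SNP pairs.

## Interaction model

For one pair (SNP A in the index gene, SNP B in a partner gene) with
minor-allele dosages `dA, dB ∈ [0, 2]`:

    logit P(case_i) = β0 + β1 dA_i + β2 dB_i + β3 dA_i dB_i + γ' c_i

where `c_i` collects reference-coded study-site indicators and the first k
ancestry principal components (k = 2 by default). Epistasis is a nonzero
β3; its significance is the two-sided Wald p from z = β̂3 / SE(β̂3) against
the standard normal. Dosages enter untransformed (additive allelic coding),
so the test is invariant to affine recoding of the covariates and
equivariant under dosage rescaling.

Fitting is Newton–Raphson (IRLS) with step halving, warm-started at the
intercept-only solution. Convergence requires max |score| < 1e-8 or a
relative log-likelihood change < 1e-10 within 50 iterations; standard
errors come from the inverse observed information at the optimum. Two
failure modes are flagged and excluded from gene-level summaries rather
than given arbitrary p-values:

* **COLLINEAR** — the design [1, dA, dB, dA·dB, c] is rank deficient
  (detected by a pivoted Cholesky of the column-normalized Gram matrix at
  relative tolerance 1e-8). This covers a SNP paired with itself or with a
  perfect-LD partner: the interaction statistic is undefined there, and
  silently emitting a p-value would bias the gene minimum.
* **NON_CONVERGED** — separation (a coefficient escaping ±15 on the
  dosage log-odds scale, an odds ratio beyond e^15) or iteration-cap
  exhaustion. In the interaction tests the bound polices only the four
  dosage-model terms, whose additive coding fixes their scale; covariate
  columns may be arbitrarily scaled, so bounding their coefficients would
  break the affine-recoding invariance of the Wald statistic.

When dosages are integer-valued and no covariates are present, the same
Newton iteration runs on the 3x3 genotype-by-genotype sufficient table
(binomial likelihood without the constant term), which is algebraically
identical to the per-sample fit but independent of sample size; the two
code paths are cross-checked against each other and against an independent
trust-region ML optimizer in the test suite.

## Gene-level summary and permutation significance

Each partner gene is summarized by the minimum Wald p over its converged
pairs. Family-wise error across all genes and pairs is controlled by the
min-p/max-T permutation construction: case-control labels are permuted
B = 1,000 times (genotypes and covariates stay attached to individuals, so
the permutation preserves the covariate structure while breaking any
label association); every gene-pair scan is recomputed per replicate and
the **experiment-wide** minimum p stored. A gene's empirical p is
`#{replicates with null minimum ≤ observed}/B` — ties count as exceedances
— and the study-wide significance threshold is the `floor(αB)`-th smallest
null minimum (the 50th most significant of 1,000 at α = 0.05), giving an
empirical level of exactly α. Referring every gene to the single
experiment-wide null is what makes near-null genes show empirical p close
to 1 even at nominally small observed minima. A per-gene null
(`keep_per_gene=True`) and the (count+1)/(B+1) estimator are available as
alternatives; labels can optionally be permuted within site strata.

Surviving pairs are re-tested in an independent replication cohort with
the same model at nominal α = 0.05; direction concordance of β̂3 with
discovery is recorded but not required. The driving-SNP rescan — the
partner-gene SNPs that carried the discovery signal tested against every
index-gene SNP in the replication cohort — is deliberately uncorrected and
labelled exploratory: it asks whether the same partner variants interact
with *different* index variants (allelic heterogeneity), not whether a
pre-registered hypothesis replicates.

## Quality control

Defaults follow standard practice for imputed case-control panels, applied
in a fixed order with first-failing-rule attribution so reports reproduce:
samples with ≥ 5% missing genotypes are dropped first, SNP statistics are
recomputed, then SNPs are dropped for missingness ≥ 5%, minor allele
frequency < 1% (strict — a SNP at exactly 1% survives), control-only
Hardy–Weinberg exact p < 1e-6, or imputation r² < 0.3. The HWE test is the
exact conditional test (sum of probabilities of heterozygote counts, given
the allele counts, no more probable than the observed one), computed on
genotypes hard-called from dosage by rounding (halves away from zero),
controls only; it is validated against an exact-rational enumeration
oracle to 1e-12. Gene regions are 0-based half-open BED intervals padded
by 10 kb on each side to catch regulatory variants; SNP positions are
1-based and converted in one routine.

## Ancestry adjustment

PCA uses the Eigenstrat construction: each SNP column is centered at 2p̂
and scaled by sqrt(p̂(1−p̂)) with the shrunk frequency estimate
p̂ = (1 + Σd)/(2 + 2n) (the plain MLE is available by flag); missing values
are mean-imputed per SNP; constant SNPs are skipped with a warning; the
top-k eigenvectors of the sample covariance are the coordinates.
Eigenvector signs are fixed by making the largest-magnitude entry positive
so results are reproducible across runs. When PCs enter the covariate
matrix their columns are standardized to unit variance (raw eigenvector
entries scale as 1/sqrt(n), which puts their coefficients on an
uninterpretable scale). PCs are recomputed per cohort —
replication samples get their own ancestry axes rather than projections
onto discovery axes.

## Synthetic cohorts

The generator produces the data features the scan depends on, not a
population-genetic simulation:

* **LD**: within each gene, consecutive SNPs form blocks (default 5 SNPs);
  haplotypes are drawn by thresholding a latent Gaussian AR(1) (ρ = 0.9
  between adjacent SNPs) at each SNP's MAF quantile, so marginal
  frequencies are exact, r² decays with index distance inside a block, and
  is zero across blocks and genes. Designated duplicate pairs copy a
  column verbatim (r² = 1), mirroring the perfect-LD driving-SNP pairs the
  method must handle. A genotype is the sum of two haplotypes drawn with
  replacement from a pool of 2,000.
* **Imputation noise**: per-SNP Gaussian noise added to the hard dosage
  and clipped to [0, 2]. Because clipping damps the noise, the scale is
  calibrated by bisection against the realized post-clip squared
  correlation with the truth (targets drawn per SNP from [0.7, 0.99] by
  default), and the *realized* r² is what lands in the SNP table — the
  filter in real studies also acts on an estimated quantity. Note that
  hard-calling noisy dosages can distort genotype proportions, so a few
  low-quality SNPs failing the HWE filter is expected behaviour, not a
  bug.
* **Confounding**: each sample carries two latent ancestry coordinates
  (standard normal) and a uniformly assigned site. Coordinate 1 shifts the
  allele frequency of half of the background SNPs (so PCA has signal) and,
  together with the site offsets, loads on disease risk (so it confounds).
  Two coordinates mirror the two adjusted PCs.
* **Disease model and ascertainment**: case probability follows the
  logistic interaction model above using the *true* pre-noise dosages of
  the planted pair; a large population is generated in batches and sampled
  down to the requested case/control quotas (retrospective design). Under
  case-control sampling the logistic slopes remain consistent; only the
  intercept absorbs the ascertainment.
* **Determinism**: one master seed; all child seeds (layout, haplotype
  pool, each cohort, noise, permutations) derive from it through
  `numpy.random.SeedSequence`, so identical configurations reproduce
  bit-identical cohorts and byte-identical result files.

What the generator does **not** emulate: recombination-map or coalescent
realism, phasing, genotyping error beyond dosage noise, relatedness,
X-chromosome dosage compensation, or realistic MAF spectra. Passing tests
therefore demonstrate the statistical machinery (calibration, FWER
control, power against a planted log-odds interaction, robustness to the
modelled confounding) — not performance on real LD structure or real
effect-size distributions.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| B | 1,000 | permutation replicates; the threshold rank is floor(0.05·B) = 50 |
| α | 0.05 | nominal family-wise level and replication cutoff |
| k | 2 | ancestry PCs entered as covariates |
| pad | 10 kb | gene-region flank on each side |
| QC | 5% / 5% / 1% / 1e-6 / 0.3 | sample miss / SNP miss / MAF / HWE / imputation r² |
| min score | 0.7 | candidate-gene confidence cutoff (inclusive) |
| β3 (demo) | ln 2.2 | planted interaction log-odds |
| n (demo) | 600 + 600 per cohort | cases + controls |
| ρ, block | 0.9, 5 | latent AR(1) correlation, SNPs per LD block |

The demonstration study sizes (600 cases + 600 controls per cohort, three
partner genes, ~180 SNPs) and the calibration experiment sizes in
`scripts/acceptance.py` (e.g. 100 global-null experiments at B = 200; 500
null Wald simulations at n = 1,000; 100 recovery draws at n = 3,000) are
the package's chosen desk-scale study conditions: large enough for the
binomial error of every reported rate to sit well inside its acceptance
band, small enough to re-run routinely.

## Design choices that were genuinely open

* **Candidate score semantics**: the confidence cutoff is inclusive
  (score ≥ 0.7000 retained), configurable.
* **Null scope**: experiment-wide min-p is the default because it is the
  only reading consistent with near-1 empirical p-values for genes with
  nominally small observed minima; a per-gene null is retained as an
  option.
* **Empirical-p estimator**: plain count/B to match the rank-threshold
  arithmetic (5/1,000 → 0.005); the add-one estimator is available where a
  strictly positive p is needed.
* **Non-converged pairs** are excluded from gene minima and itemized in
  the scan report rather than assigned p = 1: either convention biases
  nothing when non-convergence is label-independent, but exclusion keeps
  the null and observed scans symmetric.
* **Missing dosages** are handled pairwise-complete per test; imputed
  panels are near-complete, so the efficiency loss is negligible and no
  cross-test dependence on a shared complete-case subset is introduced.
* **HWE on dosages** uses rounded hard calls among controls — the
  desk-scale analogue of filtering pre-imputation genotypes.

## Known limitations

* Wald p-values are asymptotic; at very small n or very rare interactions
  (few double-carriers) they are conservative or unstable — the toy-cohort
  tests use the exact permutation reference instead.
* The permutation null assumes exchangeable labels given the retained
  covariate structure; strong site-by-case imbalance is better served by
  the stratified permutation option.
* The generator's LD is index-structured, not map-structured; r² between
  non-adjacent SNPs decays geometrically, which is faster than typical
  real decay within a gene.
* Replication cohorts are drawn from the same generative process as
  discovery; real between-study heterogeneity (platform, ancestry mix,
  phenotype definition) is out of scope.
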