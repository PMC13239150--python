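# Methods

## Model and procedure

`pleiopc` treats the common-variant architecture shared across D
case-control disorders as approximately low rank. For SNP i and disorder
t, the association Z-score is `z_it = β_it / se_it`, oriented to a common
effect allele. After quality filters (below), the SNP-by-disorder matrix
`Z` is factorised by full-rank SVD, `Z = U S Vᵀ`, and each of the
K = D components is read as a latent dimension of psychopathology: the
phenotype singular vector column `V[:,k]` gives the disorders' signed
loadings, the SNP singular vector column `U[:,k]` the variants'.

The attribution statistics are the standard ones of the PCA/SVD
literature:

* variance explained of component k: `s_k² / Σ_j s_j²`;
* contribution of SNP i (disorder t) to component k: `U[i,k]²`
  (`V[t,k]²`) — columns of `U` and `V` are unit-norm, so contributions
  sum to one within a component;
* squared cosine of component k for disorder t:
  `(V[t,k]·s_k)² / Σ_j (V[t,j]·s_j)²`. The singular-value scaling is
  deliberate: with unscaled loadings every row of the orthonormal square
  matrix `V` would sum to one identically and carry no information.

Sign convention: each component is oriented so that its
largest-magnitude phenotype loading is positive. SVD signs are otherwise
arbitrary, and a fixed orientation keeps polygenic-score directions and
correlation signs reproducible across runs and platforms.

## Matrix construction

The fixed stage order is: per-pair thresholding → assembly → minimum-
trait retention → (optional region exclusion) → LD clumping → column
standardisation.

* **Thresholding** (`alpha`, default 10⁻³): a (SNP, disorder) Z is set
  to zero when its p-value is not below `alpha`; this removes the least
  reliable effect estimates while keeping sub-genome-wide-significant
  signal. Sensitivity settings 10⁻⁵ and 0.05 are config options.
* **Retention** (`min_traits`, default 2): SNPs with non-zero Z in fewer
  than two disorders carry no cross-disorder information for the
  factorisation and are dropped.
* **Clumping** (`window_bp` = 500 000, `r2_max` = 0.2): greedy index-SNP
  selection prioritising SNPs with non-zero Z in more disorders. The
  priority beyond that count is not fully determined by the design being
  reproduced, so ties break by larger maximum |Z| and then lexicographic
  SNP id; this makes the output a deterministic function of the input.
  Window semantics are pairwise distance ≤ `window_bp` on the same
  chromosome, bounds inclusive. r² comes from a supplied pairwise table
  (absent pairs are r² = 0); computing LD from genotype panels is out of
  scope.
* **Region exclusion**: rows inside a configured interval (typically the
  extended MHC, chr6:25,477,797–36,448,354 on hg19, whose long-range LD
  defeats clumping) are removed *before* clumping.
* **Standardisation**: each disorder column to mean 0, SD 1, with the
  population (denominator-n) SD. The choice of denominator rescales all
  columns by one common constant and cancels in every direction
  estimate; determinism matters more than the convention. Structural
  zeros (SNP absent from a GWAS) and thresholded zeros enter
  standardisation identically; a boolean mask preserves the distinction
  for diagnostics only.

Harmonisation maps every record to the reference panel's allele
orientation: swapped alleles negate β and replace EAF by 1−EAF; records
matching only after A↔T/C↔G complementation are complemented first;
strand-ambiguous SNPs (A/T, C/G) are dropped by default because their
orientation cannot be inferred from alleles alone (configurable).
Effect-scale input is declared explicitly (β or OR column) — silent
misinterpretation of the effect scale is the worst failure mode a
harmoniser can have, so no auto-detection is attempted.

## Enrichment and external correlations

The SNPs that cumulatively account for `cumulative_fraction` (default
50%, sensitivity 25%) of a component's variance are mapped to genes via
a variant-to-gene table (per SNP: the top-scoring gene plus all genes
flagged as having a transcription start site within 100 kb). The
resulting gene set is tested for over-representation in each annotated
set with the upper-tail hypergeometric probability P[X ≥ overlap]
(over-representation only; depletion is not tested), enrichment ratio =
observed/expected overlap, across sets of background-restricted size
20–500, with Benjamini–Hochberg FDR per collection. The background is an
explicit input, never inferred, because hypergeometric margins must be
consistent; query genes outside it are dropped with a warning.
Developmental-stage expression testing is the same operation applied to
stage-specific gene sets.

For external traits, component SNP loadings are standardised to Z-scores
(mean 0, SD 1 across SNPs) and Pearson-correlated with the external
GWAS's association Z-scores over the SNP intersection (missing SNPs are
excluded, not zero-filled; the two-sided p uses the t-transform with n−2
df). Pearson r is invariant to the affine standardisation of either
side, so whether the external Z's are additionally standardised is
immaterial; they are left as read. External GWAS pass through exactly
the same harmonisation as matrix inputs — an orientation mismatch here
silently flips correlation signs, which is why the harmonisation report
is always logged.

## Summary-statistics PGS evaluation

The component-k PGS weights each SNP by its signed loading `U[i,k]`,
effect allele = panel allele 1. Signed loadings, not squared
contributions, are the default: squaring destroys direction-of-effect
information and cannot produce case/control mean differences of either
sign. The squared variant remains available behind a flag for
comparison.

* **Cohort subtraction.** When the target cohort contributed to a
  discovery meta-analysis, its contribution is removed exactly:
  with w = 1/SE², `β' = (w_m β_m − w_c β_c)/(w_m − w_c)`,
  `SE' = (w_m − w_c)^{−1/2}`, p recomputed against the standard normal.
  SNPs with `w_m ≤ w_c` are degenerate and dropped with a warning.
* **Count reconstruction.** From (OR, EAF, n_case, n_control):
  in control-frequency mode `f_case = OR·f/(1−f+OR·f)`; in pooled mode
  the control frequency is the admissible root of the quadratic implied
  jointly by the OR and the pooled-frequency constraint. Pooled mode
  exists because biobank-style outputs report overall allele frequency.
* **Group-wise PGS.** Over M reconstructable SNPs,
  `mean_g = (1/M)·Σ 2 f_g w` and `sd_g = (1/M)·√(Σ w² 2 f_g (1−f_g))`,
  i.e. the per-individual score mean and SD under Hardy–Weinberg with
  post-clumping SNPs treated as independent (residual r² ≤ 0.2 is
  ignored). The 1/M scaling is cosmetic — it cancels in t and R² — but
  keeps reported means on the per-SNP-average scale. Group comparison
  uses the Welch (unequal-variance) t-test with Welch–Satterthwaite df;
  R² = t²/(t²+df) with the same df.
* **Case–case GWAS.** Both case frequencies are reconstructed, the
  case–case OR is the ratio of case odds, SE is Woolf's
  `√(1/a_A+1/b_A+1/a_B+1/b_B)` on the reconstructed case allele counts.
  Covariance induced by controls shared between the two source GWAS is
  **not** corrected for — a known simplification that leaves the
  case-case SE slightly conservative or anticonservative depending on
  overlap. The output frame is oriented so it can be fed straight back
  into the group-wise PGS (group B's case frequency plays the control
  role). Bonferroni correction at 0.05/m gates families of planned
  comparisons (m = 3 for three differential-diagnosis contrasts).

## Synthetic data: what it emulates and what it does not

`generate_model` draws K orthonormal phenotype factors and a sparse
Gaussian SNP factor matrix; `generate_sumstats` writes per-disorder
summary statistics whose Z-matrix is `signal + noise_sd·ε`, ε iid
standard normal. Noise is applied on the Z scale because the pipeline
consumes Z-scores and the null sampling distribution of a GWAS
Z-statistic has unit variance; `noise_sd = 1` is therefore the realistic
setting, and the factor scales (defaults 10, 7, 5) set the
signal-to-noise ratio. β and SE are back-derived via
`se = 1/√(2f(1−f)·n_eff)`, `n_eff = 4/(1/n_case+1/n_control)`, so files
look like genuine log-OR statistics. Default sample sizes span 20k–125k
cases and 50k–330k controls across eight disorders, the range typical of
psychiatric consortium GWAS; MAF is uniform on (0.1, 0.5).

LD is idealised as block-diagonal: equal r² within consecutive-SNP
blocks, zero across, with blocks spanning less than the 500 kb clumping
window and separated by more than it. This makes the correct clumping
result exactly computable (one index SNP per block). Target cohorts are
generated at the individual level (Binomial(2, f) genotypes per group,
case frequencies shifted by `effect_shift` along each weight's sign) and
summarised from realised counts, so analytic PGS moments can be
validated against true individual scores and count reconstruction is
exact by construction.

Passing tests on these data certify the algebra and the estimators, not
robustness to everything real GWAS bring: realistic MAF spectra,
LD that decays continuously rather than in blocks, imputation error,
sample overlap between discovery GWAS, and ascertainment effects are all
outside the generator, and results on real consortium data additionally
depend on the external resources (reference LD, variant-to-gene scores,
gene-set collections) supplied as inputs.

## Numerical choices and degenerate inputs

* SVD via LAPACK (`numpy.linalg.svd`); reconstruction and orthonormality
  are certified to 1e-8 in tests, unit-sum attribution identities to
  1e-10.
* Recovery experiments compare planted phenotype factors to the
  singular vectors of the *generated* matrix via absolute Tucker
  congruence with Hungarian matching; per-column standardisation is
  omitted there because rescaling columns by their own SDs perturbs the
  planted factor geometry.
* Cumulative-variance SNP selection sorts by contribution descending
  with ties broken by SNP id; the prefix test uses a 1e-12 tolerance so
  exact-boundary fractions are stable.
* Zero-variance columns (standardisation, loading Z-scores), empty
  matrices after filtering, all-zero singular values, empty queries and
  empty SNP intersections are fatal errors naming the offending trait,
  SNP or stage; harmonisation drops are never fatal and always counted.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf`, BH FDR from
  `statsmodels`; both are cross-checked in the test suite against
  brute-force enumeration/step-up oracles. Pearson r and its p use
  `scipy.stats.pearsonr`, cross-checked against the closed form.
* All generators take explicit integer seeds and are deterministic given
  them; written files use 17-significant-digit floats so reruns are
  byte-identical.

## Problem sizes

The shipped experiments use matrices of 2000 SNPs × 8 disorders
(roughly the scale of the clumped matrices this design produces),
10-seed recovery batches, 200-instance clumping randomisations, and
simulated target cohorts of up to 50 000 individuals per group — sizes
at which every check runs in seconds on a laptop while keeping
Monte-Carlo error well below the tested tolerances.

## Known limitations

* Indels and multi-allelic variants are unsupported; no liftover.
* No LD-score-regression genetic correlation; external-trait association
  is plain Pearson correlation of Z's over shared SNPs.
* The group-PGS independence assumption ignores residual LD (r² ≤ 0.2)
  between clumped SNPs; analytic SDs are slightly optimistic when
  residual correlation is positive.
* Case–case GWAS ignores shared-control covariance (above).
* The clumping tie-break and the exact weighting called "contribution"
  in component PGS construction are conventions chosen here (documented
  above), not uniquely determined by the design being reproduced.
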