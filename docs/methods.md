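# Methods

## Model and transform

The gene test is a linear mixed model

y = 1μ + Xβ + a + ε,  a ~ N(0, K σ²ₐ),  ε ~ N(0, I σ²ₑ),

with **X** the gene's regression design and **K** the realized
relationship matrix (RRM) computed once from all post-filter markers.
The polygenic incidence matrix is the identity: the intended data are
inbred-line panels with one record per line.

Writing h² = σ²ₐ/(σ²ₐ+σ²ₑ), Var(y|β) = (h²/(1−h²) K + I) σ²ₑ. With the
one-time eigendecomposition K = U S Uᵀ, the rotation ỹ = Uᵀy,
X̃ = Uᵀ[1 X] and rescaling by W = (h²/(1−h²))S + I gives an ordinary
regression y* = W^(−1/2)ỹ on X* = W^(−1/2)X̃ with i.i.d. errors. All
per-gene work is then plain least squares; h² only changes a diagonal
rescaling, so one eigendecomposition serves every gene and every h².

The per-gene fit is a barebones weighted regression: an intercept-only
fit on the whitened data gives the total sum of squares SSY; the full
fit gives SSE; SSR = SSY − SSE; σ̂²ₑ = SSE/df_ε with df_ε = n − df_β − 1;
and F = (SSR/df_β)/σ̂²ₑ is referred to the upper tail of
F(df_β, df_ε). The profile −2 log-likelihood used for h² estimation is
n·log σ̂²ₑ + log|W| (maximum likelihood, with the constant dropped, so
absolute values are not comparable across tools; REML is deliberately
out of scope).

Estimator conventions: coefficients solve the standard WLS normal
equations (X̃ᵀW⁻¹X̃)⁻¹X̃ᵀW⁻¹ỹ; σ̂²ₑ uses the residual-degrees-of-freedom
denominator SSE/df_ε (the F statistic requires it); p-values are the
upper F tail.

## Gene designs

SNPs are assigned to every gene whose 1-based inclusive span contains
their position (strand ignored; a SNP in two overlapping genes enters
both blocks). Genes need at least `min_snps` SNPs (default 10) after the
MAF filter (default minor-allele frequency ≥ 5%). Within a gene, missing
dosages are imputed to the SNP mean and columns are mean-centered;
monomorphic columns are dropped.

- **EPC**: PCA (SVD of the centered matrix) keeps the smallest number of
  components whose cumulative variance fraction reaches the threshold
  (default 0.80, boundary-inclusive). PCA is on centered but *unscaled*
  dosages — variance-weighted components, the common convention for
  dosage data; `scale=True` / `--pca-scale` standardizes first.
- **FPC**: the first component only (df_β = 1).
- **ALLSNP**: the centered columns themselves, reduced to a maximal
  linearly independent subset by rank-revealing QR (relative tolerance
  1e-8) so the normal equations are never singular; df_β is the retained
  rank.
- **EPCLM**: the EPC design fitted with K replaced by the identity and
  h² ≡ 0 — ordinary least squares through the same code path. It exists
  as the inflated-baseline comparator and is never refined (there is no
  polygenic parameter to optimize).

Component order follows decreasing singular value; numpy's SVD ordering
makes runs reproducible.

## Heritability estimation and the two-round scan

Genomic heritability is estimated from the intercept-only mixed model by
bounded scalar search of the profile likelihood on [1e-6, 1−1e-6]: a
25-point grid locates the basin, Brent refinement (absolute tolerance
1e-6) polishes it. On flat profiles (range < 1e-8, e.g. K = I, where the
profile is exactly constant) the lower bound is returned — the most
parsimonious reading.

Boundary behavior: ML under a singular K (the RRM from centered markers
always has a zero eigenvalue along the constant vector, absorbed by the
intercept) gains roughly log(h²/(1−h²)) as h² → 1, so on panels whose
kinship spectrum carries little information (near-identity K) the
estimate can sit at the upper bound. This is the familiar ML boundary
degeneracy under weak identification, not a solver failure; on
informative panels (structured populations, n in the hundreds to
thousands) the interior optimum dominates and recovery is accurate (see
the parameter-recovery tests).

The genome scan runs in at most two rounds. Round one fixes every gene's
polygenic h² at the genomic estimate — the EMMAX substitution — so a
single whitening serves all genes. Round two re-optimizes h² only for
genes with screening p ≤ `screen_alpha` (default 0.05), searching down
from the genomic estimate (per-gene polygenic heritability cannot exceed
it when the gene's own variance is removed from the background, and most
genes are null, so the genomic estimate is a tight upper bound).

Thresholding: Bonferroni −log₁₀(α/genes tested) at family α = 0.05.
Genomic control λ maps each F p-value to a 1-df chi-square quantile and
divides the median by 0.4549; multi-df tests are mapped through p-values
first, the usual cross-test convention.

## The simulator

`simulate_genotype_panel` emulates the features of an inbred maize
diversity panel that matter to a gene-based scan:

- dosages in {0, 2} (fully homozygous lines; `inbred=False` sums two
  haplotypes for outbred 0/1/2 data);
- genes of 10–20 SNPs tiled on 10 synthetic chromosomes with
  non-overlapping spans (SNP spacing 100 bp, inter-gene gap 10 kb);
- within-gene LD from a latent Gaussian AR(1) process (default
  ρ = 0.7) thresholded at each SNP's frequency quantile — enough
  correlation that EPC designs span multiple PCs, as in real gene
  blocks;
- target alternate-allele frequencies uniform on [0.05, 0.5];
- optional population structure: individuals split into subpopulations
  with Balding–Nichols frequency shifts (`n_subpops`, `fst`), used for
  the stratification-inflation contrasts.

What it does **not** model: long-range LD between genes, realistic
recombination or coalescent genealogy, dominance, epistasis, and
genotyping error. Between-gene independence makes the synthetic kinship
closer to identity than real maize kinship, which weakens genomic-h²
identification (see boundary note above) but leaves per-gene test
calibration intact — calibration tests passing here speak to the test
statistics, not to every property of real-panel kinship.

QTN architectures place `n_qtns` causal SNPs uniformly without
replacement over the pooled SNPs of `n_causal_genes` randomly chosen
genes (the validation design: 100 causal genes; QTN groups of
100/300/600/1000). Effect magnitudes are gamma(shape = 1.66,
scale = 0.4); signs are random ±1 by default because thousands of
all-positive effects would build an implausible directional polygenic
score (`effects_positive=True` restores all-positive draws). Phenotypes
add Gaussian noise scaled so the QTN genetic values target 60% of
phenotypic variance; the realized fraction var(g)/var(y) is reported.
No background polygenic term is added on top of the QTNs;
`simulate_polygenic_phenotype` provides the complementary pure-polygenic
(LMM-null) phenotype, parameterized by model h² (σ²ₐ = h², σ²ₑ = 1−h²),
for calibration and recovery studies. For an inbred panel diag(K) ≈ 2,
so model h² and the realized population variance fraction differ; both
parameterizations are documented on the functions that use them.

## Power study

`run_power_study` fixes the genotype panel and the causal-gene set
across replicates (the validation design reuses its causal genes) and
redraws QTN placement, effects and residuals each replicate. Kinship,
its decomposition and all per-gene design rotations are computed once —
only the phenotype changes — which is what makes the replicated study
desk-scale. Power is the fraction of causal genes passing the threshold
(a declared causal gene is a true QTG); type-I error is the fraction of
non-causal genes passing. Curves are traced over a threshold grid and
methods are compared at matched mean type-I levels by interpolation.

Default scaled-down conditions (n = 500, 200 genes, 20 causal genes,
100 QTNs, 10 replicates) keep the full study under a minute; the
full-scale design (n ≈ 2000+, thousands of genes, 50 replicates) uses
the same entry point with larger counts.

## Numerical choices

- Eigenvalues of K below a relative 1e-8 are clipped to zero; genuinely
  negative ones are an error. Symmetry is checked to the same tolerance.
- Whitened designs are solved by `lstsq`; gene designs are full rank by
  construction (PCA scores, or QR-reduced ALLSNP columns).
- SSR is clipped at zero against rounding; p-values use `scipy.stats`
  survival functions throughout.
- Degenerate genes (all SNPs monomorphic in-sample) are skipped with a
  logged reason, never fatal to a scan.
- All simulation randomness flows through `numpy.random.default_rng`
  seeds; identical (config, seed) pairs give byte-identical outputs.

## Known limitations

- Kinship uses all post-filter SNPs; no leave-one-chromosome-out or
  per-gene marker exclusion, so large genes can suffer mild proximal
  contamination.
- ML, not REML: variance estimates carry the usual O(1/n) downward bias
  and the boundary behavior described above.
- The dosage-table dialect and phenotype TSV are this tool's own simple
  contracts; PLINK binary formats and indels are out of scope.
- EPCLM exists only as a comparator; its p-values on structured data are
  known to be anticonservative by design.
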