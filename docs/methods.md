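# Methods

This note records the model, the numerical and design choices, and the
limits of what the test suite demonstrates.

## Data model and encoding

A genotype matrix holds minor-allele dosages in {0,1,2} for n individuals
by m SNPs, with unique sample IDs and rsIDs and an optional case/control
phenotype.  The binary working form uses two bits per SNP — SNP j (0-based)
owns bit columns 2j and 2j+1 — with 0→00, 1→01, 2→11, mirroring the two
parental alleles: flipping one bit is flipping one allele.  Decoding is
total; the pair 10, which the encoder never produces, decodes to genotype 1
(one minor allele present), so any binary matrix decodes to a valid
genotype matrix and the genotype always equals the number of 1-bits in its
pair.

VCF ingestion accepts biallelic sites only, treats ALT as the minor allele
and converts GT to ALT-allele dosage.  Missing genotypes are rejected: the
pipeline assumes complete matrices, and imputation is out of scope.

## The association matrix Θ

The noise law's column-association parameter is estimated from a public
reference panel of the same SNPs by a log-linear rule: diagonal entries are
log(Pr(bit=0)/Pr(bit=1)); off-diagonal entries are the negative log odds
ratio of the 2×2 joint table of two bit columns,
log[(P01·P10)/(P11·P00)].  Choices made here:

* **Laplace smoothing, pseudocount 0.5 (Jeffreys-style), default.**  The
  log-linear rule is undefined on empty cells; every marginal cell gains
  0.5 over a total inflated by 2×0.5, every joint cell 0.5 over 4×0.5.
  A pseudocount of 0 is allowed but raises on any empty cell.
* **Symmetrisation** (Θ+Θᵀ)/2: the off-diagonal formula is symmetric
  analytically; averaging kills floating-point asymmetry so that
  eigenvalue routines (`eigvalsh`) can assume symmetry.
* **Budget scaling with equality.**  Any Θ with
  s_f·‖λ(Θ)‖₂ ≤ ε_e yields a valid release; the estimate is rescaled by
  c = ε_e/(s_f·‖λ‖) so the condition binds exactly, which retains the most
  correlation signal for a given budget.  c may exceed 1 when the raw norm
  is small.  For a symmetric matrix ‖λ‖₂ equals the Frobenius norm; the
  eigenvalues are still computed explicitly so either route can
  cross-check the other.
* **Block-diagonal fallback for wide panels.**  Beyond 2,000 SNPs a dense
  4,000×4,000+ eigendecomposition stops being desk-scale, so Θ is built
  block-diagonally over contiguous windows (default 500 SNPs).  Linkage
  disequilibrium is local, and the eigenvalue norm of a block-diagonal
  matrix is the ℓ₂ norm of per-block norms, so the budget condition is
  unchanged.
* **No kinship terms.**  Sample-association matrices (family structure via
  Mendelian inheritance) are not modelled; the pipeline targets cohorts of
  unrelated individuals, and the synthetic generator produces exchangeable
  rows.  The budget condition therefore contains no row-association sums.

## Noise calibration and the privacy guarantee

With no kinship blocks the vectorised noise parameter is the Kronecker
product I_n ⊗ Θ, so the calibration statistic
κ_u = 2·rowsum(Θ)_u − Θ_uu repeats identically across individuals and is
computed once per bit column (O(m²) rather than O((nm)²)).  Noise bits are
independent Bernoulli draws with

    Pr(B_u = 1) = 1/2              if |κ_u| > ‖λ(Θ)‖₂,
                  1/(1 + exp κ_u)  otherwise (ties → sigmoid).

A sigmoid-branch column's worst-case per-bit log-likelihood ratio is
|log((1−p)/p)| = |κ_u| ≤ ‖λ(Θ)‖₂; capped columns leak nothing.  A record
differing in all 2m = s_f bits therefore leaks at most s_f·‖λ(Θ)‖₂ = ε_e.
Note the cap is *symmetric* in the sign of κ: a column with
κ_u < −‖λ‖ would otherwise sit on the sigmoid branch with loss
|κ_u| > ‖λ‖ and break the guarantee — the exhaustive enumeration oracle in
the test suite (n=1, m=2, all 16 outputs against all neighbouring bit
patterns) confirms the bound holds exactly with the symmetric cap and
fails without it when Θ carries negatively signed couplings, which
LD-structured panels routinely produce.  Flip probabilities are clamped to
[1e-12, 1−1e-12] against sigmoid saturation at extreme budgets; clamping
moves probabilities toward 1/2 and can only shrink the loss.

A diagnostic, `per_bit_privacy_loss`, returns Σ_u |log((1−p_u)/p_u)| so the
bound can be asserted on any calibration without enumeration.

The normalisation constant of the exact matrix-valued Bernoulli law is
never evaluated anywhere — avoiding it is the point of the element-wise
sampler.

## MAF restoration

Restoration transports each SNP's empirical allele distribution (2n bits
on {0,1}) onto the published MAF.  On a two-point space the earth mover's
distance between Bernoulli(ã) and Bernoulli(a) is |ã − a| and the optimal
plan is unique: move that mass from the over-represented value.  The
integer flip count floor(|ã − a|·2n) never exceeds the count of
source-value bits, and the floor leaves each restored MAF strictly within
1/(2n) of its target — since allele counts are integers, within-group
targets taken from a same-sized cohort are matched *exactly*, which is why
mean-error fidelity is typically 0.  Flipped bits are chosen uniformly
without replacement across the SNP's two columns jointly ("allele" = one
bit), seeded.  "Minor" means the designated minor allele's frequency, not
min(f, 1−f): frequencies may exceed 0.5 after noise and the bookkeeping
stays linear.

Restoration reads only the noisy bits and public targets, never the
original matrix, so it is post-processing and preserves ε_e-DP.

**Group-aware release.**  `release()` accepts either one length-m MAF
vector or a mapping {phenotype label → vector}.  The mapping form restores
each phenotype group to its own published MAFs (GWAS findings publish
case-group MAFs; control aggregates are typically public).  This matters:
at realistic budgets the flip probabilities are ≈ 1/2 and the entry-level
signal is gone, so the case/control allele contrast — which is exactly
what association tests measure — survives only through the per-group MAF
targets.  Whole-dataset restoration is kept for phenotype-free releases.
Noise is sampled once for the full matrix either way; only the
post-processing is group-aware, so the privacy guarantee is identical.

## Verifier-side GWAS

* χ² uses the 2×3 genotype table (Pearson, no continuity correction, via
  `scipy.stats.chi2_contingency`); genotype columns with zero total are
  dropped, reducing the degrees of freedom; monomorphic SNPs return p = 1
  (no evidence) rather than NaN.
* The odds-ratio test is allelic: the genotype table collapses to minor/
  major allele counts, the Haldane–Anscombe +0.5 correction is applied to
  all four cells when any is zero, and the two-sided p comes from the Wald
  statistic log(OR)/SE with SE = √(1/a+1/b+1/c+1/d).
* "Significant" is the strict inequality p < threshold; the verifier's
  threshold is α/tolerance (default 0.05/0.8 = 0.0625).
* The retention rate is the fraction of reported-significant rsIDs whose
  reproduced p-value clears the relaxed threshold.
* Error models: *flipping* replaces round(δf·m) p-values (uniform, without
  replacement) with Uniform(0,1) draws; *noise* adds Normal(0, δn²) to
  every p-value and clips to [0,1] (the range handling is this package's
  choice; p-values must stay valid).
* `validation_experiment` recomputes the reported significant set from the
  injected p-values at α, reproduces the test once on the released data,
  and reports the mean retention-rate difference (error-free minus
  error-injected) over the injection repeats with a normal 95% CI.  A
  replicate whose injected significant set is empty (possible at δf = 1
  with small m) is recorded as invalid and excluded from the mean, since
  a retention rate over an empty set is undefined.

## Membership inference and baselines

The Hamming-distance test scores a victim by their minimum genotype
Hamming distance to the shared dataset.  The threshold γ is the
fpr-quantile of the same statistic over a held-out half of the reference
panel — known non-members — so "false positive rate" keeps its standard
meaning; a victim is called member iff their statistic falls below γ.  A
`gamma_from="case_quantile"` mode calibrates instead on the shared
individuals' distances to the reference and scores victims against the
reference, for comparison with descriptions that calibrate on the case
side.  Accuracy is meaningful only when non-member victims and the
reference come from the same population as the study cohort; otherwise
the test measures distribution shift, not membership (the acceptance
script draws both from the study's control MAFs for this reason).

Laplace MAF release adds Laplace((m/n)/ε_m) noise per entry — one
individual moves each of the m MAFs by at most 1/n, so the vector ℓ₁
sensitivity is m/n with composition folded in; a `per_snp` switch
interprets ε_m per SNP (scale (1/n)/ε_m) instead.  Joint release of the
dataset and noisy MAFs costs ε_e + ε_m by sequential composition.

The local-DP baseline is 3-ary randomized response per genotype entry:
keep with probability e^ε/(e^ε+2), else one of the other two values
uniformly — per-entry ε-LDP.  No conversion between the per-SNP LDP budget
and the dataset-level ε_e is attempted; comparisons take both explicitly.

## Synthetic data

The generator emulates a reference panel and a case/control cohort:

* Per-SNP target MAFs ~ Uniform(0.05, 0.5) by default (common variants;
  rare-variant panels make every bit-level statistic noisier), or an
  explicit MAF vector for drawing extra individuals from an existing
  population.
* Haplotypes come from a first-order Gaussian-copula chain: a latent AR(1)
  normal sequence thresholded at each SNP's MAF.  Marginals are exact;
  `ld_rho` (default 0 for panels, i.e. linkage equilibrium) is the latent
  autocorrelation and the induced adjacent-allele correlation is monotone
  in it, equal at matched MAFs.  A direct allele-copying chain was
  rejected because it distorts heterogeneous marginals.
* Genotypes are sums of two independent haplotypes — Hardy–Weinberg at
  every SNP — and rows are exchangeable (no kinship), matching the
  no-kinship assumption of the noise calibration.
* The disease model is per-allele multiplicative: at causal SNPs the case
  minor-allele odds are multiplied by `effect_or` (log-additive GWAS
  model); controls sit at panel MAFs.

The study conditions used by the acceptance script and the end-to-end
tests are 200 SNPs, 300 cases + 300 controls, 5 causal SNPs at per-allele
OR 3, a 500-individual reference panel, and ε_e = 5 — a cohort size and
effect strength at which the planted associations are individually
detectable at α = 0.05 with high power, so retention is a sharp
instrument.  What passing these tests shows is that the mechanism's
guarantees (exact DP bound, MAF alignment, error separation) hold under
Hardy–Weinberg, kinship-free, common-variant data with at most first-order
LD; it does not show robustness to population structure, rare variants,
genotyping missingness or related individuals, none of which the generator
emulates.

## Numerical conventions

* A single seeded `numpy.random.Generator` drives each pipeline run;
  derived stages draw from it in a fixed order, so identical seeds give
  identical releases across platforms.
* `transport_plan` adds 1e-12 before flooring so exact-lattice differences
  (e.g. 0.15·100) are not floored down by representation error.
* Findings round-trip through JSON/TSV at full float precision (repr).
* Symmetry of Θ is validated at 1e-9; the cached eigen-norm is
  recomputable to the same tolerance.

## Known limitations

* No missing data, multi-allelic sites, imputation or phasing.
* Kinship-aware noise (family cohorts) is not implemented.
* The privacy guarantee covers the dataset release; published exact MAFs
  are treated as public inputs (use the Laplace MAF release when they are
  not).
* χ² on the released data inherits extra genotype-level sampling noise
  from restoration (restoration constrains allele counts, not genotype
  counts); the allelic odds-ratio test reproduces more tightly.
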