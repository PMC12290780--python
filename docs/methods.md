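# Methods

This document states the models, algorithms, parameter conventions and
numerical choices implemented in `sfcoupling`, together with the known
limits of the synthetic-data generator. Every empirical number quoted
here was computed by the code in this repository (tests or
`scripts/acceptance.py`); no uncomputed claims are made.

## 1. Synthetic cohort generator (`sfcoupling.synth`)

**Pedigree.** `generate_pedigree(n_mz_pairs, n_dz_pairs, n_fullsib_pairs,
n_singletons)` builds disjoint nuclear families: each twin/sib pair gets
its own parent couple; singletons get their own founders. The analysis
set (`Pedigree.analysis_ids`) is the offspring plus singletons; parents
exist only to transmit haplotypes. `hcp_style_pedigree` uses the
composition 140 MZ pairs + 85 DZ pairs + 280 full-sib individuals + 204
singletons, which under disjoint families yields 934 analysis
individuals. Real twin cohorts with this composition report fewer
subjects because twin pairs and additional siblings share families
(one individual can be counted both as a twin's co-sib and a sib-pair
member); the disjoint-family generator does not reproduce that overlap.

**Genotypes.** Biallelic SNPs on 2 synthetic chromosomes. Founder
haplotypes are drawn from a Gaussian AR(ρ) copula within LD blocks
(default block size 50 SNPs, within-block ρ = 0.8), thresholded at the
allele frequency drawn uniformly from `maf_range` (default 0.01–0.5;
the demo pipeline uses 0.05–0.5).
Gene dropping: each child inherits one haplotype per parent, chosen
independently per LD block — free recombination between blocks, none
within; the second MZ twin copies the first. Dosage = sum of the two
haplotypes ∈ {0, 1, 2}; optional missingness is injected at random.

**Covariates.** Age, sex, handedness and total brain volume with simple
marginal distributions; used only as fixed-effect columns.

**Phenotypes.** `simulate_phenotype(K, covariates, h2_true, mode=...)`
supports:

- `covariance` mode: y = μ + g + e with g ~ N(0, σ²g K), e ~ N(0, σ²e I),
  σ²g/(σ²g+σ²e) = h²_true, and μ = Xβ when covariates are supplied.
- `causal` mode: per-SNP effects γ ~ N(0, σ²β) on `n_causal` randomly
  chosen standardized SNPs; the genetic values Zγ are rescaled so the
  realized genetic variance fraction equals h²_true in expectation.
  Effects are **centered**: a nonzero mean effect would inject a fixed
  directional component (the same expected direction in every
  replicate) that is mean structure, not genetic variance, and biases
  variance-component heritability upward by several points (measured:
  +0.03–0.05 at h² = 0.4 on the 500-individual cohort before centering).

**Mesh and connectivity.** `generate_mesh` places vertices on two
Fibonacci-sphere hemispheres and assigns nested region and functional
network labels. `simulate_connectivity` plants per-vertex coupling
targets with heritability `h2_coupling` (genetic values drawn through
the supplied relationship matrix) and constructs SC/FC profile pairs
whose uncentered-cosine coupling reproduces those targets to ~1e-10.
Consequence: the heritable signal lives in the **uncentered** inner
product. Centered estimators (Pearson, Spearman) measure a different
functional of the profiles; measured on the generator, per-vertex h²
from the inner product is uncorrelated with the centered variants
(r ≈ ±0.03 across mesh seeds) while Pearson and Spearman agree with
each other (r ≈ 0.6). FC matrices are emitted row-wise (per-vertex
profiles) rather than globally symmetric, because the exact per-vertex
round-trip is incompatible with symmetry when within-network rows share
entries; symmetry validation applies to externally read profiles.

All randomness flows through named substreams:
`SeedSequence(seed, spawn_key=(crc32(name),))`, so stages are
independently reproducible and derived seeds stay below 2³¹.

## 2. Coupling measure (`sfcoupling.coupling`)

For vertex *j*, the patch E(j) is the set of same-hemisphere vertices in
the same functional network, excluding *j* itself. SC profiles are
transformed with log(1+SC) by default (`log_transform_sc=False`
disables). Coupling methods:

- `inner` (default): f₁·f₂ / (‖f₁‖‖f₂‖), clipped to [−1, 1]. Clipping
  only guards against floating-point excursions; exact identities hold
  bit-for-bit: disjoint-support profiles give exactly 0.0, and
  proportional profiles with exactly representable norms (e.g. SC
  [3, 4], FC [−3/8, −1/2]: norms 5 and 5/8) give exactly ∓1.0.
- `pearson`, `spearman`: centered (rank-)correlations via the same
  patch; zero-variance profiles yield NaN with a warning.

Optional geodesic Gaussian smoothing of SC (`smooth_sc`, bandwidth in
mesh distance units) precedes coupling.

## 3. Relatedness (`sfcoupling.relatedness`)

**QC order:** individual missingness → SNP missingness → MAF →
Hardy–Weinberg (exact test, founders/unrelateds only when a pedigree is
supplied). Defaults: individual missingness ≤ 0.10, SNP missingness
≤ 0.10, MAF ≥ 0.01, HWE p ≥ 1e-7.

**SNP GRM:** Yang-style estimator with pairwise-complete missing-data
handling: K_ab = mean over SNPs observed in both a and b of
(x_a − 2p)(x_b − 2p) / (2p(1−p)), with p the sample allele frequency.
Monomorphic SNPs (p ≤ 0 or ≥ 1) are rejected. The per-pair SNP counts
are retained and serialized. An oracle test verifies equality with a
naive double loop to 1e-12.

**Pedigree GRM:** expected relationships {1 MZ, ½ DZ/full-sib,
0 otherwise} with unit diagonal — exact rational coding, no estimation.

**PCs:** eigendecomposition of the centered GRM.

## 4. Variance components (`sfcoupling.varcomp`)

Single-trait model: y = Xβ + g + e, V = σ²g K + σ²e I. The univariate
path rotates into the eigenbasis of K (one `eigh`, reusable across
traits via `K_eig`), making each REML iteration O(n²) instead of O(n³).

AI-REML details:

- Variance floor: 1e-6 × var(y) on each variance component.
- Initialization: even split of the residualized trait variance.
- Average-information updates with step-halving (up to 30 halvings),
  accepting only candidates with non-decreasing restricted likelihood.
- **Active-set handling of boundary optima:** a component pinned at the
  floor whose score is negative is held fixed and excluded from the AI
  solve; if every parameter is pinned that way, the point satisfies the
  KKT conditions of the constrained problem and the fit is reported
  converged. Without this, null traits (σ²g truly 0) systematically
  terminate via failed step-halving and are mislabeled non-converged
  (observed on ~half of null replicates).
- Convergence: change in log-likelihood and in θ below 1e-8 (relative
  for θ); maximum 100 iterations.
- K = cI raises `NotIdentifiableError` (components not separable).
- SE of h² by the delta method from the inverse average information.
- Test of σ²g = 0 by the boundary-corrected LRT: p = ½ P(χ²₁ > Λ),
  with p = 1 at Λ = 0 (½χ²₀ + ½χ²₁ mixture). Null calibration is
  verified empirically (rejection rate within 3 binomial SEs of 5%
  over 400 null replicates).

Bivariate (genetic correlation r_g) and repeated-measures models use a
generic dense AI-REML engine with the same floors, step-halving and
active-set rule; covariance parameters are unconstrained. r_g is flagged
undefined when a genetic variance sits at the floor.

## 5. Mixed-model association scan (`sfcoupling.gwas`)

Two-step scheme: fit the null model once per trait by REML, fix V̂, then
per SNP run generalized least squares — whiten with the eigendecomposition
of K, residualize covariates by QR, and compute the Wald test for the SNP
effect. Missing dosages are mean-imputed per SNP; monomorphic SNPs are
skipped and recorded in `attrs["skipped"]`. If the null model is not
identifiable (K = I), the scan falls back to OLS, which it provably
equals in that case (oracle test vs statsmodels, 1e-8). Because V̂ is
fixed from the null model, per-SNP tests are Wald tests under the null
variance estimate (the standard two-step approximation); type-I error is
verified empirically at the 5% level (mean over 40 null traits within
0.05 ± 0.015).

Multiple testing: Bonferroni α/m, and Benjamini–Hochberg step-up
(verified against statsmodels on random p-value sets).

## 6. Loci and enrichment (`sfcoupling.loci`, `sfcoupling.enrichment`)

Genomic risk loci follow a clumping scheme: independent significant SNPs
at r² ≥ 0.6 from each other's clumps, lead SNPs mutually below r² < 0.1,
candidate tag SNPs at MAF ≥ 0.0005, and iterative merging of blocks
closer than 250 kb. An exhaustive brute-force reimplementation in the
test suite must produce identical blocks, independent SNPs and leads.

Cytobands are synthetic: fixed-width bands per chromosome, read/written
in UCSC conventions (0-based half-open converted to 1-based inclusive).
Enrichment uses the 2×2 Pearson χ² without continuity correction,
n(ad−bc)²/(r₁r₂c₁c₂), validated against `scipy.stats.chi2_contingency`.
`locus_network_enrichment` builds, for each cytoband × network pair, the
2×2 table of membership **among significant associations only**;
degenerate margins are skipped and reported.

## 7. Genetic architecture and sensitivity

`pairwise_rg` computes bivariate r_g across vertex pairs;
`fit_distance_decay` regresses r_g on geodesic distance with a quadratic
model and an F-test against the constant model (level verified on null
data). `subsample_experiment` re-estimates h² on random subcohorts
(with per-replicate re-QC of monomorphic SNPs, as any standard pipeline
re-runs QC after subsetting); its mean SE decreases monotonically in
subsample size. `relatedness_experiment` varies the fraction of related
individuals retained; `method_concordance` correlates per-vertex h²
across coupling estimators.

## 8. Generator realism limits

- Disjoint families only: the 934-individual composition above
  overcounts relative to real overlapping-family cohorts.
- 2 chromosomes, uniform SNP spacing, free recombination between LD
  blocks and none within; no recombination hotspots or MAF spectrum.
- No dominance, epistasis, gene–environment interaction, or shared
  household environment; MZ and DZ similarity differ only through the
  additive relationship.
- The heritable coupling signal is planted in the uncentered cosine;
  centered estimators see largely independent noise (section 1).
- Connectivity has no geometric autocorrelation beyond network
  membership; distance-decay structure in r_g must be planted
  explicitly.

## 9. Numerical choices

- All solvers operate in float64; exact identities (coupling 0/±1,
  pedigree GRM coding, Bonferroni arithmetic) are asserted bitwise or to
  1e-12.
- Deterministic serialization: gzip members are written with mtime 0 and
  no filename field, so pipeline reruns are byte-identical.
- Text formats use GCTA/VCF/UCSC conventions where one exists; "NA" is
  the missing token and is parsed as a literal string (pandas default NA
  inference is disabled) before explicit conversion.
- Derived seeds are always reduced below 2³¹.

## 10. Limitations

- The two-step GWAS does not re-estimate variance components per SNP
  (no leave-one-chromosome-out), so proximal contamination is possible
  at large per-SNP effects.
- The boundary LRT mixture ½χ²₀ + ½χ²₁ is asymptotic; calibration was
  verified at n ≈ 200, not for very small cohorts.
- r_g near boundaries is reported as undefined rather than constrained
  to [−1, 1] by reparameterization.
- Enrichment χ² assumes independent significant associations; LD between
  tags within a locus violates this, as it does in the analogous real
  analyses.
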