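# sfcoupling

Vertex-wise structure–function connectivity coupling as a quantitative
phenotype: cohort simulation, coupling construction, heritability
estimation, mixed-model GWAS, genomic risk locus definition, enrichment,
and genetic-correlation structure — all on fully synthetic twin/sibling
cohorts, with no external data dependencies.

## Science overview

Structural connectivity (SC, e.g. streamline counts) and functional
connectivity (FC, e.g. resting-state correlations) describe two views of
the same cortical sheet. Their *coupling* — for each cortical vertex, the
similarity between that vertex's SC profile and FC profile to all other
vertices in a local patch — is a per-subject, per-vertex scalar phenotype.
This package implements the full genetic analysis chain for that
phenotype:

1. **Synthetic cohort** (`sfcoupling.synth`): a twin/sibling pedigree
   (MZ and DZ twin pairs, full-sib pairs, singletons), gene-dropped
   biallelic genotypes with block-wise LD, covariates, and connectivity
   profiles in which coupling heritability is planted at a chosen level.
2. **Coupling** (`sfcoupling.coupling`): per-vertex SC–FC similarity
   (normalized inner product by default, Pearson or Spearman as
   alternatives) over distance-limited patches, with `log(1+SC)`
   transformation.
3. **Relatedness** (`sfcoupling.relatedness`): genotype QC (MAF,
   missingness, Hardy–Weinberg exact test), a Yang-style SNP GRM with
   pairwise-complete handling of missing dosages, a pedigree expected
   relationship matrix ({1 MZ, ½ DZ/full-sib, 0 otherwise}), and GRM PCs.
4. **Variance components** (`sfcoupling.varcomp`): AI-REML with variance
   floors, step-halving, active-set handling of boundary optima, a
   boundary-corrected likelihood-ratio test (½χ²₀ + ½χ²₁), and
   delta-method standard errors; bivariate genetic correlations and a
   repeated-measures decomposition.
5. **Association** (`sfcoupling.gwas`): a two-step mixed-model scan (null
   REML once per trait, then per-SNP generalized least squares with the
   fitted covariance), Bonferroni and Benjamini–Hochberg corrections.
6. **Loci and enrichment** (`sfcoupling.loci`, `sfcoupling.enrichment`):
   LD-clumping-based genomic risk locus definition (independent SNPs at
   r² ≥ 0.6 from lead SNPs at r² < 0.1, 250 kb merge), synthetic
   cytoband assignment, and 2×2 χ² enrichment of significant hits across
   cytoband × network cells.
7. **Genetic architecture** (`sfcoupling.genarch`): pairwise genetic
   correlations across vertices and their decay with geodesic distance.
8. **Sensitivity** (`sfcoupling.sensitivity`): subsampling, relatedness
   composition, and estimator-concordance experiments.

Everything is deterministic given a seed; named RNG substreams keep the
stages independently reproducible.

## Worked example

```python
import numpy as np
import sfcoupling as sfc

# 1. synthetic twin/sibling cohort: 45 MZ + 30 DZ + 45 full-sib pairs + 60 singletons
ped = sfc.generate_pedigree(45, 30, 45, 60, seed=42)
geno = sfc.simulate_genotypes(ped, n_snps=2000, seed=42)

# 2. genotype QC and the SNP-based relationship matrix
geno_qc, report = sfc.qc_filter(geno, pedigree=ped)
K = sfc.compute_grm(geno_qc)

# 3. connectivity profiles and vertex-wise SC-FC coupling
mesh = sfc.generate_mesh(50, n_networks=7, n_regions=20, seed=42)
profiles, targets = sfc.simulate_connectivity(mesh, ped, K, h2_coupling=0.4, seed=42)
coupling = sfc.compute_coupling(profiles, mesh, method="inner")

# 4. heritability of the first coupling vertex
fit = sfc.reml_univariate(coupling.values[:, 0], None, K)

# 5. mixed-model GWAS of a causal-mode phenotype and locus definition
pheno = sfc.simulate_phenotype(K, None, 0.4, mode="causal", n_causal=50,
                               genotypes=geno_qc, seed=7)
assoc = sfc.lmm_gwas(pheno.trait("trait"), geno_qc, None, K)
threshold = sfc.bonferroni_threshold(0.05, len(assoc))
loci = sfc.define_loci(assoc, geno_qc, threshold)
```

Output of this exact script (`python scratch/worked_example.py` with the
print statements included):

```
cohort: 300 analysis individuals, 2000 SNPs
QC: kept 1996/2000 SNPs (MAF removed 4, HWE removed 0)
GRM: mean diagonal 0.998
coupling: 300 subjects x 96 vertices, grand mean 0.500
vertex L00000: h2 = 0.315 (SE 0.109), LRT p = 3.84e-03
GWAS: 1996 SNPs, Bonferroni threshold 2.51e-05, min P = 1.54e-06, 2 genomic risk loci
```

## Command line

The `sfcoupling` entry point exposes each stage
(`simulate-cohort`, `simulate-connectivity`, `coupling`, `qc`, `grm`,
`pca`, `reml`, `gwas`, `loci`, `enrich`, `rg`, `distance-decay`,
`sensitivity`) plus an end-to-end demo pipeline:

```bash
sfcoupling run --outdir demo --seed 0
```

writes a self-contained artifact tree (pedigree, genotypes, GRM,
coupling matrix, per-vertex REML table, association summaries, loci,
enrichment and genetic-correlation tables). Reruns with the same seed and
configuration are byte-identical.

## Reproduction

`scripts/acceptance.py` recomputes the three headline quantities from
scratch at runtime:

```bash
python scripts/acceptance.py --seed 1 --out acceptance.json
```

```json
{
  "t5": {"value": 0.0, "n": 150},
  "t6": {"value": -1.0, "n": 150},
  "t8": {"value": 0.40260168330507184, "n": 200}
}
```

- `t5`: coupling of SC/FC profiles with disjoint support is exactly 0.
- `t6`: coupling of a negated, proportional profile is exactly −1.
- `t8`: mean AI-REML heritability estimate over 200 causal-mode
  replicates (true h² = 0.4, ~500-individual cohort, 2,000 SNPs);
  the recovery target is |mean − 0.4| ≤ 0.03.

`tests/test_acceptance.py` contains one test per acceptance criterion,
including oracle equivalences (naive GRM double loop, restricted
likelihood grid, OLS at K = I, exhaustive clumping, statsmodels BH,
hand χ²) and null calibration of both the mixed-model scan and the
boundary LRT.

## Layout

```
src/sfcoupling/     library (synth, coupling, relatedness, varcomp, gwas,
                    loci, enrichment, genarch, sensitivity, io, pipeline, cli)
tests/              pytest suite, acceptance tests in tests/test_acceptance.py
scripts/            acceptance.py reproduction script
docs/methods.md     model, estimators, numerical choices, limitations
```
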