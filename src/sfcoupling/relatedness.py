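"""Genotype quality control and genetic relatedness.

QC applies, in order: individual missingness, minor allele frequency
(recomputed on the retained individuals), per-SNP missingness, and the
exact Hardy-Weinberg test.  The SNP-based relationship matrix follows the
standard allele-frequency-standardized estimator

    K_jk = (1 / M_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with p_i the sample alternate-allele frequency and M_jk the count of SNPs
non-missing in both individuals.  The pedigree-based matrix codes expected
genetic similarity: 1 for MZ twins, 1/2 for DZ twins and full siblings,
0 for unrelated pairs, 1 on the diagonal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import (DZ, FOUNDER, FULL_SIB, MZ, GenotypeMatrix, GRM,
                        Pedigree, QCReport)

__all__ = ["hwe_exact_test", "qc_filter", "compute_grm", "pedigree_grm",
           "genetic_pcs"]


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test probability.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the conditional probabilities of configurations no more
    probable than the observed one (two-sided exact test).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype counts")
    n_alt = 2 * n_aa + n_Aa
    n_rare = min(n_alt, 2 * n - n_alt)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (gammaln(n + 1) - gammaln(hom_common + 1) - gammaln(hets + 1)
            - gammaln(hom_rare + 1) + hets * np.log(2.0)
            + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1))
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs_het = n_Aa
    p_obs = prob[hets == obs_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-12)].sum()))


def qc_filter(genotypes: GenotypeMatrix, ind_missing_max: float = 0.10,
              maf_min: float = 0.01, snp_missing_max: float = 0.10,
              hwe_p_min: float = 1e-7,
              pedigree: Pedigree | None = None
              ) -> tuple[GenotypeMatrix, QCReport]:
    """Standard genotype QC in the conventional order.

    (1) drop individuals with missing fraction > ``ind_missing_max``;
    (2) drop SNPs with MAF < ``maf_min`` (frequencies recomputed on the
    retained individuals); (3) drop SNPs with missing rate >
    ``snp_missing_max``; (4) drop SNPs with exact HWE p < ``hwe_p_min``.
    HWE is evaluated on founders/singletons only when a pedigree is given
    (related individuals distort the test).
    """
    if genotypes.n_individuals == 0 or genotypes.n_snps == 0:
        raise ValueError("empty genotype matrix")
    d = genotypes.dosage
    miss_ind = np.isnan(d).mean(axis=1)
    keep_ind = np.flatnonzero(miss_ind <= ind_missing_max)
    g = genotypes.subset(individuals=keep_ind)
    report = QCReport(n_individuals_in=genotypes.n_individuals,
                      n_snps_in=genotypes.n_snps,
                      removed_individuals_missing=genotypes.n_individuals
                      - keep_ind.size)

    freq = g.allele_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    keep = ~np.isnan(maf) & (maf >= maf_min)
    report.removed_snps_maf = int((~keep).sum())
    g = g.subset(snps=np.flatnonzero(keep))

    miss_snp = np.isnan(g.dosage).mean(axis=0)
    keep = miss_snp <= snp_missing_max
    report.removed_snps_missing = int((~keep).sum())
    g = g.subset(snps=np.flatnonzero(keep))

    if pedigree is not None:
        unrelated = {r.individual_id for r in pedigree.table.itertuples(index=False)
                     if r.father_id in ("0", "")}
        rows = np.array([i for i, iid in enumerate(g.individual_ids)
                         if iid in unrelated])
        hwe_d = g.dosage[rows] if rows.size else g.dosage
    else:
        hwe_d = g.dosage
    keep = np.ones(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        col = hwe_d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        counts = (int((col == 0).sum()), int((col == 1).sum()),
                  int((col == 2).sum()))
        if hwe_exact_test(*counts) < hwe_p_min:
            keep[j] = False
    report.removed_snps_hwe = int((~keep).sum())
    g = g.subset(snps=np.flatnonzero(keep))

    if g.n_snps == 0:
        raise ValueError("no variants survive QC")
    return g, report


def compute_grm(genotypes: GenotypeMatrix) -> GRM:
    """SNP-based genetic relationship matrix (Yang estimator).

    Missing dosages are handled pairwise-complete: each pair's average runs
    over the SNPs observed in both individuals.
    """
    d = genotypes.dosage
    freq = genotypes.allele_frequency()
    if np.any((freq <= 0.0) | (freq >= 1.0)):
        bad = genotypes.snp_meta.loc[
            np.flatnonzero((freq <= 0) | (freq >= 1)), "snp_id"].iloc[0]
        raise ValueError(f"monomorphic SNP {bad}: run QC first")
    w = (d - 2.0 * freq) / np.sqrt(2.0 * freq * (1.0 - freq))
    observed = (~np.isnan(d)).astype(float)
    w = np.nan_to_num(w)
    counts = observed @ observed.T
    if np.any(counts == 0):
        raise ValueError("some individual pairs share no observed SNPs")
    values = (w @ w.T) / counts
    values = (values + values.T) / 2.0
    return GRM(values, list(genotypes.individual_ids), source="snp",
               n_snps=counts.astype(int),
               family_ids=list(genotypes.family_ids))


def pedigree_grm(pedigree: Pedigree, ids: list[str] | None = None) -> GRM:
    """Expected-similarity matrix from the pedigree: MZ pairs 1, DZ pairs
    and full siblings 1/2, unrelated 0; unit diagonal.

    ``ids`` restricts and orders the output (default: analysis individuals).
    """
    if ids is None:
        ids = pedigree.analysis_ids
    index = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    values = np.eye(n)
    table = pedigree.table
    fam_of = dict(zip(table["individual_id"], table["family_id"]))
    tag_of = dict(zip(table["individual_id"], table["relationship_tag"]))
    by_family: dict[str, list[str]] = {}
    for iid in ids:
        by_family.setdefault(fam_of[iid], []).append(iid)
    for members in by_family.values():
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                a, b = members[a_i], members[b_i]
                ta, tb = tag_of[a], tag_of[b]
                if ta == MZ and tb == MZ:
                    r = 1.0
                elif {ta, tb} <= {DZ, FULL_SIB} or FOUNDER in (ta, tb):
                    # DZ twins and full siblings share half; a parent-child
                    # pair (founder present) also has expected similarity 1/2
                    r = 0.5
                else:
                    r = 0.0
                values[index[a], index[b]] = values[index[b], index[a]] = r
    return GRM(values, list(ids), source="pedigree",
               family_ids=[fam_of[i] for i in ids])


def genetic_pcs(K: GRM, n_components: int = 10) -> pd.DataFrame:
    """Top genetic principal components from the relationship matrix.

    Direct eigendecomposition of K; components are unit-norm eigenvectors
    for the largest eigenvalues, sign-fixed so each component's
    largest-magnitude loading is positive.  Eigenvalues are attached as
    ``df.attrs['eigenvalues']``.
    """
    if n_components > K.n - 1:
        raise ValueError("n_components must be <= n - 1")
    if not np.allclose(K.values, K.values.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    eigval, eigvec = np.linalg.eigh(K.values)
    order = np.argsort(eigval)[::-1][:n_components]
    vals = eigval[order]
    vecs = eigvec[:, order]
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    df = pd.DataFrame(vecs, columns=[f"PC{i+1}" for i in range(n_components)])
    df.insert(0, "individual_id", K.individual_ids)
    df.attrs["eigenvalues"] = vals
    return df
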