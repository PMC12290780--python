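"""QC filters, exact HWE, SNP and pedigree relationship matrices, PCs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sfcoupling as sfc
from sfcoupling.datatypes import GRM, GenotypeMatrix


def make_genotypes(dosage, chrom=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    meta = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": np.arange(1, m + 1) * 1000,
        "snp_id": [f"s{j}" for j in range(m)],
        "ref": "A", "alt": "G",
    })
    return GenotypeMatrix(dosage, meta, [f"i{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# exact HWE test


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent enumeration with exact integer arithmetic.

    Conditional on the allele counts, the probability of a genotype
    configuration is proportional to the exact multinomial weight
    n! 2^het / (hom_A! het! hom_a!); the two-sided exact p-value sums the
    weights of all configurations no more probable than the observed one.
    """
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa  # alt allele count
    rare = min(na, 2 * n - na)
    weights = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_a = (rare - het) // 2
        hom_A = n - het - hom_a
        weights[het] = (math.factorial(n) * 2 ** het
                        // (math.factorial(hom_A) * math.factorial(het)
                            * math.factorial(hom_a)))
    p_obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= p_obs) / sum(
        weights.values())


def test_hwe_modal_configurations_p_one():
    assert sfc.hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-12)
    assert sfc.hwe_exact_test(0, 2, 0) == pytest.approx(1.0, abs=1e-12)


def test_hwe_extreme_het_deficit():
    assert sfc.hwe_exact_test(100, 0, 100) < 1e-7


def test_hwe_matches_enumeration_oracle_grid():
    for counts in [(5, 3, 2), (10, 1, 9), (0, 10, 0), (7, 7, 7), (1, 0, 1),
                   (12, 4, 0), (3, 9, 8), (50, 20, 30)]:
        assert sfc.hwe_exact_test(*counts) == pytest.approx(
            hwe_oracle(*counts), rel=1e-9)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
def test_hwe_probability_properties(a, b, c):
    if a + b + c == 0:
        with pytest.raises(ValueError):
            sfc.hwe_exact_test(a, b, c)
        return
    p = sfc.hwe_exact_test(a, b, c)
    assert 0.0 < p <= 1.0
    assert p == pytest.approx(hwe_oracle(a, b, c), rel=1e-9)


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        sfc.hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# QC filter


def test_qc_clean_data_untouched():
    rng = np.random.default_rng(0)
    dosage = rng.binomial(2, 0.3, size=(100, 20)).astype(float)
    # binomial(2, 0.3) draws are HWE-consistent with MAF far above 0.01
    g = make_genotypes(dosage)
    out, report = sfc.qc_filter(g)
    assert report.n_snps_out == 20
    assert report.n_individuals_out == 100
    assert np.array_equal(out.dosage, dosage)


def test_qc_maf_filter():
    dosage = np.zeros((200, 2))
    # MAF 0.5 in exact HWE proportions (50/100/50) so only MAF can drop s1
    dosage[:, 0] = np.tile([0, 1, 1, 2], 50)
    dosage[0, 1] = 1.0                       # MAF 0.0025 < 0.01
    out, report = sfc.qc_filter(make_genotypes(dosage))
    assert report.removed_snps_maf == 1
    assert out.snp_ids == ["s0"]


def test_qc_missingness_hand_count():
    """6 x 5 toy: one 40%-missing individual and one 20%-missing SNP are
    exactly what the first and third filters remove."""
    rng = np.random.default_rng(1)
    dosage = rng.binomial(2, 0.5, size=(6, 5)).astype(float)
    dosage[:, dosage.std(axis=0) == 0] = 1.0
    dosage[0, [0, 1]] = np.nan           # individual 0: 2/5 = 40% missing
    dosage[2, 4] = np.nan                # SNP 4: 1/5 = 20% missing (after
    #                                      individual 0 is dropped)
    # ind_missing_max=0.3 removes only individual 0 (individual 2 is at 20%)
    out, report = sfc.qc_filter(make_genotypes(dosage), ind_missing_max=0.3,
                                maf_min=0.0, hwe_p_min=0.0)
    assert report.removed_individuals_missing == 1
    assert report.removed_snps_missing == 1
    assert out.n_individuals == 5
    assert "s4" not in out.snp_ids


def test_qc_hwe_filter_on_founders_only():
    """A SNP violating HWE only among related individuals survives when the
    pedigree restricts the test to founders/singletons."""
    ped = sfc.generate_pedigree(30, 0, 0, 60, seed=2)
    geno = sfc.simulate_genotypes(ped, 50, seed=2)
    # craft one SNP: HWE-consistent in singletons, all-het in twins
    dosage = geno.dosage.copy()
    tags = ped.table.set_index("individual_id").loc[
        geno.individual_ids, "relationship_tag"]
    is_single = (tags == "SINGLETON").to_numpy()
    dosage[~is_single, 0] = 1.0
    rng = np.random.default_rng(3)
    dosage[is_single, 0] = rng.binomial(2, 0.5, is_single.sum())
    g = GenotypeMatrix(dosage, geno.snp_meta, geno.individual_ids,
                       geno.family_ids)
    _, rep_no_ped = sfc.qc_filter(g)
    _, rep_ped = sfc.qc_filter(g, pedigree=ped)
    assert rep_ped.removed_snps_hwe <= rep_no_ped.removed_snps_hwe


def test_qc_rejects_empty():
    with pytest.raises(ValueError):
        sfc.qc_filter(make_genotypes(np.empty((0, 0))))


# ---------------------------------------------------------------------------
# SNP GRM


def test_grm_single_snp_direct_arithmetic():
    # two individuals, dosages (2, 0): p = 0.5; diagonal (2-1)^2/(2*.5*.5)=2
    g = make_genotypes([[2.0], [0.0]])
    K = sfc.compute_grm(g)
    assert K.values[0, 0] == pytest.approx(2.0, abs=1e-12)
    assert K.values[1, 1] == pytest.approx(2.0, abs=1e-12)
    assert K.values[0, 1] == pytest.approx(-2.0, abs=1e-12)


def test_grm_identical_rows_equal_entries():
    rng = np.random.default_rng(4)
    dosage = rng.binomial(2, 0.4, size=(5, 30)).astype(float)
    dosage[1] = dosage[0]  # an MZ-like pair
    K = sfc.compute_grm(make_genotypes(dosage))
    assert K.values[0, 1] == pytest.approx(K.values[0, 0], abs=1e-12)
    assert K.values[0, 1] == pytest.approx(K.values[1, 1], abs=1e-12)


def test_grm_founder_cohort_moments():
    ped = sfc.generate_pedigree(0, 0, 0, 300, seed=5)
    geno = sfc.simulate_genotypes(ped, 800, ld_block_size=1, seed=5)
    K = sfc.compute_grm(geno)
    off = K.values[~np.eye(K.n, dtype=bool)]
    assert abs(np.diag(K.values).mean() - 1.0) < 0.05
    assert abs(off.mean()) < 0.01


def test_grm_naive_double_loop_oracle():
    """Pairwise-complete estimator vs an index-by-index reimplementation on
    a 10 x 20 toy with missing calls."""
    rng = np.random.default_rng(6)
    dosage = rng.binomial(2, rng.uniform(0.1, 0.5, 20), size=(10, 20)).astype(float)
    dosage[rng.random((10, 20)) < 0.15] = np.nan
    dosage[:, np.nanstd(dosage, axis=0) == 0] = 1.0
    g = make_genotypes(dosage)
    K = sfc.compute_grm(g)
    p = np.nanmean(dosage, axis=0) / 2.0
    n, m = dosage.shape
    for j in range(n):
        for k in range(n):
            acc, cnt = 0.0, 0
            for i in range(m):
                if np.isnan(dosage[j, i]) or np.isnan(dosage[k, i]):
                    continue
                acc += ((dosage[j, i] - 2 * p[i]) * (dosage[k, i] - 2 * p[i])
                        / (2 * p[i] * (1 - p[i])))
                cnt += 1
            assert K.values[j, k] == pytest.approx(acc / cnt, abs=1e-12)
            assert K.n_snps[j, k] == cnt


def test_grm_rejects_monomorphic():
    dosage = np.zeros((4, 2))            # s0: allele frequency exactly 0
    dosage[:, 1] = [0, 1, 2, 1]
    with pytest.raises(ValueError, match="monomorphic"):
        sfc.compute_grm(make_genotypes(dosage))


# ---------------------------------------------------------------------------
# pedigree GRM


def test_pedigree_grm_exact_coding():
    ped = sfc.generate_pedigree(1, 1, 1, 2, seed=0)
    K = sfc.pedigree_grm(ped)
    ids = K.individual_ids
    idx = {iid: i for i, iid in enumerate(ids)}
    v = K.values
    assert np.allclose(np.diag(v), 1.0)
    assert v[idx["fam0001-c1"], idx["fam0001-c2"]] == 1.0     # MZ
    assert v[idx["fam0002-c1"], idx["fam0002-c2"]] == 0.5     # DZ
    assert v[idx["fam0003-c1"], idx["fam0003-c2"]] == 0.5     # full sibs
    assert v[idx["fam0004-s1"], idx["fam0005-s1"]] == 0.0     # unrelated
    assert v[idx["fam0001-c1"], idx["fam0002-c1"]] == 0.0     # across families
    assert set(np.unique(v)) <= {0.0, 0.5, 1.0}


# ---------------------------------------------------------------------------
# genetic PCs


def test_pcs_identity_spectrum():
    K = GRM(np.eye(6), [f"i{i}" for i in range(6)], source="snp")
    pcs = sfc.genetic_pcs(K, n_components=3)
    assert np.allclose(pcs.attrs["eigenvalues"], 1.0)


def test_pcs_rank_one_closed_form():
    v = np.array([3.0, 0.0, 4.0, 0.0])
    K = GRM(np.outer(v, v), [f"i{i}" for i in range(4)], source="snp")
    pcs = sfc.genetic_pcs(K, n_components=1)
    assert pcs.attrs["eigenvalues"][0] == pytest.approx(25.0, abs=1e-10)
    pc1 = pcs["PC1"].to_numpy()
    assert np.allclose(np.abs(pc1), np.abs(v) / 5.0, atol=1e-10)


def test_pcs_two_population_separation():
    rng = np.random.default_rng(7)
    a = rng.binomial(2, 0.15, size=(40, 300)).astype(float)
    b = rng.binomial(2, 0.45, size=(40, 300)).astype(float)
    g = make_genotypes(np.vstack([a, b]))
    pcs = sfc.genetic_pcs(sfc.compute_grm(g), n_components=2)
    pc1 = pcs["PC1"].to_numpy()
    # PC1 separates the populations: within-group spread below the
    # between-group mean gap (positive silhouette)
    gap = abs(pc1[:40].mean() - pc1[40:].mean())
    assert gap > 2 * max(pc1[:40].std(), pc1[40:].std())


def test_pcs_validation():
    K = GRM(np.eye(4), [f"i{i}" for i in range(4)], source="snp")
    with pytest.raises(ValueError):
        sfc.genetic_pcs(K, n_components=4)
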