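"""Generator contracts: pedigree, gene-dropped genotypes, phenotypes,
mesh and connectivity profiles."""

import numpy as np
import pytest

import sfcoupling as sfc
from sfcoupling.coupling import network_patches
from sfcoupling.datatypes import FOUNDER, MZ
from sfcoupling.synth import substream

from conftest import flat_mesh


# ---------------------------------------------------------------------------
# pedigree


def test_pedigree_study_composition():
    # disjoint families, so the composition adds up exactly
    ped = sfc.generate_pedigree(140, 85, 140, 204, seed=0)
    assert len(ped.analysis_ids) == 140 * 2 + 85 * 2 + 280 + 204 == 934


def test_pedigree_singletons_only():
    ped = sfc.generate_pedigree(0, 0, 0, 5, seed=0)
    assert len(ped.analysis_ids) == 5
    assert all(len(m) == 1 for m in ped.families().values())


def test_pedigree_one_mz_one_dz():
    ped = sfc.generate_pedigree(1, 1, 0, 0, seed=0)
    assert len(ped.families()) == 2
    tags = list(ped.table.loc[
        ped.table["relationship_tag"] != FOUNDER, "relationship_tag"])
    assert sorted(tags) == ["DZ", "DZ", "MZ", "MZ"]


def test_pedigree_rejects_empty_and_negative():
    with pytest.raises(ValueError):
        sfc.generate_pedigree(0, 0, 0, 0)
    with pytest.raises(ValueError):
        sfc.generate_pedigree(-1, 0, 0, 5)


# ---------------------------------------------------------------------------
# genotypes


def test_mz_pairs_share_genotypes():
    ped = sfc.generate_pedigree(4, 4, 0, 0, seed=2)
    geno = sfc.simulate_genotypes(ped, 80, seed=2)
    idx = {iid: i for i, iid in enumerate(geno.individual_ids)}
    for fam, members in ped.families().items():
        a, b = members
        tag = ped.table.set_index("individual_id").loc[a, "relationship_tag"]
        if tag == MZ:
            assert np.array_equal(geno.dosage[idx[a]], geno.dosage[idx[b]])
        else:
            assert not np.array_equal(geno.dosage[idx[a]], geno.dosage[idx[b]])


def test_mendelian_consistency_exhaustive():
    """Child dosage compatible with parental transmissions at every SNP.

    A parent with dosage 0 transmits 0, dosage 2 transmits 1, dosage 1
    transmits 0 or 1; the child dosage must lie within the implied bounds
    (covers all 3 x 3 parental configurations present in the draw).
    """
    ped = sfc.generate_pedigree(3, 5, 5, 0, seed=3)
    geno = sfc.simulate_genotypes(ped, 200, seed=3, include_founders=True)
    idx = {iid: i for i, iid in enumerate(geno.individual_ids)}
    lo = {0.0: 0, 1.0: 0, 2.0: 1}
    hi = {0.0: 0, 1.0: 1, 2.0: 1}
    checked = 0
    for row in ped.table.itertuples(index=False):
        if row.father_id in ("0", ""):
            continue
        c = geno.dosage[idx[row.individual_id]]
        f = geno.dosage[idx[row.father_id]]
        m = geno.dosage[idx[row.mother_id]]
        lower = np.vectorize(lo.get)(f) + np.vectorize(lo.get)(m)
        upper = np.vectorize(hi.get)(f) + np.vectorize(hi.get)(m)
        assert np.all((c >= lower) & (c <= upper))
        checked += 1
    assert checked > 0
    # in particular, both parents homozygous reference -> child 0
    dosage = geno.dosage
    for row in ped.table.itertuples(index=False):
        if row.father_id in ("0", ""):
            continue
        both_zero = (dosage[idx[row.father_id]] == 0) & \
            (dosage[idx[row.mother_id]] == 0)
        assert np.all(dosage[idx[row.individual_id]][both_zero] == 0)


def test_founder_allele_frequency_binomial():
    """400 founders at fixed MAF 0.3: per-SNP sample frequency is
    binomial(800, 0.3)/800; nearly all SNPs fall inside the 3-SE band."""
    ped = sfc.generate_pedigree(0, 0, 0, 400, seed=4)
    geno = sfc.simulate_genotypes(ped, 300, maf_range=(0.3, 0.3),
                                  ld_block_size=1, seed=4)
    freq = geno.allele_frequency()
    se = np.sqrt(0.3 * 0.7 / (2 * 400))
    outside = np.abs(freq - 0.3) > 3 * se
    # expected violation rate under the binomial oracle is ~0.27%
    assert outside.mean() <= 0.03
    assert abs(freq.mean() - 0.3) < 4 * se / np.sqrt(300)


def test_genotype_parameter_validation():
    ped = sfc.generate_pedigree(0, 0, 0, 3, seed=0)
    with pytest.raises(ValueError):
        sfc.simulate_genotypes(ped, 0)
    with pytest.raises(ValueError):
        sfc.simulate_genotypes(ped, 10, maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        sfc.simulate_genotypes(ped, 10, ld_block_size=11)


def test_genotypes_reproducible():
    ped = sfc.generate_pedigree(2, 2, 2, 2, seed=5)
    a = sfc.simulate_genotypes(ped, 50, seed=5)
    b = sfc.simulate_genotypes(ped, 50, seed=5)
    assert np.array_equal(a.dosage, b.dosage)


# ---------------------------------------------------------------------------
# phenotypes


def test_phenotype_h2_zero_covariance_is_white_noise():
    """h2 = 0 in covariance mode: replicate covariance is the identity."""
    ped = sfc.generate_pedigree(2, 0, 0, 4, seed=6)
    K = sfc.pedigree_grm(ped)
    n = K.n
    reps = 3000
    draws = np.stack([
        sfc.simulate_phenotype(K, None, 0.0, mode="covariance", seed=s)
        .trait("trait") for s in range(reps)])
    cov = np.cov(draws, rowvar=False)
    off = cov[~np.eye(n, dtype=bool)]
    # MC tolerance: entries of a sample covariance over 3000 draws
    assert np.abs(np.diag(cov) - 1.0).max() < 0.15
    assert np.abs(off).max() < 0.15


def test_phenotype_causal_mode_mz_correlation_matches_h2():
    """MZ pairs share genotypes exactly, so in causal mode the expected
    phenotypic correlation of an MZ pair equals h2 (variance bookkeeping
    oracle: shared genetic part sqrt(h2) g, independent residuals)."""
    ped = sfc.generate_pedigree(60, 0, 0, 0, seed=8)
    geno = sfc.simulate_genotypes(ped, 400, seed=8)
    h2 = 0.5
    rs = []
    for s in range(40):
        y = sfc.simulate_phenotype(None, None, h2, mode="causal",
                                   n_causal=200, genotypes=geno,
                                   seed=100 + s).trait("trait")
        rs.append(np.corrcoef(y[0::2], y[1::2])[0, 1])
    assert abs(np.mean(rs) - h2) < 0.05


def test_phenotype_causal_realized_variance_fraction():
    """The emitted trait has unit variance split exactly h2 : 1 - h2."""
    ped = sfc.generate_pedigree(0, 0, 0, 200, seed=9)
    geno = sfc.simulate_genotypes(ped, 300, seed=9)
    y = sfc.simulate_phenotype(None, None, 0.5, mode="causal", n_causal=100,
                               genotypes=geno, seed=9).trait("trait")
    # genetic and residual parts are standardized and independent draws;
    # total variance = h2 + (1-h2) + cross term (small, O(1/sqrt(n)))
    assert abs(np.var(y) - 1.0) < 0.2


def test_phenotype_validation():
    ped = sfc.generate_pedigree(0, 0, 0, 4, seed=0)
    K = sfc.pedigree_grm(ped)
    with pytest.raises(ValueError):
        sfc.simulate_phenotype(K, None, 1.5)
    with pytest.raises(ValueError):
        sfc.simulate_phenotype(None, None, 0.4, mode="covariance")
    with pytest.raises(ValueError):
        sfc.simulate_phenotype(K, None, 0.4, mode="causal")
    with pytest.raises(ValueError):
        sfc.simulate_phenotype(K, None, 0.4, mode="wat")


# ---------------------------------------------------------------------------
# mesh


def test_mesh_study_scale_labels():
    mesh = sfc.generate_mesh(2100, 7, 180, seed=0)
    assert mesh.n_vertices == 4200
    for hemi in ("L", "R"):
        sub = mesh.table[mesh.table["hemisphere"] == hemi]
        assert set(sub["network"]) == set(range(1, 8))
        assert sub["region"].nunique() == 180


def test_mesh_single_network_region():
    mesh = sfc.generate_mesh(10, 1, 1, seed=0)
    assert mesh.table["network"].nunique() == 1
    assert mesh.table["region"].nunique() == 2  # one region per hemisphere


def test_masked_vertices_excluded_from_coupling():
    mesh = sfc.generate_mesh(60, 3, 6, seed=1)
    n_masked = int(mesh.table["mask"].sum())
    assert n_masked > 0
    ped = sfc.generate_pedigree(0, 0, 0, 6, seed=1)
    K = sfc.pedigree_grm(ped)
    profiles, targets = sfc.simulate_connectivity(mesh, ped, K, seed=1)
    cpl = sfc.compute_coupling(profiles, mesh)
    assert cpl.values.shape[1] == mesh.n_vertices - n_masked
    assert cpl.vertex_ids == mesh.unmasked_ids


# ---------------------------------------------------------------------------
# connectivity round trip


def test_connectivity_round_trip_exact():
    mesh = sfc.generate_mesh(40, 2, 4, seed=2)
    ped = sfc.generate_pedigree(2, 2, 0, 2, seed=2)
    K = sfc.pedigree_grm(ped)
    profiles, targets = sfc.simulate_connectivity(mesh, ped, K,
                                                  h2_coupling=0.4, seed=2)
    cpl = sfc.compute_coupling(profiles, mesh, method="inner",
                               log_transform_sc=True)
    assert np.max(np.abs(cpl.values - targets.values)) <= 1e-10


def test_connectivity_target_one_aligns_fc_with_sc():
    """Targets at the upper clip: the FC local profile is (numerically)
    parallel to the log-transformed SC profile (theta -> 0)."""
    mesh = flat_mesh(6)
    ped = sfc.generate_pedigree(0, 0, 0, 2, seed=3)
    K = sfc.pedigree_grm(ped)
    with pytest.warns(UserWarning):
        profiles, targets = sfc.simulate_connectivity(
            mesh, ped, K, h2_coupling=0.0, seed=3,
            coupling_mean=1.0, coupling_sd=0.0)
    patches = network_patches(mesh)
    for sid in profiles.subject_ids:
        sc, fc = profiles.sc[sid], profiles.fc[sid]
        for j, v in enumerate(mesh.unmasked):
            e = patches[j]
            u = np.log1p(sc[v, e])
            cosine = (fc[v, e] @ u) / (np.linalg.norm(fc[v, e])
                                       * np.linalg.norm(u))
            assert cosine > 0.999998


def test_connectivity_h2_recovered_downstream(cohort500):
    """Coupling targets generated at h2 = 0.4 recover a heritability near
    the target through the full coupling + REML chain."""
    mesh = flat_mesh(8)
    K = cohort500["K"]
    profiles, targets = sfc.simulate_connectivity(mesh, cohort500["pedigree"],
                                                  K, h2_coupling=0.4, seed=4)
    cpl = sfc.compute_coupling(profiles, mesh)
    h2s = [sfc.reml_univariate(cpl.values[:, j], None, K,
                               K_eig=cohort500["K_eig"]).h2
           for j in range(cpl.values.shape[1])]
    assert abs(np.mean(h2s) - 0.4) < 0.12


def test_substreams_are_independent():
    a = substream(11, "phenotype").standard_normal(5)
    b = substream(11, "genotypes").standard_normal(5)
    assert not np.allclose(a, b)
    assert np.allclose(a, substream(11, "phenotype").standard_normal(5))
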