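"""LD computation, clumping into loci, and cytoband assignment."""

import numpy as np
import pandas as pd
import pytest

import sfcoupling as sfc
from sfcoupling.datatypes import GenotypeMatrix
from sfcoupling.loci import synthetic_cytobands

from test_relatedness import make_genotypes


# ---------------------------------------------------------------------------
# r^2


def test_ld_r2_self_is_one():
    g = make_genotypes([[0], [1], [2], [1], [0], [2]])
    assert sfc.ld_r2(g, "s0", "s0") == pytest.approx(1.0, abs=1e-12)


def test_ld_r2_orthogonal_deviations_zero():
    a = [0, 0, 2, 2]
    b = [0, 2, 0, 2]  # deviations orthogonal to a's
    g = make_genotypes(np.column_stack([a, b]))
    assert sfc.ld_r2(g, "s0", "s1") == pytest.approx(0.0, abs=1e-12)


def test_ld_r2_hand_computed_six_individuals():
    a = np.array([0, 1, 2, 2, 1, 0], dtype=float)
    b = np.array([0, 0, 2, 1, 1, 1], dtype=float)
    g = make_genotypes(np.column_stack([a, b]))
    am, bm = a - a.mean(), b - b.mean()
    r = (am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum())
    assert sfc.ld_r2(g, "s0", "s1") == pytest.approx(r * r, abs=1e-12)


def test_ld_r2_validation():
    g = make_genotypes([[0, 1], [1, 1], [2, 1], [0, 1]])
    with pytest.raises(KeyError):
        sfc.ld_r2(g, "s0", "nope")
    with pytest.raises(ValueError, match="monomorphic"):
        sfc.ld_r2(g, "s0", "s1")


# ---------------------------------------------------------------------------
# clumping: constructed cases


def _assoc(genotypes, p_values):
    meta = genotypes.snp_meta
    return pd.DataFrame({"SNP": meta["snp_id"], "CHR": meta["chrom"],
                         "POS": meta["pos"], "P": p_values})


def test_three_tightly_linked_snps_one_locus():
    rng = np.random.default_rng(30)
    base = rng.binomial(2, 0.4, 60).astype(float)
    dosage = np.column_stack([base, base, base])  # pairwise r^2 = 1 > 0.6
    meta = pd.DataFrame({"chrom": "1", "pos": [1000, 5000, 9000],
                         "snp_id": ["s0", "s1", "s2"], "ref": "A", "alt": "G"})
    g = GenotypeMatrix(dosage, meta, [f"i{i}" for i in range(60)])
    loci = sfc.define_loci(_assoc(g, [1e-9, 1e-8, 1e-7]), g, 1e-5)
    assert len(loci) == 1
    assert loci[0].independent_snps == ["s0"]
    assert loci[0].lead_snps == ["s0"]
    assert loci[0].lead_snp == "s0"


def test_two_unlinked_distant_snps_two_loci():
    a = np.array([0, 0, 2, 2, 1, 1], dtype=float)
    b = np.array([0, 2, 0, 2, 1, 1], dtype=float)  # r^2 = 0 with a
    meta = pd.DataFrame({"chrom": "1", "pos": [1000, 301_000],
                         "snp_id": ["s0", "s1"], "ref": "A", "alt": "G"})
    g = GenotypeMatrix(np.column_stack([a, b]), meta,
                       [f"i{i}" for i in range(6)])
    loci = sfc.define_loci(_assoc(g, [1e-9, 1e-9]), g, 1e-5)
    assert len(loci) == 2


def test_blocks_with_200kb_gap_merged():
    a = np.array([0, 0, 2, 2, 1, 1], dtype=float)
    b = np.array([0, 2, 0, 2, 1, 1], dtype=float)
    meta = pd.DataFrame({"chrom": "1", "pos": [1000, 201_000],
                         "snp_id": ["s0", "s1"], "ref": "A", "alt": "G"})
    g = GenotypeMatrix(np.column_stack([a, b]), meta,
                       [f"i{i}" for i in range(6)])
    loci = sfc.define_loci(_assoc(g, [1e-9, 1e-9]), g, 1e-5)
    assert len(loci) == 1
    assert len(loci[0].independent_snps) == 2
    assert loci[0].start == 1000 and loci[0].end == 201_000


def test_no_significant_snps_empty():
    g = make_genotypes([[0, 1], [1, 0], [2, 2], [1, 1], [0, 2], [2, 0]])
    assert sfc.define_loci(_assoc(g, [0.5, 0.4]), g, 1e-5) == []


# ---------------------------------------------------------------------------
# clumping: exhaustive oracle on small random instances


def brute_force_loci(assoc, genotypes, p_threshold, r2_ind=0.6, r2_lead=0.1,
                     maf_min=0.0005, merge_kb=250.0):
    """Independent step-by-step reimplementation of the locus definition."""
    meta = genotypes.snp_meta
    pos = dict(zip(meta["snp_id"], meta["pos"]))
    chrom = dict(zip(meta["snp_id"], meta["chrom"]))
    col = {sid: genotypes.dosage[:, j]
           for j, sid in enumerate(genotypes.snp_ids)}
    freq = {sid: col[sid].mean() / 2 for sid in col}

    def r2(a, b):
        x, y = col[a], col[b]
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    sig = assoc[assoc["P"] < p_threshold].sort_values(
        ["P", "POS"], kind="stable")
    isvs = []
    for sid in sig["SNP"]:
        if all(chrom[sid] != chrom[k] or r2(sid, k) < r2_ind for k in isvs):
            isvs.append(sid)
    leads = []
    for sid in isvs:
        if all(chrom[sid] != chrom[k] or r2(sid, k) < r2_lead for k in leads):
            leads.append(sid)
    blocks = []
    for sid in isvs:
        tags = [k for k in col
                if chrom[k] == chrom[sid]
                and min(freq[k], 1 - freq[k]) >= maf_min
                and (k == sid or r2(sid, k) >= r2_ind)]
        blocks.append({"chrom": chrom[sid],
                       "start": min(pos[k] for k in tags),
                       "end": max(pos[k] for k in tags),
                       "isvs": {sid}})
    changed = True
    while changed:
        changed = False
        blocks.sort(key=lambda b: (b["chrom"], b["start"], b["end"]))
        merged = []
        for b in blocks:
            if merged and merged[-1]["chrom"] == b["chrom"] and \
                    b["start"] - merged[-1]["end"] < merge_kb * 1000:
                merged[-1]["end"] = max(merged[-1]["end"], b["end"])
                merged[-1]["start"] = min(merged[-1]["start"], b["start"])
                merged[-1]["isvs"] |= b["isvs"]
                changed = True
            else:
                merged.append(b)
        blocks = merged
    return blocks, set(isvs), set(leads)


def random_ld_instance(seed, n_snps=12, n_ind=40):
    rng = np.random.default_rng(seed)
    cols = []
    j = 0
    while j < n_snps:
        base = rng.binomial(2, rng.uniform(0.2, 0.5), n_ind).astype(float)
        for _ in range(rng.integers(1, 4)):
            if j >= n_snps:
                break
            c = base.copy()
            flip = rng.random(n_ind) < rng.uniform(0.0, 0.4)
            c[flip] = rng.binomial(2, 0.4, flip.sum())
            if c.std() == 0:
                c[0] = (c[0] + 1) % 3
            cols.append(c)
            j += 1
    dosage = np.column_stack(cols)
    chroms = ["1"] * (n_snps // 2) + ["2"] * (n_snps - n_snps // 2)
    pos = np.concatenate([
        np.sort(rng.choice(np.arange(1, 600) * 1000, n_snps // 2,
                           replace=False)),
        np.sort(rng.choice(np.arange(1, 600) * 1000, n_snps - n_snps // 2,
                           replace=False))])
    meta = pd.DataFrame({"chrom": chroms, "pos": pos,
                         "snp_id": [f"s{k}" for k in range(n_snps)],
                         "ref": "A", "alt": "G"})
    g = GenotypeMatrix(dosage, meta, [f"i{i}" for i in range(n_ind)])
    p = rng.uniform(0, 1, n_snps)
    p[rng.random(n_snps) < 0.6] *= 1e-8
    return g, _assoc(g, p)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
def test_clumping_matches_exhaustive_oracle(seed):
    g, assoc = random_ld_instance(seed)
    loci = sfc.define_loci(assoc, g, 1e-5)
    blocks, isvs, leads = brute_force_loci(assoc, g, 1e-5)
    assert len(loci) == len(blocks)
    for locus, block in zip(loci, blocks):
        assert locus.chrom == block["chrom"]
        assert locus.start == block["start"]
        assert locus.end == block["end"]
        assert set(locus.independent_snps) == block["isvs"]
    assert {s for l in loci for s in l.independent_snps} == isvs
    assert {s for l in loci for s in l.lead_snps} == leads


def test_clumping_row_order_invariant():
    g, assoc = random_ld_instance(11)
    shuffled = assoc.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = sfc.define_loci(assoc, g, 1e-5)
    b = sfc.define_loci(shuffled, g, 1e-5)
    assert [(l.chrom, l.start, l.end, tuple(l.independent_snps))
            for l in a] == \
        [(l.chrom, l.start, l.end, tuple(l.independent_snps)) for l in b]


# ---------------------------------------------------------------------------
# cytobands


def toy_bands():
    return synthetic_cytobands({"1": 8000}, n_bands_per_arm=2)


def test_cytoband_interior_position():
    bands = toy_bands()
    # chromosome 1, length 8000: p arm 1-4000 (bands p2: 1-2000, p1:
    # 2001-4000), q arm q1: 4001-6000, q2: 6001-8000
    assert sfc.assign_cytoband("1", 4500, bands) == "1q1"
    assert sfc.assign_cytoband("1", 500, bands) == "1p2"


def test_cytoband_first_base():
    assert sfc.assign_cytoband("1", 1, toy_bands()) == "1p2"


def test_cytoband_boundary_belongs_to_lower_band():
    bands = toy_bands()
    assert sfc.assign_cytoband("1", 2000, bands) == "1p2"
    assert sfc.assign_cytoband("1", 2001, bands) == "1p1"


def test_cytoband_outside_raises():
    with pytest.raises(ValueError):
        sfc.assign_cytoband("1", 9999, toy_bands())


def test_loci_carry_cytobands():
    a = np.array([0, 0, 2, 2, 1, 1], dtype=float)
    meta = pd.DataFrame({"chrom": "1", "pos": [3000], "snp_id": ["s0"],
                         "ref": "A", "alt": "G"})
    g = GenotypeMatrix(a[:, None], meta, [f"i{i}" for i in range(6)])
    loci = sfc.define_loci(_assoc(g, [1e-9]), g, 1e-5, bands=toy_bands())
    assert loci[0].cytobands == ["1p1"]
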