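"""Genomic risk-locus definition by LD clumping and block merging.

From a summary-statistics table: (1) take the SNPs below the significance
threshold; (2) greedily select *independent significant variants* in
ascending p order, requiring LD r^2 < 0.6 with every previously selected
one; (3) among those, select *lead variants* by the same greedy rule at
r^2 < 0.1; (4) tag, per independent significant variant, all analyzed SNPs
on the same chromosome with r^2 >= 0.6 and MAF >= 0.0005; (5) the LD block
is the positional span of the tagged set; (6) blocks on one chromosome
whose closest boundaries are under 250 kb apart are merged, iteratively,
into single loci.  LD is the squared Pearson correlation of in-sample
dosages.  Cytogenetic bands are assigned by interval lookup in a
UCSC-dialect cytoband table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, Locus

__all__ = ["ld_r2", "CytobandTable", "assign_cytoband", "define_loci",
           "synthetic_cytobands"]


def ld_r2(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two SNPs' dosage vectors
    (pairwise-complete individuals)."""
    ids = genotypes.snp_ids
    try:
        ja, jb = ids.index(snp_a), ids.index(snp_b)
    except ValueError as exc:
        raise KeyError(f"SNP not in genotype matrix: {exc}") from exc
    a = genotypes.dosage[:, ja]
    b = genotypes.dosage[:, jb]
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete pairs")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic SNP in LD computation")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(dosage: np.ndarray) -> np.ndarray:
    """All-pairs r^2 for complete-data dosage columns."""
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(dosage, rowvar=False)
    return r * r


@dataclass
class CytobandTable:
    """Cytogenetic bands with 1-based inclusive intervals.

    ``table`` columns: ``chrom`` (no 'chr' prefix), ``start``, ``end``,
    ``name`` (e.g. 'p23.2'), ``stain``.  Bands must tile each chromosome
    without overlap.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "name", "stain"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cytoband table missing columns: {sorted(missing)}")
        for chrom, grp in self.table.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping bands on chromosome {chrom}")


def synthetic_cytobands(chrom_lengths: dict[str, int],
                        n_bands_per_arm: int = 4) -> CytobandTable:
    """Synthetic stand-in cytoband table tiling each chromosome.

    Each chromosome is split into a p and a q arm of equal length, each
    tiled by ``n_bands_per_arm`` equal bands named p/q + band number
    (p bands numbered outward from the centromere, UCSC style).
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        half = length // 2
        arm_spans = [("p", 0, half), ("q", half, length)]
        for arm, lo, hi in arm_spans:
            edges = np.linspace(lo, hi, n_bands_per_arm + 1).astype(int)
            for b in range(n_bands_per_arm):
                num = n_bands_per_arm - b if arm == "p" else b + 1
                rows.append((str(chrom), int(edges[b]) + 1, int(edges[b + 1]),
                             f"{arm}{num}", "gneg" if b % 2 else "gpos50"))
    return CytobandTable(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "stain"]))


def assign_cytoband(chromosome: str, position: int,
                    bands: CytobandTable) -> str:
    """Chromosome-prefixed name of the band containing the position
    (e.g. '8p23.2')."""
    chrom = str(chromosome).removeprefix("chr")
    sub = bands.table[bands.table["chrom"] == chrom]
    hit = sub[(sub["start"] <= position) & (position <= sub["end"])]
    if hit.empty:
        raise ValueError(
            f"position {chrom}:{position} outside all cytobands")
    return f"{chrom}{hit.iloc[0]['name']}"


def define_loci(assoc: pd.DataFrame, genotypes: GenotypeMatrix,
                p_threshold: float, r2_independent: float = 0.6,
                r2_lead: float = 0.1, maf_tag_min: float = 0.0005,
                merge_kb: float = 250.0,
                bands: CytobandTable | None = None) -> list[Locus]:
    """Clump a summary table into merged genomic loci.

    ``assoc`` needs columns SNP, CHR, POS, P; SNP ids must be present in
    ``genotypes``.  Ties in p are broken by smaller position, making the
    output invariant to input row order.  Returns an empty list when no
    SNP passes the threshold.
    """
    required = {"SNP", "CHR", "POS", "P"}
    if not required <= set(assoc.columns):
        raise ValueError(f"assoc table needs columns {sorted(required)}")
    sig = assoc[assoc["P"] < p_threshold].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(["P", "POS"], kind="stable").reset_index(drop=True)

    snp_index = {sid: j for j, sid in enumerate(genotypes.snp_ids)}
    missing = [s for s in sig["SNP"] if s not in snp_index]
    if missing:
        raise KeyError(f"significant SNP {missing[0]} not in genotypes")

    freq = genotypes.allele_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    meta = genotypes.snp_meta

    def r2_pair(a: int, b: int) -> float:
        da, db = genotypes.dosage[:, a], genotypes.dosage[:, b]
        ok = ~np.isnan(da) & ~np.isnan(db)
        da, db = da[ok], db[ok]
        if da.std() == 0 or db.std() == 0:
            return 0.0
        r = np.corrcoef(da, db)[0, 1]
        return float(r * r)

    # (2) greedy independent significant variants, ascending p
    independent: list[int] = []  # genotype column indices
    for row in sig.itertuples(index=False):
        j = snp_index[row.SNP]
        if all(meta.iloc[j]["chrom"] != meta.iloc[k]["chrom"]
               or r2_pair(j, k) < r2_independent for k in independent):
            independent.append(j)

    # (3) lead variants among the independent significant set
    leads: set[int] = set()
    for j in independent:  # already in ascending-p order
        if all(meta.iloc[j]["chrom"] != meta.iloc[k]["chrom"]
               or r2_pair(j, k) < r2_lead for k in leads):
            leads.add(j)

    # (4)-(5) tagged sets and LD-block spans per independent variant
    p_of = dict(zip(sig["SNP"], sig["P"]))
    blocks = []
    for j in independent:
        chrom = meta.iloc[j]["chrom"]
        same_chrom = np.flatnonzero(
            (meta["chrom"] == chrom).to_numpy() & (maf >= maf_tag_min))
        tags = [int(k) for k in same_chrom
                if k == j or r2_pair(j, k) >= r2_independent]
        pos = meta.iloc[tags]["pos"]
        blocks.append({
            "chrom": chrom, "start": int(pos.min()), "end": int(pos.max()),
            "independent": [j], "tags": set(tags),
        })

    # (6) iterative merge of nearby blocks on the same chromosome
    merged_any = True
    while merged_any:
        merged_any = False
        blocks.sort(key=lambda b: (b["chrom"], b["start"], b["end"]))
        out = []
        for b in blocks:
            if out and out[-1]["chrom"] == b["chrom"] and \
                    b["start"] - out[-1]["end"] < merge_kb * 1000:
                prev = out[-1]
                prev["end"] = max(prev["end"], b["end"])
                prev["start"] = min(prev["start"], b["start"])
                prev["independent"].extend(b["independent"])
                prev["tags"] |= b["tags"]
                merged_any = True
            else:
                out.append(b)
        blocks = out

    # assign each significant SNP to the locus of the first independent
    # variant (greedy order) that tags it
    locus_of_isv = {}
    for li, b in enumerate(blocks):
        for j in b["independent"]:
            locus_of_isv[j] = li
    assigned: dict[int, list[str]] = {li: [] for li in range(len(blocks))}
    for row in sig.itertuples(index=False):
        j = snp_index[row.SNP]
        for k in independent:
            if k == j or (meta.iloc[j]["chrom"] == meta.iloc[k]["chrom"]
                          and r2_pair(j, k) >= r2_independent):
                assigned[locus_of_isv[k]].append(row.SNP)
                break

    snp_ids = genotypes.snp_ids
    loci = []
    for li, b in enumerate(blocks):
        isvs = sorted(b["independent"],
                      key=lambda j: (p_of[snp_ids[j]], meta.iloc[j]["pos"]))
        lead_j = isvs[0]
        cyto: list[str] = []
        if bands is not None:
            seen = set()
            for j in isvs:
                name = assign_cytoband(b["chrom"], int(meta.iloc[j]["pos"]),
                                       bands)
                if name not in seen:
                    seen.add(name)
                    cyto.append(name)
        loci.append(Locus(
            chrom=str(b["chrom"]), start=b["start"], end=b["end"],
            lead_snp=snp_ids[lead_j], lead_p=float(p_of[snp_ids[lead_j]]),
            independent_snps=[snp_ids[j] for j in isvs],
            lead_snps=[snp_ids[j] for j in isvs if j in leads],
            tagged_snps=sorted(snp_ids[j] for j in b["tags"]),
            significant_snps=assigned[li],
            cytobands=cyto,
        ))
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci
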