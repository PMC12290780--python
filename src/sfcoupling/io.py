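"""Readers and writers for the interchange formats.

Dialects: VCF v4.2 with GT fields (read through cyvcf2, multiallelic
records rejected); dosage TSV (rows = SNPs, leading metadata columns, then
one column per individual, missing = "NA"); PLINK-style pedigree TSV;
GCTA-style whitespace phenotype/covariate tables with leading family and
individual id columns; GCTA text GRM (gzip triplet file plus an id file);
UCSC cytoBand.txt (0-based half-open, converted to 1-based inclusive on
read); mesh and coupling TSVs; per-subject SC/FC profile matrices in one
HDF5 container or as whitespace matrix files.

Every text writer prepends provenance comment lines ("# key=value");
readers skip comment lines.
"""

from __future__ import annotations

import gzip
import json
import hashlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (ConnectivityProfiles, CouplingMatrix, CovariateTable,
                        GenotypeMatrix, GRM, Pedigree, PhenotypeTable,
                        SurfaceMesh)
from .loci import CytobandTable

__all__ = [
    "write_genotypes_vcf", "read_genotypes_vcf", "write_genotypes_tsv",
    "read_genotypes_tsv", "read_genotypes", "write_pedigree", "read_pedigree",
    "write_gcta_table", "read_phenotypes", "read_covariates", "write_grm",
    "read_grm", "write_mesh", "read_mesh", "write_coupling", "read_coupling",
    "write_profiles_hdf5", "read_profiles_hdf5", "write_matrix",
    "read_matrix", "read_cytobands", "write_summary", "read_summary",
    "provenance_lines", "config_hash",
]

MISSING = "NA"


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(**meta) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _write_tsv(df: pd.DataFrame, path, index=False, **meta) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_lines(**meta))
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_vcf(genotypes: GenotypeMatrix, path, **meta) -> None:
    """Plain-text VCF v4.2 with GT fields only."""
    path = Path(path)
    chroms = pd.unique(genotypes.snp_meta["chrom"])
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sfcoupling\n")
        for k, v in meta.items():
            fh.write(f"##sfcoupling_{k}={v}\n")
        for chrom in chroms:
            last = genotypes.snp_meta.loc[
                genotypes.snp_meta["chrom"] == chrom, "pos"].max()
            fh.write(f"##contig=<ID={chrom},length={int(last) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.individual_ids) + "\n")
        for j, row in enumerate(genotypes.snp_meta.itertuples(index=False)):
            gts = "\t".join(
                code.get(d, "./.") if not np.isnan(d) else "./."
                for d in genotypes.dosage[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t"
                     f"{row.alt}\t.\t.\t.\tGT\t{gts}\n")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read a VCF with GT fields; multiallelic records are rejected."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, metas = [], []
    # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    mapping = np.array([0.0, 1.0, np.nan, 2.0])
    for i, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {variant.CHROM}:{variant.POS} "
                f"(record {i + 1})")
        rows.append(mapping[variant.gt_types])
        metas.append((variant.CHROM, variant.POS, variant.ID or f"var{i}",
                      variant.REF, variant.ALT[0]))
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    meta = pd.DataFrame(metas, columns=["chrom", "pos", "snp_id", "ref", "alt"])
    return GenotypeMatrix(np.array(rows).T, meta, ids)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path, **meta) -> None:
    """Dosage TSV: one row per SNP, metadata columns then individuals."""
    df = genotypes.snp_meta.copy()
    for i, iid in enumerate(genotypes.individual_ids):
        col = genotypes.dosage[i, :]
        df[iid] = [MISSING if np.isnan(v) else str(int(v)) for v in col]
    _write_tsv(df, path, **meta)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    meta_cols = ["chrom", "pos", "snp_id", "ref", "alt"]
    if df.columns[:5].tolist() != meta_cols:
        raise ValueError(f"dosage TSV must start with columns {meta_cols}")
    ids = df.columns[5:].tolist()
    meta = df[meta_cols].copy()
    meta["pos"] = meta["pos"].astype(int)
    allowed = {"0", "1", "2", MISSING}
    dosage = np.empty((len(ids), len(df)))
    for i, iid in enumerate(ids):
        col = df[iid]
        bad = set(col) - allowed
        if bad:
            line = int(np.flatnonzero(col.isin(bad))[0]) + 2
            raise ValueError(
                f"invalid dosage token {sorted(bad)[0]!r} in column "
                f"{iid} (line {line})")
        dosage[i] = [np.nan if v == MISSING else float(v) for v in col]
    return GenotypeMatrix(dosage, meta, ids)


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' or 'dosage_tsv'; inferred from suffix)."""
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "dosage_tsv"
    if format == "vcf":
        return read_genotypes_vcf(path)
    if format == "dosage_tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# pedigree, phenotypes, covariates


def write_pedigree(pedigree: Pedigree, path, **meta) -> None:
    df = pedigree.table[["family_id", "individual_id", "father_id",
                         "mother_id", "relationship_tag"]]
    _write_tsv(df, path, **meta)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return Pedigree(df[["individual_id", "family_id", "father_id",
                        "mother_id", "relationship_tag"]])


def write_gcta_table(df: pd.DataFrame, path, value_columns: list[str],
                     **meta) -> None:
    """GCTA-dialect whitespace table: FID IID then values, no header."""
    out = df[["family_id", "individual_id"] + value_columns]
    with open(path, "w") as fh:
        fh.write(provenance_lines(**meta))
        out.to_csv(fh, sep=" ", index=False, header=False, na_rep=MISSING)


def _read_gcta(path, names: list[str]) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                       names=["family_id", "individual_id"] + names,
                       dtype={0: str, 1: str}, na_values=[MISSING])


def read_phenotypes(path, trait_names: list[str]) -> PhenotypeTable:
    return PhenotypeTable(_read_gcta(path, trait_names))


def read_covariates(path) -> CovariateTable:
    names = ["age", "sex", "handedness", "total_brain_volume"]
    return CovariateTable(_read_gcta(path, names))


# ---------------------------------------------------------------------------
# GRM (GCTA text dialect)


def write_grm(grm: GRM, prefix, **meta) -> None:
    """GCTA text GRM: <prefix>.grm.gz triplets and <prefix>.grm.id ids."""
    prefix = str(prefix)
    # fixed mtime and no embedded filename keep the gzip byte-identical
    # across reruns with the same seed
    with open(prefix + ".grm.gz", "wb") as raw, \
            gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
        n = grm.n
        for i in range(n):
            for j in range(i + 1):
                gz.write((f"{i + 1}\t{j + 1}\t{int(grm.n_snps[i, j])}\t"
                          f"{grm.values[i, j]:.10g}\n").encode())
    with open(prefix + ".grm.id", "w") as fh:
        for fid, iid in zip(grm.family_ids, grm.individual_ids):
            fh.write(f"{fid}\t{iid}\n")


def read_grm(prefix, source: str = "snp") -> GRM:
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep="\t", header=None,
                      names=["family_id", "individual_id"], dtype=str)
    n = len(ids)
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    with gzip.open(prefix + ".grm.gz", "rt") as fh:
        for line in fh:
            i, j, m, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            values[i, j] = values[j, i] = float(v)
            counts[i, j] = counts[j, i] = int(m)
    return GRM(values, list(ids["individual_id"]), source=source,
               n_snps=counts, family_ids=list(ids["family_id"]))


# ---------------------------------------------------------------------------
# mesh, coupling, profiles


def write_mesh(mesh: SurfaceMesh, path, **meta) -> None:
    _write_tsv(mesh.table, path, **meta)


def read_mesh(path) -> SurfaceMesh:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"vertex_id": str, "hemisphere": str})
    df["mask"] = df["mask"].astype(bool)
    return SurfaceMesh(df)


def write_coupling(coupling: CouplingMatrix, path, **meta) -> None:
    df = coupling.to_frame()
    df.index.name = "subject_id"
    _write_tsv(df.reset_index(), path, method=coupling.method, **meta)


def read_coupling(path, method: str = "inner") -> CouplingMatrix:
    method_read = method
    with open(path) as fh:
        for line in fh:
            if line.startswith("# method="):
                method_read = line.strip().split("=", 1)[1]
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"subject_id": str})
    subjects = df["subject_id"].tolist()
    vertices = [c for c in df.columns if c != "subject_id"]
    return CouplingMatrix(df[vertices].to_numpy(dtype=float), subjects,
                          vertices, method=method_read)


def write_profiles_hdf5(profiles: ConnectivityProfiles, path, **meta) -> None:
    """One HDF5 container: /<subject>/sc and /<subject>/fc datasets."""
    with h5py.File(path, "w") as fh:
        for k, v in meta.items():
            fh.attrs[k] = str(v)
        fh.attrs["symmetric"] = bool(profiles.symmetric)
        for sid in profiles.subject_ids:
            grp = fh.create_group(str(sid))
            grp.create_dataset("sc", data=profiles.sc[sid],
                               compression="gzip")
            grp.create_dataset("fc", data=profiles.fc[sid],
                               compression="gzip")


def read_profiles_hdf5(path) -> ConnectivityProfiles:
    sc, fc = {}, {}
    with h5py.File(path, "r") as fh:
        symmetric = bool(fh.attrs.get("symmetric", False))
        for sid in fh:
            sc[sid] = fh[sid]["sc"][()]
            fc[sid] = fh[sid]["fc"][()]
    return ConnectivityProfiles(sc, fc, symmetric=symmetric)


def write_matrix(matrix: np.ndarray, path, **meta) -> None:
    """Whitespace matrix file (one profile matrix per file)."""
    with open(path, "w") as fh:
        fh.write(provenance_lines(**meta))
        np.savetxt(fh, np.asarray(matrix, dtype=float), fmt="%.10g")


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, comments="#")


# ---------------------------------------------------------------------------
# cytobands and summary statistics


def read_cytobands(path) -> CytobandTable:
    """UCSC cytoBand.txt dialect: chrN <start0> <end0> <name> <stain>,
    converted to 1-based inclusive coordinates."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "name", "stain"],
                     dtype={"chrom": str})
    df["chrom"] = df["chrom"].str.removeprefix("chr")
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return CytobandTable(df)


def write_summary(assoc: pd.DataFrame, path, **meta) -> None:
    """fastGWA-like summary TSV: CHR SNP POS A1 A2 AF1 BETA SE P."""
    _write_tsv(assoc, path, **meta)


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"CHR": str, "SNP": str})
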