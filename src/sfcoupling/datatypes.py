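"""Core in-memory containers shared across the pipeline stages.

Conventions: genotype dosages count the alternate allele and use NaN for
missing; genomic positions are 1-based inclusive; surface meshes carry one
row per vertex with hemisphere / functional-network / atlas-region labels
and a boolean mask flag (masked vertices, e.g. the corpus-callosum patch,
never enter coupling output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# relationship tags used in pedigree tables
MZ = "MZ"
DZ = "DZ"
FULL_SIB = "FULL_SIB"
SINGLETON = "SINGLETON"
FOUNDER = "FOUNDER"

RELATIONSHIP_TAGS = (MZ, DZ, FULL_SIB, SINGLETON, FOUNDER)


@dataclass
class Pedigree:
    """Family structure table.

    ``table`` has one row per individual with columns
    ``individual_id, family_id, father_id, mother_id, relationship_tag``.
    Parents precede children; founders (and singletons) have empty parent
    ids ("0").  Analysis individuals are all rows whose tag is not FOUNDER.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"individual_id", "family_id", "father_id", "mother_id",
                    "relationship_tag"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        bad = set(self.table["relationship_tag"]) - set(RELATIONSHIP_TAGS)
        if bad:
            raise ValueError(f"unknown relationship tags: {sorted(bad)}")
        seen: set[str] = set()
        for row in self.table.itertuples(index=False):
            for parent in (row.father_id, row.mother_id):
                if parent not in ("0", "", None) and parent not in seen:
                    raise ValueError(
                        f"parent {parent} of {row.individual_id} does not "
                        "precede the child in the pedigree")
            seen.add(row.individual_id)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.table["individual_id"])

    @property
    def analysis_ids(self) -> list[str]:
        """Ids of the study individuals (everything except founder parents)."""
        sel = self.table["relationship_tag"] != FOUNDER
        return list(self.table.loc[sel, "individual_id"])

    def families(self) -> dict[str, list[str]]:
        """family_id -> analysis individual ids, insertion-ordered."""
        sel = self.table["relationship_tag"] != FOUNDER
        out: dict[str, list[str]] = {}
        for row in self.table[sel].itertuples(index=False):
            out.setdefault(row.family_id, []).append(row.individual_id)
        return out

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternate-allele dosages with SNP metadata.

    ``dosage`` is a float array in {0, 1, 2, NaN}; ``snp_meta`` has columns
    ``chrom, pos, snp_id, ref, alt`` with positions strictly increasing
    within each chromosome.
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: list[str]
    family_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x SNPs)")
        n, m = self.dosage.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta length does not match dosage columns")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")
        for chrom, grp in self.snp_meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}")
        if self.family_ids is None:
            self.family_ids = list(self.individual_ids)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta["snp_id"])

    def allele_frequency(self) -> np.ndarray:
        """Sample alternate-allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def subset(self, individuals: np.ndarray | list | None = None,
               snps: np.ndarray | list | None = None) -> "GenotypeMatrix":
        """Positional subset along either axis, preserving metadata."""
        dosage = self.dosage
        ids = list(self.individual_ids)
        fids = list(self.family_ids)
        meta = self.snp_meta
        if individuals is not None:
            idx = np.asarray(individuals)
            dosage = dosage[idx]
            ids = [ids[i] for i in idx]
            fids = [fids[i] for i in idx]
        if snps is not None:
            jdx = np.asarray(snps)
            dosage = dosage[:, jdx]
            meta = meta.iloc[jdx].reset_index(drop=True)
        return GenotypeMatrix(dosage.copy(), meta.copy(), ids, fids)


@dataclass
class SurfaceMesh:
    """Labelled cortical vertex table.

    ``table`` columns: ``vertex_id, x, y, z, hemisphere (L/R),
    network (1..n_networks), region, mask`` (mask=True means excluded).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"vertex_id", "x", "y", "z", "hemisphere", "network",
                    "region", "mask"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"mesh table missing columns: {sorted(missing)}")
        if not set(self.table["hemisphere"]) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")

    @property
    def n_vertices(self) -> int:
        return len(self.table)

    @property
    def coordinates(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def unmasked(self) -> np.ndarray:
        """Positional indices of vertices that enter the coupling output."""
        return np.flatnonzero(~self.table["mask"].to_numpy())

    @property
    def unmasked_ids(self) -> list:
        return list(self.table.loc[~self.table["mask"], "vertex_id"])


@dataclass
class ConnectivityProfiles:
    """Per-subject vertex x vertex SC and FC matrices.

    SC is non-negative; FC entries lie in [-1, 1] with unit diagonal.  FC
    produced by the cohort simulator is row-profile valued (row i holds
    vertex i's local functional profile) and therefore not symmetric;
    set ``symmetric=True`` for observed data, which is validated on read.
    """

    sc: dict
    fc: dict
    symmetric: bool = False

    def __post_init__(self) -> None:
        if set(self.sc) != set(self.fc):
            raise ValueError("SC and FC subject sets differ")
        for sid, mat in self.sc.items():
            mat = np.asarray(mat, dtype=float)
            if (mat < 0).any():
                raise ValueError(f"SC for subject {sid} has negative entries")
            self.sc[sid] = mat
        for sid, mat in self.fc.items():
            mat = np.asarray(mat, dtype=float)
            if np.nanmax(np.abs(mat)) > 1 + 1e-8:
                raise ValueError(f"FC for subject {sid} outside [-1, 1]")
            if self.symmetric and not np.allclose(mat, mat.T, atol=1e-8):
                raise ValueError(f"FC for subject {sid} is not symmetric")
            self.fc[sid] = mat

    @property
    def subject_ids(self) -> list:
        return list(self.sc)


@dataclass
class CouplingMatrix:
    """Subjects x unmasked-vertices coupling values.

    ``values`` rows follow ``subject_ids``; columns follow ``vertex_ids``
    (the mesh's unmasked vertices).  ``method`` is one of
    {"inner", "pearson", "spearman"}.
    """

    values: np.ndarray
    subject_ids: list
    vertex_ids: list
    method: str = "inner"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.vertex_ids)):
            raise ValueError("coupling matrix shape does not match id lists")
        if self.method not in ("inner", "pearson", "spearman"):
            raise ValueError(f"unknown coupling method {self.method!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.vertex_ids)


@dataclass
class GRM:
    """Genetic relationship matrix with per-pair SNP counts.

    ``source`` is "snp" (Yang estimator) or "pedigree" ({0, 1/2, 1} coding).
    ``n_snps`` is an n x n array of pairwise-complete SNP counts (all equal
    for pedigree GRMs, conventionally the pedigree size 0 count -> 0).
    """

    values: np.ndarray
    individual_ids: list[str]
    source: str
    n_snps: np.ndarray | None = None
    family_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match individual ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        if self.source not in ("snp", "pedigree"):
            raise ValueError(f"unknown GRM source {self.source!r}")
        if self.n_snps is None:
            self.n_snps = np.zeros((n, n), dtype=int)
        if self.family_ids is None:
            self.family_ids = list(self.individual_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def align(self, ids: list[str]) -> "GRM":
        """Reorder/subset to the given individual ids."""
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        try:
            idx = np.array([index[i] for i in ids])
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]} not in GRM") from exc
        return GRM(self.values[np.ix_(idx, idx)], list(ids), self.source,
                   self.n_snps[np.ix_(idx, idx)],
                   [self.family_ids[i] for i in idx])


@dataclass
class CovariateTable:
    """Per-individual fixed-effect covariates.

    Base columns: age, sex (0/1), handedness, total_brain_volume.  Derived
    columns age2, age_sex, age2_sex are exact functions of the base columns
    and are (re)computed on construction.
    """

    table: pd.DataFrame

    BASE = ("age", "sex", "handedness", "total_brain_volume")

    def __post_init__(self) -> None:
        missing = set(self.BASE) - set(self.table.columns)
        if missing:
            raise ValueError(f"covariate table missing columns: {sorted(missing)}")
        t = self.table
        t["age2"] = t["age"] ** 2
        t["age_sex"] = t["age"] * t["sex"]
        t["age2_sex"] = t["age"] ** 2 * t["sex"]

    @property
    def individual_ids(self) -> list[str]:
        return list(self.table["individual_id"])

    def design_matrix(self, pcs: np.ndarray | None = None,
                      intercept: bool = True) -> np.ndarray:
        """Fixed-effect design: intercept + covariates (+ genetic PCs)."""
        cols = ["age", "age2", "sex", "age_sex", "age2_sex", "handedness",
                "total_brain_volume"]
        X = self.table[cols].to_numpy(dtype=float)
        parts = [X]
        if pcs is not None:
            parts.append(np.asarray(pcs, dtype=float))
        if intercept:
            parts.insert(0, np.ones((len(self.table), 1)))
        return np.hstack(parts)


@dataclass
class PhenotypeTable:
    """Per-individual real-valued traits, optionally with a scan index."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "individual_id" not in self.table.columns:
            raise ValueError("phenotype table needs an individual_id column")
        traits = self.trait_names
        if len(set(traits)) != len(traits):
            raise ValueError("trait names must be unique")
        if self.table[traits].isna().any().any():
            raise ValueError("phenotype table contains missing values")

    @property
    def trait_names(self) -> list[str]:
        skip = {"individual_id", "family_id", "scan"}
        return [c for c in self.table.columns if c not in skip]

    def trait(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)


@dataclass
class QCReport:
    """Counts removed by each genotype-QC filter, in application order."""

    n_individuals_in: int
    n_snps_in: int
    removed_individuals_missing: int = 0
    removed_snps_maf: int = 0
    removed_snps_missing: int = 0
    removed_snps_hwe: int = 0

    @property
    def n_individuals_out(self) -> int:
        return self.n_individuals_in - self.removed_individuals_missing

    @property
    def n_snps_out(self) -> int:
        return (self.n_snps_in - self.removed_snps_maf
                - self.removed_snps_missing - self.removed_snps_hwe)


@dataclass
class VarianceComponents:
    """Univariate REML fit: variances, heritability, SE, test, diagnostics."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    p_value: float
    n_iterations: int
    converged: bool
    sigma_c2: float | None = None  # common-environment component (repeated model)


@dataclass
class BivariateResult:
    """Bivariate REML fit: per-trait variances, genetic covariance and rg."""

    sigma_g2_1: float
    sigma_g2_2: float
    sigma_g12: float
    sigma_e2_1: float
    sigma_e2_2: float
    sigma_e12: float
    rg: float
    se_rg: float
    p_value: float
    loglik: float
    converged: bool

    @property
    def rg_defined(self) -> bool:
        return np.isfinite(self.rg)


@dataclass
class Locus:
    """A merged LD-defined genomic risk locus."""

    chrom: str
    start: int
    end: int
    lead_snp: str
    lead_p: float
    independent_snps: list[str] = field(default_factory=list)
    lead_snps: list[str] = field(default_factory=list)
    tagged_snps: list[str] = field(default_factory=list)
    significant_snps: list[str] = field(default_factory=list)
    cytobands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start exceeds end")
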