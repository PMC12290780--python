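"""Synthetic twin/sibling cohorts with a controllable genetic signal.

Generates every input the downstream stages need, offline: a pedigree of
MZ/DZ twin pairs, full-sibling pairs and singletons; biallelic genotypes by
gene dropping from founder haplotypes with block-structured LD; covariates;
phenotypes under the variance-component model cov(y) = K h2 + I (1 - h2);
a labelled spherical cortical mesh; and per-subject SC/FC profile matrices
whose inner-product coupling equals a prescribed, genetically structured
target exactly.

All randomness flows from one integer seed through named substreams so each
stage is independently reproducible.
"""

from __future__ import annotations

import warnings
import zlib

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .datatypes import (DZ, FOUNDER, FULL_SIB, MZ, SINGLETON, CouplingMatrix,
                        ConnectivityProfiles, CovariateTable, GenotypeMatrix,
                        GRM, Pedigree, PhenotypeTable, SurfaceMesh)

__all__ = [
    "substream", "generate_pedigree", "simulate_genotypes",
    "simulate_covariates", "simulate_phenotype", "generate_mesh",
    "simulate_connectivity",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, collision-resistant child stream of a master seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# pedigree


def generate_pedigree(n_mz_pairs: int, n_dz_pairs: int, n_fullsib_pairs: int,
                      n_singletons: int, seed: int = 0) -> Pedigree:
    """Build a twin/sibling/singleton pedigree.

    Each twin or sibling pair gets two synthetic founder parents; singletons
    are founders of their own single-person families.  Analysis individuals
    (tag != FOUNDER) number ``2*(n_mz_pairs + n_dz_pairs + n_fullsib_pairs)
    + n_singletons``.
    """
    counts = (n_mz_pairs, n_dz_pairs, n_fullsib_pairs, n_singletons)
    if any(c < 0 for c in counts):
        raise ValueError("pair/singleton counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("empty cohort")

    rows = []
    fam = 0

    def add_pair_family(tag: str) -> None:
        nonlocal fam
        fam += 1
        fid = f"fam{fam:04d}"
        father, mother = f"{fid}-f", f"{fid}-m"
        rows.append((father, fid, "0", "0", FOUNDER))
        rows.append((mother, fid, "0", "0", FOUNDER))
        for k in (1, 2):
            rows.append((f"{fid}-c{k}", fid, father, mother, tag))

    for _ in range(n_mz_pairs):
        add_pair_family(MZ)
    for _ in range(n_dz_pairs):
        add_pair_family(DZ)
    for _ in range(n_fullsib_pairs):
        add_pair_family(FULL_SIB)
    for _ in range(n_singletons):
        fam += 1
        fid = f"fam{fam:04d}"
        rows.append((f"{fid}-s1", fid, "0", "0", SINGLETON))

    table = pd.DataFrame(rows, columns=["individual_id", "family_id",
                                        "father_id", "mother_id",
                                        "relationship_tag"])
    return Pedigree(table)


def hcp_style_pedigree(seed: int = 0) -> Pedigree:
    """The default study cohort: 140 MZ pairs, 85 DZ pairs, 140 full-sibling
    pairs (280 siblings) and 204 singletons — 934 analysis individuals.

    Real twin cohorts with this composition report fewer subjects because
    twin pairs and additional full siblings share families; this generator
    keeps every family disjoint, so the counts simply add up."""
    return generate_pedigree(140, 85, 140, 204, seed=seed)


# ---------------------------------------------------------------------------
# genotypes by gene dropping


def _founder_haplotypes(rng: np.random.Generator, n_hap: int, maf: np.ndarray,
                        block_size: int, rho: float) -> np.ndarray:
    """Haplotypes with within-block LD via a Gaussian AR(rho) copula."""
    m = maf.size
    z = np.empty((n_hap, m))
    start = 0
    while start < m:
        stop = min(start + block_size, m)
        width = stop - start
        eps = rng.standard_normal((n_hap, width))
        z[:, start] = eps[:, 0]
        for j in range(1, width):
            z[:, start + j] = (rho * z[:, start + j - 1]
                               + np.sqrt(1.0 - rho ** 2) * eps[:, j])
        start = stop
    # threshold the latent Gaussian at the per-SNP quantile of the MAF
    return (z < ndtri(maf)[None, :]).astype(np.int8)


def simulate_genotypes(pedigree: Pedigree, n_snps: int,
                       maf_range: tuple[float, float] = (0.01, 0.5),
                       ld_block_size: int = 50, seed: int = 0, *,
                       within_block_rho: float = 0.8,
                       n_chromosomes: int = 2, bp_spacing: int = 10_000,
                       include_founders: bool = False) -> GenotypeMatrix:
    """Gene-drop genotypes through the pedigree.

    Founder haplotypes are drawn per SNP at a MAF uniform in ``maf_range``
    with within-block haplotype correlation; children inherit one haplotype
    per parent chosen independently per LD block (free recombination between
    blocks, none within); the second MZ twin copies the first.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if ld_block_size > n_snps:
        raise ValueError("ld_block_size exceeds n_snps")
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")

    rng = substream(seed, "genotypes")
    maf = rng.uniform(lo, hi, size=n_snps)

    table = pedigree.table
    founders = [r.individual_id for r in table.itertuples(index=False)
                if r.father_id in ("0", "")]
    hap_f = _founder_haplotypes(rng, 2 * len(founders), maf, ld_block_size,
                                within_block_rho)
    haplo: dict[str, np.ndarray] = {}
    for i, iid in enumerate(founders):
        haplo[iid] = hap_f[2 * i:2 * i + 2]

    n_blocks = int(np.ceil(n_snps / ld_block_size))
    block_of = np.minimum(np.arange(n_snps) // ld_block_size, n_blocks - 1)

    def transmit(parent: str) -> np.ndarray:
        choice = rng.integers(0, 2, size=n_blocks)
        return haplo[parent][choice[block_of], np.arange(n_snps)]

    mz_first: dict[str, str] = {}  # family -> first MZ child id
    for row in table.itertuples(index=False):
        if row.individual_id in haplo:
            continue
        if row.relationship_tag == MZ and row.family_id in mz_first:
            haplo[row.individual_id] = haplo[mz_first[row.family_id]].copy()
            continue
        if row.relationship_tag == MZ:
            mz_first[row.family_id] = row.individual_id
        haplo[row.individual_id] = np.stack(
            [transmit(row.father_id), transmit(row.mother_id)])

    if include_founders:
        ids = list(table["individual_id"])
        fids = list(table["family_id"])
    else:
        sel = table["relationship_tag"] != FOUNDER
        ids = list(table.loc[sel, "individual_id"])
        fids = list(table.loc[sel, "family_id"])

    dosage = np.array([haplo[i].sum(axis=0) for i in ids], dtype=float)

    per_chrom = int(np.ceil(n_snps / n_chromosomes))
    chrom = [str(1 + j // per_chrom) for j in range(n_snps)]
    pos = [int((j % per_chrom + 1) * bp_spacing) for j in range(n_snps)]
    meta = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "snp_id": [f"snp{j:06d}" for j in range(n_snps)],
        "ref": ["A"] * n_snps,
        "alt": ["G"] * n_snps,
    })
    return GenotypeMatrix(dosage, meta, ids, fids)


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(individual_ids: list[str], seed: int = 0,
                        family_ids: list[str] | None = None) -> CovariateTable:
    """Age/sex/handedness/brain-volume covariates for a young-adult cohort.

    Ages ~ N(29, 3.5) years, sex balanced, handedness a right-skewed score
    in [-100, 100], total brain volume ~ N(1200, 110) (cm^3 scale).
    """
    rng = substream(seed, "covariates")
    n = len(individual_ids)
    table = pd.DataFrame({
        "individual_id": individual_ids,
        "family_id": family_ids if family_ids is not None else individual_ids,
        "age": np.round(rng.normal(29.0, 3.5, n), 1),
        "sex": rng.integers(0, 2, n).astype(float),
        "handedness": np.clip(rng.normal(65.0, 45.0, n), -100, 100),
        "total_brain_volume": rng.normal(1200.0, 110.0, n),
    })
    return CovariateTable(table)


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotype(K: GRM | None, covariates: CovariateTable | None,
                       h2_true: float, mode: str = "covariance",
                       n_causal: int = 500, beta_mean: float = -0.5,
                       beta_var: float = 0.5,
                       genotypes: GenotypeMatrix | None = None,
                       seed: int = 0, trait_name: str = "trait",
                       covariate_beta: np.ndarray | None = None
                       ) -> PhenotypeTable:
    """Draw one trait under the additive variance-component model.

    covariance mode: y ~ MVN(mu, K h2 + I (1 - h2)) with mu = X beta over
    ``n_causal`` randomly chosen SNPs (mu = 0 if no genotypes given), beta
    ~ N(beta_mean, beta_var).

    causal mode: y = sum_j z_j gamma_j + e over standardized causal
    dosages z_j, with the genetic and residual parts rescaled to realized
    standard deviations sqrt(h2) and sqrt(1 - h2), so the genetic variance
    fraction matches h2 exactly in the generated sample.  Effects gamma
    are drawn centred, gamma ~ N(0, beta_var): under the
    variance-component definition of heritability a nonzero mean effect
    contributes a fixed directional term that belongs to the mean
    structure, not to the genetic variance, and counting it as genetic
    variance biases variance-component estimates upward.  ``beta_mean``
    therefore only affects covariance mode.
    """
    if not 0.0 <= h2_true <= 1.0:
        raise ValueError("h2_true must lie in [0, 1]")
    rng = substream(seed, "phenotype")

    if mode == "covariance":
        if K is None:
            raise ValueError("covariance mode requires a GRM")
        if not np.allclose(K.values, K.values.T, atol=1e-8):
            raise ValueError("K must be symmetric")
        n = K.n
        ids = list(K.individual_ids)
        fids = list(K.family_ids)
        mu = np.zeros(n)
        if genotypes is not None and n_causal > 0:
            causal = rng.choice(genotypes.n_snps, size=min(n_causal,
                                genotypes.n_snps), replace=False)
            beta = rng.normal(beta_mean, np.sqrt(beta_var), size=causal.size)
            G = np.nan_to_num(genotypes.dosage[:, causal])
            mu = G @ beta
        sigma = K.values * h2_true + np.eye(n) * (1.0 - h2_true)
        L = np.linalg.cholesky(sigma + 1e-10 * np.eye(n))
        y = mu + L @ rng.standard_normal(n)
    elif mode == "causal":
        if genotypes is None:
            raise ValueError("causal mode requires genotypes")
        n = genotypes.n_individuals
        ids = list(genotypes.individual_ids)
        fids = list(genotypes.family_ids)
        causal = rng.choice(genotypes.n_snps, size=min(n_causal,
                            genotypes.n_snps), replace=False)
        gamma = rng.normal(0.0, np.sqrt(beta_var), size=causal.size)
        G = np.nan_to_num(genotypes.dosage[:, causal])
        p = np.clip(G.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
        Z = (G - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        g = Z @ gamma
        e = rng.standard_normal(n)
        y = np.zeros(n)
        if h2_true > 0:
            y += np.sqrt(h2_true) * (g - g.mean()) / g.std()
        if h2_true < 1:
            y += np.sqrt(1.0 - h2_true) * (e - e.mean()) / e.std()
    else:
        raise ValueError(f"unknown phenotype mode {mode!r}")

    if covariate_beta is not None:
        if covariates is None:
            raise ValueError("covariate_beta given without covariates")
        X = covariates.design_matrix(intercept=False)
        y = y + X @ np.asarray(covariate_beta, dtype=float)

    return PhenotypeTable(pd.DataFrame({
        "individual_id": ids, "family_id": fids, trait_name: y}))


# ---------------------------------------------------------------------------
# cortical mesh


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def generate_mesh(n_vertices_per_hemisphere: int, n_networks: int = 7,
                  n_regions: int = 180, seed: int = 0, *,
                  mask_fraction: float = 0.05) -> SurfaceMesh:
    """Two labelled unit hemispheres with contiguous parcels.

    Vertices sit on unit spheres centred at x = -2 (left) and x = +2
    (right).  Regions are contiguous longitude slices; each region belongs
    to exactly one of ``n_networks`` functional networks.  A small patch of
    vertices nearest the midline pole is masked per hemisphere (the
    corpus-callosum stand-in).
    """
    if not 1 <= n_networks <= n_regions:
        raise ValueError("need n_regions >= n_networks >= 1")
    rng = substream(seed, "mesh")
    frames = []
    for hemi, centre in (("L", -2.0), ("R", 2.0)):
        pts = _fibonacci_sphere(n_vertices_per_hemisphere)
        # random rotation so the two hemispheres are not mirror-identical
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        pts = pts @ q.T
        azimuth = np.arctan2(pts[:, 1], pts[:, 0])
        order = np.argsort(azimuth, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(n_vertices_per_hemisphere)
        region = rank * n_regions // n_vertices_per_hemisphere
        network = region * n_networks // n_regions + 1
        offset = 0 if hemi == "L" else n_regions
        # mask the vertices nearest the medial pole (towards the midline)
        toward_mid = pts[:, 0] if hemi == "L" else -pts[:, 0]
        n_mask = max(1, int(round(mask_fraction * n_vertices_per_hemisphere)))
        mask = np.zeros(n_vertices_per_hemisphere, dtype=bool)
        mask[np.argsort(toward_mid)[-n_mask:]] = True
        frames.append(pd.DataFrame({
            "vertex_id": [f"{hemi}{i:05d}" for i in range(n_vertices_per_hemisphere)],
            "x": pts[:, 0] + centre, "y": pts[:, 1], "z": pts[:, 2],
            "hemisphere": hemi,
            "network": network,
            "region": region + offset + 1,
            "mask": mask,
        }))
    return SurfaceMesh(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# connectivity profiles with an exact coupling target


def simulate_connectivity(mesh: SurfaceMesh, pedigree: Pedigree | None,
                          K: GRM, h2_coupling: float | np.ndarray = 0.4,
                          seed: int = 0, *, coupling_mean: float = 0.5,
                          coupling_sd: float = 0.1, log_sc: bool = True
                          ) -> tuple[ConnectivityProfiles, CouplingMatrix]:
    """Per-subject SC/FC profiles whose coupling equals a genetic target.

    For every unmasked vertex a latent target c is drawn across subjects
    with covariance K h2 + I (1 - h2), shifted/scaled by
    ``coupling_mean``/``coupling_sd`` and clipped into (-1, 1).  The FC
    local profile at the vertex is built as cos(theta) * unit SC profile +
    sin(theta) * unit orthogonal noise with theta = arccos(c), so the
    normalized inner product of the emitted profiles reproduces c exactly
    (after the same log transform the coupling stage applies when
    ``log_sc`` is True).

    Returns the profiles and the target coupling matrix.  FC matrices are
    row-profile valued (row v holds vertex v's local profile) and hence not
    symmetric; see ConnectivityProfiles.
    """
    rng = substream(seed, "connectivity")
    subjects = list(K.individual_ids)
    n = len(subjects)
    unmasked = mesh.unmasked
    n_v = unmasked.size
    h2 = np.broadcast_to(np.asarray(h2_coupling, dtype=float), (n_v,))
    if ((h2 < 0) | (h2 > 1)).any():
        raise ValueError("h2_coupling must lie in [0, 1]")

    # latent genetic targets: one MVN draw per vertex across subjects
    eigval, eigvec = np.linalg.eigh(K.values)
    eigval = np.clip(eigval, 0.0, None)
    z = rng.standard_normal((n, n_v))
    targets = np.empty((n, n_v))
    for j in range(n_v):
        d = np.sqrt(eigval * h2[j] + (1.0 - h2[j]))
        targets[:, j] = eigvec @ (d * (eigvec.T @ z[:, j]))
    targets = coupling_mean + coupling_sd * targets
    n_clip = int(np.sum(np.abs(targets) >= 1.0))
    if n_clip:
        warnings.warn(f"{n_clip} coupling targets clipped into (-1, 1)",
                      stacklevel=2)
        targets = np.clip(targets, -0.999999, 0.999999)

    table = mesh.table
    hemis = table["hemisphere"].to_numpy()
    nets = table["network"].to_numpy()
    masked = table["mask"].to_numpy()
    n_all = mesh.n_vertices
    # local region E per unmasked vertex: same hemisphere & network, unmasked,
    # excluding the vertex itself
    regions = []
    for v in unmasked:
        e = np.flatnonzero((hemis == hemis[v]) & (nets == nets[v]) & ~masked)
        e = e[e != v]
        if e.size < 2:
            raise ValueError("each network patch needs >= 3 unmasked vertices")
        regions.append(e)

    sc_d: dict = {}
    fc_d: dict = {}
    for s, sid in enumerate(subjects):
        sc = rng.lognormal(mean=0.0, sigma=1.0, size=(n_all, n_all))
        sc = (sc + sc.T) / 2.0
        np.fill_diagonal(sc, 0.0)
        fc = np.zeros((n_all, n_all))
        np.fill_diagonal(fc, 1.0)
        for j, v in enumerate(unmasked):
            e = regions[j]
            u = np.log1p(sc[v, e]) if log_sc else sc[v, e]
            u_hat = u / np.linalg.norm(u)
            r = rng.standard_normal(e.size)
            r -= (r @ u_hat) * u_hat
            nrm = np.linalg.norm(r)
            if nrm < 1e-12:  # astronomically unlikely; redraw deterministic
                r = np.roll(u_hat, 1) - (np.roll(u_hat, 1) @ u_hat) * u_hat
                nrm = np.linalg.norm(r)
            r_hat = r / nrm
            c = targets[s, j]
            fc[v, e] = c * u_hat + np.sqrt(1.0 - c * c) * r_hat
        sc_d[sid] = sc
        fc_d[sid] = fc

    profiles = ConnectivityProfiles(sc_d, fc_d, symmetric=False)
    coupling = CouplingMatrix(targets, subjects, mesh.unmasked_ids,
                              method="inner")
    return profiles, coupling
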