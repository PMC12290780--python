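"""End-to-end pipeline driver.

Chains the stages on a synthetic cohort: cohort simulation -> connectivity
-> coupling -> genotype QC / GRM / PCs -> per-vertex heritability ->
per-vertex GWAS -> locus definition -> network enrichment -> pairwise
genetic correlation and distance decay.  Every artifact is written with a
provenance header (seed, configuration hash) so outputs are byte-identical
across reruns with the same seed.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .coupling import compute_coupling
from .datatypes import GRM
from .enrichment import map_vertices, network_enrichment
from .genarch import fit_distance_decay, pairwise_rg, vertex_distances
from .gwas import bonferroni_threshold, lmm_gwas
from .loci import define_loci, synthetic_cytobands
from .relatedness import compute_grm, genetic_pcs, qc_filter
from .synth import (generate_mesh, generate_pedigree, simulate_connectivity,
                    simulate_covariates, simulate_genotypes)
from .varcomp import reml_univariate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("sfcoupling")

ALL_STAGES = ("simulate", "coupling", "qc_grm", "reml", "gwas", "loci",
              "enrich", "rg")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Demo-scale configuration for the full chain."""

    outdir: str = "sfcoupling-run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # cohort (a scaled-down twin/sibling composition)
    n_mz_pairs: int = 45
    n_dz_pairs: int = 30
    n_fullsib_pairs: int = 45
    n_singletons: int = 60
    n_snps: int = 2000
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 50
    # mesh / connectivity
    n_vertices_per_hemisphere: int = 100
    n_networks: int = 7
    n_regions: int = 20
    h2_coupling: float = 0.4
    # QC thresholds
    ind_missing_max: float = 0.10
    maf_min: float = 0.01
    snp_missing_max: float = 0.10
    hwe_p_min: float = 1e-7
    # association / loci / enrichment / rg
    n_pcs: int = 10
    gwas_alpha: float = 0.05
    gwas_max_vertices: int = 3
    clump_r2_independent: float = 0.6
    clump_r2_lead: float = 0.1
    merge_kb: float = 250.0
    fdr_q: float = 0.05
    rg_max_vertices: int = 5
    quiet: bool = False

    def validate(self) -> None:
        if not set(self.stages) <= set(ALL_STAGES):
            raise ValueError(f"unknown stages {set(self.stages) - set(ALL_STAGES)}")
        for name, lo, hi in (("maf_min", 0, 0.5), ("fdr_q", 0, 1),
                             ("gwas_alpha", 0, 1), ("h2_coupling", 0, 1),
                             ("hwe_p_min", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a dict of artifact paths."""
    config.validate()
    if not config.quiet:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
        if not log.handlers:
            log.addHandler(handler)
        log.setLevel(logging.INFO)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config": io.config_hash(config.to_dict())}
    artifacts: dict[str, Path] = {}
    state: dict = {}
    seed = config.seed

    def done(stage):
        return stage in config.stages

    def need(stage, key, why):
        if key not in state:
            raise PipelineError(why, f"missing dependency: stage {stage!r} "
                                "was not run")

    try:
        if done("simulate"):
            log.info("simulate: cohort, genotypes, mesh, connectivity")
            ped = generate_pedigree(config.n_mz_pairs, config.n_dz_pairs,
                                    config.n_fullsib_pairs,
                                    config.n_singletons, seed=seed)
            geno = simulate_genotypes(ped, config.n_snps, config.maf_range,
                                      config.ld_block_size, seed=seed)
            cov = simulate_covariates(geno.individual_ids, seed=seed,
                                      family_ids=geno.family_ids)
            mesh = generate_mesh(config.n_vertices_per_hemisphere,
                                 config.n_networks, config.n_regions,
                                 seed=seed)
            state.update(pedigree=ped, genotypes=geno, covariates=cov,
                         mesh=mesh)
            io.write_pedigree(ped, outdir / "pedigree.tsv", **meta)
            io.write_genotypes_vcf(geno, outdir / "genotypes.vcf", **meta)
            io.write_gcta_table(cov.table, outdir / "covariates.txt",
                                ["age", "sex", "handedness",
                                 "total_brain_volume"], **meta)
            io.write_mesh(mesh, outdir / "mesh.tsv", **meta)
            artifacts.update({k: outdir / v for k, v in {
                "pedigree": "pedigree.tsv", "genotypes": "genotypes.vcf",
                "covariates": "covariates.txt", "mesh": "mesh.tsv"}.items()})

        if done("qc_grm"):
            need("simulate", "genotypes", "qc_grm")
            log.info("qc_grm: genotype QC, GRM, genetic PCs")
            geno_qc, report = qc_filter(
                state["genotypes"], config.ind_missing_max, config.maf_min,
                config.snp_missing_max, config.hwe_p_min,
                pedigree=state.get("pedigree"))
            K = compute_grm(geno_qc)
            pcs = genetic_pcs(K, n_components=config.n_pcs)
            state.update(genotypes_qc=geno_qc, qc_report=report, K=K, pcs=pcs)
            io.write_grm(K, str(outdir / "cohort"), **meta)
            artifacts["grm"] = outdir / "cohort.grm.gz"

        if done("coupling"):
            need("simulate", "mesh", "coupling")
            if "K" not in state:
                raise PipelineError("coupling", "missing dependency: stage "
                                    "'qc_grm' was not run")
            log.info("coupling: simulate connectivity, compute coupling")
            profiles, targets = simulate_connectivity(
                state["mesh"], state["pedigree"], state["K"],
                h2_coupling=config.h2_coupling, seed=seed)
            cpl = compute_coupling(profiles, state["mesh"], method="inner",
                                   log_transform_sc=True)
            state.update(profiles=profiles, coupling=cpl, targets=targets)
            io.write_coupling(cpl, outdir / "coupling.tsv", **meta)
            artifacts["coupling"] = outdir / "coupling.tsv"

        if done("reml"):
            need("coupling", "coupling", "reml")
            log.info("reml: per-vertex heritability")
            cpl = state["coupling"]
            K = state["K"]
            X = state["covariates"].design_matrix(
                pcs=state["pcs"].filter(like="PC").to_numpy())
            lam_U = np.linalg.eigh(K.values)
            rows = []
            for v_i, vid in enumerate(cpl.vertex_ids):
                fit = reml_univariate(cpl.values[:, v_i], X, K, K_eig=lam_U)
                rows.append((vid, fit.sigma_g2, fit.sigma_e2, fit.h2,
                             fit.se_h2, fit.p_value, fit.converged))
            h2_table = pd.DataFrame(rows, columns=[
                "vertex_id", "sigma_g2", "sigma_e2", "h2", "se_h2", "p",
                "converged"])
            state.update(h2_table=h2_table, design=X, K_eig=lam_U)
            io._write_tsv(h2_table, outdir / "heritability.tsv", **meta)
            artifacts["heritability"] = outdir / "heritability.tsv"

        if done("gwas"):
            need("reml", "h2_table", "gwas")
            log.info("gwas: mixed-model association on top-heritable vertices")
            h2_table = state["h2_table"]
            top = h2_table.nlargest(config.gwas_max_vertices, "h2")
            cpl = state["coupling"]
            n_tests = state["genotypes_qc"].n_snps * len(cpl.vertex_ids)
            threshold = bonferroni_threshold(config.gwas_alpha, n_tests)
            summaries = {}
            for vid in top["vertex_id"]:
                y = cpl.values[:, cpl.vertex_ids.index(vid)]
                assoc = lmm_gwas(y, state["genotypes_qc"], state["design"],
                                 state["K"], K_eig=state["K_eig"])
                io.write_summary(assoc, outdir / f"gwas_{vid}.tsv",
                                 vertex=vid, **meta)
                summaries[vid] = assoc
            state.update(gwas=summaries, gwas_threshold=threshold)
            artifacts["gwas"] = outdir

        if done("loci"):
            need("gwas", "gwas", "loci")
            log.info("loci: clumping and merging")
            meta_g = state["genotypes_qc"].snp_meta
            lengths = {str(c): int(g["pos"].max()) + 10_000
                       for c, g in meta_g.groupby("chrom")}
            bands = synthetic_cytobands(lengths)
            all_loci = []
            for vid, assoc in state["gwas"].items():
                for locus in define_loci(
                        assoc, state["genotypes_qc"],
                        state["gwas_threshold"],
                        config.clump_r2_independent, config.clump_r2_lead,
                        merge_kb=config.merge_kb, bands=bands):
                    all_loci.append((vid, locus.chrom, locus.start,
                                     locus.end, locus.lead_snp, locus.lead_p,
                                     len(locus.independent_snps),
                                     len(locus.tagged_snps),
                                     ";".join(locus.cytobands)))
            locus_table = pd.DataFrame(all_loci, columns=[
                "vertex_id", "chrom", "start", "end", "lead_snp", "lead_p",
                "n_independent", "n_tagged", "cytobands"])
            state["loci"] = locus_table
            io._write_tsv(locus_table, outdir / "loci.tsv", **meta)
            artifacts["loci"] = outdir / "loci.tsv"

        if done("enrich"):
            need("gwas", "gwas", "enrich")
            log.info("enrich: network enrichment of associations")
            labels = map_vertices(state["mesh"], "functional_network")
            rows = []
            for vid, assoc in state["gwas"].items():
                sig = assoc["P"] < state["gwas_threshold"]
                rows.append(pd.DataFrame({
                    "vertex_id": vid, "snp": assoc["SNP"],
                    "significant": sig}))
            assoc_all = pd.concat(rows, ignore_index=True)
            try:
                enrich = network_enrichment(assoc_all, labels)
            except ValueError as exc:
                raise PipelineError("enrich", str(exc)) from exc
            io._write_tsv(enrich, outdir / "enrichment.tsv", **meta)
            artifacts["enrichment"] = outdir / "enrichment.tsv"

        if done("rg"):
            need("reml", "h2_table", "rg")
            log.info("rg: pairwise genetic correlation and distance decay")
            h2_table = state["h2_table"]
            top = h2_table.nlargest(config.rg_max_vertices, "h2")
            vids = list(top["vertex_id"])
            mesh = state["mesh"]
            hemi = mesh.table.set_index("vertex_id").loc[vids, "hemisphere"]
            rg_mat = pairwise_rg(state["coupling"], vids, state["design"],
                                 state["K"], fdr_q=config.fdr_q,
                                 hemispheres=list(hemi))
            dist, intra = vertex_distances(mesh, vids)
            long = rg_mat.to_long(distances=dist)
            io._write_tsv(long, outdir / "rg.tsv", **meta)
            artifacts["rg"] = outdir / "rg.tsv"
            sub = long[long["intra_hemi"] & np.isfinite(long["rg"])]
            if len(sub) >= 4 and np.ptp(sub["distance"].to_numpy()) > 0:
                fit = fit_distance_decay(sub["rg"], sub["distance"])
                decay = pd.DataFrame([{
                    "rss_linear": fit.rss_linear,
                    "rss_quadratic": fit.rss_quadratic,
                    "residual_difference": fit.residual_difference,
                    "f_stat": fit.f_stat, "p": fit.p_value, "n": fit.n}])
                io._write_tsv(decay, outdir / "distance_decay.tsv", **meta)
                artifacts["distance_decay"] = outdir / "distance_decay.tsv"
    except PipelineError:
        raise
    except Exception as exc:  # halt with the failing stage's name
        raise PipelineError(_current_stage(state), str(exc)) from exc

    return artifacts


def _current_stage(state: dict) -> str:
    order = [("loci", "enrich/rg"), ("gwas", "loci"), ("h2_table", "gwas"),
             ("coupling", "reml"), ("K", "coupling"),
             ("genotypes", "qc_grm")]
    for key, stage in order:
        if key in state:
            return stage
    return "simulate"
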