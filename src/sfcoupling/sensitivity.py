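"""Robustness experiments for heritability estimation.

Two simulation designs evaluate the REML estimator against a known truth:
subsampling (50-90% of the cohort, GRM rebuilt per subsample) and
relatedness titration (one individual per family, then adding 10-90% of
the remaining relatives).  Per replicate a phenotype is simulated at the
target heritability (causal mode by default, so the realized genetic
fraction matches the target), re-estimated by AI-REML, and summarized as

    MSD = mean over replicates of (h2_hat - h2_true)^2

together with the mean standard error of the estimate.  A third utility
correlates per-vertex heritability vectors across coupling construction
methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CovariateTable, GenotypeMatrix, Pedigree
from .relatedness import compute_grm
from .synth import simulate_phenotype, substream
from .varcomp import reml_univariate

__all__ = ["SensitivityResult", "subsample_experiment",
           "relatedness_experiment", "method_concordance"]


@dataclass
class SensitivityResult:
    """Aggregated estimator accuracy at one grid point."""

    label: float           # subsample proportion or related fraction
    msd: float             # mean squared difference (h2_hat - h2_true)^2
    mean_se: float         # mean delta-method SE of h2_hat
    mean_h2: float
    n_replicates: int

    def to_dict(self) -> dict:
        return {"label": self.label, "msd": self.msd,
                "mean_se": self.mean_se, "mean_h2": self.mean_h2,
                "n_replicates": self.n_replicates}


def _replicate_estimates(genotypes: GenotypeMatrix,
                         covariates: CovariateTable | None,
                         subset: np.ndarray, h2_true: float, n_causal: int,
                         rep_seed: int, mode: str) -> tuple[float, float]:
    g = genotypes.subset(individuals=subset)
    # subsampling can leave rare SNPs monomorphic; drop them before the GRM
    freq = g.allele_frequency()
    poly = np.flatnonzero((freq > 0.0) & (freq < 1.0))
    if poly.size < g.n_snps:
        g = g.subset(snps=poly)
    K = compute_grm(g)
    X = None
    if covariates is not None:
        X = covariates.design_matrix()[subset]
    pheno = simulate_phenotype(K, None, h2_true, mode=mode,
                               n_causal=n_causal, genotypes=g, seed=rep_seed)
    y = pheno.trait(pheno.trait_names[0])
    fit = reml_univariate(y, X, K)
    return fit.h2, fit.se_h2


def subsample_experiment(genotypes: GenotypeMatrix,
                         covariates: CovariateTable | None,
                         proportions, h2_true: float = 0.4,
                         n_causal: int = 500, n_replicates: int = 200,
                         seed: int = 0, mode: str = "causal",
                         min_n: int = 30) -> list[SensitivityResult]:
    """Estimator accuracy across subsample proportions.

    Per replicate: draw the given proportion of individuals, rebuild the
    GRM on the subsample, simulate a phenotype at ``h2_true`` and
    re-estimate h2 by REML.  Causal SNPs are re-selected per replicate.
    """
    rng = substream(seed, "subsample")
    n = genotypes.n_individuals
    results = []
    for prop in proportions:
        if not 0.0 < prop <= 1.0:
            raise ValueError("proportions must lie in (0, 1]")
        size = int(round(prop * n))
        if size < min_n:
            raise ValueError(f"subsample of {size} below REML minimum {min_n}")
        h2s, ses = [], []
        for _ in range(n_replicates):
            subset = np.sort(rng.choice(n, size=size, replace=False))
            rep_seed = int(rng.integers(0, 2 ** 31 - 1))
            h2, se = _replicate_estimates(genotypes, covariates, subset,
                                          h2_true, n_causal, rep_seed, mode)
            h2s.append(h2)
            ses.append(se)
        h2s = np.asarray(h2s)
        results.append(SensitivityResult(
            label=float(prop), msd=float(np.mean((h2s - h2_true) ** 2)),
            mean_se=float(np.mean(ses)), mean_h2=float(np.mean(h2s)),
            n_replicates=n_replicates))
    return results


def relatedness_experiment(genotypes: GenotypeMatrix, pedigree: Pedigree,
                           fractions_related, h2_true: float = 0.4,
                           n_causal: int = 500, n_replicates: int = 200,
                           seed: int = 0, mode: str = "causal"
                           ) -> list[SensitivityResult]:
    """Estimator accuracy as related individuals are titrated in.

    The base set keeps one analysis individual per family; at each
    fraction that share of the remaining relatives is added, chosen
    uniformly at random per replicate.
    """
    rng = substream(seed, "relatedness")
    ids = list(genotypes.individual_ids)
    fam_of = dict(zip(pedigree.table["individual_id"],
                      pedigree.table["family_id"]))
    base_idx, extra_idx, seen = [], [], set()
    for i, iid in enumerate(ids):
        fam = fam_of.get(iid, iid)
        if fam in seen:
            extra_idx.append(i)
        else:
            seen.add(fam)
            base_idx.append(i)
    base_idx = np.asarray(base_idx)
    extra_idx = np.asarray(extra_idx)

    results = []
    for frac in fractions_related:
        if not 0.0 <= frac <= 1.0:
            warnings.warn(f"fraction {frac} capped into [0, 1]", stacklevel=2)
            frac = min(max(frac, 0.0), 1.0)
        n_add = int(round(frac * extra_idx.size))
        h2s, ses = [], []
        for _ in range(n_replicates):
            add = rng.choice(extra_idx, size=n_add, replace=False) \
                if n_add else np.empty(0, dtype=int)
            subset = np.sort(np.concatenate([base_idx, add]).astype(int))
            rep_seed = int(rng.integers(0, 2 ** 31 - 1))
            h2, se = _replicate_estimates(genotypes, None, subset,
                                          h2_true, n_causal, rep_seed, mode)
            h2s.append(h2)
            ses.append(se)
        h2s = np.asarray(h2s)
        results.append(SensitivityResult(
            label=float(frac), msd=float(np.mean((h2s - h2_true) ** 2)),
            mean_se=float(np.mean(ses)), mean_h2=float(np.mean(h2s)),
            n_replicates=n_replicates))
    return results


def method_concordance(h2_vectors: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-vertex heritability vectors
    across coupling construction methods."""
    names = list(h2_vectors)
    if len(names) < 2:
        raise ValueError("need at least two methods")
    arrs = {k: np.asarray(v, dtype=float) for k, v in h2_vectors.items()}
    length = {a.size for a in arrs.values()}
    if len(length) != 1 or length.pop() < 3:
        raise ValueError("vectors must share a length of at least 3")
    for k, a in arrs.items():
        if a.std() == 0:
            raise ValueError(f"heritability vector {k!r} is constant")
    rows = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            r = float(np.corrcoef(arrs[a], arrs[b])[0, 1])
            rows.append((a, b, r))
    return pd.DataFrame(rows, columns=["method_a", "method_b", "pearson_r"])
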