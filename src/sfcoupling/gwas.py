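"""Mixed-linear-model genome-wide association and multiple-testing helpers.

The association scan is the standard two-step approximation used by
large-cohort mixed-model tools: (1) fit the null model
y = X b + u + e once by REML, fixing Vhat = sg2 K + se2 I; (2) for each
SNP, a generalized-least-squares effect and Wald p-value with the
covariates included, using the fixed Vhat.  After one symmetric
eigendecomposition of K the per-SNP cost is linear in n.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .datatypes import CovariateTable, GenotypeMatrix, GRM
from .varcomp import NotIdentifiableError, reml_univariate, _as_design, _check_design

__all__ = ["lmm_gwas", "bonferroni_threshold", "bh_fdr"]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up selection and adjusted p-values.

    Returns ``(selected, adjusted)`` in the input order: ``selected`` is
    the boolean step-up selection at level ``q``; ``adjusted`` are the
    monotone BH-adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    # step-up: largest k with p_(k) <= k q / m
    crit = (np.arange(1, m + 1) * q) / m
    below = np.flatnonzero(ranked <= crit)
    selected = np.zeros(m, dtype=bool)
    if below.size:
        selected[order[:below[-1] + 1]] = True
    adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    return selected, adjusted


def lmm_gwas(trait, genotypes: GenotypeMatrix, covariates, K: GRM,
             K_eig: tuple[np.ndarray, np.ndarray] | None = None
             ) -> pd.DataFrame:
    """Per-SNP mixed-model association scan.

    Returns a summary table with columns CHR, SNP, POS, A1, A2, AF1, BETA,
    SE, P (fastGWA-style).  Monomorphic SNPs are skipped; their ids and the
    reason are recorded in ``df.attrs['skipped']``.  On a cohort with an
    uninformative GRM (K proportional to I) the scan degenerates to
    ordinary least squares, as it should.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if genotypes.n_individuals != n or K.n != n:
        raise ValueError("trait, genotypes and GRM must be aligned")
    X = _as_design(covariates, n)
    _check_design(X)

    if K_eig is None:
        lam, U = np.linalg.eigh(K.values)
    else:
        lam, U = K_eig

    try:
        null = reml_univariate(y, X, K, K_eig=(lam, U))
        if not null.converged and null.n_iterations > 1:
            raise RuntimeError(
                "null-model REML did not converge; association scan aborted")
        sg2, se2 = null.sigma_g2, null.sigma_e2
    except NotIdentifiableError:
        # K = c I: the mixed model degenerates to OLS
        b0 = np.linalg.lstsq(X, y, rcond=None)[0]
        r0 = y - X @ b0
        sg2, se2 = 0.0, float(r0 @ r0) / max(n - X.shape[1], 1)

    d = sg2 * lam + se2
    s = 1.0 / np.sqrt(d)
    y_w = s * (U.T @ y)
    X_w = s[:, None] * (U.T @ X)
    Q, _ = np.linalg.qr(X_w)
    r_y = y_w - Q @ (Q.T @ y_w)

    freq = genotypes.allele_frequency()
    dosage = genotypes.dosage
    # mean-impute missing calls for the regression only
    G = np.where(np.isnan(dosage), 2.0 * freq[None, :], dosage)
    poly = (freq > 0.0) & (freq < 1.0)

    G_w = s[:, None] * (U.T @ G[:, poly])
    R_g = G_w - Q @ (Q.T @ G_w)
    gg = np.einsum("ij,ij->j", R_g, R_g)
    gy = r_y @ R_g
    beta = gy / gg
    se = 1.0 / np.sqrt(gg)
    stat = (beta / se) ** 2
    p = chi2.sf(stat, df=1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    meta = genotypes.snp_meta.loc[poly]
    out = pd.DataFrame({
        "CHR": meta["chrom"].to_numpy(),
        "SNP": meta["snp_id"].to_numpy(),
        "POS": meta["pos"].to_numpy(),
        "A1": meta["alt"].to_numpy(),
        "A2": meta["ref"].to_numpy(),
        "AF1": freq[poly],
        "BETA": beta,
        "SE": se,
        "P": p,
    })
    out.attrs["skipped"] = {
        sid: "monomorphic"
        for sid in genotypes.snp_meta.loc[~poly, "snp_id"]}
    out.attrs["null_model"] = {"sigma_g2": sg2, "sigma_e2": se2}
    return out
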