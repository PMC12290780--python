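"""Genetic-correlation structure across coupling vertices.

Pairwise bivariate REML genetic correlations with BH-FDR flagging, vertex
Euclidean distances, and the distance-decay regression comparing a
quadratic model of genetic correlation on distance against a nested linear
model by an F-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .datatypes import CouplingMatrix, GRM, SurfaceMesh
from .gwas import bh_fdr
from .varcomp import reml_bivariate

__all__ = ["RgMatrix", "pairwise_rg", "vertex_distances",
           "DistanceDecayFit", "fit_distance_decay"]


@dataclass
class RgMatrix:
    """Vertex x vertex genetic correlations with SEs, p-values and FDR flags.

    Symmetric with unit diagonal; entries whose bivariate fit hit a
    variance boundary are NaN and never flagged.
    """

    vertex_ids: list
    rg: np.ndarray
    se: np.ndarray
    p: np.ndarray
    fdr_flag: np.ndarray
    hemispheres: list | None = None

    def to_long(self, distances: np.ndarray | None = None) -> pd.DataFrame:
        """Long-format unordered pairs (upper triangle)."""
        rows = []
        n = len(self.vertex_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rec = {
                    "vertex_a": self.vertex_ids[i],
                    "vertex_b": self.vertex_ids[j],
                    "rg": self.rg[i, j], "se": self.se[i, j],
                    "p": self.p[i, j], "fdr_flag": bool(self.fdr_flag[i, j]),
                }
                if distances is not None:
                    rec["distance"] = distances[i, j]
                if self.hemispheres is not None:
                    rec["intra_hemi"] = (self.hemispheres[i]
                                         == self.hemispheres[j])
                rows.append(rec)
        return pd.DataFrame(rows)


def pairwise_rg(coupling: CouplingMatrix, vertices: list, covariates,
                K: GRM, fdr_q: float = 0.05,
                hemispheres: list | None = None) -> RgMatrix:
    """Bivariate-REML genetic correlation for every unordered vertex pair.

    BH-FDR flags are computed over all defined pair p-values at level
    ``fdr_q``; pairs with boundary variance components stay NaN/unflagged.
    """
    if len(vertices) < 2:
        raise ValueError("need at least 2 vertices")
    frame = coupling.to_frame()
    missing = [v for v in vertices if v not in frame.columns]
    if missing:
        raise KeyError(f"vertex {missing[0]} not in coupling matrix")
    n = len(vertices)
    rg = np.eye(n)
    se = np.zeros((n, n))
    p = np.zeros((n, n))
    np.fill_diagonal(p, 0.0)
    pair_idx = []
    pair_p = []
    for i in range(n):
        for j in range(i + 1, n):
            res = reml_bivariate(frame[vertices[i]].to_numpy(),
                                 frame[vertices[j]].to_numpy(),
                                 covariates, K)
            rg[i, j] = rg[j, i] = res.rg
            se[i, j] = se[j, i] = res.se_rg
            p[i, j] = p[j, i] = res.p_value
            if np.isfinite(res.rg):
                pair_idx.append((i, j))
                pair_p.append(res.p_value)
    flags = np.zeros((n, n), dtype=bool)
    if pair_p:
        sel, _ = bh_fdr(np.asarray(pair_p), q=fdr_q)
        for (i, j), s in zip(pair_idx, sel):
            flags[i, j] = flags[j, i] = bool(s)
    return RgMatrix(list(vertices), rg, se, p, flags, hemispheres)


def vertex_distances(mesh: SurfaceMesh, vertices: list
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Euclidean distances between the given vertices, plus a
    boolean intrahemispheric-pair indicator matrix."""
    table = mesh.table.set_index("vertex_id")
    missing = [v for v in vertices if v not in table.index]
    if missing:
        raise KeyError(f"vertex {missing[0]} not on the mesh")
    xyz = table.loc[vertices, ["x", "y", "z"]].to_numpy(dtype=float)
    diff = xyz[:, None, :] - xyz[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    hemi = table.loc[vertices, "hemisphere"].to_numpy()
    intra = hemi[:, None] == hemi[None, :]
    return d, intra


@dataclass
class DistanceDecayFit:
    """Nested linear-vs-quadratic regression of rg on distance."""

    coef_linear: np.ndarray
    coef_quadratic: np.ndarray
    rss_linear: float
    rss_quadratic: float
    f_stat: float
    p_value: float
    n: int
    hemisphere: str | None = None

    @property
    def residual_difference(self) -> float:
        return self.rss_linear - self.rss_quadratic

    def slope_at(self, distance: float) -> float:
        """Derivative of the quadratic fit at the given distance."""
        b = self.coef_quadratic
        return float(b[1] + 2.0 * b[2] * distance)


def fit_distance_decay(rg_values, distances,
                       hemisphere: str | None = None) -> DistanceDecayFit:
    """Fit rg ~ d (linear) and rg ~ d + d^2 (quadratic) by least squares
    and compare them with the nested F-test
    F = (RSS_lin - RSS_quad) / (RSS_quad / (n - 3))."""
    y = np.asarray(rg_values, dtype=float)
    d = np.asarray(distances, dtype=float)
    ok = np.isfinite(y) & np.isfinite(d)
    y, d = y[ok], d[ok]
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(d) == 0:
        raise ValueError("distances are collinear (constant)")
    X1 = np.column_stack([np.ones(n), d])
    X2 = np.column_stack([np.ones(n), d, d * d])
    if np.linalg.matrix_rank(X2) < 3:
        raise ValueError("distances are collinear")
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    b2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    rss1 = float(((y - X1 @ b1) ** 2).sum())
    rss2 = float(((y - X2 @ b2) ** 2).sum())
    rss2 = min(rss2, rss1)  # guard tiny negative differences from round-off
    if rss2 == 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (rss1 - rss2) / (rss2 / (n - 3))
        p = float(f_dist.sf(f_stat, 1, n - 3))
    return DistanceDecayFit(coef_linear=b1, coef_quadratic=b2,
                            rss_linear=rss1, rss_quadratic=rss2,
                            f_stat=float(f_stat), p_value=p, n=n,
                            hemisphere=hemisphere)
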