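"""Vertex-wise structure-function coupling on a cortical mesh.

The coupling at a vertex x0 is the normalized inner product of its local
structural-connectivity profile and functional-connectivity profile,
restricted to the vertex's functional-network patch E (same hemisphere,
same network, the vertex itself excluded):

    SFC(x0) = < f1 / ||f1||, f2 / ||f2|| >,  f1 = SC(x0, .)|E, f2 = FC(x0, .)|E

with the SC profile log-transformed (log(1 + SC)) by default.  Pearson- and
Spearman-correlation variants of the same restricted profiles are provided
for robustness analyses, along with a Gaussian-kernel smoother for sparse
SC and a Pearson FC builder from BOLD time series.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import pearsonr, spearmanr

from .datatypes import ConnectivityProfiles, CouplingMatrix, SurfaceMesh

__all__ = ["smooth_sc", "fc_from_timeseries", "compute_coupling",
           "network_patches"]


def smooth_sc(sc: np.ndarray, mesh: SurfaceMesh, bandwidth: float) -> np.ndarray:
    """Gaussian-kernel smoothing of a sparse SC matrix over the mesh.

    Each row is convolved with a Gaussian kernel of the Euclidean
    inter-vertex distance (weights normalized to sum 1 per target vertex);
    symmetry is restored by averaging with the transpose.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    sc = np.asarray(sc, dtype=float)
    d = squareform(pdist(mesh.coordinates))
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    w /= w.sum(axis=0, keepdims=True)
    out = sc @ w
    return (out + out.T) / 2.0


def fc_from_timeseries(bold: np.ndarray) -> np.ndarray:
    """Pearson-correlation FC from a time x vertices BOLD array."""
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2 or bold.shape[0] < 3:
        raise ValueError("need a time x vertices array with >= 3 time points")
    sd = bold.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"constant time series at vertex index {flat[0]}")
    fc = np.corrcoef(bold, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return fc


def network_patches(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Integration region E per unmasked vertex: unmasked vertices of the
    same hemisphere and functional network, excluding the vertex itself."""
    table = mesh.table
    hemis = table["hemisphere"].to_numpy()
    nets = table["network"].to_numpy()
    masked = table["mask"].to_numpy()
    out = []
    for v in mesh.unmasked:
        e = np.flatnonzero((hemis == hemis[v]) & (nets == nets[v]) & ~masked)
        out.append(e[e != v])
    return out


def _couple(f1: np.ndarray, f2: np.ndarray, method: str) -> float:
    n1, n2 = np.linalg.norm(f1), np.linalg.norm(f2)
    if method == "inner":
        if n1 == 0 or n2 == 0:
            return np.nan
        return float(np.clip(f1 @ f2 / (n1 * n2), -1.0, 1.0))
    if f1.std() == 0 or f2.std() == 0:
        return np.nan
    if method == "pearson":
        return float(pearsonr(f1, f2).statistic)
    if method == "spearman":
        return float(spearmanr(f1, f2).statistic)
    raise ValueError(f"unknown coupling method {method!r}")


def compute_coupling(profiles: ConnectivityProfiles, mesh: SurfaceMesh,
                     method: str = "inner", log_transform_sc: bool = True,
                     log_offset: float = 1.0) -> CouplingMatrix:
    """Coupling of every subject's profiles at every unmasked vertex.

    The SC profile is transformed to ``log(log_offset + SC)`` when
    requested (the default keeps zero SC entries finite).  Vertices whose
    restricted SC or FC profile has zero norm (or zero variance, for the
    correlation variants) yield NaN with a warning: the coupling of a zero
    function is not defined.
    """
    if method not in ("inner", "pearson", "spearman"):
        raise ValueError(f"unknown coupling method {method!r}")
    subjects = profiles.subject_ids
    patches = network_patches(mesh)
    unmasked = mesh.unmasked
    n_v = unmasked.size
    values = np.empty((len(subjects), n_v))
    n_undefined = 0
    for s, sid in enumerate(subjects):
        sc = profiles.sc[sid]
        fc = profiles.fc[sid]
        if sc.shape != (mesh.n_vertices, mesh.n_vertices):
            raise ValueError(f"profile shape for subject {sid} does not "
                             "match the mesh")
        for j, v in enumerate(unmasked):
            e = patches[j]
            f1 = sc[v, e]
            if log_transform_sc:
                f1 = np.log(log_offset + f1)
            values[s, j] = _couple(f1, fc[v, e], method)
            if np.isnan(values[s, j]):
                n_undefined += 1
    if n_undefined:
        warnings.warn(f"{n_undefined} subject-vertex couplings undefined "
                      "(zero-norm profile); set to NaN", stacklevel=2)
    return CouplingMatrix(values, subjects, mesh.unmasked_ids, method=method)
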