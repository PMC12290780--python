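"""Restricted maximum-likelihood variance-component estimation.

Implements average-information (AI) REML for the additive genetic model

    y = X b + u + e,   u ~ N(0, K sigma_g^2),   e ~ N(0, I sigma_e^2)

so that cov(y) = K h2 + I (1 - h2) after scaling, with heritability
h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).  Three entry points:

* :func:`reml_univariate` — single trait, fast O(n) iterations after one
  eigendecomposition of K (reusable across traits via ``K_eig``);
* :func:`reml_bivariate` — two traits with a genetic covariance term,
  yielding the genetic correlation rg = sigma_g12 / sqrt(sg1^2 sg2^2);
* :func:`reml_repeated` — two scans per subject with the subject random
  effect split into a genetic part (pedigree covariance) and a common
  subject-environment part, plus a scan-level residual.

Numerical policy: AI (Newton-type) steps with step-halving so the
restricted likelihood never decreases; variances floored at 1e-6 times the
trait variance; convergence when both the log-likelihood change and the
parameter change drop below 1e-8; at most 100 iterations.  The h2 test is
a boundary-corrected likelihood-ratio test against sigma_g^2 = 0 using the
half-half chi-square mixture (0.5 chi2_0 + 0.5 chi2_1).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2

from .datatypes import BivariateResult, CovariateTable, GRM, VarianceComponents

__all__ = ["NotIdentifiableError", "reml_univariate", "reml_bivariate",
           "reml_repeated", "aireml", "restricted_loglik_grid"]

MAX_ITER = 100
TOL = 1e-8
FLOOR_FACTOR = 1e-6


class NotIdentifiableError(ValueError):
    """The genetic and residual components cannot be separated (K = c I)."""


def _as_design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, CovariateTable):
        return covariates.design_matrix()
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _check_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")


# ---------------------------------------------------------------------------
# fast univariate path (K eigendecomposed once, V diagonal thereafter)


def _rotated_quantities(lam, yt, Xt, sg2, se2):
    """GLS pieces for V = diag(sg2 * lam + se2) in the rotated basis."""
    v = sg2 * lam + se2
    w = 1.0 / v
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    C = np.linalg.inv(XtWX)
    b = C @ (Xw.T @ yt)
    r = yt - Xt @ b
    Py = w * r
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    loglik = -0.5 * (np.log(v).sum() + logdet_xwx + r @ Py)
    return v, w, Xw, C, Py, loglik


def _uni_loglik(lam, yt, Xt, sg2, se2) -> float:
    return _rotated_quantities(lam, yt, Xt, sg2, se2)[-1]


def restricted_loglik_grid(y, covariates, K: GRM, sg2_grid, se2_grid):
    """Restricted log-likelihood surface over a (sigma_g2, sigma_e2) grid.

    Independent of the AI-REML iteration; intended as a brute-force check
    of the optimum on small problems.
    """
    y = np.asarray(y, dtype=float)
    X = _as_design(covariates, y.size)
    lam, U = np.linalg.eigh(K.values)
    yt, Xt = U.T @ y, U.T @ X
    out = np.empty((len(sg2_grid), len(se2_grid)))
    for i, sg2 in enumerate(sg2_grid):
        for j, se2 in enumerate(se2_grid):
            out[i, j] = _uni_loglik(lam, yt, Xt, sg2, se2)
    return out


def reml_univariate(y, covariates, K: GRM,
                    K_eig: tuple[np.ndarray, np.ndarray] | None = None,
                    max_iter: int = MAX_ITER, tol: float = TOL
                    ) -> VarianceComponents:
    """AI-REML fit of the single-trait genetic model.

    ``K_eig`` may carry a precomputed ``(eigenvalues, eigenvectors)`` pair
    of K to amortize the decomposition across many traits on one cohort.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = _as_design(covariates, n)
    _check_design(X)
    if K.n != n:
        raise ValueError("GRM size does not match trait length")
    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("trait is constant")

    if K_eig is None:
        lam, U = np.linalg.eigh(K.values)
    else:
        lam, U = K_eig
    if lam.max() - lam.min() < 1e-10:
        raise NotIdentifiableError("components not identifiable (K = c I)")
    yt, Xt = U.T @ y, U.T @ X

    floor = FLOOR_FACTOR * vary
    # initialize at an even split of the residualized trait variance
    r0 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    s0 = 0.5 * float(r0 @ r0) / max(n - X.shape[1], 1)
    theta = np.array([s0, s0])

    _, w, Xw, C, Py, loglik = _rotated_quantities(lam, yt, Xt, *theta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # scores and average information in the rotated basis
        a_list = (lam, np.ones(n))
        scores = np.empty(2)
        t_vecs = []
        for k, a in enumerate(a_list):
            # tr(P A) = sum(w a) - tr(C X'W A W X)
            tr_pa = float(w @ a) - float(np.einsum(
                "ij,ji->", C, Xw.T @ (a[:, None] * Xw)))
            quad = float(Py @ (a * Py))
            scores[k] = -0.5 * (tr_pa - quad)
            t_vecs.append(a * Py)
        AI = np.empty((2, 2))
        for k in range(2):
            for l in range(k, 2):
                tl = t_vecs[l]
                Ptl = w * tl - Xw @ (C @ (Xw.T @ tl))
                AI[k, l] = AI[l, k] = 0.5 * float(t_vecs[k] @ Ptl)
        # active-set projection: a component pinned at the variance floor
        # whose score pushes it below the floor is held fixed; if every
        # component is pinned that way, the constrained optimum is reached
        active = (theta <= floor * (1.0 + 1e-9)) & (scores < 0.0)
        if active.all():
            converged = True
            break
        free = ~active
        step = np.zeros(2)
        try:
            step[free] = np.linalg.solve(AI[np.ix_(free, free)],
                                         scores[free])
        except np.linalg.LinAlgError:
            step[free] = scores[free] / max(np.abs(scores[free]).max(), 1.0)
        # step-halving: accept only non-decreasing restricted likelihood
        accepted = False
        for _ in range(30):
            cand = np.maximum(theta + step, floor)
            try:
                _, w_c, Xw_c, C_c, Py_c, ll_c = _rotated_quantities(
                    lam, yt, Xt, *cand)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if ll_c >= loglik - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        d_theta = np.abs(cand - theta).max()
        d_ll = ll_c - loglik
        theta, w, Xw, C, Py, loglik = cand, w_c, Xw_c, C_c, Py_c, ll_c
        if d_ll < tol and d_theta < tol * (1.0 + theta.max()):
            converged = True
            break

    sg2, se2 = float(theta[0]), float(theta[1])
    h2 = sg2 / (sg2 + se2)

    # delta-method SE from the inverse average information
    try:
        cov = np.linalg.inv(AI)
        grad = np.array([se2, -sg2]) / (sg2 + se2) ** 2
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = float("nan")

    # boundary-corrected LRT against sigma_g2 = 0
    p = X.shape[1]
    rss = float(r0 @ r0)
    se2_null = rss / max(n - p, 1)
    ll_null = _uni_loglik(lam, yt, Xt, 0.0, se2_null)
    lrt = max(2.0 * (loglik - ll_null), 0.0)
    p_value = 1.0 if lrt == 0.0 else float(0.5 * chi2.sf(lrt, df=1))

    return VarianceComponents(sigma_g2=sg2, sigma_e2=se2, h2=h2, se_h2=se_h2,
                              loglik=float(loglik), p_value=p_value,
                              n_iterations=n_iter, converged=converged)


# ---------------------------------------------------------------------------
# generic dense engine (bivariate and repeated-measures designs)


def aireml(y: np.ndarray, X: np.ndarray, comps: list[np.ndarray],
           init: np.ndarray | None = None,
           variance_params: list[int] | None = None,
           max_iter: int = MAX_ITER, tol: float = TOL):
    """Generic AI-REML for V = sum_k theta_k comps[k].

    ``variance_params`` lists the indices of theta that are variances
    (floored at 1e-6 var(y)); the rest are covariances and unconstrained.
    Returns ``(theta, loglik, cov_theta, n_iter, converged)`` with
    ``cov_theta`` the inverse average-information matrix.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    q = len(comps)
    if variance_params is None:
        variance_params = list(range(q))
    floor = FLOOR_FACTOR * float(np.var(y))

    if init is None:
        init = np.full(q, float(np.var(y)) / max(len(variance_params), 1))
        for k in range(q):
            if k not in variance_params:
                init[k] = 0.0
    theta = np.asarray(init, dtype=float).copy()

    def pieces(th):
        V = sum(t * A for t, A in zip(th, comps))
        L = np.linalg.cholesky(V)
        Vi = np.linalg.inv(V)
        ViX = Vi @ X
        XtViX = X.T @ ViX
        C = np.linalg.inv(XtViX)
        Viy = Vi @ y
        b = C @ (X.T @ Viy)
        Py = Viy - ViX @ b
        sign, ld_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        ld_v = 2.0 * np.log(np.diag(L)).sum()
        ll = -0.5 * (ld_v + ld_x + float(y @ Py))
        return Vi, ViX, C, Py, ll

    Vi, ViX, C, Py, loglik = pieces(theta)
    AI = np.eye(q)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        scores = np.empty(q)
        t_vecs = []
        for k, A in enumerate(comps):
            ViA = Vi @ A
            tr_pa = np.trace(ViA) - float(np.einsum(
                "ij,ji->", C, ViX.T @ (A @ ViX)))
            quad = float(Py @ (A @ Py))
            scores[k] = -0.5 * (tr_pa - quad)
            t_vecs.append(A @ Py)
        for k in range(q):
            tk = t_vecs[k]
            Ptk = Vi @ tk - ViX @ (C @ (ViX.T @ tk))
            for l in range(k, q):
                AI[k, l] = AI[l, k] = 0.5 * float(t_vecs[l] @ Ptk)
        # active-set projection: variance components pinned at the floor
        # with a negative score are held fixed (constrained optimum when
        # every parameter is pinned that way)
        active = np.zeros(q, dtype=bool)
        for k in variance_params:
            active[k] = (theta[k] <= floor * (1.0 + 1e-9)
                         and scores[k] < 0.0)
        if active.all():
            converged = True
            break
        free = ~active
        step = np.zeros(q)
        try:
            step[free] = np.linalg.solve(AI[np.ix_(free, free)],
                                         scores[free])
        except np.linalg.LinAlgError:
            step[free] = scores[free] / max(np.abs(scores[free]).max(), 1.0)
        accepted = False
        for _ in range(30):
            cand = theta + step
            for k in variance_params:
                cand[k] = max(cand[k], floor)
            try:
                Vi_c, ViX_c, C_c, Py_c, ll_c = pieces(cand)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if ll_c >= loglik - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        d_theta = np.abs(cand - theta).max()
        d_ll = ll_c - loglik
        theta, Vi, ViX, C, Py, loglik = cand, Vi_c, ViX_c, C_c, Py_c, ll_c
        if d_ll < tol and d_theta < tol * (1.0 + np.abs(theta).max()):
            converged = True
            break

    try:
        cov_theta = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov_theta = np.full((q, q), np.nan)
    return theta, float(loglik), cov_theta, n_iter, converged


def reml_bivariate(y1, y2, covariates, K: GRM,
                   max_iter: int = MAX_ITER) -> BivariateResult:
    """Two-trait AI-REML with a genetic covariance term.

    Stacks both traits over the same individuals; the genetic correlation
    is rg = sigma_g12 / sqrt(sigma_g1^2 sigma_g2^2), clipped into [-1, 1].
    When either trait's genetic variance sits at the boundary, rg is
    returned as NaN (undefined).
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = y1.size
    if y2.size != n:
        raise ValueError("traits must cover the same individuals")
    X = _as_design(covariates, n)
    _check_design(X)
    Kv, I = K.values, np.eye(n)
    Z = np.zeros((n, n))
    comps = [
        np.block([[Kv, Z], [Z, Z]]),   # sigma_g1^2
        np.block([[Z, Z], [Z, Kv]]),   # sigma_g2^2
        np.block([[Z, Kv], [Kv, Z]]),  # sigma_g12
        np.block([[I, Z], [Z, Z]]),    # sigma_e1^2
        np.block([[Z, Z], [Z, I]]),    # sigma_e2^2
        np.block([[Z, I], [I, Z]]),    # sigma_e12
    ]
    yy = np.concatenate([y1, y2])
    XX = np.vstack([np.hstack([X, np.zeros_like(X)]),
                    np.hstack([np.zeros_like(X), X])])
    v1, v2 = float(np.var(y1)), float(np.var(y2))
    # shrink the cross-covariance start so the initial V is positive definite
    # even for perfectly correlated traits
    c12 = 0.8 * float(np.cov(y1, y2)[0, 1])
    init = np.array([v1 / 2, v2 / 2, c12 / 2, v1 / 2, v2 / 2, c12 / 2])
    theta, loglik, cov_t, n_iter, converged = aireml(
        yy, XX, comps, init=init, variance_params=[0, 1, 3, 4],
        max_iter=max_iter)
    sg1, sg2_, sg12, se1, se2_, se12 = theta

    floor = 10 * FLOOR_FACTOR * float(np.var(yy))
    if sg1 <= floor or sg2_ <= floor:
        rg, se_rg = float("nan"), float("nan")
    else:
        rg = float(np.clip(sg12 / np.sqrt(sg1 * sg2_), -1.0, 1.0))
        denom = np.sqrt(sg1 * sg2_)
        grad = np.zeros(6)
        grad[0] = -sg12 / (2.0 * sg1 * denom)
        grad[1] = -sg12 / (2.0 * sg2_ * denom)
        grad[2] = 1.0 / denom
        se_rg = float(np.sqrt(max(grad @ cov_t @ grad, 0.0)))

    # LRT for sigma_g12 = 0 (interior parameter: plain chi-square df 1)
    comps0 = [comps[i] for i in (0, 1, 3, 4, 5)]
    init0 = init[[0, 1, 3, 4, 5]]
    _, ll0, _, _, _ = aireml(yy, XX, comps0, init=init0,
                             variance_params=[0, 1, 2, 3], max_iter=max_iter)
    lrt = max(2.0 * (loglik - ll0), 0.0)
    p_value = float(chi2.sf(lrt, df=1))

    return BivariateResult(sigma_g2_1=float(sg1), sigma_g2_2=float(sg2_),
                           sigma_g12=float(sg12), sigma_e2_1=float(se1),
                           sigma_e2_2=float(se2_), sigma_e12=float(se12),
                           rg=rg, se_rg=se_rg, p_value=p_value,
                           loglik=loglik, converged=converged)


def reml_repeated(y_scan1, y_scan2, covariates, K_ped: GRM,
                  max_iter: int = MAX_ITER) -> VarianceComponents:
    """Repeated-measures variance decomposition over two scans.

    The subject-level random effect is split into a genetic part with
    pedigree covariance K_ped (sigma_g^2) and a common subject-environment
    part (sigma_c^2, identity over subjects, shared across scans); the
    scan-level residual sigma_e^2 captures intra-subject variation.
    h2 = sigma_g^2 / (sigma_g^2 + sigma_c^2 + sigma_e^2).
    """
    if y_scan2 is None:
        raise ValueError("single-scan input: use reml_univariate")
    y1 = np.asarray(y_scan1, dtype=float)
    y2 = np.asarray(y_scan2, dtype=float)
    n = y1.size
    if y2.size != n:
        raise ValueError("both scans must be observed for every subject")
    X = _as_design(covariates, n)
    _check_design(X)
    J = np.ones((2, 2))
    comps = [np.kron(J, K_ped.values),   # genetic, shared across scans
             np.kron(J, np.eye(n)),      # subject environment
             np.eye(2 * n)]              # scan-level residual
    yy = np.concatenate([y1, y2])
    XX = np.vstack([X, X])
    v = float(np.var(yy))
    theta, loglik, cov_t, n_iter, converged = aireml(
        yy, XX, comps, init=np.array([v / 3, v / 3, v / 3]),
        max_iter=max_iter)
    sg2, sc2, se2 = map(float, theta)
    tot = sg2 + sc2 + se2
    h2 = sg2 / tot
    grad = np.array([(sc2 + se2), -sg2, -sg2]) / tot ** 2
    se_h2 = float(np.sqrt(max(grad @ cov_t @ grad, 0.0)))

    _, ll0, _, _, _ = aireml(yy, XX, comps[1:],
                             init=np.array([v / 2, v / 2]),
                             max_iter=max_iter)
    lrt = max(2.0 * (loglik - ll0), 0.0)
    p_value = 1.0 if lrt == 0.0 else float(0.5 * chi2.sf(lrt, df=1))

    return VarianceComponents(sigma_g2=sg2, sigma_e2=se2, h2=h2, se_h2=se_h2,
                              loglik=loglik, p_value=p_value,
                              n_iterations=n_iter, converged=converged,
                              sigma_c2=sc2)
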