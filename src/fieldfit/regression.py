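"""Weighted least squares, adaptive group lasso, and approximate LOO-CV.

Variable selection solves, per gene and per regularization strength ``lam``,

    min_beta  sum_j w_j (y_j - X_j beta)^2
              + lam * ( sum_{k in I} zeta_k |beta_k|
                        + zeta_c ||(b_cos, b_sin)||_2
                        + zeta_dc ||(b_dcos, b_dsin)||_2 )

with the intercept unpenalized, singleton groups I = {age, response,
age_response, genotype}, and the two clock harmonics (and their age
interactions) tied into 2-vector groups so the cos/sin pair enters or leaves
the model together.  Adaptive weights ``zeta`` are inverse squared pilot-OLS
coefficients (sevenfold for the response terms, whose feature carries seven
extra nonlinear parameters), giving consistent selection.  The regularization
strength is chosen by a one-standard-error rule on an approximate
leave-one-out CV error computed from the hat matrix of the active submatrix,
avoiding N refits per lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .features import COLUMN_ROLES

#: Penalized groups: name -> column indices into the 9-column design.
GROUP_INDICES: dict[str, tuple[int, ...]] = {
    "age": (1,),
    "clock": (2, 3),
    "response": (4,),
    "age_clock": (5, 6),
    "age_response": (7,),
    "genotype": (8,),
}
GROUP_ORDER = ("age", "clock", "response", "age_clock", "age_response", "genotype")
_INTERCEPT = 0
#: Groups whose feature carries 7 extra nonlinear response parameters.
_SEVENFOLD = ("response", "age_response")


@dataclass
class PenaltySpec:
    """Group structure and adaptive weights for the penalty term."""

    weights: dict[str, float]  # group name -> zeta (may be +inf)

    def __post_init__(self):
        for name in GROUP_ORDER:
            if name not in self.weights:
                raise ValueError(f"missing weight for group {name!r}")
            if not (self.weights[name] > 0):
                raise ValueError("all zeta must be > 0 (use +inf to exclude a group)")

    def finite_groups(self) -> list[str]:
        return [g for g in GROUP_ORDER if np.isfinite(self.weights[g])]


@dataclass
class RegPath:
    """A fitted regularization path with approximate LOO-CV diagnostics."""

    lambdas: np.ndarray          # decreasing
    coefficients: np.ndarray     # (n_lambda, 9)
    cv_error: np.ndarray
    cv_se: np.ndarray            # standard error of the mean CV error


def _column_norms(X: np.ndarray) -> np.ndarray:
    return np.sqrt((X**2).sum(axis=0))


def wls_fit(X, y, w) -> np.ndarray:
    """Weighted least squares; degenerate (all-zero) columns get coefficient 0."""
    Xv = X.values if hasattr(X, "values") else np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    sw = np.sqrt(w)
    active = _column_norms(Xv) > 1e-12
    beta = np.zeros(Xv.shape[1])
    if active.any():
        A = Xv[:, active] * sw[:, None]
        sol, _, rank, _ = np.linalg.lstsq(A, y * sw, rcond=1e-6)
        if rank < int(active.sum()):
            warnings.warn("rank-deficient design; collinear columns resolved by least norm")
        beta[active] = sol
    if not active.all():
        warnings.warn("degenerate design columns dropped (coefficient 0)")
    return beta


def adaptive_weights(beta_tilde) -> PenaltySpec:
    """Adaptive penalty weights from pilot (unpenalized) coefficients.

    zeta = 1/beta^2 for singletons (7/beta^2 for the response terms) and
    1/(b_cos^2 + b_sin^2) for the harmonic pairs; a zero pilot coefficient
    gives an infinite weight, i.e. the group is excluded.
    """
    b = np.asarray(beta_tilde, float)
    weights = {}
    with np.errstate(divide="ignore"):
        for name, idx in GROUP_INDICES.items():
            ss = float(np.sum(b[list(idx)] ** 2))
            mult = 7.0 if name in _SEVENFOLD else 1.0
            weights[name] = mult / ss if ss > 0 else np.inf
    return PenaltySpec(weights=weights)


def _weighted_mean(y, w):
    return float(np.sum(w * y) / np.sum(w))


def _entry_scales(Xv, y, w, pen: PenaltySpec) -> list[float]:
    """Per-group lambda at which each group would enter from the null model."""
    res = y - _weighted_mean(y, w)
    scales = []
    for g in pen.finite_groups():
        idx = list(GROUP_INDICES[g])
        if _column_norms(Xv[:, idx]).min() <= 1e-12:
            continue
        z = 2.0 * Xv[:, idx].T @ (w * res)
        scales.append(float(np.linalg.norm(z)) / pen.weights[g])
    return scales


def lambda_max(X, y, w, pen: PenaltySpec) -> float:
    """Smallest lambda at which every penalized group is zero (analytic)."""
    Xv = X.values if hasattr(X, "values") else np.asarray(X, float)
    scales = _entry_scales(Xv, np.asarray(y, float), np.asarray(w, float), pen)
    return max(scales, default=0.0)


def _pair_solve(A_eigvals, A_eigvecs, z, thresh) -> np.ndarray:
    """Exact minimizer of  b'Ab - 2z'b + thresh*||b||  for a 2-column group.

    The stationary point satisfies ``(A + thresh/(2 nu) I) b = z`` with
    ``nu = ||b||``; the scalar root is found by safeguarded Newton on
    ``psi(nu) = sqrt(sum z_i^2/(d_i + thresh/(2 nu))^2) - nu`` (decreasing).
    """
    nz = np.linalg.norm(z)
    if nz <= thresh / 2.0:
        return np.zeros(2)
    zt = A_eigvecs.T @ z
    d0, d1 = A_eigvals
    z0sq, z1sq = zt[0] ** 2, zt[1] ** 2

    def val(nu):
        c = thresh / (2.0 * nu)
        m = z0sq / (d0 + c) ** 2 + z1sq / (d1 + c) ** 2
        return np.sqrt(m) - nu

    lo, hi = 1e-300, nz / min(d0, d1)
    nu = hi
    for _ in range(100):
        c = thresh / (2.0 * nu)
        m = z0sq / (d0 + c) ** 2 + z1sq / (d1 + c) ** 2
        f = np.sqrt(m) - nu
        if f > 0:
            lo = nu
        else:
            hi = nu
        # derivative of sqrt(m) wrt nu via dc/dnu = -thresh/(2 nu^2)
        dm_dc = -2.0 * (z0sq / (d0 + c) ** 3 + z1sq / (d1 + c) ** 3)
        df = dm_dc * (-thresh / (2.0 * nu**2)) / (2.0 * np.sqrt(m)) - 1.0
        step = f / df
        nu_new = nu - step
        if not (lo < nu_new < hi):
            nu_new = 0.5 * (lo + hi)
        if abs(nu_new - nu) <= 1e-16 * nu:
            nu = nu_new
            break
        nu = nu_new
    c = thresh / (2.0 * nu)
    return A_eigvecs @ (zt / (A_eigvals + c))


def _cd_pass(Xv, y, w, beta, res, groups, pen, lam, wsum):
    """One sweep of block coordinate descent; returns max coefficient change."""
    delta = 0.0
    b_old = beta[_INTERCEPT]
    b_new = b_old + float(np.sum(w * res)) / wsum
    if b_new != b_old:
        res -= b_new - b_old
        delta = abs(b_new - b_old)
        beta[_INTERCEPT] = b_new
    for g, idx, Xg, XgW, gram11, evals, evecs in groups:
        zeta = pen.weights[g]
        b_cur = beta[idx]
        z = XgW @ (res + Xg @ b_cur)
        if gram11 is not None:
            t = lam * zeta / 2.0
            z0 = float(z[0])
            b_new = np.array([np.sign(z0) * max(abs(z0) - t, 0.0) / gram11])
        else:
            b_new = _pair_solve(evals, evecs, z, lam * zeta)
        db = b_new - b_cur
        if db.any():
            res -= Xg @ db
            delta = max(delta, float(np.max(np.abs(db))))
            beta[idx] = b_new
    return delta


def _irls_polish(Xv, y, w, beta, groups, pen, lam, max_iter=200):
    """Newton-like polish of the smooth stationarity system on the active set.

    Active groups (nonzero norm) satisfy 2 X'W(X beta - y) + lam zeta b/||b|| = 0;
    iterate weighted ridge solves with the current group norms until the
    coefficients stop moving.  Groups whose norm collapses are dropped.
    """
    active = [grp for grp in groups if np.linalg.norm(beta[grp[1]]) > 0]
    for _ in range(max_iter):
        cols = [_INTERCEPT] + [i for grp in active for i in grp[1]]
        Xa = Xv[:, cols]
        A = 2.0 * Xa.T @ (w[:, None] * Xa)
        rhs = 2.0 * Xa.T @ (w * y)
        D = np.zeros(len(cols))
        pos = 1
        for g, idx, *_ in active:
            nb = np.linalg.norm(beta[idx])
            D[pos:pos + len(idx)] = lam * pen.weights[g] / nb
            pos += len(idx)
        M = A + np.diag(D)
        b_new = np.linalg.solve(M, rhs)
        b_new += np.linalg.solve(M, rhs - M @ b_new)  # one refinement step
        change = float(np.max(np.abs(b_new - beta[cols])))
        beta[cols] = b_new
        dropped = False
        for g, idx, *_ in list(active):
            if np.linalg.norm(beta[idx]) < 1e-13:
                beta[idx] = 0.0
                active = [grp for grp in active if grp[0] != g]
                dropped = True
        if change < 1e-14 and not dropped:
            break
    return beta


def group_lasso_fit(
    X,
    y,
    w,
    pen: PenaltySpec,
    lam: float,
    *,
    beta0=None,
    tol: float = 1e-8,
    max_iter: int = 10000,
    kkt_tol: float = 1e-9,
) -> np.ndarray:
    """Adaptive group lasso: block coordinate descent plus an exact polish.

    Singleton groups are updated by soft-thresholding, harmonic pairs by an
    exact 2-D vector-thresholded solve; groups with infinite weight (zero
    pilot coefficient) or degenerate columns are fixed at zero.  Once the
    sweeps settle (max coefficient change < ``tol``) the active set's smooth
    stationarity system is polished to machine precision and the block KKT
    conditions verified to ``kkt_tol``.
    """
    Xv = X.values if hasattr(X, "values") else np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = Xv.shape
    col_ok = _column_norms(Xv) > 1e-12

    if lam == 0:
        return wls_fit(Xv, y, w)

    groups = []
    for g in pen.finite_groups():
        idx = [i for i in GROUP_INDICES[g] if col_ok[i]]
        if len(idx) != len(GROUP_INDICES[g]):
            continue  # degenerate column inside the group: force the group out
        Xg = np.ascontiguousarray(Xv[:, idx])
        XgW = np.ascontiguousarray((w[:, None] * Xg).T)
        G = XgW @ Xg
        if len(idx) == 1:
            if G[0, 0] <= 1e-12:
                continue
            groups.append((g, idx, Xg, XgW, float(G[0, 0]), None, None))
        else:
            evals, evecs = np.linalg.eigh(G)
            if evals.min() <= 1e-12:
                continue
            groups.append((g, idx, Xg, XgW, None, evals, evecs))

    beta = np.zeros(p) if beta0 is None else np.array(beta0, float)
    beta[~col_ok] = 0.0
    penalized_idx = {i for _, idx, *_ in groups for i in idx}
    for i in range(1, p):
        if i not in penalized_idx:
            beta[i] = 0.0
    res = y - Xv @ beta
    wsum = float(np.sum(w))

    # CD sweeps identify the active face; periodically the smooth stationarity
    # system on that face is solved exactly and the full KKT conditions checked.
    # Each polish minimizes over the current face, so alternating the two
    # cannot cycle; CD alone can crawl when penalized columns are strongly
    # correlated.
    scale = max(float(np.max(np.abs(2.0 * Xv.T @ (w * y)))), 1.0)
    zeta_max = max((pen.weights[g] for g, *_ in groups), default=1.0)
    # roundoff floor: stationarity of an active group cancels terms of size
    # ~lam*zeta, so machine precision limits the achievable residual
    kkt_thresh = max(kkt_tol, 1e-12 * scale, 1e-14 * lam * zeta_max)
    sweeps_between_polish = 25
    done = 0
    while done < max_iter:
        delta = np.inf
        for _ in range(sweeps_between_polish):
            delta = _cd_pass(Xv, y, w, beta, res, groups, pen, lam, wsum)
            done += 1
            if delta < tol:
                break
        beta = _irls_polish(Xv, y, w, beta, groups, pen, lam)
        # stationarity cancels terms of size ~|X'W||y| + |X'W X||beta|; with
        # near-unpenalized collinear groups |beta| can be huge and machine
        # precision bounds the achievable residual accordingly
        precancel = float(
            np.max(np.abs(Xv).T @ (w * (np.abs(y) + np.abs(Xv) @ np.abs(beta))))
        )
        if kkt_residual(Xv, y, w, pen, lam, beta) < max(kkt_thresh, 5e-13 * precancel):
            return beta
        res = y - Xv @ beta
    raise RuntimeError(f"group lasso failed to reach KKT tolerance at lam={lam:g}")


def kkt_residual(X, y, w, pen: PenaltySpec, lam: float, beta) -> float:
    """Largest violation of the block KKT conditions (diagnostic)."""
    Xv = X.values if hasattr(X, "values") else np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    res = y - Xv @ beta
    worst = abs(2.0 * float(np.sum(w * res)))  # intercept stationarity
    for g in pen.finite_groups():
        idx = list(GROUP_INDICES[g])
        if _column_norms(Xv[:, idx]).min() <= 1e-12:
            continue
        z = 2.0 * Xv[:, idx].T @ (w * res)
        b = beta[idx]
        nb = float(np.linalg.norm(b))
        if nb > 0:
            worst = max(worst, float(np.max(np.abs(z - lam * pen.weights[g] * b / nb))))
        else:
            worst = max(worst, max(0.0, float(np.linalg.norm(z)) - lam * pen.weights[g]))
    return worst


def approx_loocv(X_active, y, beta, w=None) -> tuple[float, float]:
    """Approximate leave-one-out CV error from the active-set hat matrix.

    Returns the mean and standard deviation over samples of
    ``(1 + X_j chi X_j')^2 (yhat_j - y_j)^2`` where ``chi`` expands the
    inverse Gram of the active submatrix; for an unpenalized fit this equals
    the exact PRESS residuals.  Precision weights, if given, scale rows of the
    active submatrix and the squared residuals.
    """
    Xa = X_active.values if hasattr(X_active, "values") else np.asarray(X_active, float)
    y = np.asarray(y, float)
    beta = np.asarray(beta, float)
    n, k = Xa.shape
    if n <= k:
        raise ValueError("need more samples than active columns")
    w = np.ones(n) if w is None else np.asarray(w, float)
    sw = np.sqrt(w)
    Xw = Xa * sw[:, None]
    G = Xw.T @ Xw
    Ginv = np.linalg.inv(G)
    h = np.einsum("jk,kl,jl->j", Xw, Ginv, Xw)
    if np.any(h >= 1.0):
        raise ValueError("leverage >= 1 for some sample; exact LOO undefined")
    resid = (y - Xa @ beta) * sw
    mult = 1.0 + h + h**2 / (1.0 - h)  # = X_j chi X_j' + 1 = 1/(1-h)
    e = (mult * resid) ** 2
    sd = float(np.std(e, ddof=1)) if n > 1 else 0.0
    return float(np.mean(e)), sd


def lasso_path(
    X,
    y,
    w,
    pen: PenaltySpec,
    *,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 1e-4,
) -> RegPath:
    """Fit the full lambda path with warm starts and per-lambda approximate LOO-CV."""
    Xv = X.values if hasattr(X, "values") else np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    n, p = Xv.shape
    scales = _entry_scales(Xv, y, w, pen)
    lmax = max(scales, default=0.0)
    if lmax <= 0:
        lambdas = np.array([0.0])
    else:
        # anchor the lower end to the *smallest* group-entry scale: adaptive
        # weights can spread entry points over many decades, and a path ending
        # at a fixed fraction of lambda_max would then never visit the region
        # where normally-penalized groups enter; a group whose entry scale is
        # below 1e-8*lambda_max is noise-level and does not deepen the path
        lmin = lambda_min_ratio * max(min(scales), 1e-8 * lmax)
        lambdas = np.geomspace(lmax, lmin, n_lambdas)
    coefs = np.zeros((len(lambdas), p))
    cv_err = np.zeros(len(lambdas))
    cv_se = np.zeros(len(lambdas))
    beta = None
    for i, lam in enumerate(lambdas):
        if lmax <= 0:
            beta = np.zeros(p)
            beta[_INTERCEPT] = _weighted_mean(y, w)
        else:
            beta = group_lasso_fit(Xv, y, w, pen, lam, beta0=beta)
        coefs[i] = beta
        active = [_INTERCEPT] + [j for j in range(1, p) if beta[j] != 0.0]
        mean, sd = approx_loocv(Xv[:, active], y, beta[active], w=w)
        cv_err[i] = mean
        cv_se[i] = sd / np.sqrt(n)
    return RegPath(lambdas=lambdas, coefficients=coefs, cv_error=cv_err, cv_se=cv_se)


def select_lambda(path: RegPath) -> float:
    """One-SE rule: the largest lambda whose CV error is below min + SE(min)."""
    if len(path.lambdas) == 0:
        raise ValueError("empty path")
    i_min = int(np.argmin(path.cv_error))
    thresh = path.cv_error[i_min] + path.cv_se[i_min]
    ok = np.nonzero(path.cv_error < thresh)[0]
    if len(ok) == 0:
        return float(path.lambdas[i_min])
    return float(path.lambdas[ok].max())
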