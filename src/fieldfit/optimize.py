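"""Per-gene two-step parameter optimization and cluster-based warm starts.

Fitting one gene proceeds as: (1) a deterministic grid search over the
environmental-response parameters and the responding weather factor, scoring
every setting by the weighted residual sum of a pilot least-squares fit;
(2) Nelder-Mead refinement of the continuous parameters from the best grid
point; (3) a pilot WLS fit at the refined parameters, adaptive penalty
weights, a group-lasso regularization path with approximate LOO-CV, and the
one-SE-rule choice of lambda.  A gene whose penalized coefficients are all
zero is the constant model.

The grid search is the expensive step, so the response feature vectors for
every grid point are precomputed once per (weather, schedule, grid) into a
:class:`FeatureLibrary` and scored for each gene with batched linear algebra;
the residual sum obtained this way is identical to fitting the scaled design
because scaling the response column is affine and the fixed columns span the
intercept and age.  Affinity-propagation clustering lets non-exemplar genes
skip the grid search entirely, warm-starting Nelder-Mead from their cluster
exemplar's optimum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .features import (
    COLUMN_ROLES,
    GAMMA_BOUND,
    DesignMatrix,
    ResponseParams,
    ScaleSpec,
    Schedule,
    build_design_matrix,
    clock_basis,
    env_response_feature,
    scale_unit_range,
)
from .regression import (
    GROUP_INDICES,
    PenaltySpec,
    adaptive_weights,
    lasso_path,
    select_lambda,
    wls_fit,
)
from .weather import ATTRIBUTES, WeatherSeries, resample_weather

_RESP_COLS = (COLUMN_ROLES.index("response"), COLUMN_ROLES.index("age_response"))


@dataclass(frozen=True)
class GridSpec:
    """Initial-value grid for the environmental-response parameters.

    Thresholds are specified as quantiles of the factor over the training
    window, so the same grid adapts to any weather attribute.  The spans
    cover the dose-dependent <-> dose-independent and no-gate <-> cosine <->
    rectangular regimes.
    """

    period_p_values: tuple = (1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0)
    theta_quantiles: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    gamma_f_values: tuple = (-4.0, 0.0, 4.0)
    gamma_g_values: tuple = (-2.0, 2.0, 6.0)
    theta_g_values: tuple = (-1.5, -0.5, 0.0, 0.5, 0.9)
    psi_values: tuple = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    signs: tuple = (1, -1)

    def __post_init__(self):
        for f in (
            self.period_p_values, self.theta_quantiles, self.gamma_f_values,
            self.gamma_g_values, self.theta_g_values, self.psi_values, self.signs,
        ):
            if len(f) == 0:
                raise ValueError("all GridSpec fields must be non-empty")

    @property
    def dims(self) -> tuple[int, ...]:
        return (
            len(self.period_p_values), len(self.theta_quantiles),
            len(self.gamma_f_values), len(self.gamma_g_values),
            len(self.theta_g_values), len(self.psi_values), len(self.signs),
        )

    @property
    def size(self) -> int:
        return int(np.prod(self.dims))


@dataclass
class FitOptions:
    """Knobs for the per-gene fitting pipeline."""

    grid: GridSpec = field(default_factory=GridSpec)
    factors: tuple = ATTRIBUTES
    integration_step: int = 600          # seconds; cadence of the response sums
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-4
    nm_maxiter: int = 500
    nm_fatol: float = 1e-6
    nm_xatol: float = 1e-3
    nm_step: float = 0.1                 # initial simplex step, transformed coords
    weights_used: bool = False           # recorded on the models (voom weights)


@dataclass
class GeneModel:
    """Fitted model for one gene."""

    gene_id: str
    coefficients: np.ndarray
    scale_specs: dict
    selected_lambda: float
    cv_error: float
    factor: str = "none"                 # weather attribute, or "none"
    response_params: ResponseParams | None = None
    weights_used: bool = False
    warm_params: ResponseParams | None = None  # refined params kept for warm starts
    pilot_mse: float = np.nan            # weighted MSE of the pilot WLS at warm_params

    @property
    def is_constant(self) -> bool:
        return not np.any(self.coefficients[1:])

    def nonzero_groups(self) -> frozenset[str]:
        return frozenset(
            g for g, idx in GROUP_INDICES.items() if np.any(self.coefficients[list(idx)])
        )

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "factor": self.factor,
            "response_params": self.response_params.to_dict() if self.response_params else None,
            "coefficients": {r: float(c) for r, c in zip(COLUMN_ROLES, self.coefficients)},
            "scale_specs": {k: v.to_dict() for k, v in self.scale_specs.items()},
            "selected_lambda": float(self.selected_lambda),
            "cv_error": float(self.cv_error),
            "weights_used": bool(self.weights_used),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        rp = d.get("response_params")
        return cls(
            gene_id=d["gene_id"],
            coefficients=np.array([d["coefficients"][r] for r in COLUMN_ROLES]),
            scale_specs={k: ScaleSpec.from_dict(v) for k, v in d["scale_specs"].items()},
            selected_lambda=d["selected_lambda"],
            cv_error=d["cv_error"],
            factor=d.get("factor", "none"),
            response_params=ResponseParams.from_dict(rp) if rp else None,
            weights_used=d.get("weights_used", False),
        )


@dataclass
class FitResult:
    """Fitted models for a panel of genes plus diagnostics."""

    models: list
    cluster_labels: np.ndarray | None = None
    exemplars: list | None = None
    diagnostics: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.models)

    def __len__(self):
        return len(self.models)

    def model(self, gene_id: str) -> GeneModel:
        for m in self.models:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)

    def to_jsonl(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for m in self.models:
                fh.write(json.dumps(m.to_dict()) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "FitResult":
        import json

        models = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    models.append(GeneModel.from_dict(json.loads(line)))
        return cls(models=models)


# ---------------------------------------------------------------------------
# Feature library and batched grid search


class FeatureLibrary:
    """Precomputed response-feature vectors for every grid point and factor.

    Rows are centered and normalized (span-preserving, since the design's
    fixed columns include the intercept and age), stored in float32 in the
    lexicographic enumeration order of the grid fields.
    """

    def __init__(self, ws: WeatherSeries, schedule: Schedule, grid: GridSpec, factors=ATTRIBUTES):
        self.grid = grid
        self.factors = tuple(factors)
        self.step = ws.cadence
        times = schedule.times
        p_max = max(grid.period_p_values)
        lo_cover = times.min() - pd.Timedelta(hours=p_max)
        if not ws.covers(lo_cover, times.max()):
            raise ValueError(
                f"weather record does not cover the training window plus the "
                f"longest memory period ({p_max} h)"
            )
        ts = ws.timestamps.asi8
        in_window = (ws.timestamps >= lo_cover) & (ws.timestamps <= times.max())
        hod_u, hod_inv = np.unique(ws.hours_of_day(), return_inverse=True)
        hi = np.searchsorted(ts, times.asi8, side="right")
        los = {
            p: np.searchsorted(ts, (times - pd.Timedelta(hours=p)).asi8, side="left")
            for p in grid.period_p_values
        }

        from .features import gate_fn, response_fn

        n_p, n_t, n_gf, n_gg, n_tg, n_psi, n_s = grid.dims
        N = len(times)
        self.thresholds: dict[str, np.ndarray] = {}
        self.library: dict[str, np.ndarray] = {}
        for fac in self.factors:
            w_vals = ws.values(fac)
            thetas = np.quantile(w_vals[in_window], grid.theta_quantiles)
            self.thresholds[fac] = thetas
            # response curves for all (theta, gamma_f, sign) combos
            F_resp = np.empty((n_t, n_gf, n_s, len(ts)))
            for it, th in enumerate(thetas):
                for igf, gf in enumerate(grid.gamma_f_values):
                    for isg, sg in enumerate(grid.signs):
                        F_resp[it, igf, isg] = response_fn(w_vals - th, gf, sg)
            F_resp = F_resp.reshape(-1, len(ts))
            A = np.empty((n_p, n_t, n_gf, n_gg, n_tg, n_psi, n_s, N), dtype=np.float32)
            csum = np.empty((F_resp.shape[0], len(ts) + 1))
            for igg, gg in enumerate(grid.gamma_g_values):
                for itg, tg in enumerate(grid.theta_g_values):
                    for ipsi, psi in enumerate(grid.psi_values):
                        g = gate_fn(hod_u, psi, gg, tg)[hod_inv]
                        csum[:, 0] = 0.0
                        np.cumsum(F_resp * g, axis=1, out=csum[:, 1:])
                        for ip, p in enumerate(grid.period_p_values):
                            blk = csum[:, hi] - csum[:, los[p]]
                            A[ip, :, :, igg, itg, ipsi, :, :] = blk.reshape(n_t, n_gf, n_s, N)
            flat = A.reshape(-1, N)
            flat -= flat.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(flat, axis=1)
            bad = norms <= 1e-6
            norms[bad] = 1.0
            flat /= norms[:, None]
            flat[bad] = 0.0
            self.library[fac] = flat
        self._squared = {f: v**2 for f, v in self.library.items()}

    def params_at(self, factor: str, flat_index: int) -> ResponseParams:
        g = self.grid
        ip, it, igf, igg, itg, ipsi, isg = np.unravel_index(flat_index, g.dims)
        return ResponseParams(
            factor=factor,
            period_p=g.period_p_values[ip],
            threshold_theta=float(self.thresholds[factor][it]),
            gamma_f=g.gamma_f_values[igf],
            gamma_g=g.gamma_g_values[igg],
            theta_g=g.theta_g_values[itg],
            psi=g.psi_values[ipsi],
            sign_rho=g.signs[isg],
        )


def _fixed_columns(schedule: Schedule) -> tuple[np.ndarray, np.ndarray]:
    """Non-response design columns [1, d, cos, sin, d cos, d sin, n] and scaled age."""
    d, _ = scale_unit_range(schedule.ages)
    clock = clock_basis(schedule.times)
    F = np.column_stack([
        np.ones(len(schedule)), d, clock[:, 0], clock[:, 1],
        d * clock[:, 0], d * clock[:, 1], schedule.genotypes,
    ])
    return F, d


def _batched_mse(Rlib, Rlib2, F, d, y, w) -> np.ndarray:
    """Weighted residual sums (per grid row) of WLS on [F, r, d*r], via Schur."""
    keep = np.linalg.norm(F, axis=0) > 1e-12
    Fe = F[:, keep]
    q = Fe.shape[1]
    WF = w[:, None] * Fe
    G_FF = Fe.T @ WF
    L = np.linalg.cholesky(G_FF)
    Li = np.linalg.inv(L)
    fy = Li @ (Fe.T @ (w * y))
    rss_F = float(np.sum(w * y**2) - fy @ fy)

    M = np.column_stack([WF, (w * d)[:, None] * Fe, w * y, w * d * y]).astype(np.float32)
    V = np.column_stack([w, w * d, w * d**2]).astype(np.float32)
    P = (Rlib @ M).astype(np.float64)
    Q2 = (Rlib2 @ V).astype(np.float64)

    A1 = P[:, :q] @ Li.T
    A2 = P[:, q:2 * q] @ Li.T
    S11 = Q2[:, 0] - np.einsum("ij,ij->i", A1, A1)
    S12 = Q2[:, 1] - np.einsum("ij,ij->i", A1, A2)
    S22 = Q2[:, 2] - np.einsum("ij,ij->i", A2, A2)
    t1 = P[:, 2 * q] - A1 @ fy
    t2 = P[:, 2 * q + 1] - A2 @ fy

    # Schur solve of the extra 2 columns; near-collinear (r, d*r) pairs are
    # demoted to the better single column, since float32 noise in a tiny
    # determinant can otherwise fabricate perfect fits.
    wbar = float(np.mean(w))
    s_eps = 1e-6 * wbar
    det = S11 * S22 - S12**2
    ok1a = S11 > s_eps
    ok1b = S22 > s_eps
    ok2 = ok1a & ok1b & (det > 1e-6 * S11 * S22)
    with np.errstate(divide="ignore", invalid="ignore"):
        e2 = (S22 * t1**2 - 2.0 * S12 * t1 * t2 + S11 * t2**2) / det
        e1a = np.where(ok1a, t1**2 / np.maximum(S11, s_eps), 0.0)
        e1b = np.where(ok1b, t2**2 / np.maximum(S22, s_eps), 0.0)
    e1 = np.maximum(e1a, e1b)
    extra = np.where(ok2 & (e2 >= e1) & (e2 <= rss_F * (1.0 + 1e-3)), e2, e1)
    rss = np.maximum(rss_F - np.minimum(extra, rss_F), 0.0)
    return rss / len(y)


def grid_search(
    y,
    w,
    schedule: Schedule,
    ws: WeatherSeries,
    factors=ATTRIBUTES,
    grid: GridSpec | None = None,
    *,
    library: FeatureLibrary | None = None,
) -> tuple[ResponseParams, str, np.ndarray, float]:
    """Exhaustive search of the response-parameter grid over all factors.

    For every factor x grid point the design matrix is (implicitly) rebuilt
    and scored by weighted least squares; the global minimizer wins, with
    ties broken by enumeration order (factor listing order, then the
    lexicographic grid order).  Returns the best parameters, the winning
    factor, the pilot WLS coefficients at that setting, and its weighted MSE.
    """
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if len(schedule) < 10:
        raise ValueError("need at least 10 samples")
    grid = grid or GridSpec()
    if library is None:
        library = FeatureLibrary(ws, schedule, grid, factors)
    F, d = _fixed_columns(schedule)

    best = (np.inf, None, None)
    for fac in library.factors:
        mse = _batched_mse(library.library[fac], library._squared[fac], F, d, y, w)
        i = int(np.argmin(mse))
        if mse[i] < best[0]:
            best = (float(mse[i]), fac, i)
    _, fac, i = best
    rp = library.params_at(fac, i)
    X = build_design_matrix(schedule.times, schedule.ages, schedule.genotypes, ws, rp)
    beta = wls_fit(X.values, y, w)
    resid = y - X.values @ beta
    mse = float(np.sum(w * resid**2) / len(y))
    return rp, fac, beta, mse


# ---------------------------------------------------------------------------
# Nelder-Mead refinement


def _to_vector(rp: ResponseParams) -> np.ndarray:
    return np.array([
        np.log(rp.period_p), rp.threshold_theta, rp.gamma_f,
        rp.gamma_g, rp.theta_g,
    ])


def _from_vector(u: np.ndarray, factor: str, sign_rho: int, psi: float) -> ResponseParams:
    return ResponseParams(
        factor=factor,
        period_p=float(np.exp(np.clip(u[0], -10.0, 12.0))),
        threshold_theta=float(u[1]),
        gamma_f=float(np.clip(u[2], -GAMMA_BOUND, GAMMA_BOUND)),
        gamma_g=float(np.clip(u[3], -GAMMA_BOUND, GAMMA_BOUND)),
        theta_g=float(u[4]),
        psi=psi,
        sign_rho=sign_rho,
    )


def refine_nelder_mead(init: ResponseParams, objective, options: FitOptions | None = None) -> ResponseParams:
    """Refine the continuous response parameters by Nelder-Mead.

    The memory period, threshold, and the three shape parameters are
    optimized (log memory period, clamped gammas); the gate phase psi, the
    response sign and the factor stay at their grid values, like the
    discrete settings.  The returned parameters never score worse than
    ``init``.  ``objective`` maps a ResponseParams to the weighted MSE after
    a pilot WLS fit.
    """
    options = options or FitOptions()
    x0 = _to_vector(init)
    f0 = objective(init)
    if not np.isfinite(f0):
        raise ValueError("objective not finite at the initial parameters")

    def fun(u):
        try:
            return objective(_from_vector(u, init.factor, init.sign_rho, init.psi))
        except ValueError:
            return np.inf

    simplex = np.vstack([x0] + [x0 + options.nm_step * e for e in np.eye(len(x0))])
    res = minimize(
        fun, x0, method="Nelder-Mead",
        options=dict(
            maxiter=options.nm_maxiter, fatol=options.nm_fatol,
            xatol=options.nm_xatol, initial_simplex=simplex,
        ),
    )
    if np.isfinite(res.fun) and res.fun <= f0:
        return _from_vector(res.x, init.factor, init.sign_rho, init.psi)
    return init


# ---------------------------------------------------------------------------
# Full per-gene pipeline


def _make_objective(y, w, schedule: Schedule, ws: WeatherSeries):
    """Weighted-MSE-after-pilot-WLS objective with precomputed weather arrays.

    Scoring uses the raw response feature: scaling it is affine and the fixed
    columns span the intercept and age, so the residual sum is unchanged.
    """
    from .features import gate_fn, response_fn

    times = schedule.times
    ts = ws.timestamps.asi8
    hod_u, hod_inv = np.unique(ws.hours_of_day(), return_inverse=True)
    t_i8 = times.asi8
    t_max_ns = float(t_i8.min() - ts[0])  # headroom for the memory window, ns
    hi = np.searchsorted(ts, t_i8, side="right")
    vals = {f: ws.values(f) for f in ws.attributes}
    F, d = _fixed_columns(schedule)
    keep = np.linalg.norm(F, axis=0) > 1e-12
    Fe = F[:, keep]
    sw = np.sqrt(w)
    n = len(y)
    ysw = y * sw
    wyy = float(np.sum(w * y**2))

    def objective(rp: ResponseParams) -> float:
        p_ns = rp.period_p * 3.6e12
        if p_ns > t_max_ns:
            return np.inf
        # the gate depends on time-of-day only, which has few distinct values
        g = gate_fn(hod_u, rp.psi, rp.gamma_g, rp.theta_g)[hod_inv]
        f = response_fn(vals[rp.factor] - rp.threshold_theta, rp.gamma_f, rp.sign_rho)
        csum = np.concatenate([[0.0], np.cumsum(g * f)])
        lo = np.searchsorted(ts, t_i8 - int(p_ns), side="left")
        r = csum[hi] - csum[lo]
        M = np.column_stack([Fe, r, d * r]) * sw[:, None]
        sol, rss, rank, _ = np.linalg.lstsq(M, ysw, rcond=None)
        if rank < M.shape[1] or rss.size == 0:
            resid = ysw - M @ sol
            return float(resid @ resid) / n
        return float(rss[0]) / n

    return objective


def fit_gene(
    y,
    w,
    schedule: Schedule,
    ws: WeatherSeries,
    options: FitOptions | None = None,
    *,
    gene_id: str = "gene",
    library: FeatureLibrary | None = None,
    warm_start: ResponseParams | None = None,
) -> GeneModel:
    """Fit one gene end to end (grid search unless warm-started).

    Pipeline: grid search -> Nelder-Mead -> pilot WLS -> adaptive weights ->
    group-lasso path with approximate LOO-CV -> one-SE lambda.  If every
    penalized group is zero at the selected lambda the gene gets the constant
    model (factor "none", no response parameters).
    """
    options = options or FitOptions()
    y = np.asarray(y, float)
    w = np.ones_like(y) if w is None else np.asarray(w, float)
    if len(y) != len(schedule):
        raise ValueError("expression vector length does not match the schedule")
    if ws.cadence != options.integration_step:
        ws = resample_weather(ws, options.integration_step)

    objective = _make_objective(y, w, schedule, ws)

    if warm_start is None:
        rp0, _, _, _ = grid_search(
            y, w, schedule, ws, options.factors, options.grid, library=library
        )
    else:
        rp0 = warm_start
    rp = refine_nelder_mead(rp0, objective, options)
    pilot_mse = objective(rp)

    X = build_design_matrix(schedule.times, schedule.ages, schedule.genotypes, ws, rp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta_tilde = wls_fit(X.values, y, w)
    pen = adaptive_weights(beta_tilde)
    path = lasso_path(
        X.values, y, w, pen,
        n_lambdas=options.n_lambdas, lambda_min_ratio=options.lambda_min_ratio,
    )
    lam = select_lambda(path)
    i = int(np.nonzero(path.lambdas == lam)[0][0])
    beta = path.coefficients[i].copy()

    has_response = any(beta[j] != 0.0 for j in _RESP_COLS)
    return GeneModel(
        gene_id=gene_id,
        coefficients=beta,
        scale_specs=X.scale_specs,
        selected_lambda=lam,
        cv_error=float(path.cv_error[i]),
        factor=rp.factor if has_response else "none",
        response_params=rp if has_response else None,
        weights_used=options.weights_used,
        warm_params=rp,
        pilot_mse=float(pilot_mse),
    )


def fit_genes(
    Y,
    w,
    schedule: Schedule,
    ws: WeatherSeries,
    options: FitOptions | None = None,
    *,
    gene_ids=None,
    library: FeatureLibrary | None = None,
) -> FitResult:
    """Full (non-clustered) fit of every row of a gene x sample matrix."""
    options = options or FitOptions()
    Y, W, gene_ids = _as_matrix(Y, w, gene_ids)
    if ws.cadence != options.integration_step:
        ws = resample_weather(ws, options.integration_step)
    if library is None:
        library = FeatureLibrary(ws, schedule, options.grid, options.factors)
    models = [
        fit_gene(Y[i], W[i], schedule, ws, options, gene_id=gene_ids[i], library=library)
        for i in range(Y.shape[0])
    ]
    return FitResult(models=models, diagnostics={"grid_search_calls": Y.shape[0]})


def _as_matrix(Y, w, gene_ids):
    if isinstance(Y, pd.DataFrame):
        if gene_ids is None:
            gene_ids = list(Y.index)
        Y = Y.to_numpy(float)
    else:
        Y = np.asarray(Y, float)
    if gene_ids is None:
        gene_ids = [f"gene{i + 1}" for i in range(Y.shape[0])]
    if w is None:
        W = np.ones_like(Y)
    else:
        W = w.to_numpy(float) if isinstance(w, pd.DataFrame) else np.asarray(w, float)
        if W.shape != Y.shape:
            raise ValueError("weight matrix shape does not match the expression matrix")
    return Y, W, list(gene_ids)


def cluster_fit(
    Y,
    w,
    schedule: Schedule,
    ws: WeatherSeries,
    options: FitOptions | None = None,
    *,
    gene_ids=None,
    random_state: int = 0,
) -> FitResult:
    """Cluster-based optimization: full fits for exemplars, warm starts for the rest.

    Expression patterns are z-scored per gene and clustered by affinity
    propagation (negative Euclidean similarity, median preference, damping
    0.9).  Each exemplar gets the full two-step optimization; other genes in
    the cluster skip the grid search and start Nelder-Mead from the
    exemplar's refined parameters (factor inherited).  If clustering fails to
    converge the fit falls back to full per-gene optimization, with a warning.
    """
    from sklearn.cluster import AffinityPropagation

    options = options or FitOptions()
    Y, W, gene_ids = _as_matrix(Y, w, gene_ids)
    n_genes = Y.shape[0]
    if n_genes < 2:
        raise ValueError("cluster_fit needs at least 2 genes")
    if ws.cadence != options.integration_step:
        ws = resample_weather(ws, options.integration_step)

    sd = Y.std(axis=1, ddof=0)
    Z = (Y - Y.mean(axis=1, keepdims=True)) / np.maximum(sd, 1e-8)[:, None]
    D = np.sqrt(np.maximum(
        (Z**2).sum(1)[:, None] + (Z**2).sum(1)[None, :] - 2.0 * Z @ Z.T, 0.0
    ))
    S = -D
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap = AffinityPropagation(
            affinity="precomputed", damping=0.9, preference=np.median(S),
            random_state=random_state, max_iter=500,
        ).fit(S)
    centers = np.asarray(ap.cluster_centers_indices_)
    labels = np.asarray(ap.labels_)
    if centers.size == 0 or np.any(labels < 0):
        warnings.warn("affinity propagation did not converge; falling back to full per-gene fits")
        res = fit_genes(Y, W, schedule, ws, options, gene_ids=gene_ids)
        res.cluster_labels = None
        return res

    library = FeatureLibrary(ws, schedule, options.grid, options.factors)
    models: list[GeneModel | None] = [None] * n_genes
    for c in centers:
        models[c] = fit_gene(
            Y[c], W[c], schedule, ws, options, gene_id=gene_ids[c], library=library
        )
    for i in range(n_genes):
        if models[i] is not None:
            continue
        exemplar = models[centers[labels[i]]]
        models[i] = fit_gene(
            Y[i], W[i], schedule, ws, options,
            gene_id=gene_ids[i], warm_start=exemplar.warm_params,
        )
    return FitResult(
        models=models,
        cluster_labels=labels,
        exemplars=[gene_ids[c] for c in centers],
        diagnostics={"grid_search_calls": int(centers.size), "n_clusters": int(centers.size)},
    )
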