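"""Prediction and model assessment: R^2, clock phases, response curves,
and recovery summaries against synthetic generative truths."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import COLUMN_ROLES, build_design_matrix, response_fn
from .optimize import GeneModel
from .weather import WeatherSeries

_COS = COLUMN_ROLES.index("clock_cos")
_SIN = COLUMN_ROLES.index("clock_sin")
_RESP = COLUMN_ROLES.index("response")


def predict_expression(model: GeneModel, schedule, ws: WeatherSeries) -> np.ndarray:
    """Noise-free predicted expression for new samples.

    The design matrix is rebuilt with the *training* scale specs applied to
    the new age and response columns; the response feature needs weather
    coverage of the prediction window plus the model's memory period.
    """
    if not model.scale_specs:
        raise ValueError("model carries no scale specs; cannot predict")
    if model.response_params is None:
        # constant / clock-only model: any factor works for the (zeroed) r column
        from .features import ResponseParams

        rp = ResponseParams(
            factor="temperature", period_p=1e-9, threshold_theta=np.inf,
            gamma_f=0.0, gamma_g=0.0, theta_g=-2.0, psi=0.0, sign_rho=1,
        )
    else:
        rp = model.response_params
    X = build_design_matrix(
        schedule.times, schedule.ages, schedule.genotypes, ws, rp,
        scale_specs=model.scale_specs,
    )
    return X.values @ model.coefficients


def r_squared(obs, pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (can be negative)."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observations are constant; R^2 undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def phase_of(model_or_coefs) -> float:
    """Clock phase in hours: arg(beta_cos + i beta_sin) mapped to [0, 24)."""
    if isinstance(model_or_coefs, GeneModel):
        bc, bs = model_or_coefs.coefficients[_COS], model_or_coefs.coefficients[_SIN]
    else:
        bc, bs = model_or_coefs
    if bc == 0 and bs == 0:
        raise ValueError("both clock coefficients are zero; phase undefined")
    return float(np.arctan2(bs, bc) * 24.0 / (2.0 * np.pi)) % 24.0


def circular_phase_error(a: float, b: float) -> float:
    """Shortest distance between two phases on the 24-h circle, in [0, 12]."""
    d = abs(a - b) % 24.0
    return min(d, 24.0 - d)


def response_curve(model: GeneModel, value_grid) -> np.ndarray:
    """Fitted response to the raw factor value: beta_r * f(T - theta).

    Reconstructs the thresholded nonlinearity on the factor's own scale so
    fitted and generative response shapes can be compared directly.
    """
    if model.response_params is None:
        raise ValueError("model has no response term")
    rp = model.response_params
    beta_r = model.coefficients[_RESP]
    grid = np.asarray(value_grid, float)
    return beta_r * response_fn(grid - rp.threshold_theta, rp.gamma_f, rp.sign_rho)


@dataclass
class RecoverySummary:
    """Structure-recovery bookkeeping for a synthetic benchmark fit."""

    structure_match: pd.Series          # gene_id -> bool (exact nonzero-pattern match)
    confusion: pd.DataFrame             # true factor x selected factor counts
    phase_errors: pd.Series             # gene_id -> circular error (hours)
    n_variable_correct: int
    n_constant_correct: int
    n_variable: int
    n_constant: int


def recovery_summary(models, truths) -> RecoverySummary:
    """Compare fitted models to their generative truths by gene id.

    A gene counts as recovered when the set of non-zero penalized groups in
    the fitted model equals the truth's expected groups (response coefficient
    signs are not compared: a dose-independent response mirrored about its
    threshold is observationally equivalent up to a constant).  Phase errors
    are circular distances for genes whose truth and fit both carry a clock.
    """
    by_id = {m.gene_id: m for m in models}
    missing = [t.gene_id for t in truths if t.gene_id not in by_id]
    if missing:
        raise ValueError(f"no fitted model for genes: {missing[:5]}")

    match, phase_err = {}, {}
    rows = []
    n_var_ok = n_const_ok = n_var = n_const = 0
    for t in truths:
        m = by_id[t.gene_id]
        fitted = m.nonzero_groups()
        ok = fitted == t.structure
        match[t.gene_id] = ok
        if t.is_constant:
            n_const += 1
            n_const_ok += ok
        else:
            n_var += 1
            n_var_ok += ok
        true_factor = t.response_params.factor if t.response_params is not None else "none"
        rows.append((true_factor, m.factor))
        if t.clock_amp and "clock" in fitted:
            phase_err[t.gene_id] = circular_phase_error(t.clock_phase, phase_of(m))
    conf = (
        pd.DataFrame(rows, columns=["true", "selected"])
        .value_counts()
        .unstack(fill_value=0)
    )
    return RecoverySummary(
        structure_match=pd.Series(match),
        confusion=conf,
        phase_errors=pd.Series(phase_err, dtype=float),
        n_variable_correct=n_var_ok,
        n_constant_correct=n_const_ok,
        n_variable=n_var,
        n_constant=n_const,
    )
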