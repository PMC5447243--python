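"""Model features: unified response and gate functions, clock basis, the
environmental-response covariate, scaling, and design-matrix construction.

The per-gene expression model is a linear regression

    s = X beta + eps,
    X = (1, d, cos, sin, r, d*cos, d*sin, d*r, n)

where ``d`` is the plant's age (days after transplanting, scaled to mean 0 /
range 1), ``cos``/``sin`` are a 24-h harmonic basis for the circadian clock,
``r`` integrates a nonlinear, gated, thresholded response to one weather
attribute over a gene-specific memory period, and ``n`` is a binary genotype
indicator.  The response nonlinearity interpolates continuously between a
dose-dependent ramp and a dose-independent step; the gate restricts the time
of day at which the stimulus is sensed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weather import ATTRIBUTES, WeatherSeries

#: Design-matrix columns, in order.
COLUMN_ROLES = (
    "intercept",
    "age",
    "clock_cos",
    "clock_sin",
    "response",
    "age_clock_cos",
    "age_clock_sin",
    "age_response",
    "genotype",
)

#: Shape-parameter clamp used during optimization; beyond this the response and
#: gate are numerically indistinguishable from their analytic limits.
GAMMA_BOUND = 10.0


@dataclass(frozen=True)
class ResponseParams:
    """Environmental-response parameters for one gene.

    Attributes
    ----------
    factor : weather attribute the gene responds to.
    period_p : memory period in hours (stimuli within ``[t - p, t]`` count).
    threshold_theta : response threshold, in the attribute's own units.
    gamma_f : response shape; very negative = dose-dependent ramp, very
        positive = dose-independent step.
    gamma_g : gate sharpness; large values give a rectangular gate.
    theta_g : gate threshold; below -1 the gate is effectively always open.
    psi : gate phase in hours in [0, 24) (time of maximal aperture).
    sign_rho : +1 responds above the threshold, -1 below.
    """

    factor: str
    period_p: float
    threshold_theta: float
    gamma_f: float
    gamma_g: float
    theta_g: float
    psi: float
    sign_rho: int

    def __post_init__(self):
        if self.factor not in ATTRIBUTES:
            raise ValueError(f"unknown factor {self.factor!r}")
        if not self.period_p > 0:
            raise ValueError("period_p must be positive")
        if self.sign_rho not in (+1, -1):
            raise ValueError("sign_rho must be +1 or -1")
        object.__setattr__(self, "psi", float(self.psi) % 24.0)

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "period_p": self.period_p,
            "threshold_theta": self.threshold_theta,
            "gamma_f": self.gamma_f,
            "gamma_g": self.gamma_g,
            "theta_g": self.theta_g,
            "psi": self.psi,
            "sign_rho": self.sign_rho,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseParams":
        return cls(**d)


@dataclass(frozen=True)
class ScaleSpec:
    """Affine scaling fitted on training data: ``x -> (x - offset) / scale``.

    On the training vector the result has mean 0 and range 1.  A constant
    training vector yields a degenerate spec that maps everything to 0 (the
    column is then dropped by the penalty).
    """

    offset: float
    scale: float = 1.0
    degenerate: bool = False

    def apply(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.degenerate:
            return np.zeros_like(v)
        return (v - self.offset) / self.scale

    def to_dict(self) -> dict:
        return {"offset": self.offset, "scale": self.scale, "degenerate": self.degenerate}

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleSpec":
        return cls(**d)


def scale_unit_range(v) -> tuple[np.ndarray, ScaleSpec]:
    """Scale a vector to mean 0 and range 1; returns the reusable spec."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to scale")
    rng = float(v.max() - v.min())
    if rng == 0.0:
        spec = ScaleSpec(offset=float(v.mean()), scale=1.0, degenerate=True)
        return np.zeros_like(v), spec
    spec = ScaleSpec(offset=float(v.mean()), scale=rng)
    return spec.apply(v), spec


def response_fn(x, gamma_f: float, sign_rho: int):
    """Unified environmental response ``max(0, tanh(rho e^g x)) sqrt(e^{-2g}+1)``.

    Approaches the dose-dependent ramp ``max(0, rho*x)`` as ``gamma_f -> -inf``
    and the dose-independent 0/1 step as ``gamma_f -> +inf``; zero on the
    inactive side of the threshold.
    """
    x = np.asarray(x, dtype=float)
    z = np.tanh(sign_rho * np.exp(gamma_f) * x)
    return np.maximum(0.0, z) * np.sqrt(np.exp(-2.0 * gamma_f) + 1.0)


def _log_cosh(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    small = ax < 20.0
    out = ax - np.log(2.0)
    out = out + np.log1p(np.exp(-2.0 * ax))
    return np.where(small, np.log(np.cosh(np.where(small, x, 0.0))), out)


def _log_sinh(x: np.ndarray) -> np.ndarray:
    """log(sinh(x)) for x >= 0; -inf at 0."""
    x = np.asarray(x, dtype=float)
    big = x >= 20.0
    out = np.where(big, x, 1.0) - np.log(2.0) + np.log1p(-np.exp(-2.0 * np.maximum(x, 20.0)))
    with np.errstate(divide="ignore"):
        small = np.log(np.sinh(np.where(big, 1.0, x)))
    return np.where(big, out, small)


#: tanh saturates to exactly 1.0 in double precision beyond this argument.
_TANH_SAT = 19.0


def gate_fn(T, psi: float, gamma_g: float, theta_g: float):
    """24-h-periodic gate aperture in [0, 1], equal to 1 at ``T = psi``.

    With ``h(C) = tanh(e^{gamma_g} (C - theta_g))`` and
    ``C = cos(2 pi (T - psi) / 24)`` the gate is
    ``(h(C) - h(-1)) / (h(1) - h(-1))``, computed in log space for stability.
    When tanh is saturated in double precision (|theta_g| > 1 with a large
    gamma_g) the analytic limit is returned: fully open for ``theta_g < -1``,
    fully closed for ``theta_g > 1``.
    """
    T = np.asarray(T, dtype=float)
    eg = np.exp(gamma_g)
    a = eg * (1.0 - theta_g)   # argument at C = +1
    b = eg * (-1.0 - theta_g)  # argument at C = -1
    if theta_g < -1.0 and b >= _TANH_SAT:
        return np.ones_like(T)
    if theta_g > 1.0 and -a >= _TANH_SAT:
        return np.zeros_like(T)
    C = np.cos(2.0 * np.pi * (T - psi) / 24.0)
    c = eg * (C - theta_g)
    # tanh(x)-tanh(y) = sinh(x-y)/(cosh x cosh y); all differences are >= 0 here
    log_num = _log_sinh(c - b) + _log_cosh(np.asarray(a))
    log_den = _log_sinh(np.asarray(a - b)) + _log_cosh(c)
    with np.errstate(invalid="ignore"):
        g = np.exp(log_num - log_den)
    return np.clip(np.where(np.isfinite(g), g, 0.0), 0.0, 1.0)


def clock_basis(sample_times) -> np.ndarray:
    """N x 2 matrix of (cos, sin) of the 24-h clock at each sampling time."""
    t = _hours_of_day(sample_times)
    ang = 2.0 * np.pi * t / 24.0
    return np.column_stack([np.cos(ang), np.sin(ang)])


def _hours_of_day(sample_times) -> np.ndarray:
    idx = pd.DatetimeIndex(sample_times)
    return (
        idx.hour.to_numpy()
        + idx.minute.to_numpy() / 60.0
        + idx.second.to_numpy() / 3600.0
        + idx.microsecond.to_numpy() / 3.6e9
    )


def env_response_feature(ws: WeatherSeries, sample_times, rp: ResponseParams) -> np.ndarray:
    """Integrated, gated environmental response for each sample (unscaled).

    Element j sums ``gate(T) * response(w_T - theta)`` over weather steps T in
    the closed window ``[t_j - p, t_j]``.  The weather record must cover the
    whole window for every sample.
    """
    times = pd.DatetimeIndex(sample_times)
    p = pd.Timedelta(hours=rp.period_p)
    if not ws.covers(times.min() - p, times.max()):
        raise ValueError(
            f"weather record does not cover [{times.min() - p}, {times.max()}] "
            f"needed for period_p={rp.period_p} h"
        )
    g = gate_fn(ws.hours_of_day(), rp.psi, rp.gamma_g, rp.theta_g)
    f = response_fn(ws.values(rp.factor) - rp.threshold_theta, rp.gamma_f, rp.sign_rho)
    csum = np.concatenate([[0.0], np.cumsum(g * f)])
    ts = ws.timestamps.asi8
    hi = np.searchsorted(ts, times.asi8, side="right")
    lo = np.searchsorted(ts, (times - p).asi8, side="left")
    return csum[hi] - csum[lo]


@dataclass
class DesignMatrix:
    """N x 9 covariate matrix with column metadata and training scale specs."""

    values: np.ndarray
    column_roles: tuple[str, ...] = COLUMN_ROLES
    scale_specs: dict = field(default_factory=dict)
    sample_ids: list | None = None

    def column(self, role: str) -> np.ndarray:
        return self.values[:, self.column_roles.index(role)]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def build_design_matrix(
    sample_times,
    ages,
    genotypes,
    ws: WeatherSeries,
    rp: ResponseParams,
    *,
    scale_specs: dict | None = None,
    sample_ids=None,
) -> DesignMatrix:
    """Assemble the 9-column design matrix for one gene.

    ``ages`` (days after transplanting) and the response feature are scaled to
    mean 0 / range 1 on the training data; interactions are products of the
    *scaled* columns.  Pass ``scale_specs`` (from training) to build a
    prediction design for new samples.
    """
    times = pd.DatetimeIndex(sample_times)
    ages = np.asarray(ages, dtype=float)
    genotypes = np.asarray(genotypes, dtype=float)
    n = len(times)
    if not (len(ages) == len(genotypes) == n):
        raise ValueError("sample_times, ages and genotypes must have equal length")
    if not np.all(np.isin(genotypes, (0.0, 1.0))):
        raise ValueError("genotype values must be 0 or 1")
    training = scale_specs is None
    if training and n < 10:
        raise ValueError("need at least 10 samples to fit")

    r_raw = env_response_feature(ws, times, rp)
    if training:
        d, d_spec = scale_unit_range(ages)
        r, r_spec = scale_unit_range(r_raw)
        scale_specs = {"age": d_spec, "response": r_spec}
    else:
        d = scale_specs["age"].apply(ages)
        r = scale_specs["response"].apply(r_raw)

    clock = clock_basis(times)
    X = np.column_stack(
        [
            np.ones(n),
            d,
            clock[:, 0],
            clock[:, 1],
            r,
            d * clock[:, 0],
            d * clock[:, 1],
            d * r,
            genotypes,
        ]
    )
    return DesignMatrix(values=X, scale_specs=scale_specs, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# Sample attribute table


@dataclass
class Schedule:
    """Sampling schedule: timestamps, ages and genotypes for each sample."""

    times: pd.DatetimeIndex
    ages: np.ndarray
    genotypes: np.ndarray
    sample_ids: list

    def __post_init__(self):
        self.times = pd.DatetimeIndex(self.times)
        self.ages = np.asarray(self.ages, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if not (len(self.times) == len(self.ages) == len(self.genotypes) == len(self.sample_ids)):
            raise ValueError("schedule fields must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "time": self.times,
                "age": self.ages,
                "genotype": self.genotypes.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Schedule":
        df = pd.read_csv(path, parse_dates=["time"])
        return cls(
            times=pd.DatetimeIndex(df["time"]),
            ages=df["age"].to_numpy(float),
            genotypes=df["genotype"].to_numpy(float),
            sample_ids=df["sample_id"].tolist(),
        )
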