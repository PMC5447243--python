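"""Synthetic benchmark: sampling designs, generative gene models, NB counts.

The benchmark emulates a field experiment in which rice plants are
transplanted on June 1 and leaf samples are collected weekly from June 12 to
September 18 around the clock.  Five designs trade time resolution against
replication (2-h x1, 4-h x2, 6-h x3, 8-h x4, 12-h x6); each totals 180
samples.  Expression truths combine a circadian clock, a gated nonlinear
response to temperature, and an age trend; read counts are drawn from a
negative binomial with a mean-dispersion trend.  Constant genes are included
to stabilize library sizes on the counts-per-million scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import ResponseParams, Schedule, env_response_feature, _hours_of_day
from .weather import WeatherSeries, synth_weather

#: The five sampling designs: id -> (interval hours, replicates per time).
DESIGNS = {"2h": (2, 1), "4h": (4, 2), "6h": (6, 3), "8h": (8, 4), "12h": (12, 6)}

_TRANSPLANT = (6, 1)  # June 1
_FIRST_DATE = (6, 12)
_N_WEEKS = 15


def sampling_design(design_id: str, year: int = 2008) -> Schedule:
    """Weekly 24-h sampling schedule for one of the five benchmark designs.

    15 weekly dates from June 12 to September 18; per date, 24 h of slots at
    the design's interval with its replicate count (12 slots/day, 180 total).
    Ages are days since the June 1 transplanting.  The 2009 evaluation set
    uses ``sampling_design("2h", year=2009)``.
    """
    if design_id not in DESIGNS:
        raise ValueError(f"unknown design_id {design_id!r}; choose from {sorted(DESIGNS)}")
    interval, reps = DESIGNS[design_id]
    transplant = pd.Timestamp(year=year, month=_TRANSPLANT[0], day=_TRANSPLANT[1])
    first = pd.Timestamp(year=year, month=_FIRST_DATE[0], day=_FIRST_DATE[1])
    times, ages, ids = [], [], []
    for wk in range(_N_WEEKS):
        date = first + pd.Timedelta(days=7 * wk)
        age = (date - transplant).days
        for hour in range(0, 24, interval):
            for rep in range(reps):
                times.append(date + pd.Timedelta(hours=hour))
                ages.append(age)
                ids.append(f"{date.date()}_h{hour:02d}_r{rep + 1}")
    n = len(times)
    return Schedule(
        times=pd.DatetimeIndex(times), ages=np.array(ages, float),
        genotypes=np.zeros(n), sample_ids=ids,
    )


def schedule_fixture_2008() -> Schedule:
    """The six 2008 field sampling groups (461 samples in total)."""
    times, ids = [], []

    def add(ts, tag):
        for k, t in enumerate(ts):
            times.append(t)
            ids.append(f"{tag}_{len(times):03d}")

    # 24 h at 2-h intervals from 7:00 Aug 12, 8 replicates x 13 time points = 104
    base = pd.Timestamp("2008-08-12 07:00")
    add([base + pd.Timedelta(hours=2 * i) for i in range(13) for _ in range(8)], "g1")
    # 48 h at 2-h intervals from 10:00 on nine dates, 25 points each = 225
    for d in ["2008-06-05", "2008-06-19", "2008-07-03", "2008-07-17", "2008-08-07",
              "2008-08-14", "2008-08-21", "2008-08-28", "2008-09-11"]:
        base = pd.Timestamp(d) + pd.Timedelta(hours=10)
        add([base + pd.Timedelta(hours=2 * i) for i in range(25)], "g2")
    # noon, 17 weekly dates Jun 3 - Sep 23, 3 replicates = 51
    for wk in range(17):
        t = pd.Timestamp("2008-06-03 12:00") + pd.Timedelta(days=7 * wk)
        add([t] * 3, "g3")
    # midnight, 17 weekly dates Jun 4 - Sep 24, 2 replicates = 34
    for wk in range(17):
        t = pd.Timestamp("2008-06-04 00:00") + pd.Timedelta(days=7 * wk)
        add([t] * 2, "g4")
    # 17:00-20:00 at 10-min intervals on Aug 7 = 19
    base = pd.Timestamp("2008-08-07 17:00")
    add([base + pd.Timedelta(minutes=10 * i) for i in range(19)], "g5")
    # 3:50-6:00 at 10-min intervals on Aug 8, 2 replicates x 14 points = 28
    base = pd.Timestamp("2008-08-08 03:50")
    add([base + pd.Timedelta(minutes=10 * i) for i in range(14) for _ in range(2)], "g6")

    return _finish_fixture(times, ids, year=2008)


def schedule_fixture_2009() -> Schedule:
    """The six 2009 evaluation sampling groups (108 samples in total)."""
    times, ids = [], []

    def add(ts, tag):
        for t in ts:
            times.append(t)
            ids.append(f"{tag}_{len(times):03d}")

    # 48 h at 6-h intervals from noon Aug 10, 2 replicates x 9 points = 18
    base = pd.Timestamp("2009-08-10 12:00")
    add([base + pd.Timedelta(hours=6 * i) for i in range(9) for _ in range(2)], "g1")
    # 24 h at 2-h intervals from 7:00 Aug 24, 6 replicates x 13 points = 78
    base = pd.Timestamp("2009-08-24 07:00")
    add([base + pd.Timedelta(hours=2 * i) for i in range(13) for _ in range(6)], "g2")
    add([pd.Timestamp("2009-08-31 12:00")] * 2, "g3")
    add([pd.Timestamp("2009-08-31 18:00")] * 2, "g4")
    add([pd.Timestamp("2009-10-08 11:00")] * 4, "g5")
    add([pd.Timestamp("2009-10-09 11:00")] * 4, "g6")

    return _finish_fixture(times, ids, year=2009)


def _finish_fixture(times, ids, year):
    idx = pd.DatetimeIndex(times)
    transplant = pd.Timestamp(year=year, month=6, day=1)
    ages = np.array([(t - transplant).days for t in idx], float)
    return Schedule(times=idx, ages=ages, genotypes=np.zeros(len(idx)), sample_ids=ids)


def dispersion_trend(mean_expression: float, phi0: float = 0.05, a: float = 3.0) -> float:
    """Parametric mean-dispersion trend phi(mu) = phi0 + a/mu.

    A monotone-decreasing stand-in with values typical of published bulk
    RNA-Seq trends (asymptotic overdispersion ~0.05, strong extra-Poisson
    noise at low counts); injectable wherever a dispersion is needed.
    """
    mu = np.asarray(mean_expression, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mean expression must be positive")
    out = phi0 + a / mu
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative model for one simulated gene (effects in log2 units).

    ``alpha`` is the natural log of the gene's average expression.  The
    per-sample log2 mean combines centered effect terms,

        alpha/ln 2 + clock_amp * c0(t)  +  age_coef * d
                   + response_amp * r0  +  age_clock_amp * d * c0
                   + age_response_amp * d * r0  -  (normalizer),

    where ``c0`` is the (cos+1)/2 clock curve centered over the schedule,
    ``r0`` the centered unit-range environmental response, ``d`` the scaled
    age, and the normalizer keeps the linear-scale average expression equal
    to exp(alpha) exactly.
    """

    gene_id: str
    alpha: float
    dispersion: float
    clock_amp: float = 0.0
    clock_phase: float = 0.0
    age_coef: float = 0.0
    response_amp: float = 0.0
    response_params: ResponseParams | None = None
    age_clock_amp: float = 0.0
    age_response_amp: float = 0.0

    @property
    def is_constant(self) -> bool:
        return not (
            self.clock_amp or self.age_coef or self.response_amp
            or self.age_clock_amp or self.age_response_amp
        )

    @property
    def structure(self) -> frozenset[str]:
        """Nonzero groups expected in the fitted design basis.

        The truth clock uses the (cos+1)/2 convention, so an age x clock
        effect also loads the age column; likewise the unit-interval response
        makes an age x response effect load the age column.
        """
        if self.is_constant:
            return frozenset()
        groups = set()
        if self.clock_amp:
            groups.add("clock")
        if self.response_amp:
            groups.add("response")
        if self.age_coef:
            groups.add("age")
        if self.age_clock_amp:
            groups.add("age_clock")
        if self.age_response_amp:
            groups.add("age_response")
        return frozenset(groups)

    def to_dict(self) -> dict:
        d = {
            "gene_id": self.gene_id, "alpha": self.alpha, "dispersion": self.dispersion,
            "clock_amp": self.clock_amp, "clock_phase": self.clock_phase,
            "age_coef": self.age_coef, "response_amp": self.response_amp,
            "response_params": self.response_params.to_dict() if self.response_params else None,
            "age_clock_amp": self.age_clock_amp, "age_response_amp": self.age_response_amp,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        d = dict(d)
        rp = d.get("response_params")
        d["response_params"] = ResponseParams.from_dict(rp) if rp else None
        return cls(**d)


def _temp(p, theta, gamma_f, gamma_g, theta_g, psi, sign):
    return ResponseParams(
        factor="temperature", period_p=p, threshold_theta=theta, gamma_f=gamma_f,
        gamma_g=gamma_g, theta_g=theta_g, psi=psi, sign_rho=sign,
    )


# The 31 variable truth models: clock-only genes at assorted phases,
# temperature responses (dose-dependent and -independent, above and below
# threshold, gated and ungated, memory periods 1-48 h), age trends, and
# age interactions.  A sharp gate with threshold below -1 is always open.
_NO_GATE = dict(gamma_g=10.0, theta_g=-2.0, psi=0.0)


def _variable_models() -> list[dict]:
    m: list[dict] = []
    # 7 clock-only genes; amplitudes span the 2-3 log2-unit swings of
    # strongly rhythmic field transcripts
    for phase, amp in [(0, 2.5), (3, 3.0), (6, 2.0), (9, 2.5), (12, 3.0), (15, 2.5), (18, 2.0)]:
        m.append(dict(clock_amp=amp, clock_phase=float(phase)))
    # 2 age-only genes
    m.append(dict(age_coef=2.5))
    m.append(dict(age_coef=-2.5))
    # 2 clock + age genes
    m.append(dict(clock_amp=2.5, clock_phase=4.0, age_coef=2.0))
    m.append(dict(clock_amp=2.0, clock_phase=16.0, age_coef=-2.0))
    # 2 genes with age-modulated clock amplitude
    m.append(dict(clock_amp=2.5, clock_phase=8.0, age_clock_amp=3.5))
    m.append(dict(clock_amp=2.5, clock_phase=21.0, age_coef=2.0, age_clock_amp=3.5))
    # 11 temperature-response genes.  Thresholds sit in the tails of the summer
    # temperature distribution (heat spikes above ~29-31 C, cool nights below
    # ~19 C) so responses are episodic, as for real stress-response genes.
    m.append(dict(response_amp=3.0, response_params=_temp(6, 30, -4, sign=+1, **_NO_GATE)))
    m.append(dict(response_amp=3.0, response_params=_temp(24, 29, -4, sign=+1, **_NO_GATE)))
    m.append(dict(response_amp=3.0, response_params=_temp(6, 31, 4, sign=+1, **_NO_GATE)))
    m.append(dict(response_amp=3.0, response_params=_temp(12, 19, 4, sign=-1, **_NO_GATE)))
    m.append(dict(response_amp=3.0, response_params=_temp(3, 19, -4, sign=-1, **_NO_GATE)))
    m.append(dict(response_amp=3.0, response_params=_temp(12, 29, -4, 0.0, 0.0, 12.0, +1)))
    m.append(dict(response_amp=3.0, response_params=_temp(6, 30, 4, 0.0, 0.0, 6.0, +1)))
    m.append(dict(response_amp=3.0, response_params=_temp(6, 30, -4, 6.0, 0.5, 14.0, +1)))
    m.append(dict(response_amp=3.0, response_params=_temp(12, 19, 4, 6.0, 0.0, 4.0, -1)))
    m.append(dict(response_amp=3.0, response_params=_temp(1, 31, -4, sign=+1, **_NO_GATE)))
    m.append(dict(response_amp=3.0, response_params=_temp(48, 28, -4, sign=+1, **_NO_GATE)))
    # 3 response + clock genes
    m.append(dict(response_amp=3.0, clock_amp=2.0, clock_phase=2.0,
                  response_params=_temp(6, 30, -4, sign=+1, **_NO_GATE)))
    m.append(dict(response_amp=3.0, clock_amp=2.0, clock_phase=10.0,
                  response_params=_temp(12, 30, 4, sign=+1, **_NO_GATE)))
    m.append(dict(response_amp=3.0, clock_amp=2.0, clock_phase=18.0,
                  response_params=_temp(24, 29, -4, sign=+1, **_NO_GATE)))
    # 2 response + age genes
    m.append(dict(response_amp=3.0, age_coef=2.0,
                  response_params=_temp(12, 29, -4, sign=+1, **_NO_GATE)))
    m.append(dict(response_amp=3.0, age_coef=-2.0,
                  response_params=_temp(6, 19, 4, sign=-1, **_NO_GATE)))
    # 2 genes with age-modulated response amplitude
    m.append(dict(response_amp=3.0, age_response_amp=6.0,
                  response_params=_temp(6, 30, -4, sign=+1, **_NO_GATE)))
    m.append(dict(response_amp=3.0, age_coef=2.0, age_response_amp=6.0,
                  response_params=_temp(12, 29, -4, sign=+1, **_NO_GATE)))
    assert len(m) == 31
    return m


def truth_library(seed: int = 0, constant_genes: int = 0, dispersion_fn=dispersion_trend) -> list[SyntheticTruth]:
    """31 variable generative models plus ``constant_genes`` constant genes.

    Log average expression alpha ~ Normal(5, 1) (natural log, so mean counts
    around e^5 ~ 150); dispersions follow ``dispersion_fn`` evaluated at
    exp(alpha).  The 31 variable models are fixed equations of the benchmark
    (their alphas come from a frozen draw, like the weather record they are
    paired with); ``seed`` drives the constant genes.  Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    rng_var = np.random.default_rng(20080612)  # frozen: the 31 models are fixtures
    out = []
    for k, spec in enumerate(_variable_models()):
        alpha = float(rng_var.normal(5.0, 1.0))
        out.append(SyntheticTruth(
            gene_id=f"var{k + 1:03d}", alpha=alpha,
            dispersion=float(dispersion_fn(np.exp(alpha))), **spec,
        ))
    for k in range(constant_genes):
        alpha = float(rng.normal(5.0, 1.0))
        out.append(SyntheticTruth(
            gene_id=f"const{k + 1:04d}", alpha=alpha,
            dispersion=float(dispersion_fn(np.exp(alpha))),
        ))
    return out


def true_log2_mean(truth: SyntheticTruth, schedule: Schedule, ws: WeatherSeries) -> np.ndarray:
    """Per-sample log2 mean expression under one generative model."""
    t = _hours_of_day(schedule.times)
    ages = schedule.ages
    d = (ages - ages.mean()) / max(np.ptp(ages), 1.0)
    eff = np.zeros(len(schedule))
    if truth.clock_amp or truth.age_clock_amp:
        clk01 = (np.cos(2 * np.pi * (t - truth.clock_phase) / 24.0) + 1.0) / 2.0
        c0 = clk01 - clk01.mean()
        eff += truth.clock_amp * c0 + truth.age_clock_amp * d * c0
    if truth.age_coef:
        eff += truth.age_coef * d
    if truth.response_amp or truth.age_response_amp:
        r = env_response_feature(ws, schedule.times, truth.response_params)
        span = np.ptp(r)
        r01 = (r - r.min()) / span if span > 0 else np.zeros_like(r)
        r0 = r01 - r01.mean()
        eff += truth.response_amp * r0 + truth.age_response_amp * d * r0
    # keep the linear-scale average at exp(alpha) exactly
    return truth.alpha / np.log(2.0) + eff - np.log2(np.mean(2.0**eff))


def nb_counts(
    truth: list[SyntheticTruth], schedule: Schedule, ws: WeatherSeries, seed: int = 0
) -> pd.DataFrame:
    """Draw a gene x sample negative-binomial count matrix.

    Means are ``2**log2_mean``; counts have variance ``mu + phi mu^2``
    (``numpy`` parameterization n = 1/phi, p = 1/(1 + phi mu)).
    """
    rng = np.random.default_rng(seed)
    n = len(schedule)
    counts = np.empty((len(truth), n), dtype=np.int64)
    for i, g in enumerate(truth):
        mu = 2.0 ** true_log2_mean(g, schedule, ws)
        if not np.all(np.isfinite(mu)):
            raise ValueError(f"non-finite mean for gene {g.gene_id}")
        size = 1.0 / g.dispersion
        counts[i] = rng.negative_binomial(size, size / (size + mu))
    return pd.DataFrame(counts, index=[g.gene_id for g in truth], columns=schedule.sample_ids)


def benchmark_weather(years=(2008,), step: int = 600, seed: int = 0, params=None) -> WeatherSeries:
    """Synthetic Tsukuba-like weather covering the benchmark season(s).

    Spans May 20 to October 15 of the first through last year given, at
    cadence ``step`` seconds, leaving margin for the longest memory periods
    and the October evaluation samples.
    """
    start = pd.Timestamp(year=min(years), month=5, day=20)
    end = pd.Timestamp(year=max(years), month=10, day=15)
    return synth_weather(start, end, step=step, params=params, seed=seed)
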