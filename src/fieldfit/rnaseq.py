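"""Read-count handling: log-cpm, voom-style precision weights, pseudo-RNA-Seq.

Counts are modeled on the log2 counts-per-million scale,
``y = log2((r + 0.5) * 1e6 / (R + 1))``, and each observation receives a
precision weight ``w = lo(lambda_bar)^-4`` where ``lo`` is a LOWESS trend of
square-root residual standard deviations against mean log-counts, as in the
voom approach.  Per-gene residual standard deviations come from smoothing
each gene's log-cpm time series, so slow seasonal drift is not counted as
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

#: Floor for the fitted sqrt-sd trend; keeps weights finite where LOWESS dips.
_LO_FLOOR = 1e-4


def log_cpm(counts) -> np.ndarray:
    """log2 counts per million with 0.5 / 1.0 stabilizing offsets.

    ``counts`` is a gene x sample matrix (ndarray or DataFrame) of
    non-negative integers; library sizes are the column sums.
    """
    r = counts.to_numpy() if hasattr(counts, "to_numpy") else np.asarray(counts)
    if np.any(r < 0):
        raise ValueError("negative counts")
    R = r.sum(axis=0)
    if np.any(R <= 0):
        raise ValueError("library size (column sum) must be positive")
    y = np.log2((r + 0.5) * 1.0e6 / (R + 1.0))
    if hasattr(counts, "to_numpy"):
        return pd.DataFrame(y, index=counts.index, columns=counts.columns)
    return y


@dataclass
class VoomWeights:
    """Precision weights plus the pieces they were derived from."""

    log_cpm: np.ndarray            # gene x sample
    weights: np.ndarray            # gene x sample, strictly positive
    trend_x: np.ndarray            # mean log-counts at which lo() was fitted
    trend_y: np.ndarray            # fitted sqrt-sd values
    mean_log_counts: np.ndarray    # per gene

    def lo(self, x) -> np.ndarray:
        """Piecewise-linear sqrt-sd trend, constant beyond the fitted range."""
        return np.maximum(np.interp(x, self.trend_x, self.trend_y), _LO_FLOOR)


def _smooth_per_gene(y: np.ndarray, times: pd.DatetimeIndex, frac: float) -> np.ndarray:
    """LOWESS-smooth each gene's log-cpm over time, per calendar year."""
    fitted = np.empty_like(y)
    years = times.year.to_numpy()
    for yr in np.unique(years):
        m = years == yr
        t = (times[m] - times[m][0]).total_seconds().to_numpy() / 3600.0
        order = np.argsort(t, kind="stable")
        for i in range(y.shape[0]):
            sm = lowess(y[i, m][order], t[order], frac=frac, it=0, return_sorted=False)
            out = np.empty_like(sm)
            out[order] = sm
            fitted[i, m] = out
    return fitted


def voom_weights(counts, sample_times, *, smooth_frac: float = 0.3, trend_frac: float = 0.5) -> VoomWeights:
    """Estimate per-observation precision weights from the mean-variance trend.

    Per gene the log-cpm time series is smoothed (LOWESS, span ``smooth_frac``
    per year of data) and the residual standard deviation computed; a LOWESS
    curve (span ``trend_frac``, 3 robustness iterations) of sqrt-sd against
    mean log-count gives the piecewise-linear trend ``lo``; each smoothed
    log-cpm value is shifted to a smoothed log-count and weighted by
    ``lo(.)^-4``.
    """
    r = counts.to_numpy() if hasattr(counts, "to_numpy") else np.asarray(counts)
    n_genes, n_samples = r.shape
    if n_genes < 10 or n_samples < 10:
        raise ValueError("need at least 10 genes and 10 samples")
    times = pd.DatetimeIndex(sample_times)
    y = np.asarray(log_cpm(r), float)

    fitted = _smooth_per_gene(y, times, smooth_frac)
    sigma = np.std(y - fitted, axis=1, ddof=1)

    R = r.sum(axis=0)
    log_R_bar = float(np.mean(np.log2(R + 1.0)))  # geometric mean of (R_j + 1)
    mean_log_counts = y.mean(axis=1) + log_R_bar - np.log2(1.0e6)
    if np.ptp(mean_log_counts) == 0:
        raise ValueError("degenerate mean-variance trend: all mean log-counts identical")

    sqrt_sd = np.sqrt(sigma)
    smoothed = lowess(sqrt_sd, mean_log_counts, frac=trend_frac, it=3, return_sorted=True)
    tx, ty = smoothed[:, 0], smoothed[:, 1]
    tx, uniq = np.unique(tx, return_index=True)
    ty = ty[uniq]

    # smoothed log-cpm -> smoothed log-count, per sample's own library size
    lam_bar = fitted + (np.log2(R + 1.0) - np.log2(1.0e6))[None, :]
    lo_vals = np.maximum(np.interp(lam_bar, tx, ty), _LO_FLOOR)
    w = lo_vals**-4
    return VoomWeights(
        log_cpm=y, weights=w, trend_x=tx, trend_y=ty, mean_log_counts=mean_log_counts
    )


def pseudo_rnaseq(signals, total_reads: int = 100_000_000, seed: int = 0) -> np.ndarray:
    """Draw multinomial read counts from log2-intensity signals.

    Per sample, counts ~ Multinomial(R, p) with p the base-2 softmax of the
    column's signals; column sums equal ``total_reads`` exactly.
    """
    s = signals.to_numpy() if hasattr(signals, "to_numpy") else np.asarray(signals, float)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite signals")
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty_like(s, dtype=np.int64)
    for j in range(s.shape[1]):
        col = s[:, j] - s[:, j].max()
        p = np.exp2(col)
        p /= p.sum()
        out[:, j] = rng.multinomial(total_reads, p)
    if hasattr(signals, "to_numpy"):
        return pd.DataFrame(out, index=signals.index, columns=signals.columns)
    return out
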