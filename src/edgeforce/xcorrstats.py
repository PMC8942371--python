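"""Lagged cross-correlation among per-window signal time series.

Correlations are computed per event (per window series pair) at each lag
over the overlapping segment, then averaged across events, preserving the
event count at every lag. The sign convention: ``corr(lag)`` correlates
``x(t)`` with ``y(t + lag)``, so a positive peak lag means y follows x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["XCorrResult", "cross_correlate", "peak_lag"]


@dataclass
class XCorrResult:
    lags_s: np.ndarray
    corr: np.ndarray  # ensemble mean correlation per lag (NaN if no events)
    n_pairs: np.ndarray  # events contributing per lag
    center_variable: str = "x"
    other_variable: str = "y"

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)


def _pearson(a: np.ndarray, b: np.ndarray, min_overlap: int = 4) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_overlap:
        return np.nan
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def cross_correlate(
    x_series_set,
    y_series_set,
    max_lag_s: float = 120.0,
    dt_s: float = 10.0,
    center_variable: str = "x",
    other_variable: str = "y",
    min_overlap: int = 4,
) -> XCorrResult:
    """Event-averaged lagged Pearson correlation.

    ``x_series_set`` and ``y_series_set`` are paired lists of equally sampled
    1D series (one pair per event/window). Missing samples are pairwise
    deleted; an event contributes at a lag only if the overlap has at least
    ``min_overlap`` points.
    """
    if len(x_series_set) != len(y_series_set):
        raise ValueError("x and y sets must be paired")
    if len(x_series_set) == 0:
        raise ValueError("empty series sets")
    max_lag = int(round(max_lag_s / dt_s))
    lags = np.arange(-max_lag, max_lag + 1)
    corr_sum = np.zeros(lags.size)
    n_pairs = np.zeros(lags.size, dtype=int)
    for x, y in zip(x_series_set, y_series_set):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise ValueError("paired series must have equal length")
        for i, lag in enumerate(lags):
            # correlate x(t) with y(t + lag)
            if lag >= 0:
                a, b = x[: x.size - lag], y[lag:]
            else:
                a, b = x[-lag:], y[: y.size + lag]
            r = _pearson(a, b, min_overlap)
            if np.isfinite(r):
                corr_sum[i] += r
                n_pairs[i] += 1
    with np.errstate(invalid="ignore"):
        corr = np.where(n_pairs > 0, corr_sum / np.maximum(n_pairs, 1), np.nan)
    return XCorrResult(lags_s=lags * dt_s, corr=corr, n_pairs=n_pairs,
                       center_variable=center_variable, other_variable=other_variable)


def peak_lag(result: XCorrResult, mode: str = "max") -> float:
    """Lag (s) of the correlation extremum; ties break toward smallest |lag|."""
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    c = result.corr
    ok = np.isfinite(c)
    if not ok.any():
        raise ValueError("no finite correlations")
    target = np.nanmax(c) if mode == "max" else np.nanmin(c)
    candidates = np.flatnonzero(ok & np.isclose(c, target))
    best = candidates[np.argmin(np.abs(result.lags_s[candidates]))]
    return float(result.lags_s[best])
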