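"""Protrusion/retraction event detection, alignment, and ensemble statistics.

Edge-sector displacement series are smoothed with a cubic smoothing spline,
partitioned into protrusion (rising) and retraction (falling) phases at the
local extrema of displacement, and filtered: phases moving less than
1 um or lasting less than 1 min are discarded. Retained events are aligned
at one of four anchors (protrusion/retraction onset or Vmax) and per-depth
ensemble means with bootstrap confidence intervals are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline


def _nanmean(a, axis):
    """nanmean that quietly returns NaN for all-missing slices."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(a, axis=axis)

__all__ = [
    "EdgeEvent",
    "AlignedEnsemble",
    "smooth_series",
    "detect_events",
    "znormalize",
    "align_ensembles",
    "ensemble_mean_ci",
    "bootstrap_ci_mean",
    "refine_temporal_alignment",
]

ANCHORS = ("protrusion_onset", "protrusion_vmax", "retraction_onset", "retraction_vmax")


@dataclass
class EdgeEvent:
    """One protrusion or retraction phase of an edge sector.

    ``distance_um`` is stored as a magnitude; the sign lives in ``type``.
    """

    sector: int
    type: str  # "protrusion" | "retraction"
    onset_frame: int
    vmax_frame: int
    end_frame: int
    distance_um: float
    duration_s: float
    cell_id: int = 0

    def __post_init__(self) -> None:
        if not (self.onset_frame < self.vmax_frame <= self.end_frame):
            raise ValueError("event frames must satisfy onset < vmax <= end")
        if self.type not in ("protrusion", "retraction"):
            raise ValueError(f"unknown event type {self.type!r}")

    def anchor_frame(self, anchor: str) -> int | None:
        ev_type, point = anchor.rsplit("_", 1)
        if ev_type != self.type:
            return None
        return self.onset_frame if point == "onset" else self.vmax_frame


@dataclass
class AlignedEnsemble:
    """Event-anchored stack: values[event, depth, relative time]."""

    anchor: str
    rel_time_s: np.ndarray
    depths: np.ndarray
    values: np.ndarray  # NaN where a series leaves the movie
    n_events: int
    mean: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.anchor not in ANCHORS:
            raise ValueError(f"anchor must be one of {ANCHORS}")
        if self.n_events < 1:
            raise ValueError("ensemble needs at least one event")
        self.mean = _nanmean(self.values, axis=0)


def smooth_series(y: np.ndarray, smoothing_param: float = 0.5, dt_s: float = 1.0) -> np.ndarray:
    """Cubic smoothing spline evaluated at the sample times.

    ``smoothing_param`` follows the csaps convention: 1 interpolates the data,
    values toward 0 approach the least-squares straight line. Internally the
    penalty weight is ``lam = (1 - p) / p`` on the sample-time mesh, so the
    effective smoothness depends on ``dt_s`` as it does for csaps.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 points to smooth")
    if not 0.0 < smoothing_param <= 1.0:
        raise ValueError("smoothing_param must be in (0, 1]")
    x = np.arange(y.size) * dt_s
    lam = (1.0 - smoothing_param) / smoothing_param
    spl = make_smoothing_spline(x, y, lam=lam)
    return spl(x)


def _monotone_runs(y: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal strictly monotone runs of ``y`` as (start, end, sign) sample
    index pairs. Flat stretches separate runs and belong to none; the run
    boundaries are the local extrema of the series (series endpoints
    included when the series is moving there).
    """
    s = np.sign(np.diff(y))
    runs = []
    start = None
    cur = 0.0
    for i, v in enumerate(s):
        if v == 0:
            if start is not None:
                runs.append((start, i, cur))
                start = None
            continue
        if start is None:
            start, cur = i, v
        elif v != cur:
            runs.append((start, i, cur))
            start, cur = i, v
    if start is not None:
        runs.append((start, len(s), cur))
    return runs


def detect_events(
    displacement_series: np.ndarray,
    dt_s: float,
    velocity_series: np.ndarray | None = None,
    min_distance_um: float = 1.0,
    min_duration_s: float = 60.0,
    sector: int = 0,
    cell_id: int = 0,
    return_discarded: bool = False,
):
    """Partition a (smoothed) displacement series into protrusion/retraction
    phases and keep those with distance >= ``min_distance_um`` and duration
    >= ``min_duration_s``.

    Phases run between consecutive local extrema of displacement (series
    endpoints count as phase boundaries). Rising phases are protrusions,
    falling phases retractions; Vmax is the frame of maximal speed within
    the phase, earliest frame on ties.
    """
    disp = np.asarray(displacement_series, dtype=float)
    if disp.size < 2:
        return ([], []) if return_discarded else []
    if velocity_series is None:
        velocity_series = np.gradient(disp, dt_s)
    vel = np.asarray(velocity_series, dtype=float)
    kept: list[EdgeEvent] = []
    dropped: list[EdgeEvent] = []
    for a, b, sign in _monotone_runs(disp):
        delta = disp[b] - disp[a]
        ev_type = "protrusion" if sign > 0 else "retraction"
        seg = np.abs(vel[a : b + 1])
        # ties (within numerical tolerance) break toward the earliest frame
        peak = seg.max()
        vmax = a + int(np.flatnonzero(seg >= peak * (1.0 - 1e-9))[0])
        vmax = min(max(vmax, a + 1), b)  # anchor ordering requires onset < vmax <= end
        event = EdgeEvent(
            sector=sector,
            type=ev_type,
            onset_frame=int(a),
            vmax_frame=int(vmax),
            end_frame=int(b),
            distance_um=float(abs(delta)),
            duration_s=float((b - a) * dt_s),
            cell_id=cell_id,
        )
        if event.distance_um >= min_distance_um and event.duration_s >= min_duration_s:
            kept.append(event)
        else:
            dropped.append(event)
    if return_discarded:
        return kept, dropped
    return kept


def znormalize(series: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """z-score a series over its full length; zero spread raises."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    mu = np.nanmean(x)
    sd = np.nanstd(x)
    if not np.isfinite(sd) or sd < eps:
        raise ValueError("zero spread: series cannot be z-normalized")
    return (x - mu) / sd


def _series_lookup(table: pd.DataFrame, signal: str):
    """Build {(sector, depth) -> ndarray indexed by frame} for fast slicing."""
    out = {}
    for (sector, depth), grp in table.groupby(["sector", "depth"], sort=False):
        grp = grp.sort_values("frame")
        out[(sector, depth)] = grp[signal].to_numpy(dtype=float)
    return out


def align_ensembles(
    table: pd.DataFrame,
    events: list[EdgeEvent],
    anchor: str,
    signal: str = "rac1",
    window_s: tuple[float, float] = (-120.0, 120.0),
    depths: tuple[int, ...] | None = None,
    dt_s: float | None = None,
    znorm: bool = True,
) -> AlignedEnsemble:
    """Stack per-window signal series around each event's anchor frame.

    ``table`` is a tidy window-series table with columns (sector, depth,
    frame, <signal>). Series truncated by the movie boundary contribute NaN
    beyond it. With ``znorm`` each window series is z-scored over its full
    length first; zero-spread windows are excluded.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}")
    if dt_s is None:
        if "time_s" in table.columns:
            frames = np.sort(table["frame"].unique())
            times = table.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
            dt_s = float(np.diff(times).mean()) if len(frames) > 1 else 1.0
        else:
            raise ValueError("dt_s required when the table has no time_s column")
    if depths is None:
        depths = tuple(sorted(table["depth"].unique()))
    lo = int(round(window_s[0] / dt_s))
    hi = int(round(window_s[1] / dt_s))
    rel = np.arange(lo, hi + 1)
    lookup = _series_lookup(table, signal)
    slabs = []
    for ev in events:
        af = ev.anchor_frame(anchor)
        if af is None:
            continue
        slab = np.full((len(depths), rel.size), np.nan)
        for di, d in enumerate(depths):
            series = lookup.get((ev.sector, d))
            if series is None:
                continue
            if znorm:
                try:
                    series = znormalize(series)
                except ValueError:
                    continue  # degenerate window excluded
            idx = af + rel
            ok = (idx >= 0) & (idx < series.size)
            slab[di, ok] = series[idx[ok]]
        slabs.append(slab)
    if not slabs:
        raise ValueError(f"no events match anchor {anchor!r}")
    values = np.stack(slabs)
    return AlignedEnsemble(
        anchor=anchor,
        rel_time_s=rel * dt_s,
        depths=np.asarray(depths),
        values=values,
        n_events=values.shape[0],
    )


def bootstrap_ci_mean(
    data: np.ndarray, n_boot: int = 1000, level: float = 95.0, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CI for the mean over axis 0 (events).

    ``data`` is (n_events, ...); NaNs are ignored within each resample.
    Returns (lower, upper) arrays with the trailing shape of ``data``.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 events to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = _nanmean(data[idx], axis=1)
    alpha = (100.0 - level) / 2.0
    lower = np.nanpercentile(boot_means, alpha, axis=0)
    upper = np.nanpercentile(boot_means, 100.0 - alpha, axis=0)
    return lower, upper


def ensemble_mean_ci(
    ensemble: AlignedEnsemble, n_boot: int = 1000, level: float = 95.0, seed: int | None = None
) -> dict:
    """Mean map plus percentile-bootstrap CI maps, resampling events."""
    if ensemble.n_events < 2:
        raise ValueError("need at least 2 events")
    lower, upper = bootstrap_ci_mean(ensemble.values, n_boot=n_boot, level=level, seed=seed)
    return {"mean": ensemble.mean, "ci_lower": lower, "ci_upper": upper, "level": level}


def refine_temporal_alignment(
    table: pd.DataFrame,
    depth: int = 5,
    signal: str = "traction_pa",
    corr_threshold: float = 0.5,
) -> pd.DataFrame:
    """QC report on frame-to-frame consistency of the depth-5 traction
    profile along the edge.

    For each frame the traction values across sectors at ``depth`` are
    correlated with the previous frame's profile. Frames whose correlation
    drops below ``corr_threshold`` (corrupted ordering) or whose profile is
    bitwise identical to the previous frame (duplicated frame) are flagged.
    Report only; the table is never mutated.
    """
    sub = table[table["depth"] == depth]
    if sub.empty:
        raise ValueError(f"no rows at depth {depth}")
    wide = sub.pivot_table(index="frame", columns="sector", values=signal)
    frames = wide.index.to_numpy()
    vals = wide.to_numpy()
    # profiles with spread well below the stack's typical spread carry no
    # ordering information (quiescent stretches): not judged by correlation
    stds = np.nanstd(vals, axis=1)
    floor = 0.5 * np.nanmedian(stds)
    rows = []
    for i in range(1, len(frames)):
        a, b = vals[i - 1], vals[i]
        ok = np.isfinite(a) & np.isfinite(b)
        structured = ok.sum() >= 3 and min(a[ok].std(), b[ok].std()) > floor
        corr = (float(np.corrcoef(a[ok], b[ok])[0, 1]) if structured else np.nan)
        duplicate = bool(ok.any() and np.array_equal(a[ok], b[ok])
                         and b[ok].std() > 0)
        flagged = duplicate or (np.isfinite(corr) and corr < corr_threshold)
        rows.append({"frame": int(frames[i]), "corr_prev": corr,
                     "duplicate": duplicate, "flagged": flagged})
    return pd.DataFrame(rows)
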