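"""Optogenetic perturbation quantification.

Difference-in-difference (DID) curves compare onset-aligned perturbed event
groups — grouped by the offset between photoactivation time and the
expected Vmax — against unperturbed control events; traction changes are
quantified per cell and per window; and a resampling false-discovery-rate
procedure decides significance of a perturbed group against a much larger
control pool.

The FDR procedure: the control pool is subsampled to the perturbed group
size many times; per time point the spread of the grouped series is
compared against the spread of the pooled two-group series with a
two-sample t test, yielding a P value; a label-shuffled regrouping of the
same data yields a null P value. Storey q-values are computed over the
grouped and the randomized P sets; significance requires the mean grouped
q-value to fall below the 0.1th percentile of the randomized q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .events import EdgeEvent, detect_events

__all__ = [
    "ControlSet",
    "DIDResult",
    "FDRResult",
    "build_controls",
    "group_by_offset",
    "did_curves",
    "traction_change_cellwise",
    "traction_change_windowwise",
    "fdr_resampling",
    "storey_qvalues",
]


@dataclass
class ControlSet:
    """Onset-aligned unperturbed control events."""

    events: list[EdgeEvent]
    velocity: np.ndarray  # (n_events, n_rel) NaN beyond each event's series
    distance: np.ndarray  # running integral of velocity from onset
    rel_time_s: np.ndarray
    mean_t_vmax_s: float


@dataclass
class DIDResult:
    rel_time_s: np.ndarray
    control_mean: np.ndarray
    control_n: int
    diffs: dict  # offset_s -> difference curve (group mean - control mean)
    group_means: dict
    group_n: dict
    quantity: str = "velocity"


@dataclass
class FDRResult:
    p_grouped: np.ndarray  # per-time-point mean P over iterations
    p_randomized: np.ndarray
    q_grouped: np.ndarray  # Storey q per (iteration x time) P value
    q_randomized: np.ndarray
    threshold: float  # 0.1th percentile of randomized q
    mean_grouped_q: float
    significant: bool
    n_iter: int
    warnings: list = field(default_factory=list)


# --------------------------------------------------------------------------
# event extraction and grouping


def _sector_series(table: pd.DataFrame, column: str) -> dict[int, np.ndarray]:
    depth1 = table[table["depth"] == table["depth"].min()]
    out = {}
    for sector, grp in depth1.groupby("sector", sort=True):
        out[sector] = grp.sort_values("frame")[column].to_numpy(dtype=float)
    return out


def build_controls(
    table: pd.DataFrame,
    t_act_s: float | None = None,
    rel_window_s: float = 300.0,
    dt_s: float | None = None,
    min_distance_um: float = 1.0,
    min_duration_s: float = 60.0,
) -> ControlSet:
    """Extract events (completed before ``t_act_s`` if given), align their
    velocity series at onset, and report the mean onset-to-Vmax time."""
    if dt_s is None:
        times = table.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
        dt_s = float(np.diff(times).mean())
    disp = _sector_series(table, "displacement_um")
    vel = _sector_series(table, "velocity_um_per_s")
    events: list[EdgeEvent] = []
    for sector, d in disp.items():
        evs = detect_events(d, dt_s, velocity_series=vel[sector],
                            min_distance_um=min_distance_um,
                            min_duration_s=min_duration_s, sector=sector)
        for ev in evs:
            if t_act_s is None or ev.end_frame * dt_s <= t_act_s:
                events.append(ev)
    if not events:
        raise ValueError("no control events before the activation time")
    n_rel = int(round(rel_window_s / dt_s)) + 1
    rel = np.arange(n_rel)
    velocity = np.full((len(events), n_rel), np.nan)
    for i, ev in enumerate(events):
        series = vel[ev.sector]
        idx = ev.onset_frame + rel
        ok = idx < series.size
        velocity[i, ok] = series[idx[ok]]
    distance = np.nancumsum(np.where(np.isfinite(velocity), velocity, 0.0), axis=1) * dt_s
    distance[~np.isfinite(velocity)] = np.nan
    mean_t_vmax = float(np.mean([(ev.vmax_frame - ev.onset_frame) * dt_s for ev in events]))
    return ControlSet(events, velocity, distance, rel * dt_s, mean_t_vmax)


def group_by_offset(
    events: list[EdgeEvent],
    t_act_s,
    mean_t_vmax_s: float,
    offsets_s,
    tolerance_s: float = 2.5,
    dt_s: float = 5.0,
) -> dict[float, list[EdgeEvent]]:
    """Assign each event to the offset group nearest
    ``t_act - (onset + mean_t_vmax)`` within ``tolerance_s``; events outside
    every tolerance band are dropped.

    ``t_act_s`` is a scalar activation time, or a mapping sector -> t_act
    when activations were triggered per event.
    """
    offsets = np.asarray(sorted(set(offsets_s)), dtype=float)
    if offsets.size != len(list(offsets_s)):
        raise ValueError("offsets must be distinct")
    groups: dict[float, list[EdgeEvent]] = {float(o): [] for o in offsets}
    for ev in events:
        t_act = t_act_s[ev.sector] if hasattr(t_act_s, "__getitem__") else t_act_s
        delta = t_act - (ev.onset_frame * dt_s + mean_t_vmax_s)
        dists = np.abs(offsets - delta)
        k = int(np.argmin(dists))
        if dists[k] <= tolerance_s:
            groups[float(offsets[k])].append(ev)
    return groups


def did_curves(
    groups: dict,
    controls: ControlSet,
    table: pd.DataFrame,
    quantity: str = "velocity",
    dt_s: float | None = None,
) -> DIDResult:
    """Onset-aligned group means minus the control mean at each relative time.

    ``groups`` maps offset -> list of perturbed EdgeEvents detected on the
    perturbed table; ``quantity`` is 'velocity' or 'distance' (cumulative
    signed displacement from onset).
    """
    if quantity not in ("velocity", "distance"):
        raise ValueError("quantity must be 'velocity' or 'distance'")
    if not any(groups.values()):
        raise ValueError("all perturbed groups are empty")
    if dt_s is None:
        dt_s = float(np.diff(controls.rel_time_s).mean())
    vel_lookup = _sector_series(table, "velocity_um_per_s")
    rel = np.arange(controls.rel_time_s.size)
    ctrl = controls.velocity if quantity == "velocity" else controls.distance
    with np.errstate(invalid="ignore"):
        control_mean = np.nanmean(ctrl, axis=0)
    diffs, gmeans, gns = {}, {}, {}
    for offset, evs in groups.items():
        if not evs:
            continue
        mat = np.full((len(evs), rel.size), np.nan)
        for i, ev in enumerate(evs):
            series = vel_lookup[ev.sector]
            idx = ev.onset_frame + rel
            ok = idx < series.size
            mat[i, ok] = series[idx[ok]]
        if quantity == "distance":
            dist = np.nancumsum(np.where(np.isfinite(mat), mat, 0.0), axis=1) * dt_s
            dist[~np.isfinite(mat)] = np.nan
            mat = dist
        with np.errstate(invalid="ignore"):
            gmean = np.nanmean(mat, axis=0)
        diffs[offset] = gmean - control_mean
        gmeans[offset] = gmean
        gns[offset] = len(evs)
    return DIDResult(controls.rel_time_s, control_mean, ctrl.shape[0],
                     diffs, gmeans, gns, quantity)


# --------------------------------------------------------------------------
# traction change quantification


def traction_change_cellwise(
    cell_traction_series: list[np.ndarray],
    t_act_s: float,
    dt_s: float,
    before_span_s: tuple[float, float] = (-60.0, 0.0),
    after_span_s: tuple[float, float] = (180.0, 240.0),
) -> dict:
    """Per-cell traction ratio (after / before activation) plus paired t test.

    Each element of ``cell_traction_series`` is one cell's mean traction in
    the perturbed region over time. 'Before' covers the minute preceding
    activation, 'after' minutes 3-4 following it.
    """
    befores, afters = [], []
    for series in cell_traction_series:
        t = np.arange(len(series)) * dt_s - t_act_s
        b = series[(t > before_span_s[0]) & (t <= before_span_s[1])]
        a = series[(t > after_span_s[0]) & (t <= after_span_s[1])]
        if b.size == 0 or a.size == 0:
            raise ValueError("a cell does not cover both time spans")
        befores.append(float(np.mean(b)))
        afters.append(float(np.mean(a)))
    befores = np.asarray(befores)
    afters = np.asarray(afters)
    ratios = afters / befores
    if len(ratios) >= 2 and np.ptp(afters - befores) > 0:
        tstat, p = stats.ttest_rel(afters, befores)
    else:
        tstat, p = np.nan, 1.0
    return {"ratio": ratios, "mean_ratio": float(ratios.mean()),
            "t": float(tstat) if np.isfinite(tstat) else np.nan, "p": float(p)}


def traction_change_windowwise(
    table: pd.DataFrame,
    events: list[EdgeEvent],
    t_act_s: float,
    horizon_s: float = 120.0,
    depth: int = 2,
    dt_s: float | None = None,
    onset_window_s: float = 20.0,
) -> dict:
    """Traction change over ``horizon_s`` in the depth-``depth`` windows of
    sectors whose event initiated within ``onset_window_s`` before activation,
    compared (two-sample t test) to phase-matched control windows whose
    events completed before activation."""
    if dt_s is None:
        times = table.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
        dt_s = float(np.diff(times).mean())
    sub = table[table["depth"] == depth]
    force = {s: g.sort_values("frame")["traction_pa"].to_numpy(dtype=float)
             for s, g in sub.groupby("sector")}
    perturbed = [ev for ev in events
                 if t_act_s - onset_window_s <= ev.onset_frame * dt_s <= t_act_s]
    if not perturbed:
        raise ValueError("no events initiated within the pre-activation window")
    ctrl = [ev for ev in events if ev.end_frame * dt_s < t_act_s]
    mean_phase = float(np.mean([t_act_s - ev.onset_frame * dt_s for ev in perturbed]))
    h = int(round(horizon_s / dt_s))

    def change(ev: EdgeEvent, t0_s: float) -> float | None:
        series = force.get(ev.sector)
        if series is None:
            return None
        i0 = int(round(t0_s / dt_s))
        i1 = i0 + h
        if i0 < 0 or i1 >= series.size:
            return None
        return float(series[i1] - series[i0])

    pert_changes = [c for ev in perturbed if (c := change(ev, t_act_s)) is not None]
    ctrl_changes = [c for ev in ctrl
                    if (c := change(ev, ev.onset_frame * dt_s + mean_phase)) is not None]
    if not pert_changes or not ctrl_changes:
        raise ValueError("insufficient phase-matched windows")
    tstat, p = stats.ttest_ind(pert_changes, ctrl_changes)
    return {"perturbed_changes": np.asarray(pert_changes),
            "control_changes": np.asarray(ctrl_changes),
            "diff": float(np.mean(pert_changes) - np.mean(ctrl_changes)),
            "t": float(tstat), "p": float(p)}


# --------------------------------------------------------------------------
# resampling FDR


def storey_qvalues(p: np.ndarray, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey positive-FDR q-values with the smoother pi0 estimate."""
    p = np.asarray(p, dtype=float).ravel()
    m = p.size
    if m == 0:
        raise ValueError("empty p-value set")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    if np.all(pi0_l == 0):
        pi0 = 1e-8
    else:
        spl = UnivariateSpline(lambdas, pi0_l, k=3, s=None)
        pi0 = float(np.clip(spl(lambdas[-1]), 1e-8, 1.0))
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _welch_p(a: np.ndarray, b: np.ndarray, axis: int = 1) -> np.ndarray:
    """Two-sided Welch t-test p-values along ``axis`` (vectorized)."""
    na = a.shape[axis]
    nb = b.shape[axis]
    ma = a.mean(axis=axis)
    mb = b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1) / na
    vb = b.var(axis=axis, ddof=1) / nb
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), np.where(np.isfinite(df), df, 1.0))
    return np.where(np.isfinite(t), p, 1.0)


def _spread_vs_pooled_p(group_a: np.ndarray, group_b: np.ndarray,
                        strategy: str) -> np.ndarray:
    """Per-time-point P values comparing within-group spread to pooled spread.

    ``group_a``/``group_b`` are stacked (..., n, T). 'sd_vs_pooled' t-tests
    the absolute deviations about each group's own mean against the absolute
    deviations about the grand mean (sensitive to mean shifts between the
    groups); 'levene' t-tests the two groups' deviations about the pooled
    mean against each other.
    """
    axis = group_a.ndim - 2
    pooled = np.concatenate([group_a, group_b], axis=axis)
    grand = pooled.mean(axis=axis, keepdims=True)
    if strategy == "sd_vs_pooled":
        dev_within = np.concatenate(
            [np.abs(group_a - group_a.mean(axis=axis, keepdims=True)),
             np.abs(group_b - group_b.mean(axis=axis, keepdims=True))], axis=axis)
        dev_pooled = np.abs(pooled - grand)
        return _welch_p(dev_within, dev_pooled, axis=axis)
    if strategy == "levene":
        dev_a = np.abs(group_a - grand)
        dev_b = np.abs(group_b - grand)
        return _welch_p(dev_a, dev_b, axis=axis)
    raise ValueError(f"unknown strategy {strategy!r}")


def fdr_resampling(
    control_series: np.ndarray,
    perturbed_series: np.ndarray,
    n_iter: int = 10000,
    threshold_pct: float = 0.1,
    seed: int | None = None,
    strategy: str = "sd_vs_pooled",
    fixed_threshold: float | None = None,
) -> FDRResult:
    """Resampling FDR comparison of a small perturbed group against a large
    control pool.

    Per iteration the control pool is subsampled (without replacement) to the
    perturbed size; per time point a spread-comparison t test gives a grouped
    P value, and the same test on label-shuffled data gives a randomized P
    value. Storey q-values are computed over all grouped and all randomized P
    values; ``significant`` means the mean grouped q-value is below the
    ``threshold_pct`` percentile of the randomized q-values (or below
    ``fixed_threshold`` if given).
    """
    C = np.asarray(control_series, dtype=float)
    P = np.asarray(perturbed_series, dtype=float)
    if P.ndim != 2 or C.ndim != 2 or C.shape[1] != P.shape[1]:
        raise ValueError("series must be 2D (n_series, n_timepoints) with equal T")
    n_p = P.shape[0]
    if n_p < 2:
        raise ValueError("perturbed group needs at least 2 series")
    if C.shape[0] < n_p:
        raise ValueError("control pool must be at least as large as the perturbed group")
    warnings = []
    if n_iter < 100:
        warnings.append(f"n_iter={n_iter} is low; results may be unstable")
    rng = np.random.default_rng(seed)
    T = P.shape[1]
    p_grouped = np.empty((n_iter, T))
    p_rand = np.empty((n_iter, T))
    chunk = max(1, min(n_iter, int(2e7 / (2 * n_p * T) + 1)))
    done = 0
    while done < n_iter:
        I = min(chunk, n_iter - done)
        # subsample the control pool without replacement, per iteration
        idx = np.argsort(rng.random((I, C.shape[0])), axis=1)[:, :n_p]
        sub = C[idx]  # (I, n_p, T)
        Pb = np.broadcast_to(P, (I, n_p, T))
        p_grouped[done : done + I] = _spread_vs_pooled_p(sub, Pb, strategy)
        pool = np.concatenate([sub, Pb], axis=1)
        perm = np.argsort(rng.random((I, 2 * n_p)), axis=1)
        ga = np.take_along_axis(pool, perm[:, :n_p, None], axis=1)
        gb = np.take_along_axis(pool, perm[:, n_p:, None], axis=1)
        p_rand[done : done + I] = _spread_vs_pooled_p(ga, gb, strategy)
        done += I
    q_grouped = storey_qvalues(p_grouped)
    q_rand = storey_qvalues(p_rand)
    threshold = (float(fixed_threshold) if fixed_threshold is not None
                 else float(np.percentile(q_rand, threshold_pct)))
    mean_q = float(q_grouped.mean())
    return FDRResult(
        p_grouped=p_grouped.mean(axis=0),
        p_randomized=p_rand.mean(axis=0),
        q_grouped=q_grouped,
        q_randomized=q_rand,
        threshold=threshold,
        mean_grouped_q=mean_q,
        significant=bool(mean_q < threshold),
        n_iter=n_iter,
        warnings=warnings,
    )
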