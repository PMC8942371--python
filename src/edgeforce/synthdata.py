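"""Seeded synthetic data with ground truth for every pipeline stage.

The generator emulates a migrating cell on a soft (6.9 kPa) substrate imaged
at 10-s cadence: each edge sector executes scheduled protrusion/retraction
events (half-cosine displacement ramps, so the velocity peak Vmax sits
analytically at the event midpoint), and per-window Rac1-GTP, RhoA-GTP and
traction-force signals carry the lead/lag structure of the biology being
modelled:

* Rac1 rises ``rac1_to_onset_lead_s`` (default 40 s) before protrusion onset,
  dips to a nadir at protrusion Vmax and peaks at retraction Vmax;
* RhoA mirrors Rac1 advanced by ``rhoa_to_rac1_lead_s`` (default 25 s) with
  the Vmax excursions sign-inverted;
* traction force follows Rac1 with a delay of ``rac1_to_force_lag_s``
  (default 40 s).

Signal excursions are Gaussian bumps (sigma 15 s); amplitudes attenuate
exponentially with window depth. Two seeds separate the biology (event
schedule) from the measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .tfm import DisplacementField, TractionMap, fttc_forward, ElasticParams

__all__ = ["SynthConfig", "GroundTruth", "make_window_series", "make_bead_pair",
           "make_cell_movie", "make_perturbation_dataset"]

TABLE_COLUMNS = ["cell_id", "sector", "depth", "frame", "time_s", "rac1", "rhoa",
                 "traction_pa", "displacement_um", "velocity_um_per_s"]


@dataclass
class SynthConfig:
    """Generation parameters. Units: um, s, Pa.

    ``noise_sd`` maps signal name -> additive Gaussian SD; signals absent
    from the dict are noiseless. ``schedule_seed`` pins the event schedule
    independently of the noise seed so noise can vary with fixed biology.
    """

    frame_interval_s: float = 10.0
    pixel_size_um: float = 0.2
    youngs_modulus_pa: float = 6900.0
    poisson_ratio: float = 0.5
    rhoa_to_rac1_lead_s: float = 25.0
    rac1_to_onset_lead_s: float = 40.0
    rac1_to_force_lag_s: float = 40.0
    event_amplitude_um: tuple[float, float] = (1.5, 4.0)
    event_duration_s: tuple[float, float] = (90.0, 240.0)
    event_gap_s: tuple[float, float] = (20.0, 60.0)
    bump_sigma_s: float = 15.0
    rac1_baseline: float = 1.0
    rac1_gain: float = 1.0
    rhoa_baseline: float = 1.0
    rhoa_gain: float = 1.0
    force_baseline_pa: float = 100.0
    force_coupling_pa: float = 30.0
    rhoa_force_coupling_pa: float = 0.0  # optional extra coupling, off by default
    depth_decay: float = 3.0
    noise_sd: dict = field(default_factory=lambda: {
        "rac1": 1.0, "rhoa": 1.0, "force_pa": 10.0, "displacement_um": 0.0})
    bead_density_per_um2: float = 0.8
    psf_sigma_px: float = 1.5
    n_sectors: int = 20
    n_depths: int = 10
    n_frames: int = 120
    seed: int = 0
    schedule_seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_interval_s and pixel_size_um must be > 0")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if self.n_frames <= 0 or self.n_sectors <= 0 or self.n_depths <= 0:
            raise ValueError("n_frames, n_sectors, n_depths must be positive")
        for name in ("event_amplitude_um", "event_duration_s", "event_gap_s"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (low, high) range")
        if self.bump_sigma_s <= 0:
            raise ValueError("bump_sigma_s must be > 0")

    def schedule_rng(self) -> np.random.Generator:
        s = self.seed if self.schedule_seed is None else self.schedule_seed
        return np.random.default_rng([int(s), 101])

    def noise_rng(self) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), 211])


@dataclass
class GroundTruth:
    """Generative ground truth used by parameter-recovery tests."""

    event_schedule: pd.DataFrame  # sector, type, onset_s, vmax_s, end_s, amplitude_um
    true_signals: pd.DataFrame | None = None  # noiseless per (sector, frame), depth-1 scale
    true_displacement_field: DisplacementField | None = None
    true_traction_field: TractionMap | None = None
    true_masks: np.ndarray | None = None


def _gauss_bump(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _half_cosine_ramp(t: np.ndarray, onset: float, duration: float, amplitude: float) -> np.ndarray:
    """Signed displacement ramp: 0 before onset, amplitude after the end,
    half-cosine in between (velocity maximal at the midpoint)."""
    phase = np.clip((t - onset) / duration, 0.0, 1.0)
    return amplitude * 0.5 * (1.0 - np.cos(np.pi * phase))


def _schedule_sector(rng: np.random.Generator, config: SynthConfig,
                     total_s: float) -> list[dict]:
    """Alternating protrusion/retraction events with quiescent gaps.

    Onsets are snapped to the frame grid and durations to an even number of
    frames, so onset and Vmax (event midpoint) both fall on sampled frames
    and detected anchors can be compared to the schedule exactly.
    """
    dt = config.frame_interval_s
    events = []
    t = float(rng.uniform(*config.event_gap_s))
    kind = "protrusion"
    while True:
        dur = float(rng.uniform(*config.event_duration_s))
        amp = float(rng.uniform(*config.event_amplitude_um))
        onset = round(t / dt) * dt
        dur = max(2 * dt, round(dur / (2 * dt)) * 2 * dt)
        if onset + dur > total_s - dt:
            break
        events.append({"type": kind, "onset_s": onset, "end_s": onset + dur,
                       "vmax_s": onset + dur / 2.0,
                       "amplitude_um": amp if kind == "protrusion" else -amp})
        t = onset + dur + float(rng.uniform(*config.event_gap_s))
        kind = "retraction" if kind == "protrusion" else "protrusion"
    return events


def _sector_signals(times: np.ndarray, events: list[dict], config: SynthConfig):
    """Noiseless displacement/velocity/Rac1/RhoA/force for one sector."""
    dt = config.frame_interval_s
    disp = np.zeros_like(times)
    rac1 = np.full_like(times, config.rac1_baseline)
    rhoa = np.full_like(times, config.rhoa_baseline)
    g, s = config.rac1_gain, config.bump_sigma_s
    gr = config.rhoa_gain
    lead = config.rac1_to_onset_lead_s
    adv = config.rhoa_to_rac1_lead_s
    for ev in events:
        disp += _half_cosine_ramp(times, ev["onset_s"], ev["end_s"] - ev["onset_s"],
                                  ev["amplitude_um"])
        if ev["type"] == "protrusion":
            rac1 += g * _gauss_bump(times, ev["onset_s"] - lead, s)
            rac1 -= g * _gauss_bump(times, ev["vmax_s"], s)
            rhoa += gr * _gauss_bump(times, ev["onset_s"] - lead - adv, s)
            rhoa += gr * _gauss_bump(times, ev["vmax_s"] - adv, s)
        else:
            rac1 += g * _gauss_bump(times, ev["vmax_s"], s)
            rhoa -= gr * _gauss_bump(times, ev["vmax_s"] - adv, s)
    vel = np.zeros_like(disp)
    vel[1:] = np.diff(disp) / dt
    force = _coupled_force(rac1, rhoa, config)
    return disp, vel, rac1, rhoa, force


def _coupled_force(rac1: np.ndarray, rhoa: np.ndarray, config: SynthConfig) -> np.ndarray:
    """force(t) = baseline + coupling * (Rac1(t - lag) - Rac1 baseline),
    with quiescent (baseline) pre-history; optional RhoA term."""
    dt = config.frame_interval_s
    lag_frames = int(round(config.rac1_to_force_lag_s / dt))
    shifted = np.full_like(rac1, config.rac1_baseline)
    if lag_frames < rac1.size:
        if lag_frames > 0:
            shifted[lag_frames:] = rac1[:-lag_frames]
        else:
            shifted = rac1.copy()
    force = config.force_baseline_pa + config.force_coupling_pa * (
        shifted - config.rac1_baseline)
    if config.rhoa_force_coupling_pa != 0.0:
        shifted_r = np.full_like(rhoa, config.rhoa_baseline)
        if 0 < lag_frames < rhoa.size:
            shifted_r[lag_frames:] = rhoa[:-lag_frames]
        elif lag_frames == 0:
            shifted_r = rhoa.copy()
        force += config.rhoa_force_coupling_pa * (shifted_r - config.rhoa_baseline)
    return force


def _assemble_table(per_sector: dict, config: SynthConfig,
                    rng: np.random.Generator, cell_id: int = 0) -> pd.DataFrame:
    """Tidy table over sectors x depths x frames with depth attenuation and
    per-entry noise."""
    dt = config.frame_interval_s
    n_frames = config.n_frames
    depths = np.arange(1, config.n_depths + 1)
    atten = np.exp(-(depths - 1) / config.depth_decay)
    sd = config.noise_sd
    frames = np.arange(n_frames)
    rows = []
    for sector, sig in per_sector.items():
        disp, vel, rac1, rhoa, force = sig
        disp_noisy = disp + rng.normal(0, sd.get("displacement_um", 0.0) or 0.0,
                                       n_frames) if sd.get("displacement_um") else disp
        if sd.get("displacement_um"):
            vel_noisy = np.zeros_like(disp_noisy)
            vel_noisy[1:] = np.diff(disp_noisy) / dt
        else:
            vel_noisy = vel
        for di, d in enumerate(depths):
            a = atten[di]
            r1 = config.rac1_baseline + (rac1 - config.rac1_baseline) * a
            rh = config.rhoa_baseline + (rhoa - config.rhoa_baseline) * a
            fo = config.force_baseline_pa + (force - config.force_baseline_pa) * a
            if sd.get("rac1"):
                r1 = r1 + rng.normal(0, sd["rac1"], n_frames)
            if sd.get("rhoa"):
                rh = rh + rng.normal(0, sd["rhoa"], n_frames)
            if sd.get("force_pa"):
                fo = fo + rng.normal(0, sd["force_pa"], n_frames)
            rows.append(pd.DataFrame({
                "cell_id": cell_id, "sector": sector, "depth": d, "frame": frames,
                "time_s": frames * dt, "rac1": r1, "rhoa": rh, "traction_pa": fo,
                "displacement_um": disp_noisy, "velocity_um_per_s": vel_noisy}))
    return pd.concat(rows, ignore_index=True)[TABLE_COLUMNS]


def make_window_series(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a per-window signal table plus its generative ground truth.

    The table covers ``n_sectors x n_depths x n_frames``; ground-truth
    signals are stored at depth-1 (unattenuated) scale.
    """
    dt = config.frame_interval_s
    times = np.arange(config.n_frames) * dt
    total_s = config.n_frames * dt
    srng = config.schedule_rng()
    per_sector = {}
    sched_rows = []
    truth_rows = []
    for sector in range(1, config.n_sectors + 1):
        events = _schedule_sector(srng, config, total_s)
        sig = _sector_signals(times, events, config)
        per_sector[sector] = sig
        for ev in events:
            sched_rows.append({"sector": sector, **ev})
        disp, vel, rac1, rhoa, force = sig
        truth_rows.append(pd.DataFrame({
            "sector": sector, "frame": np.arange(config.n_frames), "time_s": times,
            "rac1": rac1, "rhoa": rhoa, "force_pa": force,
            "displacement_um": disp, "velocity_um_per_s": vel}))
    table = _assemble_table(per_sector, config, config.noise_rng())
    schedule = pd.DataFrame(
        sched_rows, columns=["sector", "type", "onset_s", "end_s", "vmax_s",
                             "amplitude_um"])
    truth = GroundTruth(event_schedule=schedule,
                        true_signals=pd.concat(truth_rows, ignore_index=True))
    return table, truth


# --------------------------------------------------------------------------
# bead image forward model


def _render_beads(positions: np.ndarray, amplitudes: np.ndarray,
                  shape: tuple[int, int], sigma: float) -> np.ndarray:
    img = np.zeros(shape)
    r = int(np.ceil(4 * sigma))
    H, W = shape
    for (y, x), amp in zip(positions, amplitudes):
        yi, xi = int(round(y)), int(round(x))
        y0, y1 = max(yi - r, 0), min(yi + r + 1, H)
        x0, x1 = max(xi - r, 0), min(xi + r + 1, W)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amp * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
    return img


def make_bead_pair(
    traction: TractionMap | DisplacementField,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, DisplacementField]:
    """Render a (reference, deformed) fluorescent-bead image pair.

    ``traction`` may be a :class:`TractionMap` on the pixel grid — the
    displacement is then computed through the elastic forward model — or a
    :class:`DisplacementField` injected directly (bypassing elasticity, e.g.
    rigid-shift fixtures). Beads are 2D Gaussian spots with amplitude jitter;
    in the deformed image each bead moves by the displacement interpolated at
    its position.
    """
    if config.bead_density_per_um2 <= 0:
        raise ValueError("bead_density_per_um2 must be > 0")
    if rng is None:
        rng = config.noise_rng()
    if isinstance(traction, TractionMap):
        disp = fttc_forward(traction, ElasticParams(
            youngs_modulus_pa=config.youngs_modulus_pa,
            poisson_ratio=config.poisson_ratio, reg_lambda=0.0))
    else:
        disp = traction
    H, W = disp.u_um.shape
    px = disp.spacing_um  # pixel grid
    area_um2 = H * W * px * px
    n_beads = int(round(config.bead_density_per_um2 * area_um2))
    pos = np.column_stack([rng.uniform(0, H - 1, n_beads),
                           rng.uniform(0, W - 1, n_beads)])
    amps = rng.uniform(0.7, 1.3, n_beads) * 1000.0
    ref = _render_beads(pos, amps, (H, W), config.psf_sigma_px)
    u_at = ndimage.map_coordinates(disp.u_um, pos.T, order=1, mode="nearest")
    v_at = ndimage.map_coordinates(disp.v_um, pos.T, order=1, mode="nearest")
    moved = pos + np.column_stack([v_at, u_at]) / px  # (dy, dx) in pixels
    deformed = _render_beads(moved, amps, (H, W), config.psf_sigma_px)
    return ref, deformed, disp


# --------------------------------------------------------------------------
# cell movie rendering


def make_cell_movie(
    config: SynthConfig,
    radius_um: float = 12.0,
    field_um: float = 40.0,
    cell_intensity: float = 1000.0,
    background: float = 100.0,
    image_noise_sd: float = 10.0,
) -> tuple[dict, GroundTruth]:
    """Render a star-convex cell movie whose per-sector radius follows the
    event schedule and whose FRET/mTFP1 ratio encodes the true Rac1 signal.

    Returns ``{"mtfp": ImageStack, "fret": ImageStack}`` plus ground truth
    with per-frame boolean masks.
    """
    from .imaging import ImageStack  # local import to avoid cycles

    dt = config.frame_interval_s
    times = np.arange(config.n_frames) * dt
    total_s = config.n_frames * dt
    srng = config.schedule_rng()
    nrng = config.noise_rng()
    sectors = np.arange(config.n_sectors)
    theta_s = (sectors + 0.5) * 2 * np.pi / config.n_sectors

    disp_by_sector = np.zeros((config.n_sectors, config.n_frames))
    rac1_by_sector = np.zeros((config.n_sectors, config.n_frames))
    sched_rows = []
    for i in range(config.n_sectors):
        events = _schedule_sector(srng, config, total_s)
        disp, vel, rac1, rhoa, force = _sector_signals(times, events, config)
        disp_by_sector[i] = disp
        rac1_by_sector[i] = rac1
        for ev in events:
            sched_rows.append({"sector": i + 1, **ev})

    max_r = radius_um + np.max(np.abs(disp_by_sector))
    if max_r >= field_um / 2.0:
        raise ValueError("cell radius exceeds the field of view")
    n_px = int(round(field_um / config.pixel_size_um))
    c = (n_px - 1) / 2.0
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    rho_um = np.hypot(yy - c, xx - c) * config.pixel_size_um
    theta = np.mod(np.arctan2(yy - c, xx - c), 2 * np.pi)
    # nearest angular sector per pixel
    sector_of_px = np.floor(theta / (2 * np.pi / config.n_sectors)).astype(int)
    sector_of_px = np.clip(sector_of_px, 0, config.n_sectors - 1)

    masks = np.zeros((config.n_frames, n_px, n_px), dtype=bool)
    mtfp = np.zeros((config.n_frames, n_px, n_px))
    fret = np.zeros((config.n_frames, n_px, n_px))
    theta_ext = np.concatenate([theta_s - 2 * np.pi, theta_s, theta_s + 2 * np.pi])
    for t in range(config.n_frames):
        r_ext = np.tile(radius_um + disp_by_sector[:, t], 3)
        r_of_theta = np.interp(theta.ravel(), theta_ext, r_ext).reshape(theta.shape)
        mask = rho_um <= r_of_theta
        masks[t] = mask
        m_clean = np.where(mask, cell_intensity, 0.0) + background
        rac_px = rac1_by_sector[sector_of_px, t]
        f_clean = np.where(mask, cell_intensity * rac_px, 0.0) + background
        if image_noise_sd > 0:
            m_clean = m_clean + nrng.normal(0, image_noise_sd, mask.shape)
            f_clean = f_clean + nrng.normal(0, image_noise_sd, mask.shape)
        mtfp[t] = np.clip(m_clean, 0, None)
        fret[t] = np.clip(f_clean, 0, None)

    schedule = pd.DataFrame(
        sched_rows, columns=["sector", "type", "onset_s", "end_s", "vmax_s",
                             "amplitude_um"])
    truth = GroundTruth(event_schedule=schedule, true_masks=masks)
    stacks = {
        "mtfp": ImageStack(mtfp, config.pixel_size_um, dt, "mTFP1"),
        "fret": ImageStack(fret, config.pixel_size_um, dt, "FRET"),
    }
    return stacks, truth


# --------------------------------------------------------------------------
# optogenetic perturbation scenarios


def make_perturbation_dataset(
    config: SynthConfig,
    offsets_s: tuple[float, ...] = (-10.0, -15.0, -20.0, -25.0),
    effect_um_per_s: float = 0.02,
    event_type: str = "protrusion",
    n_control: int = 200,
    n_per_group: int = 60,
    effect_rise_s: float = 20.0,
    force_effect_pa: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Control and perturbed window tables for optogenetic scenarios.

    Every sector carries exactly one event (onset early in the movie). In
    the perturbed table an additive velocity effect ramps up linearly over
    ``effect_rise_s`` starting at the activation time
    ``t_act = onset + E[duration]/2 + offset`` (offset negative = activation
    before the expected Vmax), modelling photoactivatable-Rac1 kinetics.
    ``force_effect_pa`` optionally steps the traction signal the same way.
    """
    if event_type not in ("protrusion", "retraction"):
        raise ValueError("event_type must be protrusion or retraction")
    dt = config.frame_interval_s
    times = np.arange(config.n_frames) * dt
    srng = config.schedule_rng()
    nrng = config.noise_rng()

    def one_event(sector_kind: str):
        dur = float(srng.uniform(*config.event_duration_s))
        dur = max(2 * dt, round(dur / (2 * dt)) * 2 * dt)
        amp = float(srng.uniform(*config.event_amplitude_um))
        onset = round(float(srng.uniform(40.0, 80.0)) / dt) * dt
        if sector_kind == "retraction":
            amp = -amp
        return {"type": sector_kind, "onset_s": onset, "end_s": onset + dur,
                "vmax_s": onset + dur / 2.0, "amplitude_um": amp}

    def build(sectors_events, cell_id):
        per_sector = {}
        rows = []
        for sector, (ev, t_act, offset) in enumerate(sectors_events, start=1):
            disp, vel, rac1, rhoa, force = _sector_signals(times, [ev], config)
            if t_act is not None:
                ramp = np.clip((times - t_act) / max(effect_rise_s, dt), 0.0, 1.0)
                ramp[times < t_act] = 0.0
                vel = vel + effect_um_per_s * ramp
                disp = np.concatenate([[disp[0]], disp[0] + np.cumsum(vel[1:]) * dt])
                if force_effect_pa:
                    force = force + force_effect_pa * ramp
            per_sector[sector] = (disp, vel, rac1, rhoa, force)
            rows.append({"sector": sector, **ev,
                         "t_act_s": np.nan if t_act is None else t_act,
                         "offset_s": offset})
        table = _assemble_table(per_sector, config, nrng, cell_id=cell_id)
        sched = pd.DataFrame(rows)
        return table, sched

    control_events = [(one_event(event_type), None, np.nan)
                      for _ in range(n_control)]
    control_table, control_sched = build(control_events, cell_id=0)
    # activation offsets are targeted against the mean time-to-Vmax the
    # experimenter measures on the control population
    expected_t_vmax = float(np.mean(
        [(ev["vmax_s"] - ev["onset_s"]) for ev, _, _ in control_events]))

    pert_events = []
    for offset in offsets_s:
        for _ in range(n_per_group):
            ev = one_event(event_type)
            t_act = ev["onset_s"] + expected_t_vmax + offset
            pert_events.append((ev, t_act, offset))
    pert_table, pert_sched = build(pert_events, cell_id=1)

    schedule = pd.concat([control_sched.assign(group="control"),
                          pert_sched.assign(group="perturbed")],
                         ignore_index=True)
    truth = GroundTruth(event_schedule=schedule)
    return control_table, pert_table, truth


def with_updates(config: SynthConfig, **kwargs) -> SynthConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
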