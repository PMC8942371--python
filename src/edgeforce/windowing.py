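"""Cell segmentation and edge window sampling.

The segmented cell edge is partitioned into sectors of ~1 um arc length;
behind each sector, 1-um-deep probing windows run from the edge toward the
cell center. Per sector the signed normal edge displacement between
consecutive contours gives the local protrusion (+) / retraction (-)
velocity, and per window the mean biosensor ratio / traction magnitude is
extracted into a tidy table.

Sector correspondence across frames: the sector count is fixed from the
first frame; on every later frame the equal-arc-length partition is
re-anchored at the contour point nearest the previous frame's first-sector
center, so sectors track the same material edge region for smoothly moving
contours (no merges or splits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import LinearRing, Polygon
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .events import smooth_series

__all__ = [
    "CellMaskStack",
    "WindowGrid",
    "segment_cell",
    "build_window_grid",
    "compute_edge_dynamics",
    "sample_window_means",
    "build_window_table",
    "track_cell_center",
]


@dataclass
class CellMaskStack:
    """Boolean T x H x W masks, one connected component per frame."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    failed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.failed is None:
            self.failed = np.zeros(self.data.shape[0], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class FrameGrid:
    """Per-frame window geometry: label maps plus the contour it came from."""

    sector_map: np.ndarray  # int H x W; 0 outside windows, 1..S inside
    depth_map: np.ndarray  # int H x W; 0 outside, 1..D inside
    contour_px: np.ndarray  # (N, 2) subpixel (row, col) closed contour
    arclength_um: np.ndarray  # cumulative arc length per contour vertex
    sector_of_vertex: np.ndarray  # sector index (1..S) per contour vertex
    perimeter_um: float


@dataclass
class WindowGrid:
    frames: list[FrameGrid]
    n_sectors: int
    n_depths: int
    sector_width_um: float
    depth_um: float
    pixel_size_um: float


def segment_cell(stack) -> CellMaskStack:
    """Threshold-based segmentation: Otsu threshold, largest connected
    component, hole filling, light morphological closing.

    Frames with no usable foreground are flagged failed (empty mask).
    """
    data = stack.data
    T = data.shape[0]
    masks = np.zeros(data.shape, dtype=bool)
    failed = np.zeros(T, dtype=bool)
    for t in range(T):
        frame = data[t]
        finite = frame[np.isfinite(frame)]
        if finite.size == 0 or np.ptp(finite) < 1e-12:
            failed[t] = True
            continue
        th = threshold_otsu(finite)
        fg = np.where(np.isfinite(frame), frame, -np.inf) > th
        if not fg.any():
            failed[t] = True
            continue
        lab, n = ndimage.label(fg)
        if n == 0:
            failed[t] = True
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        m = lab == keep
        m = ndimage.binary_fill_holes(m)
        m = ndimage.binary_closing(m, structure=disk(2))
        m = ndimage.binary_fill_holes(m)
        masks[t] = m
    return CellMaskStack(masks, stack.pixel_size_um, stack.frame_interval_s, failed)


def _main_contour(mask: np.ndarray, smooth_sigma_px: float = 2.0) -> np.ndarray:
    """Longest 0.5-level contour of the mask, smoothed along its length.

    Marching-squares contours of binary masks are staircases whose length
    overestimates the true boundary; a periodic Gaussian smoothing of the
    vertex coordinates (sigma in pixels of arc) recovers the subpixel edge.
    """
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    contour = max(contours, key=len)
    closed = np.allclose(contour[0], contour[-1])
    if closed:
        contour = contour[:-1]
    if smooth_sigma_px > 0 and len(contour) > 8:
        seg = np.linalg.norm(np.diff(contour, axis=0), axis=1).mean()
        sigma = smooth_sigma_px / max(seg, 1e-6)
        contour = np.column_stack([
            ndimage.gaussian_filter1d(contour[:, 0], sigma, mode="wrap"),
            ndimage.gaussian_filter1d(contour[:, 1], sigma, mode="wrap"),
        ])
    return _resample_contour(contour)


def _resample_contour(contour: np.ndarray, spacing_px: float = 0.5) -> np.ndarray:
    """Resample a closed contour at uniform arc-length spacing."""
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(round(total / spacing_px)), 8)
    targets = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack([
        np.interp(targets, arc, closed[:, 0]),
        np.interp(targets, arc, closed[:, 1]),
    ])


def _arc_lengths(contour: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Cumulative arc length (um) per vertex of the closed contour."""
    seg = np.linalg.norm(np.diff(contour, axis=0), axis=1)
    closing = np.linalg.norm(contour[0] - contour[-1])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum * pixel_size_um, (cum[-1] + closing) * pixel_size_um


def build_window_grid(
    masks: CellMaskStack,
    sector_width_um: float = 1.0,
    depth_um: float = 1.0,
    n_depths: int = 10,
) -> WindowGrid:
    """Partition the edge of every frame into S = round(perimeter/width)
    equal-arc-length sectors and the interior into 1-um depth bands.

    Raises if the first-frame cell is smaller than a single window.
    """
    px = masks.pixel_size_um
    frames: list[FrameGrid] = []
    n_sectors = None
    prev_anchor_xy = None
    for t in range(masks.n_frames):
        mask = masks.data[t]
        if not mask.any():
            raise ValueError(f"empty mask at frame {t}")
        contour = _main_contour(mask)
        arc, perimeter = _arc_lengths(contour, px)
        if n_sectors is None:
            n_sectors = int(round(perimeter / sector_width_um))
            if n_sectors < 1:
                raise ValueError("cell smaller than one window")
        # anchor the sector partition at the vertex nearest the previous
        # frame's anchor point so sectors correspond across frames
        if prev_anchor_xy is None:
            start_idx = 0
        else:
            d = np.linalg.norm(contour - prev_anchor_xy, axis=1)
            start_idx = int(np.argmin(d))
        prev_anchor_xy = contour[start_idx]
        arc0 = arc[start_idx]
        frac = np.mod(arc - arc0, perimeter) / perimeter
        sector_of_vertex = np.minimum((frac * n_sectors).astype(int), n_sectors - 1) + 1

        # depth bands from the inward Euclidean distance to the edge
        dist_um = ndimage.distance_transform_edt(mask) * px
        depth_map = np.where(mask, np.ceil(dist_um / depth_um).astype(int), 0)
        depth_map = np.where(depth_map > n_depths, 0, depth_map)
        # pixels exactly on the contour line get depth 1
        depth_map[mask & (depth_map == 0) & (dist_um <= depth_um)] = 1

        # sector assignment: nearest contour vertex
        inside = depth_map > 0
        iy, ix = np.nonzero(inside)
        tree = cKDTree(contour)
        _, nearest = tree.query(np.column_stack([iy, ix]))
        sector_map = np.zeros(mask.shape, dtype=int)
        sector_map[iy, ix] = sector_of_vertex[nearest]
        frames.append(FrameGrid(sector_map, depth_map, contour, arc,
                                sector_of_vertex, perimeter))
    return WindowGrid(frames, n_sectors, n_depths, sector_width_um, depth_um, px)


def compute_edge_dynamics(
    masks: CellMaskStack, grid: WindowGrid, dt_s: float
) -> pd.DataFrame:
    """Signed normal edge displacement and velocity per sector.

    For each sector, the mean signed distance from its frame t-1 contour
    points to the frame t contour (+ = the old edge point is now interior,
    i.e. protrusion). Velocity is the per-frame increment divided by dt;
    displacement is the cumulative sum, so velocity integrates back to
    displacement exactly.
    """
    if masks.n_frames < 2:
        raise ValueError("need at least 2 frames")
    px = grid.pixel_size_um
    S = grid.n_sectors
    T = masks.n_frames
    increments = np.zeros((S, T))
    for t in range(1, T):
        prev = grid.frames[t - 1]
        ring = LinearRing(np.vstack([grid.frames[t].contour_px,
                                     grid.frames[t].contour_px[:1]]))
        poly = Polygon(ring)
        pts = shapely.points(prev.contour_px)
        dist = shapely.distance(pts, ring) * px
        inside = shapely.contains(poly, pts)
        signed = np.where(inside, dist, -dist)
        for s in range(1, S + 1):
            sel = prev.sector_of_vertex == s
            if sel.any():
                increments[s - 1, t] = float(np.mean(signed[sel]))
    velocity = increments / dt_s
    displacement = np.cumsum(increments, axis=1)
    rows = []
    for s in range(S):
        rows.append(pd.DataFrame({
            "sector": s + 1, "frame": np.arange(T), "time_s": np.arange(T) * dt_s,
            "displacement_um": displacement[s], "velocity_um_per_s": velocity[s]}))
    return pd.concat(rows, ignore_index=True)


def sample_window_means(
    maps: np.ndarray, grid: WindowGrid, min_defined_frac: float = 0.25
) -> pd.DataFrame:
    """Per-window mean of a T x H x W value stack (NaN = undefined pixel).

    Windows in which fewer than ``min_defined_frac`` of the pixels are
    defined are reported as NaN (missing), never zero.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    S, D = grid.n_sectors, grid.n_depths
    rows = []
    for t, fg in enumerate(grid.frames):
        frame = maps[t]
        label = (fg.sector_map - 1) * D + fg.depth_map  # 1-based composite
        label = np.where((fg.sector_map > 0) & (fg.depth_map > 0), label, 0)
        nbins = S * D + 1
        finite = np.isfinite(frame)
        total = np.bincount(label.ravel(), minlength=nbins).astype(float)
        defined = np.bincount(label.ravel(), weights=finite.ravel(), minlength=nbins)
        sums = np.bincount(label.ravel(),
                           weights=np.where(finite, frame, 0.0).ravel(),
                           minlength=nbins)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / defined
        for s in range(1, S + 1):
            for d in range(1, D + 1):
                k = (s - 1) * D + d
                if total[k] == 0:
                    continue  # window absent at this depth
                frac = defined[k] / total[k]
                val = means[k] if frac >= min_defined_frac else np.nan
                rows.append({"sector": s, "depth": d, "frame": t, "value": val})
    return pd.DataFrame(rows)


def build_window_table(
    signal_maps: dict,
    masks: CellMaskStack,
    grid: WindowGrid,
    dt_s: float,
    cell_id: int = 0,
) -> pd.DataFrame:
    """Assemble the tidy window-series table from per-pixel value stacks.

    ``signal_maps`` maps column name (e.g. ``"rac1"``, ``"traction_pa"``) to
    a T x H x W array; per-sector edge displacement/velocity columns are
    depth-independent.
    """
    dyn = compute_edge_dynamics(masks, grid, dt_s)
    out = None
    for name, stack in signal_maps.items():
        sampled = sample_window_means(stack, grid).rename(columns={"value": name})
        out = sampled if out is None else out.merge(
            sampled, on=["sector", "depth", "frame"], how="outer")
    if out is None:
        raise ValueError("no signal maps given")
    out = out.merge(dyn, on=["sector", "frame"], how="left")
    out["cell_id"] = cell_id
    out = out.sort_values(["sector", "depth", "frame"]).reset_index(drop=True)
    return out


def track_cell_center(
    masks: CellMaskStack, dt_s: float, smoothing_param: float = 0.5
) -> float:
    """Migration speed (um/hour) of the smoothed center-of-area path."""
    if masks.n_frames < 2:
        raise ValueError("need at least 2 frames")
    px = masks.pixel_size_um
    centers = np.array([ndimage.center_of_mass(m) for m in masks.data]) * px
    if masks.n_frames >= 4:
        cy = smooth_series(centers[:, 0], smoothing_param, dt_s)
        cx = smooth_series(centers[:, 1], smoothing_param, dt_s)
    else:
        cy, cx = centers[:, 0], centers[:, 1]
    steps = np.hypot(np.diff(cy), np.diff(cx))
    return float(steps.mean() / dt_s * 3600.0)
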