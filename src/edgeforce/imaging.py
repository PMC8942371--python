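"""FRET ratio computation and stage-drift registration.

Ratiometric FRET biosensor processing: both channels are background
subtracted and median filtered, the FRET/donor ratio is formed, and the
ratio image is median filtered again. Registration corrects rigid stage
drift of the bead channel toward a reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tfm import correlate_shift

__all__ = ["ImageStack", "RatioStack", "compute_fret_ratio", "register_stack"]


@dataclass
class ImageStack:
    """A T x H x W intensity stack with physical calibration."""

    data: np.ndarray
    pixel_size_um: float = 0.2
    frame_interval_s: float = 10.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be T x H x W")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration fields must be positive")
        if np.nanmin(self.data) < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class RatioStack:
    """Per-pixel ratio stack; NaN marks pixels where the ratio is undefined."""

    data: np.ndarray
    pixel_size_um: float = 0.2
    frame_interval_s: float = 10.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]


def compute_fret_ratio(
    num: ImageStack,
    den: ImageStack,
    background: float | tuple[float, float] = 0.0,
    median_radius_px: int = 1,
) -> RatioStack:
    """Background-subtract and median-filter both channels, divide, and
    median-filter the ratio.

    ``background`` is a scalar applied to both channels or a (num, den)
    pair. Pixels whose denominator falls below an epsilon of the channel's
    dynamic range are marked NaN (never infinite). Negative intensities after
    background subtraction are clipped to zero.
    """
    if num.data.shape != den.data.shape:
        raise ValueError("numerator and denominator stacks must match in shape")
    if median_radius_px < 0:
        raise ValueError("median_radius_px must be >= 0")
    if np.isscalar(background):
        bg_num = bg_den = float(background)  # type: ignore[arg-type]
    else:
        bg_num, bg_den = (float(b) for b in background)  # type: ignore[misc]
    if bg_num < 0 or bg_den < 0:
        raise ValueError("background must be >= 0")

    size = 2 * median_radius_px + 1
    out = np.empty_like(num.data)
    for t in range(num.data.shape[0]):
        a = np.clip(num.data[t] - bg_num, 0, None)
        b = np.clip(den.data[t] - bg_den, 0, None)
        if median_radius_px > 0:
            a = ndimage.median_filter(a, size=size)
            b = ndimage.median_filter(b, size=size)
        rng = float(b.max() - b.min())
        eps = 1e-6 * rng if rng > 0 else 1e-12
        ratio = np.where(b > eps, a / np.where(b > eps, b, 1.0), np.nan)
        if median_radius_px > 0:
            finite = np.isfinite(ratio)
            # median-filter defined pixels only; NaNs stay NaN
            tmp = np.where(finite, ratio, 0.0)
            filt = ndimage.median_filter(tmp, size=size)
            ratio = np.where(finite, filt, np.nan)
        out[t] = ratio
    return RatioStack(out, num.pixel_size_um, num.frame_interval_s)


def register_stack(
    stack: ImageStack, reference: np.ndarray, max_shift_px: float = 32.0
) -> tuple[ImageStack, "np.ndarray"]:
    """Register every frame toward ``reference`` (translation only).

    Drift is estimated by the correlation peak (integer peak + parabolic
    subpixel refinement). Returns the shifted stack and per-frame records
    ``(dy_px, dx_px, failed)``; offsets are the corrections applied. An
    all-flat frame cannot be registered; it is flagged and the previous
    frame's offset is carried forward.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != stack.data.shape[1:]:
        raise ValueError("reference must match the frame geometry")
    T = stack.n_frames
    offsets = np.zeros((T, 2))
    failed = np.zeros(T, dtype=bool)
    registered = np.empty_like(stack.data)
    prev = np.zeros(2)
    for t in range(T):
        frame = stack.data[t]
        drift = correlate_shift(reference, frame, max_shift_px)
        if drift is None:
            failed[t] = True
            shift = prev
        else:
            shift = -np.asarray(drift)  # correction undoes the drift
        offsets[t] = shift
        prev = shift
        registered[t] = ndimage.shift(frame, shift, order=1, mode="nearest")
    reg = ImageStack(
        registered, stack.pixel_size_um, stack.frame_interval_s, stack.channel
    )
    record = np.column_stack([offsets, failed.astype(float)])
    return reg, record
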