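"""Traction force microscopy: bead-displacement PIV and Fourier-transform
traction cytometry (FTTC).

The substrate is modelled as a linear elastic half space (Boussinesq
solution). In Fourier space the surface displacement ``u(k)`` produced by a
tangential traction ``t(k)`` is ``u = G(k) t`` with the 2x2 kernel

    G(k) = 2 (1 + nu) / (E k^3) * [[(1-nu) k^2 + nu ky^2,  -nu kx ky],
                                   [-nu kx ky,  (1-nu) k^2 + nu kx^2]]

where ``E`` is the Young's modulus and ``nu`` the Poisson ratio. The inverse
problem is solved per wavevector with zeroth-order Tikhonov regularization;
the DC component is set to zero (no net translation / zero net force
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline, griddata

__all__ = [
    "ElasticParams",
    "DisplacementField",
    "TractionMap",
    "correlate_shift",
    "estimate_displacement_field",
    "fttc_forward",
    "fttc_inverse",
    "fill_gaps",
    "smooth_field",
    "reconstruct_traction",
    "mean_traction_in_region",
]


@dataclass
class ElasticParams:
    """Elastic substrate parameters.

    youngs_modulus_pa : Young's modulus E in Pa (> 0).
    poisson_ratio     : nu, dimensionless, in [0, 0.5]; 0.5 is the
                        incompressible-gel convention for polyacrylamide.
    reg_lambda        : Tikhonov weight (um/Pa); 0 disables regularization.
    """

    youngs_modulus_pa: float = 6900.0
    poisson_ratio: float = 0.5
    reg_lambda: float = 1e-4

    def __post_init__(self) -> None:
        if self.youngs_modulus_pa <= 0:
            raise ValueError("youngs_modulus_pa must be > 0")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")


@dataclass
class DisplacementField:
    """Gridded in-plane displacement field.

    ``u_um``/``v_um`` are displacements along x (columns) and y (rows) in um
    on a regular grid with node spacing ``spacing_um``. ``valid`` flags nodes
    where the estimate is trustworthy.
    """

    u_um: np.ndarray
    v_um: np.ndarray
    spacing_um: float
    x_px: np.ndarray | None = None
    y_px: np.ndarray | None = None
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.u_um = np.asarray(self.u_um, dtype=float)
        self.v_um = np.asarray(self.v_um, dtype=float)
        if self.u_um.shape != self.v_um.shape:
            raise ValueError("u and v grids must have the same shape")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if self.valid is None:
            self.valid = np.ones(self.u_um.shape, dtype=bool)

    @property
    def magnitude_um(self) -> np.ndarray:
        return np.hypot(self.u_um, self.v_um)


@dataclass
class TractionMap:
    """Gridded surface stress field in Pa."""

    tx_pa: np.ndarray
    ty_pa: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        self.tx_pa = np.asarray(self.tx_pa, dtype=float)
        self.ty_pa = np.asarray(self.ty_pa, dtype=float)
        if self.tx_pa.shape != self.ty_pa.shape:
            raise ValueError("tx and ty grids must have the same shape")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")

    @property
    def magnitude_pa(self) -> np.ndarray:
        return np.hypot(self.tx_pa, self.ty_pa)


def _boussinesq_kernel(shape, spacing_um, params):
    """Return G11, G12, G22 (um/Pa) on the FFT frequency grid; DC left at 0."""
    ny, nx = shape
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing_um)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing_um)
    KX, KY = np.meshgrid(kx, ky)
    k = np.hypot(KX, KY)
    k_safe = np.where(k == 0, 1.0, k)
    E = params.youngs_modulus_pa
    nu = params.poisson_ratio
    pref = 2.0 * (1.0 + nu) / (E * k_safe**3)
    g11 = pref * ((1.0 - nu) * k_safe**2 + nu * KY**2)
    g22 = pref * ((1.0 - nu) * k_safe**2 + nu * KX**2)
    g12 = pref * (-nu * KX * KY)
    dc = k == 0
    g11[dc] = g22[dc] = g12[dc] = 0.0
    return g11, g12, g22


def fttc_forward(traction: TractionMap, params: ElasticParams) -> DisplacementField:
    """Surface displacement produced by a traction field (no regularization)."""
    g11, g12, g22 = _boussinesq_kernel(traction.tx_pa.shape, traction.spacing_um, params)
    Tx = np.fft.fft2(traction.tx_pa)
    Ty = np.fft.fft2(traction.ty_pa)
    U = g11 * Tx + g12 * Ty
    V = g12 * Tx + g22 * Ty
    u = np.fft.ifft2(U).real
    v = np.fft.ifft2(V).real
    return DisplacementField(u_um=u, v_um=v, spacing_um=traction.spacing_um)


def fttc_inverse(field: DisplacementField, params: ElasticParams) -> TractionMap:
    """Recover traction from a gap-filled regular displacement field.

    Solves ``(G^T G + lambda^2 I) t = G^T u`` per wavevector; the zero
    frequency (rigid translation / net force) is suppressed.
    """
    if not np.all(np.isfinite(field.u_um)) or not np.all(np.isfinite(field.v_um)):
        raise ValueError("displacement field contains non-finite values; gap-fill first")
    g11, g12, g22 = _boussinesq_kernel(field.u_um.shape, field.spacing_um, params)
    U = np.fft.fft2(field.u_um)
    V = np.fft.fft2(field.v_um)
    lam2 = params.reg_lambda**2
    # G is symmetric; normal equations stay 2x2 per wavevector.
    a11 = g11 * g11 + g12 * g12 + lam2
    a12 = g11 * g12 + g12 * g22
    a22 = g12 * g12 + g22 * g22 + lam2
    b1 = g11 * U + g12 * V
    b2 = g12 * U + g22 * V
    det = a11 * a22 - a12 * a12
    dc = np.zeros(det.shape, dtype=bool)
    dc[0, 0] = True
    det_safe = np.where(dc | (det == 0), 1.0, det)
    Tx = (a22 * b1 - a12 * b2) / det_safe
    Ty = (a11 * b2 - a12 * b1) / det_safe
    Tx[dc] = Ty[dc] = 0.0
    Tx[det == 0] = Ty[det == 0] = 0.0
    tx = np.fft.ifft2(Tx).real
    ty = np.fft.ifft2(Ty).real
    return TractionMap(tx_pa=tx, ty_pa=ty, spacing_um=field.spacing_um)


def correlate_shift(
    a: np.ndarray, b: np.ndarray, max_shift_px: float
) -> tuple[float, float] | None:
    """Rigid (dy, dx) displacement of ``b`` relative to ``a``.

    Zero-padded FFT cross-correlation of the mean-subtracted images with
    overlap-area correction (removes the bias of circular correlation toward
    zero lag), integer peak restricted to ``max_shift_px``, parabolic
    subpixel refinement. Returns None when either image is flat.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have identical shapes")
    a0 = a - a.mean()
    b0 = b - b.mean()
    if a0.std() < 1e-12 or b0.std() < 1e-12:
        return None
    ny, nx = a.shape
    my, mx = 2 * ny, 2 * nx
    c = np.fft.ifft2(np.fft.fft2(b0, (my, mx)) * np.conj(np.fft.fft2(a0, (my, mx)))).real
    c = np.fft.fftshift(c)
    cy, cx = my // 2, mx // 2
    wy = np.clip(ny - np.abs(np.arange(-cy, my - cy)), 1, None) / ny
    wx = np.clip(nx - np.abs(np.arange(-cx, mx - cx)), 1, None) / nx
    c = c / np.outer(wy, wx)
    sy = int(min(max_shift_px, ny // 2 - 1))
    sx = int(min(max_shift_px, nx // 2 - 1))
    sub = c[cy - sy : cy + sy + 1, cx - sx : cx + sx + 1]
    p = np.unravel_index(np.argmax(sub), sub.shape)
    peak = (p[0] + cy - sy, p[1] + cx - sx)
    dy, dx = _subpixel_offset(c, peak)
    return (peak[0] - cy + dy, peak[1] - cx + dx)


def _peak_interp(c0: float, cm: float, cp: float) -> float:
    """1D subpixel offset of a correlation peak from its two neighbours.

    Gaussian (log-parabolic) interpolation when all three samples are
    positive — exact for Gaussian-shaped peaks — with a parabolic fallback.
    """
    if min(c0, cm, cp) > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = 2.0 * (2.0 * l0 - lm - lp)
        if denom > 0:
            return float(np.clip((lp - lm) / denom, -1.0, 1.0))
    denom = 2.0 * (2.0 * c0 - cm - cp)
    if denom != 0:
        return float(np.clip((cp - cm) / denom, -1.0, 1.0))
    return 0.0


def _subpixel_offset(c: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Subpixel refinement of a 2D correlation peak, one axis at a time."""
    py, px = peak
    dy = dx = 0.0
    if 0 < py < c.shape[0] - 1:
        dy = _peak_interp(c[py, px], c[py - 1, px], c[py + 1, px])
    if 0 < px < c.shape[1] - 1:
        dx = _peak_interp(c[py, px], c[py, px - 1], c[py, px + 1])
    return dy, dx


def estimate_displacement_field(
    image: np.ndarray,
    reference: np.ndarray,
    window_px: int = 32,
    spacing_px: int = 8,
    pixel_size_um: float = 0.2,
    max_shift_px: float | None = None,
    n_passes: int = 2,
) -> DisplacementField:
    """PIV bead-displacement estimation between a deformed image and its
    cell-free reference.

    Interrogation windows of ``window_px`` are centred on a regular node grid
    with ``spacing_px`` spacing; per node the FFT cross-correlation peak of the
    mean-subtracted windows is refined by parabolic fits. Flat windows (no
    beads) are flagged invalid; outliers under the normalized-median test are
    replaced by the local median and flagged. With ``n_passes`` > 1 the
    image is iteratively un-warped by the current field estimate and a
    correction pass is added (predictor-corrector window deformation), which
    suppresses the bias from displacement gradients inside a window.
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    field = _piv_single_pass(image, reference, window_px, spacing_px,
                             pixel_size_um, max_shift_px)
    for _ in range(n_passes - 1):
        filled = fill_gaps(field)
        warped = _unwarp(image, filled, pixel_size_um)
        inc = _piv_single_pass(warped, reference, window_px, spacing_px,
                               pixel_size_um, max_shift_px)
        field = DisplacementField(
            u_um=filled.u_um + inc.u_um,
            v_um=filled.v_um + inc.v_um,
            spacing_um=field.spacing_um,
            x_px=field.x_px,
            y_px=field.y_px,
            valid=inc.valid,
        )
    return field


def _unwarp(image: np.ndarray, field: DisplacementField, pixel_size_um: float) -> np.ndarray:
    """Pull the deformed image back by the field (sample at x + u)."""
    H, W = image.shape
    fu = RectBivariateSpline(field.y_px, field.x_px, field.u_um / pixel_size_um,
                             kx=1, ky=1)
    fv = RectBivariateSpline(field.y_px, field.x_px, field.v_um / pixel_size_um,
                             kx=1, ky=1)
    yy = np.arange(H)
    xx = np.arange(W)
    U = fu(yy, xx)
    V = fv(yy, xx)
    YY, XX = np.mgrid[0:H, 0:W]
    return ndimage.map_coordinates(image, [YY + V, XX + U], order=3, mode="nearest")


def _piv_single_pass(
    image: np.ndarray,
    reference: np.ndarray,
    window_px: int,
    spacing_px: int,
    pixel_size_um: float,
    max_shift_px: float | None,
) -> DisplacementField:
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError("image and reference must have identical shapes")
    if window_px < 8:
        raise ValueError("window_px must be >= 8")
    H, W = image.shape
    half = window_px // 2
    if max_shift_px is None:
        max_shift_px = window_px / 4.0
    ys = np.arange(half, H - half + 1, spacing_px)
    xs = np.arange(half, W - half + 1, spacing_px)
    u = np.zeros((len(ys), len(xs)))
    v = np.zeros((len(ys), len(xs)))
    valid = np.ones((len(ys), len(xs)), dtype=bool)
    for i, yc in enumerate(ys):
        for j, xc in enumerate(xs):
            a = reference[yc - half : yc + half, xc - half : xc + half]
            b = image[yc - half : yc + half, xc - half : xc + half]
            # displacement of b (deformed) relative to a (reference)
            shift = correlate_shift(a, b, max_shift_px)
            if shift is None:
                valid[i, j] = False
                continue
            v[i, j] = shift[0] * pixel_size_um
            u[i, j] = shift[1] * pixel_size_um
    u, v, valid = _median_outlier_filter(u, v, valid)
    return DisplacementField(
        u_um=u,
        v_um=v,
        spacing_um=spacing_px * pixel_size_um,
        x_px=xs,
        y_px=ys,
        valid=valid,
    )


def _median_outlier_filter(u, v, valid, thresh: float = 2.0, eps: float = 0.02):
    """Westerweel normalized-median test; outliers -> local median, flagged."""
    out_u = u.copy()
    out_v = v.copy()
    valid = valid.copy()
    for comp, out in ((u, out_u), (v, out_v)):
        med = ndimage.median_filter(comp, size=3, mode="nearest")
        resid = np.abs(comp - med)
        resid_med = ndimage.median_filter(resid, size=3, mode="nearest")
        r = resid / (resid_med + eps)
        bad = (r > thresh) & valid
        out[bad] = med[bad]  # replaced by local median, node flagged
        valid[bad] = False
    return out_u, out_v, valid


def fill_gaps(field: DisplacementField) -> DisplacementField:
    """Bilinear interpolation of invalid nodes (nearest fallback at borders)."""
    if field.valid.all():
        return field
    if not field.valid.any():
        raise ValueError("no valid nodes to interpolate from")
    yy, xx = np.mgrid[0 : field.u_um.shape[0], 0 : field.u_um.shape[1]]
    pts = np.column_stack([yy[field.valid], xx[field.valid]])
    tgt = np.column_stack([yy.ravel(), xx.ravel()])
    filled = {}
    for name, comp in (("u", field.u_um), ("v", field.v_um)):
        lin = griddata(pts, comp[field.valid], tgt, method="linear")
        near = griddata(pts, comp[field.valid], tgt, method="nearest")
        lin = np.where(np.isnan(lin), near, lin)
        filled[name] = lin.reshape(comp.shape)
    return DisplacementField(
        u_um=filled["u"],
        v_um=filled["v"],
        spacing_um=field.spacing_um,
        x_px=field.x_px,
        y_px=field.y_px,
        valid=np.ones_like(field.valid),
    )


def smooth_field(field: DisplacementField, sigma_nodes: float = 1.2) -> DisplacementField:
    """Gaussian low-pass of the node field before inversion.

    The inverse elastic operator amplifies like |k|, so white measurement
    noise at the PIV noise floor dominates the traction estimate unless the
    field is band-limited first; ``sigma_nodes`` is in node-grid units.
    """
    if sigma_nodes <= 0:
        return field
    return DisplacementField(
        u_um=ndimage.gaussian_filter(field.u_um, sigma_nodes),
        v_um=ndimage.gaussian_filter(field.v_um, sigma_nodes),
        spacing_um=field.spacing_um,
        x_px=field.x_px,
        y_px=field.y_px,
        valid=field.valid,
    )


def reconstruct_traction(
    image: np.ndarray,
    reference: np.ndarray,
    params: ElasticParams,
    window_px: int = 32,
    spacing_px: int = 8,
    pixel_size_um: float = 0.2,
    smooth_sigma_nodes: float = 1.2,
    n_passes: int = 2,
) -> tuple[TractionMap, DisplacementField]:
    """Full inverse pipeline: PIV -> gap fill -> band-limit -> FTTC."""
    field = estimate_displacement_field(image, reference, window_px, spacing_px,
                                        pixel_size_um, n_passes=n_passes)
    field = fill_gaps(field)
    field = smooth_field(field, smooth_sigma_nodes)
    return fttc_inverse(field, params), field


def mean_traction_in_region(traction: TractionMap, mask: np.ndarray) -> float:
    """Mean traction magnitude (Pa) over the masked nodes."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != traction.tx_pa.shape:
        raise ValueError("mask shape must match the traction grid")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(traction.magnitude_pa[mask].mean())
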