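import numpy as np
import pytest

from edgeforce import synthdata, tfm


def disk_mask(r_px: float, n: int = 128, center: float | None = None) -> np.ndarray:
    c = (n - 1) / 2 if center is None else center
    yy, xx = np.mgrid[0:n, 0:n]
    return np.hypot(yy - c, xx - c) <= r_px


@pytest.fixture(scope="session")
def traction_patch():
    """Smooth dipole traction patch (sigma 8 um, 400 Pa) on a 256-px grid."""
    px = 0.2
    n = 256
    yy, xx = np.mgrid[0:n, 0:n]
    s = 8.0 / px
    tx = 400.0 * np.exp(-((yy - 80) ** 2 + (xx - 80) ** 2) / (2 * s**2))
    tx -= 400.0 * np.exp(-((yy - 176) ** 2 + (xx - 176) ** 2) / (2 * s**2))
    return tfm.TractionMap(tx_pa=tx, ty_pa=0.6 * tx, spacing_um=px)


@pytest.fixture(scope="session")
def bead_reference():
    """A static bead-channel frame for registration tests."""
    n = 128
    zero = tfm.DisplacementField(np.zeros((n, n)), np.zeros((n, n)), 0.2)
    ref, _, _ = synthdata.make_bead_pair(zero, synthdata.SynthConfig(seed=5))
    return ref


@pytest.fixture(scope="session")
def default_table():
    """Mid-size window-series table with generator defaults (seeded)."""
    cfg = synthdata.SynthConfig(n_sectors=40, n_frames=200, n_depths=2, seed=9)
    table, truth = synthdata.make_window_series(cfg)
    return table, truth, cfg
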