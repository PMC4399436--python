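import numpy as np
import pytest

from epidose.beam_model import default_beam_model
from epidose.grids import DensityGrid, TermaGrid


@pytest.fixture(scope="session")
def beam_model():
    return default_beam_model()


def make_uniform_grid(n=21, spacing=0.25, density=1.0):
    origin = -(n - 1) / 2 * spacing * np.ones(3)
    return DensityGrid(
        density * np.ones((n, n, n)), spacing * np.ones(3), origin
    )


def make_point_terma(density_grid, value=1.0):
    t = np.zeros(density_grid.values.shape)
    c = tuple(s // 2 for s in t.shape)
    t[c] = value
    return TermaGrid(t, density_grid.spacing_cm.copy(), density_grid.origin_cm.copy())


def smooth_dose_pair(n=20, seed=1, sigma=10.0, amp=0.035, spacing=0.1):
    """Random smooth reference/evaluated dose pair at 1 mm spacing.

    Smoothness is chosen so the gamma minimizers are resolved by both the
    0.2 mm shell search and the 0.1 mm brute-force lattice.
    """
    from scipy.ndimage import gaussian_filter

    from epidose.grids import DoseGrid

    rng = np.random.default_rng(seed)
    v = gaussian_filter(rng.uniform(0.0, 1.0, (n, n, n)), sigma)
    v = 0.45 + 0.10 * (v - v.min()) / (v.max() - v.min())
    w = gaussian_filter(rng.uniform(-1.0, 1.0, (n, n, n)), sigma)
    e = v + amp * v.max() * w / np.abs(w).max()
    origin = -0.5 * (n - 1) * spacing * np.ones(3)
    return (
        DoseGrid(v, spacing * np.ones(3), origin),
        DoseGrid(e, spacing * np.ones(3), origin),
    )


@pytest.fixture(scope="session")
def water21(beam_model):
    """21^3 water grid, point TERMA, engine + oracle doses (shared, costly)."""
    from epidose.engine import collapsed_cone_superpose, point_kernel_superpose_oracle

    den = make_uniform_grid(21, 0.25)
    terma = make_point_terma(den)
    dose_cc = collapsed_cone_superpose(terma, den, beam_model.cck, beam_model.cone_set)
    dose_or = point_kernel_superpose_oracle(terma, den, beam_model.point_kernel)
    return den, terma, dose_cc, dose_or
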