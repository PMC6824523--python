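import numpy as np
import pytest

from uncsampler import default_config
from uncsampler.config import EfficiencyCurve


@pytest.fixture
def cfg():
    """Default analysis physics: f_V=1.6, χ=1.4, ρ=2.0, unit efficiency."""
    return default_config()


@pytest.fixture
def sphere_cfg():
    """Sphere limit: f_V = π/6, χ = 1, ρ_p = ρ₀ — every diameter collapses."""
    return default_config().with_(
        volume_shape_factor=np.pi / 6.0,
        dynamic_shape_factor=1.0,
        particle_density_g_cm3=1.0,
    )


@pytest.fixture
def degraded_curve():
    return EfficiencyCurve.default_placeholder()


def random_histogram(rng, n_bins=256):
    """A random bimodal-ish grey-level histogram with ≥2 populated bins."""
    mode = rng.integers(0, 3)
    hist = np.zeros(n_bins, dtype=np.int64)
    if mode == 0:  # two gaussian humps
        lo = rng.normal(rng.uniform(40, 100), rng.uniform(3, 20), size=rng.integers(200, 5000))
        hi = rng.normal(rng.uniform(120, 220), rng.uniform(3, 20), size=rng.integers(10, 2000))
        vals = np.clip(np.concatenate([lo, hi]).astype(int), 0, n_bins - 1)
        hist = np.bincount(vals, minlength=n_bins)
    elif mode == 1:  # uniform sparse
        idx = rng.choice(n_bins, size=rng.integers(2, 40), replace=False)
        hist[idx] = rng.integers(1, 1000, size=len(idx))
    else:  # single hump plus a few outliers
        vals = np.clip(rng.normal(128, 30, size=rng.integers(100, 3000)).astype(int), 0, n_bins - 1)
        hist = np.bincount(vals, minlength=n_bins)
        hist[rng.integers(0, n_bins)] += rng.integers(1, 50)
    if np.count_nonzero(hist) < 2:  # ensure non-degenerate
        hist[10] += 1
        hist[200] += 1
    return hist
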