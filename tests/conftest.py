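import numpy as np
import pytest

from lesiontrack.synthesis import SimulationConfig, render_series


def clean_kwargs(**overrides):
    """A defect-free, low-nuisance configuration for geometry tests."""
    kw = dict(p_missing_day=0.0, p_no_dot=0.0, p_duplicate=0.0,
              p_wrong_angle=0.0, noise_sd=0.0, colour_cast_sd=0.0,
              lighting_gain_range=(1.0, 1.0), tilt_max_deg=0.0,
              annotation_jitter_px=0.0, area_noise_sd=0.0)
    kw.update(overrides)
    return kw


@pytest.fixture(scope="session")
def clean_series():
    """3 lesions × 10 days, no defect processes, mild photometric nuisance."""
    cfg = SimulationConfig(n_lesions=3, n_days=10, rng_seed=11,
                           **clean_kwargs(noise_sd=2.0, tilt_max_deg=8.0,
                                          lighting_gain_range=(0.9, 1.1)))
    return cfg, render_series(cfg)


@pytest.fixture(scope="session")
def batch200():
    """200 defect-free images (20 lesions × 10 days) with realistic nuisance."""
    cfg = SimulationConfig(n_lesions=20, n_days=10, rng_seed=2026,
                           p_missing_day=0.0, p_no_dot=0.0, p_duplicate=0.0,
                           p_wrong_angle=0.0)
    images, truths, _ = render_series(cfg)
    assert len(images) == 200
    return cfg, images, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
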