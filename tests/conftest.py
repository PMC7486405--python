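import numpy as np
import pytest

import lcrclim as lc


@pytest.fixture(scope="session")
def small_config():
    """12 counties x 10 years: big enough to estimate, fast enough to share."""
    return lc.GeneratorConfig(n_states=3, counties_per_state=4,
                              years=(2000, 2009), seed=42)


@pytest.fixture(scope="session")
def small_sim(small_config):
    weather = lc.generate_weather(small_config)
    losses, liabilities, truth = lc.generate_losses(weather, small_config)
    return weather, losses, liabilities, truth


@pytest.fixture(scope="session")
def small_panel(small_config, small_sim):
    """LCR panel merged with the full degree-day schedule."""
    weather, losses, liabilities, _ = small_sim
    lcr = lc.build_lcr_panel(losses, liabilities, crop=small_config.crop)
    expo = lc.season_exposure(weather, small_config.season)
    return lc.merge_exposures(lcr, expo)


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Noise-free draw: the latent process is exactly the estimation model."""
    cfg = lc.GeneratorConfig(n_states=3, counties_per_state=4,
                             years=(2000, 2009), seed=7, noise_sd=0.0,
                             county_effect_sd=0.0, year_effect_sd=0.0,
                             dropout_rate=0.0)
    weather = lc.generate_weather(cfg)
    losses, liabilities, truth = lc.generate_losses(weather, cfg)
    return cfg, weather, losses, liabilities, truth


def numeric_daily_dd(tmin, tmax, threshold, steps=100_000):
    """Independent oracle: trapezoid-free Riemann mean of the sine curve's
    exceedance over one diurnal period."""
    t = np.linspace(0.0, 2 * np.pi, steps, endpoint=False)
    m = 0.5 * (tmax + tmin)
    w = 0.5 * (tmax - tmin)
    return float(np.maximum(0.0, m + w * np.sin(t) - threshold).mean())
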