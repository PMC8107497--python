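import numpy as np
import pytest

from nflreflect import maps, pipeline
from nflreflect.synthdata import SimulationConfig


@pytest.fixture(scope="session")
def small_config():
    """Fast generator configuration used across tests (128 px grid)."""
    return SimulationConfig(seed=11, grid_n=128)


@pytest.fixture(scope="session")
def small_grid(small_config):
    n = small_config.grid_n
    return pipeline.build_default_grid((n, n), small_config.pixel_size_mm,
                                       bend=small_config.trajectory_bend)


@pytest.fixture()
def flat_reflectance():
    """Constant 0 dB reflectance map, valid outside a 0.9 mm disc."""
    n = 128
    p = 4.5 / n
    r = maps.radius_map((n, n), p)
    valid = r >= 0.9
    values = np.where(valid, 0.0, np.nan)
    return maps.ReflectanceMap(values, valid, pixel_size_mm=p)


def harmonic_map(n=128, const=0.0, a1=0.0, phi1=0.0, a2=0.0, phi2=0.0, disc_r=0.9):
    """Reflectance map with prescribed azimuthal harmonic content."""
    p = 4.5 / n
    r = maps.radius_map((n, n), p)
    x, y = maps.pixel_grid_mm((n, n), p)
    th = np.arctan2(y, x)
    vals = const + a1 * np.cos(th - phi1) + a2 * np.cos(2 * th - phi2)
    valid = r >= disc_r
    return maps.ReflectanceMap(np.where(valid, vals, np.nan), valid, pixel_size_mm=p)
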