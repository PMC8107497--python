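"""Remove beam-incidence-angle bias by azimuthal band-stop filtering.

Injects a known first-degree harmonic (the signature of a tilted OCT
beam) into a map and shows that the filter annihilates it while leaving
the azimuthal mean and higher-degree structure untouched.  Then
demonstrates the repeatability gain on repeated scans of the same eyes.
"""

import numpy as np

from nflreflect import azfilter, grid, maps, pipeline, stats
from nflreflect.synthdata import SimulationConfig, make_eye, make_repeat_scans

# --- bias annihilation on a constructed map -------------------------------
n, p = 160, 4.5 / 160
r = maps.radius_map((n, n), p)
x, y = maps.pixel_grid_mm((n, n), p)
theta = np.arctan2(y, x)
bias = 1.8 * np.cos(theta - 0.9)          # incidence-angle bias, 1.8 dB
structure = 1.2 * np.cos(2 * theta)       # genuine double-hump-like content
valid = r >= 0.9
m = maps.ReflectanceMap(np.where(valid, structure + bias, np.nan), valid, pixel_size_mm=p)
filtered = azfilter.azimuthal_filter(m)
ann = (r >= 1.1) & (r <= 2.0)
resid = np.nanmax(np.abs(filtered.values_db[ann] - structure[ann]))
print(f"max residual after removing a 1.8 dB bias: {resid:.2e} dB (machine precision)")

# --- repeatability on repeat scans ----------------------------------------
config = SimulationConfig(seed=2, grid_n=128)
g = pipeline.build_default_grid((128, 128), config.pixel_size_mm)
rng = np.random.default_rng(2)
before, after = [], []
for i in range(10):
    truth = make_eye(config, "normal", rng, f"eye-{i}")
    vu, vf = [], []
    for nfl, ppec in make_repeat_scans(config, truth, 2, rng):
        refl = maps.normalize_to_db(pipeline.ratio_pipeline(nfl, ppec), config.ratio_scale)
        vu.append(grid.aggregate(refl, g))
        vf.append(grid.aggregate(azfilter.azimuthal_filter(refl), g))
    before.append(np.array(vu))
    after.append(np.array(vf))
print(f"pooled repeat-scan SD: {stats.pooled_sd(before):.2f} dB unfiltered "
      f"-> {stats.pooled_sd(after):.2f} dB filtered")
# The drop is the measurement-noise reduction the filter buys: the bias
# changes between repeat scans and the band-stop removes it.
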