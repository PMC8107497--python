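"""Build a normalized NFL reflectance map for one synthetic eye.

Generates an NFL-band and a PPEC-band intensity map, forms their ratio,
inpaints vessel shadows, normalizes by the annulus reference and converts
to dB, then removes the first-degree azimuthal harmonic.
"""

import numpy as np

from nflreflect import maps, pipeline
from nflreflect.synthdata import SimulationConfig, make_eye, make_normal_map

config = SimulationConfig(seed=1, grid_n=160)
rng = np.random.default_rng(1)
truth = make_eye(config, "normal", rng, "demo-eye")
nfl, ppec = make_normal_map(config, truth.age, truth.axial_length, rng, truth=truth)

ratio = pipeline.ratio_pipeline(nfl, ppec)
norm_const = maps.annulus_mean(ratio)  # single-eye stand-in for the population constant
refl = pipeline.process_scan(nfl, ppec, norm_const)

ann = (refl.radius() >= 1.1) & (refl.radius() <= 2.0) & refl.valid_mask
print(f"eye age {truth.age:.0f} y, axial length {truth.axial_length:.1f} mm, "
      f"incidence bias {truth.bias_amp:.2f} dB")
print(f"normalization constant (linear ratio): {norm_const:.3f}")
print(f"annulus reflectance: mean {np.mean(refl.values_db[ann]):+.2f} dB, "
      f"SD {np.std(refl.values_db[ann]):.2f} dB")
# The mean is ~0 dB by construction (the map is normalized to the annulus
# reference); the SD reflects the double-hump angular profile plus noise.
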