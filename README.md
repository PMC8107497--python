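# nflreflect

Peripapillary **nerve fiber layer (NFL) reflectance analysis** for glaucoma
diagnosis from en-face OCT maps.

Glaucoma destroys retinal ganglion-cell axons, and the NFL's OCT
reflectivity falls before the layer measurably thins. Raw reflectivity is a
poor diagnostic, though, because it is confounded by beam coupling (media
opacity, defocus) and by the beam incidence angle, which varies across any
clinical scan. This package implements a processing chain that strips those
confounds and quantifies the focal loss that early glaucoma produces:

1. **Normalized reflectance map** — the axially summed NFL-band intensity is
   divided by the mean intensity of the photoreceptor/pigment-epithelium
   complex (PPEC) band, which shares the beam-coupling attenuation but not
   the NFL's angle sensitivity. The ratio is referenced to a
   normal-population constant and expressed in dB; vessel shadows are
   inpainted from neighboring pixels.
2. **Azimuthal band-stop filter** — beam tilt imposes a first-degree angular
   harmonic `a1·cos θ + b1·sin θ` on the peripapillary annulus. The filter
   estimates and removes exactly this component per radial ring (masked
   least squares at the exact pixel azimuths), preserving the azimuthal
   mean and all higher harmonics that carry nerve-fiber-bundle defects.
3. **Equal-flux superpixel grid** — the 1.1–2.0 mm annulus is divided into
   32 tracks parallel to the arcuate fiber trajectories × 5 radial
   segments = 160 superpixels. Track widths equalize nerve-fiber flux, so
   the glaucoma-vulnerable arcuate bundles get denser coverage.
4. **Normative model** — a linear mixed-effects fit on normal eyes
   (superpixel as random effect; age, axial length, their interaction and
   gender as fixed effects) yields per-superpixel Gaussian reference bands
   after adjustment to age 50 and the reference axial length, with 5% and
   1% cutoffs `μ_s − 1.6449 σ_s` and `μ_s − 2.3263 σ_s`.
5. **Diagnostic parameters** — average reflectance (mean of the 160
   adjusted values); low-reflectance superpixel count (below the 5%
   cutoff); **focal reflectance loss**
   `FL = Σ_{s low} (x_s − μ_s) / 160` (dB, ≤ 0); and a five-way defect
   pattern (diffuse / wedge / other-grouping / isolated / none) from
   connected components on the track×segment lattice.
6. **Statistics** — clustered-data nonparametric AROC (cluster-robust
   variance), sensitivity at 99% specificity via a KDE-estimated cutoff,
   exact McNemar and Wilcoxon tests, pooled-SD repeatability, bootstrap
   comparison of Pearson correlations, 0.632+ bootstrap cross-validation,
   Gaussian-mixture clustering of focal-vs-diffuse loss, and two-segment
   piecewise regression against visual-field mean deviation.

A first-class synthetic-data module generates eyes with the double-hump
angular reflectance profile, realistic population variability, per-scan
incidence bias, vessel masks and parameterized wedge/diffuse defects, so
the entire pipeline is testable without clinical data.

## Worked example

```python
import numpy as np
from nflreflect import metrics, normative, pipeline
from nflreflect.synthdata import SimulationConfig, make_cohort

config = SimulationConfig(seed=4, n_normal=35, n_ppg=0, n_pg=5, grid_n=128)
cohort, gt = pipeline.process_cohort(make_cohort(config), config)
model = normative.fit_lme(cohort, method="lme")

cov = cohort.covariates
i = int(np.flatnonzero(cov.group == "PG")[0])
adjusted = normative.adjust(cohort.vectors[i], cov.age[i], cov.axial_length[i], model)
result = metrics.compute_diagnostics(adjusted, model)
```

Run as `python examples/04_normative_and_diagnostics.py`, this prints:

```
PG eye PG-000 (VF MD -4.6 dB):
  average reflectance: -9.17 dB
  low-reflectance superpixels (5% / 1% cutoff): 160 / 156 of 160
  focal reflectance loss: -8.98 dB
  defect pattern: diffuse
```

The eye's adjusted reflectance sits far below the normative bands in every
superpixel (count 160/160), the focal loss of −9 dB quantifies how far, and
the full-width contiguous extent of the low region classifies the defect as
diffuse — the severe-glaucoma signature. A healthy eye prints values near
0 dB, counts near the nominal 5% false-positive level (≈ 8 of 160) and
pattern `none`. The scripts in `examples/` walk through each capability
(map construction, filtering, grid, normative model, cohort statistics)
with one runnable narrative apiece.

A thin CLI mirrors the pipeline for shell use:

```bash
nflreflect simulate --seed 1 --out run/
nflreflect evaluate --cohort run/cohort.csv --out run/eval/
```

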