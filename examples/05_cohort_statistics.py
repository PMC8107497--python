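"""Diagnostic-accuracy statistics on a full synthetic cohort.

Simulates a 35/30/35 normal/preperimetric/perimetric cohort, evaluates
the three reflectance parameters (clustered-data AROC, sensitivity at
99% specificity), clusters focal-vs-average loss with a Gaussian
mixture, and fits the two-segment regression against visual-field MD
that exposes the measurement floor in advanced disease.
"""

import numpy as np

from nflreflect import pipeline, stats
from nflreflect.synthdata import SimulationConfig, make_cohort

config = SimulationConfig(seed=5, grid_n=128)
cohort, _ = pipeline.process_cohort(make_cohort(config), config)
ev = pipeline.evaluate_cohort(cohort, fit_method="lme")

print("AROC (cluster-robust 95% CI):")
for _, row in ev["roc"].iterrows():
    print(f"  {row.parameter:24s} {row.auc:.3f}  [{row.ci_lo:.3f}, {row.ci_hi:.3f}]")

print("\nsensitivity at 99% specificity:")
print(ev["sensitivity"].pivot(index="parameter", columns="subgroup",
                              values="sensitivity").round(3))

print("\ndefect patterns by group:")
print(ev["patterns"])

res = ev["results"]
labels, means = stats.gmm_cluster(res.focal_loss, res.average_reflectance, k=3, seed=0)
print("\nGaussian-mixture loss clusters (focal, average means in dB):")
for k, (f, a) in enumerate(means):
    n_norm = int(np.sum((labels == k) & (res.group == "normal")))
    print(f"  cluster {k}: focal {f:+.2f}, average {a:+.2f}  "
          f"({np.sum(labels == k)} eyes, {n_norm} normal)")

fit = stats.piecewise_fit(cohort.covariates.vf_md, res.focal_loss, breakpoint=-6.0)
print("\nfocal loss vs VF MD (two-segment, breakpoint -6 dB):")
for seg, d in fit.items():
    print(f"  {seg}: slope {d['slope']:+.3f} dB/dB, r {d['r']:+.2f}, "
          f"p {d['p']:.3g}, n {d['n']}")
# The mild segment (MD > -6) correlates with severity; the advanced
# segment flattens as reflectance loss reaches its floor.
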