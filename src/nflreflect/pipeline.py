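"""End-to-end orchestration: scans -> reflectance maps -> superpixel
vectors -> normative model -> diagnostic tables.

The per-eye chain is: NFL/PPEC ratio, vessel inpainting, right-eye
orientation, normalization to dB against the population constant,
azimuthal band-stop filtering, and superpixel aggregation.  The
population normalization constant (mean over the normal training eyes of
the per-map mean linear ratio in the 1.1-2.0 mm annulus) and the
normative model are fitted on normal eyes only and then applied to every
eye.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import azfilter, grid as gridmod, maps, metrics, normative, stats

__all__ = [
    "build_default_grid",
    "ratio_pipeline",
    "estimate_normalization_constant",
    "process_scan",
    "process_cohort",
    "evaluate_cohort",
]


def build_default_grid(shape, pixel_size_mm, disc_center=(0.0, 0.0), bend=0.35,
                       flux_profile=gridmod.default_flux_profile) -> gridmod.SuperpixelGrid:
    """The standard 32 x 5 equal-flux grid for a given map geometry."""
    trajectory = gridmod.TrajectoryModel(bend=bend)
    boundaries = gridmod.equal_flux_track_boundaries(flux_profile)
    return gridmod.build_grid(trajectory, boundaries, shape, pixel_size_mm, disc_center)


def ratio_pipeline(nfl: maps.IntensityMap, ppec: maps.IntensityMap) -> maps.IntensityMap:
    """Ratio, vessel inpainting and right-eye orientation (linear scale)."""
    ratio = maps.compute_ratio_map(nfl, ppec)
    ratio = maps.inpaint_vessels(ratio)
    return maps.orient_right_eye(ratio)


def estimate_normalization_constant(ratio_maps) -> float:
    """Population mean of per-map mean linear ratios in the analytic zone."""
    means = [maps.annulus_mean(m) for m in ratio_maps]
    if not means:
        raise ValueError("no ratio maps supplied")
    return float(np.mean(means))


def process_scan(
    nfl: maps.IntensityMap,
    ppec: maps.IntensityMap,
    normalization_constant: float,
    apply_filter: bool = True,
) -> maps.ReflectanceMap:
    """Full single-scan map chain, ending in a (filtered) dB map."""
    ratio = ratio_pipeline(nfl, ppec)
    refl = maps.normalize_to_db(ratio, normalization_constant)
    if apply_filter:
        refl = azfilter.azimuthal_filter(refl)
    return refl


def process_cohort(eyes, config, apply_filter: bool = True, grid=None):
    """Render and process a synthetic cohort into superpixel vectors.

    ``eyes`` is a list of :class:`~nflreflect.synthdata.EyeTruth` from
    :func:`~nflreflect.synthdata.make_cohort`.  Scan rendering draws its
    pixel noise from per-eye substreams of ``config.seed``, so the whole
    run is a pure function of the configuration.  Returns
    ``(CohortTable, ground_truth)`` where the ground truth records each
    eye's injected defect burden.
    """
    from . import synthdata

    ratio_maps = []
    for i, truth in enumerate(eyes):
        rng = np.random.default_rng([config.seed, i, 7])
        nfl, ppec = synthdata.make_normal_map(
            config, truth.age, truth.axial_length, rng, truth=truth
        )
        ratio_maps.append(ratio_pipeline(nfl, ppec))

    normal_ratios = [m for m, t in zip(ratio_maps, eyes) if t.group == "normal"]
    norm_const = estimate_normalization_constant(normal_ratios)

    if grid is None:
        grid = build_default_grid(ratio_maps[0].shape, ratio_maps[0].pixel_size_mm,
                                  bend=config.trajectory_bend)
    vectors = np.empty((len(eyes), grid.n_superpixels))
    for i, ratio in enumerate(ratio_maps):
        refl = maps.normalize_to_db(ratio, norm_const)
        if apply_filter:
            refl = azfilter.azimuthal_filter(refl)
        vectors[i] = gridmod.aggregate(refl, grid)

    cov = pd.DataFrame(
        dict(
            eye_id=[t.eye_id for t in eyes],
            group=[t.group for t in eyes],
            age=[t.age for t in eyes],
            axial_length=[t.axial_length for t in eyes],
            gender=[t.gender for t in eyes],
            vf_md=[t.vf_md for t in eyes],
        )
    )
    gt = pd.DataFrame(
        dict(
            eye_id=[t.eye_id for t in eyes],
            group=[t.group for t in eyes],
            n_defects=[len(t.defects) for t in eyes],
            defect_kind=[t.defects[0].kind if t.defects else "none" for t in eyes],
            total_depth_db=[sum(d.depth_db for d in t.defects) for t in eyes],
            defect_burden_db=[synthdata.defect_burden(t) for t in eyes],
            bias_amp_db=[t.bias_amp for t in eyes],
        )
    )
    table = normative.CohortTable(cov, vectors)
    table.normalization_constant = norm_const
    return table, gt


def evaluate_cohort(
    cohort: normative.CohortTable,
    fit_method: str = "lme",
    cross_validate: bool = False,
    n_trials: int = 200,
    seed: int = 0,
    specificity: float = 0.99,
):
    """Fit the normative model and produce the diagnostic tables.

    Returns a dict with the fitted ``model`` and DataFrames:
    ``results`` (per-eye parameters and pattern), ``group_stats``
    (normal-vs-glaucoma means, SDs and rank-sum p), ``roc`` (AROC with
    cluster-robust CI per parameter), ``sensitivity`` (at the target
    specificity, per subgroup) and ``patterns`` (pattern counts by
    group).  With ``cross_validate=True`` the per-eye parameters come
    from 0.632+ bootstrap cross-validation instead of resubstitution.
    """
    model = normative.fit_lme(cohort, method=fit_method)
    cov = cohort.covariates

    rows = []
    for i in range(len(cov)):
        adj = normative.adjust(cohort.vectors[i], cov["age"].iloc[i],
                               cov["axial_length"].iloc[i], model)
        res = metrics.compute_diagnostics(adj, model)
        rows.append(dict(eye_id=cov["eye_id"].iloc[i], group=cov["group"].iloc[i],
                         average_reflectance=res.average_reflectance,
                         low_count_5=res.low_count_5, low_count_1=res.low_count_1,
                         focal_loss=res.focal_loss, pattern=res.pattern))
    results = pd.DataFrame(rows)

    if cross_validate:
        cv = normative.bootstrap_632(cohort, n_trials=n_trials, seed=seed)
        for col in ("average_reflectance", "low_count_5", "low_count_1", "focal_loss"):
            results[col] = cv[col].to_numpy()

    is_normal = (results["group"] == "normal").to_numpy()
    is_disease = ~is_normal
    params = {
        "average_reflectance": -results["average_reflectance"].to_numpy(),
        "low_count_5": results["low_count_5"].to_numpy().astype(float),
        "focal_loss": -results["focal_loss"].to_numpy(),
    }  # all oriented so higher score = more disease

    group_rows, roc_rows, sens_rows = [], [], []
    for name, score in params.items():
        raw = -score if name != "low_count_5" else score
        group_rows.append(dict(
            parameter=name,
            normal_mean=float(np.mean(raw[is_normal])),
            normal_sd=float(np.std(raw[is_normal], ddof=1)),
            glaucoma_mean=float(np.mean(raw[is_disease])),
            glaucoma_sd=float(np.std(raw[is_disease], ddof=1)),
            p_ranksum=stats.wilcoxon_ranksum(raw[is_normal], raw[is_disease]),
        ))
        roc = stats.auc_clustered(score, is_disease)
        roc_rows.append(dict(parameter=name, auc=roc.auc, se=roc.se,
                             ci_lo=roc.ci95[0], ci_hi=roc.ci95[1]))
        for sub in ("PPG", "PG", "all"):
            sel = is_disease if sub == "all" else (results["group"] == sub).to_numpy()
            if sel.any():
                sens = stats.sensitivity_at_specificity(
                    score[is_normal], score[sel], specificity, direction="upper")
                sens_rows.append(dict(parameter=name, subgroup=sub, sensitivity=sens))

    patterns = (
        results.groupby(["group", "pattern"]).size().unstack(fill_value=0)
        .reindex(columns=list(metrics.PATTERNS), fill_value=0)
    )
    return dict(
        model=model,
        results=results,
        group_stats=pd.DataFrame(group_rows),
        roc=pd.DataFrame(roc_rows),
        sensitivity=pd.DataFrame(sens_rows),
        patterns=patterns,
    )
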