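"""Synthetic en-face reflectance data with the statistical structure the
pipeline assumes.

The generator emulates, not simulates, OCT physics: a normal eye is an
angular reflectance template (double-hump profile peaking at the
inferotemporal and superotemporal arcuate bundles, with a secondary
superonasal peak) plus

* a per-eye smooth angular noise field (log-normal multiplicative
  texture, ~10 deg correlation length) carrying the individual variation
  of normal eyes;
* a per-scan first-degree azimuthal harmonic ``A*cos(theta - phi)`` in
  dB - the beam-incidence-angle bias the azimuthal filter removes;
* white pixel noise (speckle residue, averaged away by superpixels);
* curvilinear vessel shadows and a central disc mask.

Defaults are calibrated to the repeatability and population-variability
figures the pipeline is designed around: intrinsic per-superpixel
population SD 1.78 dB plus a Rayleigh(1.19 dB) incidence-bias amplitude
(so the unfiltered population SD is ~2.14 dB), and per-repeat noise of
0.57 dB with a Rayleigh(0.46 dB) bias jitter between repeat scans (so the
unfiltered pooled repeatability SD is ~0.73 dB).

Glaucomatous eyes receive trajectory-aligned wedge or diffuse defects of
parameterized depth and angular extent, with depth tied to the simulated
visual-field mean deviation and capped at a reflectance floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import grid as gridmod
from .maps import IntensityMap, pixel_grid_mm, radius_map

__all__ = [
    "SimulationConfig",
    "DefectSpec",
    "angular_template",
    "make_normal_map",
    "inject_defect",
    "make_repeat_scans",
    "make_cohort",
    "make_superpixel_cohort",
    "make_eye",
    "EyeTruth",
]


@dataclass(frozen=True)
class DefectSpec:
    """A reflectance defect along the fiber trajectories.

    ``center_angle`` and ``width`` are entry angles (rad) at the inner
    annulus radius; ``depth_db`` is the attenuation applied to the NFL
    intensity inside the defect.  ``kind`` is ``"wedge"`` (narrow, full
    radial span) or ``"diffuse"`` (wider than a quadrant); small
    ``r_min_mm``/``r_max_mm`` windows produce non-wedge groupings or
    isolated superpixels.
    """

    center_angle: float
    width: float
    depth_db: float
    kind: str = "wedge"
    r_min_mm: float = 0.0
    r_max_mm: float = np.inf

    def __post_init__(self):
        if self.depth_db < 0:
            raise ValueError("defect depth must be >= 0")
        if not 0 < self.width < 2 * np.pi:
            raise ValueError("defect width must be in (0, 2*pi)")


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort generator."""

    seed: int = 0
    n_normal: int = 35
    n_ppg: int = 30
    n_pg: int = 35
    grid_n: int = 200  # pixels per side over the 4.5 mm scan
    scan_mm: float = 4.5
    disc_radius_mm: float = 0.9
    #: (center_rad, height_db, kappa) von Mises bumps of the normal template
    template_bumps: tuple = (
        (gridmod.THETA_IT, 3.5, 6.0),
        (gridmod.THETA_ST, 3.0, 6.0),
        (gridmod.THETA_SN, 1.5, 8.0),
    )
    population_sd_db: float = 1.78  # intrinsic per-superpixel SD of normals
    noise_corr_deg: float = 10.0
    #: fraction of intrinsic noise variance that varies radially (the rest
    #: is a purely angular, track-coherent component)
    noise_radial_fraction: float = 0.42
    noise_radial_corr_mm: float = 0.35
    bias_amplitude_db: float = 1.19  # Rayleigh scale of the incidence-bias amplitude
    repeat_noise_sd_db: float = 0.57  # per-scan angular measurement noise
    bias_jitter_db: float = 0.46  # Rayleigh scale of per-repeat bias change
    pixel_noise_sd_db: float = 0.3
    ratio_scale: float = 0.8  # true linear NFL/PPEC ratio at 0 dB
    n_vessels: int = 10
    vessel_width_px: int = 2
    vessel_attenuation: float = 0.4
    beta_age: float = -0.03  # dB / year
    beta_axl: float = -0.4  # dB / mm
    beta_interaction: float = 0.0
    depth_cap_db: float = 12.0  # reflectance floor
    trajectory_bend: float = 0.35

    @property
    def pixel_size_mm(self) -> float:
        return self.scan_mm / self.grid_n


@dataclass
class EyeTruth:
    """Everything needed to regenerate one eye's scans."""

    eye_id: str
    group: str
    age: float
    axial_length: float
    gender: str
    vf_md: float
    noise_coeffs: np.ndarray  # intrinsic noise field: (r_knot, theta) samples
    bias_amp: float
    bias_phase: float
    defects: list = field(default_factory=list)
    global_loss_db: float = 0.0  # eye-wide diffuse attenuation
    laterality: str = "OD"


def angular_template(config: SimulationConfig, theta):
    """Normal-eye reflectance template (dB) as a function of azimuth.

    Offset so that the linear-scale mean over azimuth is exactly 1, which
    makes the normalized annulus mean of a noise-free normal map 0 dB by
    construction.
    """
    theta = np.asarray(theta, dtype=float)
    dense = np.linspace(0, 2 * np.pi, 4096, endpoint=False)

    def raw(t):
        out = np.zeros_like(t)
        for center, height, kappa in config.template_bumps:
            out = out + height * np.exp(kappa * (np.cos(t - center) - 1.0))
        return out

    offset = 10 * np.log10(np.mean(10 ** (raw(dense) / 10)))
    return raw(theta) - offset


_NOISE_GRID = 720
#: radial knots (mm) of the intrinsic noise field, spanning the filter annulus
_NOISE_R_KNOTS = np.linspace(0.8, 2.3, 7)


def _smooth_angular(white, corr_deg):
    """Circularly smooth rows of ``white`` and zero their first harmonic
    (which would be indistinguishable from incidence bias)."""
    n = white.shape[-1]
    k = np.fft.rfftfreq(n, d=1.0 / n)  # harmonic numbers
    sigma_k = 1.0 / np.deg2rad(corr_deg)
    spec = np.fft.rfft(white, axis=-1) * np.exp(-0.5 * (k / sigma_k) ** 2)
    spec[..., 1] = 0.0
    return np.fft.irfft(spec, n, axis=-1)


def _sample_angular_noise(rng, sd_db, corr_deg, n_grid=_NOISE_GRID):
    """Smooth periodic angular field, zero first harmonic, SD ``sd_db``."""
    if sd_db == 0:
        return np.zeros(n_grid)
    fieldv = _smooth_angular(rng.standard_normal(n_grid), corr_deg)
    sd = fieldv.std()
    return fieldv * (sd_db / sd) if sd > 0 else fieldv


def _sample_noise_field(config, rng, n_grid=_NOISE_GRID):
    """Intrinsic (r, theta) noise field of one eye.

    Sum of a purely angular, radially coherent component and a component
    that decorrelates radially (correlation length
    ``noise_radial_corr_mm``); total per-location SD is
    ``population_sd_db``.  Returned as samples at the radial knots.
    """
    from scipy import ndimage

    sd = config.population_sd_db
    if sd == 0:
        return np.zeros((len(_NOISE_R_KNOTS), n_grid))
    frac = config.noise_radial_fraction
    ang = _sample_angular_noise(rng, np.sqrt(1 - frac) * sd, config.noise_corr_deg, n_grid)
    white = rng.standard_normal((len(_NOISE_R_KNOTS), n_grid))
    spacing = _NOISE_R_KNOTS[1] - _NOISE_R_KNOTS[0]
    rad = ndimage.gaussian_filter1d(white, config.noise_radial_corr_mm / spacing,
                                    axis=0, mode="nearest")
    rad = _smooth_angular(rad, config.noise_corr_deg)
    rsd = rad.std()
    if rsd > 0:
        rad *= np.sqrt(frac) * sd / rsd
    return ang[None, :] + rad


def _eval_angular(fieldv, theta):
    n = len(fieldv)
    pos = np.mod(np.asarray(theta), 2 * np.pi) / (2 * np.pi) * n
    i0 = np.floor(pos).astype(int) % n
    i1 = (i0 + 1) % n
    fr = pos - np.floor(pos)
    return fieldv[i0] * (1 - fr) + fieldv[i1] * fr


def _eval_field(field2d, r, theta):
    """Bilinear evaluation of a (r_knot, theta) field at map coordinates."""
    field2d = np.atleast_2d(field2d)
    if field2d.shape[0] == 1:
        return _eval_angular(field2d[0], theta)
    knots = _NOISE_R_KNOTS
    rc = np.clip(r, knots[0], knots[-1])
    ki = np.clip(np.searchsorted(knots, rc) - 1, 0, len(knots) - 2)
    frac = (rc - knots[ki]) / (knots[ki + 1] - knots[ki])
    lo = _gather_rows(field2d, ki, theta)
    hi = _gather_rows(field2d, ki + 1, theta)
    return lo * (1 - frac) + hi * frac


def _gather_rows(field2d, row_idx, theta):
    n = field2d.shape[1]
    pos = np.mod(np.asarray(theta), 2 * np.pi) / (2 * np.pi) * n
    i0 = np.floor(pos).astype(int) % n
    i1 = (i0 + 1) % n
    fr = pos - np.floor(pos)
    return field2d[row_idx, i0] * (1 - fr) + field2d[row_idx, i1] * fr


def _covariate_shift(config, age, axl):
    return (
        config.beta_age * (age - 50.0)
        + config.beta_axl * (axl - 23.6)
        + config.beta_interaction * (age * axl - 50.0 * 23.6)
    )


def _vessel_mask(config: SimulationConfig, rng) -> np.ndarray:
    """Radially oriented curvilinear vessel shadows leaving the disc."""
    from scipy import ndimage

    n = config.grid_n
    mask = np.zeros((n, n), dtype=bool)
    p = config.pixel_size_mm
    r_max = config.scan_mm * 0.75
    for _ in range(config.n_vessels):
        theta0 = rng.uniform(0, 2 * np.pi)
        drift = rng.normal(0.0, 0.25)
        curve = rng.normal(0.0, 0.15)
        rr = np.arange(config.disc_radius_mm * 0.8, r_max, p / 2)
        th = theta0 + drift * (rr - rr[0]) + curve * (rr - rr[0]) ** 2
        x = rr * np.cos(th)
        y = rr * np.sin(th)
        col = np.round(x / p + (n - 1) / 2).astype(int)
        row = np.round((n - 1) / 2 - y / p).astype(int)
        ok = (row >= 0) & (row < n) & (col >= 0) & (col < n)
        mask[row[ok], col[ok]] = True
    if config.vessel_width_px > 1:
        mask = ndimage.binary_dilation(mask, iterations=config.vessel_width_px - 1)
    return mask


def _trajectory(config) -> gridmod.TrajectoryModel:
    return gridmod.TrajectoryModel(bend=config.trajectory_bend)


def _defect_region(config, defect: DefectSpec, shape, pixel_size_mm) -> np.ndarray:
    """Boolean pixel mask of a trajectory-aligned defect."""
    traj = _trajectory(config)
    r = radius_map(shape, pixel_size_mm)
    x, y = pixel_grid_mm(shape, pixel_size_mm)
    theta = np.arctan2(y, x)
    theta0 = traj.entry_angle(r, theta)
    d = np.mod(theta0 - defect.center_angle + np.pi, 2 * np.pi) - np.pi
    region = (np.abs(d) <= defect.width / 2) & (r >= config.disc_radius_mm)
    region &= (r >= defect.r_min_mm) & (r <= defect.r_max_mm)
    return region


def make_normal_map(config: SimulationConfig, age: float, axl: float, rng,
                    truth: EyeTruth | None = None, bias: tuple | None = None):
    """Generate one scan: (NFL IntensityMap, PPEC IntensityMap).

    When ``truth`` is given, its intrinsic noise field and defects are
    used (for repeat scans); ``bias`` overrides the per-scan incidence
    bias ``(amplitude_db, phase)``.
    """
    n = config.grid_n
    p = config.pixel_size_mm
    r = radius_map((n, n), p)
    x, y = pixel_grid_mm((n, n), p)
    theta = np.arctan2(y, x)

    db = angular_template(config, theta) + _covariate_shift(config, age, axl)
    if truth is not None and np.size(truth.noise_coeffs):
        db = db + _eval_field(truth.noise_coeffs, r, theta)
    if truth is not None and truth.global_loss_db:
        db = db - truth.global_loss_db
    if bias is None and truth is not None:
        bias = (truth.bias_amp, truth.bias_phase)
    if bias is not None:
        db = db + bias[0] * np.cos(theta - bias[1])
    if config.pixel_noise_sd_db > 0:
        db = db + rng.normal(0.0, config.pixel_noise_sd_db, size=(n, n))

    ratio = config.ratio_scale * 10 ** (db / 10)
    disc = r < config.disc_radius_mm
    vessels = _vessel_mask(config, rng) & ~disc
    ppec_vals = np.full((n, n), 1.0)
    # smooth beam-coupling variation affects both bands and cancels in the ratio
    coupling = 1.0 + 0.15 * np.cos(2 * np.pi * x / config.scan_mm) * np.cos(np.pi * y / config.scan_mm)
    ppec_vals = ppec_vals * coupling
    nfl_vals = ratio * ppec_vals
    nfl_vals[vessels] *= config.vessel_attenuation  # vessel shadow
    nfl_vals[disc] = 0.0

    common = dict(pixel_size_mm=p, disc_center=(0.0, 0.0), disc_mask=disc,
                  vessel_mask=vessels, laterality="OD" if truth is None else truth.laterality)
    nfl = IntensityMap(values=nfl_vals, **common)
    ppec = IntensityMap(values=ppec_vals, **common)
    if truth is not None:
        for defect in truth.defects:
            nfl, _ = inject_defect(nfl, defect, config=config)
    return nfl, ppec


def inject_defect(nfl: IntensityMap, defect: DefectSpec, grid=None,
                  config: SimulationConfig | None = None):
    """Attenuate the NFL intensity inside a trajectory-aligned defect.

    Returns ``(attenuated map, ground-truth superpixel mask or None)``.
    The ground-truth mask (computed when a :class:`SuperpixelGrid` is
    supplied) marks superpixels with at least half their pixels inside
    the defect region.
    """
    config = config or SimulationConfig(grid_n=nfl.shape[0])
    region = _defect_region(config, defect, nfl.shape, nfl.pixel_size_mm)
    values = nfl.values.copy()
    values[region] *= 10 ** (-defect.depth_db / 10)
    out = replace(nfl, values=values)
    gt = None
    if grid is not None:
        n_sp = grid.n_superpixels
        lab = grid.labels
        inside = np.bincount(lab[(lab >= 0) & region], minlength=n_sp)
        total = np.maximum(grid.counts, 1)
        gt = (inside / total >= 0.5) & (grid.counts > 0)
        if defect.depth_db == 0:
            gt = np.zeros(n_sp, dtype=bool)
    return out, gt


def make_repeat_scans(config: SimulationConfig, truth: EyeTruth, n_repeats: int, rng):
    """Repeated scans of one eye: same intrinsic reflectance, fresh
    incidence bias (base bias plus Rayleigh jitter), fresh measurement
    noise per repeat."""
    scans = []
    for _ in range(n_repeats):
        jitter_amp = rng.rayleigh(config.bias_jitter_db) if config.bias_jitter_db > 0 else 0.0
        jitter_phase = rng.uniform(0, 2 * np.pi)
        a = truth.bias_amp * math.cos(truth.bias_phase) + jitter_amp * math.cos(jitter_phase)
        b = truth.bias_amp * math.sin(truth.bias_phase) + jitter_amp * math.sin(jitter_phase)
        bias = (math.hypot(a, b), math.atan2(b, a))
        scan_noise = _sample_angular_noise(rng, config.repeat_noise_sd_db, config.noise_corr_deg)
        base = np.atleast_2d(truth.noise_coeffs)
        t = replace(truth, noise_coeffs=base + scan_noise[None, :])
        scans.append(make_normal_map(config, truth.age, truth.axial_length, rng, truth=t, bias=bias))
    return scans


_GROUP_COVARIATES = {
    # group: (age mean, age sd, axl mean, axl sd, p_male, md mean, md sd, md range)
    "normal": (60.0, 10.8, 23.6, 0.9, 8 / 35, 0.23, 1.24, (-2.0, 2.5)),
    "PPG": (65.1, 8.7, 24.7, 1.0, 12 / 30, -0.63, 1.89, (-7.3, 2.0)),
    "PG": (66.9, 8.8, 24.6, 1.3, 21 / 35, -6.06, 5.20, (-19.3, 0.3)),
}

#: Defect-pattern mixture per group, matching the observed prevalence of
#: glaucomatous (diffuse/wedge) and incidental patterns.
_PATTERN_MIX = {
    "normal": {"none": 1.0},
    "PPG": {"diffuse": 10 / 30, "wedge": 12 / 30, "other_grouping": 4 / 30,
            "isolated": 3 / 30, "none": 1 / 30},
    "PG": {"diffuse": 24 / 35, "wedge": 11 / 35},
}


def _draw_covariates(group, rng):
    am, asd, xm, xsd, p_male, mm, msd, mrange = _GROUP_COVARIATES[group]
    age = float(np.clip(rng.normal(am, asd), 40.0, 80.0))
    axl = float(rng.normal(xm, xsd))
    gender = "male" if rng.uniform() < p_male else "female"
    md = float(np.clip(rng.normal(mm, msd), *mrange))
    return age, axl, gender, md


def _draw_defects(config, group, md, rng):
    """Defect list and eye-wide diffuse loss for one eye.

    Glaucomatous eyes carry a shallow global attenuation (axon dropout is
    never perfectly focal) plus a pattern-defining defect whose depth
    grows with field-loss severity, capped at the reflectance floor.
    Defect depths must clear the ~3 dB normative cutoff by a couple of
    population SDs to be recognized by the operational pattern rules.
    """
    mix = _PATTERN_MIX[group]
    kinds = list(mix)
    kind = kinds[rng.choice(len(kinds), p=np.array([mix[k] for k in kinds]))]
    if kind == "none":
        return [], 0.0
    severity = max(0.0, -md)
    track_w = 2 * np.pi / 32  # mean track width
    cap = config.depth_cap_db
    glob = float(rng.uniform(0.5, 2.0)) if group == "PPG" else float(rng.uniform(1.5, 3.5))
    if kind == "diffuse":
        base = 6.0 if group == "PPG" else 7.0
        depth = float(np.clip(base + 0.5 * severity + rng.normal(0, 0.8), 4.0, cap))
        width = rng.uniform(12, 24) * track_w
        return [DefectSpec(rng.uniform(0, 2 * np.pi), width, depth, kind="diffuse")], glob
    if kind == "wedge":
        base = 6.5 if group == "PPG" else 8.0
        depth = float(np.clip(base + 0.6 * severity + rng.normal(0, 1.0), 4.5, cap))
        width = rng.uniform(1.5, 4.0) * track_w
        center = gridmod.THETA_IT if rng.uniform() < 0.6 else gridmod.THETA_ST
        center += rng.normal(0, 0.25)
        return [DefectSpec(center, width, depth, kind="wedge")], glob
    if kind == "other_grouping":
        depth = float(np.clip(6.5 + rng.normal(0, 1.0), 5.0, cap))
        return [DefectSpec(rng.uniform(0, 2 * np.pi), rng.uniform(1.2, 2.2) * track_w,
                           depth, kind="wedge", r_min_mm=1.25, r_max_mm=1.85)], 0.5 * glob
    # isolated: a single-superpixel-scale dab
    depth = float(np.clip(6.5 + rng.normal(0, 1.0), 5.0, cap))
    r0 = rng.uniform(1.2, 1.8)
    return [DefectSpec(rng.uniform(0, 2 * np.pi), 0.9 * track_w, depth,
                       kind="wedge", r_min_mm=r0, r_max_mm=r0 + 0.18)], 0.5 * glob


def make_eye(config: SimulationConfig, group: str, rng, eye_id: str) -> EyeTruth:
    """Draw one eye's covariates, intrinsic texture, bias and defects."""
    age, axl, gender, md = _draw_covariates(group, rng)
    noise = _sample_noise_field(config, rng)
    amp = rng.rayleigh(config.bias_amplitude_db) if config.bias_amplitude_db > 0 else 0.0
    phase = rng.uniform(0, 2 * np.pi)
    defects, global_loss = _draw_defects(config, group, md, rng)
    laterality = "OD" if rng.uniform() < 0.5 else "OS"
    return EyeTruth(eye_id=eye_id, group=group, age=age, axial_length=axl, gender=gender,
                    vf_md=md, noise_coeffs=noise, bias_amp=amp, bias_phase=phase,
                    defects=defects, global_loss_db=global_loss, laterality=laterality)


def defect_burden(truth: EyeTruth, r_in: float = 1.1, r_out: float = 2.0) -> float:
    """Expected mean reflectance loss (dB) over the analytic annulus.

    Ground-truth severity for scoring: global loss plus each defect's
    depth weighted by the fraction of the annulus it covers.
    """
    burden = truth.global_loss_db
    for d in truth.defects:
        r_lo = max(d.r_min_mm, r_in)
        r_hi = min(d.r_max_mm, r_out)
        rfrac = max(0.0, r_hi - r_lo) / (r_out - r_in)
        burden += d.depth_db * (d.width / (2 * np.pi)) * rfrac
    return float(burden)


def make_cohort(config: SimulationConfig):
    """Generate the full cohort of eye truths (pure function of config).

    Returns a list of :class:`EyeTruth`.  Use
    :func:`nflreflect.pipeline.process_cohort` to turn them into a
    :class:`~nflreflect.normative.CohortTable` of superpixel vectors.
    """
    rng = np.random.default_rng(config.seed)
    eyes = []
    for group, count in (("normal", config.n_normal), ("PPG", config.n_ppg), ("PG", config.n_pg)):
        for i in range(count):
            eyes.append(make_eye(config, group, rng, eye_id=f"{group}-{i:03d}"))
    return eyes


def make_superpixel_cohort(
    n_eyes: int = 35,
    seed: int = 0,
    beta_age: float = -0.03,
    beta_axl: float = -0.4,
    beta_interaction: float = 0.0,
    noise_sd: float = 1.78,
    n_superpixels: int = 160,
    group: str = "normal",
):
    """Vector-level cohort generator for normative-model studies.

    Draws covariates from the normal-group distribution and produces
    superpixel vectors ``mu_s + beta.cov + iid noise`` directly, skipping
    image synthesis; the residual structure matches the mixed-model
    assumptions exactly, which makes it the right substrate for
    coefficient-recovery and type-I-error studies.
    """
    from .normative import CohortTable
    import pandas as pd

    rng = np.random.default_rng(seed)
    config = SimulationConfig()
    sp_theta = np.linspace(0, 2 * np.pi, n_superpixels, endpoint=False)
    mu_s = angular_template(config, sp_theta)
    rows = []
    vectors = np.empty((n_eyes, n_superpixels))
    for i in range(n_eyes):
        age, axl, gender, md = _draw_covariates(group, rng)
        shift = (beta_age * (age - 50.0) + beta_axl * (axl - 23.6)
                 + beta_interaction * (age * axl - 50.0 * 23.6))
        vectors[i] = mu_s + shift + rng.normal(0.0, noise_sd, n_superpixels)
        rows.append(dict(eye_id=f"sim-{i:03d}", group=group, age=age,
                         axial_length=axl, gender=gender, vf_md=md))
    return CohortTable(pd.DataFrame(rows), vectors)
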