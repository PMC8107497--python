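"""Normative reference model for superpixel reflectance.

Normal-eye superpixel reflectance depends on age and axial length (longer
eyes are scanned at effectively larger retinal radii and show lower NFL
reflectance).  A linear mixed-effects regression with the superpixel
location as a random intercept and age, axial length, their interaction
and gender as fixed effects quantifies these dependencies on the normal
cohort; measured vectors are then adjusted to a reference age of 50 years
and the normal-group mean axial length before comparison with the
per-superpixel Gaussian reference distribution.  The 5% and 1% normative
cutoffs are Gaussian quantiles of the adjusted normal values per
superpixel.

Diagnostic-accuracy estimates computed on the same normal eyes that built
the cutoffs are optimistic; :func:`bootstrap_632` provides 0.632+
bootstrap cross-validation in which each trial fits the adjustment and
cutoffs on a bootstrap resample of the normal cohort and evaluates
out-of-bag normal eyes (and all glaucoma eyes), averaging per-eye
parameters across trials.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import metrics

__all__ = [
    "CohortTable",
    "NormativeModel",
    "REFERENCE_AGE",
    "REFERENCE_AXIAL_LENGTH",
    "fit_lme",
    "adjust",
    "cutoffs",
    "bootstrap_632",
]

REFERENCE_AGE = 50.0
#: Normal-group mean axial length (mm).
REFERENCE_AXIAL_LENGTH = 23.6

Z5 = float(sps.norm.ppf(0.95))  # 1.6449
Z1 = float(sps.norm.ppf(0.99))  # 2.3263


@dataclass
class CohortTable:
    """Per-eye covariates plus superpixel reflectance vectors.

    ``covariates`` holds one row per analyzed eye (one eye per
    participant) with columns ``eye_id, group, age, axial_length, gender,
    vf_md`` and optionally thickness parameters; ``vectors`` is the
    aligned (n_eyes, n_superpixels) array of superpixel reflectance in dB.
    """

    covariates: pd.DataFrame
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if len(self.covariates) != len(self.vectors):
            raise ValueError("covariate table and vector array lengths differ")

    @property
    def n_superpixels(self) -> int:
        return self.vectors.shape[1]

    def subset(self, mask) -> "CohortTable":
        mask = np.asarray(mask)
        return CohortTable(self.covariates.iloc[mask].reset_index(drop=True), self.vectors[mask])

    def normals(self) -> "CohortTable":
        return self.subset(np.flatnonzero((self.covariates["group"] == "normal").to_numpy()))


@dataclass
class NormativeModel:
    """Fitted covariate coefficients and per-superpixel reference bands."""

    beta_age: float  # dB per year
    beta_axl: float  # dB per mm
    beta_interaction: float  # dB per (year * mm)
    beta_gender: float  # dB, male vs female (fit only; not used in adjustment)
    mu: np.ndarray  # per-superpixel mean of adjusted normal reflectance (dB)
    sigma: np.ndarray  # per-superpixel SD (dB)
    reference_age: float = REFERENCE_AGE
    reference_axl: float = REFERENCE_AXIAL_LENGTH
    normalization_constant: float = 1.0
    fit_method: str = "lme"
    pvalues: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(~(self.sigma > 0) & np.isfinite(self.mu)):
            raise ValueError("per-superpixel SD must be positive")

    @property
    def q5(self) -> np.ndarray:
        return self.mu - Z5 * self.sigma

    @property
    def q1(self) -> np.ndarray:
        return self.mu - Z1 * self.sigma

    def to_json(self, path=None) -> str:
        payload = {
            "beta_age": self.beta_age,
            "beta_axl": self.beta_axl,
            "beta_interaction": self.beta_interaction,
            "beta_gender": self.beta_gender,
            "reference_age": self.reference_age,
            "reference_axl": self.reference_axl,
            "normalization_constant": self.normalization_constant,
            "fit_method": self.fit_method,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "pvalues": self.pvalues,
            "se": self.se,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "NormativeModel":
        import os

        if isinstance(source, os.PathLike) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
        return cls(
            beta_age=payload["beta_age"],
            beta_axl=payload["beta_axl"],
            beta_interaction=payload["beta_interaction"],
            beta_gender=payload["beta_gender"],
            mu=np.array(payload["mu"]),
            sigma=np.array(payload["sigma"]),
            reference_age=payload["reference_age"],
            reference_axl=payload["reference_axl"],
            normalization_constant=payload["normalization_constant"],
            fit_method=payload["fit_method"],
            pvalues=payload.get("pvalues", {}),
            se=payload.get("se", {}),
        )


def _design(age, axl, gender, ref_age=REFERENCE_AGE, ref_axl=REFERENCE_AXIAL_LENGTH):
    """Fixed-effect regressors, centered at the reference covariates.

    The interaction enters as the centered product ``z1*z2`` for
    numerical conditioning; :func:`_uncenter` converts the fitted
    coefficients to the raw-product parameterization used by
    :func:`adjust`.
    """
    z1 = np.asarray(age, dtype=float) - ref_age
    z2 = np.asarray(axl, dtype=float) - ref_axl
    g = np.asarray(gender)
    if g.dtype.kind in "OUS":
        g = (g == "male").astype(float)
    return np.column_stack([z1, z2, z1 * z2, g.astype(float)])


def _uncenter(gamma, cov, ref_age=REFERENCE_AGE, ref_axl=REFERENCE_AXIAL_LENGTH):
    """Map centered-interaction coefficients to the raw parameterization.

    With ``age*axl - ref_age*ref_axl = z1*z2 + ref_axl*z1 + ref_age*z2``,
    the raw coefficients are ``b_age = g1 - ref_axl*g3``,
    ``b_axl = g2 - ref_age*g3``, ``b_int = g3``; standard errors follow by
    the delta method from the centered covariance matrix.
    """
    g1, g2, g3, g4 = gamma
    beta = np.array([g1 - ref_axl * g3, g2 - ref_age * g3, g3, g4])
    T = np.array([
        [1.0, 0.0, -ref_axl, 0.0],
        [0.0, 1.0, -ref_age, 0.0],
        [0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ])
    se = np.sqrt(np.diag(T @ cov @ T.T))
    return beta, se


_COLNAMES = ["age", "axial_length", "age_x_axial_length", "gender"]


def _check_rank(X):
    full = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        bad = [name for j, name in enumerate(_COLNAMES) if np.ptp(X[:, j]) == 0]
        if not bad:
            bad = _COLNAMES
        raise ValueError(f"rank-deficient design; collinear or constant columns: {bad}")


def fit_lme(cohort: CohortTable, method: str = "lme", weights=None) -> NormativeModel:
    """Fit the normative model on the normal eyes of a cohort.

    ``method='lme'`` fits a linear mixed model (REML) with a random
    intercept per superpixel.  ``method='ols'`` is a fast fixed-effects
    approximation (superpixel-demeaned ordinary least squares) whose
    coefficient estimates coincide with the mixed model's on balanced
    data; it is used inside bootstrap loops.  ``weights`` optionally
    repeats eyes (bootstrap multiplicities).

    After fitting, every normal eye is adjusted to the reference
    covariates and the per-superpixel mean and SD of the adjusted values
    define the Gaussian reference bands.
    """
    normals = cohort.normals()
    if len(normals.covariates) < 3:
        raise ValueError("need at least 3 normal eyes to fit the normative model")
    cov = normals.covariates
    X_eye = _design(cov["age"], cov["axial_length"], cov["gender"])
    _check_rank(X_eye)

    n_eyes, n_sp = normals.vectors.shape
    w_eye = np.ones(n_eyes) if weights is None else np.asarray(weights, dtype=float)

    # long format: one row per (eye, superpixel) with a finite value
    vals = normals.vectors
    finite = np.isfinite(vals)
    eye_idx, sp_idx = np.nonzero(finite)
    y = vals[eye_idx, sp_idx]
    X = X_eye[eye_idx]
    w = w_eye[eye_idx]

    if method == "lme":
        import statsmodels.api as sm

        keep = w > 0
        rep = (np.repeat(np.arange(len(y))[keep], w[keep].astype(int))
               if weights is not None else np.arange(len(y)))
        exog = sm.add_constant(X[rep], has_constant="add")
        md = sm.MixedLM(y[rep], exog, groups=sp_idx[rep])
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = md.fit(reml=True)
        gamma = np.asarray(res.fe_params)[1:5]
        cov_g = np.asarray(res.cov_params())[1:5, 1:5]
        dof = len(y) - n_sp - 4
    elif method == "ols":
        gamma, cov_g, dof = _fit_demeaned_ols(y, X, sp_idx, w, n_sp)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    beta, se_vals = _uncenter(gamma, cov_g)
    t = np.divide(beta, se_vals, out=np.zeros(4), where=se_vals > 0)
    pvals = dict(zip(_COLNAMES, 2 * sps.t.sf(np.abs(t), max(dof, 1))))
    se = dict(zip(_COLNAMES, se_vals))

    model = NormativeModel(
        beta_age=float(beta[0]),
        beta_axl=float(beta[1]),
        beta_interaction=float(beta[2]),
        beta_gender=float(beta[3]),
        mu=np.zeros(n_sp),
        sigma=np.ones(n_sp),
        fit_method=method,
        pvalues={k: float(v) for k, v in pvals.items()},
        se={k: float(v) for k, v in se.items()},
    )
    adj = np.array([
        adjust(vals[i], cov["age"].iloc[i], cov["axial_length"].iloc[i], model)
        for i in range(n_eyes)
    ])
    mu = np.empty(n_sp)
    sigma = np.empty(n_sp)
    for s in range(n_sp):
        col = adj[:, s]
        ws = w_eye[np.isfinite(col)]
        col = col[np.isfinite(col)]
        if len(col) < 2 or ws.sum() < 2:
            raise ValueError(f"superpixel {s}: not enough normal values for a reference band")
        m = np.average(col, weights=ws)
        v = np.average((col - m) ** 2, weights=ws) * ws.sum() / max(ws.sum() - 1, 1)
        mu[s], sigma[s] = m, np.sqrt(v)
    if np.any(sigma <= 0):
        raise ValueError("zero reference SD in at least one superpixel")
    model.mu = mu
    model.sigma = sigma
    return model


def _fit_demeaned_ols(y, X, sp_idx, w, n_sp):
    """Weighted OLS of superpixel-demeaned values on the covariates."""
    sw = np.bincount(sp_idx, weights=w, minlength=n_sp)
    sy = np.bincount(sp_idx, weights=w * y, minlength=n_sp)
    y_dm = y - (sy / np.maximum(sw, 1e-12))[sp_idx]
    Xm = np.array([np.average(X[:, j], weights=w) for j in range(X.shape[1])])
    Xc = X - Xm
    XtWX = Xc.T @ (w[:, None] * Xc)
    # pinv: a bootstrap resample may make a column (e.g. gender) constant
    XtWX_inv = np.linalg.pinv(XtWX)
    gamma = XtWX_inv @ (Xc.T @ (w * y_dm))
    resid = y_dm - Xc @ gamma
    dof = max(w.sum() - n_sp - X.shape[1], 1)
    s2 = float(np.sum(w * resid**2) / dof)
    cov_gamma = s2 * XtWX_inv
    return gamma, cov_gamma, dof


def adjust(vector, age, axial_length, model: NormativeModel) -> np.ndarray:
    """Adjust a superpixel vector to the reference age and axial length.

    ``adjusted_s = value_s - b_age*(age - 50) - b_axl*(axl - ref_axl)
    - b_int*(age*axl - 50*ref_axl)``.  Gender is retained in the fit but,
    as in standard normative practice, not adjusted for.
    """
    if age is None or axial_length is None or not np.isfinite([age, axial_length]).all():
        raise ValueError("age and axial length are required for adjustment")
    vector = np.asarray(vector, dtype=float)
    shift = (
        model.beta_age * (age - model.reference_age)
        + model.beta_axl * (axial_length - model.reference_axl)
        + model.beta_interaction * (age * axial_length - model.reference_age * model.reference_axl)
    )
    return vector - shift


def cutoffs(model: NormativeModel):
    """Per-superpixel Gaussian (q5, q1) cutoffs of the normative bands."""
    if np.any(model.sigma <= 0):
        raise ValueError("cutoffs undefined with non-positive SD")
    return model.q5, model.q1


def bootstrap_632(
    cohort: CohortTable,
    n_trials: int = 200,
    seed: int = 0,
    method: str = "ols",
) -> pd.DataFrame:
    """0.632+ bootstrap cross-validated diagnostic parameters per eye.

    Each trial resamples the normal eyes with replacement (leaving on
    average 36.8% out of bag), fits the adjustment and cutoffs on the
    in-bag sample, and evaluates the diagnostic parameters for the
    out-of-bag normal eyes and for every glaucoma eye.  Parameters are
    averaged per eye over the trials in which the eye was evaluated.
    Raises if some normal eye was never out of bag - rerun with more
    trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    normal_idx = np.flatnonzero((cohort.covariates["group"] == "normal").to_numpy())
    other_idx = np.flatnonzero((cohort.covariates["group"] != "normal").to_numpy())
    n_eyes = len(cohort.covariates)
    n_norm = len(normal_idx)
    if n_norm < 3:
        raise ValueError("need at least 3 normal eyes")

    sums = np.zeros((n_eyes, 4))
    counts = np.zeros(n_eyes)
    for _ in range(n_trials):
        draw = rng.integers(0, n_norm, size=n_norm)
        mult = np.bincount(draw, minlength=n_norm).astype(float)
        model = fit_lme(cohort.subset(normal_idx), method=method, weights=mult)
        oob = normal_idx[mult == 0]
        for i in np.concatenate([oob, other_idx]):
            adj = adjust(
                cohort.vectors[i],
                cohort.covariates["age"].iloc[i],
                cohort.covariates["axial_length"].iloc[i],
                model,
            )
            res = metrics.compute_diagnostics(adj, model)
            sums[i] += (res.average_reflectance, res.low_count_5, res.low_count_1, res.focal_loss)
            counts[i] += 1
    never = normal_idx[counts[normal_idx] == 0]
    if len(never):
        raise ValueError(
            f"{len(never)} normal eye(s) were never out-of-bag after {n_trials} trials; "
            "increase n_trials"
        )
    avg = sums / counts[:, None]
    out = cohort.covariates[["eye_id", "group"]].copy()
    out["average_reflectance"] = avg[:, 0]
    out["low_count_5"] = avg[:, 1]
    out["low_count_1"] = avg[:, 2]
    out["focal_loss"] = avg[:, 3]
    out["n_trials_evaluated"] = counts
    return out
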