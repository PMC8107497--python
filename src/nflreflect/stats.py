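"""Diagnostic-accuracy and association statistics.

Covers the statistical toolkit used to evaluate the reflectance
parameters: nonparametric ROC area with a cluster-robust variance (so
that two eyes of one participant can share a cluster), sensitivity at a
fixed high specificity with the cutoff taken from a kernel density
estimate of the normal-score distribution, exact McNemar and Wilcoxon
tests, pooled-SD repeatability, bootstrap comparison of Pearson
correlations, Gaussian-mixture clustering of focal-versus-diffuse loss,
and two-segment piecewise regression against visual-field mean deviation
with a fixed breakpoint (floor-effect analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RocResult",
    "auc_clustered",
    "sensitivity_at_specificity",
    "mcnemar",
    "pooled_sd",
    "pearson_compare_bootstrap",
    "gmm_cluster",
    "piecewise_fit",
    "wilcoxon_ranksum",
    "compare_auc",
]


@dataclass(frozen=True)
class RocResult:
    """Nonparametric AUC with cluster-robust standard error and 95% CI."""

    auc: float
    se: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    n_clusters: int


def _psi(pos, neg):
    """Mann-Whitney kernel matrix: 1 if pos > neg, 0.5 on ties."""
    diff = pos[:, None] - neg[None, :]
    return np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))


def auc_clustered(scores, labels, cluster_ids=None) -> RocResult:
    """Nonparametric ROC area for possibly clustered observations.

    ``labels`` are 1 for diseased, 0 for non-diseased; higher ``scores``
    must indicate disease (negate a parameter that decreases with
    disease).  The AUC is the Mann-Whitney statistic over all
    diseased/non-diseased pairs with ties counted half.  The variance is
    the cluster-level components estimator of the clustered nonparametric
    ROC literature; with singleton clusters it reduces to the DeLong-type
    structural-components variance.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if cluster_ids is None:
        cluster_ids = np.arange(len(scores))
    cluster_ids = np.asarray(cluster_ids)
    if labels.all() or not labels.any():
        raise ValueError("both diseased and non-diseased observations are required")

    pos = scores[labels]
    neg = scores[~labels]
    M, N = len(pos), len(neg)
    psi = _psi(pos, neg)
    theta = float(psi.mean())

    v10 = psi.mean(axis=1)  # per diseased unit
    v01 = psi.mean(axis=0)  # per non-diseased unit
    clusters = np.unique(cluster_ids)
    I = len(clusters)
    pos_cl = cluster_ids[labels]
    neg_cl = cluster_ids[~labels]
    X = np.array([v10[pos_cl == c].sum() for c in clusters])
    Y = np.array([v01[neg_cl == c].sum() for c in clusters])
    m_i = np.array([(pos_cl == c).sum() for c in clusters])
    n_i = np.array([(neg_cl == c).sum() for c in clusters])
    dx = X - m_i * theta
    dy = Y - n_i * theta
    I10 = int((m_i > 0).sum())
    I01 = int((n_i > 0).sum())
    var = 0.0
    if I10 > 1:
        var += I10 / (I10 - 1) * np.sum(dx**2) / M**2
    if I01 > 1:
        var += I01 / (I01 - 1) * np.sum(dy**2) / N**2
    if I > 1:
        var += 2 * I / (I - 1) * np.sum(dx * dy) / (M * N)
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi = max(0.0, theta - 1.96 * se), min(1.0, theta + 1.96 * se)
    return RocResult(theta, se, (lo, hi), M, N, I)


def compare_auc(scores_a, scores_b, labels, cluster_ids=None):
    """Paired z-test of two parameters' AUCs on the same eyes.

    Uses the cluster-robust variance of the difference of the two
    Mann-Whitney statistics.  Returns ``(auc_a, auc_b, p)``.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if cluster_ids is None:
        cluster_ids = np.arange(len(labels))
    cluster_ids = np.asarray(cluster_ids)

    def components(scores):
        pos, neg = scores[labels], scores[~labels]
        psi = _psi(pos, neg)
        return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)

    ta, v10a, v01a = components(scores_a)
    tb, v10b, v01b = components(scores_b)
    clusters = np.unique(cluster_ids)
    pos_cl, neg_cl = cluster_ids[labels], cluster_ids[~labels]
    M, N = int(labels.sum()), int((~labels).sum())
    dx = np.array([(v10a - v10b)[pos_cl == c].sum() - (pos_cl == c).sum() * (ta - tb) for c in clusters])
    dy = np.array([(v01a - v01b)[neg_cl == c].sum() - (neg_cl == c).sum() * (ta - tb) for c in clusters])
    I10 = int(np.isin(clusters, pos_cl).sum())
    I01 = int(np.isin(clusters, neg_cl).sum())
    I = len(clusters)
    var = 0.0
    if I10 > 1:
        var += I10 / (I10 - 1) * np.sum(dx**2) / M**2
    if I01 > 1:
        var += I01 / (I01 - 1) * np.sum(dy**2) / N**2
    if I > 1:
        var += 2 * I / (I - 1) * np.sum(dx * dy) / (M * N)
    if var <= 0:
        return ta, tb, 1.0
    z = (ta - tb) / np.sqrt(var)
    return ta, tb, float(2 * sps.norm.sf(abs(z)))


def sensitivity_at_specificity(
    normal_scores,
    disease_scores,
    specificity: float = 0.99,
    direction: str | None = None,
) -> float:
    """Sensitivity when the cutoff fixes specificity on the normal group.

    The cutoff is found on a Gaussian kernel density estimate (Silverman
    bandwidth) of the normal scores: the point where the smoothed CDF
    leaves ``1 - specificity`` probability on the disease-indicating
    side.  ``direction='lower'`` means low scores indicate disease (the
    default when the disease mean is below the normal mean).
    """
    normal_scores = np.asarray(normal_scores, dtype=float)
    disease_scores = np.asarray(disease_scores, dtype=float)
    if len(normal_scores) < 10:
        raise ValueError("need at least 10 normal scores to estimate the cutoff")
    if np.std(normal_scores) == 0:
        raise ValueError("degenerate (zero-variance) normal scores")
    if not 0 < specificity < 1:
        raise ValueError("specificity must be in (0, 1)")
    if direction is None:
        direction = "lower" if np.mean(disease_scores) < np.mean(normal_scores) else "upper"

    kde = sps.gaussian_kde(normal_scores)
    span = normal_scores.max() - normal_scores.min()
    lo = normal_scores.min() - 5 * span - 10 * kde.factor * np.std(normal_scores)
    hi = normal_scores.max() + 5 * span + 10 * kde.factor * np.std(normal_scores)
    tail = 1.0 - specificity

    if direction == "lower":
        f = lambda c: kde.integrate_box_1d(-np.inf, c) - tail
    else:
        f = lambda c: kde.integrate_box_1d(c, np.inf) - tail
    from scipy.optimize import brentq

    cut = brentq(f, lo, hi, xtol=1e-10)
    if direction == "lower":
        return float(np.mean(disease_scores < cut))
    return float(np.mean(disease_scores > cut))


def mcnemar(detect_a, detect_b) -> float:
    """Exact McNemar p-value for paired detection indicators.

    Two-sided exact binomial test on the discordant pairs; returns 1.0
    when there are no discordant pairs.
    """
    a = np.asarray(detect_a).astype(bool)
    b = np.asarray(detect_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("paired detection vectors must have equal length")
    n01 = int(np.sum(~a & b))
    n10 = int(np.sum(a & ~b))
    if n01 + n10 == 0:
        return 1.0
    return float(sps.binomtest(n10, n10 + n01, 0.5).pvalue)


def pooled_sd(repeats) -> float:
    """Pooled within-eye, within-superpixel SD over repeated scans (dB).

    ``repeats`` is a sequence of per-eye arrays of shape
    ``(n_repeats, n_superpixels)``; each eye needs at least two repeats.
    The pooled SD is the square root of the mean (over eyes and
    superpixels) of the within-cell sample variance.
    """
    variances = []
    for eye in repeats:
        eye = np.asarray(eye, dtype=float)
        if eye.ndim != 2 or eye.shape[0] < 2:
            raise ValueError("each eye needs >= 2 repeated scans")
        variances.append(np.var(eye, axis=0, ddof=1))
    return float(np.sqrt(np.mean(np.concatenate(variances))))


def pearson_compare_bootstrap(x1, x2, y, reps: int = 2000, seed: int = 0):
    """Compare two Pearson correlations with a shared outcome by bootstrap.

    Resamples eyes with replacement; ``p_diff`` is the two-sided bootstrap
    p-value of ``r(x1, y) - r(x2, y)``.  Returns ``(r1, r2, p_diff)``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    r1 = float(np.corrcoef(x1, y)[0, 1])
    r2 = float(np.corrcoef(x2, y)[0, 1])
    diffs = np.empty(reps)
    for i in range(reps):
        idx = rng.integers(0, n, size=n)
        with np.errstate(invalid="ignore"):
            d1 = np.corrcoef(x1[idx], y[idx])[0, 1]
            d2 = np.corrcoef(x2[idx], y[idx])[0, 1]
        diffs[i] = d1 - d2
    diffs = diffs[np.isfinite(diffs)]
    if len(diffs) == 0:
        return r1, r2, 1.0
    p = 2 * min(np.mean(diffs <= 0), np.mean(diffs >= 0))
    return r1, r2, float(min(p, 1.0))


def gmm_cluster(focal_loss, average_loss, k: int = 3, seed: int = 0):
    """Gaussian-mixture clustering of focal versus overall loss.

    Fits a ``k``-component full-covariance 2-D Gaussian mixture (best of
    10 seeded EM restarts by likelihood) and returns ``(labels, means)``
    with component means ordered by decreasing average loss (cluster 0 =
    least loss).
    """
    from sklearn.mixture import GaussianMixture

    X = np.column_stack([np.asarray(focal_loss, float), np.asarray(average_loss, float)])
    gm = GaussianMixture(n_components=k, covariance_type="full", n_init=10, random_state=seed)
    raw = gm.fit_predict(X)
    order = np.argsort(-gm.means_[:, 1])  # healthiest (highest average) first
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw], gm.means_[order]


def piecewise_fit(x, y, breakpoint: float = -6.0):
    """Two-segment regression of a parameter against VF mean deviation.

    Fits independent least-squares lines on the ``x > breakpoint`` (no or
    mild field loss) and ``x < breakpoint`` (moderate to severe) subsets.
    Returns a dict per segment with slope, intercept, Pearson r, p and n;
    segments with fewer than 3 points are flagged with ``fitted=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = {}
    for name, sel in (("high_md", x > breakpoint), ("low_md", x < breakpoint)):
        seg = {"n": int(sel.sum()), "fitted": False, "slope": np.nan,
               "intercept": np.nan, "r": np.nan, "p": np.nan}
        if sel.sum() >= 3 and np.ptp(x[sel]) > 0:
            res = sps.linregress(x[sel], y[sel])
            seg.update(fitted=True, slope=float(res.slope), intercept=float(res.intercept),
                       r=float(res.rvalue), p=float(res.pvalue))
        out[name] = seg
    return out


def wilcoxon_ranksum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact for small untied samples)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)
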