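"""Diagnostic parameters and reflectance-loss pattern classification.

Three parameters summarize an eye's covariate-adjusted superpixel vector
against the normative model:

* **average reflectance** - mean of all superpixel values (dB);
* **low-reflectance superpixel count** - number of superpixels strictly
  below the normative 5% (or 1%) cutoff;
* **focal reflectance loss** - sum of (value - normative mean) over the
  low-reflectance superpixels, divided by the total superpixel count
  (160), in dB.  Restricting the sum to superpixels with significant loss
  makes the statistic insensitive to measurement noise in healthy areas.

The spatial arrangement of low-reflectance superpixels on the 32-track by
5-segment lattice is classified into five defect patterns.  Wedge and
diffuse patterns are characteristic of glaucoma; isolated superpixels and
small non-wedge groupings also occur in normal eyes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import N_SEGMENTS, N_TRACKS

__all__ = [
    "DiagnosticResult",
    "PATTERNS",
    "average_reflectance",
    "low_reflectance_count",
    "focal_reflectance_loss",
    "significance_map",
    "classify_pattern",
    "compute_diagnostics",
]

#: Pattern labels in decreasing glaucoma-severity order.
PATTERNS = ("diffuse", "wedge", "other_grouping", "isolated", "none")


@dataclass(frozen=True)
class DiagnosticResult:
    """Per-eye diagnostic parameters and defect pattern."""

    average_reflectance: float
    low_count_5: int
    low_count_1: int
    focal_loss: float
    significance: np.ndarray  # per-superpixel label: 0 normal, 1 borderline, 2 abnormal
    pattern: str


def _check(values, reference=None):
    values = np.asarray(values, dtype=float)
    if reference is not None and len(values) != len(np.asarray(reference)):
        raise ValueError("superpixel vector and reference lengths differ")
    return values


def average_reflectance(adjusted) -> float:
    """Mean of the adjusted superpixel values; missing (NaN) excluded."""
    adjusted = _check(adjusted)
    if np.all(np.isnan(adjusted)):
        raise ValueError("all superpixel values missing")
    return float(np.nanmean(adjusted))


def low_reflectance_count(adjusted, cutoffs) -> int:
    """Number of superpixels strictly below their cutoff.

    Ties at the cutoff are not counted (a measure-zero event for
    continuous reflectance); missing values never count.
    """
    adjusted = _check(adjusted, cutoffs)
    with np.errstate(invalid="ignore"):
        return int(np.sum(adjusted < np.asarray(cutoffs, dtype=float)))


def low_mask(adjusted, cutoffs) -> np.ndarray:
    """Boolean mask of low-reflectance superpixels (strict inequality)."""
    adjusted = _check(adjusted, cutoffs)
    with np.errstate(invalid="ignore"):
        return adjusted < np.asarray(cutoffs, dtype=float)


def focal_reflectance_loss(adjusted, mu, cutoffs, n_total: int | None = None) -> float:
    """Summed deviation from the normative mean over low superpixels, / 160.

    Non-positive by construction: low superpixels lie below the cutoff and
    hence below the normative mean.  Zero when no superpixel is low.
    """
    adjusted = _check(adjusted, cutoffs)
    mu = np.asarray(mu, dtype=float)
    if len(mu) != len(adjusted):
        raise ValueError("normative mean vector length mismatch")
    n_total = len(adjusted) if n_total is None else n_total
    mask = low_mask(adjusted, cutoffs)
    if not mask.any():
        return 0.0
    return float(np.sum(adjusted[mask] - mu[mask]) / n_total)


def significance_map(adjusted, q5, q1) -> np.ndarray:
    """Classify each superpixel: 0 normal, 1 borderline (1st-5th
    percentile of the normal population), 2 abnormal (below the 1st)."""
    adjusted = _check(adjusted, q5)
    q5 = np.asarray(q5, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    if len(q1) != len(adjusted):
        raise ValueError("cutoff vector length mismatch")
    out = np.zeros(len(adjusted), dtype=int)
    with np.errstate(invalid="ignore"):
        out[adjusted < q5] = 1
        out[adjusted < q1] = 2
    return out


def _components(mask2d: np.ndarray) -> list[np.ndarray]:
    """Connected components under 4-connectivity with cyclic track wrap.

    ``mask2d`` is (n_tracks, n_segments).  Diagonal adjacency is not
    contiguity.  Returns a list of boolean component masks.
    """
    from scipy import ndimage

    lab, n = ndimage.label(mask2d, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if n == 0:
        return []
    # merge labels across the track seam (row 0 adjacent to row -1)
    parent = list(range(n + 1))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for s in range(mask2d.shape[1]):
        a, b = lab[0, s], lab[-1, s]
        if a and b and find(a) != find(b):
            parent[find(a)] = find(b)
    roots = {}
    comps = []
    for i in range(1, n + 1):
        r = find(i)
        if r not in roots:
            roots[r] = len(comps)
            comps.append(np.zeros_like(mask2d))
        comps[roots[r]] |= lab == i
    return comps


def classify_pattern(
    mask,
    n_tracks: int = N_TRACKS,
    n_segments: int = N_SEGMENTS,
    quadrant_tracks: int | None = None,
) -> str:
    """Classify the low-reflectance mask into one of five defect patterns.

    On the (track, segment) lattice with cyclic wrap in the track
    dimension and 4-connectivity:

    * ``diffuse`` - full-width loss (all segments low) in a run of more
      than a quadrant of consecutive tracks (> 8 of 32);
    * ``wedge`` - a connected component touching both the inner and the
      outer edge of the annulus;
    * ``other_grouping`` - a connected component of 3 or more superpixels
      that is not a wedge;
    * ``isolated`` - low superpixels present but none of the above;
    * ``none`` - empty mask.

    When several patterns coexist the most severe one (the order above) is
    reported.
    """
    mask = np.asarray(mask, dtype=bool).reshape(n_tracks, n_segments)
    if not mask.any():
        return "none"
    if quadrant_tracks is None:
        quadrant_tracks = n_tracks // 4
    full = mask.all(axis=1)
    if _longest_cyclic_run(full) > quadrant_tracks:
        return "diffuse"
    comps = _components(mask)
    sizes = [c.sum() for c in comps]
    wedge = any(c[:, 0].any() and c[:, -1].any() for c in comps)
    if wedge:
        return "wedge"
    if any(s >= 3 for s in sizes):
        return "other_grouping"
    return "isolated"


def _longest_cyclic_run(flags: np.ndarray) -> int:
    if flags.all():
        return len(flags)
    if not flags.any():
        return 0
    doubled = np.concatenate([flags, flags])
    best = run = 0
    for f in doubled:
        run = run + 1 if f else 0
        best = max(best, run)
    return min(best, len(flags))


def glaucomatous_pattern_fraction(counts, groups=None) -> float:
    """Fraction of eyes showing a glaucomatous (diffuse or wedge) pattern.

    ``counts`` maps group name to a ``{pattern: n_eyes}`` mapping (a
    pattern-count table); ``groups`` restricts the calculation to a
    subset of groups (default: all groups in the table).
    """
    if groups is None:
        groups = list(counts)
    glauc = total = 0
    for g in groups:
        row = counts[g]
        glauc += int(row.get("diffuse", 0)) + int(row.get("wedge", 0))
        total += int(sum(row.get(p, 0) for p in PATTERNS))
    if total == 0:
        raise ValueError("empty pattern-count table")
    return glauc / total


def compute_diagnostics(adjusted, model, pattern_level: int = 5) -> DiagnosticResult:
    """Full diagnostic read-out of an adjusted superpixel vector.

    ``model`` is a :class:`~nflreflect.normative.NormativeModel`.
    ``pattern_level`` selects which cutoff mask (5 or 1 percent) drives
    pattern classification; the 5% low-reflectance mask is the default.
    """
    adjusted = _check(adjusted, model.mu)
    lc5 = low_reflectance_count(adjusted, model.q5)
    lc1 = low_reflectance_count(adjusted, model.q1)
    cut = model.q5 if pattern_level == 5 else model.q1
    return DiagnosticResult(
        average_reflectance=average_reflectance(adjusted),
        low_count_5=lc5,
        low_count_1=lc1,
        focal_loss=focal_reflectance_loss(adjusted, model.mu, model.q5),
        significance=significance_map(adjusted, model.q5, model.q1),
        pattern=classify_pattern(low_mask(adjusted, cut)),
    )
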