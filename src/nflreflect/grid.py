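"""Equal-flux superpixel grid over the peripapillary annulus.

The 1.1-2.0 mm annulus around the disc is partitioned into 32 angular
tracks running parallel to the average nerve fiber trajectory, times 5
radial segments of equal width (0.18 mm), giving 160 superpixels.  Track
widths are adjusted so every track carries the same nerve fiber flux
(cross-sectional NFL area transected perpendicular to the fibers), so the
thick superior and inferior arcuate bundles - the regions glaucoma attacks
first - are covered by narrower, denser tracks.

Angular convention (right-eye orientation): azimuth 0 at the temporal
horizontal, increasing counterclockwise, so 90 deg is superior and 180 deg
nasal.  On the clinical clock face this puts 11:00 superotemporally and
6:30 inferotemporally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import R_IN_MM, R_OUT_MM, ReflectanceMap, pixel_grid_mm, radius_map

__all__ = [
    "TrajectoryModel",
    "SuperpixelGrid",
    "default_flux_profile",
    "equal_flux_track_boundaries",
    "build_grid",
    "aggregate",
    "N_TRACKS",
    "N_SEGMENTS",
]

N_TRACKS = 32
N_SEGMENTS = 5

#: Peak azimuths (rad) of the normal NFL profile: inferotemporal (6:30),
#: superotemporal (11:00) and superonasal (1:00) bundles.
THETA_IT = np.deg2rad(285.0)
THETA_ST = np.deg2rad(60.0)
THETA_SN = np.deg2rad(120.0)


def default_flux_profile(theta):
    """Angular nerve-fiber flux density (arbitrary units, strictly positive).

    A double-hump profile with major inferotemporal / superotemporal
    arcuate bundles and a secondary superonasal bundle, mimicking the
    normal angular NFL thickness distribution.
    """
    theta = np.asarray(theta, dtype=float)

    def bump(center, kappa):
        return np.exp(kappa * (np.cos(theta - center) - 1.0))

    return 0.6 + 0.9 * bump(THETA_IT, 6.0) + 0.8 * bump(THETA_ST, 6.0) + 0.25 * bump(THETA_SN, 8.0)


@dataclass(frozen=True)
class TrajectoryModel:
    """Parametric arcuate nerve-fiber-course model.

    A fiber entering the annulus at azimuth ``theta0`` (at ``r_in``)
    follows ``theta(r) = theta0 - bend * sin(theta0) * u(r)`` with
    ``u(r) = (r - r_in) / (r_out - r_in)``: superior fibers arc temporally
    downward toward the raphe, inferior fibers arc upward, nasal fibers
    run radially.  For ``|bend| < 1`` the map ``theta0 -> theta`` is
    strictly monotone at every radius, so trajectories never cross.
    ``bend = 0`` gives straight radial tracks.
    """

    bend: float = 0.35
    r_in: float = R_IN_MM
    r_out: float = R_OUT_MM

    def __post_init__(self):
        if not abs(self.bend) < 1.0:
            raise ValueError("|bend| must be < 1 for non-crossing trajectories")

    def _u(self, r):
        return np.clip((np.asarray(r, dtype=float) - self.r_in) / (self.r_out - self.r_in), 0.0, 1.0)

    def azimuth(self, r, theta0):
        """Azimuth of the fiber with entry angle ``theta0`` at radius ``r``."""
        return np.asarray(theta0) - self.bend * np.sin(theta0) * self._u(r)

    def entry_angle(self, r, theta):
        """Invert ``azimuth``: entry angle of the fiber through ``(r, theta)``.

        Solved by fixed-point iteration ``theta0 <- theta + bend*u*sin(theta0)``,
        a contraction for ``|bend| < 1``.
        """
        u = self._u(r)
        theta0 = np.array(theta, dtype=float, copy=True)
        for _ in range(60):
            theta0 = theta + self.bend * u * np.sin(theta0)
        return theta0


def equal_flux_track_boundaries(
    flux_profile=default_flux_profile,
    n_tracks: int = N_TRACKS,
    theta_start: float = 0.0,
    n_quad: int = 8192,
) -> np.ndarray:
    """Entry angles of the ``n_tracks`` track boundaries.

    Boundaries are placed so the integral of the (periodic, strictly
    positive) flux profile between consecutive boundaries is the same for
    every track; track 0 starts at ``theta_start`` (temporal horizontal).
    ``flux_profile`` may be a callable of azimuth or an array of samples
    on a uniform grid over ``[0, 2*pi)``.
    """
    grid = theta_start + np.linspace(0.0, 2 * np.pi, n_quad + 1)
    if callable(flux_profile):
        f = np.asarray(flux_profile(grid), dtype=float)
    else:
        samples = np.asarray(flux_profile, dtype=float)
        pts = np.linspace(0.0, 2 * np.pi, len(samples), endpoint=False)
        f = np.interp(np.mod(grid, 2 * np.pi), pts, samples, period=2 * np.pi)
    if not np.all(f > 0):
        raise ValueError("flux profile must be strictly positive everywhere")
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(grid))])
    targets = cum[-1] * np.arange(n_tracks) / n_tracks
    return np.mod(np.interp(targets, cum, grid), 2 * np.pi)


@dataclass
class SuperpixelGrid:
    """160-superpixel partition of the peripapillary annulus.

    ``labels`` assigns each pixel ``track * n_segments + segment`` or -1
    outside the annulus.  Track 0 starts at the temporal horizontal and
    indices increase counterclockwise; segment 0 is innermost.
    """

    labels: np.ndarray
    boundaries: np.ndarray
    trajectory: TrajectoryModel
    pixel_size_mm: float
    disc_center: tuple[float, float] = (0.0, 0.0)
    n_tracks: int = N_TRACKS
    n_segments: int = N_SEGMENTS
    r_in: float = R_IN_MM
    r_out: float = R_OUT_MM
    counts: np.ndarray = field(init=False)

    def __post_init__(self):
        n_sp = self.n_tracks * self.n_segments
        self.counts = np.bincount(self.labels[self.labels >= 0].ravel(), minlength=n_sp)

    @property
    def n_superpixels(self) -> int:
        return self.n_tracks * self.n_segments


def build_grid(
    trajectory: TrajectoryModel,
    boundaries: np.ndarray,
    shape,
    pixel_size_mm: float,
    disc_center=(0.0, 0.0),
    n_segments: int = N_SEGMENTS,
) -> SuperpixelGrid:
    """Label every annulus pixel with its (track, segment) superpixel.

    Each pixel's entry angle is recovered by inverting the trajectory
    model at the pixel's ``(r, theta)``; its track is the interval between
    consecutive equal-flux boundaries containing that entry angle, and its
    segment the equal-width radial ring containing ``r``.  Raises if any
    superpixel is empty at this pixel resolution.
    """
    boundaries = np.sort(np.mod(np.asarray(boundaries, dtype=float), 2 * np.pi))
    n_tracks = len(boundaries)
    r = radius_map(shape, pixel_size_mm, disc_center)
    x, y = pixel_grid_mm(shape, pixel_size_mm, disc_center)
    theta = np.arctan2(y, x)
    ann = (r >= trajectory.r_in) & (r <= trajectory.r_out)
    labels = np.full(shape, -1, dtype=np.int32)
    theta0 = np.mod(trajectory.entry_angle(r[ann], theta[ann]), 2 * np.pi)
    track = np.searchsorted(boundaries, theta0, side="right") - 1
    track = np.mod(track, n_tracks)  # angles below boundaries[0] wrap to the last track
    seg_w = (trajectory.r_out - trajectory.r_in) / n_segments
    segment = np.minimum(((r[ann] - trajectory.r_in) / seg_w).astype(int), n_segments - 1)
    labels[ann] = track * n_segments + segment
    grid = SuperpixelGrid(
        labels=labels,
        boundaries=boundaries,
        trajectory=trajectory,
        pixel_size_mm=pixel_size_mm,
        disc_center=tuple(disc_center),
        n_tracks=n_tracks,
        n_segments=n_segments,
        r_in=trajectory.r_in,
        r_out=trajectory.r_out,
    )
    if np.any(grid.counts == 0):
        empty = np.flatnonzero(grid.counts == 0)
        raise ValueError(f"superpixels {empty.tolist()} are empty at this pixel resolution")
    return grid


def aggregate(map_: ReflectanceMap, grid: SuperpixelGrid) -> np.ndarray:
    """Mean reflectance (dB) of each superpixel; NaN where no valid pixel.

    Vector ordering is ``track * n_segments + segment``.
    """
    if map_.shape != grid.labels.shape or not np.isclose(map_.pixel_size_mm, grid.pixel_size_mm):
        raise ValueError("map and grid do not share geometry")
    n_sp = grid.n_superpixels
    sel = (grid.labels >= 0) & map_.valid_mask
    lab = grid.labels[sel]
    vals = map_.values_db[sel]
    sums = np.bincount(lab, weights=vals, minlength=n_sp)
    counts = np.bincount(lab, minlength=n_sp)
    out = np.full(n_sp, np.nan)
    nonzero = counts > 0
    out[nonzero] = sums[nonzero] / counts[nonzero]
    return out
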