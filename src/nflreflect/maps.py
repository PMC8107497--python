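"""Normalized NFL reflectance maps.

An en-face scan is represented on a square Cartesian grid of pixel centers.
The coordinate frame has its origin at the optic disc center, x increasing
to the right and y increasing upward, in mm.  After transformation to
right-eye (OD) orientation, +x points temporally and the azimuth
``atan2(y, x)`` increases counterclockwise from the temporal horizontal.

The normalized reflectance is the per-pixel ratio of the axially summed
NFL-band intensity to the axially averaged PPEC-band intensity, divided by
a population reference (the mean over normal eyes of the per-map mean ratio
in the 1.1-2.0 mm annulus) and expressed on a decibel scale.  OCT intensity
is a power quantity, so dB means ``10 * log10`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "IntensityMap",
    "ReflectanceMap",
    "GeometryError",
    "compute_ratio_map",
    "inpaint_vessels",
    "normalize_to_db",
    "annulus_mean",
    "orient_right_eye",
    "pixel_grid_mm",
    "radius_map",
]

#: Analytic zone bounds (mm from disc center).
R_IN_MM = 1.1
R_OUT_MM = 2.0

#: Default sampling: 400 A-lines across a 4.5 mm scan.
DEFAULT_PIXEL_SIZE_MM = 4.5 / 400


class GeometryError(ValueError):
    """Raised when two maps do not share grid geometry."""


def pixel_grid_mm(shape, pixel_size_mm, disc_center=(0.0, 0.0)):
    """Return ``(x, y)`` mm coordinates of pixel centers relative to the disc.

    Row 0 is the top of the image; y increases upward.
    """
    n_rows, n_cols = shape
    cx, cy = disc_center
    x = (np.arange(n_cols) - (n_cols - 1) / 2.0) * pixel_size_mm - cx
    y = ((n_rows - 1) / 2.0 - np.arange(n_rows)) * pixel_size_mm - cy
    return np.meshgrid(x, y)


def radius_map(shape, pixel_size_mm, disc_center=(0.0, 0.0)):
    """Per-pixel distance (mm) from the disc center."""
    x, y = pixel_grid_mm(shape, pixel_size_mm, disc_center)
    return np.hypot(x, y)


@dataclass
class IntensityMap:
    """Linear-scale en-face intensity grid with masks and geometry.

    Parameters
    ----------
    values
        2-D non-negative intensity grid (linear scale).
    pixel_size_mm
        Edge length of one pixel in mm.
    disc_center
        ``(x, y)`` of the optic disc center in mm, in the grid-centered
        frame (``(0, 0)`` when the scan is perfectly centered).
    disc_mask, vessel_mask
        Boolean grids marking the optic disc and large retinal vessels.
    laterality
        ``"OD"`` (right) or ``"OS"`` (left).
    """

    values: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    disc_center: tuple[float, float] = (0.0, 0.0)
    disc_mask: np.ndarray | None = None
    vessel_mask: np.ndarray | None = None
    laterality: str = "OD"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise GeometryError("intensity grid must be square 2-D")
        if self.disc_mask is None:
            self.disc_mask = np.zeros(self.values.shape, dtype=bool)
        if self.vessel_mask is None:
            self.vessel_mask = np.zeros(self.values.shape, dtype=bool)
        self.disc_mask = np.asarray(self.disc_mask, dtype=bool)
        self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
        half = self.values.shape[0] * self.pixel_size_mm / 2.0
        if max(abs(self.disc_center[0]), abs(self.disc_center[1])) >= half:
            raise GeometryError("disc_center lies outside the grid")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")

    @property
    def shape(self):
        return self.values.shape

    def radius(self):
        return radius_map(self.shape, self.pixel_size_mm, self.disc_center)

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_size_mm, other.pixel_size_mm)
            and np.allclose(self.disc_center, other.disc_center)
        )


@dataclass
class ReflectanceMap:
    """Normalized NFL reflectance in dB with a validity mask.

    ``valid_mask`` is False over the optic disc (reflectance undefined) and
    wherever the underlying ratio was unusable; ``values_db`` is finite
    wherever ``valid_mask`` is True.
    """

    values_db: np.ndarray
    valid_mask: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    disc_center: tuple[float, float] = (0.0, 0.0)
    laterality: str = "OD"
    normalization_constant: float = 1.0
    filtered: bool = field(default=False, compare=False)

    def __post_init__(self):
        self.values_db = np.asarray(self.values_db, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values_db.shape != self.valid_mask.shape:
            raise GeometryError("values_db and valid_mask shapes differ")
        if not np.all(np.isfinite(self.values_db[self.valid_mask])):
            raise ValueError("non-finite reflectance inside the valid region")

    @property
    def shape(self):
        return self.values_db.shape

    def radius(self):
        return radius_map(self.shape, self.pixel_size_mm, self.disc_center)


def compute_ratio_map(nfl: IntensityMap, ppec: IntensityMap) -> IntensityMap:
    """NFL/PPEC reflectance ratio map (linear, dimensionless).

    Pixels where the PPEC reference falls below ``1e-6`` times its median
    are unusable for division; they are flagged by adding them to the
    vessel mask so that the subsequent inpainting step fills them from
    neighboring pixels.
    """
    if not nfl.same_geometry(ppec):
        raise GeometryError("NFL and PPEC maps do not share geometry")
    eps = 1e-6 * float(np.median(ppec.values[ppec.values > 0])) if np.any(ppec.values > 0) else 0.0
    bad = ~(ppec.values > eps)
    if bad.all():
        raise ValueError("PPEC reference non-positive everywhere; ratio undefined")
    ratio = np.zeros_like(nfl.values)
    np.divide(nfl.values, ppec.values, out=ratio, where=~bad)
    return IntensityMap(
        values=ratio,
        pixel_size_mm=nfl.pixel_size_mm,
        disc_center=nfl.disc_center,
        disc_mask=nfl.disc_mask | ppec.disc_mask,
        vessel_mask=nfl.vessel_mask | ppec.vessel_mask | (bad & ~nfl.disc_mask),
        laterality=nfl.laterality,
    )


def inpaint_vessels(
    map_: IntensityMap,
    vessel_mask: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> IntensityMap:
    """Replace vessel pixels with values diffused from neighboring pixels.

    Masked pixels are first seeded with their nearest unmasked value and
    then relaxed by iterative 4-neighbor mean diffusion (Jacobi sweeps over
    the masked set only) until the largest update falls below ``tol``.
    Unmasked pixels are bit-identical to the input; the procedure cannot
    introduce values outside the range of the surrounding data.  Disc
    pixels are outside the diffusion domain.
    """
    mask = map_.vessel_mask if vessel_mask is None else np.asarray(vessel_mask, dtype=bool)
    domain = ~map_.disc_mask
    fill = mask & domain
    if not fill.any():
        return replace(map_, values=map_.values.copy(), vessel_mask=mask)
    if not (domain & ~fill).any():
        raise ValueError("vessel mask covers the entire valid region; nothing to inpaint from")

    values = map_.values.copy()
    # Seed with nearest known value for fast diffusion convergence.
    known = domain & ~fill
    idx = ndimage.distance_transform_edt(~known, return_distances=False, return_indices=True)
    values[fill] = values[idx[0][fill], idx[1][fill]]

    kernel_domain = domain.astype(float)
    for _ in range(max_iter):
        num = _neighbor_sum(values * kernel_domain)
        den = _neighbor_sum(kernel_domain)
        with np.errstate(invalid="ignore"):
            mean = num / den
        updated = np.where(fill & (den > 0), mean, values)
        delta = np.max(np.abs(updated[fill] - values[fill])) if fill.any() else 0.0
        values = updated
        if delta < tol:
            break
    return replace(map_, values=values, vessel_mask=mask)


def _neighbor_sum(a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a)
    out[1:, :] += a[:-1, :]
    out[:-1, :] += a[1:, :]
    out[:, 1:] += a[:, :-1]
    out[:, :-1] += a[:, 1:]
    return out


def normalize_to_db(
    ratio_map: IntensityMap,
    normalization_constant: float,
    db_factor: float = 10.0,
) -> ReflectanceMap:
    """Normalize a ratio map by the population constant and convert to dB.

    ``values_db = db_factor * log10(ratio / normalization_constant)``.
    ``db_factor`` is 10 for the power-style convention (default; OCT
    intensity is a power quantity) or 20 for the amplitude convention.
    """
    if not normalization_constant > 0:
        raise ValueError("normalization constant must be positive")
    valid = ~ratio_map.disc_mask & (ratio_map.values > 0)
    values_db = np.full(ratio_map.shape, np.nan)
    values_db[valid] = db_factor * np.log10(ratio_map.values[valid] / normalization_constant)
    return ReflectanceMap(
        values_db=values_db,
        valid_mask=valid,
        pixel_size_mm=ratio_map.pixel_size_mm,
        disc_center=ratio_map.disc_center,
        laterality=ratio_map.laterality,
        normalization_constant=normalization_constant,
    )


def annulus_mean(map_, r_in: float = R_IN_MM, r_out: float = R_OUT_MM) -> float:
    """Mean over valid pixels of the ``r_in <= r <= r_out`` annulus.

    Accepts an :class:`IntensityMap` (valid = outside disc) or a
    :class:`ReflectanceMap` (its ``valid_mask``).
    """
    r = map_.radius()
    ann = (r >= r_in) & (r <= r_out)
    if isinstance(map_, ReflectanceMap):
        sel = ann & map_.valid_mask
        data = map_.values_db
    else:
        sel = ann & ~map_.disc_mask
        data = map_.values
    if not sel.any():
        raise ValueError("annulus contains no valid pixels")
    return float(np.mean(data[sel]))


def orient_right_eye(map_):
    """Mirror left-eye (OS) maps horizontally into right-eye orientation.

    OD maps are returned unchanged (a copy).  Mirroring swaps the nasal
    and temporal sides and flips the x component of the disc center; the
    multiset of pixel values is preserved exactly.
    """
    if map_.laterality == "OD":
        if isinstance(map_, ReflectanceMap):
            return replace(map_, values_db=map_.values_db.copy())
        return replace(map_, values=map_.values.copy())
    if map_.laterality != "OS":
        raise ValueError(f"unknown laterality {map_.laterality!r}")
    cx, cy = map_.disc_center
    new_center = (-cx, cy)
    if isinstance(map_, ReflectanceMap):
        return replace(
            map_,
            values_db=map_.values_db[:, ::-1].copy(),
            valid_mask=map_.valid_mask[:, ::-1].copy(),
            disc_center=new_center,
            laterality="OD",
        )
    return replace(
        map_,
        values=map_.values[:, ::-1].copy(),
        disc_mask=map_.disc_mask[:, ::-1].copy(),
        vessel_mask=map_.vessel_mask[:, ::-1].copy(),
        disc_center=new_center,
        laterality="OD",
    )
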