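"""Reading and writing maps, grids, models and result tables.

Raster maps travel as plain 2-D CSV grids (or 32-bit float TIFF / PNG
where a viewer is wanted) with a JSON sidecar holding the geometry
metadata (pixel size, disc center, laterality); masks are 0/1 rasters.
Superpixel vectors and diagnostic results are CSV tables; the normative
model serializes to JSON via :meth:`NormativeModel.to_json`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .maps import IntensityMap, ReflectanceMap

__all__ = [
    "save_map",
    "load_intensity_map",
    "load_reflectance_map",
    "save_grid_raster",
    "render_map_png",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_grid(path: Path, array: np.ndarray, fmt: str = "%.9g"):
    if path.suffix.lower() in (".tif", ".tiff"):
        import imageio.v3 as iio

        iio.imwrite(path, array.astype(np.float32))
    else:
        np.savetxt(path, array, delimiter=",", fmt=fmt)


def _read_grid(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import imageio.v3 as iio

        return np.asarray(iio.imread(path), dtype=float)
    return np.loadtxt(path, delimiter=",")


def save_map(map_, path):
    """Write a map as a value grid plus mask grids and a JSON sidecar."""
    path = Path(path)
    meta = {
        "pixel_size_mm": map_.pixel_size_mm,
        "disc_center": list(map_.disc_center),
        "laterality": map_.laterality,
    }
    if isinstance(map_, ReflectanceMap):
        meta["kind"] = "reflectance_db"
        meta["normalization_constant"] = map_.normalization_constant
        _write_grid(path, np.where(map_.valid_mask, map_.values_db, np.nan))
        _write_grid(path.with_name(path.stem + "_valid" + path.suffix),
                    map_.valid_mask.astype(np.uint8), fmt="%d")
    else:
        meta["kind"] = "intensity_linear"
        _write_grid(path, map_.values)
        _write_grid(path.with_name(path.stem + "_disc" + path.suffix),
                    map_.disc_mask.astype(np.uint8), fmt="%d")
        _write_grid(path.with_name(path.stem + "_vessel" + path.suffix),
                    map_.vessel_mask.astype(np.uint8), fmt="%d")
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_intensity_map(path) -> IntensityMap:
    path = Path(path)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    values = _read_grid(path)
    disc = _read_grid(path.with_name(path.stem + "_disc" + path.suffix)).astype(bool)
    vessel = _read_grid(path.with_name(path.stem + "_vessel" + path.suffix)).astype(bool)
    return IntensityMap(values=values, pixel_size_mm=meta["pixel_size_mm"],
                        disc_center=tuple(meta["disc_center"]), disc_mask=disc,
                        vessel_mask=vessel, laterality=meta["laterality"])


def load_reflectance_map(path) -> ReflectanceMap:
    path = Path(path)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    values = _read_grid(path)
    valid = _read_grid(path.with_name(path.stem + "_valid" + path.suffix)).astype(bool)
    values = np.where(valid, values, np.nan)
    return ReflectanceMap(values_db=values, valid_mask=valid,
                          pixel_size_mm=meta["pixel_size_mm"],
                          disc_center=tuple(meta["disc_center"]),
                          laterality=meta["laterality"],
                          normalization_constant=meta.get("normalization_constant", 1.0))


def save_grid_raster(grid, path):
    """Superpixel labels as an integer raster (-1 outside) + JSON metadata."""
    path = Path(path)
    np.savetxt(path, grid.labels, delimiter=",", fmt="%d")
    meta = {
        "n_tracks": grid.n_tracks,
        "n_segments": grid.n_segments,
        "r_in_mm": grid.r_in,
        "r_out_mm": grid.r_out,
        "pixel_size_mm": grid.pixel_size_mm,
        "disc_center": list(grid.disc_center),
        "boundaries_rad": grid.boundaries.tolist(),
        "trajectory_bend": grid.trajectory.bend,
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def render_map_png(map_, path, vmin=-8.0, vmax=4.0):
    """Render a reflectance (or significance) map to a PNG for inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4), dpi=120)
    if isinstance(map_, ReflectanceMap):
        img = np.where(map_.valid_mask, map_.values_db, np.nan)
        im = ax.imshow(img, cmap="viridis", vmin=vmin, vmax=vmax)
        fig.colorbar(im, ax=ax, label="NFL reflectance (dB)")
    else:
        im = ax.imshow(map_.values, cmap="gray")
        fig.colorbar(im, ax=ax, label="intensity (linear)")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
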