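"""Grid container and raster/vector I/O.

Conventions, used everywhere in the package:

* 0-based (row, col) indexing; the geotransform origin is the upper-left
  *corner* of pixel (0, 0); y decreases with increasing row.
* all point-in-pixel tests use pixel-centre semantics;
* CRS is pass-through metadata (synthetic scenes live in a local metric
  frame).

Rasters are written as single- or multi-band TIFF with the geotransform,
nodata sentinel and layer name serialised as JSON in the image-description
tag; reference zones travel as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["GridSpec", "RasterGrid", "ImageCollection", "read_raster",
           "write_raster"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up metric grid."""

    rows: int
    cols: int
    pixel_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0  # y of the upper-left corner; rows go down

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all pixel centres, shape (rows, cols)."""
        xs = self.origin_x + (np.arange(self.cols) + 0.5) * self.pixel_size
        ys = self.origin_y - (np.arange(self.rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def xy_to_rowcol(self, x, y):
        """Indices of the pixels containing points (x, y); may be off-grid."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.pixel_size)
        row = np.floor((self.origin_y - np.asarray(y)) / self.pixel_size)
        return row.astype(int), col.astype(int)


@dataclass
class RasterGrid:
    """A single named layer of float values on a :class:`GridSpec`.

    NaN is the in-memory nodata representation; ``nodata`` records the
    sentinel to use on disk.
    """

    values: np.ndarray
    grid: GridSpec
    name: str = ""
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: value shape {self.values.shape} does "
                f"not match grid {self.grid.shape}")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def with_values(self, values: np.ndarray, name: str | None = None
                    ) -> "RasterGrid":
        return RasterGrid(values, self.grid, name if name is not None
                          else self.name, self.nodata)


@dataclass
class ImageCollection:
    """Monthly multi-band scenes on a common grid.

    Each scene is ``(month, {band: 2-D array}, cloud_mask-or-None)``;
    months are unique integers in 1..12 and cloud masks are boolean arrays
    (True = obscured) applying to optical scenes only.
    """

    grid: GridSpec
    scenes: list[tuple[int, dict[str, np.ndarray], np.ndarray | None]] = \
        field(default_factory=list)

    def __post_init__(self) -> None:
        months = [m for m, _, _ in self.scenes]
        if len(set(months)) != len(months):
            raise ValueError("scene timestamps must be unique")
        for m, bands, mask in self.scenes:
            for b, arr in bands.items():
                if arr.shape != self.grid.shape:
                    raise ValueError(f"band {b} of month {m} off-grid")
            if mask is not None and mask.shape != self.grid.shape:
                raise ValueError(f"cloud mask of month {m} off-grid")

    @property
    def months(self) -> list[int]:
        return [m for m, _, _ in self.scenes]

    @property
    def band_names(self) -> list[str]:
        return list(self.scenes[0][1]) if self.scenes else []

    def subset(self, months) -> "ImageCollection":
        months = set(months)
        return ImageCollection(
            self.grid, [s for s in self.scenes if s[0] in months])


# ---------------------------------------------------------------------------
# raster I/O (TIFF + JSON header in the description tag)
# ---------------------------------------------------------------------------

def write_raster(raster: RasterGrid, path: str | Path) -> Path:
    """Write a layer as TIFF; geotransform/nodata/name go in the header."""
    path = Path(path)
    vals = raster.values.copy()
    vals[~np.isfinite(vals)] = raster.nodata
    meta = {
        "origin_x": raster.grid.origin_x,
        "origin_y": raster.grid.origin_y,
        "pixel_size": raster.grid.pixel_size,
        "nodata": raster.nodata,
        "name": raster.name,
    }
    tifffile.imwrite(path, vals.astype(np.float64),
                     description=json.dumps(meta))
    return path


def read_raster(path: str | Path) -> RasterGrid:
    """Read a layer written by :func:`write_raster` (round-trip exact)."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            vals = page.asarray().astype(np.float64)
            meta = json.loads(page.description or "{}")
    except Exception as exc:  # pragma: no cover - defensive
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    if vals.ndim != 2:
        raise IOError(f"cannot read raster {path}: expected a 2-D layer")
    grid = GridSpec(vals.shape[0], vals.shape[1],
                    float(meta.get("pixel_size", 1.0)),
                    float(meta.get("origin_x", 0.0)),
                    float(meta.get("origin_y", 0.0)))
    nodata = float(meta.get("nodata", -9999.0))
    vals[vals == nodata] = np.nan
    return RasterGrid(vals, grid, str(meta.get("name", path.stem)), nodata)
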