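"""Categorical raster data model and I/O.

The substrate of every landscape metric in this package is a rectangular
grid of integer land-cover codes with square cells.  Geographic
georeferencing beyond the cell size is carried as opaque metadata and never
enters any computation: all of the landscape math here is purely grid-based.

Areas are expressed in hm² (hectares, 1 hm² = 10,000 m²) throughout the
package; unit conversion happens only at I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CategoricalRaster",
    "DriverTable",
    "landscape_area",
    "read_raster",
    "write_ascii_grid",
    "read_ascii_grid",
    "read_geotiff",
    "write_geotiff",
    "read_legend",
    "write_legend",
    "read_climate_csv",
]

#: square meters per hectare
M2_PER_HM2 = 10_000.0


class RasterError(ValueError):
    """Raised for invalid raster construction or I/O."""


@dataclass(frozen=True)
class CategoricalRaster:
    """An integer-coded land-cover grid with square cells.

    Parameters
    ----------
    grid
        2-D integer array of class codes, row-major with the origin at the
        top-left corner.
    cell_size
        Side length of a (square) cell, in meters.
    nodata
        Integer code reserved for missing cells.  Nodata cells are excluded
        from the landscape area, from patch delineation, and from
        transition matrices.
    legend
        Mapping from class code to class name.  Every non-nodata cell value
        must appear in the legend.
    meta
        Opaque metadata (e.g. a geotransform) preserved through I/O but
        never used in computation.
    """

    grid: np.ndarray
    cell_size: float
    nodata: int
    legend: Mapping[int, str]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.size == 0:
            raise RasterError("grid must be a non-empty 2-D array")
        if not np.issubdtype(grid.dtype, np.integer):
            if np.issubdtype(grid.dtype, np.floating) and np.all(
                np.isfinite(grid) & (grid == np.round(grid))
            ):
                grid = grid.astype(np.int64)
            else:
                raise RasterError("grid values must be exactly integral")
        object.__setattr__(self, "grid", grid)
        if not self.cell_size > 0:
            raise RasterError("cell_size must be > 0")
        if int(self.nodata) in self.legend:
            raise RasterError("nodata code must not appear in the legend")
        codes = np.unique(grid)
        unknown = [int(c) for c in codes if c != self.nodata and int(c) not in self.legend]
        if unknown:
            raise RasterError(f"grid contains codes absent from legend: {unknown}")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def cell_area_hm2(self) -> float:
        """Area of one cell in hm²."""
        return self.cell_size**2 / M2_PER_HM2

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return self.grid != self.nodata

    def comparable(self, other: "CategoricalRaster") -> bool:
        """Two rasters are comparable iff same shape, cell size and legend."""
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and dict(self.legend) == dict(other.legend)
        )

    def class_mask(self, class_code: int) -> np.ndarray:
        if int(class_code) not in self.legend:
            raise RasterError(f"class code {class_code} not in legend")
        return self.grid == class_code

    def class_proportions(self) -> pd.Series:
        """Proportion of the valid landscape occupied by each legend class."""
        n_valid = int(self.valid_mask.sum())
        if n_valid == 0:
            raise RasterError("empty landscape")
        counts = {
            code: int(np.count_nonzero(self.grid == code)) for code in sorted(self.legend)
        }
        return pd.Series(counts, dtype=float) / n_valid


def landscape_area(raster: CategoricalRaster) -> float:
    """Total landscape area A in hm²: (count of non-nodata cells) × cell area."""
    n = int(raster.valid_mask.sum())
    if n == 0:
        raise RasterError("empty landscape")
    return n * raster.cell_area_hm2


# -- driver / climate tables ---------------------------------------------


@dataclass(frozen=True)
class DriverTable:
    """Yearly driver series: a strictly increasing year index plus one
    numeric series per factor, with optional units."""

    years: tuple[int, ...]
    factors: Mapping[str, np.ndarray]
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        object.__setattr__(self, "years", years)
        factors = {k: np.asarray(v, dtype=float) for k, v in self.factors.items()}
        for name, series in factors.items():
            if series.shape != (len(years),):
                raise ValueError(f"factor {name!r} length != number of years")
        object.__setattr__(self, "factors", factors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(self.factors), index=pd.Index(self.years, name="year"))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, units: Mapping[str, str] | None = None) -> "DriverTable":
        return cls(
            years=tuple(int(y) for y in frame.index),
            factors={str(c): frame[c].to_numpy(dtype=float) for c in frame.columns},
            units=dict(units or {}),
        )


def read_driver_csv(path: str | Path) -> DriverTable:
    """Read a driver table CSV with a `year` column and one column per factor."""
    frame = pd.read_csv(path)
    if "year" not in frame.columns:
        raise ValueError("driver CSV must have a 'year' column")
    return DriverTable.from_frame(frame.set_index("year"))


def read_climate_csv(path: str | Path) -> pd.DataFrame:
    """Read monthly climate records: station, year, month, T (°C), R (mm)."""
    frame = pd.read_csv(path)
    required = {"station", "year", "month", "T", "R"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    if not frame["month"].between(1, 12).all():
        raise ValueError("month must be in 1..12")
    if (frame["R"] < 0).any():
        raise ValueError("precipitation R must be >= 0")
    return frame


# -- legend I/O -----------------------------------------------------------


def read_legend(path: str | Path) -> dict[int, str]:
    """Read a legend CSV with columns ``code,name``."""
    frame = pd.read_csv(path)
    if not {"code", "name"} <= set(frame.columns):
        raise ValueError("legend CSV must have columns 'code' and 'name'")
    return {int(row.code): str(row.name) for row in frame.itertuples(index=False)}


def write_legend(legend: Mapping[int, str], path: str | Path) -> None:
    pd.DataFrame(
        {"code": list(legend.keys()), "name": list(legend.values())}
    ).to_csv(path, index=False)


# -- ESRI ASCII grid ------------------------------------------------------

_ASCII_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}


def read_ascii_grid(
    path: str | Path,
    legend: Mapping[int, str],
    nodata: int | None = None,
    cell_size_override: float | None = None,
) -> CategoricalRaster:
    """Read an ESRI ASCII grid (.asc) into a :class:`CategoricalRaster`.

    The header NODATA_value is used unless ``nodata`` is given explicitly.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _ASCII_HEADER_KEYS and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    if "ncols" not in header or "nrows" not in header:
        raise RasterError(f"{path}: missing ncols/nrows header")
    values = np.loadtxt(data_lines, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        values = values.reshape(nrows, ncols)
    if not np.all(values == np.round(values)):
        raise RasterError(f"{path}: grid is not exactly integer-valued")
    grid = values.astype(np.int64)
    if nodata is None:
        nodata = int(header.get("nodata_value", -9999))
    cell_size = cell_size_override if cell_size_override is not None else header.get("cellsize")
    if cell_size is None:
        raise RasterError(f"{path}: no cellsize header and no override given")
    meta = {
        "xllcorner": header.get("xllcorner", 0.0),
        "yllcorner": header.get("yllcorner", 0.0),
    }
    return CategoricalRaster(grid, float(cell_size), int(nodata), dict(legend), meta)


def write_ascii_grid(raster: CategoricalRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid; round-trips grid, nodata and cell size exactly."""
    with open(path, "w") as fh:
        nrows, ncols = raster.shape
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.meta.get('xllcorner', 0.0)}\n")
        fh.write(f"yllcorner {raster.meta.get('yllcorner', 0.0)}\n")
        fh.write(f"cellsize {raster.cell_size:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        for row in raster.grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


# -- GeoTIFF --------------------------------------------------------------


def read_geotiff(
    path: str | Path,
    legend: Mapping[int, str],
    nodata: int = -9999,
    cell_size_override: float | None = None,
) -> CategoricalRaster:
    """Read a single-band integer GeoTIFF.

    Cell size is taken from the GeoTIFF ModelPixelScale tag unless
    overridden; non-square pixels are rejected without an override.
    """
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        scale_tag = page.tags.get(33550)  # ModelPixelScaleTag
        scale = tuple(scale_tag.value[:2]) if scale_tag is not None else None
    if arr.ndim != 2:
        raise RasterError(f"{path}: expected a single-band raster")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise RasterError(f"{path}: grid is not exactly integer-valued")
        arr = arr.astype(np.int64)
    if cell_size_override is not None:
        cell_size = float(cell_size_override)
    elif scale is None:
        raise RasterError(f"{path}: no ModelPixelScale tag and no cell_size_override")
    elif abs(scale[0] - scale[1]) > 1e-9 * max(scale):
        raise RasterError(f"{path}: non-square pixels {scale} require cell_size_override")
    else:
        cell_size = float(scale[0])
    return CategoricalRaster(arr, cell_size, int(nodata), dict(legend))


def write_geotiff(raster: CategoricalRaster, path: str | Path) -> None:
    import tifffile

    scale = (float(raster.cell_size), float(raster.cell_size), 0.0)
    tifffile.imwrite(
        str(path),
        raster.grid.astype(np.int32),
        extratags=[(33550, "d", 3, scale, True)],
    )


def read_raster(
    path: str | Path,
    legend: Mapping[int, str],
    format: str | None = None,
    nodata: int | None = None,
    cell_size_override: float | None = None,
) -> CategoricalRaster:
    """Read a categorical raster, dispatching on ``format`` or file suffix.

    Supported formats: ``"ascii"`` (ESRI ASCII grid) and ``"geotiff"``.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "geotiff" if suffix in {".tif", ".tiff"} else "ascii"
    if format == "ascii":
        return read_ascii_grid(path, legend, nodata=nodata, cell_size_override=cell_size_override)
    if format == "geotiff":
        return read_geotiff(
            path, legend, nodata=-9999 if nodata is None else nodata,
            cell_size_override=cell_size_override,
        )
    raise RasterError(f"unknown raster format {format!r}")


def table_to_json(frame: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular output as JSON (records plus index)."""
    payload = json.loads(frame.to_json(orient="split"))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
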