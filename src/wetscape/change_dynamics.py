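"""Inter-date land-cover transition (transfer) matrices.

Entry (i, j) of a transition matrix is the area (hm²) of cells classed i
at the first date and j at the second; the diagonal is stability.  Cells
that are nodata in either date are excluded, and the excluded area is
reported so conservation can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .raster_core import CategoricalRaster, RasterError

__all__ = ["TransitionMatrix", "WetlandFlows", "transition_matrix", "wetland_flows"]


@dataclass(frozen=True)
class TransitionMatrix:
    """Class × class area flows between two dates.

    ``areas`` is indexed by from-class code (rows) and to-class code
    (columns), in hm².  Row sums equal the first-date class areas and
    column sums the second-date class areas over the jointly valid cells.
    """

    areas: pd.DataFrame
    label_from: str
    label_to: str
    cell_area_hm2: float
    excluded_area_hm2: float

    @property
    def counts(self) -> pd.DataFrame:
        """Cell counts instead of areas."""
        return (self.areas / self.cell_area_hm2).round().astype(int)

    @property
    def total_area(self) -> float:
        return float(self.areas.to_numpy().sum())

    def row_sums(self) -> pd.Series:
        return self.areas.sum(axis=1)

    def col_sums(self) -> pd.Series:
        return self.areas.sum(axis=0)


class WetlandFlows(NamedTuple):
    """Focal-class flow summary (hm²)."""

    wetland_to_grassland: float
    grassland_to_wetland: float
    wetland_to_others: float


def transition_matrix(
    raster_t: CategoricalRaster,
    raster_t1: CategoricalRaster,
    label_from: str = "t",
    label_to: str = "t+1",
) -> TransitionMatrix:
    """Cross-tabulate two comparable rasters into area flows.

    The rasters must share shape, cell size and legend; cells nodata in
    either date are excluded and their area reported separately.
    """
    if not raster_t.comparable(raster_t1):
        raise RasterError("rasters are not comparable (shape, cell_size, legend)")
    codes = sorted(raster_t.legend)
    codes_arr = np.array(codes)
    valid = raster_t.valid_mask & raster_t1.valid_mask
    a = raster_t.grid[valid]
    b = raster_t1.grid[valid]
    n = len(codes)
    ai = np.searchsorted(codes_arr, a)
    bi = np.searchsorted(codes_arr, b)
    counts = np.bincount(ai * n + bi, minlength=n * n).reshape(n, n)
    cell_area = raster_t.cell_area_hm2
    excluded = float((~valid).sum() * cell_area)
    frame = pd.DataFrame(counts * cell_area, index=pd.Index(codes, name="from"),
                         columns=pd.Index(codes, name="to"))
    return TransitionMatrix(frame, str(label_from), str(label_to), cell_area, excluded)


def wetland_flows(
    matrix: TransitionMatrix, wetland_code: int, grassland_code: int
) -> WetlandFlows:
    """Wetland→grassland, grassland→wetland and total wetland outflow (hm²).

    "Wetland to others" is the focal class's total outflow — all wetland
    area converted to any non-wetland class, grassland included.
    """
    areas = matrix.areas
    for code in (wetland_code, grassland_code):
        if code not in areas.index:
            raise KeyError(f"class code {code} not in legend")
    w, g = wetland_code, grassland_code
    out_total = float(areas.loc[w].sum() - areas.loc[w, w])
    return WetlandFlows(
        wetland_to_grassland=float(areas.loc[w, g]),
        grassland_to_wetland=float(areas.loc[g, w]),
        wetland_to_others=out_total,
    )
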