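import numpy as np
import pytest
from hypothesis import settings

from wetscape.raster_core import CategoricalRaster

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

LEGEND6 = {
    1: "grassland",
    2: "woodland",
    3: "wetland",
    4: "river",
    5: "artificial",
    6: "unused",
}

BINARY_LEGEND = {0: "background", 1: "wetland"}


@pytest.fixture
def legend6():
    return dict(LEGEND6)


@pytest.fixture
def small_raster():
    """5×5 two-class raster, 30 m cells, with one 2×2 wetland block."""
    grid = np.ones((5, 5), dtype=int)
    grid[1:3, 1:3] = 3
    return CategoricalRaster(grid, 30.0, -9999, LEGEND6)


def make_binary_raster(grid, cell_size=30.0, nodata=-9999):
    return CategoricalRaster(np.asarray(grid, dtype=int), cell_size, nodata, BINARY_LEGEND)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with wetscape)
# ---------------------------------------------------------------------------


def flood_fill_label(mask, connectivity):
    """Label connected components of a boolean mask by iterative flood fill."""
    mask = np.asarray(mask, dtype=bool)
    nrows, ncols = mask.shape
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros((nrows, ncols), dtype=int)
    current = 0
    for r in range(nrows):
        for c in range(ncols):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                labels[r, c] = current
                while stack:
                    r0, c0 = stack.pop()
                    for dr, dc in neigh:
                        rr, cc = r0 + dr, c0 + dc
                        if (
                            0 <= rr < nrows
                            and 0 <= cc < ncols
                            and mask[rr, cc]
                            and labels[rr, cc] == 0
                        ):
                            labels[rr, cc] = current
                            stack.append((rr, cc))
    return labels, current


def count_edges_bruteforce(grid, nodata):
    """Count boundary cell edges one by one: different class, nodata, or
    grid border."""
    grid = np.asarray(grid)
    nrows, ncols = grid.shape
    edges = 0
    for r in range(nrows):
        for c in range(ncols):
            if grid[r, c] == nodata:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nrows and 0 <= cc < ncols):
                    edges += 1
                elif grid[rr, cc] != grid[r, c]:
                    edges += 1
    return edges


def transition_counts_bruteforce(grid_a, grid_b, codes, nodata):
    """Per-cell loop cross-tabulation of two class grids."""
    counts = {(i, j): 0 for i in codes for j in codes}
    nrows, ncols = np.asarray(grid_a).shape
    for r in range(nrows):
        for c in range(ncols):
            a, b = int(grid_a[r, c]), int(grid_b[r, c])
            if a != nodata and b != nodata:
                counts[(a, b)] += 1
    return counts


def bin_counts_bruteforce(areas, edges):
    """Scalar-loop binning: (0, e0), [e0, e1), ..., [e_last, inf)."""
    counts = [0] * (len(edges) + 1)
    for a in areas:
        k = 0
        for e in edges:
            if a >= e:
                k += 1
        counts[k] += 1
    return counts
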