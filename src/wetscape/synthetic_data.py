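"""Synthetic multi-date landscapes and driver series with known ground truth.

Landscapes are generated by seeded region growing: each class receives a
set of seed cells with per-seed growth weights, and cells are assigned in
first-arrival order where a seed's frontier advances at a rate
proportional to its weight (weighted first-passage growth on the grid).
Heavy-tailed weights give a long-tailed patch-size spectrum — many small
patches, a few very large ones — which is the regime alpine-wetland maps
show.  Class quotas are exact cell counts, so realized class proportions
match their targets up to one cell.

Change regimes evolve a landscape between dates:

``fragmentation``  cuts corridors through large focal-class patches so the
                   patch count rises while the class area barely moves;
``edge-erosion``   peels the focal class inward from patch boundaries,
                   shrinking area and the largest patches;
``recovery``       regrows the focal class outward from existing patches
                   and sprinkles new small patches;
``stationary``     returns the landscape unchanged.

A single integer seed governs every stochastic choice, so all outputs are
bitwise reproducible.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .patch_engine import _STRUCTURES, label_patches
from .raster_core import CategoricalRaster, DriverTable

__all__ = [
    "DEFAULT_LEGEND",
    "ZOIGE_LIKE_PROPORTIONS",
    "LandscapeScenario",
    "ChangeScenario",
    "generate_landscape",
    "evolve_landscape",
    "generate_driver_system",
]

#: the six-class alpine land-cover scheme used throughout
DEFAULT_LEGEND: dict[int, str] = {
    1: "grassland",
    2: "woodland",
    3: "wetland",
    4: "river",
    5: "artificial",
    6: "unused",
}

#: default class proportions emulating a grassland-dominated alpine
#: plateau with ~10.6% wetland
ZOIGE_LIKE_PROPORTIONS: dict[int, float] = {
    1: 0.60,
    2: 0.15,
    3: 0.106,
    4: 0.02,
    5: 0.014,
    6: 0.11,
}

WETLAND_CODE = 3
GRASSLAND_CODE = 1


@dataclass(frozen=True)
class LandscapeScenario:
    """Recipe for one synthetic landscape.

    ``seeds_per_class`` controls patch granularity (more seeds → more,
    smaller patches); ``weight_sigma`` is the log-normal sigma of per-seed
    growth weights (larger → longer-tailed patch sizes).
    """

    shape: tuple[int, int] = (200, 200)
    cell_size: float = 100.0  # meters; 1 cell = 1 hm²
    proportions: Mapping[int, float] = field(
        default_factory=lambda: dict(ZOIGE_LIKE_PROPORTIONS)
    )
    seeds_per_class: Mapping[int, int] = field(default_factory=dict)
    weight_sigma: float = 1.5
    legend: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    nodata: int = -9999
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("proportions must be nonnegative")
        unknown = set(self.proportions) - set(self.legend)
        if unknown:
            raise ValueError(f"proportions given for codes absent from legend: {unknown}")


@dataclass(frozen=True)
class ChangeScenario:
    """Recipe for evolving a landscape between two dates.

    ``intensity`` is regime-specific: the fraction of large patches cut
    (fragmentation), erosion steps are ``steps``, and the fraction of the
    dilation ring regrown (recovery).
    """

    regime: str = "stationary"
    intensity: float = 0.3
    steps: int = 1
    focal_class: int = WETLAND_CODE
    recipient_class: int = GRASSLAND_CODE
    n_new_patches: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in {"fragmentation", "edge-erosion", "recovery", "stationary"}:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must be in [0, 1]")
        if self.steps < 0:
            raise ValueError("steps must be >= 0")


def _quotas(n_cells: int, proportions: Mapping[int, float]) -> dict[int, int]:
    """Exact per-class cell quotas by largest remainder, summing to n_cells."""
    codes = sorted(proportions)
    raw = {c: proportions[c] * n_cells for c in codes}
    quotas = {c: int(np.floor(raw[c])) for c in codes}
    short = n_cells - sum(quotas.values())
    for c in sorted(codes, key=lambda c: raw[c] - quotas[c], reverse=True)[:short]:
        quotas[c] += 1
    return quotas


def generate_landscape(scenario: LandscapeScenario) -> CategoricalRaster:
    """Realize a scenario as a categorical raster by seeded region growing."""
    rng = np.random.default_rng(scenario.seed)
    nrows, ncols = scenario.shape
    n_cells = nrows * ncols
    quotas = _quotas(n_cells, scenario.proportions)
    grid = np.full((nrows, ncols), -1, dtype=np.int64)

    default_seeds = {
        c: max(1, round(quotas[c] / 400)) for c in quotas if quotas[c] > 0
    }
    default_seeds.update(
        {c: int(v) for c, v in scenario.seeds_per_class.items() if quotas.get(c, 0) > 0}
    )

    heap: list[tuple[float, int, int, int, int, float]] = []
    counter = 0
    taken: set[tuple[int, int]] = set()
    for code in sorted(default_seeds):
        n_seeds = min(default_seeds[code], quotas[code])
        weights = rng.lognormal(mean=0.0, sigma=scenario.weight_sigma, size=n_seeds)
        for w in weights:
            while True:
                r, c = int(rng.integers(nrows)), int(rng.integers(ncols))
                if (r, c) not in taken:
                    taken.add((r, c))
                    break
            heapq.heappush(heap, (rng.exponential() / w, counter, r, c, code, w))
            counter += 1

    remaining = dict(quotas)
    n_assigned = 0
    while heap and n_assigned < n_cells:
        t, _, r, c, code, w = heapq.heappop(heap)
        if grid[r, c] != -1 or remaining[code] == 0:
            continue
        grid[r, c] = code
        remaining[code] -= 1
        n_assigned += 1
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and grid[rr, cc] == -1:
                heapq.heappush(heap, (t + rng.exponential() / w, counter, rr, cc, code, w))
                counter += 1

    # enclosed leftovers (frontier of an exhausted class): hand them to
    # classes with unmet quota, in scan order
    if n_assigned < n_cells:
        open_codes = [c for c, k in remaining.items() if k > 0]
        rows, cols = np.nonzero(grid == -1)
        for r, c in zip(rows, cols):
            code = next(c_ for c_ in open_codes if remaining[c_] > 0)
            grid[r, c] = code
            remaining[code] -= 1
            open_codes = [c_ for c_ in open_codes if remaining[c_] > 0] or open_codes

    return CategoricalRaster(
        grid, scenario.cell_size, scenario.nodata, dict(scenario.legend)
    )


# -- change regimes --------------------------------------------------------


def _fragmentation(grid: np.ndarray, sc: ChangeScenario, rng: np.random.Generator,
                   raster: CategoricalRaster) -> np.ndarray:
    """Cut 2-cell-wide corridors through large focal patches.

    Bands are 2 cells wide because a 1-cell gap does not disconnect an
    8-connected patch.  Cuts retry until the patch count strictly rises.
    """
    focal = sc.focal_class
    before = len(label_patches(raster, focal, 8))
    for _attempt in range(10):
        out = grid.copy()
        labels, n = ndimage.label(out == focal, structure=_STRUCTURES[8])
        if n == 0:
            return out
        sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        order = np.argsort(sizes)[::-1]
        big = [i + 1 for i in order if sizes[i] >= 12]
        if not big:
            big = [int(order[0]) + 1]
        n_cut = max(1, int(round(sc.intensity * len(big))))
        for lab in big[:n_cut]:
            rows, cols = np.nonzero(labels == lab)
            row_ok = rows.max() - rows.min() >= 3
            col_ok = cols.max() - cols.min() >= 3
            if not (row_ok or col_ok):
                continue
            cut_rows = row_ok and (not col_ok or rng.random() < 0.5)
            if cut_rows:
                r0 = int(rng.integers(rows.min() + 1, rows.max() - 1))
                band = (labels == lab) & np.isin(
                    np.arange(grid.shape[0])[:, None], (r0, r0 + 1)
                )
            else:
                c0 = int(rng.integers(cols.min() + 1, cols.max() - 1))
                band = (labels == lab) & np.isin(
                    np.arange(grid.shape[1])[None, :], (c0, c0 + 1)
                )
            out[band] = sc.recipient_class
        check = CategoricalRaster(out, raster.cell_size, raster.nodata, dict(raster.legend))
        if len(label_patches(check, focal, 8)) > before:
            return out
    return out


def _edge_erosion(grid: np.ndarray, sc: ChangeScenario) -> np.ndarray:
    mask = grid == sc.focal_class
    eroded = ndimage.binary_erosion(
        mask, structure=_STRUCTURES[8], iterations=max(1, sc.steps)
    )
    out = grid.copy()
    out[mask & ~eroded] = sc.recipient_class
    return out


def _recovery(grid: np.ndarray, sc: ChangeScenario, rng: np.random.Generator) -> np.ndarray:
    mask = grid == sc.focal_class
    ring = ndimage.binary_dilation(mask, structure=_STRUCTURES[8]) & ~mask
    candidates = ring & (grid == sc.recipient_class)
    out = grid.copy()
    rows, cols = np.nonzero(candidates)
    if len(rows):
        pick = rng.random(len(rows)) < sc.intensity
        out[rows[pick], cols[pick]] = sc.focal_class
    # new small patches on recipient land, 1–5 cells each
    rows, cols = np.nonzero(out == sc.recipient_class)
    for _ in range(sc.n_new_patches):
        if not len(rows):
            break
        k = int(rng.integers(len(rows)))
        r, c = int(rows[k]), int(cols[k])
        blob = [(r, c)]
        for _ in range(int(rng.integers(0, 5))):
            r0, c0 = blob[int(rng.integers(len(blob)))]
            dr, dc = rng.integers(-1, 2, size=2)
            rr, cc = r0 + int(dr), c0 + int(dc)
            if 0 <= rr < out.shape[0] and 0 <= cc < out.shape[1] and out[rr, cc] == sc.recipient_class:
                blob.append((rr, cc))
        for rr, cc in blob:
            out[rr, cc] = sc.focal_class
    return out


def evolve_landscape(raster: CategoricalRaster, scenario: ChangeScenario) -> CategoricalRaster:
    """Apply a change regime, returning a new comparable raster."""
    rng = np.random.default_rng(scenario.seed)
    grid = raster.grid
    if scenario.regime == "stationary":
        out = grid.copy()
    elif scenario.regime == "fragmentation":
        out = _fragmentation(grid, scenario, rng, raster)
    elif scenario.regime == "edge-erosion":
        out = _edge_erosion(grid, scenario)
    elif scenario.regime == "recovery":
        out = _recovery(grid, scenario, rng)
    else:  # pragma: no cover - guarded by ChangeScenario
        raise ValueError(f"unknown regime {scenario.regime!r}")
    out[~raster.valid_mask] = raster.nodata
    return CategoricalRaster(out, raster.cell_size, raster.nodata, dict(raster.legend))


# -- driver systems --------------------------------------------------------


def generate_driver_system(
    n_years: int,
    effect_profile: Mapping[str, float],
    seed: int = 0,
    start_year: int = 1995,
) -> tuple[DriverTable, np.ndarray]:
    """Driver series with controlled association to a target series.

    Each factor is the target modulated by multiplicative noise of the
    given standard deviation and an arbitrary unit scale; lower-noise
    factors are by construction more grey-relationally similar to the
    target, so the expected GRA ranking follows the noise ordering.
    Returns the driver table and the target series.
    """
    if n_years < 2:
        raise ValueError("need at least 2 years")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years)
    # smooth, positive target: gentle decline plus slow oscillation
    target = 10.6 - 1.2 * t / max(n_years - 1, 1) + 0.4 * np.sin(2 * np.pi * t / 7.0)
    factors: dict[str, np.ndarray] = {}
    for name, sd in effect_profile.items():
        scale = float(rng.lognormal(mean=2.0, sigma=1.0))
        noise = 1.0 + sd * rng.standard_normal(n_years)
        factors[name] = np.abs(target * noise) * scale
    years = tuple(range(start_year, start_year + n_years))
    return DriverTable(years=years, factors=factors), target
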