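"""Class-level and landscape-level pattern indices and change statistics.

Indices
-------
WA   class area (hm²), the sum of the class's patch areas.
WP   class percentage of the landscape, 100·WA/A.
PN   patch number.
PD   patch density, reported per 100 hm² (= per km²).  Printed PD series
     in the wetland literature (thousands of patches over ~4·10⁶ hm² with
     PD ≈ 0.17) are only consistent with per-km² scaling, so outputs are
     tagged with that unit.
LCI  landscape change index, ½·|WP(t+1) − WP(t)| per interval.
LSI  landscape shape index, 0.25·E/√A with E the total boundary length of
     all patches (m) and A the landscape area (m²); 1 for a single square.
SHDI Shannon diversity of class proportions, −Σ pᵢ ln pᵢ.
SHEI Shannon evenness, SHDI/ln(n).

Percent-change annotations follow the study-table convention: the first
date is the baseline "(*)" and each later date carries the signed percent
change relative to the previous date, rounded half-away-from-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .patch_engine import label_patches
from .raster_core import CategoricalRaster, RasterError, landscape_area

__all__ = [
    "ClassMetrics",
    "LandscapeMetrics",
    "class_metrics",
    "lci",
    "lsi",
    "total_edge_length",
    "shdi",
    "shdi_from_raster",
    "shei",
    "percent_change",
    "annotate_series",
    "round_half_away",
    "metric_series",
]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round to ``decimals`` places with ties going away from zero.

    Python's builtin ``round`` is banker's rounding; printed landscape
    tables round half away from zero (e.g. +5.95 → +6.0 at 1 d.p.).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassMetrics:
    """Per-date metrics for one class."""

    label: str
    class_code: int
    pn: int
    wa: float  # hm²
    wp: float  # percent of landscape
    pd: float  # patches per 100 hm² (per km²)


@dataclass(frozen=True)
class LandscapeMetrics:
    """Per-date landscape-level metrics."""

    label: str
    lsi: float
    shdi: float
    shei: float
    n_classes: int


def class_metrics(
    raster: CategoricalRaster,
    class_code: int,
    connectivity: int = 8,
    area_override: float | None = None,
    label: str = "",
) -> ClassMetrics:
    """PN, WA, WP and PD for one class.

    ``area_override`` substitutes a user-supplied landscape area A (hm²)
    for the raster-derived one, e.g. to reproduce published tables whose
    source raster is not available.
    """
    patch_set = label_patches(raster, class_code, connectivity)
    a = float(area_override) if area_override is not None else landscape_area(raster)
    wa = patch_set.total_area
    return ClassMetrics(
        label=label,
        class_code=int(class_code),
        pn=len(patch_set),
        wa=wa,
        wp=100.0 * wa / a,
        pd=len(patch_set) / (a / 100.0),
    )


def lci(wp_prev: float, wp_next: float) -> float:
    """Landscape change index for one interval: ½·|WP(t+1) − WP(t)|.

    Symmetric in its arguments and zero iff the class percentage is
    unchanged.  Both WP values must lie in [0, 100].
    """
    for wp in (wp_prev, wp_next):
        if not 0.0 <= wp <= 100.0:
            raise ValueError(f"WP out of range [0, 100]: {wp}")
    return 0.5 * abs(wp_next - wp_prev)


def total_edge_length(raster: CategoricalRaster) -> float:
    """Total patch boundary length E in meters, over all classes.

    Each internal cell edge separating two different classes is counted
    once; edges against nodata cells and the grid boundary are included,
    so a landscape filled by a single square class has E = 4·s·cell_size.
    """
    grid = raster.grid
    valid = raster.valid_mask
    if not valid.any():
        raise RasterError("empty landscape")
    edges = 0
    # vertical neighbors
    diff = (grid[:-1, :] != grid[1:, :]) & valid[:-1, :] & valid[1:, :]
    edges += int(diff.sum())
    nod = (valid[:-1, :] != valid[1:, :])
    edges += int(nod.sum())
    # horizontal neighbors
    diff = (grid[:, :-1] != grid[:, 1:]) & valid[:, :-1] & valid[:, 1:]
    edges += int(diff.sum())
    nod = (valid[:, :-1] != valid[:, 1:])
    edges += int(nod.sum())
    # grid boundary
    edges += int(valid[0, :].sum() + valid[-1, :].sum())
    edges += int(valid[:, 0].sum() + valid[:, -1].sum())
    return edges * raster.cell_size


def lsi(raster: CategoricalRaster) -> float:
    """Landscape shape index 0.25·E/√A with A in m²."""
    e = total_edge_length(raster)
    a_m2 = landscape_area(raster) * 10_000.0
    return 0.25 * e / math.sqrt(a_m2)


def shdi(proportions: Sequence[float], atol: float = 1e-9) -> float:
    """Shannon diversity −Σ pᵢ ln pᵢ of class proportions summing to 1.

    Zero entries contribute nothing; the maximum ln(n) is attained at
    uniform proportions.
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > max(atol, 1e-9):
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def shdi_from_raster(raster: CategoricalRaster) -> float:
    """SHDI over the legend classes of a raster (nodata excluded)."""
    props = raster.class_proportions()
    return shdi(props.to_numpy(), atol=1e-9)


def shei(shdi_value: float, n_classes: int) -> float:
    """Shannon evenness SHDI/ln(n), in [0, 1]."""
    if n_classes < 2:
        raise ValueError("SHEI requires n_classes >= 2")
    hmax = math.log(n_classes)
    if not 0.0 <= shdi_value <= hmax + 1e-12:
        raise ValueError(f"SHDI {shdi_value} outside [0, ln {n_classes}]")
    return shdi_value / hmax


def landscape_level_metrics(
    raster: CategoricalRaster,
    n_classes: int | None = None,
    focal_class: int | None = None,
    label: str = "",
) -> LandscapeMetrics:
    """LSI, SHDI and SHEI for one raster.

    By default SHDI runs over all legend classes and SHEI uses
    H_MAX = ln(number of legend classes).  Passing ``focal_class`` with
    ``n_classes=2`` switches to the binary focal-vs-rest profile (SHDI of
    [p, 1−p], H_MAX = ln 2), the mode that matches published wetland
    tables whose evenness column is SHDI/ln 2.
    """
    n = int(n_classes) if n_classes is not None else len(raster.legend)
    if focal_class is not None and n == 2:
        p = float(raster.class_proportions()[focal_class])
        h = shdi([p, 1.0 - p])
    else:
        h = shdi_from_raster(raster)
    return LandscapeMetrics(label=label, lsi=lsi(raster), shdi=h, shei=shei(h, n), n_classes=n)


# -- change annotations ----------------------------------------------------


def percent_change(prev: float, cur: float) -> float:
    """Signed percent change of ``cur`` relative to ``prev``."""
    if prev == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    return 100.0 * (cur - prev) / prev


def annotate_series(values: Sequence[float], decimals: int = 1) -> list[str]:
    """Baseline/percent-change annotations for a date-ordered series.

    The first entry is the baseline ``"(*)"``; entry t (t > 0) is the
    signed percent change versus entry t−1, rounded half-away-from-zero to
    ``decimals`` places (e.g. ``"+5.9%"``).  A zero previous value yields
    ``"n/a"``.
    """
    if len(values) == 0:
        raise ValueError("need at least one value")
    out = ["(*)"]
    for prev, cur in zip(values, values[1:]):
        if prev == 0:
            out.append("n/a")
            continue
        pc = round_half_away(percent_change(prev, cur), decimals)
        out.append(f"{pc:+.{decimals}f}%")
    return out


def metric_series(
    rasters: Sequence[CategoricalRaster],
    labels: Sequence[str],
    class_code: int,
    connectivity: int = 8,
    n_classes: int | None = None,
    area_override: float | None = None,
) -> pd.DataFrame:
    """Per-date class and landscape metrics with annotation columns.

    Returns a DataFrame indexed by date label with columns PN, WA, WP, PD,
    LSI, SHDI, SHEI, the per-interval LCI, and an annotation column per
    metric mirroring the published table convention.
    """
    if len(rasters) != len(labels):
        raise ValueError("labels must match rasters")
    rows = []
    for raster, label in zip(rasters, labels):
        cm = class_metrics(raster, class_code, connectivity, area_override, label=str(label))
        lm = landscape_level_metrics(
            raster, n_classes, focal_class=class_code, label=str(label)
        )
        rows.append(
            {
                "PN": cm.pn,
                "WA": cm.wa,
                "WP": cm.wp,
                "PD": cm.pd,
                "LSI": lm.lsi,
                "SHDI": lm.shdi,
                "SHEI": lm.shei,
            }
        )
    frame = pd.DataFrame(rows, index=pd.Index(labels, name="date"))
    frame["LCI"] = [math.nan] + [
        lci(a, b) for a, b in zip(frame["WP"], frame["WP"][1:])
    ]
    for col in ("PN", "WA", "WP", "PD", "LSI", "SHDI", "SHEI"):
        frame[f"{col}_change"] = annotate_series(frame[col].to_list())
    return frame
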