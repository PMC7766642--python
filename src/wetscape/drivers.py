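"""Grey relational analysis (GRA) of change drivers, and evaporation.

GRA ranks candidate driver series by their similarity to a characteristic
target series.  With a target x₀ and factors xᵢ (all length n), the
pointwise deviations Δᵢ(k) = |x₀(k) − xᵢ(k)| are compared against the
global extremes over all factors and time points:

    ε_i(k) = (Δmin + ρ·Δmax) / (Δ_i(k) + ρ·Δmax)

where ρ is the resolution coefficient (default 0.5), damping the pull of
the maximum deviation.  The correlation degree r_i = mean_k ε_i(k) lies in
(0, 1]; factors are ranked by descending r_i (1 = strongest, ties broken
by input order).

Because drivers are usually in incommensurate units (mm, head of
livestock, 10⁴ yuan…), each series should be made dimensionless first; the
default is mean-value normalization (each series divided by its own mean),
the standard GRA practice for mixed socioeconomic/climate series.

Evaporation: monthly pan-style evaporation is estimated from monthly
precipitation R (mm) and mean temperature T (°C) as

    E = 3100·R / (3100 + 1.8·R²·exp(−34.4·T / (235.0 + T)))

which tends to R as R → 0 and increases with T at fixed R > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GreySystem",
    "GreyResult",
    "grey_normalize",
    "grey_coefficients",
    "grey_degrees",
    "grey_relational_analysis",
    "monthly_evaporation",
    "annual_aggregate",
]


@dataclass(frozen=True)
class GreySystem:
    """Target sequence x0 plus named factor sequences, with resolution
    coefficient rho ∈ (0, 1]."""

    x0: np.ndarray
    factors: Mapping[str, np.ndarray]
    rho: float = 0.5
    normalization: str = "none"

    def __post_init__(self) -> None:
        x0 = np.asarray(self.x0, dtype=float)
        if x0.ndim != 1 or len(x0) < 2:
            raise ValueError("x0 must be a 1-D sequence of length >= 2")
        object.__setattr__(self, "x0", x0)
        factors = {k: np.asarray(v, dtype=float) for k, v in self.factors.items()}
        for name, xs in factors.items():
            if xs.shape != x0.shape:
                raise ValueError(f"factor {name!r} length != target length")
        object.__setattr__(self, "factors", factors)
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must be in (0, 1]")


@dataclass(frozen=True)
class GreyResult:
    """Correlation coefficients, degrees, and 1-based ranking."""

    coefficients: pd.DataFrame  # factors × time points
    degrees: pd.Series  # r_i per factor
    ranking: pd.Series  # rank per factor, 1 = strongest
    rho: float
    normalization: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"correlation_degree": self.degrees, "sort": self.ranking}
        )


def _normalize_one(xs: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return xs
    if mode == "mean":
        divisor = xs.mean()
    elif mode == "initial-value":
        divisor = xs[0]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if divisor == 0:
        raise ZeroDivisionError(f"{mode} normalization divisor is zero")
    return xs / divisor


def grey_normalize(system: GreySystem, mode: str = "mean") -> GreySystem:
    """Make all sequences dimensionless.

    ``mode`` is one of ``"mean"`` (divide each series by its own mean),
    ``"initial-value"`` (divide by its first element) or ``"none"``.
    """
    return replace(
        system,
        x0=_normalize_one(system.x0, mode),
        factors={k: _normalize_one(v, mode) for k, v in system.factors.items()},
        normalization=mode,
    )


def grey_coefficients(system: GreySystem) -> pd.DataFrame:
    """Correlation coefficients ε_i(k), one row per factor.

    Δmin and Δmax are global over all factors and all time points.  If
    every factor is identical to the target (Δmax = 0) all ε are 1.
    """
    names = list(system.factors)
    deltas = np.abs(
        np.stack([system.factors[n] for n in names]) - system.x0[None, :]
    )
    dmin, dmax = deltas.min(), deltas.max()
    if dmax == 0:
        eps = np.ones_like(deltas)
    else:
        eps = (dmin + system.rho * dmax) / (deltas + system.rho * dmax)
    return pd.DataFrame(eps, index=pd.Index(names, name="factor"))


def grey_degrees(coefficients: pd.DataFrame, system: GreySystem | None = None) -> GreyResult:
    """Correlation degrees r_i = mean_k ε_i(k), ranked descending.

    Ties are broken by input (row) order, so the ranking is always a
    permutation of 1..k.
    """
    degrees = coefficients.mean(axis=1)
    order = np.argsort(-degrees.to_numpy(), kind="stable")
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    ranking = pd.Series(ranks, index=degrees.index, name="sort")
    return GreyResult(
        coefficients=coefficients,
        degrees=degrees.rename("correlation_degree"),
        ranking=ranking,
        rho=system.rho if system is not None else 0.5,
        normalization=system.normalization if system is not None else "none",
    )


def grey_relational_analysis(
    x0: Sequence[float],
    factors: Mapping[str, Sequence[float]],
    rho: float = 0.5,
    normalization: str = "mean",
) -> GreyResult:
    """Normalize, compute coefficients, and rank — the full GRA pipeline."""
    system = grey_normalize(GreySystem(np.asarray(x0, float), dict(factors), rho), normalization)
    return grey_degrees(grey_coefficients(system), system)


# -- evaporation -----------------------------------------------------------


def monthly_evaporation(R, T):
    """Monthly evaporation E (mm) from precipitation R (mm) and mean
    temperature T (°C).

    Accepts scalars or arrays.  Raises for negative R or T ≤ −235 °C (the
    formula's singularity).
    """
    R = np.asarray(R, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(R < 0):
        raise ValueError("precipitation R must be >= 0")
    if np.any(T <= -235.0):
        raise ValueError("temperature T must exceed -235 °C")
    e = 3100.0 * R / (3100.0 + 1.8 * R**2 * np.exp(-34.4 * T / (235.0 + T)))
    return float(e) if e.ndim == 0 else e


@dataclass(frozen=True)
class AnnualClimate:
    """Per-station-year aggregates plus multi-station yearly means."""

    per_station: pd.DataFrame  # station, year, T_mean, R_sum, E_sum, complete
    yearly: pd.DataFrame  # year, T_mean, R_sum, E_sum over complete station-years
    incomplete: pd.DataFrame = field(default_factory=pd.DataFrame)


def annual_aggregate(records: pd.DataFrame) -> AnnualClimate:
    """Aggregate monthly station records to yearly values.

    ``records`` needs columns station, year, month, T, R.  For each
    station-year with all 12 months present the yearly mean temperature,
    precipitation sum and evaporation sum are computed; incomplete
    station-years are flagged and excluded from the multi-station
    averages.  Duplicate (station, year, month) rows raise.
    """
    required = {"station", "year", "month", "T", "R"}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    dup = records.duplicated(subset=["station", "year", "month"])
    if dup.any():
        raise ValueError("duplicate (station, year, month) records")
    records = records.copy()
    records["E"] = monthly_evaporation(records["R"].to_numpy(), records["T"].to_numpy())
    grouped = records.groupby(["station", "year"]).agg(
        T_mean=("T", "mean"),
        R_sum=("R", "sum"),
        E_sum=("E", "sum"),
        n_months=("month", "nunique"),
    )
    grouped["complete"] = grouped["n_months"] == 12
    per_station = grouped.reset_index()
    complete = per_station[per_station["complete"]]
    yearly = (
        complete.groupby("year")[["T_mean", "R_sum", "E_sum"]].mean().reset_index()
    )
    incomplete = per_station[~per_station["complete"]]
    return AnnualClimate(per_station=per_station, yearly=yearly, incomplete=incomplete)


def impute_linear(table, factor: str, year: int):
    """Linearly extrapolate one missing year from the two prior points.

    Returns the imputed value; the caller decides whether to append it.
    Intended for patching a single trailing gap in a driver series and
    always reported as imputed by the CLI.
    """
    frame = table.to_frame() if hasattr(table, "to_frame") else table
    series = frame[factor].dropna()
    prior = series[series.index < year]
    if len(prior) < 2:
        raise ValueError("need two prior points to extrapolate")
    (y1, v1), (y2, v2) = list(prior.items())[-2:]
    slope = (v2 - v1) / (y2 - y1)
    return v2 + slope * (year - y2)
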