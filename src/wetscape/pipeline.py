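"""End-to-end pipeline: multi-date rasters in, landscape-change tables out.

A run is described by a :class:`RunConfig` (usually loaded from YAML).
Rasters are either read from disk, one per date, or generated
synthetically from a base scenario plus a change regime per interval.
Every run writes the class-metric series, the per-interval change index,
the patch-size frequency and level tables, the landscape-level index
series, and the inter-date transfer summaries, as CSV and JSON, plus a
plain-text log recording every effective setting so reproductions are
self-describing.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import change_dynamics, landscape_metrics, patch_engine, synthetic_data
from .raster_core import CategoricalRaster, read_legend, read_raster, table_to_json

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("wetscape")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, with reproducible defaults."""

    dates: Sequence[int]
    output_dir: str = "wetscape_out"
    rasters: Sequence[str] = ()
    synthetic: Mapping | None = None
    legend: Mapping[int, str] | str | None = None
    wetland_code: int = synthetic_data.WETLAND_CODE
    grassland_code: int = synthetic_data.GRASSLAND_CODE
    connectivity: int = 8
    n_classes: int | None = None
    area_override: float | None = None
    nodata: int = -9999
    seed: int = 0
    annotation_decimals: int = 1

    def __post_init__(self) -> None:
        dates = tuple(int(d) for d in self.dates)
        if len(dates) < 2:
            raise ValueError("need at least two dates")
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("dates must be strictly increasing")
        object.__setattr__(self, "dates", dates)
        if self.rasters and self.synthetic is not None:
            raise ValueError("give either raster paths or a synthetic block, not both")
        if not self.rasters and self.synthetic is None:
            raise ValueError("no inputs: give raster paths or a synthetic block")
        if self.rasters and len(self.rasters) != len(dates):
            raise ValueError("need one raster per date")
        for p in self.rasters:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _load_rasters(config: RunConfig) -> list[CategoricalRaster]:
    if config.rasters:
        if config.legend is None:
            raise ValueError("raster inputs need a legend (path or mapping)")
        legend = (
            read_legend(config.legend)
            if isinstance(config.legend, (str, Path))
            else {int(k): str(v) for k, v in config.legend.items()}
        )
        return [
            read_raster(p, legend, nodata=config.nodata) for p in config.rasters
        ]
    spec = dict(config.synthetic or {})
    regimes = spec.pop("regimes", ["stationary"] * (len(config.dates) - 1))
    if len(regimes) != len(config.dates) - 1:
        raise ValueError("need one change regime per interval")
    if "shape" in spec:
        spec["shape"] = tuple(spec["shape"])
    scenario = synthetic_data.LandscapeScenario(seed=config.seed, **spec)
    rasters = [synthetic_data.generate_landscape(scenario)]
    for k, regime in enumerate(regimes):
        if isinstance(regime, str):
            regime = {"regime": regime}
        change = synthetic_data.ChangeScenario(
            focal_class=config.wetland_code,
            recipient_class=config.grassland_code,
            seed=config.seed + 1 + k,
            **regime,
        )
        rasters.append(synthetic_data.evolve_landscape(rasters[-1], change))
    return rasters


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every analysis stage and write the report bundle.

    Returns the tables keyed by name; the same tables are written to
    ``output_dir`` as CSV and JSON together with ``run.log``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")
        logger.info(msg)

    log(f"run start; dates={list(config.dates)} seed={config.seed}")
    log(
        "settings: connectivity=%d n_classes=%s area_override=%s nodata=%d "
        "wetland_code=%d grassland_code=%d annotation_decimals=%d"
        % (
            config.connectivity,
            config.n_classes,
            config.area_override,
            config.nodata,
            config.wetland_code,
            config.grassland_code,
            config.annotation_decimals,
        )
    )

    stage = "input"
    tables: dict[str, pd.DataFrame] = {}
    try:
        rasters = _load_rasters(config)
        log(f"loaded {len(rasters)} rasters, shape {rasters[0].shape}")

        stage = "metrics"
        series = landscape_metrics.metric_series(
            rasters,
            [str(d) for d in config.dates],
            config.wetland_code,
            connectivity=config.connectivity,
            n_classes=config.n_classes,
            area_override=config.area_override,
        )
        tables["class_metrics"] = series[
            ["PN", "PN_change", "WA", "WA_change", "WP", "WP_change"]
        ]
        tables["landscape_metrics"] = series[
            ["PD", "PD_change", "LSI", "LSI_change", "SHDI", "SHDI_change",
             "SHEI", "SHEI_change"]
        ]
        intervals = [f"{a}-{b}" for a, b in zip(config.dates, config.dates[1:])]
        tables["lci"] = pd.DataFrame(
            {"interval": intervals, "LCI": series["LCI"].to_list()[1:]}
        ).set_index("interval")

        stage = "patch structure"
        bins, levels = {}, {}
        for raster, date in zip(rasters, config.dates):
            patch_set = patch_engine.label_patches(
                raster, config.wetland_code, config.connectivity
            )
            table = patch_engine.size_frequency(patch_set)
            bins[date] = dict(zip(table.bin_labels, table.bin_counts))
            levels[date] = dict(zip(patch_engine.LEVEL_NAMES, table.level_areas))
        tables["size_frequency"] = pd.DataFrame(bins)
        tables["level_areas"] = pd.DataFrame(levels)

        stage = "transfer"
        flows = {}
        for (a, b), (r0, r1) in zip(
            zip(config.dates, config.dates[1:]), zip(rasters, rasters[1:])
        ):
            matrix = change_dynamics.transition_matrix(r0, r1, str(a), str(b))
            matrix.areas.to_csv(out / f"transfer_matrix_{a}_{b}.csv")
            flows[f"{a}-{b}"] = change_dynamics.wetland_flows(
                matrix, config.wetland_code, config.grassland_code
            )._asdict()
            log(f"transfer {a}->{b}: excluded area {matrix.excluded_area_hm2} hm²")
        tables["transfer_summary"] = pd.DataFrame(flows)
    except Exception as exc:
        log(f"FAILED at stage '{stage}': {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    for name, frame in tables.items():
        frame.to_csv(out / f"{name}.csv")
        table_to_json(frame, out / f"{name}.json")
    log(f"wrote {len(tables)} tables to {out}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return tables
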