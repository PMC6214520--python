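"""End-to-end orchestration: hazard -> AC index -> filter -> V -> quadrants -> regressions.

A single :class:`PipelineConfig` drives the run.  Outputs are plain CSV/JSON
and are byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape

from . import __version__, capacity, hazard, regression, vulnerability
from .errors import FireEquityError, InvalidConfigError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, loadable from YAML or JSON."""

    raster_path: str
    tracts_path: str
    attributes_path: str
    output_dir: str
    rescale_in_min: float = 0.0
    rescale_in_max: float = 1.0
    include_nonburnable: bool = True
    moderate_threshold: float = 0.4
    indicator_specs: list[dict] | None = None  # [{column, name, domain, direction}]
    ac_split: float = 0.5
    whp_split: float | None = None             # default: midpoint(threshold, 1)
    mins_mode: str = "filtered"                # "filtered" or "global"
    taus: tuple[float, ...] = (0.05, 0.95)
    predictor: str = "proportion"
    cv_window: float = 0.25
    n_boot: int = 200
    seed: int = 0
    group_columns: list[str] | None = None     # default: all pop_* except pop_total
    log_level: str = "INFO"

    def __post_init__(self):
        for tau in self.taus:
            if not 0 < tau < 1:
                raise InvalidConfigError(f"tau must be in (0, 1), got {tau}")
        if self.mins_mode not in ("filtered", "global"):
            raise InvalidConfigError(f"unknown mins_mode {self.mins_mode!r}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.pop("kind", None)
        raw["taus"] = tuple(raw.get("taus", (0.05, 0.95)))
        return cls(**raw)

    def specs(self) -> tuple[capacity.IndicatorSpec, ...]:
        if self.indicator_specs is None:
            return capacity.DEFAULT_INDICATORS
        return tuple(
            capacity.IndicatorSpec(
                s["column"], s.get("name", s["column"]), s["domain"],
                s.get("direction", "higher_is_worse"),
            )
            for s in self.indicator_specs
        )


def read_tracts_geojson(path) -> list:
    """Read (tract_id, polygon) pairs from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    tracts = []
    for feat in gj.get("features", []):
        tid = feat.get("properties", {}).get("tract_id")
        if tid is None:
            raise InvalidConfigError("GeoJSON feature missing 'tract_id' property")
        tracts.append((str(tid), shape(feat["geometry"])))
    return tracts


def _validate_columns(table: pd.DataFrame, config: PipelineConfig) -> list[str]:
    specs = config.specs()
    missing = [s.column for s in specs if s.column not in table.columns]
    if missing:
        raise PipelineError(
            "validate", f"missing indicator column(s): {', '.join(missing)}"
        )
    if config.group_columns is not None:
        groups = list(config.group_columns)
    else:
        groups = [c for c in table.columns if c.startswith("pop_") and c != "pop_total"]
    absent = [g for g in groups if g not in table.columns]
    if absent:
        raise PipelineError("validate", f"missing group column(s): {', '.join(absent)}")
    if not groups:
        raise PipelineError("validate", "no race/ethnicity group columns found")
    return groups


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the result bundle to ``config.output_dir``.

    Outputs: tract_hazard.csv, ac_index.csv, vulnerability.csv,
    representation.csv, inequity.csv and run_manifest.json.  Returns a dict of
    the in-memory tables plus the manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except FireEquityError as exc:
            raise PipelineError(name, str(exc)) from exc

    raster = stage("read_raster", hazard.read_ascii_grid, config.raster_path)
    tracts = stage("read_tracts", read_tracts_geojson, config.tracts_path)
    table = pd.read_csv(config.attributes_path, dtype={"tract_id": str})
    groups = _validate_columns(table, config)

    rescaled = stage(
        "rescale", hazard.rescale_hazard, raster,
        config.rescale_in_min, config.rescale_in_max,
    )
    tract_hz = stage(
        "zonal_mean", hazard.zonal_mean, rescaled, tracts,
        include_nonburnable=config.include_nonburnable,
    )
    filtered = stage(
        "filter", hazard.filter_at_least_moderate, tract_hz, config.moderate_threshold
    )
    ac = stage("ac_index", capacity.compute_ac_index, table, config.specs())

    if config.mins_mode == "filtered":
        base = filtered.merge(ac[["tract_id", "ac"]], on="tract_id")
        params = vulnerability.VulnerabilityParams.from_data(
            base["ac"], base["whp"], ac_split=config.ac_split,
            whp_split=config.whp_split, moderate_threshold=config.moderate_threshold,
        )
    else:
        all_joined = tract_hz.merge(ac[["tract_id", "ac"]], on="tract_id")
        params = vulnerability.VulnerabilityParams.from_data(
            all_joined["ac"], all_joined["whp"], ac_split=config.ac_split,
            whp_split=config.whp_split, moderate_threshold=config.moderate_threshold,
        )
    vuln, params = stage(
        "vulnerability", vulnerability.build_vulnerability_table,
        filtered, ac, params=params,
    )
    rep = stage(
        "representation", vulnerability.representation_ratios, vuln, table, groups
    )
    ineq = stage(
        "inequity", regression.fit_group_disparities, vuln, table, groups,
        taus=config.taus, predictor=config.predictor, cv_window=config.cv_window,
        n_boot=config.n_boot, seed=config.seed,
    )

    quad_counts = vuln["quadrant"].value_counts().to_dict()
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "counts": {
            "tracts_total": int(len(tract_hz)),
            "tracts_filtered": int(len(vuln)),
            "quadrants": {q: int(quad_counts.get(q, 0)) for q in vulnerability.QUADRANTS},
        },
        "vulnerability_params": dataclasses.asdict(params),
    }

    outputs = {
        "tract_hazard.csv": tract_hz,
        "ac_index.csv": ac,
        "vulnerability.csv": vuln,
        "representation.csv": rep,
        "inequity.csv": ineq,
    }
    try:
        for name, df in outputs.items():
            df.to_csv(outdir / name, index=False, lineterminator="\n")
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception:
        for name in list(outputs) + ["run_manifest.json"]:
            (outdir / name).unlink(missing_ok=True)
        raise

    logger.info(
        "pipeline complete: %d tracts, %d after filter, quadrants %s",
        len(tract_hz), len(vuln), manifest["counts"]["quadrants"],
    )
    return {"manifest": manifest, "params": params, **{
        k.removesuffix(".csv"): v for k, v in outputs.items()
    }}
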