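"""Configuration and end-to-end pipeline plumbing.

A run is its config: a single validated structure (serializable to JSON)
holding the cohort composition, flow conditions, numerics, metric options
and statistics options, plus the seed.  ``run_pipeline`` executes the
stages — cohort synthesis (metric- or geometry-mode), optional CFD, metric
extraction and the comparison-table statistics — and writes every stage
output with provenance (schema version, config hash, seed).  Identical
config + seed gives byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .cohort import (
    CohortConfig,
    cohort_to_frame,
    run_cohort_cfd,
    sample_geometry_cohort,
    sample_metric_cohort,
)
from .solver import FlowConditions, Numerics
from .stats import HEMODYNAMIC_PARAMS, backward_stepwise_logistic, build_comparison_tables, univariate_screen

__all__ = ["PipelineConfig", "run_pipeline", "SCHEMA_VERSION"]

SCHEMA_VERSION = "hemoshear-run-1"


class FlowModel(BaseModel):
    density: float = 1050.0
    viscosity: float = 3.5e-3
    mean_flow: float = 185.0
    max_flow: float = 301.0
    heart_rate: float = 64.0
    n_cycles: int = 3
    reference_diameter: float | None = None

    def build(self) -> FlowConditions:
        return FlowConditions(**self.model_dump())


class NumericsModel(BaseModel):
    steps_per_cycle: int = 200
    alpha_u: float = 0.7
    alpha_p: float = 0.3
    tol_mass: float = 1e-5
    tol_steady: float = 1e-6
    cell_size: float | None = None  # mm; None -> caliber / 8

    def build(self) -> Numerics:
        d = self.model_dump()
        d.pop("cell_size")
        return Numerics(**d)


class CohortModel(BaseModel):
    n_ruptured: int = 41
    n_unruptured: int = 31
    narrow_fraction_ruptured: float = 0.5
    narrow_fraction_unruptured: float = 0.5
    mode: str = "metric"
    parent_caliber: float = 3.24
    quartile_kind: str = "iqr"

    def build(self, seed: int) -> CohortConfig:
        return CohortConfig(seed=seed, **self.model_dump())


class StatsOptions(BaseModel):
    screen_alpha: float = 0.05
    removal_p: float = 0.10


class MetricOptions(BaseModel):
    hwss_mode: str = "time-averaged"
    threshold_fraction: float = 0.1
    probe_distance: float = 10.0
    probe_extent: float = 2.0
    probe_side: str = "upstream"


class PipelineConfig(BaseModel):
    """Resolved configuration of one reproducible run."""

    seed: int = 0
    cohort: CohortModel = Field(default_factory=CohortModel)
    flow: FlowModel = Field(default_factory=FlowModel)
    numerics: NumericsModel = Field(default_factory=NumericsModel)
    metrics: MetricOptions = Field(default_factory=MetricOptions)
    stats: StatsOptions = Field(default_factory=StatsOptions)

    @field_validator("seed")
    @classmethod
    def _seed_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be >= 0")
        return v

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the configured pipeline and write all stage outputs.

    Writes ``config.json`` (resolved config + hash), ``cohort.csv``,
    ``table_*.csv``, ``screen.json`` and ``logistic.json`` under
    ``out_dir``; returns the in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "schema": SCHEMA_VERSION,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.model_dump(),
    }
    (out / "config.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    ccfg = config.cohort.build(config.seed)
    failures: list = []
    if ccfg.mode == "metric":
        records = sample_metric_cohort(ccfg)
    else:
        geoms = sample_geometry_cohort(ccfg)
        records, failures = run_cohort_cfd(
            geoms,
            config.flow.build(),
            config.numerics.build(),
            cell_size=config.numerics.cell_size,
            hwss_mode=config.metrics.hwss_mode,
        )
    frame = cohort_to_frame(records)
    frame.insert(0, "schema", SCHEMA_VERSION)
    frame.insert(1, "config_hash", config.config_hash())
    frame.to_csv(out / "cohort.csv", index=False, float_format="%.10g")

    tables = build_comparison_tables(frame)
    for name, tab in tables.items():
        tab.to_csv(out / f"table_{name}.csv", index=False, float_format="%.10g")

    frame = frame.assign(ruptured=(frame["rupture_label"] == "ruptured").astype(int))
    screened = univariate_screen(frame, HEMODYNAMIC_PARAMS, alpha=config.stats.screen_alpha)
    (out / "screen.json").write_text(
        json.dumps({"schema": SCHEMA_VERSION, "screened": screened}, indent=2)
    )
    logistic = None
    if screened:
        fit = backward_stepwise_logistic(frame, screened, removal_p=config.stats.removal_p)
        logistic = {
            "retained": list(fit.retained),
            "coefficients": fit.coefficients,
            "p_values": fit.p_values,
            "trace": [list(t) for t in fit.trace],
            "separation_flagged": fit.separation_flagged,
        }
        (out / "logistic.json").write_text(
            json.dumps({"schema": SCHEMA_VERSION, **logistic}, indent=2)
        )
    if failures:
        (out / "failures.json").write_text(
            json.dumps({"schema": SCHEMA_VERSION, "failures": failures}, indent=2)
        )
    return {
        "records": records,
        "frame": frame,
        "tables": tables,
        "screened": screened,
        "logistic": logistic,
        "failures": failures,
    }
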