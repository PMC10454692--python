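"""End-to-end orchestration: read/simulate -> correct -> fit -> contrasts.

A run is described by a :class:`RunConfig` (built in code, from CLI options,
or from a YAML file) and produces, in the output directory:

* ``corrected_curves.csv`` — blank- and minimum-corrected curves (long form);
* ``metrics.csv`` — per-well (od_max, r_max, auc) with annotations;
* ``contrasts.csv`` — all Tukey pairwise contrasts per strain and metric;
* ``deltas.csv`` — the oriented report rows: each prebiotic vs control
  (delta_c), inulin vs XOS (delta_ix) and, when a glucose control is
  present, each condition vs glucose (delta_glucose);
* ``summary.json`` — machine-readable run summary (schema version 1).

Identical config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrasts as cst
from . import growth, io, preprocess
from .exceptions import ConfigError, FitError, PipelineError
from .simulate import generate_experiment, preset_scenarios

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything needed for one analysis run.

    Exactly one of (``timeseries_path`` + ``layout_path``) or ``scenario``
    must be given.
    """

    outdir: str
    timeseries_path: str | None = None
    layout_path: str | None = None
    scenario: str | None = None
    time_unit: str = "hours"
    threshold_c: float = growth.DERIV_THRESHOLD
    no_growth_floor: float = growth.NO_GROWTH_FLOOR
    alpha: float = 0.05
    control_label: str = "control"
    inulin_label: str = "inulin"
    xos_label: str = "XOS"
    glucose_label: str = "glucose"
    seed: int = 0
    log_level: str = "INFO"
    pre_average: bool = False

    def validate(self) -> None:
        has_files = self.timeseries_path is not None and self.layout_path is not None
        has_partial_files = (self.timeseries_path is None) != (self.layout_path is None)
        if has_partial_files:
            raise ConfigError("timeseries_path and layout_path must be given together")
        if has_files == (self.scenario is not None):
            raise ConfigError(
                "exactly one of (timeseries_path + layout_path) or scenario required"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.threshold_c <= 0:
            raise ConfigError(f"threshold_c must be > 0, got {self.threshold_c}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def _metric_record(well_id, entry, metrics) -> io.MetricRecord:
    w = metrics.window
    return io.MetricRecord(
        well_id=well_id,
        strain=entry.strain,
        condition=entry.condition,
        experiment=entry.experiment_id,
        replicate=entry.replicate,
        od_max=metrics.od_max,
        r_max=metrics.r_max,
        auc=metrics.auc,
        window_start=w.t_start if not w.empty else math.nan,
        window_end=w.t_end_w if not w.empty else math.nan,
        converged=metrics.fit.converged if metrics.fit is not None else False,
    )


def contrast_rows_for_strain(
    metrics_df: pd.DataFrame, config: RunConfig
) -> tuple[list[dict], list[dict], dict]:
    """Fit the blocked ANOVA per metric and build contrast/delta rows."""
    all_rows: list[dict] = []
    delta_rows: list[dict] = []
    diagnostics: dict = {}
    strain = metrics_df["strain"].iloc[0]
    for metric in cst.METRICS:
        obs = cst.MetricObservations(
            strain=strain,
            metric=metric,
            data=metrics_df.rename(columns={metric: "value", "experiment": "block"})[
                ["value", "condition", "block", "replicate"]
            ],
        )
        if obs.design_flags:
            diagnostics[metric] = {"flags": obs.design_flags}
            continue
        if config.pre_average:
            obs = cst.pre_average_blocks(obs)
        fit = cst.fit_blocked_anova(obs)
        pairs = cst.tukey_pairwise(fit, alpha=config.alpha)
        diagnostics[metric] = cst.residual_diagnostics(fit)
        for c in pairs:
            all_rows.append(_contrast_row(strain, metric, "all_pairs", c))
        labels = set(metrics_df["condition"].unique())
        if {config.control_label, config.inulin_label, config.xos_label} <= labels:
            tables = cst.delta_tables(
                pairs,
                control_label=config.control_label,
                inulin_label=config.inulin_label,
                xos_label=config.xos_label,
                glucose_label=config.glucose_label,
            )
            for lab, c in sorted(tables.delta_c.items()):
                delta_rows.append(_contrast_row(strain, metric, "delta_c", c))
            delta_rows.append(_contrast_row(strain, metric, "delta_ix", tables.delta_ix))
            for lab, c in sorted(tables.delta_glucose.items()):
                delta_rows.append(_contrast_row(strain, metric, "delta_glucose", c))
    return all_rows, delta_rows, diagnostics


def _contrast_row(strain: str, metric: str, comparison: str, c: cst.ContrastResult) -> dict:
    return {
        "strain": strain,
        "metric": metric,
        "comparison": comparison,
        "pair": f"{c.pair[0]} - {c.pair[1]}",
        "estimate": c.estimate,
        "ci_low": c.ci_low,
        "ci_high": c.ci_high,
        "p_adj": c.p_adj,
        "significant": c.significant,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all outputs; returns the summary."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, outdir, written)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(getattr(exc, "_stage", "unknown"), exc) from exc


def _run(config: RunConfig, outdir: Path, written: list[Path]) -> dict:
    stage = "load"
    try:
        if config.scenario is not None:
            presets = preset_scenarios(seed=config.seed)
            if config.scenario not in presets:
                raise ConfigError(
                    f"unknown scenario {config.scenario!r}; "
                    f"choose from {sorted(presets)}"
                )
            curves, layout, _truth = generate_experiment(presets[config.scenario])
        else:
            layout = io.read_layout(config.layout_path)
            curves = io.read_plate_timeseries(
                config.timeseries_path, layout, time_unit=config.time_unit
            )

        stage = "validate"
        report = io.validate_run(curves)

        stage = "correct"
        corrected, _refs = preprocess.correct_plate(curves)
        p = outdir / "corrected_curves.csv"
        io.write_corrected_curves(corrected, p)
        written.append(p)

        stage = "fit"
        records: list[io.MetricRecord] = []
        failures: list[dict] = []
        for cc in corrected:
            entry = cc.source.layout
            try:
                m = growth.compute_metrics(
                    cc, c=config.threshold_c,
                    no_growth_floor=config.no_growth_floor, seed=config.seed,
                )
            except FitError as e:
                failures.append({"well_id": cc.source.well_id, "error": str(e)})
                continue
            records.append(_metric_record(cc.source.well_id, entry, m))
        p = outdir / "metrics.csv"
        io.write_metrics_table(records, p)
        written.append(p)

        stage = "contrasts"
        mdf = pd.DataFrame([vars(r) for r in records], columns=io.METRIC_COLUMNS)
        all_rows: list[dict] = []
        delta_rows: list[dict] = []
        diagnostics: dict = {}
        if not mdf.empty:
            for strain, grp in mdf.groupby("strain", sort=True):
                rows, drows, diag = contrast_rows_for_strain(grp, config)
                all_rows += rows
                delta_rows += drows
                diagnostics[strain] = diag
        p = outdir / "contrasts.csv"
        io.write_contrasts_table(all_rows, p)
        written.append(p)
        p = outdir / "deltas.csv"
        io.write_contrasts_table(delta_rows, p)
        written.append(p)

        stage = "summary"
        summary = {
            "schema_version": SUMMARY_SCHEMA_VERSION,
            "config": {
                k: v for k, v in asdict(config).items() if k != "log_level"
            },
            "n_curves": len(curves),
            "n_blank_wells": sum(1 for c in curves if c.layout.is_blank),
            "n_corrected": len(corrected),
            "n_fitted": len(records),
            "n_no_growth": int(sum(1 for r in records if not r.converged)),
            "n_nonconverged": len(failures),
            "nonconverged_wells": failures,
            "validation_flags": report.to_records(),
            "diagnostics": _jsonable(diagnostics),
            "outputs": sorted(str(p.name) for p in written),
        }
        p = outdir / "summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
        return summary
    except Exception as exc:
        exc._stage = stage  # type: ignore[attr-defined]
        raise


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    return obj
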