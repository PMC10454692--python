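"""Reading plate-reader OD600 exports and plate layouts; writing result tables.

Supported time-series dialects (auto-detected from the header):

* **wide** — one ``time`` column plus one column per well::

      time,E1-A1,E1-A2
      0.0,0.051,0.049

* **long** — three columns ``well,time,od``::

      well,time,od
      E1-A1,0.0,0.051

Times are converted to hours internally; the layout is a separate CSV/YAML
config mapping wells to (strain, condition, experiment, replicate, blank flag)
because instrument exports carry no such metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, LayoutError, PlateValidationError

logger = logging.getLogger(__name__)

#: design cadence of the assay, in minutes between consecutive readings
DESIGN_CADENCE_MIN = 20.0
#: minimal total observation span, in hours
DESIGN_MIN_SPAN_H = 15.0
#: maximal optical density at the first reading of an inoculated well
DESIGN_MAX_START_OD = 0.2
#: minimal number of readings needed for a meaningful logistic fit
MIN_POINTS = 10


@dataclass(frozen=True)
class LayoutEntry:
    """One well's annotations: who grows in it, on what, in which experiment."""

    well_id: str
    strain: str
    condition: str
    experiment_id: str
    replicate: int
    is_blank: bool


@dataclass
class PlateLayout:
    """A collection of well annotations for one or more experiments."""

    entries: list[LayoutEntry]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.experiment_id, e.well_id)
            if key in seen:
                raise LayoutError(
                    f"duplicate well {e.well_id!r} in experiment {e.experiment_id!r}"
                )
            seen.add(key)
            if not e.is_blank and e.replicate < 1:
                raise LayoutError(f"well {e.well_id!r}: replicate must be >= 1")
        # every medium used by an inoculated well needs a blank in the same experiment
        blanks = {(e.experiment_id, e.condition) for e in self.entries if e.is_blank}
        for e in self.entries:
            if not e.is_blank and (e.experiment_id, e.condition) not in blanks:
                raise LayoutError(
                    f"medium {e.condition!r} has no blank well in experiment "
                    f"{e.experiment_id!r} (well {e.well_id!r} needs one)"
                )

    def by_well(self) -> dict[str, LayoutEntry]:
        return {e.well_id: e for e in self.entries}

    @property
    def wells(self) -> list[str]:
        return [e.well_id for e in self.entries]


@dataclass
class TimeSeriesCurve:
    """One well's OD600 readings over time, annotated with its layout entry."""

    well_id: str
    layout: LayoutEntry
    times: np.ndarray  # hours since the first reading of the experiment
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise PlateValidationError(
                f"well {self.well_id!r}: times and od lengths differ"
            )
        if not np.all(np.isfinite(self.od)) or not np.all(np.isfinite(self.times)):
            raise PlateValidationError(f"well {self.well_id!r}: non-finite values")
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise PlateValidationError(
                f"well {self.well_id!r}: times not strictly increasing at row {row}"
            )

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ValidationFlag:
    well_id: str
    flag: str
    detail: str


@dataclass
class ValidationReport:
    """Soft design-deviation flags; deviations warn rather than exclude."""

    flags: list[ValidationFlag] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags

    def to_records(self) -> list[dict]:
        return [vars(f) for f in self.flags]


def read_layout(path: str | Path) -> PlateLayout:
    """Read a plate layout from CSV (columns well,strain,condition,experiment,
    replicate,is_blank) or YAML (a ``wells:`` list of mappings)."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rows = doc["wells"] if isinstance(doc, dict) else doc
        entries = [
            LayoutEntry(
                well_id=str(r["well"]),
                strain=str(r.get("strain", "")),
                condition=str(r["condition"]),
                experiment_id=str(r["experiment"]),
                replicate=int(r.get("replicate", 1)),
                is_blank=bool(r.get("is_blank", False)),
            )
            for r in rows
        ]
    else:
        df = pd.read_csv(path)
        required = {"well", "condition", "experiment"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"layout file missing columns: {sorted(missing)}")
        entries = [
            LayoutEntry(
                well_id=str(r.well),
                strain=str(getattr(r, "strain", "") or ""),
                condition=str(r.condition),
                experiment_id=str(r.experiment),
                replicate=int(getattr(r, "replicate", 1)),
                is_blank=_as_bool(getattr(r, "is_blank", False)),
            )
            for r in df.itertuples(index=False)
        ]
    return PlateLayout(entries)


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"1", "true", "yes", "y"}
    return bool(x)


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "well": e.well_id,
                "strain": e.strain,
                "condition": e.condition,
                "experiment": e.experiment_id,
                "replicate": e.replicate,
                "is_blank": e.is_blank,
            }
            for e in layout.entries
        ]
    )
    df.to_csv(path, index=False)


def read_plate_timeseries(
    path: str | Path,
    layout: PlateLayout,
    time_unit: str = "hours",
) -> list[TimeSeriesCurve]:
    """Parse a wide or long delimited OD600 table into per-well curves.

    Wells present in the file but absent from the layout are logged and
    skipped; a layout well with no data column raises
    :class:`PlateValidationError`. Times are shifted so each returned curve
    starts at t = 0 h.
    """
    if time_unit not in {"minutes", "hours"}:
        raise ValueError(f"time_unit must be 'minutes' or 'hours', got {time_unit!r}")
    factor = 1.0 / 60.0 if time_unit == "minutes" else 1.0
    df = pd.read_csv(path, sep=None, engine="python")
    cols_lower = {c.lower(): c for c in df.columns}

    by_well = layout.by_well()
    curves: list[TimeSeriesCurve] = []

    if {"well", "time", "od"} <= set(cols_lower):
        wcol, tcol, ocol = (cols_lower[k] for k in ("well", "time", "od"))
        present = []
        for well, grp in df.groupby(wcol, sort=True):
            well = str(well)
            present.append(well)
            if well not in by_well:
                logger.warning("well %s in file but not in layout; skipped", well)
                continue
            times = grp[tcol].to_numpy(dtype=float) * factor
            _check_monotone(times, well)
            curves.append(
                TimeSeriesCurve(
                    well_id=well,
                    layout=by_well[well],
                    times=times - times[0],
                    od=grp[ocol].to_numpy(dtype=float),
                )
            )
        missing = sorted(set(by_well) - set(present))
    else:
        if "time" not in cols_lower:
            raise FormatError(
                f"no time column found in {path} (columns: {list(df.columns)})"
            )
        tcol = cols_lower["time"]
        times = df[tcol].to_numpy(dtype=float) * factor
        _check_monotone(times, "<time column>")
        times = times - times[0]
        data_wells = [c for c in df.columns if c != tcol]
        for well in data_wells:
            if well not in by_well:
                logger.warning("well %s in file but not in layout; skipped", well)
                continue
            curves.append(
                TimeSeriesCurve(
                    well_id=well,
                    layout=by_well[well],
                    times=times.copy(),
                    od=df[well].to_numpy(dtype=float),
                )
            )
        missing = sorted(set(by_well) - set(data_wells))
    if missing:
        raise PlateValidationError(
            f"layout wells with no data column in {path}: {missing}"
        )
    return curves


def _check_monotone(times: np.ndarray, label: str) -> None:
    diffs = np.diff(times)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        raise PlateValidationError(
            f"{label}: time values not strictly increasing at row {int(bad[0]) + 1}"
        )


def validate_run(curves: Iterable[TimeSeriesCurve]) -> ValidationReport:
    """Flag design deviations: start OD, total span, cadence, short series.

    All checks are advisory; curves are never excluded automatically.
    """
    report = ValidationReport()
    for c in curves:
        if len(c) < MIN_POINTS:
            report.flags.append(
                ValidationFlag(c.well_id, "too-few-points", f"{len(c)} readings")
            )
            continue
        if not c.layout.is_blank and c.od[0] >= DESIGN_MAX_START_OD:
            report.flags.append(
                ValidationFlag(
                    c.well_id,
                    "start-od",
                    f"first reading {c.od[0]:.3f} >= {DESIGN_MAX_START_OD}",
                )
            )
        span = c.times[-1] - c.times[0]
        if span < DESIGN_MIN_SPAN_H:
            report.flags.append(
                ValidationFlag(c.well_id, "span", f"{span:.2f} h < {DESIGN_MIN_SPAN_H} h")
            )
        med_step_min = float(np.median(np.diff(c.times))) * 60.0
        if math.isfinite(med_step_min) and abs(med_step_min - DESIGN_CADENCE_MIN) > 0.1 * DESIGN_CADENCE_MIN:
            report.flags.append(
                ValidationFlag(
                    c.well_id,
                    "cadence",
                    f"median interval {med_step_min:.1f} min deviates from "
                    f"{DESIGN_CADENCE_MIN:.0f} min by > 10%",
                )
            )
    return report


# ---------------------------------------------------------------------------
# result tables

METRIC_COLUMNS = [
    "well_id",
    "strain",
    "condition",
    "experiment",
    "replicate",
    "od_max",
    "r_max",
    "auc",
    "window_start",
    "window_end",
    "converged",
]


@dataclass
class MetricRecord:
    """One row of the per-curve metrics table."""

    well_id: str
    strain: str
    condition: str
    experiment: str
    replicate: int
    od_max: float
    r_max: float
    auc: float
    window_start: float  # NaN when the growth window is empty
    window_end: float
    converged: bool


def write_metrics_table(records: Sequence[MetricRecord], path: str | Path) -> None:
    """Write metric records as CSV; floats keep full round-trip precision."""
    df = pd.DataFrame([vars(r) for r in records], columns=METRIC_COLUMNS)
    df.to_csv(path, index=False)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metrics table missing columns: {sorted(missing)}")
    return df


CONTRAST_COLUMNS = [
    "strain",
    "metric",
    "comparison",
    "pair",
    "estimate",
    "ci_low",
    "ci_high",
    "p_adj",
    "significant",
]


def write_contrasts_table(rows: Sequence[dict], path: str | Path) -> None:
    """Write contrast rows (dicts with :data:`CONTRAST_COLUMNS` keys) as CSV."""
    df = pd.DataFrame(list(rows), columns=CONTRAST_COLUMNS)
    df.to_csv(path, index=False)


def write_corrected_curves(corrected, path: str | Path) -> None:
    """Dump corrected curves in the long dialect (well, time, od)."""
    frames = []
    for cc in corrected:
        frames.append(
            pd.DataFrame(
                {"well": cc.source.well_id, "time": cc.source.times, "od": cc.od_adj}
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["well", "time", "od"]
    )
    out.to_csv(path, index=False)
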