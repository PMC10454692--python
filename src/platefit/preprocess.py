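"""Blank correction of raw OD600 curves.

For each medium in each experiment, the blank (uninoculated) wells are
averaged pointwise into a reference series. Every inoculated curve on that
medium is corrected in two fixed steps, in this order:

1. subtract the blank reference at each time point;
2. subtract the minimum of the resulting series (per curve).

Step 2 guarantees ``min(od_adj) == 0`` exactly and makes the correction
invariant to any constant offset in the raw signal. Intermediate values may
be negative after step 1 (a well dipping below its blank); they are never
clipped, because clipping would bias the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, MissingBlankError
from .io import TimeSeriesCurve

#: maximal time-grid discrepancy treated as "the same grid", in hours
GRID_TOL_H = 1e-6


@dataclass
class BlankReference:
    """Pointwise mean of the blank wells for one (medium, experiment)."""

    times: np.ndarray
    od: np.ndarray
    blank_ref_id: str
    n_wells: int


@dataclass
class CorrectedCurve:
    """A blank- and minimum-corrected curve; ``min(od_adj) == 0`` exactly."""

    source: TimeSeriesCurve
    od_adj: np.ndarray
    blank_ref_id: str
    min_subtracted: float

    @property
    def times(self) -> np.ndarray:
        return self.source.times

    def __len__(self) -> int:
        return self.od_adj.size


def _check_grid(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape or np.max(np.abs(a - b)) > GRID_TOL_H:
        raise AlignmentError(f"time grids differ for {what}")


def average_blanks(
    blank_curves: list[TimeSeriesCurve],
    condition: str | None = None,
    experiment_id: str | None = None,
) -> BlankReference:
    """Average blank wells for one medium and experiment into a reference.

    Raises :class:`MissingBlankError` when the collection is empty and
    :class:`AlignmentError` when the wells are not on a shared time grid.
    """
    if not blank_curves:
        raise MissingBlankError(condition or "?", experiment_id or "?")
    base = blank_curves[0]
    for c in blank_curves[1:]:
        _check_grid(base.times, c.times, f"blank wells {base.well_id}/{c.well_id}")
    od = np.mean([c.od for c in blank_curves], axis=0)
    cond = condition if condition is not None else base.layout.condition
    exp = experiment_id if experiment_id is not None else base.layout.experiment_id
    return BlankReference(
        times=base.times.copy(),
        od=od,
        blank_ref_id=f"{cond}@{exp}",
        n_wells=len(blank_curves),
    )


def correct_curve(curve: TimeSeriesCurve, blank_ref: BlankReference) -> CorrectedCurve:
    """Blank-subtract then minimum-subtract one curve.

    ``od_adj[i] = (od[i] - blank[i]) - min_j(od[j] - blank[j])``
    """
    _check_grid(curve.times, blank_ref.times, f"well {curve.well_id} vs blank")
    diff = curve.od - blank_ref.od
    m = float(np.min(diff))
    return CorrectedCurve(
        source=curve,
        od_adj=diff - m,
        blank_ref_id=blank_ref.blank_ref_id,
        min_subtracted=m,
    )


def correct_plate(
    curves: list[TimeSeriesCurve],
) -> tuple[list[CorrectedCurve], dict[tuple[str, str], BlankReference]]:
    """Correct all inoculated wells of a run against their matching blanks.

    Blanks are grouped by (condition, experiment); a medium with inoculated
    wells but no blanks raises :class:`MissingBlankError`.
    """
    blanks: dict[tuple[str, str], list[TimeSeriesCurve]] = {}
    for c in curves:
        if c.layout.is_blank:
            blanks.setdefault((c.layout.condition, c.layout.experiment_id), []).append(c)
    refs = {
        key: average_blanks(group, condition=key[0], experiment_id=key[1])
        for key, group in blanks.items()
    }
    corrected = []
    for c in curves:
        if c.layout.is_blank:
            continue
        key = (c.layout.condition, c.layout.experiment_id)
        if key not in refs:
            raise MissingBlankError(*key)
        corrected.append(correct_curve(c, refs[key]))
    return corrected, refs
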