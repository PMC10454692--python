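import numpy as np
import pytest

from platefit.io import LayoutEntry, PlateLayout, TimeSeriesCurve
from platefit.preprocess import CorrectedCurve


def make_entry(well_id="W1", strain="S", condition="control", experiment="E1",
               replicate=1, is_blank=False):
    return LayoutEntry(well_id, strain, condition, experiment, replicate, is_blank)


def make_curve(times, od, **entry_kwargs):
    entry = make_entry(**entry_kwargs)
    return TimeSeriesCurve(entry.well_id, entry, np.asarray(times, float),
                           np.asarray(od, float))


def make_corrected(times, od_adj, **entry_kwargs):
    """Wrap arrays as a CorrectedCurve without running the correction."""
    od_adj = np.asarray(od_adj, float)
    src = make_curve(times, od_adj, **entry_kwargs)
    return CorrectedCurve(source=src, od_adj=od_adj, blank_ref_id="test",
                          min_subtracted=0.0)


@pytest.fixture
def assay_times():
    """20-minute cadence over 16 h: the study's design grid (49 points)."""
    return np.arange(49) * (20.0 / 60.0)


@pytest.fixture
def simple_layout():
    entries = [
        make_entry("A1", condition="control", replicate=1),
        make_entry("A2", condition="control", replicate=2),
        make_entry("B1", condition="control", replicate=1, is_blank=True,
                   strain="medium-blank"),
    ]
    return PlateLayout(entries)
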