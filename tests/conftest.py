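"""Shared fixtures: handcrafted traces with enumerable structure and one
small synthetic cohort reused across pipeline tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from agingnoise.pipeline import CellTrace
from agingnoise.synthetic import generate_cohort, scenario_preset


def make_trace(
    cell_id: str,
    lifespan: int,
    intensity: float = 2000.0,
    gen_duration: float = 90.0,
    interval: float = 10.0,
    intensities=None,
    skip_snapshots=(),
) -> CellTrace:
    """Regular trace: divisions every gen_duration, snapshots every interval.

    With the defaults every generation carries 9 snapshots. skip_snapshots
    is a set of (generation, snapshot-within-generation) pairs to omit;
    intensities, when given, is a callable time -> value.
    """
    div = np.arange(lifespan + 1) * gen_duration
    times = []
    for g in range(1, lifespan + 1):
        n_per_gen = int(gen_duration / interval)
        for j in range(n_per_gen):
            if (g, j) in skip_snapshots:
                continue
            times.append(div[g - 1] + j * interval)
    times = np.array(times)
    vals = (
        np.full(times.size, float(intensity))
        if intensities is None
        else np.array([intensities(t) for t in times])
    )
    return CellTrace(
        cell_id=cell_id,
        times=times,
        frame_ids=(times / interval).astype(int),
        intensities=vals,
        division_times=div,
        background_subtracted=True,
    )


@pytest.fixture
def twelve_cell_cohort():
    """Hand-enumerable 12-cell cohort.

    Survivors of the ON + lifespan>=10 filters: 10 cells. Window counts
    after last-4-generation exclusion (windows need both generations, >=4
    snapshots each, >=8 total):
      c01 lifespan 23 -> generations 1-19 retained -> 9 windows
      c02 lifespan 10 -> generations 1-6 -> 3 windows
      c03 lifespan 9  -> excluded (short-lived)
      c04 lifespan 30, mean 500 -> excluded (OFF)
      c05 lifespan 10, generation 2 has only 3 snapshots -> windows 2,3 only
      c06..c12 lifespan 14 -> generations 1-10 -> 5 windows each
    Total windows: 9 + 3 + 2 + 7*5 = 49.
    """
    rng = np.random.default_rng(123)

    def noisy(base):
        return lambda t: base * (1 + 0.1 * rng.standard_normal())

    cells = [
        make_trace("c01", 23, intensities=noisy(2000.0)),
        make_trace("c02", 10, intensities=noisy(1500.0)),
        make_trace("c03", 9, intensities=noisy(1800.0)),
        make_trace("c04", 30, intensities=noisy(500.0)),
        make_trace(
            "c05", 10, intensities=noisy(1500.0),
            skip_snapshots={(2, j) for j in range(3, 9)},
        ),
    ]
    for i in range(6, 13):
        cells.append(make_trace(f"c{i:02d}", 14, intensities=noisy(1000.0 + 200 * i)))
    return cells


@pytest.fixture(scope="session")
def wt_cohort():
    """Small wild-type-like cohort shared by pipeline-level tests."""
    cfg = dataclasses.replace(scenario_preset("wt"), n_cells=25)
    return generate_cohort(cfg, seed=2024)
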