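import numpy as np
import pandas as pd
import pytest

from cvifkit.design import TimeGrid, assemble_design, canonical_hrf, make_regressor
from cvifkit.design import EventTable
from cvifkit.mid import CUEFEEDBACK, SATURATED, SATURATED_WITH_DERIVS
from cvifkit.mid import build_design, generate_mid_schedule
from cvifkit.simulate import SimulationStudy


def event_table(onsets, duration, name, run=0):
    return EventTable(
        pd.DataFrame(
            {
                "onset": onsets,
                "duration": [duration] * len(onsets),
                "trial_type": [name] * len(onsets),
                "run": [run] * len(onsets),
            }
        )
    )


@pytest.fixture(scope="session")
def toy_grid():
    """A 50 s single-run grid at the standard 0.8 s resolution."""
    return TimeGrid(run_lengths=(50.0,), dt=0.8, oversampling=50)


@pytest.fixture(scope="session")
def toy_kernel(toy_grid):
    return canonical_hrf(toy_grid.dt_micro)


@pytest.fixture(scope="session")
def adjacent_pair_design(toy_grid, toy_kernel):
    """Two conditions with 1 s events presented back to back: the classic
    high condition-signal-overlap situation."""
    onsets_a = [2.0, 12.0, 22.0, 32.0, 42.0]
    x_a = make_regressor(event_table(onsets_a, 1.0, "A"), toy_grid, "boxcar", toy_kernel)
    x_b = make_regressor(
        event_table([o + 1.0 for o in onsets_a], 1.0, "B"), toy_grid, "boxcar", toy_kernel
    )
    return assemble_design({"A": x_a, "B": x_b}, toy_grid)


@pytest.fixture(scope="session")
def mid_schedule():
    return generate_mid_schedule(seed=0)


@pytest.fixture(scope="session")
def saturated_design(mid_schedule):
    return build_design(mid_schedule, SATURATED)


@pytest.fixture(scope="session")
def cuefeedback_design(mid_schedule):
    return build_design(mid_schedule, CUEFEEDBACK)


@pytest.fixture(scope="session")
def saturated_derivs_design(mid_schedule):
    return build_design(mid_schedule, SATURATED_WITH_DERIVS)


@pytest.fixture(scope="session")
def small_study():
    """A reduced-size subject pool shared by the simulation test suites."""
    return SimulationStudy(48, seed=123)
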