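import dataclasses

import numpy as np
import pandas as pd
import pytest

from openwindow import SimulationConfig, table_marker_presets
from openwindow.engine import TALLY_COLUMNS, SimulationTrace


@pytest.fixture(scope="session")
def presets():
    return {s.marker: s for s in table_marker_presets()}


@pytest.fixture
def fast_config():
    """A short, small run for engine unit tests."""
    return SimulationConfig(ticks=40, grid_width=15, grid_height=15,
                            initial_cd4=30, initial_cd8=22, initial_apc=8,
                            initial_pathogen=10, seed=7)


def make_trace(total=None, cd4=None, cd8=None, pathogen=None):
    """Build a minimal SimulationTrace from explicit per-tick series."""
    series = [s for s in (total, cd4, cd8, pathogen) if s is not None]
    n = len(series[0])
    cd4 = np.asarray(cd4 if cd4 is not None else np.full(n, 10.0), float)
    cd8 = np.asarray(cd8 if cd8 is not None else np.full(n, 10.0), float)
    frame = pd.DataFrame(
        {
            "tick": np.arange(n),
            "cd4": cd4,
            "cd8": cd8,
            "apc": np.zeros(n),
            "pathogen": np.asarray(
                pathogen if pathogen is not None else np.zeros(n), float
            ),
            "cd4_cd8_ratio": np.divide(
                cd4, cd8, out=np.full(n, np.nan), where=cd8 != 0
            ),
            "total_immune": np.asarray(
                total if total is not None else cd4 + cd8, float
            ),
            "mean_energy": np.full(n, 5.0),
            "lactate": np.zeros(n),
            "total_glucose": np.full(n, 100.0),
        }
    )
    for col in TALLY_COLUMNS:
        frame[col] = 0
    return SimulationTrace(frame)


@pytest.fixture
def trace_factory():
    return make_trace
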