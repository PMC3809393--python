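import numpy as np
import pandas as pd
import pytest

from gamfoci.simulate import MicrocolonyTrace


def make_trace(n_foci: int, n_divisions: int, colony_id: str = "c",
               t_end: float = 10.0) -> MicrocolonyTrace:
    """Minimal valid trace with the given final counts (linear accrual)."""
    times = np.linspace(0.0, t_end, 11)
    cum_div = np.round(np.linspace(0, n_divisions, 11)).astype(int)
    cum_foc = np.round(np.linspace(0, n_foci, 11)).astype(int)
    frames = pd.DataFrame(
        {
            "time_h": times,
            "n_cells": 1 + cum_div,
            "cum_divisions": cum_div,
            "cum_foci": cum_foc,
        }
    )
    events = pd.DataFrame(columns=["time_h", "kind", "cell_id"])
    return MicrocolonyTrace(colony_id=colony_id, frames=frames, events=events)


@pytest.fixture
def hand_traces():
    """Six colonies: three with 1 focus / 100 divisions, three with 2/100."""
    return [
        make_trace(1, 100, "a"), make_trace(1, 100, "b"), make_trace(1, 100, "c"),
        make_trace(2, 100, "d"), make_trace(2, 100, "e"), make_trace(2, 100, "f"),
    ]
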