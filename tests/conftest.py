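import numpy as np
import pandas as pd
import pytest

from loadresponse import SimulationConfig, simulate_change_values


@pytest.fixture
def clinical_changes() -> pd.DataFrame:
    """One 24-subject change table from the clinical-interest scenario."""
    return simulate_change_values(SimulationConfig(seed=0))


@pytest.fixture
def small_panel() -> pd.DataFrame:
    """Hand-built duplicate panel: 2 subjects x 2 markers x 1 load, t0/t1."""
    rows = []
    values = {
        (1, "COMP", "t0"): (98.0, 102.0),
        (1, "COMP", "t1"): (120.0, 124.0),
        (2, "COMP", "t0"): (50.0, 50.0),
        (2, "COMP", "t1"): (60.0, 62.0),
        (1, "IL-6", "t0"): (4.0, 5.0),
        (1, "IL-6", "t1"): (7.0, 7.0),
        (2, "IL-6", "t0"): (10.0, 30.0),
        (2, "IL-6", "t1"): (20.0, 20.0),
    }
    for (sid, marker, tp), (r1, r2) in values.items():
        for rep, v in ((1, r1), (2, r2)):
            rows.append((sid, marker, 100, 0, tp, rep, v, False))
    return pd.DataFrame(rows, columns=[
        "subject_id", "marker", "load_pct", "load_code", "timepoint",
        "replicate", "concentration", "out_of_range"])


def make_change_table(deltas: dict, marker: str = "M", timepoint: str = "t1",
                      scale: str = "relative") -> pd.DataFrame:
    """Change table from {subject: (delta at loads -1, 0, +1)}."""
    rows = []
    for sid, triple in deltas.items():
        for load, d in zip((-1, 0, 1), triple):
            rows.append((sid, marker, load, timepoint, float(d), scale))
    return pd.DataFrame(rows, columns=[
        "subject_id", "marker", "load_code", "timepoint", "delta", "scale"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
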