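"""Shared fixtures: small simulated experiments and trace builders."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from flysleep.dams_io import ActivityTrace
from flysleep.synthetic_data import SimulationConfig, simulate_experiment


def trace_from_counts(
    counts, condition: str = "fed", start_zt: float = 0.0, fly_id: str = "T:01"
) -> ActivityTrace:
    """Build a minimal annotated trace directly from a counts array (no
    file round-trip), for oracle and arithmetic tests."""
    counts = np.asarray(counts, dtype=int)
    n = len(counts)
    zt = (start_zt + np.arange(n) / 60.0) % 24.0
    minutes = pd.DataFrame(
        {
            "datetime": [datetime(2012, 6, 4, 10, 0) + timedelta(minutes=i) for i in range(n)],
            "beam_breaks": counts,
            "zt": zt,
            "phase": np.where(zt < 12.0, "day", "night"),
            "condition": condition,
        }
    )
    return ActivityTrace(fly_id, "L1", "ME", "F", 25.0, minutes)


def brute_force_bouts(counts, min_bout: int = 5) -> list[tuple[int, int]]:
    """Independent oracle: scan every maximal zero run by walking the
    sequence one minute at a time."""
    bouts = []
    start = None
    for i, c in enumerate(list(counts) + [1]):  # sentinel wake minute
        if c == 0:
            if start is None:
                start = i
        else:
            if start is not None:
                if i - start >= min_bout:
                    bouts.append((start, i - start))
                start = None
    return bouts


SMALL_SIM = dict(
    lines_per_population=2,
    flies_per_line=3,
    vials_per_line=3,
    replicates_per_line=2,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(**SMALL_SIM)


@pytest.fixture(scope="session")
def small_experiment(small_config, tmp_path_factory):
    """One small simulated experiment written to disk (shared read-only)."""
    out = tmp_path_factory.mktemp("smallsim")
    ledger = simulate_experiment(small_config, seed=11, out_dir=out)
    return {"dir": out, "ledger": ledger, "config": small_config}
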