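"""Sleep-bout scoring and sleep/activity phenotypes.

Fly sleep is scored behaviorally: a sleep bout is a maximal run of at
least ``min_bout`` (default 5) consecutive minutes with zero beam breaks,
the standard definition for activity-monitor data.  From the bouts we
derive the phenotypes analyzed downstream — total sleep as a percentage
of the period, bout number, mean bout length, mean beam breaks per awake
minute, and the within-fly percent change in sleep between fed and
starved conditions (negative = sleep suppression by starvation).

Bouts spanning the day/night boundary are split at the boundary for
phase-level sleep minutes (so day + night minutes always sum to the
whole-window total) but counted once, at their start phase, for
phase-level bout numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from flysleep.dams_io import ActivityTrace

MIN_BOUT_DEFAULT = 5


@dataclass(frozen=True)
class SleepBout:
    """A maximal zero-activity run of length >= min_bout minutes."""

    start: int          # index into the window's minute sequence
    length: int         # minutes
    phase_at_start: str
    condition: str


@dataclass(frozen=True)
class SleepSummary:
    fly_id: str
    condition: str
    period: str                    # "whole" | "day" | "night"
    n_minutes: int
    sleep_minutes: int
    total_sleep_pct: float
    bout_number: int
    mean_bout_length: float        # NaN when bout_number == 0
    mean_awake_movement: float     # NaN when no awake minutes


def _window(trace: ActivityTrace, condition: str) -> pd.DataFrame:
    win = trace.minutes[trace.minutes["condition"] == condition]
    if win.empty:
        raise ValueError(f"trace {trace.fly_id} has no {condition!r} minutes")
    return win.reset_index(drop=True)


def _zero_runs(breaks: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of every maximal run of zeros, vectorized."""
    zero = np.concatenate(([0], (breaks == 0).astype(np.int8), [0]))
    d = np.diff(zero)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def score_sleep(
    trace: ActivityTrace,
    condition: str = "fed",
    min_bout: int = MIN_BOUT_DEFAULT,
) -> list[SleepBout]:
    """Score sleep bouts within one condition window of a trace.

    Returns exactly the maximal runs of consecutive zero-count minutes
    with run length >= ``min_bout``, clipped to the window.  A window
    shorter than ``min_bout`` yields an empty result with a warning.
    """
    win = _window(trace, condition)
    if len(win) < min_bout:
        warnings.warn(
            f"window {condition!r} of {trace.fly_id} is shorter than "
            f"min_bout={min_bout}; no bouts scored",
            stacklevel=2,
        )
        return []
    breaks = win["beam_breaks"].to_numpy()
    phases = win["phase"].to_numpy()
    return [
        SleepBout(start, length, str(phases[start]), condition)
        for start, length in _zero_runs(breaks)
        if length >= min_bout
    ]


def _sleep_mask(n: int, bouts: list[SleepBout]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for b in bouts:
        mask[b.start : b.start + b.length] = True
    return mask


def summarize_sleep(
    trace: ActivityTrace,
    bouts: list[SleepBout],
    condition: str = "fed",
    period: str = "whole",
) -> SleepSummary:
    """Summarize one (condition, period) cell for one fly.

    ``period`` restricts the summary to day (ZT in [0, 12)) or night
    minutes; bouts crossing the boundary contribute their within-period
    minutes but are counted (as a bout) only in the period of their start.
    Total sleep is the percentage of period minutes spent in a bout; mean
    awake movement is beam breaks per non-bout minute (NaN if the fly
    never woke).
    """
    win = _window(trace, condition)
    asleep = _sleep_mask(len(win), bouts)
    if period == "whole":
        in_period = np.ones(len(win), dtype=bool)
    elif period in ("day", "night"):
        in_period = (win["phase"] == period).to_numpy()
    else:
        raise ValueError(f"unknown period {period!r}")

    n_minutes = int(in_period.sum())
    sleep_minutes = int((asleep & in_period).sum())
    bout_number = sum(
        1 for b in bouts if period == "whole" or b.phase_at_start == period
    )
    mean_bout_length = (
        sleep_minutes / bout_number if bout_number > 0 else float("nan")
    )
    awake = in_period & ~asleep
    n_awake = int(awake.sum())
    mean_awake_movement = (
        float(win.loc[awake, "beam_breaks"].sum() / n_awake)
        if n_awake > 0
        else float("nan")
    )
    return SleepSummary(
        fly_id=trace.fly_id,
        condition=condition,
        period=period,
        n_minutes=n_minutes,
        sleep_minutes=sleep_minutes,
        total_sleep_pct=100.0 * sleep_minutes / n_minutes,
        bout_number=bout_number,
        mean_bout_length=mean_bout_length,
        mean_awake_movement=mean_awake_movement,
    )


def percent_change_sleep(fed_pct: float, starved_pct: float) -> float:
    """Within-fly percent change in sleep, 100*(starved-fed)/fed.

    Undefined (ValueError) when the fly slept zero minutes while fed; such
    flies are excluded upstream with a logged reason.
    """
    if fed_pct <= 0:
        raise ValueError("percent change undefined: fed sleep is zero")
    return 100.0 * (starved_pct - fed_pct) / fed_pct


def summarize_fly(
    trace: ActivityTrace, min_bout: int = MIN_BOUT_DEFAULT
) -> pd.DataFrame:
    """All (condition, period) summaries for one fly, plus percent change.

    Returns a tidy frame with one row per (condition in {fed, starved},
    period in {whole, day, night}) and a ``pct_change_sleep`` column
    populated on the starved/whole row (NaN if fed sleep was zero).
    """
    rows = []
    pct: dict[str, float] = {}
    for condition in ("fed", "starved"):
        bouts = score_sleep(trace, condition, min_bout)
        for period in ("whole", "day", "night"):
            s = summarize_sleep(trace, bouts, condition, period)
            rows.append(s.__dict__.copy())
            if period == "whole":
                pct[condition] = s.total_sleep_pct
    out = pd.DataFrame(rows)
    out["line"] = trace.line_id
    out["population"] = trace.population
    out["sex"] = trace.sex
    out["temperature"] = trace.temperature
    out["pct_change_sleep"] = np.nan
    if pct["fed"] > 0:
        mask = (out["condition"] == "starved") & (out["period"] == "whole")
        out.loc[mask, "pct_change_sleep"] = percent_change_sleep(
            pct["fed"], pct["starved"]
        )
    return out


def summarize_flies(
    traces, min_bout: int = MIN_BOUT_DEFAULT
) -> pd.DataFrame:
    """Per-fly summaries for a collection of traces (tidy, concatenated)."""
    return pd.concat(
        [summarize_fly(t, min_bout) for t in traces], ignore_index=True
    )


def aggregate_lines(per_fly: pd.DataFrame) -> pd.DataFrame:
    """Line-level means +/- SE of every sleep phenotype.

    Input is the output of :func:`summarize_flies`; the result has one row
    per line x sex x temperature x condition x period, shaped like the
    published supplemental phenotype tables.
    """
    keys = ["population", "line", "sex", "temperature", "condition", "period"]
    vals = [
        "total_sleep_pct",
        "mean_bout_length",
        "bout_number",
        "mean_awake_movement",
        "pct_change_sleep",
    ]
    g = per_fly.groupby(keys, dropna=False)[vals]
    mean = g.mean()
    se = g.sem()
    out = mean.join(se, lsuffix="", rsuffix="_se").reset_index()
    out["n_flies"] = g.size().to_numpy()
    return out


def hourly_profile(traces, condition: str = "fed", min_bout: int = MIN_BOUT_DEFAULT) -> pd.DataFrame:
    """Mean minutes asleep per ZT hour (and SE over flies) for a group.

    For the starved window hours are indexed from the starvation start
    (hour 0 = first starved hour) rather than from lights-on, matching how
    starvation time courses are plotted.  Requires >= 2 flies.
    """
    traces = list(traces)
    if len(traces) < 2:
        raise ValueError(
            f"hourly profile needs >=2 flies, got {len(traces)}"
        )
    per_fly_hour = []
    for t in traces:
        win = _window(t, condition)
        bouts = score_sleep(t, condition, min_bout)
        asleep = _sleep_mask(len(win), bouts)
        hour_idx = np.arange(len(win)) // 60
        minutes_asleep = pd.Series(asleep.astype(int)).groupby(hour_idx).sum()
        per_fly_hour.append(minutes_asleep)
    mat = pd.DataFrame(per_fly_hour)
    return pd.DataFrame(
        {
            "hour": mat.columns.to_numpy(),
            "mean_sleep_min": mat.mean(axis=0).to_numpy(),
            "se_sleep_min": mat.std(axis=0, ddof=1).to_numpy() / np.sqrt(len(mat)),
            "n_flies": len(mat),
        }
    )
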