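"""Reading TriKinetics Drosophila Activity Monitor (DAM) files and
annotating per-minute beam-break traces with experimental protocol.

A DAM monitor records, once per minute, the number of infrared beam breaks
for each of its 32 channels (one fly per channel).  The on-disk format is a
tab-separated table: reading index, date, time, a status code, six
reserved/diagnostic columns (the last of which is the light sensor), then
the 32 channel counts — 42 columns in total (the classic DAM2 layout).

Annotation converts wall-clock time into Zeitgeber time (ZT: hours since
lights-on; ZT 0–12 is the light phase under a 12:12 LD cycle) and labels
each minute with the feeding condition implied by the protocol:
``acclimation`` days, ``fed`` baseline days, a 24 h ``starved`` window
beginning at the configured clock time (ZH3 when lights-on is 10:00 and
starvation starts at 13:00), and ``excluded`` for minutes outside all
three windows (e.g. the transfer gap between baseline end and starvation
start).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_CHANNELS = 32
DAM2_COLUMNS = 42  # index, date, time, status, 6 reserved (incl. light), 32 counts
_DATE_FMT = "%d %b %y"
_TIME_FMT = "%H:%M:%S"


class MonitorFormatError(ValueError):
    """A monitor file violates the expected tab-separated layout."""


class ProtocolCoverageError(ValueError):
    """The recording ends before the protocol windows are complete."""


@dataclass(frozen=True)
class MonitorReading:
    """One row of a monitor file: a per-minute snapshot of all 32 channels."""

    reading_index: int
    timestamp: datetime
    status_code: int
    light_sensor: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != N_CHANNELS:
            raise ValueError(
                f"expected {N_CHANNELS} channel counts, got {len(self.counts)}"
            )


@dataclass(frozen=True)
class ExperimentProtocol:
    """Timing of the acclimation / baseline / starvation design.

    Defaults reproduce the study design: lights on at 10:00 local time
    (ZH0), 2 acclimation days, 2 fed baseline days, then a 24 h starvation
    window initiated at 13:00 (ZH3) on the following day.
    """

    lights_on: time = time(10, 0)
    acclimation_days: int = 2
    baseline_days: int = 2
    starvation_start: time = time(13, 0)
    starvation_hours: float = 24.0

    def windows(self, first_timestamp: datetime) -> dict[str, tuple[datetime, datetime]]:
        """Absolute [start, end) windows anchored at the first lights-on
        at or before the first reading."""
        anchor = datetime.combine(first_timestamp.date(), self.lights_on)
        if anchor > first_timestamp:
            anchor -= timedelta(days=1)
        accl_end = anchor + timedelta(days=self.acclimation_days)
        base_end = accl_end + timedelta(days=self.baseline_days)
        starve_start = datetime.combine(base_end.date(), self.starvation_start)
        if starve_start < base_end:
            starve_start += timedelta(days=1)
        starve_end = starve_start + timedelta(hours=self.starvation_hours)
        return {
            "acclimation": (anchor, accl_end),
            "fed": (accl_end, base_end),
            "starved": (starve_start, starve_end),
        }


@dataclass
class ActivityTrace:
    """Per-fly annotated minute series.

    ``minutes`` columns: ``datetime``, ``zt`` (hours in [0, 24)), ``phase``
    ("day"/"night"), ``condition`` ("acclimation" | "fed" | "starved" |
    "excluded"), ``beam_breaks``.
    """

    fly_id: str
    line_id: str
    population: str
    sex: str
    temperature: float
    minutes: pd.DataFrame = field(repr=False)

    def window(self, condition: str) -> pd.DataFrame:
        return self.minutes[self.minutes["condition"] == condition]


@dataclass(frozen=True)
class QCVerdict:
    fly_id: str
    flagged: bool
    terminal_quiet_minutes: int
    death_time_estimate: datetime | None


def read_monitor_file(path: str | Path, dialect: str = "dam2") -> list[MonitorReading]:
    """Parse a monitor text file into :class:`MonitorReading` rows.

    Only the 42-column DAM2-style dialect is implemented; the channel
    counts are taken from the final 32 columns.  Raises
    :class:`MonitorFormatError` naming the first malformed row.
    """
    if dialect != "dam2":
        raise ValueError(f"unsupported monitor dialect: {dialect!r}")
    path = Path(path)
    readings: list[MonitorReading] = []
    prev_ts: datetime | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != DAM2_COLUMNS:
                raise MonitorFormatError(
                    f"{path.name}: row {lineno} has {len(parts)} columns, "
                    f"expected {DAM2_COLUMNS}"
                )
            try:
                idx = int(parts[0])
                ts = datetime.strptime(f"{parts[1]} {parts[2]}", f"{_DATE_FMT} {_TIME_FMT}")
                status = int(parts[3])
                light = int(parts[9])
                counts = tuple(int(c) for c in parts[-N_CHANNELS:])
            except ValueError as exc:
                raise MonitorFormatError(f"{path.name}: row {lineno}: {exc}") from exc
            if any(c < 0 for c in counts):
                raise MonitorFormatError(f"{path.name}: row {lineno}: negative count")
            if prev_ts is not None and ts <= prev_ts:
                raise MonitorFormatError(
                    f"{path.name}: row {lineno}: timestamps not strictly increasing"
                )
            prev_ts = ts
            readings.append(MonitorReading(idx, ts, status, light, counts))
    return readings


def write_monitor_file(readings: Iterable[MonitorReading], path: str | Path) -> None:
    """Write readings back to the 42-column DAM2 text layout (round-trip
    inverse of :func:`read_monitor_file`)."""
    with open(path, "w") as fh:
        for r in readings:
            row = [
                str(r.reading_index),
                r.timestamp.strftime(_DATE_FMT),
                r.timestamp.strftime(_TIME_FMT),
                str(r.status_code),
                "0", "0", "0", "0", "0",
                str(r.light_sensor),
                *[str(c) for c in r.counts],
            ]
            fh.write("\t".join(row) + "\n")


def _resample_to_minutes(frame: pd.DataFrame) -> pd.DataFrame:
    """Sum sub-minute bins into 1-minute bins; all downstream metrics are
    defined per minute."""
    frame = frame.set_index("datetime")
    out = frame.resample("1min").sum()
    return out.reset_index()


def annotate_trace(
    readings: Sequence[MonitorReading],
    channel: int,
    metadata: dict,
    protocol: ExperimentProtocol | None = None,
) -> ActivityTrace:
    """Extract one channel and label every minute with ZT, light phase and
    feeding condition.

    ``metadata`` must provide ``line``, ``population``, ``sex``,
    ``temperature`` and may provide ``monitor`` (used in the fly id).
    Raises :class:`ProtocolCoverageError` if the recording ends before the
    starvation window does.
    """
    if not 1 <= channel <= N_CHANNELS:
        raise ValueError(f"channel must be 1..{N_CHANNELS}, got {channel}")
    if protocol is None:
        protocol = ExperimentProtocol()
    if not readings:
        raise ValueError("no readings")

    frame = pd.DataFrame(
        {
            "datetime": [r.timestamp for r in readings],
            "beam_breaks": [r.counts[channel - 1] for r in readings],
        }
    )
    step = frame["datetime"].diff().dropna()
    if len(step) and step.min() < timedelta(minutes=1):
        frame = _resample_to_minutes(frame)

    windows = protocol.windows(frame["datetime"].iloc[0])
    if frame["datetime"].iloc[-1] < windows["starved"][1] - timedelta(minutes=1):
        raise ProtocolCoverageError(
            "recording ends at "
            f"{frame['datetime'].iloc[-1]} before starvation window end "
            f"{windows['starved'][1]}"
        )

    anchor = windows["acclimation"][0]
    elapsed_h = (frame["datetime"] - anchor) / pd.Timedelta(hours=1)
    frame["zt"] = elapsed_h.to_numpy() % 24.0
    frame["phase"] = np.where(frame["zt"] < 12.0, "day", "night")

    condition = np.full(len(frame), "excluded", dtype=object)
    for label, (start, end) in windows.items():
        mask = (frame["datetime"] >= start) & (frame["datetime"] < end)
        condition[mask.to_numpy()] = label
    frame["condition"] = condition

    monitor = metadata.get("monitor", "M1")
    return ActivityTrace(
        fly_id=f"{monitor}:{channel:02d}",
        line_id=str(metadata["line"]),
        population=str(metadata["population"]),
        sex=str(metadata["sex"]),
        temperature=float(metadata["temperature"]),
        minutes=frame,
    )


def flag_dead_or_escaped(
    trace: ActivityTrace, terminal_quiet_hours: float = 12.0
) -> tuple[QCVerdict, ActivityTrace]:
    """Flag flies whose trace ends in a long run of zero activity.

    A fly whose final contiguous zero-activity run is at least
    ``terminal_quiet_hours`` is presumed dead or escaped; flagged flies
    should be excluded from fed-period summaries.  The start of the
    terminal zero run doubles as a death-time estimate during starvation
    (a cross-check only — LD50 comes from vial censuses, not from traces).
    Returns the verdict and the trace truncated at the estimated death.
    """
    breaks = trace.minutes["beam_breaks"].to_numpy()
    n = len(breaks)
    nonzero = np.flatnonzero(breaks)
    run = n if len(nonzero) == 0 else n - 1 - nonzero[-1]
    flagged = run >= terminal_quiet_hours * 60
    death_time = None
    truncated = trace
    if flagged and run > 0:
        start_idx = n - run
        death_time = trace.minutes["datetime"].iloc[start_idx]
        truncated = ActivityTrace(
            trace.fly_id,
            trace.line_id,
            trace.population,
            trace.sex,
            trace.temperature,
            trace.minutes.iloc[:start_idx].reset_index(drop=True),
        )
    return QCVerdict(trace.fly_id, bool(flagged), int(run), death_time), truncated


def read_channel_metadata(path: str | Path) -> pd.DataFrame:
    """Read the channel→fly metadata CSV (monitor, channel, line,
    population, sex, temperature)."""
    meta = pd.read_csv(path)
    required = {"monitor", "channel", "line", "population", "sex", "temperature"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return meta


def traces_to_tidy(traces: Iterable[ActivityTrace]) -> pd.DataFrame:
    """Concatenate traces into one tidy per-minute table."""
    frames = []
    for t in traces:
        f = t.minutes.copy()
        f.insert(0, "fly_id", t.fly_id)
        f["line"] = t.line_id
        f["population"] = t.population
        f["sex"] = t.sex
        f["temperature"] = t.temperature
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
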