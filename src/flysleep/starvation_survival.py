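"""Starvation resistance (LD50) from vial survival censuses.

Starvation resistance is the time, in hours on agar-only medium, at which
half the flies in a vial are dead.  Vials start with 10 flies and are
censused a few times per day (3x at 21 °C, 6x at 25 °C).  The default
estimator interpolates linearly between the two censuses bracketing the
half-death point and takes the earliest crossing; a step-function
alternative (the last census before the crossing) is available for
sensitivity checks.  Vials whose survivors never fall to half by the last
census are right-censored and excluded from line-level means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CensusError(ValueError):
    """A survival census violates its invariants (e.g. survivors increase)."""


@dataclass(frozen=True)
class SurvivalCensus:
    """Survivor counts over time for one vial of (nominally) 10 flies."""

    vial_id: str
    line_id: str
    population: str
    sex: str
    temperature: float
    initial_count: int
    observations: tuple[tuple[float, int], ...]  # (elapsed_hours, survivors)

    def validate(self) -> None:
        hours = [h for h, _ in self.observations]
        counts = [s for _, s in self.observations]
        if not self.observations:
            raise CensusError(f"vial {self.vial_id}: no observations")
        if hours[0] != 0 or counts[0] != self.initial_count:
            raise CensusError(
                f"vial {self.vial_id}: first observation must be "
                f"(0 h, {self.initial_count})"
            )
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise CensusError(f"vial {self.vial_id}: census times not increasing")
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise CensusError(f"vial {self.vial_id}: survivor count increases")
        if any(c < 0 or c > self.initial_count for c in counts):
            raise CensusError(f"vial {self.vial_id}: survivors out of range")


@dataclass(frozen=True)
class LD50Estimate:
    vial_id: str
    ld50_hours: float
    censored: bool
    method: str  # "interpolated" | "step"


@dataclass(frozen=True)
class LineLD50:
    line_id: str
    mean_ld50: float
    median_ld50: float
    se_ld50: float
    n_vials: int
    n_censored: int
    factors: dict = field(default_factory=dict)


def vial_ld50(census: SurvivalCensus, method: str = "interpolated") -> LD50Estimate:
    """Hours until half the vial is dead.

    ``interpolated`` (default) treats the survival curve as piecewise
    linear between censuses and returns the earliest time it equals
    ``initial_count / 2``; an exact-half count at a census time yields that
    census time.  ``step`` returns the first census time at which
    survivors <= half.  Vials never reaching half are censored at the last
    census.
    """
    census.validate()
    half = census.initial_count / 2.0
    hours = np.array([h for h, _ in census.observations], dtype=float)
    surv = np.array([s for _, s in census.observations], dtype=float)

    below = np.flatnonzero(surv <= half)
    if len(below) == 0:
        return LD50Estimate(census.vial_id, float(hours[-1]), True, method)
    i = below[0]
    if method == "step" or surv[i] == half or i == 0:
        return LD50Estimate(census.vial_id, float(hours[i]), False, method)
    if method != "interpolated":
        raise ValueError(f"unknown LD50 method {method!r}")
    # linear crossing between censuses i-1 (above half) and i (below half)
    t = hours[i - 1] + (surv[i - 1] - half) / (surv[i - 1] - surv[i]) * (
        hours[i] - hours[i - 1]
    )
    return LD50Estimate(census.vial_id, float(t), False, method)


def line_ld50(
    estimates: list[LD50Estimate],
    line_id: str,
    factors: dict | None = None,
    min_uncensored: int = 2,
) -> LineLD50:
    """Mean and median LD50 over a line's vials (censored vials dropped).

    Downstream models consume the mean; the median is reported alongside
    (the two are near-identical for approximately symmetric death-time
    distributions).  Raises if fewer than ``min_uncensored`` vials crossed
    the half-death point.
    """
    values = np.array([e.ld50_hours for e in estimates if not e.censored])
    n_censored = sum(e.censored for e in estimates)
    if len(values) < min_uncensored:
        raise CensusError(
            f"line {line_id}: only {len(values)} uncensored vials "
            f"({n_censored} censored); excluded from models"
        )
    return LineLD50(
        line_id=line_id,
        mean_ld50=float(values.mean()),
        median_ld50=float(np.median(values)),
        se_ld50=float(values.std(ddof=1) / np.sqrt(len(values))),
        n_vials=len(values),
        n_censored=int(n_censored),
        factors=factors or {},
    )


def censuses_from_frame(table: pd.DataFrame) -> list[SurvivalCensus]:
    """Build censuses from a tidy CSV table (vial_id, line, population,
    sex, temperature, initial_count, elapsed_hours, survivors)."""
    out = []
    keys = ["vial_id", "line", "population", "sex", "temperature"]
    for (vial, line, pop, sex, temp), grp in table.groupby(keys, sort=False):
        grp = grp.sort_values("elapsed_hours")
        initial = int(grp["initial_count"].iloc[0]) if "initial_count" in grp else int(
            grp["survivors"].iloc[0]
        )
        obs = tuple(
            (float(h), int(s))
            for h, s in zip(grp["elapsed_hours"], grp["survivors"])
        )
        out.append(
            SurvivalCensus(str(vial), str(line), str(pop), str(sex), float(temp), initial, obs)
        )
    return out


def ld50_table(
    censuses: list[SurvivalCensus], method: str = "interpolated"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vial- and line-level LD50 tables from a list of censuses.

    The line table has one row per line x sex x temperature (mean, median,
    SE, vial counts); lines with <2 uncensored vials in a cell are dropped
    with their reason recorded in the ``excluded`` attribute of the frame.
    """
    vial_rows = []
    for c in censuses:
        est = vial_ld50(c, method)
        vial_rows.append(
            {
                "vial_id": c.vial_id,
                "line": c.line_id,
                "population": c.population,
                "sex": c.sex,
                "temperature": c.temperature,
                "ld50_hours": est.ld50_hours,
                "censored": est.censored,
            }
        )
    vials = pd.DataFrame(vial_rows)

    line_rows, excluded = [], []
    for (line, pop, sex, temp), grp in vials.groupby(
        ["line", "population", "sex", "temperature"], sort=False
    ):
        ests = [
            LD50Estimate(r.vial_id, r.ld50_hours, r.censored, method)
            for r in grp.itertuples()
        ]
        try:
            ll = line_ld50(ests, line)
        except CensusError as exc:
            excluded.append(str(exc))
            continue
        line_rows.append(
            {
                "line": line,
                "population": pop,
                "sex": sex,
                "temperature": temp,
                "mean_ld50": ll.mean_ld50,
                "median_ld50": ll.median_ld50,
                "se_ld50": ll.se_ld50,
                "n_vials": ll.n_vials,
                "n_censored": ll.n_censored,
            }
        )
    lines = pd.DataFrame(line_rows)
    lines.attrs["excluded"] = excluded
    return vials, lines
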