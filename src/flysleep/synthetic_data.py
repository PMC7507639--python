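"""Synthetic two-population fly experiments with a ground-truth ledger.

Generates complete raw datasets — activity-monitor files, starvation
survival censuses and metabolic assay plates — for the full factorial
design: 2 populations (temperate ME, tropical PC) x 10 isofemale lines x
2 sexes x 2 temperatures (21 °C, 25 °C), under a 12:12 light:dark cycle
with 2 acclimation days, 2 fed baseline days and a 24 h starvation window
beginning at ZH3.

Per-fly activity is a two-state semi-Markov chain over minutes: awake
minutes emit zero-truncated Poisson beam breaks (so quiet wakefulness is
never mistaken for sleep under the >=5 min zero-activity rule, a
deliberate simulator simplification), sleep is entered with a
phase-specific per-minute hazard, and bout lengths are shifted-geometric
with a configurable mean and a 5 min floor.  Starvation multiplies bout
length (down) and awake activity (up) while leaving the bout-initiation
hazard untouched, so bout number is unaffected by starvation — the
qualitative structure reported for these populations (PC sleeps more at
night through longer bouts; ME moves more when awake).

Line-level starvation resistance can be coupled to line-level sleep under
starvation through a bivariate-normal correlation ``rho`` set per
population (PC positive, ME zero by default), which is what the
per-population sleep-vs-LD50 regressions downstream are designed to
detect.

Every generator returns a ground-truth ledger holding the true
parameters and realized per-fly/per-line values, so pipeline outputs can
be checked against what was actually simulated.  Identical seed and
config give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from flysleep.dams_io import (
    N_CHANNELS,
    ExperimentProtocol,
    MonitorReading,
    write_monitor_file,
)

DAY_MINUTES = 720
FULL_DAY = 1440
MIN_BOUT = 5


@dataclass(frozen=True)
class PopulationSleepModel:
    """Per-population semi-Markov sleep parameters (per-minute rates)."""

    hazard_day: float        # wake->sleep probability per awake day minute
    hazard_night: float
    mean_bout_day: float     # minutes; must exceed the 5 min floor
    mean_bout_night: float
    activity_rate: float     # Poisson mean beam breaks per awake minute


@dataclass(frozen=True)
class SimulationConfig:
    """The simulated world.  Defaults encode the study design itself
    (populations, line counts, fly numbers, census schedules) and
    field-realistic rates for everything the design leaves open."""

    populations: tuple[str, ...] = ("ME", "PC")
    lines_per_population: int = 10
    sexes: tuple[str, ...] = ("F", "M")
    temperatures: tuple[float, ...] = (21.0, 25.0)
    flies_per_line: int = 24          # per line x sex x temperature (20-32 assayed)

    sleep: dict = field(
        default_factory=lambda: {
            "ME": PopulationSleepModel(0.040, 0.080, 15.0, 25.0, 2.5),
            "PC": PopulationSleepModel(0.040, 0.080, 15.0, 45.0, 1.5),
        }
    )
    line_bout_sd: float = 0.15        # log-normal sd of line effect on bout means
    line_hazard_sd: float = 0.10      # log-normal sd of line effect on hazards
    starved_bout_multiplier: float = 0.6
    starved_activity_multiplier: float = 1.3

    # survival model (hours)
    base_death_mean: float = 25.0     # PC male at 25 deg C
    me_offset: float = 15.0
    female_offset: float = 10.0
    temp21_offset: float = 8.0
    line_death_sd: float = 4.0
    vial_death_sd: float = 1.5
    fly_death_sd: float = 3.0
    rho: dict = field(default_factory=lambda: {"ME": 0.0, "PC": 0.9})
    vials_per_line: int = 6
    flies_per_vial: int = 10
    censuses_per_day: dict = field(default_factory=lambda: {21.0: 3, 25.0: 6})

    # metabolite model (mg analyte per mg protein)
    glucose_mean: dict = field(default_factory=lambda: {"ME": 0.15, "PC": 0.20})
    tga_mean: dict = field(default_factory=lambda: {"ME": 0.30, "PC": 0.22})
    cantons_glucose: float = 0.18
    cantons_tga: float = 0.25
    akhr_tga_ratio: float = 3.0       # elevated TGA, control contract
    akhr_glucose_ratio: float = 1.0   # similar glucose, control contract
    protein_mean_mg: float = 0.5
    well_cv: float = 0.15
    line_metabolite_sd: float = 0.10  # log scale
    plate_effect_sd: float = 0.25     # log scale, multiplicative on analyte
    replicates_per_line: int = 4
    control_wells: int = 4
    lines_per_plate: int = 10

    protocol: ExperimentProtocol = field(default_factory=ExperimentProtocol)

    def validate(self) -> None:
        for pop, m in self.sleep.items():
            if not (0 <= m.hazard_day <= 1 and 0 <= m.hazard_night <= 1):
                raise ValueError(f"{pop}: hazards must be probabilities")
            if min(m.mean_bout_day, m.mean_bout_night) <= MIN_BOUT:
                raise ValueError(f"{pop}: mean bout length must exceed {MIN_BOUT} min")
            if m.activity_rate < 0:
                raise ValueError(f"{pop}: activity rate must be >= 0")
        if self.starved_bout_multiplier <= 0 or self.starved_activity_multiplier <= 0:
            raise ValueError("starvation multipliers must be positive")
        for pop, r in self.rho.items():
            if abs(r) > 1:
                raise ValueError(f"{pop}: |rho| must be <= 1")

    def design_cells(self):
        for pop in self.populations:
            for li in range(self.lines_per_population):
                line = f"{pop}{li + 1:02d}"
                for sex in self.sexes:
                    for temp in self.temperatures:
                        yield pop, line, sex, temp


# ---------------------------------------------------------------------------
# activity


def _total_minutes(protocol: ExperimentProtocol) -> tuple[int, int, int]:
    """(total, starvation-start, starvation-end) in minutes from first
    lights-on; assumes the 12:12 design."""
    accl = protocol.acclimation_days * FULL_DAY
    base = protocol.baseline_days * FULL_DAY
    lights_on_min = protocol.lights_on.hour * 60 + protocol.lights_on.minute
    starve_clock = protocol.starvation_start.hour * 60 + protocol.starvation_start.minute
    offset = (starve_clock - lights_on_min) % FULL_DAY
    start = accl + base + offset
    end = start + int(protocol.starvation_hours * 60)
    return end, start, end


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson; lam == 0 degenerates to all ones."""
    if lam <= 0:
        return np.ones(size, dtype=np.int64)
    out = rng.poisson(lam, size)
    zeros = np.flatnonzero(out == 0)
    while len(zeros):
        out[zeros] = rng.poisson(lam, len(zeros))
        zeros = zeros[out[zeros] == 0]
    return out


def _bout_length(rng: np.random.Generator, mean: float) -> int:
    """Shifted geometric with floor MIN_BOUT and the given mean."""
    mean = max(mean, MIN_BOUT + 1e-6)
    p = 1.0 / (mean - MIN_BOUT + 1.0)
    return MIN_BOUT + int(rng.geometric(p)) - 1


def _simulate_fly_counts(
    rng: np.random.Generator,
    model: PopulationSleepModel,
    bout_scale: float,
    hazard_scale: float,
    config: SimulationConfig,
) -> np.ndarray:
    """Minute-resolution beam-break counts for one fly (semi-Markov walk,
    O(bouts) not O(minutes))."""
    total, s_start, s_end = _total_minutes(config.protocol)
    counts = np.zeros(total, dtype=np.int64)
    boundaries = sorted(
        set(list(range(0, total + 1, DAY_MINUTES)) + [s_start, s_end, total])
    )

    t = 0
    while t < total:
        phase_is_day = (t % FULL_DAY) < DAY_MINUTES
        starved = s_start <= t < s_end
        hazard = (model.hazard_day if phase_is_day else model.hazard_night) * hazard_scale
        hazard = min(hazard, 1.0)
        next_b = next(b for b in boundaries if b > t)
        # awake stretch: geometric number of wake minutes before sleep onset
        if hazard <= 0:
            wake = next_b - t + 1  # stays awake past the boundary: no sleep onset
        else:
            wake = int(rng.geometric(hazard))
        start = t
        wake_end = min(start + wake, next_b)
        lam = model.activity_rate * (
            config.starved_activity_multiplier if starved else 1.0
        )
        counts[start:wake_end] = _truncated_poisson(rng, lam, wake_end - start)
        t = wake_end
        if start + wake > next_b or t >= total:
            continue  # stretch truncated by a boundary: re-enter wake there
        # sleep bout, entered at phase/condition of entry; truncated only at
        # the starvation transfer and at the end of recording
        mean = (model.mean_bout_day if phase_is_day else model.mean_bout_night)
        mean *= bout_scale * (config.starved_bout_multiplier if starved else 1.0)
        length = _bout_length(rng, mean)
        cut = s_start if t < s_start else total
        t = min(t + length, cut)
    return counts


def _sleep_minutes(counts: np.ndarray, min_bout: int = MIN_BOUT) -> int:
    """Minutes inside maximal zero runs >= min_bout (generator-side
    bookkeeping of the same behavioral sleep definition)."""
    z = np.concatenate(([0], (counts == 0).astype(np.int8), [0]))
    d = np.diff(z)
    starts = np.flatnonzero(d == 1)
    lengths = np.flatnonzero(d == -1) - starts
    return int(lengths[lengths >= min_bout].sum())


def simulate_activity(
    config: SimulationConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate every fly's activity; optionally write monitor files.

    Returns a ledger dict with ``counts`` (fly_key -> minute array),
    ``flies`` (metadata frame, incl. monitor/channel assignment),
    ``line_params`` (true per-line multipliers) and ``realized`` (per-fly
    fed/starved sleep minutes and percentages bookkept by the generator).
    When ``out_dir`` is given, DAM2-format monitor files and the
    channel-metadata CSV are written there.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    total, s_start, s_end = _total_minutes(config.protocol)
    fed_start = config.protocol.acclimation_days * FULL_DAY
    fed_end = fed_start + config.protocol.baseline_days * FULL_DAY

    line_params: dict[str, dict] = {}
    for pop in config.populations:
        for li in range(config.lines_per_population):
            line = f"{pop}{li + 1:02d}"
            line_params[line] = {
                "population": pop,
                "bout_scale": float(np.exp(rng.normal(0, config.line_bout_sd))),
                "hazard_scale": float(np.exp(rng.normal(0, config.line_hazard_sd))),
            }

    counts: dict[str, np.ndarray] = {}
    fly_rows, realized_rows = [], []
    fly_no = 0
    for pop, line, sex, temp in config.design_cells():
        model = config.sleep[pop]
        lp = line_params[line]
        for rep in range(config.flies_per_line):
            monitor = fly_no // N_CHANNELS + 1
            channel = fly_no % N_CHANNELS + 1
            key = f"M{monitor:03d}:{channel:02d}"
            c = _simulate_fly_counts(
                rng, model, lp["bout_scale"], lp["hazard_scale"], config
            )
            counts[key] = c
            fly_rows.append(
                {
                    "monitor": f"M{monitor:03d}",
                    "channel": channel,
                    "line": line,
                    "population": pop,
                    "sex": sex,
                    "temperature": temp,
                }
            )
            fed_sleep = _sleep_minutes(c[fed_start:fed_end])
            starved_sleep = _sleep_minutes(c[s_start:s_end])
            realized_rows.append(
                {
                    "fly_id": key,
                    "line": line,
                    "population": pop,
                    "sex": sex,
                    "temperature": temp,
                    "fed_sleep_min": fed_sleep,
                    "starved_sleep_min": starved_sleep,
                    "fed_sleep_pct": 100.0 * fed_sleep / (fed_end - fed_start),
                    "starved_sleep_pct": 100.0 * starved_sleep / (s_end - s_start),
                }
            )
            fly_no += 1

    flies = pd.DataFrame(fly_rows)
    realized = pd.DataFrame(realized_rows)
    ledger = {
        "counts": counts,
        "flies": flies,
        "line_params": line_params,
        "realized": realized,
        "n_minutes": total,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_monitor_files(config, counts, flies, out_dir)
        flies.to_csv(out_dir / "channel_metadata.csv", index=False)
        ledger["out_dir"] = out_dir
    return ledger


def _write_monitor_files(
    config: SimulationConfig,
    counts: dict[str, np.ndarray],
    flies: pd.DataFrame,
    out_dir: Path,
) -> list[Path]:
    total, _, _ = _total_minutes(config.protocol)
    t0 = datetime(2012, 6, 4, config.protocol.lights_on.hour, config.protocol.lights_on.minute)
    paths = []
    for monitor, grp in flies.groupby("monitor", sort=False):
        mat = np.zeros((total, N_CHANNELS), dtype=np.int64)
        for row in grp.itertuples():
            mat[:, row.channel - 1] = counts[f"{monitor}:{row.channel:02d}"]
        readings = []
        for i in range(total):
            ts = t0 + timedelta(minutes=i)
            light = 1 if (i % FULL_DAY) < DAY_MINUTES else 0
            readings.append(MonitorReading(i + 1, ts, 1, light, tuple(mat[i].tolist())))
        path = out_dir / f"{monitor}.txt"
        write_monitor_file(readings, path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# survival


def draw_line_effects(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Standard-normal line-level latent sleep scores, one per line (used
    when survival is simulated without an activity run)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    for pop in config.populations:
        for li in range(config.lines_per_population):
            rows.append(
                {
                    "population": pop,
                    "line": f"{pop}{li + 1:02d}",
                    "sleep_z": float(rng.normal()),
                }
            )
    return pd.DataFrame(rows)


def simulate_survival(
    config: SimulationConfig,
    seed: int,
    line_sleep: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate vial starvation censuses coupled (via rho) to line sleep.

    ``line_sleep`` carries one row per line with columns ``population``,
    ``line`` and either ``sleep_z`` (already standardized) or
    ``starved_sleep_pct`` (standardized within population here); when
    omitted, latent scores are drawn fresh.  Line mean death times are
    rho-correlated with those scores within each population; per-fly
    death times add vial and fly noise (negatives resampled, count
    logged).  Censuses run 3x/day at 21 °C and 6x/day at 25 °C.

    Returns a ledger with the tidy ``census`` table, ``line_death_means``
    and the realized fly death times.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    if line_sleep is None:
        line_sleep = draw_line_effects(config, seed)
    line_sleep = line_sleep.copy()
    if "sleep_z" not in line_sleep:
        line_sleep["sleep_z"] = line_sleep.groupby("population")[
            "starved_sleep_pct"
        ].transform(lambda s: (s - s.mean()) / (s.std(ddof=0) or 1.0))

    line_death = {}
    for row in line_sleep.itertuples():
        rho = float(config.rho.get(row.population, 0.0))
        noise = rng.normal()
        z = rho * row.sleep_z + np.sqrt(1 - rho**2) * noise
        base = config.base_death_mean + (config.me_offset if row.population == "ME" else 0.0)
        line_death[row.line] = base + config.line_death_sd * z

    census_rows, death_rows = [], []
    n_resampled = 0
    for pop, line, sex, temp in config.design_cells():
        mean = (
            line_death[line]
            + (config.female_offset if sex == "F" else 0.0)
            + (config.temp21_offset if temp == 21.0 else 0.0)
        )
        interval = 24.0 / config.censuses_per_day[temp]
        for v in range(config.vials_per_line):
            vial_id = f"{line}_{sex}_{int(temp)}_{v + 1}"
            vial_eff = rng.normal(0, config.vial_death_sd)
            deaths = rng.normal(mean + vial_eff, config.fly_death_sd, config.flies_per_vial)
            bad = deaths <= 0
            while bad.any():
                n_resampled += int(bad.sum())
                deaths[bad] = rng.normal(mean + vial_eff, config.fly_death_sd, int(bad.sum()))
                bad = deaths <= 0
            last = float(np.ceil(deaths.max() / interval) * interval)
            times = np.arange(0.0, last + interval / 2, interval)
            for t in times:
                census_rows.append(
                    {
                        "vial_id": vial_id,
                        "line": line,
                        "population": pop,
                        "sex": sex,
                        "temperature": temp,
                        "initial_count": config.flies_per_vial,
                        "elapsed_hours": float(t),
                        "survivors": int((deaths > t).sum()),
                    }
                )
            death_rows.append(
                {
                    "vial_id": vial_id,
                    "line": line,
                    "population": pop,
                    "sex": sex,
                    "temperature": temp,
                    "true_half_death": float(np.median(deaths)),
                }
            )

    census = pd.DataFrame(census_rows)
    ledger = {
        "census": census,
        "line_death_means": line_death,
        "vial_truth": pd.DataFrame(death_rows),
        "line_sleep": line_sleep,
        "n_resampled": n_resampled,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        census.to_csv(out_dir / "survival_census.csv", index=False)
    return ledger


# ---------------------------------------------------------------------------
# plates


def simulate_plates(
    config: SimulationConfig,
    seed: int,
    invert_control_rate: float = 0.0,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate glucose and TGA assay plates with controls and a
    multiplicative log-normal plate effect on the analyte channel.

    Each plate holds up to ``lines_per_plate`` experimental lines (one
    replicate well per line x sex) plus ``control_wells`` Canton-S and
    Akhr wells; plates are generated per temperature x analyte x
    replicate.  ``invert_control_rate`` makes the stated fraction of
    plates violate the control contract (Akhr TGA pulled down to the
    Canton-S level) to exercise the QC power.  Returns a ledger with the
    tidy ``plates`` table, true line means and per-plate factors.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    line_truth = {}
    for pop in config.populations:
        for li in range(config.lines_per_population):
            line = f"{pop}{li + 1:02d}"
            line_truth[line] = {
                "glucose": config.glucose_mean[pop] * np.exp(rng.normal(0, config.line_metabolite_sd)),
                "TGA": config.tga_mean[pop] * np.exp(rng.normal(0, config.line_metabolite_sd)),
            }

    lines = list(line_truth)
    chunks = [
        lines[i : i + config.lines_per_plate]
        for i in range(0, len(lines), config.lines_per_plate)
    ]
    rows, plate_meta = [], []
    plate_no = 0
    for temp in config.temperatures:
        for rep in range(config.replicates_per_line):
            for chunk in chunks:
                plate_no += 1
                plate_id = f"P{plate_no:03d}"
                g = float(np.exp(rng.normal(0, config.plate_effect_sd)))
                inverted = bool(rng.random() < invert_control_rate)
                well_no = 0

                def add_well(genotype, analyte, true_ratio, sex):
                    nonlocal well_no
                    well_no += 1
                    protein = config.protein_mean_mg * np.exp(
                        rng.normal(0, config.well_cv)
                    )
                    analyte_mg = (
                        true_ratio * protein * g * np.exp(rng.normal(0, config.well_cv))
                    )
                    rows.append(
                        {
                            "plate_id": plate_id,
                            "well": f"W{well_no:02d}",
                            "genotype": genotype,
                            "analyte": analyte,
                            "analyte_mg": float(analyte_mg),
                            "protein_mg": float(protein),
                            "sex": sex,
                            "temperature": temp,
                        }
                    )

                for analyte in ("glucose", "TGA"):
                    for line in chunk:
                        for sex in config.sexes:
                            add_well(line, analyte, line_truth[line][analyte], sex)
                    cs_level = (
                        config.cantons_glucose if analyte == "glucose" else config.cantons_tga
                    )
                    if analyte == "TGA":
                        akhr_level = cs_level * (1.0 if inverted else config.akhr_tga_ratio)
                    else:
                        akhr_level = cs_level * config.akhr_glucose_ratio
                    for _ in range(config.control_wells):
                        add_well("CantonS", analyte, cs_level, "mixed")
                    for _ in range(config.control_wells):
                        add_well("Akhr", analyte, akhr_level, "mixed")
                plate_meta.append(
                    {
                        "plate_id": plate_id,
                        "temperature": temp,
                        "plate_factor": g,
                        "inverted_controls": inverted,
                    }
                )

    plates = pd.DataFrame(rows)
    ledger = {
        "plates": plates,
        "line_truth": line_truth,
        "plate_meta": pd.DataFrame(plate_meta),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        plates.to_csv(out_dir / "metabolic_plates.csv", index=False)
    return ledger


def simulate_experiment(
    config: SimulationConfig, seed: int, out_dir: str | Path
) -> dict:
    """Run all three generators, coupling survival to the realized
    line-level starved sleep, and write every raw file to ``out_dir``."""
    out_dir = Path(out_dir)
    activity = simulate_activity(config, seed, out_dir)
    line_sleep = (
        activity["realized"]
        .groupby(["population", "line"], as_index=False)["starved_sleep_pct"]
        .mean()
    )
    survival = simulate_survival(config, seed, line_sleep, out_dir)
    plates = simulate_plates(config, seed, out_dir=out_dir)
    return {"activity": activity, "survival": survival, "plates": plates}
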