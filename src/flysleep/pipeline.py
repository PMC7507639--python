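"""End-to-end orchestration: simulate (or load) raw data, score sleep,
estimate LD50, normalize metabolites, fit the models, emit report tables.

Every report table is recomputed from tidy intermediates that are also
written to disk, so any number in a report can be traced back to raw
monitor rows, census rows or plate wells.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from flysleep import dams_io, metabolic_assays, sleep_metrics, starvation_survival
from flysleep import stats_models
from flysleep.synthetic_data import SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "flysleep_run"
    min_bout: int = 5
    terminal_quiet_hours: float = 12.0
    alpha: float = 0.05
    inference: tuple[str, ...] = ("ols", "bayes")
    bayes_iterations: int = 2000
    bayes_chains: int = 4
    simulate: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "inference" in raw:
            raw["inference"] = tuple(raw["inference"])
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(**self.simulate)


def parse_monitor_dir(
    raw_dir: Path, protocol=None
) -> list[dams_io.ActivityTrace]:
    """Parse every monitor file in a directory against its channel
    metadata CSV into annotated traces."""
    meta = dams_io.read_channel_metadata(raw_dir / "channel_metadata.csv")
    traces = []
    for monitor, grp in meta.groupby("monitor", sort=False):
        readings = dams_io.read_monitor_file(raw_dir / f"{monitor}.txt")
        for row in grp.itertuples():
            traces.append(
                dams_io.annotate_trace(
                    readings,
                    int(row.channel),
                    {
                        "monitor": monitor,
                        "line": row.line,
                        "population": row.population,
                        "sex": row.sex,
                        "temperature": row.temperature,
                    },
                    protocol,
                )
            )
    return traces


def assemble_line_table(
    per_fly_sleep: pd.DataFrame,
    ld50_lines: pd.DataFrame,
    metabolites: pd.DataFrame,
) -> pd.DataFrame:
    """Join the line x sex x temperature phenotype means consumed by the
    LD50 models: mean LD50, starved sleep phenotypes and metabolite
    levels."""
    keys = ["population", "line", "sex", "temperature"]
    starved = per_fly_sleep[
        (per_fly_sleep["condition"] == "starved") & (per_fly_sleep["period"] == "whole")
    ]
    sleep = (
        starved.groupby(keys, as_index=False)
        .agg(
            total_sleep_starved=("total_sleep_pct", "mean"),
            starved_mean_movement=("mean_awake_movement", "mean"),
            pct_change_sleep=("pct_change_sleep", "mean"),
        )
    )
    out = sleep.merge(
        ld50_lines[keys + ["mean_ld50", "median_ld50"]], on=keys, how="inner"
    )
    if metabolites is not None and len(metabolites):
        out = out.merge(
            metabolites[
                ["line", "sex", "temperature", "glucose_per_protein", "tga_per_protein"]
            ],
            on=["line", "sex", "temperature"],
            how="left",
        )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Simulate-then-analyze with one seed; writes the report bundle.

    Outputs under ``config.out_dir``: raw/ (monitor files, census, plates),
    intermediates (per-fly and per-line sleep tables, vial and line LD50,
    metabolite summaries, the joined line phenotype table) and reports
    (linear-model and Bayesian coefficient tables, ANOVA, per-population
    sleep-vs-LD50 regressions, QC log).  Returns the tables in memory.
    """
    out = Path(config.out_dir)
    raw = out / "raw"
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation_config()
    logger.info("simulating experiment (seed=%d)", config.seed)
    simulate_experiment(sim, config.seed, raw)

    logger.info("parsing monitor files")
    traces = parse_monitor_dir(raw, sim.protocol)
    qc_lines = []
    kept = []
    for t in traces:
        verdict, _ = dams_io.flag_dead_or_escaped(t, config.terminal_quiet_hours)
        if verdict.flagged:
            qc_lines.append(
                f"fly {t.fly_id}: terminal quiet run of "
                f"{verdict.terminal_quiet_minutes} min; excluded from fed summaries"
            )
        else:
            kept.append(t)

    logger.info("scoring sleep for %d flies", len(kept))
    per_fly = sleep_metrics.summarize_flies(kept, config.min_bout)
    per_line = sleep_metrics.aggregate_lines(per_fly)
    per_fly.to_csv(out / "sleep_per_fly.csv", index=False)
    per_line.to_csv(out / "sleep_per_line.csv", index=False)

    census = pd.read_csv(raw / "survival_census.csv")
    vials, ld50_lines = starvation_survival.ld50_table(
        starvation_survival.censuses_from_frame(census)
    )
    vials.to_csv(out / "ld50_vials.csv", index=False)
    ld50_lines.to_csv(out / "ld50_lines.csv", index=False)
    qc_lines += [f"ld50: {msg}" for msg in ld50_lines.attrs.get("excluded", [])]

    plates = pd.read_csv(raw / "metabolic_plates.csv")
    metab, verdicts = metabolic_assays.summarize_plates(plates, config.alpha)
    metab.to_csv(out / "metabolites_per_line.csv", index=False)
    qc_lines += [
        f"plate {v.plate_id}: {v.verdict} ({v.reason})"
        for v in verdicts
        if v.verdict != "pass"
    ]

    pheno = assemble_line_table(per_fly, ld50_lines, metab)
    pheno.to_csv(out / "line_phenotypes.csv", index=False)

    reports: dict = {"phenotypes": pheno, "sleep_per_line": per_line}
    anova = stats_models.anova_ld50(pheno)
    anova.to_csv(out / "anova_ld50.csv")
    reports["anova"] = anova

    fig4 = pd.concat(
        [
            stats_models.regress_sleep_on_ld50(pheno, pred)
            for pred in ("total_sleep_starved", "pct_change_sleep")
        ],
        ignore_index=True,
    )
    fig4.to_csv(out / "sleep_ld50_regressions.csv", index=False)
    reports["regressions"] = fig4

    for flavor in ("metabolism", "behavior"):
        if "ols" in config.inference:
            fit = stats_models.fit_linear_ld50(pheno.dropna(), flavor)
            fit.coefficients.assign(
                adj_r_squared=fit.adj_r_squared,
                F=fit.f_statistic,
                df_model=fit.df_model,
                df_resid=fit.df_resid,
            ).to_csv(out / f"linear_{flavor}.csv", index=False)
            reports[f"ols_{flavor}"] = fit
        if "bayes" in config.inference:
            post = stats_models.fit_bayes_ld50(
                pheno.dropna(),
                flavor,
                seed=config.seed,
                chains=config.bayes_chains,
                iterations=config.bayes_iterations,
            )
            post.table.to_csv(out / f"bayes_{flavor}.csv", index=False)
            pd.DataFrame(post.ppc_draws).to_csv(
                out / f"bayes_{flavor}_ppc.csv", index=False
            )
            reports[f"bayes_{flavor}"] = post

    (out / "qc_log.txt").write_text("\n".join(qc_lines) + "\n")
    (out / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(config), default=str, indent=2)
    )
    return reports
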