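# flysleep

Sleep, starvation resistance and stored-metabolite phenotyping for
*Drosophila* activity-monitor experiments, built around a two-population
isofemale-line design (a temperate "ME" and a tropical "PC" population,
10 lines each, both sexes, 21 °C and 25 °C).

The package answers one scientific question end to end: **does sleep — a
putatively energy-conserving behavior — explain variation in starvation
resistance, between and within populations?** It turns raw data into the
statistical models that address this:

- **Activity → sleep.** TriKinetics Drosophila Activity Monitor (DAM)
  files record infrared beam breaks per fly per minute. Sleep is the
  behavioral standard: a maximal run of ≥ 5 consecutive minutes with zero
  beam breaks. Minutes are annotated with Zeitgeber time (ZT = hours
  since lights-on; day = ZT ∈ [0, 12) under 12:12 LD) and with the
  feeding condition implied by the protocol — 2 acclimation days, 2 fed
  baseline days, then 24 h of starvation starting at ZH3. Phenotypes per
  fly and period: total sleep (% of period), bout number, mean bout
  length, mean beam breaks per awake minute, and the within-fly percent
  change in sleep, 100·(starved − fed)/fed.
- **Censuses → LD50.** Starvation resistance is the time at which half of
  a 10-fly vial is dead, estimated as the earliest crossing of the
  piecewise-linear interpolated survival curve (censuses 3×/day at 21 °C,
  6×/day at 25 °C); line values are means over ≥ 6 vials.
- **Plates → metabolites.** Whole-body glucose and triglyceride (TGA) per
  mg protein, with per-plate QC against Canton-S and *Akhr*-mutant control
  wells (*Akhr*: elevated TGA, normal glucose) and an optional Canton-S
  normalization that cancels multiplicative plate effects exactly.
- **Models.** Bonferroni-corrected Welch t-test families; sequential
  ANOVA of LD50 with line nested in population; MANOVA of the sleep
  phenotypes (Pillai's trace); per-population OLS regressions of LD50 on
  sleep-when-starved and percent change in sleep; and two fixed-effect
  models of line-mean LD50 — a *metabolism* flavor (sex, temperature,
  population, glucose, TGA) and a *behavior* flavor (sex, temperature,
  population, percent change in sleep, starved mean movement, total sleep
  when starved) — fit by OLS and by a 4-chain Bayesian sampler on the
  QR-reparameterized design with rHat convergence checks and
  posterior-predictive draws.

Because real monitor data are not bundled, `flysleep.synthetic_data`
simulates the whole experiment (semi-Markov sleep/wake chains, vial
censuses, assay plates) with a ground-truth ledger, including a per-line
coupling ρ between sleep-under-starvation and death time that is positive
in PC and zero in ME — the structure the per-population regressions are
designed to detect.

## Worked example

```python
from flysleep.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=1, out_dir="demo",
                simulate=dict(lines_per_population=4, flies_per_line=6,
                              vials_per_line=6, replicates_per_line=2))
reports = run_pipeline(cfg)
print(reports["anova"].round(2))
```

```
                    df   sum_sq  mean_sq        F  PR(>F)
sex                1.0   774.20   774.20  1137.27     0.0
temperature        1.0   471.53   471.53   692.67     0.0
population         1.0  2461.77  2461.77  3616.25     0.0
line(population)   6.0   289.64    48.27    70.91     0.0
Residual          22.0    14.98     0.68      NaN     NaN
```

Population, sex and temperature all shape starvation resistance, and
lines within populations differ heritably (the nested term has
2·(k−1) = 6 df for k = 4 lines per population). The per-population
regressions recover the built-in coupling — significant for PC females,
flat for ME:

```
population sex           predictor  slope  r_squared     p  n
        ME   F total_sleep_starved -0.862      0.263 0.193  8
        ME   M total_sleep_starved -0.442      0.128 0.384  8
        PC   F total_sleep_starved  1.898      0.651 0.015  8
        PC   M total_sleep_starved  0.753      0.188 0.283  8
```

and the Bayesian behavior model reports posterior means with 95%
credible intervals and rHat = 1.0 for every term (`reports
["bayes_behavior"].table`), e.g. Sex (M) −9.92 [−12.37, −7.56]: males die
about 10 h earlier than females at equal covariates.

The same steps are available as shell commands:
`flysleep simulate|parse|sleep|ld50|metabolics|stats|run` (see
`flysleep --help`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a scaled-down synthetic
design (10 lines per population, fewer flies per line than the study for
runtime): it simulates monitor files, censuses and plates, re-parses
them, scores sleep, estimates LD50, normalizes metabolites, and fits the
ANOVA, OLS and Bayesian models, printing the model fit summaries and
writing the JSON result file.
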