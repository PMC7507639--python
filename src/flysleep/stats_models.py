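"""Statistical models of starvation resistance, sleep and metabolism.

Implements the full inferential layer of the analysis:

- Bonferroni-corrected families of pairwise Welch t-tests,
- sequential (Type I) ANOVA of line-mean LD50 with isofemale line nested
  within population,
- MANOVA of the sleep/movement phenotypes (Pillai's trace with univariate
  follow-ups),
- per-population OLS regressions of sleep phenotypes on LD50,
- the two fixed-effect models of LD50 — "metabolism" flavor (sex,
  temperature, population, glucose, TGA) and "behavior" flavor (sex,
  temperature, population, percent change in sleep, starved mean
  movement, total sleep when starved) — with either OLS or Bayesian
  inference.

The Bayesian fit QR-reparameterizes the design matrix and draws from the
exact conditional posteriors of a conjugate Gaussian linear model
(weakly-informative Normal prior on the rotated coefficients,
inverse-gamma on the residual variance) with 4 independent chains;
convergence is checked with the rHat potential-scale-reduction statistic
and posterior-predictive draws are returned for density-overlay checks.
With the default weak priors the posterior coincides with the one a
Hamiltonian Monte Carlo sampler would target for the same model.

Factor coding is treatment coding with reference levels Female, 21 °C and
the ME population, so reported effects are Sex(M), Temperature(25) and
Population(PC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)

RESPONSE = "mean_ld50"
METABOLISM_PREDICTORS = (
    "glucose_per_protein",
    "tga_per_protein",
)
BEHAVIOR_PREDICTORS = (
    "pct_change_sleep",
    "starved_mean_movement",
    "total_sleep_starved",
)
_FACTOR_TERMS = (
    'C(sex, Treatment("F"))',
    "C(temperature, Treatment(21.0))",
    'C(population, Treatment("ME"))',
)


class ConvergenceError(RuntimeError):
    """MCMC convergence diagnostic failed; summaries are withheld."""


@dataclass(frozen=True)
class TestFamily:
    """A Bonferroni-corrected family of pairwise Welch t-tests."""

    family: str
    alpha: float
    results: pd.DataFrame  # comparison, t, p_raw, significant
    skipped: tuple[str, ...] = ()

    @property
    def threshold(self) -> float:
        return self.alpha / max(len(self.results), 1)


@dataclass(frozen=True)
class LinearFitSummary:
    flavor: str
    coefficients: pd.DataFrame  # term, estimate, se, t, p
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    n: int


@dataclass(frozen=True)
class PosteriorSummary:
    flavor: str
    table: pd.DataFrame  # term, Estimate, Est.Error, l-95% CI, u-95% CI, rHat, MCSE
    sigma: pd.Series
    ppc_draws: np.ndarray = field(repr=False)  # (n_ppc, n_obs) replicated responses
    observed: np.ndarray = field(repr=False)
    n_chains: int = 4
    n_draws: int = 0


def model_formula(flavor: str, response: str = RESPONSE) -> str:
    """Patsy formula for the metabolism or behavior flavor."""
    if flavor == "metabolism":
        extra = METABOLISM_PREDICTORS
    elif flavor == "behavior":
        extra = BEHAVIOR_PREDICTORS
    else:
        raise ValueError(f"unknown model flavor {flavor!r}")
    return f"{response} ~ " + " + ".join(_FACTOR_TERMS + extra)


_TERM_LABELS = {
    'C(sex, Treatment("F"))[T.M]': "Sex (M)",
    "C(temperature, Treatment(21.0))[T.25.0]": "Temperature (25)",
    'C(population, Treatment("ME"))[T.PC]': "Population (PC)",
    "glucose_per_protein": "Glucose (mg Glu / mg Protein)",
    "tga_per_protein": "Triglyceride (mg TGA / mg Protein)",
    "pct_change_sleep": "Percent change in sleep",
    "starved_mean_movement": "Starved mean movement (beam breaks / min)",
    "total_sleep_starved": "Total sleep when starved",
}


def _pretty(terms) -> list[str]:
    return [_TERM_LABELS.get(t, t) for t in terms]


# ---------------------------------------------------------------------------
# pairwise tests


def pairwise_tests(
    comparisons: list[tuple[str, np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> TestFamily:
    """Welch two-tailed t-tests with Bonferroni control over the family.

    ``comparisons`` is a list of (label, group_a, group_b); a comparison
    whose pooled variance is zero (or with <2 observations in a group) is
    skipped with a logged reason and does not count toward the family
    size.
    """
    rows, skipped = [], []
    for label, a, b in comparisons:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            skipped.append(f"{label}: fewer than 2 observations")
            continue
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                rows.append({"comparison": label, "t": 0.0, "p_raw": 1.0})
                continue
            skipped.append(f"{label}: degenerate (zero) variances")
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"comparison": label, "t": float(res.statistic), "p_raw": float(res.pvalue)})
    for msg in skipped:
        logger.warning("pairwise test skipped: %s", msg)
    table = pd.DataFrame(rows, columns=["comparison", "t", "p_raw"])
    m = max(len(table), 1)
    table["significant"] = table["p_raw"] < alpha / m
    return TestFamily("pairwise", alpha, table, tuple(skipped))


# ---------------------------------------------------------------------------
# ANOVA / MANOVA


def _nested_line_codes(table: pd.DataFrame) -> pd.Series:
    """Recode line labels 0..k-1 within each population so the nested
    term C(population):C(line_code) is full rank on a balanced design."""
    return (
        table.groupby("population")["line"]
        .transform(lambda s: pd.Categorical(s).codes)
        .astype(int)
    )


def anova_ld50(
    table: pd.DataFrame,
    response: str = RESPONSE,
    nest_line: bool = True,
    typ: int = 1,
) -> pd.DataFrame:
    """Sequential ANOVA of line-mean LD50 on sex, temperature, population
    and (optionally) line nested within population.

    On the full design (k lines per population, 2 populations) the
    population term has 1 df and the line-within-population term 2(k-1)
    df.  Raises if any factorial cell is empty.
    """
    cells = table.groupby(["sex", "temperature", "population"]).size()
    expected = (
        table["sex"].nunique() * table["temperature"].nunique() * table["population"].nunique()
    )
    if len(cells) != expected:
        raise ValueError(f"missing factorial cells; found {len(cells)} of {expected}")

    work = table.copy()
    formula = f"{response} ~ C(sex) + C(temperature) + C(population)"
    if nest_line:
        work["line_code"] = _nested_line_codes(work)
        formula += " + C(population):C(line_code)"
    fit = smf.ols(formula, data=work).fit()
    out = anova_lm(fit, typ=typ)

    def clean(label: str) -> str:
        if "line_code" in label:
            return "line(population)"
        if label.startswith("C(") and label.endswith(")"):
            return label[2:-1]
        return label

    out.index = [clean(i) for i in out.index]
    return out


def manova_sleep(
    per_fly: pd.DataFrame,
    responses: tuple[str, ...] = (
        "total_sleep_pct",
        "mean_bout_length",
        "bout_number",
        "mean_awake_movement",
    ),
    terms: str = 'C(temperature) + C(sex) + C(population)/C(line_code)',
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """MANOVA of the sleep/movement phenotypes with univariate follow-ups.

    Returns the Pillai's-trace table per model term and a dict of
    univariate sequential ANOVA tables (one per response).  A singular
    response covariance (e.g. duplicated responses) raises with advice to
    reduce the response set.
    """
    work = per_fly.dropna(subset=list(responses)).copy()
    if "line_code" in terms and "line_code" not in work:
        work["line_code"] = _nested_line_codes(work)
    resp_cov = np.cov(work[list(responses)].to_numpy().T)
    if np.linalg.matrix_rank(resp_cov) < len(responses):
        raise ValueError(
            "response covariance is singular; remove collinear/duplicated "
            "responses before running the MANOVA"
        )
    formula = " + ".join(responses) + " ~ " + terms
    mv = MANOVA.from_formula(formula, data=work)
    res = mv.mv_test()
    rows = []
    for term, payload in res.results.items():
        stat = payload["stat"]
        if "Pillai's trace" in stat.index:
            row = stat.loc["Pillai's trace"]
            rows.append(
                {
                    "term": term,
                    "pillai": float(row["Value"]),
                    "F": float(row["F Value"]),
                    "df_num": float(row["Num DF"]),
                    "df_den": float(row["Den DF"]),
                    "p": float(row["Pr > F"]),
                }
            )
    pillai = pd.DataFrame(rows)

    followups = {}
    for r in responses:
        fit = smf.ols(f"{r} ~ {terms}", data=work).fit()
        followups[r] = anova_lm(fit, typ=1)
    return pillai, followups


def regress_sleep_on_ld50(
    line_means: pd.DataFrame,
    predictor: str,
    response: str = RESPONSE,
    groupby: tuple[str, ...] = ("population", "sex"),
) -> pd.DataFrame:
    """Per-group OLS of line-mean LD50 on a sleep phenotype.

    One regression per group (default population x sex); groups with
    fewer than 3 line means are skipped.  Returns slope, intercept, R²,
    p-value and n per group.
    """
    rows = []
    for key, grp in line_means.groupby(list(groupby), sort=False):
        sub = grp.dropna(subset=[predictor, response])
        if len(sub) < 3:
            logger.warning("regression group %s skipped: n=%d < 3", key, len(sub))
            continue
        fit = stats.linregress(sub[predictor], sub[response])
        row = dict(zip(groupby, key if isinstance(key, tuple) else (key,)))
        row.update(
            predictor=predictor,
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2),
            p=float(fit.pvalue),
            n=len(sub),
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linear and Bayesian models of LD50


def fit_linear_ld50(
    table: pd.DataFrame, flavor: str, response: str = RESPONSE
) -> LinearFitSummary:
    """OLS fit of the metabolism- or behavior-flavor model of LD50.

    On the full 20-line x 2-sex x 2-temperature design (80 line means)
    the metabolism model has F degrees of freedom (5, 74) and the
    behavior model (6, 73).  Rank-deficient designs raise with the
    aliased terms named.
    """
    formula = model_formula(flavor, response)
    y, X = patsy.dmatrices(formula, table, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        aliased = [X.columns[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"design is rank deficient; aliased terms: {_pretty(aliased)}")
    fit = sm.OLS(y, X).fit()
    coefs = pd.DataFrame(
        {
            "term": _pretty(X.columns),
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return LinearFitSummary(
        flavor=flavor,
        coefficients=coefs,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n=int(fit.nobs),
    )


def _gibbs_linear(
    y: np.ndarray,
    X: np.ndarray,
    seed: int,
    chains: int,
    iterations: int,
    warmup: int,
    prior_scale: float,
    prior_a: float,
    prior_b: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Gibbs sampler for the Gaussian linear model on the QR-rotated
    design.

    The thin QR factorization X = Q R with Q* = sqrt(n-1) Q makes
    Q*'Q* = (n-1) I, so the conditional posterior of the rotated
    coefficients is diagonal and each sweep is O(p).  Returns
    (beta draws, sigma draws) with shapes (chains, kept, p) and
    (chains, kept).
    """
    n, p = X.shape
    q, r = np.linalg.qr(X)
    scale = np.sqrt(n - 1)
    q_star = q * scale
    r_star = r / scale
    qty = q_star.T @ y                      # (p,)
    yty = float(y @ y)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chain_rngs = rng.spawn(chains)

    tau2 = (prior_scale * max(np.std(y), 1e-12)) ** 2
    kept = iterations - warmup
    theta_draws = np.empty((chains, kept, p))
    sigma_draws = np.empty((chains, kept))

    for c, crng in enumerate(chain_rngs):
        sigma2 = float(np.var(y)) * np.exp(crng.normal(0, 1))  # overdispersed start
        theta = crng.normal(0, 1, size=p) * np.sqrt(sigma2)
        for it in range(iterations):
            prec = (n - 1) / sigma2 + 1.0 / tau2
            mean = (qty / sigma2) / prec
            theta = mean + crng.normal(0, 1, size=p) / np.sqrt(prec)
            rss = yty - 2 * theta @ qty + (n - 1) * theta @ theta
            sigma2 = 1.0 / crng.gamma(prior_a + n / 2, 1.0 / (prior_b + max(rss, 1e-12) / 2))
            if it >= warmup:
                theta_draws[c, it - warmup] = theta
                sigma_draws[c, it - warmup] = np.sqrt(sigma2)

    r_inv = np.linalg.inv(r_star)
    beta_draws = theta_draws @ r_inv.T
    return beta_draws, sigma_draws


def fit_bayes_ld50(
    table: pd.DataFrame,
    flavor: str,
    response: str = RESPONSE,
    seed: int = 0,
    chains: int = 4,
    iterations: int = 2000,
    prior_scale: float = 100.0,
    prior_a: float = 0.001,
    prior_b: float = 0.001,
    n_ppc: int = 100,
    rhat_limit: float = 1.05,
) -> PosteriorSummary:
    """Bayesian fit of the metabolism- or behavior-flavor model of LD50.

    The design matrix is QR-reparameterized (which also verifies it is
    full rank) and the posterior is sampled with 4 chains of a conjugate
    Gibbs sampler; priors are weakly informative (Normal with sd
    ``prior_scale`` x sd(y) on the rotated coefficients, near-flat
    inverse-gamma on the residual variance), so estimates agree with OLS
    in the large-n limit.  Reports per-coefficient posterior mean
    (Estimate), sd (Est.Error), central 95% credible interval, rHat and
    Monte-Carlo standard error, plus posterior-predictive replicate
    responses for a density-overlay check.  Any rHat above ``rhat_limit``
    raises :class:`ConvergenceError` and withholds the summaries.
    """
    import arviz as az

    formula = model_formula(flavor, response)
    y_df, X_df = patsy.dmatrices(formula, table, return_type="dataframe")
    X = X_df.to_numpy()
    y = y_df.to_numpy().ravel()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after QR check")

    warmup = iterations // 2
    beta, sigma = _gibbs_linear(
        y, X, seed, chains, iterations, warmup, prior_scale, prior_a, prior_b
    )

    idata = az.from_dict(
        posterior={"beta": beta, "sigma": sigma},
        coords={"term": list(X_df.columns)},
        dims={"beta": ["term"]},
    )
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rhat_beta = np.asarray(rhat["beta"])
    rhat_sigma = float(rhat["sigma"])
    worst = max(float(rhat_beta.max()), rhat_sigma)
    if worst > rhat_limit:
        raise ConvergenceError(
            f"rHat up to {worst:.3f} exceeds {rhat_limit}; summaries withheld"
        )

    flat = beta.reshape(-1, beta.shape[-1])
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    sd = flat.std(axis=0, ddof=1)
    mcse = sd / np.sqrt(np.asarray(ess["beta"]))
    table_out = pd.DataFrame(
        {
            "term": _pretty(X_df.columns),
            "Estimate": flat.mean(axis=0),
            "Est.Error": sd,
            "l-95% CI": lo,
            "u-95% CI": hi,
            "rHat": rhat_beta,
            "MCSE": mcse,
        }
    )
    sflat = sigma.ravel()
    sigma_summary = pd.Series(
        {
            "Estimate": sflat.mean(),
            "Est.Error": sflat.std(ddof=1),
            "l-95% CI": np.percentile(sflat, 2.5),
            "u-95% CI": np.percentile(sflat, 97.5),
            "rHat": rhat_sigma,
        },
        name="sigma",
    )

    ppc_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    pick = ppc_rng.choice(len(flat), size=min(n_ppc, len(flat)), replace=False)
    ppc = flat[pick] @ X.T + sflat[pick, None] * ppc_rng.normal(size=(len(pick), len(y)))

    return PosteriorSummary(
        flavor=flavor,
        table=table_out,
        sigma=sigma_summary,
        ppc_draws=ppc,
        observed=y,
        n_chains=chains,
        n_draws=iterations - warmup,
    )
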