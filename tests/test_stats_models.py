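"""Pairwise test families, nested ANOVA/MANOVA, group regressions and the
OLS/Bayesian models of starvation resistance."""

import numpy as np
import pandas as pd
import pytest

from flysleep import stats_models as sm


def make_design(rng, n_lines=10, sigma=3.0, beta_pct=0.5):
    """Line-mean table simulated from the behavior-flavor model with
    known coefficients (one row per line x sex x temperature)."""
    rows = []
    for pop in ("ME", "PC"):
        for li in range(n_lines):
            glu = rng.normal(0.18, 0.03)
            tga = rng.normal(0.26, 0.05)
            for sex in ("F", "M"):
                for temp in (21.0, 25.0):
                    rows.append(
                        dict(
                            population=pop,
                            line=f"{pop}{li:02d}",
                            sex=sex,
                            temperature=temp,
                            glucose_per_protein=glu,
                            tga_per_protein=tga,
                            pct_change_sleep=rng.normal(-20, 15),
                            starved_mean_movement=rng.normal(2.5, 0.5),
                            total_sleep_starved=rng.normal(40, 10),
                        )
                    )
    t = pd.DataFrame(rows)
    mu = (
        45.0
        - 9.0 * (t.sex == "M")
        - 8.0 * (t.temperature == 25.0)
        - 4.0 * (t.population == "PC")
        + beta_pct * t.pct_change_sleep
        - 3.0 * t.starved_mean_movement
        + 0.05 * t.total_sleep_starved
    )
    t["mean_ld50"] = mu + rng.normal(0, sigma, len(t))
    return t


class TestPairwise:
    def test_identical_groups_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        fam = sm.pairwise_tests([("same", a, a.copy())])
        row = fam.results.iloc[0]
        assert row["t"] == 0.0 and not row["significant"]

    def test_bonferroni_threshold_scales_with_family(self):
        rng = np.random.default_rng(0)
        comps = [(f"c{i}", rng.normal(0, 1, 10), rng.normal(0, 1, 10)) for i in range(20)]
        fam = sm.pairwise_tests(comps, alpha=0.05)
        assert fam.threshold == pytest.approx(0.0025)
        # a raw p of 0.01 would not clear a 20-test family
        assert (fam.results.loc[fam.results.p_raw.between(0.0025, 0.05), "significant"] == False).all()  # noqa: E712

    def test_degenerate_groups_skipped(self):
        fam = sm.pairwise_tests([("flat", np.ones(5), np.full(5, 2.0)), ("tiny", [1.0], [2.0, 3.0])])
        assert len(fam.skipped) == 2 and len(fam.results) == 0

    def test_familywise_error_rate_controlled_under_null(self):
        """1,000 simulated null families of 5 tests: the Bonferroni
        family-wise error rate stays at or below alpha (within binomial
        noise)."""
        rng = np.random.default_rng(1)
        n_fam, fam_size, n = 1000, 5, 10
        errors = 0
        for _ in range(n_fam):
            comps = [
                (f"c{i}", rng.normal(0, 1, n), rng.normal(0, 1, n))
                for i in range(fam_size)
            ]
            fam = sm.pairwise_tests(comps, alpha=0.05)
            errors += int(fam.results["significant"].any())
        # FWER <= 0.05; allow 3 binomial SEs above
        assert errors / n_fam <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_fam)


class TestAnova:
    def test_nested_design_degrees_of_freedom(self):
        rng = np.random.default_rng(2)
        table = make_design(rng)
        out = sm.anova_ld50(table)
        assert out.loc["population", "df"] == 1
        assert out.loc["line(population)", "df"] == 18
        assert out.loc["sex", "df"] == 1

    def test_missing_cells_rejected(self):
        rng = np.random.default_rng(3)
        table = make_design(rng)
        with pytest.raises(ValueError, match="missing"):
            sm.anova_ld50(table[~((table.sex == "M") & (table.temperature == 25.0))])

    def test_null_response_f_near_one(self):
        """With a pure-noise response, each term's F statistic averages
        about 1 over replicates."""
        rng = np.random.default_rng(4)
        fs = {"sex": [], "population": [], "line(population)": []}
        for _ in range(60):
            table = make_design(rng)
            table["mean_ld50"] = rng.normal(0, 1, len(table))
            out = sm.anova_ld50(table)
            for k in fs:
                fs[k].append(out.loc[k, "F"])
        for k, v in fs.items():
            assert abs(np.mean(v) - 1.0) < 0.45, k


class TestManova:
    RESPONSES = ("total_sleep_pct", "mean_bout_length", "bout_number", "mean_awake_movement")

    def _per_fly(self, rng, pop_shift=0.0, n=12):
        rows = []
        for pop in ("ME", "PC"):
            for li in range(3):
                for sex in ("F", "M"):
                    for temp in (21.0, 25.0):
                        for _ in range(n):
                            rows.append(
                                dict(
                                    population=pop,
                                    line=f"{pop}{li}",
                                    sex=sex,
                                    temperature=temp,
                                    total_sleep_pct=rng.normal(50 + pop_shift * (pop == "PC"), 8),
                                    mean_bout_length=rng.normal(20, 4),
                                    bout_number=rng.normal(40, 6),
                                    mean_awake_movement=rng.normal(2.5, 0.4),
                                )
                            )
        return pd.DataFrame(rows)

    def test_duplicated_response_raises_singularity(self):
        rng = np.random.default_rng(5)
        frame = self._per_fly(rng)
        frame["dup"] = frame["total_sleep_pct"]
        with pytest.raises(ValueError, match="singular"):
            sm.manova_sleep(frame, responses=self.RESPONSES + ("dup",))

    def test_injected_population_effect_detected_and_localized(self):
        rng = np.random.default_rng(6)
        frame = self._per_fly(rng, pop_shift=8.0)
        pillai, follow = sm.manova_sleep(frame)
        pop_row = pillai[pillai.term.str.contains("population")]
        assert (pop_row["p"] < 0.01).any()
        assert follow["total_sleep_pct"].loc["C(population)", "PR(>F)"] < 0.01
        assert follow["bout_number"].loc["C(population)", "PR(>F)"] > 0.01

    def test_null_pillai_p_not_small_on_average(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(10):
            pillai, _ = sm.manova_sleep(self._per_fly(rng, n=6))
            ps.append(pillai[pillai.term.str.contains("sex")]["p"].iloc[0])
        assert np.mean(ps) > 0.2  # roughly uniform p-values under the null


class TestGroupRegression:
    def test_collinear_points_recover_slope(self):
        table = pd.DataFrame(
            {
                "population": "PC",
                "sex": "F",
                "total_sleep_starved": np.arange(10.0),
                "mean_ld50": 2.0 * np.arange(10.0) + 1.0,
            }
        )
        out = sm.regress_sleep_on_ld50(table, "total_sleep_starved")
        assert out.slope.iloc[0] == pytest.approx(2.0)
        assert out.r_squared.iloc[0] == pytest.approx(1.0)

    def test_small_groups_skipped(self):
        table = pd.DataFrame(
            {
                "population": ["ME", "ME"],
                "sex": ["F", "F"],
                "total_sleep_starved": [1.0, 2.0],
                "mean_ld50": [3.0, 4.0],
            }
        )
        out = sm.regress_sleep_on_ld50(table, "total_sleep_starved")
        assert out.empty


class TestLinearModel:
    def test_structural_degrees_of_freedom(self):
        rng = np.random.default_rng(8)
        table = make_design(rng)
        met = sm.fit_linear_ld50(table, "metabolism")
        beh = sm.fit_linear_ld50(table, "behavior")
        assert (met.df_model, met.df_resid) == (5, 74)
        assert (beh.df_model, beh.df_resid) == (6, 73)

    def test_noiseless_response_recovers_coefficients(self):
        rng = np.random.default_rng(9)
        table = make_design(rng, sigma=0.0)
        fit = sm.fit_linear_ld50(table, "behavior")
        coef = fit.coefficients.set_index("term")["estimate"]
        assert coef["Percent change in sleep"] == pytest.approx(0.5, abs=1e-8)
        assert coef["Sex (M)"] == pytest.approx(-9.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_rank_deficiency_names_aliased_terms(self):
        rng = np.random.default_rng(10)
        table = make_design(rng)
        table["tga_per_protein"] = 2.0 * table["glucose_per_protein"]
        with pytest.raises(ValueError, match="rank deficient"):
            sm.fit_linear_ld50(table, "metabolism")


class TestBayesModel:
    def test_intercept_only_posterior_matches_sample_mean(self):
        rng = np.random.default_rng(11)
        y = rng.normal(30, 4, 200)
        # intercept-only model exercises the Gibbs core directly
        from flysleep.stats_models import _gibbs_linear

        beta, _ = _gibbs_linear(
            y, np.ones((len(y), 1)), seed=3, chains=4, iterations=2000,
            warmup=1000, prior_scale=100.0, prior_a=0.001, prior_b=0.001,
        )
        flat = beta.reshape(-1)
        mc_se = flat.std(ddof=1) / np.sqrt(200)  # conservative ESS bound
        assert abs(flat.mean() - y.mean()) < max(4 * mc_se, 0.05)

    def test_posterior_means_match_ols_with_weak_priors(self):
        rng = np.random.default_rng(12)
        table = pd.concat([make_design(rng) for _ in range(4)], ignore_index=True)
        post = sm.fit_bayes_ld50(table, "behavior", seed=4)
        fit = sm.fit_linear_ld50(table, "behavior")
        merged = post.table.merge(
            fit.coefficients, left_on="term", right_on="term"
        )
        z = np.abs(merged["Estimate"] - merged["estimate"]) / merged["MCSE"]
        assert (z < 3).all()

    def test_credible_interval_orders_and_rhat(self):
        rng = np.random.default_rng(13)
        table = make_design(rng)
        post = sm.fit_bayes_ld50(table, "metabolism", seed=5)
        t = post.table
        assert ((t["l-95% CI"] <= t["Estimate"]) & (t["Estimate"] <= t["u-95% CI"])).all()
        assert (t["rHat"] < 1.02).all()
        assert post.ppc_draws.shape[1] == len(table)

    def test_table_carries_reported_row_labels(self):
        rng = np.random.default_rng(14)
        post = sm.fit_bayes_ld50(make_design(rng), "behavior", seed=6)
        assert {"Sex (M)", "Temperature (25)", "Population (PC)", "Percent change in sleep"} <= set(post.table.term)
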