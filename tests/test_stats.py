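import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from osteoquant import stats as S
from osteoquant.synthetic import CohortSpec, gen_cohort


def brute_force_wmw_p(x, y):
    """Independent oracle: enumerate every labeling of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled, method="average")
    nx = len(x)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    center = nx * len(y) / 2
    stats = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        u = ranks[list(combo)].sum() - nx * (nx + 1) / 2
        stats.append(u)
    stats = np.asarray(stats)
    eps = 1e-9
    p_low = np.mean(stats <= u_obs + eps)
    p_high = np.mean(stats >= u_obs - eps)
    return min(1.0, 2 * min(p_low, p_high))


class TestWMW:
    def test_fully_separated_5_vs_8(self):
        x = [10.0, 11, 12, 13, 14]
        y = [1.0, 2, 3, 4, 5, 6, 7, 8]
        u, p = S.wilcoxon_mann_whitney(x, y)
        assert u == 40.0
        assert p == pytest.approx(2 / math.comb(13, 5), rel=1e-12)
        assert p == pytest.approx(0.0016, abs=5e-5)

    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0]
        _, p = S.wilcoxon_mann_whitney(x, x)
        assert p == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, p = S.wilcoxon_mann_whitney(x, y)
            assert p == pytest.approx(brute_force_wmw_p(x, y), rel=1e-12)

    def test_matches_oracle_with_ties(self, rng):
        for _ in range(10):
            x = rng.integers(0, 4, size=5).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            _, p = S.wilcoxon_mann_whitney(x, y)
            assert p == pytest.approx(brute_force_wmw_p(x, y), rel=1e-12)

    def test_matches_scipy_exact_no_ties(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=7)
        _, p = S.wilcoxon_mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(float(ref), rel=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            S.wilcoxon_mann_whitney([1.0], [2.0, 3.0])


class TestPercentDifference:
    @pytest.mark.parametrize(
        "treated,control,expected",
        [
            (9.90, 5.00, 98),       # HbA1c
            (354.50, 236.50, 50),   # Tb.Sp
            (1.48, 2.06, -28),      # Tt.Ar
            (5.0, 5.0, 0),
        ],
    )
    def test_printed_values(self, treated, control, expected):
        assert S.round_half_away(S.percent_difference(treated, control)) == expected

    def test_half_away_from_zero(self):
        assert S.round_half_away(2.5) == 3
        assert S.round_half_away(-2.5) == -3
        assert S.round_half_away(2.4) == 2

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            S.percent_difference(1.0, 0.0)


class TestLMM:
    def test_balanced_two_group_equals_mean_difference(self):
        # no replicates, no covariates: genotype estimate = difference of means
        rng = np.random.default_rng(1)
        rows = []
        for g, mean in (("A", 10.0), ("B", 13.0)):
            for i in range(6):
                rows.append(
                    {"mouse": f"{g}{i}", "genotype": g,
                     "y": mean + rng.normal(), "quadrant": "AL",
                     "region": "endosteal", "microstructure": "lamellar"}
                )
        df = pd.DataFrame(rows)
        fit = S.fit_lmm(df, "y", fixed=["genotype"], nested=())
        obs_diff = df[df.genotype == "B"].y.mean() - df[df.genotype == "A"].y.mean()
        est = fit.fixed_effects.loc["C(genotype)[T.B]", "estimate"]
        assert est == pytest.approx(obs_diff, rel=1e-6)

    def test_zero_variance_collapses_to_ols(self):
        spec = CohortSpec(
            hierarchy_variances={"mouse": 0.0, "quadrant": 0.0, "region": 0.0,
                                 "residual": 1.0},
        )
        cohort = gen_cohort(spec, seed=3)
        df = cohort.merged()
        fit = S.fit_lmm(df, "E_s", fixed=["genotype"], nested=())
        import statsmodels.formula.api as smf

        ols = smf.ols("E_s ~ C(genotype)", data=df).fit()
        est = fit.fixed_effects.loc["C(genotype)[T.TallyHO]", "estimate"]
        assert est == pytest.approx(ols.params["C(genotype)[T.TallyHO]"], rel=1e-3)

    def test_identical_replicates_when_all_variances_zero(self):
        spec = CohortSpec(
            hierarchy_variances={"mouse": 0.0, "quadrant": 0.0, "region": 0.0,
                                 "residual": 0.0},
        )
        cohort = gen_cohort(spec, seed=4)
        per_mouse_sd = cohort.points.groupby("mouse")["E_s"].std()
        assert (per_mouse_sd.fillna(0) < 1e-12).all()

    @pytest.mark.slow
    def test_genotype_ci_coverage(self):
        # 95% containment-t intervals cover the true effect 93-97 times in 100
        spec = CohortSpec()
        truth = (
            spec.outcomes["E_s"].mean_diabetic - spec.outcomes["E_s"].mean_control
        )
        covered = 0
        for i in range(100):
            cohort = gen_cohort(spec, seed=1000 + i)
            fit = S.fit_lmm(cohort.merged(), "E_s")
            row = fit.fixed_effects.loc["C(genotype)[T.TallyHO]"]
            covered += bool(row.ci_low <= truth <= row.ci_high)
        assert 93 <= covered <= 97


class TestTukey:
    def test_two_levels_equals_t_test(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        df = pd.DataFrame(
            {"y": np.concatenate([a, b]), "g": ["a"] * 30 + ["b"] * 30}
        )
        res = S.tukey_hsd(df, "y", "g")
        t_p = sps.ttest_ind(a, b).pvalue
        assert res.p_adj.iloc[0] == pytest.approx(t_p, rel=1e-6)

    def test_three_groups_against_range_oracle(self, rng):
        groups = [rng.normal(m, 1, 40) for m in (0.0, 0.1, 2.0)]
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], 40),
            }
        )
        res = S.tukey_hsd(df, "y", "g").set_index(["level_a", "level_b"])
        # oracle: studentized-range p from the classical formula
        n = 40
        dfw = 3 * (n - 1)
        msw = np.mean([np.var(g, ddof=1) for g in groups])
        for (la, lb), row in res.iterrows():
            ga = groups["abc".index(la)]
            gb = groups["abc".index(lb)]
            q = abs(ga.mean() - gb.mean()) / np.sqrt(msw / n)
            p_oracle = sps.studentized_range.sf(q, 3, dfw)
            assert row.p_adj == pytest.approx(p_oracle, abs=1e-6)

    def test_identical_groups_large_p(self, rng):
        y = rng.normal(size=60)
        df = pd.DataFrame({"y": y, "g": np.repeat(["a", "b", "c"], 20)})
        df["y"] = np.tile(y[:20], 3)
        res = S.tukey_hsd(df, "y", "g")
        assert (res.p_adj > 0.99).all()


class TestLevene:
    def test_identical_groups_w_zero(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        w, p = S.levene([g, g.copy()])
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_unequal_variances_detected(self):
        detections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 3, 50)
            _, p = S.levene([a, b])
            detections += p < 0.01
        assert detections >= 19

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            S.levene([np.arange(5.0)])


class TestLinreg:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = S.linreg(x, 2 * x + 1)
        assert res["R2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)
        assert res["p"] < 1e-10

    def test_null_slope_coverage(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            res = S.linreg(x, y)
            hits += abs(res["slope"]) <= 2 * res["stderr"]
        assert hits >= 93

    def test_two_points_degenerate_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = S.linreg([0.0, 1.0], [0.0, 1.0])
        assert res["R2"] == pytest.approx(1.0)


class TestAncova:
    def test_equal_slopes_interaction_near_zero(self, rng):
        n = 100
        x = rng.normal(size=2 * n)
        g = np.repeat(["a", "b"], n)
        y = 2 * x + np.where(g == "a", 0.0, 1.0) + rng.normal(0, 0.5, 2 * n)
        res = S.ancova_slopes(x, y, g)
        assert abs(res["interaction_estimate"]) <= 2 * res["interaction_se"]

    def test_different_slopes_detected(self, rng):
        n = 60
        x = rng.normal(size=2 * n)
        g = np.repeat(["a", "b"], n)
        slope = np.where(g == "a", 1.0, 3.0)
        y = slope * x + rng.normal(0, 0.5, 2 * n)
        res = S.ancova_slopes(x, y, g)
        assert res["interaction_p"] < 0.01

    def test_tiny_group_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            S.ancova_slopes([1, 2, 3, 4], [1, 2, 3, 4], ["a", "a", "a", "b"])


class TestStepwiseAICc:
    def test_aicc_limit_equals_aic(self):
        # AICc - AIC = 2k(k+1)/(n-k-1) -> 0 as n grows
        n, k = 100_000, 3
        assert 2 * k * (k + 1) / (n - k - 1) < 0.01

    @staticmethod
    def _ductility_like(seed, n=13, r2_target=0.83):
        rng = np.random.default_rng(seed)
        cry = rng.normal(0.0595, 0.0002, n)
        col = rng.normal(1.55, 0.02, n)
        signal = -124.73 * cry - 1.3 * col
        noise_sd = np.std(signal) * np.sqrt(1 / r2_target - 1)
        y = 0.97 + signal + rng.normal(0, noise_sd, n)
        return pd.DataFrame(
            {
                "y": y, "crystallinity": cry, "collagen_maturity": col,
                "d1": rng.normal(size=n), "d2": rng.normal(size=n),
                "d3": rng.normal(size=n),
            }
        )

    @pytest.mark.slow
    def test_true_pair_recovered(self):
        # support recovery: the selected model contains both true predictors
        hits = 0
        exact = 0
        for seed in range(100):
            df = self._ductility_like(seed)
            res = S.stepwise_aicc(
                df, "y",
                ["crystallinity", "collagen_maturity", "d1", "d2", "d3"],
            )
            hits += {"crystallinity", "collagen_maturity"} <= set(res.selected)
            exact += set(res.selected) == {"crystallinity", "collagen_maturity"}
        assert hits >= 80
        assert exact >= 60  # decoys are usually eliminated too

    @pytest.mark.slow
    def test_selection_frequency_nondecreasing_in_n(self):
        freqs = []
        for n in (13, 60):
            hit = 0
            for seed in range(40):
                df = self._ductility_like(seed, n=n)
                res = S.stepwise_aicc(
                    df, "y",
                    ["crystallinity", "collagen_maturity", "d1", "d2", "d3"],
                )
                hit += {"crystallinity", "collagen_maturity"} <= set(res.selected)
            freqs.append(hit)
        assert freqs[1] >= freqs[0]

    def test_pure_noise_selects_intercept_majority(self):
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(20, 4)), columns=["y", "a", "b", "c"])
            res = S.stepwise_aicc(df, "y", ["a", "b", "c"])
            wins += len(res.selected) == 0
        assert wins > 20

    def test_aicc_trace_minimal(self):
        df = self._ductility_like(0)
        res = S.stepwise_aicc(df, "y", ["crystallinity", "collagen_maturity", "d1"])
        visited = [a for _, a in res.trace]
        assert res.aicc <= min(visited) + 1e-9


class TestGlucose:
    def test_constant_mean(self):
        mean, missing = S.lifetime_average_glucose([200.0] * 16)
        assert mean == 200.0 and missing == 0

    def test_arithmetic_series(self):
        mean, _ = S.lifetime_average_glucose(np.arange(100.0, 260.0, 10.0))
        assert mean == pytest.approx(175.0)

    def test_missing_weeks_skipped(self):
        mean, missing = S.lifetime_average_glucose([100.0, np.nan, 200.0])
        assert mean == pytest.approx(150.0) and missing == 1

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            S.lifetime_average_glucose([np.nan, np.nan])


class TestInclusionFilter:
    @staticmethod
    def _glucose_table(values_by_mouse, genotypes):
        rows = []
        for mouse, vals in values_by_mouse.items():
            for week, v in enumerate(vals, 1):
                rows.append(
                    {"mouse": mouse, "genotype": genotypes[mouse],
                     "week": week, "glucose": v}
                )
        return pd.DataFrame(rows)

    def test_low_glucose_diabetics_excluded(self):
        values = {f"T{i}": [300.0] * 4 for i in range(10)}
        values["T0"] = [300.0, 240.0, 300.0, 300.0]
        values["T1"] = [240.0, 300.0, 300.0, 300.0]
        genotypes = {m: "TallyHO" for m in values}
        table = self._glucose_table(values, genotypes)
        keep = S.diabetic_inclusion_filter(table)
        assert len(keep) == 8
        assert "T0" not in keep and "T1" not in keep

    def test_zero_threshold_keeps_all(self):
        values = {"T0": [100.0], "T1": [50.0]}
        genotypes = {m: "TallyHO" for m in values}
        table = self._glucose_table(values, genotypes)
        assert len(S.diabetic_inclusion_filter(table, threshold=0.0)) == 2

    def test_controls_never_excluded(self):
        values = {"C0": [100.0] * 4, "T0": [300.0] * 4}
        genotypes = {"C0": "C57Bl/6J", "T0": "TallyHO"}
        table = self._glucose_table(values, genotypes)
        keep = S.diabetic_inclusion_filter(table)
        assert "C0" in keep and "T0" in keep


class TestMassAdjustmentInteraction:
    def test_adjustment_preserves_percent_difference_when_mass_independent(self, rng):
        # slope 0: adjusting cannot move the group means (beyond noise in slopes)
        from osteoquant.flexural import mass_adjust

        n = 500
        genotype = np.array(["C57Bl/6J"] * n + ["TallyHO"] * n)
        mass = np.concatenate([rng.normal(33.8, 3.3, n), rng.normal(38.8, 7.4, n)])
        y = np.concatenate([rng.normal(10, 1, n), rng.normal(12, 1, n)])
        adj = mass_adjust(y, mass, genotype)
        pct_raw = S.percent_difference(y[n:].mean(), y[:n].mean())
        pct_adj = S.percent_difference(adj[n:].mean(), adj[:n].mean())
        assert pct_adj == pytest.approx(pct_raw, abs=1.0)
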