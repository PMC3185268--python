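import numpy as np
import pytest

from triageiv import instruments as ins
from triageiv import synthetic_data as sd
from triageiv.benchmarks import balance_study_config
from triageiv.glm_core import fit_linear

from conftest import make_cohort, two_by_two_cohort


class TestStandardizedDifference:
    def test_equal_means_give_zero(self, rng):
        a = rng.normal(5, 2, 50)
        b = a + 0.0
        assert ins.standardized_difference(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_unit_separation_gives_one(self):
        # means 1 vs 0, both sample SDs exactly 1 -> pooled sqrt((1+1)/2) = 1
        half = np.sqrt(0.5)
        a = np.array([1 - half, 1 + half])
        b = np.array([-half, half])
        assert ins.standardized_difference(a, b, kind="continuous") == pytest.approx(1.0)

    def test_binary_hand_computation(self):
        # proportions 0.6 vs 0.5 -> 0.1 / sqrt((0.24 + 0.25)/2)
        a = np.repeat([1, 0], [6, 4])
        b = np.repeat([1, 0], [5, 5])
        expected = 0.1 / np.sqrt((0.24 + 0.25) / 2)
        assert ins.standardized_difference(a, b) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.20203, abs=1e-4)

    def test_zero_spread_is_undefined(self):
        d = ins.standardized_difference([1.0, 1.0, 1.0], [2.0, 2.0], kind="continuous")
        assert np.isnan(d)

    def test_sign_is_group1_minus_group0(self):
        d = ins.standardized_difference([2.0, 3.0], [0.0, 1.0], kind="continuous")
        assert d > 0


class TestFirstStageStrength:
    def test_six_row_closed_form(self):
        """Bivariate OLS computed by hand: X=(0,0,1,1,1,1) on Z=(0,0,0,1,1,1)
        gives slope 2/3, se 1/3, t=2, F=4, partial r2 = 4/(4+4)."""
        cohort = make_cohort(
            treatment=[0, 0, 1, 1, 1, 1],
            outcome=[0, 1, 0, 1, 0, 1],
            instruments={"z": [0, 0, 0, 1, 1, 1]},
        )
        s = ins.first_stage_strength(cohort, "z")
        assert s.coefficient == pytest.approx(2 / 3, abs=1e-12)
        assert s.coefficient_se == pytest.approx(1 / 3, abs=1e-12)
        assert s.partial_f == pytest.approx(4.0, abs=1e-10)
        assert s.partial_r2 == pytest.approx(0.5, abs=1e-10)
        assert s.df_resid == 4

    def test_partial_f_equals_nested_model_anova_f(self, rng):
        """Single-instrument partial F must equal the sum-of-squares F from
        comparing the first-stage model with and without the instrument."""
        for _ in range(10):
            n = 40
            w = rng.normal(size=(n, 2))
            z = rng.binomial(1, 0.5, n)
            x = (rng.random(n) < 0.3 + 0.3 * z).astype(int)
            cohort = make_cohort(
                x, rng.binomial(1, 0.5, n),
                covariates={"w1": w[:, 0], "w2": w[:, 1]},
                instruments={"z": z},
            )
            s = ins.first_stage_strength(cohort, "z", ("w1", "w2"))
            full = fit_linear(np.column_stack([z, w]), x)
            reduced = fit_linear(w, x)
            rss_full = np.sum((x - full.fitted_values) ** 2)
            rss_red = np.sum((x - reduced.fitted_values) ** 2)
            df = n - 4
            f_anova = (rss_red - rss_full) / (rss_full / df)
            assert s.partial_f == pytest.approx(f_anova, abs=1e-8)

    def test_partial_r2_equals_squared_partial_correlation(self, rng):
        """Brute-force oracle: correlate the residuals of X~W and Z~W."""
        n = 60
        w = rng.normal(size=(n, 1))
        z = rng.binomial(1, 0.5, n).astype(float)
        x = (rng.random(n) < 0.3 + 0.3 * z).astype(int)
        cohort = make_cohort(
            x, rng.binomial(1, 0.5, n), covariates={"w": w[:, 0]},
            instruments={"z": z},
        )
        s = ins.first_stage_strength(cohort, "z", ("w",))
        rx = x - fit_linear(w, x).fitted_values
        rz = z - fit_linear(w, z).fitted_values
        r = np.corrcoef(rx, rz)[0, 1]
        assert s.partial_r2 == pytest.approx(r * r, abs=1e-10)

    def test_useless_instrument_has_near_zero_strength(self, rng):
        n = 20_000
        z = rng.binomial(1, 0.5, n)
        x = rng.binomial(1, 0.6, n)
        cohort = make_cohort(x, rng.binomial(1, 0.3, n), instruments={"z": z})
        s = ins.first_stage_strength(cohort, "z")
        assert s.partial_r2 < 0.001


class TestInstrumentTreatmentOr:
    def test_cross_product_ratio(self):
        cohort = two_by_two_cohort(
            {(1, 1, 0): 80, (1, 0, 0): 20, (0, 1, 0): 60, (0, 0, 0): 40}
        )
        # outcome degenerate is fine here: only X~Z fitted
        oratio, lo, hi = ins.instrument_treatment_or(cohort, "z")
        assert oratio == pytest.approx((80 * 40) / (20 * 60), abs=1e-6)
        assert lo < oratio < hi

    def test_independent_z_gives_unit_or(self, rng):
        n = 30_000
        z = rng.binomial(1, 0.5, n)
        x = rng.binomial(1, 0.7, n)
        cohort = make_cohort(x, rng.binomial(1, 0.3, n), instruments={"z": z})
        oratio, lo, hi = ins.instrument_treatment_or(cohort, "z")
        assert oratio == pytest.approx(1.0, abs=0.1)

    def test_ci_widens_as_counts_shrink(self):
        big = two_by_two_cohort(
            {(1, 1, 0): 800, (1, 0, 0): 200, (0, 1, 0): 600, (0, 0, 0): 400}
        )
        small = two_by_two_cohort(
            {(1, 1, 0): 80, (1, 0, 0): 20, (0, 1, 0): 60, (0, 0, 0): 40}
        )
        _, lo_b, hi_b = ins.instrument_treatment_or(big, "z")
        _, lo_s, hi_s = ins.instrument_treatment_or(small, "z")
        assert np.log(hi_s) - np.log(lo_s) > np.log(hi_b) - np.log(lo_b)


class TestDichotomize:
    def _country_cohort(self):
        # country A: admission 0.70 (7/10); country B: 0.90 (9/10)
        x = [1] * 7 + [0] * 3 + [1] * 9 + [0] * 1
        country = ["A"] * 10 + ["B"] * 10
        cohort = make_cohort(x, [0, 1] * 10)
        cohort.data["country"] = country
        return cohort

    def test_threshold_085_splits_countries(self):
        cohort = self._country_cohort()
        col = ins.dichotomize_by_group_rate(cohort, "country", threshold=0.85)
        assert col.name == "country_high_rate"
        by_country = dict(zip(cohort.data["country"], col))
        assert by_country == {"A": 0, "B": 1}

    def test_all_groups_above_threshold_warns_degenerate(self):
        cohort = self._country_cohort()
        with pytest.warns(UserWarning, match="degenerate"):
            col = ins.dichotomize_by_group_rate(cohort, "country", threshold=0.5)
        assert col.nunique() == 1

    def test_even_split_threshold_balances_group_sizes(self, rng):
        # three groups of sizes 30/30/40 with rates 0.5/0.7/0.9: the most even
        # 2-way split puts the 40-patient group alone (40 vs 60)
        x = np.concatenate([
            rng.binomial(1, 0.5, 30) * 0 + ([1] * 15 + [0] * 15),
            [1] * 21 + [0] * 9,
            [1] * 36 + [0] * 4,
        ])
        cohort = make_cohort(x, [0, 1] * 50)
        cohort.data["country"] = ["A"] * 30 + ["B"] * 30 + ["C"] * 40
        thr = ins.even_split_threshold(cohort, "country")
        col = ins.dichotomize_by_group_rate(cohort, "country", threshold=thr)
        assert col.sum() == 40  # group C alone


class TestEvaluateCandidates:
    def test_strong_candidate_ranks_before_weak(self, rng):
        n = 3000
        z_strong = rng.binomial(1, 0.5, n)
        z_noise = rng.binomial(1, 0.5, n)
        x = (rng.random(n) < 0.3 + 0.4 * z_strong).astype(int)
        cohort = make_cohort(
            x, rng.binomial(1, 0.3, n),
            covariates={"w": rng.normal(size=n)},
            instruments={"z_strong": z_strong, "z_noise": z_noise},
        )
        reports = ins.evaluate_candidates(cohort, ["z_noise", "z_strong"], ("w",))
        assert reports[0].name == "z_strong"
        assert not reports[0].weak and reports[1].weak

    def test_balance_breaks_ties_between_strong_candidates(self, rng):
        """Two candidates of similar strength: the one unrelated to the
        covariates (smaller residual imbalance by IV) ranks first."""
        n = 6000
        w = rng.normal(size=n)
        z_clean = rng.binomial(1, 0.5, n)
        z_dirty = (rng.random(n) < 1 / (1 + np.exp(-(0.0 + 1.2 * w)))).astype(int)
        lp = -0.5 + 1.0 * z_clean + 1.0 * z_dirty + 0.3 * w
        x = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        cohort = make_cohort(
            x, rng.binomial(1, 0.3, n), covariates={"w": w},
            instruments={"z_clean": z_clean, "z_dirty": z_dirty},
        )
        reports = ins.evaluate_candidates(cohort, ["z_dirty", "z_clean"], ("w",))
        assert all(not r.weak for r in reports)
        assert reports[0].name == "z_clean"
        assert reports[0].mean_abs_d_by_iv < reports[1].mean_abs_d_by_iv

    def test_true_instrument_beats_noise_in_simulation(self):
        wins = 0
        for rep in range(20):
            cfg = balance_study_config(seed=4000 + rep)
            cohort = sd.simulate_cohort(cfg)
            rng = np.random.default_rng(rep)
            cohort.data["pure_noise"] = rng.binomial(1, 0.5, cohort.n)
            reports = ins.evaluate_candidates(
                cohort, ["pure_noise", "practice_pattern"], cfg.covariate_names
            )
            wins += reports[0].name == "practice_pattern"
        assert wins >= 18

    def test_randomized_instrument_balances_covariates_at_scale(self):
        """Stratifying by a valid instrument balances covariates; stratifying
        by the confounded treatment does not."""
        cfg = balance_study_config(seed=99, n_patients=30_000)
        cohort = sd.simulate_cohort(cfg)
        rep = ins.evaluate_instrument(cohort, "practice_pattern", cfg.covariate_names)
        assert rep.mean_abs_d_by_iv < 0.05
        assert rep.mean_abs_d_by_treatment > 0.15
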