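import itertools

import numpy as np
import pytest

from triageiv import propensity as ps
from triageiv import synthetic_data as sd
from triageiv.benchmarks import balance_study_config
from triageiv.errors import TriageIVError

from conftest import make_cohort


def cohort_with_scores(treatment, logit_ps, caliper):
    """Cohort plus a hand-built PropensityFit with prescribed logit scores."""
    n = len(treatment)
    cohort = make_cohort(treatment, [0, 1] * (n // 2) + [0] * (n % 2))
    lps = np.asarray(logit_ps, dtype=float)
    fit = ps.PropensityFit(
        model=None, ps=1 / (1 + np.exp(-lps)), logit_ps=lps,
        caliper=caliper, covariate_names=(),
    )
    return cohort, fit


class TestCaliper:
    def test_hand_computed_sample_sd(self):
        # SD of {-1, 0, 1, 2} with n-1 denominator is sqrt(5/3) = 1.29099
        assert ps.caliper_from_logit_ps([-1, 0, 1, 2]) == pytest.approx(
            0.2 * 1.29099, abs=1e-4
        )

    def test_degenerate_scores_hit_floor(self):
        assert ps.caliper_from_logit_ps([0.3, 0.3, 0.3]) == ps.MIN_CALIPER

    def test_independent_treatment_gives_flat_score(self, rng):
        n = 2000
        cohort = make_cohort(
            rng.binomial(1, 0.6, n), rng.binomial(1, 0.3, n),
            covariates={"w": rng.normal(size=n)},
        )
        fit = ps.fit_propensity(cohort, ("w",))
        assert fit.ps.std() < 0.05
        assert np.allclose(fit.ps.mean(), 0.6, atol=0.05)

    def test_confounded_cohort_score_discriminates_arms(self):
        cfg = balance_study_config(seed=11)
        cohort = sd.simulate_cohort(cfg)
        fit = ps.fit_propensity(cohort, cfg.covariate_names)
        x = cohort.treatment
        assert fit.ps[x == 1].mean() > fit.ps[x == 0].mean()


class TestMatching:
    def test_single_pair_within_caliper(self):
        cohort, fit = cohort_with_scores([1, 0], [0.0, 0.1], caliper=0.26)
        matched = ps.match_without_replacement(fit, cohort, seed=0)
        assert matched.pairs == [(0, 1)]
        assert matched.n_unmatched_treated == 0

    def test_no_pairs_outside_caliper(self):
        cohort, fit = cohort_with_scores([1, 1, 0, 0], [0, 0, 5, 5], caliper=0.26)
        matched = ps.match_without_replacement(fit, cohort, seed=0)
        assert matched.n_pairs == 0
        assert matched.n_unmatched_treated == 2
        assert matched.n_unmatched_control == 2

    def test_matches_exhaustive_greedy_oracle_on_all_orders(self):
        """The seeded greedy matcher must land in the set of outcomes produced
        by brute-force greedy matching over every processing order."""
        treatment = [0, 0, 1, 1, 1]
        lps = [0.05, 0.42, 0.0, 0.4, 0.5]
        caliper = 0.30
        cohort, fit = cohort_with_scores(treatment, lps, caliper)

        minority = [i for i, t in enumerate(treatment) if t == 0]
        majority = [i for i, t in enumerate(treatment) if t == 1]
        oracle_outcomes = set()
        for order in itertools.permutations(minority):
            used, pairs = set(), []
            for i in order:
                best, best_d = None, None
                for j in majority:
                    if j in used:
                        continue
                    d = abs(lps[i] - lps[j])
                    if d <= caliper and (best_d is None or d < best_d or (d == best_d and j < best)):
                        best, best_d = j, d
                if best is not None:
                    used.add(best)
                    pairs.append((best, i))  # (treated, control)
            oracle_outcomes.add(frozenset(pairs))

        for seed in range(12):
            matched = ps.match_without_replacement(fit, cohort, seed=seed)
            assert frozenset(matched.pairs) in oracle_outcomes

    def test_no_reuse_and_all_pairs_within_caliper(self):
        cfg = balance_study_config(seed=21)
        cohort = sd.simulate_cohort(cfg)
        fit = ps.fit_propensity(cohort, cfg.covariate_names)
        matched = ps.match_without_replacement(fit, cohort, seed=5)
        ids = matched.matched_ids()
        assert len(ids) == len(set(ids))
        lps = dict(zip(cohort.patient_id, fit.logit_ps))
        for t, c in matched.pairs:
            assert abs(lps[t] - lps[c]) <= matched.caliper_used + 1e-12

    def test_pair_count_monotone_in_caliper(self):
        cfg = balance_study_config(seed=31)
        cohort = sd.simulate_cohort(cfg)
        counts = []
        for mult in (0.05, 0.2, 1.0):
            fit = ps.fit_propensity(cohort, cfg.covariate_names, caliper_multiplier=mult)
            counts.append(ps.match_without_replacement(fit, cohort, seed=1).n_pairs)
        assert counts == sorted(counts)

    def test_identical_score_multisets_match_every_minority_patient(self):
        lps = [0.1, 0.5, 0.9, 0.1, 0.5, 0.9, 1.4]
        treatment = [1, 1, 1, 0, 0, 0, 1]
        cohort, fit = cohort_with_scores(treatment, lps, caliper=0.2)
        matched = ps.match_without_replacement(fit, cohort, seed=7)
        assert matched.n_pairs == 3  # whole minority (controls) matched
        assert matched.n_unmatched_control == 0

    def test_deterministic_given_seed(self):
        cfg = balance_study_config(seed=41)
        cohort = sd.simulate_cohort(cfg)
        fit = ps.fit_propensity(cohort, cfg.covariate_names)
        a = ps.match_without_replacement(fit, cohort, seed=9)
        b = ps.match_without_replacement(fit, cohort, seed=9)
        assert a.pairs == b.pairs


class TestMatchedEffect:
    def _matched_cohort(self, rate1, rate0, n_per_arm):
        k1, k0 = int(rate1 * n_per_arm), int(rate0 * n_per_arm)
        x = [1] * n_per_arm + [0] * n_per_arm
        y = [1] * k1 + [0] * (n_per_arm - k1) + [1] * k0 + [0] * (n_per_arm - k0)
        cohort = make_cohort(x, y)
        pairs = [(i, i + n_per_arm) for i in range(n_per_arm)]
        matched = ps.MatchedCohort(pairs, 0.2, 0, 0)
        return cohort, matched

    def test_identical_rates_give_null_effect(self):
        cohort, matched = self._matched_cohort(0.3, 0.3, 100)
        assert ps.matched_effect(cohort, matched, "OR").point == pytest.approx(1.0, abs=1e-8)
        assert ps.matched_effect(cohort, matched, "RD").point == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_on_proportions(self):
        cohort, matched = self._matched_cohort(0.30, 0.25, 200)
        rd = ps.matched_effect(cohort, matched, "RD")
        orr = ps.matched_effect(cohort, matched, "OR")
        assert rd.point == pytest.approx(0.05, abs=1e-12)
        assert orr.point == pytest.approx((0.30 / 0.70) / (0.25 / 0.75), abs=1e-6)
        assert rd.ci_low < 0.05 < rd.ci_high

    def test_too_few_pairs_rejected(self):
        cohort, matched = self._matched_cohort(0.5, 0.5, 2)
        matched.pairs = matched.pairs[:1]
        with pytest.raises(TriageIVError):
            ps.matched_effect(cohort, matched, "RD")


class TestBalanceTable:
    def test_identical_groups_are_balanced(self, rng):
        w = rng.normal(size=50)
        cohort = make_cohort(
            [1] * 50 + [0] * 50, rng.binomial(1, 0.3, 100), covariates={"w": np.tile(w, 2)}
        )
        # same covariate multiset in both arms by construction
        table = ps.balance_table(cohort, ("w",))
        assert abs(table.loc["w", "standardized_difference"]) < 1e-12

    def test_matching_reduces_imbalance(self):
        cfg = balance_study_config(seed=51)
        cohort = sd.simulate_cohort(cfg)
        fit = ps.fit_propensity(cohort, cfg.covariate_names)
        matched = ps.match_without_replacement(fit, cohort, seed=3)
        pre = ps.balance_table(cohort, cfg.covariate_names)
        post = ps.balance_table(cohort, cfg.covariate_names, matched=matched)
        from triageiv.instruments import mean_abs_d

        assert mean_abs_d(post) < mean_abs_d(pre)
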