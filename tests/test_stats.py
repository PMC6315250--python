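"""Trial statistics: transform, mixed model, power, t-tests, exact test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from ergoload.errors import DesignError
from ergoload.simulate import TrialScenario, generate_trial
from ergoload.stats import (
    apply_design_effect,
    baseline_tests,
    fisher_exact_rxc,
    fit_itt_model,
    log_transform_outcome,
    power_sample_size,
    validate_trial_dataset,
)
from oracles import fisher_p_by_product_enumeration, power_by_simulation


class TestLogTransform:
    def test_zero_maps_to_zero(self):
        y, meta = log_transform_outcome([0])
        assert y[0] == 0.0 and meta["offset"] == 1

    def test_typical_count(self):
        y, _ = log_transform_outcome([180])
        assert y[0] == pytest.approx(np.log(181.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform_outcome([-1])


class TestPower:
    def test_trial_sample_size(self):
        """20 % reduction, 20 % SD, alpha 5 %, power 80 % -> 17 per group."""
        assert power_sample_size(20, 20, 0.05, 0.80) == 17

    def test_large_effect_floor(self):
        assert power_sample_size(1e6, 1.0, 0.05, 0.80) == 2

    def test_higher_power_against_simulation(self):
        n = power_sample_size(20, 20, 0.05, 0.90)
        rng = np.random.default_rng(0)
        # Monte-Carlo power curve: n achieves 90 %, n-1 does not
        assert power_by_simulation(n, 20, 20, 0.05, rng) >= 0.895
        assert power_by_simulation(n - 1, 20, 20, 0.05, rng) < 0.90

    def test_monotonicity(self):
        assert power_sample_size(30, 20) <= power_sample_size(20, 20)
        assert power_sample_size(20, 30) >= power_sample_size(20, 20)
        assert power_sample_size(20, 20, 0.01) >= power_sample_size(20, 20, 0.05)
        assert power_sample_size(20, 20, 0.05, 0.9) >= power_sample_size(20, 20, 0.05, 0.8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_sample_size(-1, 20)
        with pytest.raises(ValueError):
            power_sample_size(20, 20, alpha=1.5)


class TestDesignEffect:
    def test_trial_inflation(self):
        assert apply_design_effect(17, 1.5) == 26

    def test_identity(self):
        assert apply_design_effect(10, 1.0) == 10

    def test_ceiling(self):
        assert apply_design_effect(10, 1.25) == 13

    def test_invalid(self):
        with pytest.raises(ValueError):
            apply_design_effect(1, 1.5)
        with pytest.raises(ValueError):
            apply_design_effect(10, 0.9)


def two_arm_baseline(a_vals, b_vals):
    rows = []
    for i, v in enumerate(a_vals):
        rows.append({"subject": f"a{i}", "cluster": "ca", "arm": "intervention",
                     "time": "baseline", "log_events": 1.0, "age": v})
    for i, v in enumerate(b_vals):
        rows.append({"subject": f"b{i}", "cluster": "cb", "arm": "control",
                     "time": "baseline", "log_events": 1.0, "age": v})
    return pd.DataFrame(rows)


def standardized(n, mean, sd, seed):
    x = np.random.default_rng(seed).normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestBaselineTests:
    def test_identical_arms(self):
        d = two_arm_baseline([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        row = baseline_tests(d, ["age"]).iloc[0]
        assert row.t == pytest.approx(0.0) and row.p == pytest.approx(1.0)

    def test_pooled_t_closed_form(self):
        """Means 34.2 vs 41.2, common SD 12.5, n 32 vs 48: t = 7 / (12.5 sqrt(1/32+1/48))."""
        a = standardized(48, 41.2, 12.5, 1)
        b = standardized(32, 34.2, 12.5, 2)
        row = baseline_tests(two_arm_baseline(b, a), ["age"]).iloc[0]
        expected = 7.0 / (12.5 * np.sqrt(1 / 32 + 1 / 48))
        assert abs(row.t) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(2.45, abs=0.01)

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 25)
        row = baseline_tests(two_arm_baseline(a, b), ["age"], welch=True).iloc[0]
        # arms are ordered alphabetically (control first) in the output
        t, p = spstats.ttest_ind(b, a, equal_var=False)
        assert row.t == pytest.approx(t) and row.p == pytest.approx(p)

    def test_tiny_arm_rejected(self):
        with pytest.raises(DesignError):
            baseline_tests(two_arm_baseline([1.0], [1.0, 2.0]), ["age"])


class TestFisherExact:
    def test_diagonal_2x2(self):
        assert fisher_exact_rxc([[5, 0], [0, 5]]) == pytest.approx(2 / 252, rel=1e-9)

    def test_identical_rows_p_one(self):
        assert fisher_exact_rxc([[3, 4, 5], [3, 4, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_2x2_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 12, (2, 2))
        assert fisher_exact_rxc(t) == pytest.approx(spstats.fisher_exact(t)[1], rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_2x3_matches_product_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = rng.integers(0, 8, (2, 3))
        assert fisher_exact_rxc(t) == pytest.approx(fisher_p_by_product_enumeration(t), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_3x3_matches_product_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        t = rng.integers(0, 5, (3, 3))
        assert fisher_exact_rxc(t) == pytest.approx(fisher_p_by_product_enumeration(t), rel=1e-9)

    def test_p_in_unit_interval(self):
        assert 0 < fisher_exact_rxc([[40, 1], [1, 40]]) <= 1

    def test_enumeration_bounds_enforced(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            fisher_exact_rxc(np.ones((4, 2), dtype=int))
        with pytest.raises(ValueError, match="Monte-Carlo"):
            fisher_exact_rxc([[400, 200], [100, 50]])


def degenerate_trial():
    ts = TrialScenario(
        n_clusters_per_arm=3, cluster_size_range=(4, 4),
        sd_cluster=0.0, sd_subject=0.0, sd_residual=0.0, dropout={}, seed=0,
        beta={"intercept": 5.0, "time_fu1": 0.2, "time_fu2": 0.4,
              "arm": 0.1, "interaction_fu1": -0.3, "interaction_fu2": -0.5},
    )
    return generate_trial(ts)


class TestMixedModel:
    def test_degenerate_fit_equals_ols(self):
        """With all random-effect variances at zero the fixed effects are the
        ordinary least-squares solution (here: exact cell means)."""
        res = fit_itt_model(degenerate_trial())
        p = res.params
        assert res.singular  # variance components pinned at ~0 are flagged
        assert p["Intercept"] == pytest.approx(5.0, abs=1e-5)
        assert p[[k for k in p.index if "arm" in k and ":" not in k][0]] == pytest.approx(0.1, abs=1e-5)
        inter = sorted(k for k in p.index if ":" in k)
        assert p[inter[0]] == pytest.approx(-0.3, abs=1e-5)
        assert p[inter[1]] == pytest.approx(-0.5, abs=1e-5)

    def test_contrasts_are_lsmean_differences(self):
        res = fit_itt_model(degenerate_trial())
        assert res.between_group["fu1"][0] == pytest.approx(0.1 - 0.3, abs=1e-5)
        assert res.between_group["fu2"][0] == pytest.approx(0.1 - 0.5, abs=1e-5)
        assert res.within_group["control"]["fu2"][0] == pytest.approx(0.4, abs=1e-5)
        assert res.within_group["intervention"]["fu2"][0] == pytest.approx(-0.1, abs=1e-5)

    def test_parameter_recovery_moderate_noise(self):
        """Across a handful of replicates the interaction estimate centers on
        the truth and its 95 % CI covers it most of the time."""
        estimates, covered = [], 0
        for seed in range(10):
            ts = TrialScenario(
                n_clusters_per_arm=15, cluster_size_range=(6, 8),
                sd_cluster=0.2, sd_subject=0.4, sd_residual=0.5, seed=seed,
                beta={"intercept": 5.2, "time_fu1": 0.3, "time_fu2": 0.5,
                      "arm": 0.0, "interaction_fu1": -0.3, "interaction_fu2": -0.3},
            )
            res = fit_itt_model(generate_trial(ts))
            k = sorted(n for n in res.params.index if ":" in n)[1]  # arm x fu2
            estimates.append(res.params[k])
            lo, hi = res.conf_int.loc[k]
            covered += lo < -0.3 < hi
            assert 0 < res.vc["residual"] < 1.0
        assert np.mean(estimates) == pytest.approx(-0.3, abs=0.1)
        assert covered >= 8

    def test_adjusted_model_drops_constant_gender(self):
        ts = TrialScenario(seed=3)
        res = fit_itt_model(generate_trial(ts), adjusted=True)
        assert "gender" in res.dropped_covariates
        assert any("baseline_outcome" in k for k in res.params.index)
        assert res.adjusted and "baseline" not in res.between_group

    def test_missing_followups_still_fit(self):
        d = generate_trial(TrialScenario(seed=5, dropout={"fu1": 0.3, "fu2": 0.5}))
        res = fit_itt_model(d)
        assert res.n_obs < 3 * res.n_subjects
        assert np.isfinite(res.interaction_p)

    def test_too_few_clusters_rejected(self):
        d = generate_trial(TrialScenario(n_clusters_per_arm=1, seed=0))
        with pytest.raises(DesignError):
            fit_itt_model(d)

    def test_subject_in_two_arms_rejected(self):
        d = generate_trial(TrialScenario(seed=0))
        d.loc[d.index[-1], "subject"] = d.subject.iloc[0]
        with pytest.raises(DesignError):
            validate_trial_dataset(d)
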