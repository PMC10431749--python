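"""Behavioral summaries, mixed ANOVA, correlation z-tests, nested models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import patsim
from patsim.config import rng_for
from patsim.group import (
    cluster_behavior_correlation,
    compute_pr,
    fisher_z_test_two_correlations,
    mixed_anova_2x2,
    nested_model_comparison,
    pr_long,
)

from conftest import make_recognition_table
import oracles


class TestComputePr:
    def test_worked_example_rates(self):
        # 100 old (50 hits), 100 new (26 FAs): hit .50, FA .26, Pr .24
        t = make_recognition_table(hits=50, misses=50, fas=26, crs=74)
        out = compute_pr(t)
        assert out.loc["s1", "hit_rate"] == pytest.approx(0.50)
        assert out.loc["s1", "fa_rate"] == pytest.approx(0.26)
        assert out.loc["s1", "pr"] == pytest.approx(0.24)
        assert not out.loc["s1", "excluded"]

    def test_all_old_responses_pr_zero(self):
        t = make_recognition_table(hits=10, misses=0, fas=10, crs=0)
        out = compute_pr(t)
        assert out.loc["s1", "hit_rate"] == 1.0
        assert out.loc["s1", "fa_rate"] == 1.0
        assert out.loc["s1", "pr"] == 0.0

    def test_negative_pr_flagged_for_exclusion(self):
        t = make_recognition_table(hits=2, misses=8, fas=8, crs=2)
        assert compute_pr(t).loc["s1", "excluded"].item() is True

    def test_trial_order_invariance(self):
        t = make_recognition_table(hits=7, misses=3, fas=2, crs=8)
        shuffled = t.sample(frac=1.0, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(compute_pr(t), compute_pr(shuffled))

    def test_random_responses_give_pr_near_zero(self):
        rng = rng_for(0, "rand")
        n = 2000
        hits = int(rng.binomial(n, 0.5))
        fas = int(rng.binomial(n, 0.5))
        t = make_recognition_table(hits=hits, misses=n - hits,
                                   fas=fas, crs=n - fas)
        pr = compute_pr(t).loc["s1", "pr"]
        assert abs(pr) < 4 * np.sqrt(2 * 0.25 / n)

    def test_response_bias_is_old_response_rate(self):
        t = make_recognition_table(hits=6, misses=4, fas=2, crs=8)
        assert compute_pr(t).loc["s1", "response_bias"] == pytest.approx(0.4)


def _toy_pr_table(values):
    """4-subject, 2x2 long table; values keyed (group, subject, category)."""
    rows = []
    for (g, s, c), v in values.items():
        rows.append({"subject": s, "age_group": g, "category": c, "pr": v})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_hand_sum_of_squares(self):
        rng = rng_for(1, "anova")
        rows = {}
        for gi, g in enumerate(("young", "old")):
            for si in range(4):
                s = f"{g}{si}"
                for c in ("face", "house"):
                    rows[(g, s, c)] = rng.normal(0.3 + 0.1 * gi, 0.1)
        data = _toy_pr_table(rows)
        got = mixed_anova_2x2(data).set_index("effect")["F"]
        want = oracles.mixed_anova_ss(data)
        assert got["age_group"] == pytest.approx(want["F_age"], rel=1e-8)
        assert got["category"] == pytest.approx(want["F_category"], rel=1e-8)
        assert got["age_group:category"] == pytest.approx(
            want["F_interaction"], rel=1e-8
        )

    def test_equal_group_means_give_tiny_f(self):
        rows = {}
        for g in ("young", "old"):
            for si in range(3):
                for ci, c in enumerate(("face", "house")):
                    rows[(g, f"{g}{si}", c)] = 0.2 + 0.05 * ci + 0.01 * si
        got = mixed_anova_2x2(_toy_pr_table(rows)).set_index("effect")
        assert got.loc["age_group", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_incomplete_within_factor_rejected(self):
        data = _toy_pr_table({("young", "s1", "face"): 0.2,
                              ("young", "s2", "face"): 0.3,
                              ("young", "s2", "house"): 0.4,
                              ("old", "s3", "face"): 0.1,
                              ("old", "s3", "house"): 0.2})
        with pytest.raises(ValueError):
            mixed_anova_2x2(data)

    def test_null_interaction_rejected_at_nominal_rate(self):
        """Additive age effect, no interaction: interaction significant in
        at most ~nominal share of simulations."""
        rejections = 0
        n_sim = 40
        for seed in range(n_sim):
            rng = rng_for(seed, "anova_null")
            rows = {}
            for gi, g in enumerate(("young", "old")):
                for si in range(8):
                    s = f"{g}{si}"
                    subj_eff = rng.normal(0, 0.05)
                    for c in ("face", "house"):
                        rows[(g, s, c)] = (
                            0.25 + 0.08 * gi + subj_eff + rng.normal(0, 0.05)
                        )
            aov = mixed_anova_2x2(_toy_pr_table(rows)).set_index("effect")
            rejections += aov.loc["age_group:category", "p"] < 0.05
        assert rejections <= np.ceil(0.05 * n_sim + 3 * np.sqrt(0.05 * 0.95 * n_sim))


class TestFisherZTest:
    def test_equal_correlations_give_zero(self):
        assert fisher_z_test_two_correlations(0.5, 20, 0.5, 30) == 0.0

    def test_worked_example_value(self):
        # correlations 0.83 vs 0.42 at n = 35 each
        z = fisher_z_test_two_correlations(0.83, 35, 0.42, 35)
        assert z == pytest.approx(2.9617, abs=1e-3)

    def test_antisymmetry(self):
        a = fisher_z_test_two_correlations(0.7, 25, 0.3, 40)
        b = fisher_z_test_two_correlations(0.3, 40, 0.7, 25)
        assert a == pytest.approx(-b)

    def test_input_guards(self):
        with pytest.raises(ValueError):
            fisher_z_test_two_correlations(1.0, 20, 0.5, 20)
        with pytest.raises(ValueError):
            fisher_z_test_two_correlations(0.5, 3, 0.5, 20)


class TestNestedModels:
    @pytest.fixture(scope="class")
    def data(self):
        rng = rng_for(2, "nested")
        n = 60
        age = np.repeat([-0.5, 0.5], n // 2)
        x = rng.normal(size=n)
        y = 0.5 * age + 0.8 * x + rng.normal(size=n)
        return pd.DataFrame({"y": y, "age": age, "x": x,
                             "noise": rng.normal(size=n)})

    def test_partial_f_equals_squared_t(self, data):
        cmp = nested_model_comparison(data, "y", "age", "age + x")
        t = cmp["fit2"].tvalues["x"]
        assert cmp["F"] == pytest.approx(t**2, rel=1e-8)
        assert cmp["p"] == pytest.approx(cmp["fit2"].pvalues["x"], rel=1e-8)

    def test_true_covariate_improves_fit(self, data):
        cmp = nested_model_comparison(data, "y", "age", "age + x")
        assert cmp["r2_2"] > cmp["r2_1"]
        assert cmp["p"] < 1e-6

    def test_identical_blocks_rejected(self, data):
        with pytest.raises(ValueError):
            nested_model_comparison(data, "y", "age", "age")

    def test_pure_noise_addition_is_null_f(self):
        """Adding a noise column: partial F has its nominal null law
        (checked by KS over simulated datasets)."""
        from scipy import stats
        ps = []
        for seed in range(300):
            rng = rng_for(seed, "nullf")
            n = 30
            df = pd.DataFrame({
                "y": rng.normal(size=n),
                "x": rng.normal(size=n),
                "noise": rng.normal(size=n),
            })
            cmp = nested_model_comparison(df, "y", "x", "x + noise")
            ps.append(cmp["p"])
        d, p = stats.kstest(ps, "uniform")
        assert p > 0.01

    def test_collinear_full_block_handled(self, data):
        d = data.copy()
        d["x2"] = d["x"]  # exact copy -> rank-deficient full block
        cmp = nested_model_comparison(d, "y", "x", "x + x2 + noise")
        assert np.isfinite(cmp["F"])


class TestClusterBehaviorCorrelation:
    def test_perfect_linear_relationship(self):
        v = np.linspace(0, 1, 12)
        groups = np.array(["young"] * 6 + ["old"] * 6)
        out = cluster_behavior_correlation(v, 2 * v + 1, groups)
        assert out.loc["all", "r"] == pytest.approx(1.0)
        assert out.loc["young", "r"] == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = rng_for(3, "corr")
        v = rng.normal(size=20)
        y = rng.normal(size=20)
        groups = np.array(["young"] * 10 + ["old"] * 10)
        out = cluster_behavior_correlation(v, y, groups)
        want = np.cov(v, y)[0, 1] / (np.std(v, ddof=1) * np.std(y, ddof=1))
        assert out.loc["all", "r"] == pytest.approx(want, abs=1e-12)

    def test_constant_values_flagged(self):
        v = np.ones(10)
        groups = np.array(["young"] * 5 + ["old"] * 5)
        out = cluster_behavior_correlation(v, np.arange(10.0), groups)
        assert out.loc["all", "degenerate"].item() is True
        assert np.isnan(out.loc["all", "r"])
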