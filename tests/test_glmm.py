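"""Laplace logistic GLMM: reductions, symmetries, and an lme4 cross-check."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from patsim.config import rng_for
from patsim.glmm import LogisticGLMM, firth_logistic


def simulate_glmm_data(n_subjects=20, n_trials=24, slope=1.0, intercept=-1.0,
                       re_sd=(0.5, 0.3), seed=0, with_age=True):
    rng = rng_for(seed, "glmm_data")
    rows = []
    for s in range(n_subjects):
        u0 = rng.normal(0.0, re_sd[0])
        u1 = rng.normal(0.0, re_sd[1])
        x = rng.normal(1.0, 0.4, n_trials)
        age = -0.5 if s < n_subjects // 2 else 0.5
        eta = intercept + u0 + (slope + u1) * x + (0.4 * age if with_age else 0.0)
        y = (rng.random(n_trials) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        rows.append(pd.DataFrame(
            {"subject": f"s{s:02d}", "age": age, "x": x, "y": y}
        ))
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="module")
def glmm_data():
    return simulate_glmm_data(seed=3)


class TestReductions:
    def test_no_random_effects_equals_pooled_logit(self, glmm_data):
        model = LogisticGLMM.from_formula("y ~ age + x + (1 | subject)",
                                          glmm_data)
        ours = model.fit(re_structure="none")
        ref = sm.Logit(
            model.endog, model.exog
        ).fit(disp=0)
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.bse, ref.bse, atol=1e-5)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_flipping_outcomes_negates_log_odds_pooled(self, glmm_data):
        flipped = glmm_data.assign(y=1.0 - glmm_data["y"])
        a = LogisticGLMM.from_formula("y ~ age + x + (1 | subject)",
                                      glmm_data).fit(re_structure="none")
        b = LogisticGLMM.from_formula("y ~ age + x + (1 | subject)",
                                      flipped).fit(re_structure="none")
        np.testing.assert_allclose(a.params, -b.params, atol=1e-6)

    def test_flipping_outcomes_negates_log_odds_mixed(self, glmm_data):
        flipped = glmm_data.assign(y=1.0 - glmm_data["y"])
        a = LogisticGLMM.from_formula("y ~ x + (1 | subject)",
                                      glmm_data).fit()
        b = LogisticGLMM.from_formula("y ~ x + (1 | subject)",
                                      flipped).fit()
        np.testing.assert_allclose(a.params, -b.params, atol=1e-3)


class TestAgainstLme4:
    def test_fixed_effects_match_glmer(self, tmp_path):
        """Independent oracle: lme4::glmer (Laplace) on the same data.

        Fixture with well-identified variance components: at boundary
        (singular) optima the two optimizers can legitimately land on
        different solutions, so the test asserts the oracle fit itself is
        non-singular.
        """
        data = simulate_glmm_data(n_subjects=24, seed=5)
        ours = LogisticGLMM.from_formula(
            "y ~ age + x + (1 + x | subject)", data
        ).fit()
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            f <- glmer(y ~ age + x + (1 + x | subject), data=d, family=binomial)
            co <- summary(f)$coefficients
            write.csv(co, '{tmp_path}/out.csv')
            cat(isSingular(f), as.numeric(logLik(f)), '\\n')
        """))
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        singular, llf_ref = proc.stdout.strip().split()
        assert singular == "FALSE"
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        np.testing.assert_allclose(
            ours.params, ref["Estimate"].to_numpy(), atol=5e-3
        )
        # SE conventions differ slightly across packages (observed vs
        # expected information details); a few percent is the usual spread
        np.testing.assert_allclose(
            ours.bse, ref["Std. Error"].to_numpy(), rtol=0.05
        )
        assert ours.llf == pytest.approx(float(llf_ref), abs=0.05)


class TestStructuresAndFallbacks:
    def test_requested_structures_are_recorded(self, glmm_data):
        m = LogisticGLMM.from_formula("y ~ x + (1 + x | subject)", glmm_data)
        for structure in ("full", "diagonal", "intercept"):
            fit = m.fit(re_structure=structure, ladder=False)
            assert fit.re_structure_used == structure
            assert fit.cov_re.shape[0] == (1 if structure == "intercept" else 2)

    def test_fallback_llf_never_beats_fuller_model(self, glmm_data):
        m = LogisticGLMM.from_formula("y ~ x + (1 + x | subject)", glmm_data)
        full = m.fit(re_structure="full", ladder=False)
        diag = m.fit(re_structure="diagonal", ladder=False)
        inter = m.fit(re_structure="intercept", ladder=False)
        assert full.llf >= diag.llf - 1e-4
        assert diag.llf >= inter.llf - 1e-4

    def test_complete_separation_triggers_firth(self):
        rng = rng_for(5, "sep")
        n = 40
        x = rng.normal(size=n)
        y = (x > 0).astype(float)  # perfectly separated
        data = pd.DataFrame({"x": x, "y": y,
                             "subject": ["a", "b"] * (n // 2)})
        with pytest.warns(UserWarning, match="separation"):
            fit = LogisticGLMM.from_formula("y ~ x + (1 | subject)", data).fit()
        assert fit.separation
        assert np.all(np.isfinite(fit.params))
        assert np.all(np.isfinite(fit.bse))

    def test_firth_shrinks_relative_to_ml_on_small_samples(self):
        rng = rng_for(6, "firth")
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        y = (X[:, 1] + rng.normal(0, 1.5, 12) > 0).astype(float)
        beta, cov = firth_logistic(X, y)
        assert np.all(np.isfinite(beta))
        assert np.all(np.diag(cov) > 0)

    def test_age_coding_symmetry(self, glmm_data):
        """Recoding young/old as +/- instead of -/+ negates age terms only."""
        swapped = glmm_data.assign(age=-glmm_data["age"])
        a = LogisticGLMM.from_formula("y ~ age + x + (1 | subject)",
                                      glmm_data).fit(ladder=False,
                                                     re_structure="intercept")
        b = LogisticGLMM.from_formula("y ~ age + x + (1 | subject)",
                                      swapped).fit(ladder=False,
                                                   re_structure="intercept")
        names = a.model.exog_names
        i_age = names.index("age")
        assert a.params[i_age] == pytest.approx(-b.params[i_age], abs=1e-4)
        for j, n in enumerate(names):
            if "age" not in n:
                assert a.params[j] == pytest.approx(b.params[j], abs=1e-4)

    def test_summary_contains_key_fields(self, glmm_data):
        fit = LogisticGLMM.from_formula("y ~ x + (1 | subject)", glmm_data).fit()
        text = fit.summary()
        assert "logLik" in text and "odds_ratio" in text
        frame = fit.summary_frame()
        assert (frame["ci_low"] <= frame["estimate"]).all()
        assert (frame["estimate"] <= frame["ci_high"]).all()


def test_null_slope_rejected_at_nominal_rate():
    """With a zero planted slope, the slope fixed effect is rejected at
    roughly the nominal 5% level across simulations."""
    rejections = 0
    n_sim = 30
    for seed in range(n_sim):
        data = simulate_glmm_data(n_subjects=12, n_trials=16, slope=0.0,
                                  seed=300 + seed)
        fit = LogisticGLMM.from_formula(
            "y ~ age + x + (1 | subject)", data
        ).fit(ladder=False, re_structure="intercept")
        rejections += fit.pvalues[fit.model.exog_names.index("x")] < 0.05
    assert rejections <= np.ceil(0.05 * n_sim + 3 * np.sqrt(0.05 * 0.95 * n_sim))


def test_ci_covers_true_slope_in_quick_recovery():
    """Short recovery check (the full 100-fit coverage run lives in the
    acceptance suite)."""
    hits = 0
    for seed in range(10):
        data = simulate_glmm_data(seed=100 + seed)
        fit = LogisticGLMM.from_formula(
            "y ~ age + x + (1 + x | subject)", data
        ).fit()
        lo, hi = fit.conf_int()[fit.model.exog_names.index("x")]
        hits += lo <= 1.0 <= hi
    assert hits >= 8
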