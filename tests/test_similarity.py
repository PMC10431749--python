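"""Similarity measures against brute-force pair enumeration and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import patsim
from patsim.config import DEFAULT_CLAMP_R, rng_for
from patsim.glm import BetaImage
from patsim.similarity import (
    between_category_similarity,
    category_reinstatement_specificity,
    category_specificity,
    fisher_z_corr,
    item_reinstatement_specificity,
    pairwise_fisher_z,
    reinstatement_measures,
    trialwise_measures,
    within_category_similarity,
)

import oracles


class TestFisherZCorr:
    def test_perfect_correlation_is_clamped_finite(self):
        z = fisher_z_corr([1, 2, 3], [1, 2, 3])
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(DEFAULT_CLAMP_R))

    def test_perfect_anticorrelation(self):
        z = fisher_z_corr([1, 2, 3], [3, 2, 1])
        assert z == pytest.approx(-np.arctanh(DEFAULT_CLAMP_R))

    def test_hand_computed_value(self):
        # Pearson r of [1,2,3] vs [1,2,4] is 0.981981; atanh gives 2.350199
        z = fisher_z_corr([1, 2, 3], [1, 2, 4])
        assert z == pytest.approx(2.350199, abs=1e-5)

    def test_zero_variance_is_missing(self):
        assert np.isnan(fisher_z_corr([1, 1, 1], [1, 2, 3]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fisher_z_corr([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            fisher_z_corr([1], [2])

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 8))
        z = fisher_z_corr(x, y)
        assert z == pytest.approx(fisher_z_corr(y, x))
        assert abs(z) <= np.arctanh(DEFAULT_CLAMP_R) + 1e-12


def _random_beta(n_items=4, n_vox=30, seed=0, phase="encoding"):
    """Small two-run BetaImage with arbitrary (signal-free) patterns."""
    rng = rng_for(seed, "fixture", phase)
    rows = []
    for run in (1, 2):
        for cat in ("face", "house"):
            for i in range(n_items):
                rows.append({"run": run, "phase": phase, "category": cat,
                             "item": f"{cat}{i}", "old": i < n_items // 2,
                             "subject": "s1", "age_group": "young"})
    trials = pd.DataFrame(rows)
    if phase == "recognition":
        # recognition shows each item once: split items across runs
        keep = [
            (r["run"] == 1) == (int(r["item"][-1]) % 2 == 0)
            for _, r in trials.iterrows()
        ]
        trials = trials[np.array(keep)].reset_index(drop=True)
    X = rng.normal(size=(len(trials), n_vox))
    grid = (n_vox, 1, 1)
    return BetaImage(
        betas=X, trials=trials, mask=np.ones(grid, bool),
        affine=np.eye(4) * 2.0, voxel_size_mm=2.0,
    )


@pytest.fixture(scope="module")
def enc_beta():
    return _random_beta(seed=21)


@pytest.fixture(scope="module")
def rec_beta():
    return _random_beta(seed=22, phase="recognition")


class TestOracleEquivalence:
    def test_within_matches_brute_force(self, enc_beta):
        cols = np.arange(enc_beta.n_voxels)
        for cat in ("face", "house"):
            got = within_category_similarity(enc_beta, cols, cat)
            want, n = oracles.brute_within_category(enc_beta, cols, cat)
            assert got.value == pytest.approx(want, abs=1e-12)
            assert got.n_pairs == n

    def test_between_matches_brute_force(self, enc_beta):
        cols = np.arange(enc_beta.n_voxels)
        got = between_category_similarity(enc_beta, cols, "face")
        want, n = oracles.brute_between_category(enc_beta, cols, "face")
        assert got.value == pytest.approx(want, abs=1e-12)
        assert got.n_pairs == n

    def test_specificity_is_difference(self, enc_beta):
        cols = np.arange(enc_beta.n_voxels)
        w, _ = oracles.brute_within_category(enc_beta, cols, "house")
        b, _ = oracles.brute_between_category(enc_beta, cols, "house")
        assert category_specificity(enc_beta, cols, "house") == pytest.approx(
            w - b, abs=1e-12
        )

    def test_reinstatement_matches_brute_force(self, enc_beta, rec_beta):
        cols = np.arange(enc_beta.n_voxels)
        got = reinstatement_measures(enc_beta, rec_beta, cols, "face")
        want = oracles.brute_reinstatement(enc_beta, rec_beta, cols, "face")
        for key in want:
            assert got[key].value == pytest.approx(want[key], abs=1e-12)

    def test_trialwise_rec_spec_matches_brute_force(self, enc_beta, rec_beta):
        cols = np.arange(rec_beta.n_voxels)
        tw = trialwise_measures(enc_beta, rec_beta, cols)
        want = oracles.brute_rec_trial_spec(rec_beta, cols)
        for idx, val in want.items():
            assert tw.loc[idx, "rec_cat_spec"] == pytest.approx(val, abs=1e-12)


class TestConstruction:
    def test_identical_patterns_reach_clamped_maximum(self):
        beta = _random_beta(seed=30)
        # make all face patterns identical across both runs
        face = beta.trials.category.to_numpy() == "face"
        beta.betas[face] = beta.betas[np.flatnonzero(face)[0]]
        w = within_category_similarity(beta, None, "face")
        assert w.value == pytest.approx(np.arctanh(DEFAULT_CLAMP_R))

    def test_shared_template_makes_between_close_to_within(self):
        rng = rng_for(31, "shared")
        beta = _random_beta(seed=31)
        template = rng.normal(size=beta.n_voxels) * 3.0
        beta.betas = beta.betas * 0.2 + template
        w = within_category_similarity(beta, None, "face").value
        b = between_category_similarity(beta, None, "face").value
        assert abs(w - b) < 0.1

    def test_orthogonal_templates_make_between_smaller(self):
        rng = rng_for(32, "orth")
        beta = _random_beta(seed=32)
        tf = rng.normal(size=beta.n_voxels)
        th = rng.normal(size=beta.n_voxels)
        cat = beta.trials.category.to_numpy()
        beta.betas = beta.betas * 0.3 + np.where(
            (cat == "face")[:, None], tf, th
        )
        w = within_category_similarity(beta, None, "face").value
        b = between_category_similarity(beta, None, "face").value
        assert w > b

    def test_copied_recognition_patterns_maximize_item_reinstatement(self):
        enc = _random_beta(seed=33)
        rec = _random_beta(seed=34, phase="recognition")
        # copy each recognition pattern from the item's run-1 encoding trial
        et = enc.trials
        for j, (_, row) in enumerate(rec.trials.iterrows()):
            src = et[(et.item == row["item"]) & (et.run == 1)].index[0]
            rec.betas[j] = enc.betas[et.index.get_loc(src)]
        m = reinstatement_measures(enc, rec, None, "face")
        assert m["within_item"].value > m["within_category"].value
        assert item_reinstatement_specificity(enc, rec, None, "face") > 0

    def test_no_item_signal_makes_item_reinstatement_null(self):
        """Without item templates, within-item and within-category
        reinstatement coincide in expectation."""
        cfg = patsim.SimConfig(
            n_subjects_per_group=1, n_items_per_category=8,
            grid_shape=(6, 6, 6), item_signal_sd=0.0, seed=35,
        )
        diffs = []
        for seed in range(10):
            betas, _ = patsim.simulate_beta_patterns(
                patsim.SimConfig(**{**cfg.__dict__, "seed": seed,
                                    "signal_region_cat": None,
                                    "signal_region_item": None})
            )
            b = betas["y01"]
            diffs.append(
                item_reinstatement_specificity(
                    b["encoding"], b["recognition"], None, "face"
                )
            )
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.02


class TestInvariants:
    def test_voxel_permutation_and_constant_shift(self, enc_beta):
        base = category_specificity(enc_beta, None, "face")
        perm = rng_for(40, "perm").permutation(enc_beta.n_voxels)
        shuffled = BetaImage(
            betas=enc_beta.betas[:, perm] + 7.5,
            trials=enc_beta.trials, mask=enc_beta.mask,
            affine=enc_beta.affine, voxel_size_mm=2.0,
        )
        assert category_specificity(shuffled, None, "face") == pytest.approx(
            base, abs=1e-12
        )

    def test_iid_noise_specificity_near_zero(self):
        vals = [
            category_specificity(_random_beta(n_vox=1000, seed=50 + s), None, "face")
            for s in range(12)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3

    def test_label_shuffled_categories_null(self, enc_beta):
        """Random category relabeling: specificity expectation 0."""
        rng = rng_for(41, "shuffle")
        vals = []
        for _ in range(30):
            t = enc_beta.trials.copy()
            # shuffle the item -> category map consistently across runs
            items = list(t["item"].unique())
            cats = list(
                t.drop_duplicates("item").set_index("item").loc[items, "category"]
            )
            new_cat = dict(zip(items, [cats[i] for i in rng.permutation(len(cats))]))
            t["category"] = t["item"].map(new_cat)
            shuffled = BetaImage(
                betas=enc_beta.betas, trials=t, mask=enc_beta.mask,
                affine=enc_beta.affine, voxel_size_mm=2.0,
            )
            vals.append(category_specificity(shuffled, None, "face"))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3.5 * se + 1e-3

    def test_trialwise_mean_equals_subject_level(self, enc_beta, rec_beta):
        cols = np.arange(rec_beta.n_voxels)
        tw = trialwise_measures(enc_beta, rec_beta, cols)
        for cat in ("face", "house"):
            sel = rec_beta.trials.category == cat
            subject_level = category_specificity(rec_beta, cols, cat)
            assert tw.loc[sel.to_numpy(), "rec_cat_spec"].mean() == pytest.approx(
                subject_level, abs=1e-12
            )

    def test_single_voxel_cluster_undefined(self, enc_beta, rec_beta):
        tw = trialwise_measures(enc_beta, rec_beta, np.array([3]))
        assert tw.isna().all().all()

    def test_new_items_have_no_item_reinstatement(self, enc_beta, rec_beta):
        tw = trialwise_measures(enc_beta, rec_beta, None)
        new = ~rec_beta.trials["old"].to_numpy(dtype=bool)
        assert tw.loc[new, "item_rein"].isna().all()
        assert tw.loc[~new, "item_rein"].notna().all()


def test_undefined_pairs_dropped_not_zero_filled():
    beta = _random_beta(seed=60)
    # zero out one run-2 face trial -> its pairs become undefined
    t = beta.trials
    victim = t[(t.run == 2) & (t.category == "face")].index[0]
    beta.betas[t.index.get_loc(victim)] = 0.0
    got = within_category_similarity(beta, None, "face")
    want, n = oracles.brute_within_category(
        beta, np.arange(beta.n_voxels), "face"
    )
    assert got.value == pytest.approx(want, abs=1e-12)
    assert got.n_pairs == n
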