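"""Synthetic study generator with planted ground truth.

Emulates the face/house incidental-encoding + old/new recognition design:
two age groups, two identical encoding runs, a two-run recognition test, and
voxel patterns carrying category-level and item-level signal whose amplitude
is attenuated in the old group (the planted dedifferentiation effect).
Memory outcomes arise from trial-wise latent distinctiveness through a
logistic link with group-specific response bias, so every downstream test —
similarity measures, searchlight maps, cluster inference, interindividual
models, trial-wise mixed models — has a recoverable truth.

Generative model per trial (voxel vector v):

    v = s_t * T_cat  (in the category block)
      + g   * T_item (in the item block of the trial's category)
      + noise_sd * N(0, I)

where T_cat ~ N(0, cat_signal_sd^2), T_item ~ N(0, item_signal_sd^2) are
subject-specific templates shared across runs and phases (the item template
shared across encoding and recognition is the reinstatement signal),
g = 1 for young and dediff_factor_old for old subjects, and the latent
trial distinctiveness s_t = g * max(0, N(latent_spec_mean, latent_spec_sd)).

Old-item recognition responses follow

    P("old") = logistic(bias_group + u0_s + (memory_slope + u1_s) * s_t)

with subject random intercept u0 and slope u1; new items use the intercept
alone, so the group-specific bias reproduces the groups' false-alarm rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .config import CATEGORIES, ConfigError, SimConfig, rng_for
from .glm import BetaImage, BoldRun, convolve_trials

__all__ = [
    "GroundTruth",
    "make_trial_table",
    "simulate_beta_patterns",
    "simulate_bold_run",
    "simulate_memory_outcomes",
    "simulate_null_maps",
    "simulate_subject_measures",
    "subject_ids",
]


def subject_ids(config: SimConfig) -> pd.DataFrame:
    n = config.n_subjects_per_group
    return pd.DataFrame(
        {
            "subject": [f"y{i + 1:02d}" for i in range(n)]
            + [f"o{i + 1:02d}" for i in range(n)],
            "age_group": ["young"] * n + ["old"] * n,
        }
    )


@dataclass
class GroundTruth:
    """Planted quantities, reproducible from (SimConfig, seed)."""

    config: SimConfig
    templates: dict  # subject -> {"cat": {c: vec}, "item": {item: vec}}
    latent_spec: pd.Series  # indexed like the trial table
    subject_effects: pd.DataFrame  # u0, u1, group factor per subject
    coefficients: dict = field(default_factory=dict)

    def group_factor(self, age_group: str) -> float:
        return 1.0 if age_group == "young" else self.config.dediff_factor_old

    def searchlight_support(self, category: str, radius_mm: float) -> np.ndarray:
        """Voxels whose searchlight sphere overlaps the planted block.

        A searchlight map carries planted signal wherever the sphere
        intersects the signal region, i.e. the block dilated by the radius.
        """
        from .searchlight import sphere_offsets

        offs = sphere_offsets(radius_mm, self.config.voxel_size_mm)
        struct = np.zeros(tuple(2 * np.abs(offs).max(axis=0) + 1), dtype=bool)
        struct[tuple((offs + np.abs(offs).max(axis=0)).T)] = True
        return binary_dilation(self.config.signal_region_cat[category], struct)


def _onsets(n_trials: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.iti_range_s
    itis = rng.uniform(lo, hi, size=n_trials)
    starts = np.concatenate([[itis[0]], itis[1:]]).cumsum()
    starts += np.arange(n_trials) * config.stim_duration_s
    return starts


def make_trial_table(config: SimConfig) -> pd.DataFrame:
    """Trial metadata for every subject, phase and run.

    Encoding: 2 identical runs, each presenting every old item exactly once,
    in category blocks with alternating order (starting category
    counterbalanced across subjects).  Recognition: 2 runs jointly containing
    each old and each new item once, blocked by category.
    """
    config.validate()
    n_old = config.n_old_per_category
    item_rng = rng_for(config.seed, "items")
    items = {}
    for cat in CATEGORIES:
        labels = [f"{cat}{i:03d}" for i in range(config.n_items_per_category)]
        perm = item_rng.permutation(len(labels))
        items[cat] = {
            "old": [labels[i] for i in perm[:n_old]],
            "new": [labels[i] for i in perm[n_old:]],
        }

    rows = []
    for subj_i, (subject, age_group) in enumerate(
        subject_ids(config).itertuples(index=False)
    ):
        start_cat = CATEGORIES[subj_i % 2]  # counterbalanced block order
        other_cat = CATEGORIES[1 - subj_i % 2]
        # recognition run assignment: each item appears in exactly one run
        rec_rng = rng_for(config.seed, "recsplit", subject)
        rec_assign = {}
        for cat in CATEGORIES:
            for status in ("old", "new"):
                pool = list(items[cat][status])
                rec_rng.shuffle(pool)
                half = len(pool) // 2
                for it in pool[:half]:
                    rec_assign.setdefault(1, []).append((cat, it, status == "old"))
                for it in pool[half:]:
                    rec_assign.setdefault(2, []).append((cat, it, status == "old"))

        for phase in ("encoding", "recognition"):
            for run in (1, 2):
                order_rng = rng_for(config.seed, "order", subject, phase, run)
                run_rows = []
                for block_i, cat in enumerate((start_cat, other_cat)):
                    if phase == "encoding":
                        block_items = [(cat, it, True) for it in items[cat]["old"]]
                    else:
                        block_items = [
                            t for t in rec_assign[run] if t[0] == cat
                        ]
                    block_items = [
                        block_items[k]
                        for k in order_rng.permutation(len(block_items))
                    ]
                    for cat_, item, old in block_items:
                        run_rows.append((block_i, cat_, item, old))
                onset_rng = rng_for(config.seed, "onsets", subject, phase, run)
                onsets = _onsets(len(run_rows), config, onset_rng)
                for t, ((block_i, cat_, item, old), onset) in enumerate(
                    zip(run_rows, onsets)
                ):
                    rows.append(
                        {
                            "subject": subject,
                            "age_group": age_group,
                            "phase": phase,
                            "run": run,
                            "block": block_i,
                            "trial": t,
                            "category": cat_,
                            "item": item,
                            "old": old,
                            "onset_s": onset,
                        }
                    )
    table = pd.DataFrame(rows)
    table["response"] = pd.Series([pd.NA] * len(table), dtype="object")
    table["outcome"] = pd.Series([pd.NA] * len(table), dtype="object")
    return table


def simulate_beta_patterns(
    config: SimConfig,
    trial_table: pd.DataFrame | None = None,
) -> tuple[dict, GroundTruth]:
    """Per-subject (encoding, recognition) BetaImage pairs plus ground truth.

    Patterns follow the generative model in the module docstring; encoding
    and recognition presentations of the same item share the item template.
    """
    if trial_table is None:
        trial_table = make_trial_table(config)
    grid = tuple(config.grid_shape)
    mask = np.ones(grid, dtype=bool)
    cat_cols = {
        c: np.flatnonzero(config.signal_region_cat[c][mask]) for c in CATEGORIES
    }
    item_cols = {
        c: np.flatnonzero(config.signal_region_item[c][mask]) for c in CATEGORIES
    }
    V = int(mask.sum())

    betas: dict = {}
    templates: dict = {}
    latent = pd.Series(np.nan, index=trial_table.index, dtype=float)
    subj_rows = []
    for subject, sub_tab in trial_table.groupby("subject", sort=False):
        age_group = sub_tab["age_group"].iloc[0]
        g = 1.0 if age_group == "young" else config.dediff_factor_old
        rng = rng_for(config.seed, "betas", subject)
        t_cat = {
            c: rng.normal(0.0, config.cat_signal_sd, cat_cols[c].size)
            for c in CATEGORIES
        }
        t_item = {}
        for c in CATEGORIES:
            for item in sorted(sub_tab.loc[sub_tab.category == c, "item"].unique()):
                t_item[item] = rng.normal(
                    0.0, config.item_signal_sd, item_cols[c].size
                )
        templates[subject] = {"cat": t_cat, "item": t_item}
        u0 = rng.normal(0.0, config.subject_bias_sd)
        u1 = rng.normal(0.0, config.subject_slope_sd)
        subj_rows.append(
            {"subject": subject, "age_group": age_group, "u0": u0, "u1": u1, "g": g}
        )

        base = rng.normal(
            config.latent_spec_mean, config.latent_spec_sd, len(sub_tab)
        ).clip(min=0.0)
        spec = g * base
        latent.loc[sub_tab.index] = spec

        betas[subject] = {}
        for phase in ("encoding", "recognition"):
            ph = sub_tab[sub_tab.phase == phase]
            X = rng.normal(0.0, config.noise_sd, (len(ph), V))
            for i, (row_idx, row) in enumerate(ph.iterrows()):
                c = row["category"]
                X[i, cat_cols[c]] += latent.loc[row_idx] * t_cat[c]
                X[i, item_cols[c]] += g * t_item[row["item"]]
            trials = ph.copy()
            betas[subject][phase] = BetaImage(
                betas=X,
                trials=trials,
                mask=mask,
                affine=config.affine,
                voxel_size_mm=config.voxel_size_mm,
            )

    truth = GroundTruth(
        config=config,
        templates=templates,
        latent_spec=latent,
        subject_effects=pd.DataFrame(subj_rows).set_index("subject"),
        coefficients={
            "memory_slope": config.memory_slope,
            "bias_young": config.bias_young,
            "bias_old": config.bias_old,
            "subject_bias_sd": config.subject_bias_sd,
            "subject_slope_sd": config.subject_slope_sd,
            "dediff_factor_old": config.dediff_factor_old,
        },
    )
    return betas, truth


def simulate_memory_outcomes(
    truth: GroundTruth,
    config: SimConfig,
    trial_table: pd.DataFrame,
) -> pd.DataFrame:
    """Attach old/new responses and hit/miss/FA/CR outcomes.

    P("old") = logistic(bias_group + u0 + (slope + u1) * latent specificity)
    for old items; new items use the intercept alone.
    """
    out = trial_table.copy()
    for subject, sub_tab in out.groupby("subject", sort=False):
        rec = sub_tab[sub_tab.phase == "recognition"]
        age_group = rec["age_group"].iloc[0]
        bias = config.bias_young if age_group == "young" else config.bias_old
        u0 = truth.subject_effects.loc[subject, "u0"]
        u1 = truth.subject_effects.loc[subject, "u1"]
        spec = truth.latent_spec.loc[rec.index].to_numpy()
        old = rec["old"].to_numpy(dtype=bool)
        eta = bias + u0 + np.where(old, (config.memory_slope + u1) * spec, 0.0)
        p_old = 1.0 / (1.0 + np.exp(-eta))
        rng = rng_for(config.seed, "outcomes", subject)
        resp_old = rng.random(len(rec)) < p_old
        response = np.where(resp_old, "old", "new")
        outcome = np.where(
            old,
            np.where(resp_old, "hit", "miss"),
            np.where(resp_old, "fa", "cr"),
        )
        out.loc[rec.index, "response"] = response
        out.loc[rec.index, "outcome"] = outcome
    return out


def simulate_bold_run(
    config: SimConfig,
    betas: np.ndarray,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    motion_sd: float = 0.0,
    noise_sd: float | None = None,
    n_scans: int | None = None,
) -> BoldRun:
    """BOLD time series from planted trial amplitudes.

    series = sum_t beta_t * (1.2-s boxcar (*) HRF) + motion-coupled drift +
    Gaussian noise.  Motion parameters are a 6-column random walk emitted
    alongside; with motion_sd = 0 both the walk and its coupling vanish.
    """
    if noise_sd is None:
        noise_sd = config.noise_sd
    onsets = trials["onset_s"].to_numpy(dtype=float)
    needed = int(np.ceil((onsets.max() + config.stim_duration_s + 20.0) / config.tr_s))
    if n_scans is None:
        n_scans = needed
    reg = convolve_trials(onsets, config.stim_duration_s, config.tr_s, n_scans)
    betas = np.asarray(betas, dtype=float)
    if betas.shape[0] != len(trials):
        raise ConfigError("beta rows do not match trial count")
    V = betas.shape[1]
    Y = reg @ betas
    motion = np.zeros((n_scans, 6))
    if motion_sd > 0:
        motion = rng.normal(0.0, motion_sd, (n_scans, 6)).cumsum(axis=0)
        coupling = rng.normal(0.0, motion_sd, (6, V))
        Y = Y + motion @ coupling
    if noise_sd > 0:
        Y = Y + rng.normal(0.0, noise_sd, Y.shape)
    grid = tuple(config.grid_shape)
    if V != int(np.prod(grid)):
        raise ConfigError("beta columns do not match grid size")
    data = Y.T.reshape(grid + (n_scans,))
    return BoldRun(
        data=data,
        tr_s=config.tr_s,
        motion=motion,
        run_id=int(trials["run"].iloc[0]),
        phase=str(trials["phase"].iloc[0]),
    )


def simulate_null_maps(
    n_subjects: int,
    grid_shape,
    rng: np.random.Generator,
    smooth_sigma_vox: float = 2.0,
) -> np.ndarray:
    """Exchangeable null searchlight maps: smoothed Gaussian random fields.

    Searchlight maps are spatially smooth by construction (neighbouring
    spheres share most voxels), so the null emulation smooths i.i.d. noise
    with a Gaussian kernel of comparable footprint and rescales to unit
    variance.  Returns (n_subjects, x, y, z).
    """
    maps = rng.normal(size=(n_subjects,) + tuple(grid_shape))
    if smooth_sigma_vox > 0:
        for i in range(n_subjects):
            maps[i] = gaussian_filter(maps[i], smooth_sigma_vox)
        maps /= maps.std()
    return maps


def simulate_subject_measures(
    n_per_group: int = 35,
    seed: int = 0,
    enc_age_effect: float = -0.8,
    rec_loading: float = 0.65,
    rein_loading: float = 0.88,
    pr_loading: float = 0.6,
) -> pd.DataFrame:
    """Interindividual measures with encoding specificity as the driver.

    Age (coded -0.5 young / +0.5 old) shifts encoding specificity by
    ``enc_age_effect`` standard deviations; retrieval specificity,
    reinstatement specificity and memory performance load on encoding
    specificity only, so conditioning on encoding specificity removes the
    age effect from every downstream measure by construction.
    """
    rng = rng_for(seed, "subject_measures")
    n = 2 * n_per_group
    age = np.repeat([-0.5, 0.5], n_per_group)
    enc = rng.normal(size=n) + enc_age_effect * age

    def load(loading):
        return loading * enc + np.sqrt(1.0 - loading**2) * rng.normal(size=n)

    return pd.DataFrame(
        {
            "subject": [f"s{i:03d}" for i in range(n)],
            "age_group": np.where(age < 0, "young", "old"),
            "age": age,
            "enc_spec": enc,
            "rec_spec": load(rec_loading),
            "rein_spec": load(rein_loading),
            "pr": load(pr_loading),
        }
    )
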