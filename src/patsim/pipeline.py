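"""End-to-end orchestration: simulate -> trial GLM -> searchlight maps ->
cluster inference -> interindividual and trial-wise models.

Stage outputs are pure functions of (config, seed).  Whole-group searchlight
effects are established first; age contrasts and brain-behavior regressions
are then restricted to the regions showing a whole-group effect.  All
artifacts are written under a derivatives-style output root with JSON
sidecars, plus a run manifest (seed, config hash, versions, per-stage wall
times).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    ClusterPermutationTest,
    cluster_mean_extract,
    restrict_search_space,
)
from .config import (
    CATEGORIES,
    PermutationScheme,
    SearchlightSpec,
    SimConfig,
    config_hash,
)
from .glm import fit_trial_betas
from .group import (
    cluster_behavior_correlation,
    compute_pr,
    mixed_anova_2x2,
    nested_model_comparison,
    pr_long,
)
from .io import (
    save_beta_image,
    save_motion,
    save_trial_table,
    save_volume,
    write_sidecar,
)
from .searchlight import (
    searchlight_reinstatement_maps,
    searchlight_specificity_maps,
)
from .synth import (
    make_trial_table,
    simulate_beta_patterns,
    simulate_bold_run,
    simulate_memory_outcomes,
)
from .trial_models import run_cluster_glmm_suite
from .config import rng_for

logger = logging.getLogger("patsim")

ALL_STAGES = ("simulate", "glm", "searchlight", "cluster", "models")

#: measure key -> (family, category); family 'spec' uses one phase,
#: 'rein' uses encoding x recognition.
MEASURES = {
    "enc_spec_face": ("encoding", "face"),
    "enc_spec_house": ("encoding", "house"),
    "rec_spec_face": ("recognition", "face"),
    "rec_spec_house": ("recognition", "house"),
    "cat_rein_face": ("reinstatement_category", "face"),
    "cat_rein_house": ("reinstatement_category", "house"),
    "item_rein_face": ("reinstatement_item", "face"),
    "item_rein_house": ("reinstatement_item", "house"),
}


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    searchlight: SearchlightSpec = field(default_factory=SearchlightSpec)
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    voxel_alpha: float = 0.005
    min_cluster_voxels: int = 10
    connectivity: int = 26
    sim_mode: str = "betas"  # 'betas' (direct patterns) or 'bold' (LSS chain)
    measures: tuple = tuple(MEASURES)
    model_category: str = "house"
    out_dir: str = "patsim_out"
    seed: int = 0

    def __post_init__(self):
        self.searchlight.voxel_size_mm = self.sim.voxel_size_mm
        self.sim.seed = self.seed

    def scheme(self, kind: str) -> PermutationScheme:
        return PermutationScheme(
            kind=kind,
            n_perm=self.n_perm,
            cluster_alpha=self.cluster_alpha,
            voxel_alpha=self.voxel_alpha,
            min_cluster_voxels=self.min_cluster_voxels,
            connectivity=self.connectivity,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim = SimConfig(**raw.pop("sim", {}))
        sl = SearchlightSpec(**raw.pop("searchlight", {}))
        return cls(sim=sim, searchlight=sl, **raw)


def _central_roi(grid_shape) -> np.ndarray:
    """Small central block used as the default trial-activity ROI."""
    roi = np.zeros(grid_shape, dtype=bool)
    c = [s // 2 for s in grid_shape]
    roi[c[0] - 1 : c[0] + 2, c[1] - 1 : c[1] + 2, c[2] - 1 : c[2] + 2] = True
    return roi


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Execute the requested stages in order and return the run manifest."""
    stages = list(ALL_STAGES if stages is None else stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "version": __version__,
        "stages": {},
    }
    ctx: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in stages:
                continue
            t0 = time.perf_counter()
            logger.info("stage %s ...", stage)
            _STAGE_FNS[stage](config, ctx, out)
            manifest["stages"][stage] = round(time.perf_counter() - t0, 3)
    finally:
        write_sidecar(manifest, out / "manifest.json")
    return manifest


def _stage_simulate(config, ctx, out):
    table = make_trial_table(config.sim)
    betas, truth = simulate_beta_patterns(config.sim, table)
    table = simulate_memory_outcomes(truth, config.sim, table)
    ctx.update(trial_table=table, truth=truth, sim_betas=betas)
    save_trial_table(table, out / "trials.tsv")
    write_sidecar(
        {
            "coefficients": truth.coefficients,
            "latent_spec_mean_by_group": table.join(truth.latent_spec.rename("s"))
            .groupby("age_group")["s"].mean().to_dict(),
        },
        out / "ground_truth.json",
    )
    if config.sim_mode == "betas":
        ctx["betas"] = betas


def _stage_glm(config, ctx, out):
    """Simulate BOLD runs from the planted patterns and re-estimate betas
    with the least-squares-separate GLM (only in 'bold' mode)."""
    if config.sim_mode != "bold":
        ctx.setdefault("betas", ctx.get("sim_betas"))
        return
    sim = config.sim
    mask = np.ones(tuple(sim.grid_shape), dtype=bool)
    fitted: dict = {}
    for subject, phases in ctx["sim_betas"].items():
        fitted[subject] = {}
        for phase, beta in phases.items():
            parts = []
            for run in sorted(beta.trials["run"].unique()):
                trials = beta.trials[beta.trials["run"] == run]
                rows = beta.trials["run"].to_numpy() == run
                rng = rng_for(sim.seed, "bold", subject, phase, run)
                bold = simulate_bold_run(
                    sim, beta.betas[rows], trials, rng, motion_sd=0.05
                )
                save_motion(
                    bold.motion,
                    out / "bold" / subject / f"{phase}_run{run}_motion.tsv",
                )
                parts.append(
                    fit_trial_betas(
                        bold, trials, mask,
                        affine=sim.affine, voxel_size_mm=sim.voxel_size_mm,
                        duration_s=sim.stim_duration_s,
                    )
                )
            merged = parts[0]
            merged.betas = np.concatenate([p.betas for p in parts], axis=0)
            merged.trials = pd.concat([p.trials for p in parts])
            fitted[subject][phase] = merged
            save_beta_image(merged, out / "betas" / subject / phase)
    ctx["betas"] = fitted


def _stage_searchlight(config, ctx, out):
    betas = ctx["betas"]
    spec = config.searchlight
    subjects = list(betas)
    stacks = {m: [] for m in config.measures}
    for subject in subjects:
        enc, rec = betas[subject]["encoding"], betas[subject]["recognition"]
        spec_maps = {
            "encoding": searchlight_specificity_maps(enc, spec),
            "recognition": searchlight_specificity_maps(rec, spec),
        }
        rein_maps = searchlight_reinstatement_maps(enc, rec, spec)
        for m in config.measures:
            family, cat = MEASURES[m]
            if family in ("encoding", "recognition"):
                vol = spec_maps[family][cat]
            elif family == "reinstatement_category":
                vol = rein_maps[("category", cat)]
            else:
                vol = rein_maps[("item", cat)]
            stacks[m].append(vol)
            save_volume(vol, enc.affine, out / "maps" / m / f"{subject}.nii.gz")
        write_sidecar(
            {"radius_mm": spec.radius_mm, "min_voxels": spec.min_voxels,
             "measures": list(config.measures)},
            out / "maps" / f"{subject}_sidecar.json",
        )
    ctx["maps"] = {m: np.stack(v) for m, v in stacks.items()}
    ctx["subjects"] = subjects


def _stage_cluster(config, ctx, out):
    maps, subjects = ctx["maps"], ctx["subjects"]
    table = ctx["trial_table"]
    groups = (
        table.drop_duplicates("subject").set_index("subject")
        .loc[subjects, "age_group"].to_numpy()
    )
    pr = compute_pr(table)
    mask = np.ones(tuple(config.sim.grid_shape), dtype=bool)
    whole, restricted = {}, {}
    (out / "clusters").mkdir(parents=True, exist_ok=True)
    for m in config.measures:
        res = ClusterPermutationTest(maps[m], mask, config.scheme("sign_flip")).fit()
        whole[m] = res
        res.cluster_table().to_csv(
            out / "clusters" / f"{m}_wholegroup.tsv", sep="\t", index=False
        )
        search = restrict_search_space(res.significant_clusters, mask.shape)
        if not search.any():
            logger.warning("measure %s: no whole-group clusters; "
                           "restricted tests skipped", m)
            continue
        save_volume(search.astype(float), config.sim.affine,
                    out / "clusters" / f"{m}_searchmask.nii.gz")
        age = ClusterPermutationTest(
            maps[m], search, config.scheme("group_shuffle"), groups=groups
        ).fit()
        cat = MEASURES[m][1]
        beh = ClusterPermutationTest(
            maps[m], search, config.scheme("covariate_shuffle"),
            covariate=pr.loc[subjects, f"pr_{cat}"].to_numpy(),
        ).fit()
        restricted[m] = {"age": age, "behavior": beh}
        age.cluster_table().to_csv(
            out / "clusters" / f"{m}_age.tsv", sep="\t", index=False)
        beh.cluster_table().to_csv(
            out / "clusters" / f"{m}_behavior.tsv", sep="\t", index=False)
    ctx["whole_group"] = whole
    ctx["restricted"] = restricted


def _largest_cluster(result):
    sig = result.significant_clusters
    return max(sig, key=lambda c: c.size) if sig else None


def _stage_models(config, ctx, out):
    table = ctx["trial_table"]
    maps, subjects = ctx["maps"], ctx["subjects"]
    whole = ctx["whole_group"]
    summary = compute_pr(table)
    summary.to_csv(out / "behavior_summary.tsv", sep="\t")
    anova = mixed_anova_2x2(pr_long(summary))
    anova.to_csv(out / "behavior_anova.tsv", sep="\t", index=False)
    results = {"anova": anova.to_dict("records")}

    cat = config.model_category
    cluster_means = {}
    for label, mkey in (
        ("EncSpec", f"enc_spec_{cat}"),
        ("RecSpec", f"rec_spec_{cat}"),
        ("ReinSpec", f"cat_rein_{cat}"),
    ):
        cl = _largest_cluster(whole.get(mkey)) if mkey in whole else None
        if cl is not None:
            cluster_means[label] = cluster_mean_extract(maps[mkey], cl)
    if len(cluster_means) == 3:
        data = pd.DataFrame(cluster_means, index=subjects)
        data["age"] = [
            -0.5 if g == "young" else 0.5
            for g in table.drop_duplicates("subject")
            .set_index("subject").loc[subjects, "age_group"]
        ]
        data["pr"] = summary.loc[subjects, f"pr_{cat}"].to_numpy()
        comparisons = {
            "rec_on_enc": nested_model_comparison(
                data, "RecSpec", "age", "age + EncSpec"),
            "rein_on_enc": nested_model_comparison(
                data, "ReinSpec", "age", "age + EncSpec"),
            "pr_add_rein": nested_model_comparison(
                data, "pr", "age * RecSpec", "age * RecSpec + age * ReinSpec"),
            "pr_add_rec": nested_model_comparison(
                data, "pr", "age * ReinSpec", "age * ReinSpec + age * RecSpec"),
            "pr_add_enc": nested_model_comparison(
                data, "pr", "age * RecSpec + age * ReinSpec",
                "age * RecSpec + age * ReinSpec + age * EncSpec"),
        }
        results["model_comparisons"] = {
            k: {kk: v[kk] for kk in ("r2_1", "r2_2", "F", "df_num", "df_den", "p")}
            for k, v in comparisons.items()
        }
        corr = cluster_behavior_correlation(
            data["EncSpec"], data["pr"],
            np.where(data["age"] < 0, "young", "old"),
        )
        results["enc_behavior_correlation"] = corr.reset_index().to_dict("records")

    clusters = []
    for m in config.measures:
        cl = _largest_cluster(whole.get(m)) if m in whole else None
        if cl is not None:
            clusters.append(
                {"name": m, "measure": MEASURES[m][0], "cluster": cl}
            )
    glmm_report = run_cluster_glmm_suite(
        clusters, ctx["betas"], table,
        hipp_mask=_central_roi(tuple(config.sim.grid_shape)),
    )
    glmm_report.to_csv(out / "glmm_report.tsv", sep="\t", index=False)
    write_sidecar(results, out / "model_results.json")
    ctx["model_results"] = results
    ctx["glmm_report"] = glmm_report


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "glm": _stage_glm,
    "searchlight": _stage_searchlight,
    "cluster": _stage_cluster,
    "models": _stage_models,
}
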