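"""Trial-wise mixed-effects memory models.

Links binary recognition outcomes (hit/miss, old items only) to trial-wise
pattern distinctiveness within clusters, to item- and category-level
reinstatement, and to hippocampal activity, via logistic mixed models with
subject random effects (see :mod:`patsim.glmm`).

Covariate conventions: age is a centred two-level factor (-0.5 young, +0.5
old); response bias is each subject's overall proportion of "old" responses;
hippocampal activity is the trial-wise ROI mean z-scored within subject.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .glm import BetaImage
from .glmm import LogisticGLMM
from .similarity import trialwise_measures

__all__ = [
    "hippocampal_activity",
    "assemble_trial_dataset",
    "run_cluster_glmm_suite",
    "CATSPEC_FORMULA",
    "REINSTATEMENT_FORMULA",
]

CATSPEC_FORMULA = "outcome ~ age * cat_spec + resp_bias + (1 + cat_spec | subject)"
REINSTATEMENT_FORMULA = (
    "outcome ~ age * hipp + age * item_rein + age * cat_rein + resp_bias"
    " + (1 + hipp + item_rein + cat_rein | subject)"
)

_MEASURE_COLUMN = {
    "encoding": "enc_cat_spec",
    "recognition": "rec_cat_spec",
    "reinstatement_category": "cat_rein",
    "reinstatement_item": "item_rein",
}


def hippocampal_activity(beta: BetaImage, roi_mask: np.ndarray) -> np.ndarray:
    """Trial-wise ROI mean activity, z-scored across trials within subject.

    Zero across-trial variance (e.g. constant betas) is guarded: returns
    zeros with a warning instead of dividing by zero.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != beta.mask.shape:
        raise ValueError("ROI mask does not match the beta grid")
    cols = roi_mask[beta.mask]
    if not cols.any():
        raise ValueError("ROI mask is empty within the brain mask")
    vals = np.nanmean(beta.betas[:, cols], axis=1)
    sd = np.nanstd(vals)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("zero variance in ROI activity; z-scores set to 0")
        return np.zeros_like(vals)
    return (vals - np.nanmean(vals)) / sd


def _cluster_cols(cluster, mask):
    """Column indices (into the in-mask voxel axis) of a cluster."""
    if hasattr(cluster, "mask"):
        cmask = cluster.mask(mask.shape)
    else:
        cmask = np.asarray(cluster, dtype=bool)
    return np.flatnonzero(cmask[mask])


def assemble_trial_dataset(
    betas: dict,
    trial_table: pd.DataFrame,
    cluster,
    measure: str,
    hipp_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format modelling table across subjects for one cluster.

    ``betas`` maps subject -> {"encoding": BetaImage, "recognition":
    BetaImage}; ``measure`` selects which trial-wise similarity covariate
    plays the role of category specificity ('encoding', 'recognition',
    'reinstatement_category' or 'reinstatement_item').  Rows are old
    recognition trials with a response; trials with undefined covariates are
    dropped (count reported via the ``n_dropped`` attribute).
    """
    if measure not in _MEASURE_COLUMN:
        raise ValueError(f"unknown measure {measure!r}")
    rec_tab = trial_table[trial_table["phase"] == "recognition"]
    bias = (
        rec_tab.assign(is_old_resp=lambda d: (d["response"] == "old").astype(float))
        .groupby("subject")["is_old_resp"].mean()
    )
    frames = []
    for subject, phases in betas.items():
        enc, rec = phases["encoding"], phases["recognition"]
        cols = _cluster_cols(cluster, enc.mask)
        tw = trialwise_measures(enc, rec, cols if cols.size else None)
        if cols.size < 2:
            tw[:] = np.nan
        # responses live on the master trial table; beta trial rows keep the
        # same index, so outcomes are joined through it
        rt = trial_table.loc[rec.trials.index]
        sel = rt["old"].astype(bool) & rt["response"].notna()
        rows = sel.index[sel]
        df = pd.DataFrame(
            {
                "subject": subject,
                "age": -0.5 if rt["age_group"].iloc[0] == "young" else 0.5,
                "outcome": (rt.loc[rows, "outcome"] == "hit").astype(float),
                "resp_bias": bias.get(subject, np.nan),
                "cat_spec": tw.loc[rows, _MEASURE_COLUMN[measure]],
                "item_rein": tw.loc[rows, "item_rein"],
                "cat_rein": tw.loc[rows, "cat_rein"],
            }
        )
        if hipp_mask is not None:
            hipp = hippocampal_activity(rec, hipp_mask)
            df["hipp"] = pd.Series(hipp, index=rt.index).loc[rows]
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    needed = ["outcome", "cat_spec", "resp_bias"] + (
        ["hipp", "item_rein", "cat_rein"] if hipp_mask is not None else []
    )
    complete = data[needed].notna().all(axis=1)
    out = data[complete].reset_index(drop=True)
    out.attrs["n_dropped"] = int((~complete).sum())
    return out


def run_cluster_glmm_suite(
    clusters: list,
    betas: dict,
    trial_table: pd.DataFrame,
    hipp_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit the trial-wise models for every cluster and tabulate fixed effects.

    ``clusters`` is a list of dicts with keys ``name``, ``measure`` (one of
    the keys accepted by :func:`assemble_trial_dataset`) and ``cluster``
    (a Cluster or boolean mask).  Category-specificity models are fitted for
    every cluster; item-reinstatement clusters additionally receive the
    reinstatement + hippocampal-activity model when an ROI mask is supplied.
    Returns one row per (cluster, model, fixed effect).
    """
    rows = []
    for spec in clusters:
        name, measure, cluster = spec["name"], spec["measure"], spec["cluster"]
        jobs = [("catspec", CATSPEC_FORMULA, None)]
        if measure == "reinstatement_item" and hipp_mask is not None:
            jobs.append(("reinstatement", REINSTATEMENT_FORMULA, hipp_mask))
        for model_name, formula, roi in jobs:
            data = assemble_trial_dataset(
                betas, trial_table, cluster, measure, hipp_mask=roi
            )
            if data.empty or data["outcome"].nunique() < 2:
                warnings.warn(f"cluster {name!r}: no usable trials; skipped")
                continue
            fit = LogisticGLMM.from_formula(formula, data).fit()
            frame = fit.summary_frame()
            frame.insert(0, "cluster", name)
            frame.insert(1, "measure", measure)
            frame.insert(2, "model", model_name)
            frame.insert(3, "term", frame.index)
            frame["re_structure"] = fit.re_structure_used
            frame["converged"] = fit.converged
            frame["n_trials"] = len(data)
            frame["n_dropped"] = data.attrs.get("n_dropped", 0)
            rows.append(frame.reset_index(drop=True))
    if not rows:
        return pd.DataFrame(
            columns=["cluster", "measure", "model", "term", "estimate", "se",
                     "z", "p", "ci_low", "ci_high", "odds_ratio"]
        )
    return pd.concat(rows, ignore_index=True)
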