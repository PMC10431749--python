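"""Cross-run pattern-similarity measures.

All measures are means of Fisher z-transformed Pearson correlations between
trial-wise beta patterns, with pairs restricted to trials from *different*
runs (same-run pairs are contaminated by temporally correlated haemodynamic
noise and never enter any measure):

* within-category similarity: each stimulus against all non-identical
  same-category stimuli in the other run, averaged per stimulus and then
  across stimuli;
* between-category similarity: each stimulus against all other-category
  stimuli in the other run;
* category specificity: within minus between (the distinctiveness measure);
* reinstatement: encoding patterns against recognition patterns, at the item
  level (same item), the category level (same category, different item) and
  between categories, computed against each encoding run separately and then
  averaged across the two encoding runs.

Zero-variance patterns yield undefined correlations; undefined pairs are
dropped from means (with the pair count decremented), never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CATEGORIES, DEFAULT_CLAMP_R

__all__ = [
    "SimilarityValue",
    "fisher_z",
    "fisher_z_corr",
    "pairwise_fisher_z",
    "within_category_similarity",
    "between_category_similarity",
    "category_specificity",
    "reinstatement_measures",
    "category_reinstatement_specificity",
    "item_reinstatement_specificity",
    "trialwise_measures",
]


@dataclass
class SimilarityValue:
    """A similarity estimate in Fisher-z units plus the pair count behind it."""

    value: float
    n_pairs: int

    def __float__(self):
        return float(self.value)


def fisher_z(r, clamp_r: float = DEFAULT_CLAMP_R):
    """atanh with the correlation magnitude first capped at ``clamp_r``."""
    return np.arctanh(np.clip(r, -clamp_r, clamp_r))


def fisher_z_corr(x, y, clamp_r: float = DEFAULT_CLAMP_R) -> float:
    """Fisher z-transformed Pearson correlation of two pattern vectors.

    Returns NaN (an undefined-similarity signal) if either vector has zero
    variance; raises on length mismatch or fewer than 2 samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        return np.nan
    return float(fisher_z((xc @ yc) / (nx * ny), clamp_r))


def pairwise_fisher_z(X1, X2, clamp_r: float = DEFAULT_CLAMP_R) -> np.ndarray:
    """(n1, n2) matrix of Fisher-z correlations between pattern rows.

    Rows with zero variance produce NaN entries.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("pattern lengths differ")
    if X1.shape[1] < 2:
        return np.full((X1.shape[0], X2.shape[0]), np.nan)
    Z1 = X1 - X1.mean(axis=1, keepdims=True)
    Z2 = X2 - X2.mean(axis=1, keepdims=True)
    n1 = np.linalg.norm(Z1, axis=1)
    n2 = np.linalg.norm(Z2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Z1 @ Z2.T) / np.outer(n1, n2)
    r[n1 == 0.0, :] = np.nan
    r[:, n2 == 0.0] = np.nan
    return fisher_z(r, clamp_r)


def _anchor_means(Z: np.ndarray, include: np.ndarray, axis: int = 1):
    """Per-anchor mean over included, finite pairs.

    Returns (means, pair_counts) along the anchor axis (rows by default).
    """
    ok = np.isfinite(Z) & include
    sums = np.where(ok, Z, 0.0).sum(axis=axis)
    counts = ok.sum(axis=axis)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def _subset(beta, voxels):
    X = beta.betas if voxels is None else beta.betas[:, voxels]
    return X


def _phase_pairs(beta, voxels, category, partners, clamp_r):
    """Anchor means for one single-phase measure.

    partners: 'within' (same category, different item) or 'between'
    (other category).  Anchors are every trial of ``category``; partner
    trials always come from the other run.
    """
    trials = beta.trials
    X = _subset(beta, voxels)
    if X.shape[1] < 2:
        return np.array([]), 0
    runs = sorted(trials["run"].unique())
    if len(runs) != 2:
        raise ValueError("cross-run similarity requires exactly 2 runs")
    r1 = trials["run"].to_numpy() == runs[0]
    cat = trials["category"].to_numpy()
    item = trials["item"].to_numpy()
    A, B = np.flatnonzero(r1), np.flatnonzero(~r1)
    Z = pairwise_fisher_z(X[A], X[B], clamp_r)
    if partners == "within":
        inc = (cat[A][:, None] == category) & (cat[B][None, :] == category)
        inc &= item[A][:, None] != item[B][None, :]
    else:
        inc = (cat[A][:, None] == category) & (cat[B][None, :] != category)
    m_a, c_a = _anchor_means(Z, inc, axis=1)
    if partners == "within":
        inc_b = inc
    else:
        inc_b = (cat[B][None, :] == category) & (cat[A][:, None] != category)
    m_b, c_b = _anchor_means(Z, inc_b, axis=0)
    keep_a = cat[A] == category
    keep_b = cat[B] == category
    values = np.concatenate([m_a[keep_a], m_b[keep_b]])
    n_pairs = int(c_a[keep_a].sum() + c_b[keep_b].sum())
    return values, n_pairs


def within_category_similarity(
    beta, voxels=None, category: str = "face", clamp_r: float = DEFAULT_CLAMP_R
) -> SimilarityValue:
    """Mean z-correlation of each stimulus to all non-identical same-category
    stimuli in the other run, averaged across stimuli."""
    values, n_pairs = _phase_pairs(beta, voxels, category, "within", clamp_r)
    if values.size == 0 or not np.isfinite(values).any():
        return SimilarityValue(np.nan, 0)
    return SimilarityValue(float(np.nanmean(values)), n_pairs)


def between_category_similarity(
    beta, voxels=None, category: str = "face", clamp_r: float = DEFAULT_CLAMP_R
) -> SimilarityValue:
    """Mean z-correlation of each stimulus to all other-category stimuli in
    the other run, averaged across stimuli."""
    values, n_pairs = _phase_pairs(beta, voxels, category, "between", clamp_r)
    if values.size == 0 or not np.isfinite(values).any():
        return SimilarityValue(np.nan, 0)
    return SimilarityValue(float(np.nanmean(values)), n_pairs)


def category_specificity(
    beta, voxels=None, category: str = "face", clamp_r: float = DEFAULT_CLAMP_R
) -> float:
    """Within-category minus between-category similarity (distinctiveness)."""
    w = within_category_similarity(beta, voxels, category, clamp_r)
    b = between_category_similarity(beta, voxels, category, clamp_r)
    return w.value - b.value


def reinstatement_measures(
    enc,
    rec,
    voxels=None,
    category: str = "face",
    clamp_r: float = DEFAULT_CLAMP_R,
    include_new: bool = True,
) -> dict:
    """Item-level, within-category and between-category reinstatement.

    Each measure is computed against each encoding run separately and then
    averaged across the two encoding runs.  Same-item pairs are excluded
    from within-category reinstatement.  ``include_new=False`` restricts
    recognition partners to old items.
    """
    Xe = _subset(enc, voxels)
    Xr = _subset(rec, voxels)
    if Xe.shape[1] < 2:
        nanv = SimilarityValue(np.nan, 0)
        return {"within_item": nanv, "within_category": nanv, "between_category": nanv}
    et = enc.trials
    rt = rec.trials
    rsel = np.ones(len(rt), dtype=bool)
    if not include_new:
        rsel = rt["old"].to_numpy(dtype=bool)
    rcat = rt["category"].to_numpy()
    ritem = rt["item"].to_numpy()
    per_run = {"within_item": [], "within_category": [], "between_category": []}
    counts = {k: 0 for k in per_run}
    for run in sorted(et["run"].unique()):
        esel = (et["run"].to_numpy() == run) & (et["category"].to_numpy() == category)
        eidx = np.flatnonzero(esel)
        eitem = et["item"].to_numpy()[eidx]
        Z = pairwise_fisher_z(Xe[eidx], Xr, clamp_r)
        same_item = (eitem[:, None] == ritem[None, :]) & rsel[None, :]
        within = (
            (rcat[None, :] == category)
            & (eitem[:, None] != ritem[None, :])
            & rsel[None, :]
        )
        between = (rcat[None, :] != category) & rsel[None, :]
        for key, inc in (
            ("within_item", same_item),
            ("within_category", within),
            ("between_category", between),
        ):
            m, c = _anchor_means(Z, inc, axis=1)
            per_run[key].append(np.nanmean(m) if np.isfinite(m).any() else np.nan)
            counts[key] += int(c.sum())
    return {
        k: SimilarityValue(
            float(np.nanmean(v)) if np.isfinite(v).any() else np.nan, counts[k]
        )
        for k, v in ((k, np.asarray(v)) for k, v in per_run.items())
    }


def category_reinstatement_specificity(
    enc, rec, voxels=None, category: str = "face", **kw
) -> float:
    """Within-category minus between-category reinstatement."""
    m = reinstatement_measures(enc, rec, voxels, category, **kw)
    return m["within_category"].value - m["between_category"].value


def item_reinstatement_specificity(
    enc, rec, voxels=None, category: str = "face", **kw
) -> float:
    """Within-item minus within-category reinstatement."""
    m = reinstatement_measures(enc, rec, voxels, category, **kw)
    return m["within_item"].value - m["within_category"].value


def trialwise_measures(
    enc,
    rec,
    voxels=None,
    clamp_r: float = DEFAULT_CLAMP_R,
    include_new: bool = True,
) -> pd.DataFrame:
    """Per-trial similarity covariates over a fixed voxel set (e.g. a cluster).

    Indexed by the recognition trial rows, with columns:

    * ``rec_cat_spec``: the trial's recognition-phase category specificity
      (same cross-run pairing rules as the subject-level measure, so the
      per-subject mean over trials equals the subject-level value);
    * ``enc_cat_spec``: the item's encoding-phase category specificity,
      averaged over its two encoding presentations (old items only);
    * ``item_rein``: within-item minus within-category reinstatement for the
      trial (old items only);
    * ``cat_rein``: within- minus between-category reinstatement for the
      trial.

    Voxel sets smaller than 2 voxels yield all-NaN covariates.
    """
    rt = rec.trials
    out = pd.DataFrame(
        index=rt.index,
        columns=["rec_cat_spec", "enc_cat_spec", "item_rein", "cat_rein"],
        dtype=float,
    )
    Xe = _subset(enc, voxels)
    Xr = _subset(rec, voxels)
    if Xr.shape[1] < 2:
        return out
    et = enc.trials
    rcat = rt["category"].to_numpy()
    ritem = rt["item"].to_numpy()
    rrun = rt["run"].to_numpy()
    rold = rt["old"].to_numpy(dtype=bool)
    runs = sorted(rt["run"].unique())

    # recognition-phase trial category specificity (cross-run partners)
    A = np.flatnonzero(rrun == runs[0])
    B = np.flatnonzero(rrun == runs[1])
    Z = pairwise_fisher_z(Xr[A], Xr[B], clamp_r)
    within = (rcat[A][:, None] == rcat[B][None, :]) & (
        ritem[A][:, None] != ritem[B][None, :]
    )
    between = rcat[A][:, None] != rcat[B][None, :]
    for axis, anchors in ((1, A), (0, B)):
        wm, _ = _anchor_means(Z, within, axis=axis)
        bm, _ = _anchor_means(Z, between, axis=axis)
        out.loc[rt.index[anchors], "rec_cat_spec"] = wm - bm

    # reinstatement covariates: recognition trials as anchors, encoding
    # partners per run, averaged across encoding runs
    eitem = et["item"].to_numpy()
    ecat = et["category"].to_numpy()
    erun = et["run"].to_numpy()
    wi_runs, wc_runs, bc_runs, enc_spec_runs = [], [], [], []
    for run in sorted(et["run"].unique()):
        eidx = np.flatnonzero(erun == run)
        Zr = pairwise_fisher_z(Xr, Xe[eidx], clamp_r)  # (n_rec, n_enc_run)
        same_item = ritem[:, None] == eitem[eidx][None, :]
        within = (rcat[:, None] == ecat[eidx][None, :]) & ~same_item
        between = rcat[:, None] != ecat[eidx][None, :]
        wi, _ = _anchor_means(Zr, same_item, axis=1)
        wc, _ = _anchor_means(Zr, within, axis=1)
        bc, _ = _anchor_means(Zr, between, axis=1)
        wi_runs.append(wi)
        wc_runs.append(wc)
        bc_runs.append(bc)

        # encoding-phase trialwise specificity for this run's presentations
        other = np.flatnonzero(erun != run)
        Ze = pairwise_fisher_z(Xe[eidx], Xe[other], clamp_r)
        ew = (ecat[eidx][:, None] == ecat[other][None, :]) & (
            eitem[eidx][:, None] != eitem[other][None, :]
        )
        eb = ecat[eidx][:, None] != ecat[other][None, :]
        ewm, _ = _anchor_means(Ze, ew, axis=1)
        ebm, _ = _anchor_means(Ze, eb, axis=1)
        enc_spec_runs.append(pd.Series(ewm - ebm, index=eitem[eidx]))

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        wi = np.nanmean(np.column_stack(wi_runs), axis=1)
        wc = np.nanmean(np.column_stack(wc_runs), axis=1)
        bc = np.nanmean(np.column_stack(bc_runs), axis=1)
    out["item_rein"] = np.where(rold, wi - wc, np.nan)
    out["cat_rein"] = wc - bc
    enc_spec = pd.concat(enc_spec_runs).groupby(level=0).mean()
    out["enc_cat_spec"] = [
        enc_spec.get(it, np.nan) if is_old else np.nan
        for it, is_old in zip(ritem, rold)
    ]
    return out
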