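"""Independent brute-force oracles used to validate the vectorized paths.

Everything here is deliberately naive (explicit loops, enumeration, BFS) and
shares no code with the implementations it checks.
"""

import math
from collections import deque

import numpy as np

from patsim.similarity import fisher_z_corr


def _rows(beta, phase_filter=None):
    t = beta.trials
    return t


def brute_within_category(beta, voxels, category, clamp_r=1 - 1e-7):
    t = beta.trials
    X = beta.betas[:, voxels]
    runs = sorted(t["run"].unique())
    vals = []
    n_pairs = 0
    for i in range(len(t)):
        ti = t.iloc[i]
        if ti["category"] != category:
            continue
        zs = []
        for j in range(len(t)):
            tj = t.iloc[j]
            if tj["run"] == ti["run"]:
                continue
            if tj["category"] != category or tj["item"] == ti["item"]:
                continue
            z = fisher_z_corr(X[i], X[j], clamp_r)
            if np.isfinite(z):
                zs.append(z)
        if zs:
            vals.append(np.mean(zs))
            n_pairs += len(zs)
    return (np.mean(vals) if vals else np.nan), n_pairs


def brute_between_category(beta, voxels, category, clamp_r=1 - 1e-7):
    t = beta.trials
    X = beta.betas[:, voxels]
    vals = []
    n_pairs = 0
    for i in range(len(t)):
        ti = t.iloc[i]
        if ti["category"] != category:
            continue
        zs = []
        for j in range(len(t)):
            tj = t.iloc[j]
            if tj["run"] == ti["run"] or tj["category"] == category:
                continue
            z = fisher_z_corr(X[i], X[j], clamp_r)
            if np.isfinite(z):
                zs.append(z)
        if zs:
            vals.append(np.mean(zs))
            n_pairs += len(zs)
    return (np.mean(vals) if vals else np.nan), n_pairs


def brute_reinstatement(enc, rec, voxels, category, clamp_r=1 - 1e-7,
                        include_new=True):
    et, rt = enc.trials, rec.trials
    Xe = enc.betas[:, voxels]
    Xr = rec.betas[:, voxels]
    out = {}
    for key in ("within_item", "within_category", "between_category"):
        per_run = []
        for run in sorted(et["run"].unique()):
            vals = []
            for i in range(len(et)):
                ei = et.iloc[i]
                if ei["run"] != run or ei["category"] != category:
                    continue
                zs = []
                for j in range(len(rt)):
                    rj = rt.iloc[j]
                    if not include_new and not rj["old"]:
                        continue
                    same_item = rj["item"] == ei["item"]
                    same_cat = rj["category"] == category
                    want = {
                        "within_item": same_item,
                        "within_category": same_cat and not same_item,
                        "between_category": not same_cat,
                    }[key]
                    if not want:
                        continue
                    z = fisher_z_corr(Xe[i], Xr[j], clamp_r)
                    if np.isfinite(z):
                        zs.append(z)
                if zs:
                    vals.append(np.mean(zs))
            per_run.append(np.mean(vals) if vals else np.nan)
        out[key] = np.nanmean(per_run)
    return out


def brute_rec_trial_spec(rec, voxels, clamp_r=1 - 1e-7):
    """Per-recognition-trial category specificity (cross-run partners)."""
    rt = rec.trials
    X = rec.betas[:, voxels]
    out = {}
    for i in range(len(rt)):
        ti = rt.iloc[i]
        w, b = [], []
        for j in range(len(rt)):
            tj = rt.iloc[j]
            if tj["run"] == ti["run"]:
                continue
            z = fisher_z_corr(X[i], X[j], clamp_r)
            if not np.isfinite(z):
                continue
            if tj["category"] == ti["category"] and tj["item"] != ti["item"]:
                w.append(z)
            elif tj["category"] != ti["category"]:
                b.append(z)
        out[rt.index[i]] = (np.mean(w) - np.mean(b)) if w and b else np.nan
    return out


def enumerate_sphere(radius_mm, voxel_size_mm, reach=20):
    """Lattice enumeration of integer offsets within the Euclidean ball."""
    count = 0
    for dx in range(-reach, reach + 1):
        for dy in range(-reach, reach + 1):
            for dz in range(-reach, reach + 1):
                d = voxel_size_mm * math.sqrt(dx**2 + dy**2 + dz**2)
                if d <= radius_mm + 1e-9:
                    count += 1
    return count


def flood_fill_clusters(binary, connectivity=26):
    """BFS connected components; returns a list of frozensets of coords."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    seen = set()
    comps = []
    coords = list(map(tuple, np.argwhere(binary)))
    members = set(coords)
    for start in coords:
        if start in seen:
            continue
        comp = set()
        queue = deque([start])
        seen.add(start)
        while queue:
            x, y, z = queue.popleft()
            comp.add((x, y, z))
            for dx, dy, dz in offs:
                nb = (x + dx, y + dy, z + dz)
                if nb in members and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return comps


def mixed_anova_ss(data):
    """Hand sum-of-squares decomposition for a balanced 2x2 mixed design.

    data: long DataFrame with subject, age_group (between), category
    (within), pr.  Returns dict of F statistics.
    """
    groups = sorted(data["age_group"].unique())
    cats = sorted(data["category"].unique())
    subjects = data["subject"].unique()
    n_per = len(subjects) // len(groups)
    k = len(cats)
    grand = data["pr"].mean()
    ss_between_subj = 0.0
    for s in subjects:
        ss_between_subj += k * (data.loc[data.subject == s, "pr"].mean() - grand) ** 2
    ss_age = 0.0
    for g in groups:
        sel = data[data.age_group == g]
        ss_age += len(sel) * (sel["pr"].mean() - grand) ** 2
    ss_subj_within = ss_between_subj - ss_age
    ss_cat = 0.0
    for c in cats:
        sel = data[data.category == c]
        ss_cat += len(sel) * (sel["pr"].mean() - grand) ** 2
    ss_cells = 0.0
    for g in groups:
        for c in cats:
            sel = data[(data.age_group == g) & (data.category == c)]
            ss_cells += len(sel) * (sel["pr"].mean() - grand) ** 2
    ss_inter = ss_cells - ss_age - ss_cat
    ss_total = ((data["pr"] - grand) ** 2).sum()
    ss_within = ss_total - ss_between_subj
    ss_err = ss_within - ss_cat - ss_inter
    df_age = len(groups) - 1
    df_subj = len(subjects) - len(groups)
    df_cat = k - 1
    df_int = df_age * df_cat
    df_err = df_subj * df_cat
    return {
        "F_age": (ss_age / df_age) / (ss_subj_within / df_subj),
        "F_category": (ss_cat / df_cat) / (ss_err / df_err),
        "F_interaction": (ss_inter / df_int) / (ss_err / df_err),
    }
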