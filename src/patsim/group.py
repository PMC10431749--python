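"""Behavioral summaries and interindividual statistics.

Corrected recognition (Pr = hit rate - false-alarm rate) per category and
overall, the 2 (age group) x 2 (category) mixed ANOVA, Pearson brain-behavior
correlations with Fisher z-tests for age differences, and nested OLS model
comparisons (partial F) for the encoding-specificity questions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.formula.api as smf
from scipy import stats

from .config import CATEGORIES

__all__ = [
    "compute_pr",
    "pr_long",
    "mixed_anova_2x2",
    "fisher_z_test_two_correlations",
    "nested_model_comparison",
    "cluster_behavior_correlation",
]


def _rates(rec: pd.DataFrame) -> tuple:
    old = rec[rec["old"].astype(bool)]
    new = rec[~rec["old"].astype(bool)]
    hit = np.nan if old.empty else float((old["response"] == "old").mean())
    fa = np.nan if new.empty else float((new["response"] == "old").mean())
    return hit, fa


def compute_pr(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject hit/FA rates and Pr, per category and overall.

    Also derives the response-bias covariate (each subject's overall
    proportion of "old" responses) and flags subjects with Pr < 0 for
    exclusion (responding "old" more readily to new than to old items).
    """
    rec = trial_table[trial_table["phase"] == "recognition"]
    if rec.empty or rec["response"].isna().all():
        raise ValueError("no recognition trials with responses")
    rows = []
    for subject, sub in rec.groupby("subject", sort=False):
        hit, fa = _rates(sub)
        row = {
            "subject": subject,
            "age_group": sub["age_group"].iloc[0],
            "hit_rate": hit,
            "fa_rate": fa,
            "pr": hit - fa,
            "response_bias": float((sub["response"] == "old").mean()),
        }
        for cat in CATEGORIES:
            h, f = _rates(sub[sub["category"] == cat])
            row[f"hit_rate_{cat}"] = h
            row[f"fa_rate_{cat}"] = f
            row[f"pr_{cat}"] = h - f
        row["excluded"] = row["pr"] < 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def pr_long(summary: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-category Pr table for the mixed ANOVA."""
    rows = []
    for subject, row in summary.iterrows():
        for cat in CATEGORIES:
            rows.append(
                {
                    "subject": subject,
                    "age_group": row["age_group"],
                    "category": cat,
                    "pr": row[f"pr_{cat}"],
                }
            )
    return pd.DataFrame(rows)


def mixed_anova_2x2(data: pd.DataFrame) -> pd.DataFrame:
    """2-way mixed factorial ANOVA: age group (between) x category (within).

    Expects the long table from :func:`pr_long`; returns one row per effect
    (age_group, category, interaction) with F, df and p.
    """
    counts = data.groupby("subject")["category"].nunique()
    if (counts != len(CATEGORIES)).any():
        raise ValueError("every subject needs a Pr value for each category")
    aov = pg.mixed_anova(
        data=data, dv="pr", within="category", between="age_group",
        subject="subject",
    )
    aov = aov.rename(columns={"Source": "effect", "p-unc": "p", "p_unc": "p"})
    aov["effect"] = aov["effect"].replace({"Interaction": "age_group:category"})
    return aov[["effect", "DF1", "DF2", "F", "p"]]


def fisher_z_test_two_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """z test for the difference of two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float((np.arctanh(r1) - np.arctanh(r2)) / se)


def nested_model_comparison(data: pd.DataFrame, response: str,
                            block1, block2) -> dict:
    """Partial-F comparison of two nested OLS blocks.

    Blocks are right-hand-side formula strings (patsy syntax, e.g.
    ``"age * rec_spec"``) or lists of terms; block1 must be nested in
    block2.  F = ((RSS1 - RSS2)/ddf) / (RSS2/df2).
    """
    rhs1 = block1 if isinstance(block1, str) else " + ".join(block1)
    rhs2 = block2 if isinstance(block2, str) else " + ".join(block2)
    fit1 = smf.ols(f"{response} ~ {rhs1}", data=data).fit()
    fit2 = smf.ols(f"{response} ~ {rhs2}", data=data).fit()
    ddf = fit1.df_resid - fit2.df_resid
    if ddf <= 0:
        raise ValueError("block2 must add at least one estimable term to block1")
    if fit2.ssr > fit1.ssr + 1e-10:
        raise ValueError("blocks are not nested (RSS increased)")
    F = ((fit1.ssr - fit2.ssr) / ddf) / (fit2.ssr / fit2.df_resid)
    p = float(stats.f.sf(F, ddf, fit2.df_resid))
    return {
        "r2_1": float(fit1.rsquared),
        "r2_2": float(fit2.rsquared),
        "F": float(F),
        "df_num": float(ddf),
        "df_den": float(fit2.df_resid),
        "p": p,
        "fit1": fit1,
        "fit2": fit2,
    }


def cluster_behavior_correlation(values, pr, groups) -> pd.DataFrame:
    """Pearson r of cluster-mean specificity with Pr: all, young, old.

    Constant inputs yield r = NaN with a flag rather than an error.
    """
    values = np.asarray(values, dtype=float)
    pr = np.asarray(pr, dtype=float)
    groups = np.asarray(groups)
    rows = []
    subsets = {"all": np.ones(values.size, dtype=bool),
               "young": groups == "young",
               "old": groups == "old"}
    for name, sel in subsets.items():
        v, y = values[sel], pr[sel]
        ok = np.isfinite(v) & np.isfinite(y)
        v, y = v[ok], y[ok]
        degenerate = v.size < 3 or np.ptp(v) == 0 or np.ptp(y) == 0
        if degenerate:
            rows.append({"group": name, "r": np.nan, "p": np.nan,
                         "n": int(v.size), "degenerate": True})
            continue
        r, p = stats.pearsonr(v, y)
        rows.append({"group": name, "r": float(r), "p": float(p),
                     "n": int(v.size), "degenerate": False})
    return pd.DataFrame(rows).set_index("group")
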