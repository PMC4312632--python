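"""Clinical-characteristics summary of a two-group cohort.

Per-group mean ± SD with independent-samples (pooled-variance) t-tests for
continuous covariates, and percentages with Pearson chi-square tests
(no continuity correction) for binary covariates — the conventions of the
SPSS-style baseline table.  Rounding happens only at the formatting layer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "summarize_continuous",
    "summarize_continuous_from_stats",
    "summarize_categorical",
    "percentage",
    "clinical_summary_table",
]


def _two_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(int)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    return values[groups == 1], values[groups == 0]


def summarize_continuous(values, groups, equal_var: bool = True) -> dict:
    """Per-group mean/SD/n and the two-sided t-test P value.

    Group 1 is the minority (excess) class.  ``equal_var=True`` gives the
    pooled-variance test (the conventional primary row); set False for Welch.
    """
    g1, g0 = _two_groups(values, groups)
    if g1.size < 2 or g0.size < 2:
        raise ValueError("each group needs at least two values")
    t, p = stats.ttest_ind(g1, g0, equal_var=equal_var)
    return {
        "mean1": float(g1.mean()), "sd1": float(g1.std(ddof=1)), "n1": int(g1.size),
        "mean0": float(g0.mean()), "sd0": float(g0.std(ddof=1)), "n0": int(g0.size),
        "t": float(t), "p": float(p),
    }


def summarize_continuous_from_stats(mean1, sd1, n1, mean0, sd0, n0,
                                    equal_var: bool = True) -> dict:
    """Same test computed from printed summary statistics instead of raw data."""
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean0, sd0, n0,
                                      equal_var=equal_var)
    return {"mean1": mean1, "sd1": sd1, "n1": n1,
            "mean0": mean0, "sd0": sd0, "n0": n0,
            "t": float(t), "p": float(p)}


def percentage(present: int, absent: int) -> float:
    """100 * present / (present + absent), the baseline-table percentage."""
    if present < 0 or absent < 0 or present + absent == 0:
        raise ValueError("counts must be non-negative and not both zero")
    return 100.0 * present / (present + absent)


def summarize_categorical(flags, groups) -> dict:
    """Per-group percentage with counts and the Pearson chi-square P value.

    A covariate constant across the whole cohort has an undefined chi-square;
    the result carries ``p = nan`` and ``degenerate = True``.
    """
    flags = np.asarray(flags).astype(int)
    groups = np.asarray(groups).astype(int)
    if flags.shape != groups.shape:
        raise ValueError("flags and groups must align")
    out = {}
    for g in (1, 0):
        f = flags[groups == g]
        if f.size == 0:
            raise ValueError("both groups must be nonempty")
        present = int(f.sum())
        absent = int(f.size - present)
        out[f"present{g}"] = present
        out[f"absent{g}"] = absent
        out[f"pct{g}"] = percentage(present, absent)
    table = np.array(
        [[out["present1"], out["absent1"]], [out["present0"], out["absent0"]]]
    )
    if (table.sum(axis=0) == 0).any():
        out["p"] = float("nan")
        out["chi2"] = float("nan")
        out["degenerate"] = True
        return out
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    out["chi2"] = float(chi2)
    out["p"] = float(p)
    out["degenerate"] = False
    return out


def clinical_summary_table(
    df: pd.DataFrame,
    group_col: str = "group",
    continuous=None,
    categorical=None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Render the baseline table: Total / group-1 / group-0 columns plus P.

    ``continuous`` and ``categorical`` are lists of column names; by default
    numeric non-binary columns are treated as continuous and {0,1} columns
    as categorical.
    """
    groups = df[group_col].to_numpy().astype(int)
    candidates = [c for c in df.columns if c not in (group_col, "sample_id")]
    if continuous is None:
        continuous = [
            c for c in candidates
            if not set(pd.unique(df[c].dropna())) <= {0, 1}
        ]
    if categorical is None:
        categorical = [c for c in candidates if c not in continuous]

    rows = []
    for c in continuous:
        v = df[c].to_numpy(dtype=float)
        s = summarize_continuous(v, groups, equal_var=equal_var)
        rows.append({
            "characteristic": c,
            "total": f"{v.mean():.2f} ± {v.std(ddof=1):.2f}",
            "group1": f"{s['mean1']:.2f} ± {s['sd1']:.2f}",
            "group0": f"{s['mean0']:.2f} ± {s['sd0']:.2f}",
            "p": s["p"],
        })
    for c in categorical:
        f = df[c].to_numpy().astype(int)
        s = summarize_categorical(f, groups)
        tot_p, tot_a = int(f.sum()), int(f.size - f.sum())
        rows.append({
            "characteristic": c,
            "total": f"{percentage(tot_p, tot_a):.1f}% ({tot_p}/{tot_a})",
            "group1": f"{s['pct1']:.1f}% ({s['present1']}/{s['absent1']})",
            "group0": f"{s['pct0']:.1f}% ({s['present0']}/{s['absent0']})",
            "p": s["p"],
        })
    return pd.DataFrame(rows)
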