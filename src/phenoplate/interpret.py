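"""Replicate summaries and differential-fitness testing.

Two contrast axes are supported, mirroring the two questions a screen can
ask:

* ``across_conditions`` (the recommended default for condition-specific
  effects): for each strain, compare its corrected fitness in each
  condition against the same strain in the control condition.
* ``within_condition``: for each strain, compare it against the pooled
  reference population of all other non-grid strains in the same condition.

The default test is Student's pooled two-sample t-test on corrected values:
with the triplicate designs typical of these screens it holds its nominal
size, whereas the Welch-Satterthwaite approximation is noticeably
conservative below n of about 5.  Welch's t-test (for strongly
heteroscedastic contrasts) and a rank-sum (Mann-Whitney) alternative for
heavy-tailed data are available via the ``test`` argument.  Effect size is
reported as the ratio of medians (condition/control), and p-values are
adjusted by Benjamini-Hochberg across all contrasts of one invocation.
Grid-control rows are excluded from testing by default: they define the
reference, they are not hypotheses.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, SchemaError


def summarise_replicates(
    table: pd.DataFrame,
    group_by: Sequence[str],
    value_col: str = "corrected_value",
) -> pd.DataFrame:
    """Per-group n, mean, median, sample SD, CV and missing count."""
    group_by = list(group_by)
    if not group_by:
        raise SchemaError("group_by must name at least one column")
    for col in group_by + [value_col]:
        if col not in table.columns:
            raise SchemaError(f"table lacks column {col!r}")
    g = table.groupby(group_by, sort=True, dropna=False)[value_col]
    out = g.agg(
        n="count",
        mean="mean",
        median="median",
        sd=lambda x: x.std(ddof=1),
        n_missing=lambda x: int(x.isna().sum()),
    ).reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["cv"] = out["sd"] / out["mean"]
    return out


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    arr = np.asarray(p, dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method != "BH":
        raise ConfigurationError(f"unknown adjustment method {method!r}")
    if arr.size == 0:
        return arr.copy()
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out


def _welch_from_stats(m1, v1, n1, m2, v2, n2):
    """Vectorised Welch t-test from per-group summary statistics."""
    m1, v1, n1 = (np.asarray(x, dtype=float) for x in (m1, v1, n1))
    m2, v2, n2 = (np.asarray(x, dtype=float) for x in (m2, v2, n2))
    se2 = v1 / n1 + v2 / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p = np.where(degenerate, np.where(m1 == m2, 1.0, 0.0), p)
    return t, df, p


def _student_from_stats(m1, v1, n1, m2, v2, n2):
    """Vectorised pooled-variance Student t-test from summary statistics."""
    m1, v1, n1 = (np.asarray(x, dtype=float) for x in (m1, v1, n1))
    m2, v2, n2 = (np.asarray(x, dtype=float) for x in (m2, v2, n2))
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se2 = sp2 * (1 / n1 + 1 / n2)
        t = (m1 - m2) / np.sqrt(se2)
        p = 2 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p = np.where(degenerate, np.where(m1 == m2, 1.0, 0.0), p)
    return t, df, p


def test_condition_effects(
    table: pd.DataFrame,
    control_condition: str,
    axis: str = "across_conditions",
    value_col: str = "corrected_value",
    test: str = "student",
    adjust: str = "global",
    include_grid: bool = False,
) -> pd.DataFrame:
    """Differential-fitness contrasts with BH multiple-testing correction.

    Returns one row per contrast with replicate counts, means, the ratio of
    medians (condition/control), the raw and adjusted p-value and, for
    contrasts that could not be tested (fewer than 2 replicates on either
    side), a ``reason`` instead of a p-value.  The output ordering is
    deterministic (sorted by strain, then condition).
    """
    for col in ("strain", "condition", value_col):
        if col not in table.columns:
            raise SchemaError(f"table lacks column {col!r}")
    if axis not in ("across_conditions", "within_condition"):
        raise ConfigurationError(f"unknown contrast axis {axis!r}")
    if test not in ("student", "welch", "ranksum"):
        raise ConfigurationError(f"unknown test {test!r}")
    if adjust not in ("global", "per_condition"):
        raise ConfigurationError(f"unknown adjustment scope {adjust!r}")

    df = table.copy()
    if not include_grid and "is_grid" in df.columns:
        df = df[~df["is_grid"].astype(bool)]
    df = df[np.isfinite(df[value_col].to_numpy(dtype=float))]
    if axis == "across_conditions" and control_condition not in set(df["condition"]):
        raise ConfigurationError(f"control condition {control_condition!r} not in table")

    grp = (
        df.groupby(["strain", "condition"], sort=True)[value_col]
        .agg(n="count", mean="mean", var=lambda x: x.var(ddof=1), median="median", total="sum")
        .reset_index()
    )

    if axis == "across_conditions":
        ctrl = grp[grp["condition"] == control_condition].set_index("strain")
        cond = grp[grp["condition"] != control_condition]
        res = cond.join(ctrl[["n", "mean", "var", "median"]], on="strain", rsuffix="_ctrl")
        res = res.rename(
            columns={
                "n": "n_cond", "mean": "mean_cond", "var": "var_cond", "median": "median_cond",
                "n_ctrl": "n_ctrl", "mean_ctrl": "mean_ctrl", "var_ctrl": "var_ctrl",
                "median_ctrl": "median_ctrl",
            }
        )
        res["n_ctrl"] = res["n_ctrl"].fillna(0).astype(int)
    else:
        # reference population: all other non-grid colonies in the condition
        cond_stats = df.groupby("condition")[value_col].agg(["count", "sum", "median"])
        sq = df.groupby("condition")[value_col].apply(lambda x: float((x**2).sum()))
        res = grp.rename(
            columns={"n": "n_cond", "mean": "mean_cond", "var": "var_cond", "median": "median_cond"}
        )
        N = cond_stats.loc[res["condition"], "count"].to_numpy(float)
        S = cond_stats.loc[res["condition"], "sum"].to_numpy(float)
        S2 = sq.loc[res["condition"]].to_numpy(float)
        n1 = res["n_cond"].to_numpy(float)
        s1 = res["total"].to_numpy(float)
        s2_1 = res["mean_cond"].to_numpy(float) ** 2 * n1 + res["var_cond"].fillna(0).to_numpy(
            float
        ) * (n1 - 1)
        n_ref = N - n1
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_ref = (S - s1) / n_ref
            var_ref = ((S2 - s2_1) - n_ref * mean_ref**2) / (n_ref - 1)
        res["n_ctrl"] = n_ref.astype(int)
        res["mean_ctrl"] = mean_ref
        res["var_ctrl"] = var_ref
        # ratio is taken against the condition-wide median (the plate-median
        # reference); recomputing a leave-one-strain-out median is not
        # worth the cost for a robust statistic
        res["median_ctrl"] = cond_stats.loc[res["condition"], "median"].to_numpy(float)

    valid = (res["n_cond"] >= 2) & (res["n_ctrl"] >= 2)
    stat_fn = _welch_from_stats if test == "welch" else _student_from_stats
    t, dfree, p = stat_fn(
        res["mean_cond"], res["var_cond"].fillna(0), res["n_cond"],
        res["mean_ctrl"], res["var_ctrl"].fillna(0), res["n_ctrl"],
    )
    if test == "ranksum":
        p = _ranksum_pvalues(df, res, control_condition, axis, value_col)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = res["median_cond"].to_numpy(float) / res["median_ctrl"].to_numpy(float)

    out = pd.DataFrame(
        {
            "strain": res["strain"].to_numpy(),
            "condition": res["condition"].to_numpy(),
            "control_condition": control_condition if axis == "across_conditions" else "population",
            "n_cond": res["n_cond"].to_numpy(int),
            "n_ctrl": res["n_ctrl"].to_numpy(int),
            "effect_ratio": ratio,
            "mean_cond": res["mean_cond"].to_numpy(float),
            "mean_ctrl": res["mean_ctrl"].to_numpy(float),
            "p_value": np.where(valid, p, np.nan),
            "test_name": {"student": "student-t", "welch": "welch-t", "ranksum": "mann-whitney"}[test],
            "reason": np.where(valid, "", "insufficient replicates"),
        }
    )
    out = out.sort_values(["strain", "condition"], kind="mergesort").reset_index(drop=True)
    if adjust == "global":
        out["p_adj"] = adjust_pvalues(out["p_value"].to_numpy())
    else:
        out["p_adj"] = np.nan
        for _, idx in out.groupby("condition").groups.items():
            out.loc[idx, "p_adj"] = adjust_pvalues(out.loc[idx, "p_value"].to_numpy())
    return out


def _ranksum_pvalues(df, res, control_condition, axis, value_col):
    """Mann-Whitney U p-values (loop; only used when test='ranksum')."""
    groups = {
        key: sub[value_col].to_numpy(dtype=float)
        for key, sub in df.groupby(["strain", "condition"])
    }
    by_condition = {
        cond: sub[value_col].to_numpy(dtype=float) for cond, sub in df.groupby("condition")
    }
    p = np.full(len(res), np.nan)
    for i, row in enumerate(res.itertuples(index=False)):
        a = groups.get((row.strain, row.condition), np.array([]))
        if axis == "across_conditions":
            b = groups.get((row.strain, control_condition), np.array([]))
        else:
            pool = by_condition[row.condition]
            b = np.concatenate([pool[: 0]] + [v for k, v in groups.items()
                                              if k[1] == row.condition and k[0] != row.strain])
        if len(a) >= 2 and len(b) >= 2:
            p[i] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return p
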