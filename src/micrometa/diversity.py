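"""Fisher's log-series alpha diversity and group comparisons.

Fisher's alpha is the parameter of the log-series species-abundance model,
defined implicitly by S = alpha * ln(1 + N/alpha) for observed richness S and
total count N. It is comparatively insensitive to sample-size differences,
which is why it is used here instead of rarefied richness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

__all__ = ["fisher_alpha", "diversity_table", "compare_diversity"]


def fisher_alpha(S: int, N: int, tol: float = 1e-12) -> float:
    """Solve S = alpha * ln(1 + N/alpha) for alpha by bracketed root-finding.

    The left side is strictly increasing in alpha, so the root is unique.
    Requires S >= 1 and N > S; raises ValueError otherwise (alpha undefined).
    """
    if S < 1:
        raise ValueError("fisher_alpha undefined for S < 1")
    if N <= S:
        raise ValueError("fisher_alpha undefined for N <= S")

    def f(a):
        return a * np.log1p(N / a) - S

    lo = 1e-12
    hi = 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e18:
            raise RuntimeError("failed to bracket fisher alpha root")
    return float(brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))


def diversity_table(table: pd.DataFrame, partition=None, fractions=("whole",)) -> pd.DataFrame:
    """Per-sample S, N and Fisher's alpha, optionally per core/satellite fraction.

    ``partition`` (a :class:`micrometa.partition.PartitionResult`) is required
    for the "core"/"satellite" fractions. Samples where alpha is undefined
    (S = 0 or N <= S) get NaN.
    """
    rows = []
    for fraction in fractions:
        if fraction == "whole":
            sub = table
        else:
            if partition is None:
                raise ValueError("core/satellite fractions require a partition")
            sub = table.loc[sorted(partition.fraction_taxa(fraction) & set(table.index))]
        for sample in table.columns:
            counts = sub[sample]
            S = int((counts > 0).sum())
            N = int(counts.sum())
            try:
                alpha = fisher_alpha(S, N)
            except ValueError:
                alpha = float("nan")
            rows.append({"sample_id": sample, "fraction": fraction, "S": S, "N": N, "alpha": alpha})
    return pd.DataFrame(rows)


def compare_diversity(values, groups, equal_var: bool = True) -> dict:
    """Two-sample t-test of a diversity measure between two groups.

    ``groups`` assigns each value to one of exactly two labels. Returns the t
    statistic, two-sided and one-sided P values (both emitted since published
    tables rarely state the tail), group means and sizes. Pooled-variance
    (classic) test by default; Welch via ``equal_var=False``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 records")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = float("inf") * np.sign(a.mean() - b.mean()), 0.0
        return _ttest_dict(labels, a, b, t, p)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return _ttest_dict(labels, a, b, float(res.statistic), float(res.pvalue))


def _ttest_dict(labels, a, b, t, p_two):
    return {
        "group_a": labels[0],
        "group_b": labels[1],
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "t": t,
        "p_two_sided": p_two,
        "p_one_sided": p_two / 2.0 if t == t else float("nan"),
    }


def diversity_comparisons(div: pd.DataFrame, sample_metadata: pd.DataFrame, group_col: str) -> pd.DataFrame:
    """All pairwise group t-tests of alpha, per fraction, for one grouping column."""
    rows = []
    for fraction, block in div.groupby("fraction"):
        g = sample_metadata[group_col].reindex(block["sample_id"]).to_numpy()
        labels = pd.unique(g)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                mask = np.isin(g, [labels[i], labels[j]])
                try:
                    res = compare_diversity(block["alpha"].to_numpy()[mask], g[mask])
                except ValueError:
                    continue
                res["fraction"] = fraction
                res["grouping"] = group_col
                rows.append(res)
    return pd.DataFrame(rows)
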