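"""Median-split helminth-burden dysbiosis analysis.

Hosts are split at the median helminth count (high group strictly above the
median). For every taxon present in both burden groups, the volcano analysis
reports the log2 fold change of mean relative abundance (high over low;
positive = higher under high burden) and a two-sample t-test P value on
per-sample relative abundances, flagged at P < 0.05 without multiplicity
correction (a Benjamini-Hochberg column is emitted alongside but does not
drive the flags). Taxa detected in only one group have infinite fold change
and are routed instead to the gained/lost rank-abundance accounting, tagged
with their core/satellite labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from micrometa.comparison import to_relative

__all__ = ["BurdenSplit", "split_by_median", "volcano", "gained_lost"]


@dataclass
class BurdenSplit:
    """High/low burden grouping at the median count (high = strictly above)."""

    median: float
    high: list
    low: list

    @property
    def n_high(self) -> int:
        return len(self.high)

    @property
    def n_low(self) -> int:
        return len(self.low)


def split_by_median(burden: pd.Series) -> BurdenSplit:
    """Split ids by their burden count at the median; ties go to the low group."""
    burden = burden.dropna()
    if burden.nunique() < 2:
        raise ValueError("need >= 2 distinct burden values to split")
    med = float(burden.median())
    high = list(burden.index[burden > med])
    low = list(burden.index[burden <= med])
    if not high:
        raise ValueError("high-burden group is empty")
    return BurdenSplit(median=med, high=high, low=low)


def _bh_adjust(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        prev = min(prev, p[idx] * m / k)
        adj[idx] = prev
    return adj


def _group_columns(table, split):
    high = [c for c in table.columns if c in set(split.high)]
    low = [c for c in table.columns if c in set(split.low)]
    if not high or not low:
        raise ValueError("both burden groups need >= 1 sample in the table")
    return high, low


def volcano(table: pd.DataFrame, split: BurdenSplit, partition=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-taxon fold change and t-test between burden groups.

    ``split.high``/``split.low`` must name columns of ``table``. Only taxa with
    reads in both groups are analysed. Returns a DataFrame indexed by taxon
    with fraction label (if a partition is given), mean relative abundances,
    log2 fold change, raw ratio, t, P, BH-adjusted P and the significance flag.
    """
    high, low = _group_columns(table, split)
    rel = to_relative(table)
    H = rel[high].to_numpy(float)
    L = rel[low].to_numpy(float)
    in_high = table[high].sum(axis=1).to_numpy() > 0
    in_low = table[low].sum(axis=1).to_numpy() > 0
    both = in_high & in_low

    rows = []
    for k in np.flatnonzero(both):
        h, l = H[k], L[k]
        mh, ml = h.mean(), l.mean()
        if h.std(ddof=1) == 0 and l.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if np.isclose(mh, ml) else (np.inf * np.sign(mh - ml), 0.0)
        else:
            res = stats.ttest_ind(h, l, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "taxon_id": table.index[k],
                "mean_rel_high": mh,
                "mean_rel_low": ml,
                "fold_change": mh / ml,
                "log2_fold_change": float(np.log2(mh / ml)),
                "t": t,
                "P": p,
            }
        )
    out = pd.DataFrame(rows).set_index("taxon_id")
    if len(out):
        out["P_bh"] = _bh_adjust(out["P"].to_numpy())
        out["significant"] = out["P"] < alpha
    if partition is not None:
        out.insert(0, "fraction", partition.taxa["label"].reindex(out.index))
    out.attrs["n_high"] = len(high)
    out.attrs["n_low"] = len(low)
    out.attrs["alpha"] = alpha
    return out


def gained_lost(table: pd.DataFrame, split: BurdenSplit, partition=None) -> pd.DataFrame:
    """Taxa detected in exactly one burden group, as a rank-abundance listing.

    status "lost" = reads only in the low-burden group; "gained" = only in the
    high-burden group. Mean relative abundance is taken within the group where
    the taxon occurs; rows are sorted by status then descending abundance.
    """
    high, low = _group_columns(table, split)
    rel = to_relative(table)
    in_high = table[high].sum(axis=1) > 0
    in_low = table[low].sum(axis=1) > 0

    rows = []
    for taxon in table.index[in_low & ~in_high]:
        rows.append({"taxon_id": taxon, "status": "lost", "mean_rel_abundance": rel.loc[taxon, low].mean()})
    for taxon in table.index[in_high & ~in_low]:
        rows.append({"taxon_id": taxon, "status": "gained", "mean_rel_abundance": rel.loc[taxon, high].mean()})
    out = pd.DataFrame(rows, columns=["taxon_id", "status", "mean_rel_abundance"]).set_index("taxon_id")
    if partition is not None:
        out.insert(0, "fraction", partition.taxa["label"].reindex(out.index))
    out = out.sort_values(["status", "mean_rel_abundance"], ascending=[True, False])
    out["rank"] = out.groupby("status")["mean_rel_abundance"].rank(ascending=False, method="first").astype(int)
    return out
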