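"""Bray-Curtis dissimilarity, ANOSIM and SIMPER.

ANOSIM (Clarke 1993) ranks all pairwise dissimilarities (ties mid-ranked) and
contrasts mean between-group and within-group ranks:

    R = (mean_rank_between - mean_rank_within) / (n(n-1)/4),

scaled to [-1, 1]. Significance comes from random relabelling of samples with
the add-one rule, ties counted as extreme:
P = (1 + #{permuted R >= observed R}) / (1 + n_perm).

SIMPER decomposes the mean between-group Bray-Curtis dissimilarity into
additive per-taxon contributions: for each between-group sample pair (i, j)
taxon k contributes |x_ik - x_jk| / sum_l(x_il + x_jl); averaging over pairs
and summing over taxa recovers the overall mean dissimilarity exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import distance
from scipy.stats import rankdata

__all__ = ["bray_curtis", "bray_curtis_matrix", "anosim", "anosim_exact", "simper", "AnosimResult", "to_relative"]


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(distance.braycurtis(x, y))


def to_relative(table: pd.DataFrame, percent: bool = True) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 100 by default)."""
    colsum = table.sum(axis=0)
    rel = table.divide(colsum.where(colsum > 0, 1.0), axis=1)
    return rel * 100.0 if percent else rel


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between the samples (columns) of a table."""
    dm = distance.squareform(distance.pdist(table.to_numpy(float).T, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.columns, columns=table.columns)


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: object
    group_sizes: dict
    mean_between: float   # mean between-group dissimilarity (original scale)
    sd_between: float

    def summary(self) -> str:
        sizes = ", ".join(f"{k}: {v}" for k, v in self.group_sizes.items())
        return (
            f"ANOSIM R = {self.R:.4f}, P = {self.p:.4g} "
            f"({self.n_permutations} permutations; groups {sizes}; "
            f"between-group dissimilarity {self.mean_between:.3f} +/- {self.sd_between:.3f} s.d.)"
        )


def _condensed_indices(n):
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _anosim_r(ranks, between, denom):
    return (ranks[between].mean() - ranks[~between].mean()) / denom


def _prepare(dm, groups):
    d = dm.to_numpy(float) if isinstance(dm, pd.DataFrame) else np.asarray(dm, float)
    groups = np.asarray(groups)
    n = d.shape[0]
    if d.shape != (n, n) or len(groups) != n:
        raise ValueError("dissimilarity matrix and groups are inconsistent")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")
    ii, jj = _condensed_indices(n)
    vals = d[ii, jj]
    ranks = rankdata(vals)  # mid-rank ties
    denom = n * (n - 1) / 4.0
    return groups, labels, counts, ii, jj, vals, ranks, denom


def anosim(dm, groups, n_perm: int = 9999, seed=None) -> AnosimResult:
    """ANOSIM permutation test on a square dissimilarity matrix.

    ``groups`` labels each row/column. The permutation null relabels samples at
    random ``n_perm`` times.
    """
    groups, labels, counts, ii, jj, vals, ranks, denom = _prepare(dm, groups)
    between = groups[ii] != groups[jj]
    r_obs = _anosim_r(ranks, between, denom)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        g = rng.permutation(groups)
        r = _anosim_r(ranks, g[ii] != g[jj], denom)
        if r >= r_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return AnosimResult(
        R=float(r_obs),
        p=float(p),
        n_permutations=n_perm,
        seed=seed,
        group_sizes={str(l): int(c) for l, c in zip(labels, counts)},
        mean_between=float(vals[between].mean()),
        sd_between=float(vals[between].std(ddof=1)) if between.sum() > 1 else float("nan"),
    )


def anosim_exact(dm, groups) -> AnosimResult:
    """Exact ANOSIM for two groups: enumerate all distinct relabellings.

    P = #{relabellings with R >= observed} / #relabellings (the identity is one
    of them). Feasible for small n only.
    """
    groups, labels, counts, ii, jj, vals, ranks, denom = _prepare(dm, groups)
    if len(labels) != 2:
        raise ValueError("exact enumeration implemented for exactly 2 groups")
    n = len(groups)
    between_obs = groups[ii] != groups[jj]
    r_obs = _anosim_r(ranks, between_obs, denom)
    n_ge = total = 0
    for members in itertools.combinations(range(n), int(counts[0])):
        g = np.full(n, labels[1], dtype=object)
        g[list(members)] = labels[0]
        r = _anosim_r(ranks, g[ii] != g[jj], denom)
        total += 1
        if r >= r_obs - 1e-12:
            n_ge += 1
    return AnosimResult(
        R=float(r_obs),
        p=n_ge / total,
        n_permutations=total,
        seed=None,
        group_sizes={str(l): int(c) for l, c in zip(labels, counts)},
        mean_between=float(vals[between_obs].mean()),
        sd_between=float(vals[between_obs].std(ddof=1)) if between_obs.sum() > 1 else float("nan"),
    )


def simper(table: pd.DataFrame, groups, relative: bool = True) -> pd.DataFrame:
    """SIMPER decomposition of between-group Bray-Curtis dissimilarity.

    ``table`` is taxa x samples; ``groups`` labels each sample with one of two
    group names. Abundances are converted to per-sample percentages unless
    ``relative=False``. Returns a per-taxon DataFrame sorted by decreasing
    contribution, with columns av_dissim (mean contribution to pairwise
    dissimilarity), contrib_pct, cum_pct and mean abundance per group;
    av_dissim sums to the overall mean between-group dissimilarity.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("SIMPER compares exactly 2 groups")
    if (groups == labels[0]).sum() == 0 or (groups == labels[1]).sum() == 0:
        raise ValueError("both groups need >= 1 sample")
    x = to_relative(table) if relative else table.astype(float)
    A = x.loc[:, groups == labels[0]].to_numpy()
    B = x.loc[:, groups == labels[1]].to_numpy()
    # diff[k, i, j] = |A_ki - B_kj|; denom[i, j] = total abundance of pair (i, j)
    diff = np.abs(A[:, :, None] - B[:, None, :])
    denom = A.sum(axis=0)[:, None] + B.sum(axis=0)[None, :]
    contrib = (diff / denom[None, :, :]).mean(axis=(1, 2))
    total = contrib.sum()
    order = np.argsort(-contrib, kind="stable")
    out = pd.DataFrame(
        {
            "av_dissim": contrib[order],
            "contrib_pct": 100.0 * contrib[order] / total,
            f"mean_abundance_{labels[0]}": A.mean(axis=1)[order],
            f"mean_abundance_{labels[1]}": B.mean(axis=1)[order],
        },
        index=table.index[order],
    )
    out.insert(2, "cum_pct", out["contrib_pct"].cumsum())
    out.attrs["overall_mean_dissimilarity"] = float(total)
    out.attrs["groups"] = (labels[0], labels[1])
    return out
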