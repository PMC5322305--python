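"""Raup-Crick probability-based similarity and assembly classification.

For two presence/absence communities over a shared metacommunity taxon pool,
the null model draws, for each community, its observed richness in taxa from
the pool without replacement, with selection probability proportional to each
taxon's pool occupancy (or uniform under the equal-weight model). The
similarity index is the probability that a null pair shares fewer taxa than
observed, counting ties at half weight:

    S_RC = [ #(null shared < observed) + 0.5 * #(null shared = observed) ] / n_rand

so S_RC > 0.95 marks pairs significantly *more* similar than chance
(deterministically similar), S_RC < 0.05 significantly less similar
(deterministically dissimilar), and the band between them stochastic assembly.
The half-weight tie rule makes S_RC approximately uniform when both
communities are themselves draws from the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["raup_crick_pair", "raup_crick_matrix", "classify_assembly", "AssemblyClassification", "pair_values"]


def _weights(pool_occupancies, pool_size, null_model):
    if null_model == "equal_weight" or pool_occupancies is None:
        return np.ones(pool_size, dtype=float)
    if null_model != "occupancy_weighted":
        raise ValueError(f"unknown null model {null_model!r}")
    w = np.asarray(pool_occupancies, dtype=float)
    if (w <= 0).any():
        raise ValueError("pool occupancies must be positive for occupancy weighting")
    return w


def _null_masks(rng, weights, richness, n_rand):
    """Boolean (n_rand, pool) masks of weighted draws without replacement.

    Uses exponential sort keys (Efraimidis-Spirakis): the `richness` smallest
    values of Exp(1)/w select taxa with probability proportional to w.
    """
    pool = len(weights)
    keys = rng.exponential(size=(n_rand, pool)) / weights
    idx = np.argpartition(keys, richness - 1, axis=1)[:, :richness]
    mask = np.zeros((n_rand, pool), dtype=bool)
    mask[np.repeat(np.arange(n_rand), richness), idx.ravel()] = True
    return mask


def _src_from_null(null_shared, observed_shared, n_rand):
    below = np.count_nonzero(null_shared < observed_shared)
    ties = np.count_nonzero(null_shared == observed_shared)
    return (below + 0.5 * ties) / n_rand


def raup_crick_pair(
    presence_a,
    presence_b,
    pool_occupancies=None,
    n_rand: int = 1000,
    seed=None,
    null_model: str = "occupancy_weighted",
) -> float:
    """Monte-Carlo Raup-Crick similarity of two presence/absence communities.

    ``presence_a``/``presence_b`` are boolean (or 0/1) vectors over the
    metacommunity pool; ``pool_occupancies`` gives each pool taxon's occupancy
    frequency (required for the occupancy-weighted null).
    """
    a = np.asarray(presence_a).astype(bool)
    b = np.asarray(presence_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("presence vectors must share the taxon pool")
    pool = a.size
    ra, rb = int(a.sum()), int(b.sum())
    if ra < 1 or rb < 1:
        raise ValueError("each community needs richness >= 1")
    if max(ra, rb) > pool:
        raise ValueError("richness exceeds pool size")
    w = _weights(pool_occupancies, pool, null_model)
    rng = np.random.default_rng(seed)
    shared = int((a & b).sum())
    null_shared = (_null_masks(rng, w, ra, n_rand) & _null_masks(rng, w, rb, n_rand)).sum(axis=1)
    return float(_src_from_null(null_shared, shared, n_rand))


def raup_crick_matrix(
    table: pd.DataFrame,
    n_rand: int = 1000,
    seed=None,
    null_model: str = "occupancy_weighted",
) -> pd.DataFrame:
    """Pairwise S_RC over all samples of a metacommunity count (or presence) table.

    The pool is the set of taxa present in at least one sample; occupancy
    weights come from that pool. One set of ``n_rand`` null communities is
    drawn per sample (at its observed richness) and reused across its pairs.
    Returns a symmetric DataFrame with NaN on the diagonal (self-pairs are not
    defined) and NaN for samples with zero richness.
    """
    presence = (table.to_numpy() > 0)
    occ = presence.sum(axis=1)
    pool_mask = occ > 0
    presence = presence[pool_mask]
    w = _weights(occ[pool_mask], int(pool_mask.sum()), null_model)

    samples = list(table.columns)
    n = len(samples)
    rng = np.random.default_rng(seed)
    richness = presence.sum(axis=0)
    masks = [
        _null_masks(rng, w, int(r), n_rand) if r >= 1 else None
        for r in richness
    ]
    out = np.full((n, n), np.nan)
    for i in range(n):
        if masks[i] is None:
            continue
        for j in range(i + 1, n):
            if masks[j] is None:
                continue
            obs = int((presence[:, i] & presence[:, j]).sum())
            null_shared = (masks[i] & masks[j]).sum(axis=1)
            out[i, j] = out[j, i] = _src_from_null(null_shared, obs, n_rand)
    return pd.DataFrame(out, index=samples, columns=samples)


def pair_values(src: pd.DataFrame) -> np.ndarray:
    """Upper-triangle S_RC values of a pairwise matrix, NaN pairs dropped."""
    arr = src.to_numpy(float)
    iu = np.triu_indices(arr.shape[0], k=1)
    vals = arr[iu]
    return vals[~np.isnan(vals)]


@dataclass
class AssemblyClassification:
    """Percentages of pairs in each assembly class, with an S_RC histogram."""

    n_pairs: int
    pct_det_similar: float      # S_RC > 0.95
    pct_stochastic: float       # 0.05 <= S_RC <= 0.95
    pct_det_dissimilar: float   # S_RC < 0.05
    histogram: pd.DataFrame     # bin_left, bin_right, count (width 0.05)

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "pct_det_similar": self.pct_det_similar,
            "pct_stochastic": self.pct_stochastic,
            "pct_det_dissimilar": self.pct_det_dissimilar,
        }


def classify_assembly(src, bin_width: float = 0.05) -> AssemblyClassification:
    """Classify pairwise S_RC values into deterministic/stochastic fractions.

    Accepts a pairwise matrix (DataFrame) or a flat array of pair values.
    """
    vals = pair_values(src) if isinstance(src, pd.DataFrame) else np.asarray(src, float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no S_RC pairs to classify")
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("S_RC values must lie in [0, 1]")
    n = vals.size
    det_sim = np.count_nonzero(vals > 0.95)
    det_dis = np.count_nonzero(vals < 0.05)
    stoch = n - det_sim - det_dis
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    counts, _ = np.histogram(vals, bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    return AssemblyClassification(
        n_pairs=int(n),
        pct_det_similar=100.0 * det_sim / n,
        pct_stochastic=100.0 * stoch / n,
        pct_det_dissimilar=100.0 * det_dis / n,
        histogram=hist,
    )
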