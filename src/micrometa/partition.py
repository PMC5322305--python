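"""Occupancy-abundance structure and core/satellite partitioning.

Each taxon of a metacommunity (one gut site's set of samples) is summarised by
its occupancy (number of samples with a non-zero count), mean abundance over
*all* samples (zeros included) and index of dispersion I = variance/mean. Under
random (Poisson) placement, (n-1)*I follows a chi-square distribution with n-1
degrees of freedom, so taxa whose dispersion exceeds the upper confidence limit
are non-randomly distributed ("core"); the rest, together with taxa observed in
a single sample only (whose spatial dispersion carries no information), form
the "satellite" group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TaxonStats",
    "PartitionResult",
    "dispersion_index",
    "chi2_confidence_limit",
    "occupancy_abundance_regression",
    "partition_core_satellite",
    "partition_bookkeeping",
]


@dataclass
class TaxonStats:
    taxon_id: str
    occupancy: int
    mean_abundance: float
    variance: float
    dispersion: float  # NaN when the mean is zero (undefined)


@dataclass
class PartitionResult:
    """Per-taxon statistics and core/satellite labels for one metacommunity.

    ``taxa`` is a DataFrame indexed by taxon id with columns occupancy,
    mean_abundance, variance, dispersion, label ("core"/"satellite") and
    satellite_reason ("random_dispersion"/"single_sample", empty for core).
    """

    taxa: pd.DataFrame
    n_samples: int
    tail: float
    chi2_limit: float          # threshold on the I scale: chi2_{1-tail, n-1}/(n-1)
    regression: dict           # occupancy ~ log10(mean abundance) OLS summary
    core_abundance_share: float

    @property
    def n_core(self) -> int:
        return int((self.taxa["label"] == "core").sum())

    @property
    def n_satellite(self) -> int:
        return int((self.taxa["label"] == "satellite").sum())

    @property
    def core_taxa(self) -> set:
        return set(self.taxa.index[self.taxa["label"] == "core"])

    @property
    def satellite_taxa(self) -> set:
        return set(self.taxa.index[self.taxa["label"] == "satellite"])

    def fraction_taxa(self, fraction: str) -> set:
        if fraction == "whole":
            return set(self.taxa.index)
        if fraction in ("core", "satellite"):
            return set(self.taxa.index[self.taxa["label"] == fraction])
        raise ValueError(f"unknown fraction {fraction!r}")


def dispersion_index(counts) -> float:
    """Variance-to-mean ratio of one taxon's counts across all samples.

    Sample variance (n-1 denominator); zeros included. Returns NaN when the
    mean is zero (taxon absent: dispersion undefined).
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("counts must be a 1-D vector over >= 2 samples")
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(x.var(ddof=1) / m)


def chi2_confidence_limit(n_samples: int, tail: float = 0.025) -> float:
    """Upper confidence limit for the index of dispersion under Poisson placement.

    Returns chi2_{1-tail, n-1} / (n-1): a taxon with I above this value (i.e.
    (n-1)*I above the chi-square quantile — the comparison is identical on
    either scale) is over-dispersed beyond what random placement explains.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < tail < 0.5:
        raise ValueError("tail must lie in (0, 0.5)")
    df = n_samples - 1
    return float(stats.chi2.isf(tail, df) / df)


def occupancy_abundance_regression(table: pd.DataFrame) -> dict:
    """OLS fit of occupancy on log10(mean abundance) across taxa.

    Uses taxa with non-zero mean. Returns slope, intercept, r2, F (1, m-2 df)
    and the two-sided P value.
    """
    occ = (table > 0).sum(axis=1).to_numpy(float)
    mean = table.mean(axis=1).to_numpy(float)
    keep = mean > 0
    if keep.sum() < 3:
        raise ValueError("need >= 3 taxa with non-zero mean abundance")
    x = np.log10(mean[keep])
    y = occ[keep]
    fit = stats.linregress(x, y)
    m = keep.sum()
    # for simple regression F(1, m-2) = t^2
    f_stat = float("inf") if fit.stderr == 0 else (fit.slope / fit.stderr) ** 2
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "F": float(f_stat),
        "df": (1, int(m) - 2),
        "P": float(fit.pvalue),
        "n_taxa": int(m),
    }


def partition_core_satellite(table: pd.DataFrame, tail: float = 0.025) -> PartitionResult:
    """Partition a metacommunity's taxa into core and satellite groups.

    Taxa observed in exactly one sample are satellites (reason
    ``single_sample``); remaining taxa whose dispersion does not exceed the
    upper chi-square confidence limit are satellites (``random_dispersion``);
    all others are core. All-zero taxa are dropped (not part of the
    metacommunity). Also reports the share of total reads held by the core
    group and the occupancy-abundance regression.
    """
    if table.shape[1] < 2:
        raise ValueError("metacommunity needs >= 2 samples")
    table = table.loc[(table.sum(axis=1) > 0)]
    if table.empty:
        raise ValueError("count table has no non-zero taxa")
    n = table.shape[1]
    limit = chi2_confidence_limit(n, tail)

    arr = table.to_numpy(float)
    occ = (arr > 0).sum(axis=1)
    mean = arr.mean(axis=1)
    var = arr.var(axis=1, ddof=1)
    disp = np.divide(var, mean, out=np.full(len(mean), np.nan), where=mean > 0)

    label = np.where(disp > limit, "core", "satellite")
    reason = np.where(label == "satellite", "random_dispersion", "")
    single = occ == 1
    label[single] = "satellite"
    reason[single] = "single_sample"

    taxa = pd.DataFrame(
        {
            "occupancy": occ.astype(int),
            "mean_abundance": mean,
            "variance": var,
            "dispersion": disp,
            "label": label,
            "satellite_reason": reason,
        },
        index=table.index,
    )
    total = arr.sum()
    core_share = float(arr[label == "core"].sum() / total) if total > 0 else float("nan")
    try:
        regression = occupancy_abundance_regression(table)
    except ValueError:  # fewer than 3 non-zero taxa: regression not meaningful
        regression = None
    return PartitionResult(
        taxa=taxa,
        n_samples=n,
        tail=tail,
        chi2_limit=limit,
        regression=regression,
        core_abundance_share=core_share,
    )


def partition_bookkeeping(n_total: int, n_random_dispersion: int, n_single_sample: int) -> dict:
    """Core/satellite accounting from metacommunity totals.

    Satellites = randomly dispersed taxa + single-sample taxa; core is the
    remainder. Useful for checking a partition against published totals.
    """
    if min(n_total, n_random_dispersion, n_single_sample) < 0:
        raise ValueError("counts must be non-negative")
    n_sat = n_random_dispersion + n_single_sample
    if n_sat > n_total:
        raise ValueError("satellite components exceed the total")
    return {"n_core": n_total - n_sat, "n_satellite": n_sat, "n_total": n_total}
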