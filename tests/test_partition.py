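"""Core/satellite partitioning: dispersion, chi-square limits, labels, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from micrometa.partition import (
    chi2_confidence_limit,
    dispersion_index,
    occupancy_abundance_regression,
    partition_bookkeeping,
    partition_core_satellite,
)


def brute_force_partition(table, tail=0.025):
    """Independent reimplementation: per-taxon I and chi-square bound from first
    principles (explicit loops, raw chi-square scale)."""
    n = table.shape[1]
    labels = {}
    for taxon in table.index:
        x = [float(v) for v in table.loc[taxon]]
        occ = sum(v > 0 for v in x)
        if occ == 0:
            continue
        if occ == 1:
            labels[taxon] = "satellite"
            continue
        m = sum(x) / n
        var = sum((v - m) ** 2 for v in x) / (n - 1)
        statistic = (n - 1) * var / m
        labels[taxon] = "core" if statistic > stats.chi2.ppf(1 - tail, n - 1) else "satellite"
    return labels


class TestDispersionIndex:
    def test_zero_variance(self):
        assert dispersion_index([2, 2, 2, 2]) == 0.0

    def test_hand_computed(self):
        # mean 2, sample variance (3*(0-2)^2 + (8-2)^2)/3 = 16
        assert dispersion_index([0, 0, 0, 8]) == pytest.approx(8.0)

    def test_zero_mean_flagged_nan(self):
        assert np.isnan(dispersion_index([0, 0, 0]))

    def test_poisson_converges_to_one(self, rng):
        x = rng.poisson(7.0, size=20000)
        se = np.sqrt(2.0 / (len(x) - 1))
        assert abs(dispersion_index(x) - 1.0) < 3 * se + 0.01


class TestChi2Limit:
    def test_n2_quantile(self):
        assert chi2_confidence_limit(2, 0.025) == pytest.approx(5.0239, abs=1e-3)

    def test_matches_quantile_oracle(self):
        expected = stats.chi2.isf(0.025, 38) / 38
        assert chi2_confidence_limit(39, 0.025) == pytest.approx(expected, abs=1e-9)

    def test_limit_grows_without_bound_as_tail_shrinks(self):
        tails = [0.1, 0.025, 1e-4, 1e-12, 1e-300]
        limits = [chi2_confidence_limit(10, t) for t in tails]
        assert all(b > a for a, b in zip(limits, limits[1:]))
        assert limits[-1] > 100  # effectively no taxon can be non-random

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chi2_confidence_limit(1)
        with pytest.raises(ValueError):
            chi2_confidence_limit(10, 0.7)


class TestRegression:
    def test_exact_collinearity(self):
        """Table built so occupancy = 2 * log10(mean abundance) exactly -> r2 = 1."""
        n = 10
        tab = pd.DataFrame(0, index=[f"t{i}" for i in range(4)], columns=[f"s{i}" for i in range(n)])
        for taxon, mean in zip(tab.index, [10, 100, 10_000, 100_000]):
            occ = int(2 * np.log10(mean))
            tab.loc[taxon, tab.columns[:occ]] = n * mean // occ
        assert ((tab > 0).sum(axis=1) == 2 * np.log10(tab.mean(axis=1))).all()
        reg = occupancy_abundance_regression(tab)
        assert reg["r2"] == pytest.approx(1.0, abs=1e-12)
        assert reg["slope"] == pytest.approx(2.0, abs=1e-9)

    def test_hand_least_squares_five_taxa(self):
        tab = pd.DataFrame(
            [[3, 0, 1, 0], [10, 12, 0, 4], [50, 60, 40, 30], [1, 0, 0, 0], [7, 2, 9, 1]],
            index=list("abcde"),
            columns=[f"s{i}" for i in range(4)],
        )
        reg = occupancy_abundance_regression(tab)
        x = np.log10(tab.mean(axis=1).to_numpy())
        y = (tab > 0).sum(axis=1).to_numpy(float)
        # hand least squares
        xm, ym = x.mean(), y.mean()
        slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
        r2 = (((x - xm) * (y - ym)).sum() ** 2) / (((x - xm) ** 2).sum() * ((y - ym) ** 2).sum())
        assert reg["slope"] == pytest.approx(slope, abs=1e-12)
        assert reg["r2"] == pytest.approx(r2, abs=1e-12)

    def test_default_synthetic_positive(self, prov_table):
        reg = occupancy_abundance_regression(prov_table)
        assert reg["slope"] > 0 and reg["P"] < 0.05


class TestPartition:
    def test_single_sample_taxon_is_satellite(self):
        tab = pd.DataFrame(
            np.vstack([np.eye(1, 10, 0) * 50, np.full((1, 10), 5)]),
            index=["once", "everywhere"],
            columns=[f"s{i}" for i in range(10)],
        ).astype(int)
        res = partition_core_satellite(tab)
        assert res.taxa.loc["once", "label"] == "satellite"
        assert res.taxa.loc["once", "satellite_reason"] == "single_sample"

    def test_zero_dispersion_is_satellite(self):
        tab = pd.DataFrame(
            {f"s{i}": [4, v] for i, v in enumerate([0, 9, 3, 0, 7, 0, 2, 5, 1, 8])},
            index=["constant", "filler"],
        )
        res = partition_core_satellite(tab)
        assert res.taxa.loc["constant", "label"] == "satellite"

    def test_exhaustive_exclusive_labels(self, prov_table):
        res = partition_core_satellite(prov_table)
        assert res.n_core + res.n_satellite == len(res.taxa)
        assert set(res.taxa["label"]) <= {"core", "satellite"}

    def test_monotone_in_tail(self, prov_table):
        """A stricter (smaller) tail raises the limit: core set can only shrink."""
        loose = partition_core_satellite(prov_table, tail=0.05).core_taxa
        strict = partition_core_satellite(prov_table, tail=0.005).core_taxa
        assert strict <= loose

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(2, 10))
        n_samp = int(rng.integers(3, 12))
        tab = pd.DataFrame(
            rng.poisson(rng.uniform(0.2, 20, size=(n_taxa, 1)), size=(n_taxa, n_samp)),
            index=[f"t{i}" for i in range(n_taxa)],
            columns=[f"s{i}" for i in range(n_samp)],
        )
        tab = tab.loc[tab.sum(axis=1) > 0]
        if tab.empty:
            return
        res = partition_core_satellite(tab)
        expected = brute_force_partition(tab)
        assert res.taxa["label"].to_dict() == expected

    def test_truth_recovery_on_default_synthetic(self, default_sim, prov_table):
        """>= 90% of designed core and satellite taxa get the right label."""
        res = partition_core_satellite(prov_table)
        truth = default_sim.truth
        present = set(prov_table.index)
        true_core = truth.core_taxa["proventriculus"] & present
        true_sat = truth.satellite_taxa["proventriculus"] & present
        core_rec = len(true_core & res.core_taxa) / len(true_core)
        sat_rec = len(true_sat & res.satellite_taxa) / len(true_sat)
        assert core_rec >= 0.9
        assert sat_rec >= 0.9

    def test_core_holds_most_reads(self, prov_table):
        res = partition_core_satellite(prov_table)
        assert res.core_abundance_share > 0.5

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            partition_core_satellite(pd.DataFrame(np.zeros((3, 4)), columns=list("abcd")))


class TestBookkeeping:
    @pytest.mark.parametrize(
        "total,random_disp,single,core,satellite",
        [
            (291, 126, 69, 96, 195),
            (409, 165, 103, 141, 268),
            (334, 97, 98, 139, 195),
        ],
    )
    def test_metacommunity_accounting(self, total, random_disp, single, core, satellite):
        book = partition_bookkeeping(total, random_disp, single)
        assert book["n_core"] == core
        assert book["n_satellite"] == satellite

    def test_overflow_rejected(self):
        with pytest.raises(ValueError):
            partition_bookkeeping(10, 8, 5)
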