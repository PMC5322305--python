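"""Generator: reproducibility, demographic moments, count-table structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micrometa.partition import dispersion_index, occupancy_abundance_regression
from micrometa.simulate import (
    BURDEN_RANGE,
    FEMALE_BURDEN,
    MALE_BURDEN,
    GeneratorConfig,
    generate_host_metadata,
    simulate_dataset,
)


def clamped_normal_mean(mu, sigma, lo, hi):
    """Analytic mean of clip(X, lo, hi) for X ~ Normal(mu, sigma) (oracle)."""
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    # E[clip] = mu - E[(X-hi)+] + E[(lo-X)+], via partial expectations
    upper_excess = sigma * (stats.norm.pdf(b) - b * (1 - stats.norm.cdf(b)))
    lower_deficit = sigma * (stats.norm.pdf(a) + a * stats.norm.cdf(a))
    return mu - upper_excess + lower_deficit


class TestHostMetadata:
    def test_default_config_ranges_and_sexes(self):
        hosts = generate_host_metadata(GeneratorConfig(n_hosts=40, seed=1))
        assert len(hosts) == 40
        assert hosts["nematode_count"].between(*BURDEN_RANGE).all()
        assert set(hosts["sex"]) == {"M", "F"}
        assert hosts["age_years"].between(3, 17).all()
        assert hosts["chicks_fledged"].between(1, 3).all()
        assert set(hosts["phenology"]) <= {"early", "late"}

    def test_single_host(self):
        hosts = generate_host_metadata(GeneratorConfig(n_hosts=1, seed=0))
        assert len(hosts) == 1
        assert hosts["nematode_count"].iloc[0] >= BURDEN_RANGE[0]

    def test_nonpositive_host_count_rejected(self):
        with pytest.raises(ValueError):
            generate_host_metadata(GeneratorConfig(n_hosts=0))

    def test_sex_burden_difference_matches_clamped_moment_oracle(self):
        """Monte-Carlo male-female burden gap matches the analytic clamped-normal
        difference (~8 before clamping) within 3 s.e. at n = 10 000 per sex."""
        hosts = generate_host_metadata(GeneratorConfig(n_hosts=20000, seed=3))
        males = hosts.loc[hosts.sex == "M", "nematode_count"]
        females = hosts.loc[hosts.sex == "F", "nematode_count"]
        expected = clamped_normal_mean(*MALE_BURDEN, *BURDEN_RANGE) - clamped_normal_mean(
            *FEMALE_BURDEN, *BURDEN_RANGE
        )
        se = np.sqrt(males.var() / len(males) + females.var() / len(females))
        observed = males.mean() - females.mean()
        assert abs(observed - expected) < 3 * se
        assert abs(observed - 8.0) < 1.0  # close to the nominal 28 - 20 gap

    def test_seed_reproducibility(self):
        a = generate_host_metadata(GeneratorConfig(seed=5))
        b = generate_host_metadata(GeneratorConfig(seed=5))
        c = generate_host_metadata(GeneratorConfig(seed=6))
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)


class TestCounts:
    def test_same_seed_bit_identical_different_seed_differs(self):
        a = simulate_dataset(GeneratorConfig(seed=2))
        b = simulate_dataset(GeneratorConfig(seed=2))
        c = simulate_dataset(GeneratorConfig(seed=3))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert not a.counts.equals(c.counts)

    def test_counts_nonnegative_ids_unique(self, default_sim):
        assert (default_sim.counts.to_numpy() >= 0).all()
        assert default_sim.counts.index.is_unique
        assert default_sim.counts.columns.is_unique
        assert default_sim.counts.to_numpy().dtype.kind == "i"

    def test_site_sample_counts(self, default_sim):
        sizes = default_sim.sample_metadata["site"].value_counts().to_dict()
        assert sizes == {"cloaca": 39, "proventriculus": 38, "faeces": 10}

    def test_truth_partition_exhaustive_disjoint(self, default_sim):
        t = default_sim.truth
        all_taxa = set(default_sim.counts.index)
        for site in t.core_taxa:
            assert t.core_taxa[site] | t.satellite_taxa[site] == all_taxa
            assert not (t.core_taxa[site] & t.satellite_taxa[site])
            assert t.single_sample_taxa[site] <= t.satellite_taxa[site]

    def test_occupancy_abundance_relationship_positive(self, prov_table):
        reg = occupancy_abundance_regression(prov_table)
        assert reg["slope"] > 0
        assert reg["P"] < 0.05

    def test_core_overdispersed_satellites_poisson(self, default_sim, prov_table):
        """Truth-core taxa have mean dispersion >> 1; non-single-sample
        truth-satellites average I ~ 1 within 3 s.e. (Poisson placement)."""
        truth = default_sim.truth
        present = set(prov_table.index)
        core = sorted(truth.core_taxa["proventriculus"] & present)
        sats = sorted(
            (truth.satellite_taxa["proventriculus"] - truth.single_sample_taxa["proventriculus"])
            - set(truth.responders["proventriculus"])
            & present
        )
        sats = [t for t in sats if t in present]
        core_I = [dispersion_index(prov_table.loc[t]) for t in core]
        sat_I = np.array([dispersion_index(prov_table.loc[t]) for t in sats])
        sat_I = sat_I[~np.isnan(sat_I)]
        assert np.nanmean(core_I) > 5.0
        n = prov_table.shape[1]
        # Var(I) ~ 2/(n-1) for Poisson; s.e. of the mean over taxa
        se = np.sqrt(2.0 / (n - 1) / len(sat_I))
        assert abs(sat_I.mean() - 1.0) < 3 * se + 0.05

    def test_single_sample_taxa_present_once(self, default_sim, prov_table):
        singles = default_sim.truth.single_sample_taxa["proventriculus"] & set(prov_table.index)
        occ = (prov_table.loc[sorted(singles)] > 0).sum(axis=1)
        assert (occ == 1).all()

    def test_determinism_one_identical_presence(self):
        """Degenerate template: full determinism, core-only pool, deep libraries
        make every sample's presence/absence identical."""
        cfg = GeneratorConfig(
            n_hosts=12,
            sites={"gut": 12},
            n_taxa=30,
            frac_core=1.0,
            determinism={"gut": 1.0},
            burden_effect={"gut": 0.0},
            library_size_mean=1e6,
            seed=4,
        )
        sim = simulate_dataset(cfg)
        presence = sim.counts.to_numpy() > 0
        assert (presence == presence[:, [0]]).all()

    def test_zero_burden_effect_null_fold_changes(self):
        """With burden_effect = 0, responder taxa show no systematic fold-change
        excess over non-responders."""
        cfg = GeneratorConfig(
            n_hosts=40,
            sites={"gut": 40},
            n_taxa=200,
            burden_effect={"gut": 0.0},
            seed=9,
        )
        sim = simulate_dataset(cfg)
        tab = sim.counts.loc[sim.counts.sum(axis=1) > 0]
        burden = sim.sample_metadata["nematode_count"]
        high = burden > burden.median()
        rel = tab / tab.sum(axis=0)
        mh = rel.loc[:, high.values].mean(axis=1)
        ml = rel.loc[:, ~high.values].mean(axis=1)
        both = (mh > 0) & (ml > 0)
        lfc = np.log2(mh[both] / ml[both])
        resp = lfc.index.isin(sim.truth.responders["gut"])
        if resp.sum() >= 3:
            t, p = stats.ttest_ind(np.abs(lfc[resp]), np.abs(lfc[~resp]))
            assert p > 0.01

    def test_invalid_frac_core_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(frac_core=1.5).validate()
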