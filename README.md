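# micrometa

Metacommunity analysis of host-associated microbiota.

`micrometa` is for ecologists and microbiologists analysing 16S phylotype
count tables from wild-host gut surveys — settings where a population of hosts
is sampled at one or more gastrointestinal sites and each site's set of
samples is treated as a metacommunity of local bacterial communities. It
implements, as a tested and reusable pipeline, the classical toolkit for
asking how such communities are structured and what host factors shape them:

- **Core/satellite partitioning.** Each taxon's index of dispersion
  I = s²/x̄ across the n samples is compared against the chi-square limit for
  Poisson placement ((n−1)·I ~ χ²ₙ₋₁): taxa over-dispersed beyond
  χ²₁₋tail,ₙ₋₁ are non-randomly distributed **core** taxa; randomly dispersed
  and single-sample taxa form the rare **satellite** group. The
  occupancy–abundance relationship (occupancy vs log₁₀ mean abundance, OLS)
  checks metacommunity coherence.
- **Fisher's log-series alpha** per local community (solving
  S = α·ln(1 + N/α)), with two-sample t-tests between sites, sexes and
  whole/core/satellite fractions.
- **Raup–Crick stochasticity.** Monte-Carlo null (default 1000
  randomizations, occupancy-weighted draws) giving pairwise
  S_RC ∈ [0, 1]; pairs with S_RC > 0.95 are deterministically similar,
  < 0.05 deterministically dissimilar, between stochastic.
- **Bray–Curtis / ANOSIM / SIMPER.** Rank-based ANOSIM
  R = (r̄_B − r̄_W)/(n(n−1)/4) with seeded permutation (and exact enumeration)
  P values; SIMPER decomposes mean between-group dissimilarity into per-taxon
  contributions that sum exactly to the total.
- **CCA with forward selection.** Canonical correspondence analysis of the
  chi-square-standardized table on host variables (age, sex, burden,
  phenology), with Monte-Carlo forward selection (1000 permutations,
  P < 0.05) and percent-of-variation reporting including an "undetermined"
  remainder.
- **Burden dysbiosis.** Hosts split at the median helminth count; per-taxon
  log2 fold changes and t-tests between high- and low-burden groups (volcano
  table), with taxa detected in only one group routed to a gained/lost
  rank-abundance accounting.

A synthetic-data generator (`micrometa.simulate`) reproduces the statistical
structure these analyses assume — over-dispersed templated core taxa vs
Poisson satellites, sex-linked host mass and parasite burden, per-site
determinism gradients, burden-responder taxa — and returns ground-truth labels
so every stage can be tested for parameter recovery. See `docs/methods.md`
for the models, conventions and generator details.

## Worked example

```python
import micrometa as mm

sim = mm.simulate_dataset(mm.GeneratorConfig(seed=1))
meta = sim.sample_metadata
cols = meta.index[meta["site"] == "proventriculus"]
table = sim.counts[cols]
table = table.loc[table.sum(axis=1) > 0]

part = mm.partition_core_satellite(table, tail=0.025)
print(f"taxa: {len(part.taxa)}  core: {part.n_core}  satellite: {part.n_satellite}")
print(f"chi2 limit on I: {part.chi2_limit:.3f}   core read share: {100*part.core_abundance_share:.2f}%")
r = part.regression
print(f"occupancy ~ log10(abundance): r2 = {r['r2']:.2f}, F(1,{r['df'][1]}) = {r['F']:.1f}, P = {r['P']:.2g}")

src = mm.raup_crick_matrix(table, n_rand=1000, seed=2)
cls = mm.classify_assembly(src)
print(f"Raup-Crick: {cls.pct_det_similar:.1f}% deterministic-similar, "
      f"{cls.pct_stochastic:.1f}% stochastic ({cls.n_pairs} pairs)")

split = mm.split_by_median(meta.loc[table.columns, "nematode_count"])
volc = mm.volcano(table, split, part)
gl = mm.gained_lost(table, split, part)
print(f"burden median {split.median:.0f}: {int(volc['significant'].sum())} taxa with significant "
      f"fold changes; {(gl.status=='lost').sum()} lost, {(gl.status=='gained').sum()} gained in the high group")
```

prints

```
taxa: 291  core: 101  satellite: 190
chi2 limit on I: 1.505   core read share: 99.97%
occupancy ~ log10(abundance): r2 = 0.95, F(1,289) = 6107.1, P = 2.1e-196
Raup-Crick: 100.0% deterministic-similar, 0.0% stochastic (703 pairs)
burden median 25: 8 taxa with significant fold changes; 63 lost, 47 gained in the high group
```

Read top to bottom: this simulated stomach-site metacommunity of 291 taxa
splits into 101 over-dispersed core taxa holding 99.97% of all reads and 190
satellites; occupancy rises steeply and near-linearly with log abundance (a
coherent metacommunity); every pair of local communities is far more similar
than the occupancy-weighted null expects (deterministic assembly); and the
high-burden host group shows a modest number of significant per-taxon shifts
plus a turnover of rare taxa detected in only one burden group.

The same stages are available from the shell:

```sh
micrometa simulate --seed 1 --out-dir demo
micrometa partition --table demo/counts.tsv --out demo/partition.tsv
micrometa raupcrick --table demo/counts.tsv --seed 2 --out demo/src.tsv
micrometa run-all --seed 1 --out-dir demo_full     # full per-site pipeline
```

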