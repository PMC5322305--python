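# Methods

`micrometa` analyses taxa-by-sample 16S count tables from linked host-associated
microbiomes within a metacommunity framework. This note documents the models and
procedures, the conventions adopted where the methodology is genuinely
underdetermined, the synthetic-data generator, and the numerical choices.

## Core/satellite partitioning by index of dispersion

Each taxon of a metacommunity (the set of samples from one gut site) gets an
occupancy (samples with count > 0), a mean abundance over *all* samples (zeros
included), and an index of dispersion I = s²/x̄ with the n−1 variance
denominator. Under random (Poisson) placement across the n samples,
(n−1)·I ~ χ²ₙ₋₁, so taxa with (n−1)·I above the upper quantile χ²₁₋tail,ₙ₋₁
are non-randomly (over-)dispersed. The partition rule is:

- taxa occurring in exactly one sample → **satellite** (`single_sample`): a
  single occurrence carries no dispersion information;
- taxa with I at or below χ²₁₋tail,ₙ₋₁/(n−1) → **satellite**
  (`random_dispersion`);
- everything else → **core**.

`tail` defaults to 0.025, i.e. the upper bound of the central 95% interval.
Field descriptions of this procedure speak of a "2.5% confidence limit line"
without fixing the tail unambiguously; we use the upper quantile (non-random ⇔
over-dispersed beyond the 97.5th percentile), consistent with the observation
that essentially no taxa fall below the symmetric lower limit in real tables.
The tail is configurable and the choice is a documented convention, not a claim
about any particular study's intent. The partition is exhaustive and exclusive;
shrinking the tail (stricter limit) can only move taxa from core to satellite.

The occupancy–abundance regression is an ordinary least-squares fit of
occupancy on log₁₀(mean abundance) over taxa with non-zero mean; F = t² with
(1, m−2) degrees of freedom.

## Fisher's log-series alpha

α solves S = α·ln(1 + N/α), where S is observed richness and N the total
count. The left side is strictly increasing in α, so the root is unique; we
bracket it and solve with Brent's method to a residual below 1e−8. α is
undefined (flagged NaN in tables) for S = 0 or N ≤ S. No rarefaction is
applied: α's comparative insensitivity to sample size is the reason this index
is used. Group comparisons use classic pooled-variance two-sample t-tests by
default (Welch available); both two-sided and one-sided P values are emitted
because published tables rarely state the tail.

## Raup–Crick similarity and assembly classification

For presence/absence communities A and B over the metacommunity pool, the null
draws, n_rand times (default 1000), richness(A) and richness(B) taxa without
replacement, with probability proportional to pool occupancy (the
`occupancy_weighted` model; `equal_weight` is available — for equal weights the
null shared-richness distribution is exactly hypergeometric, which the tests
exploit as a closed-form oracle). Then

S_RC = [#(null shared < observed) + ½·#(null shared = observed)] / n_rand.

The half-weight tie rule makes S_RC approximately uniform under the null, so
the classification S_RC > 0.95 (deterministically similar), S_RC < 0.05
(deterministically dissimilar), else stochastic, has ≈5% nominal rates on null
data. Weighted sampling without replacement uses exponential sort keys
(Efraimidis–Spirakis), vectorised over randomizations; in the pairwise matrix
one set of null communities is drawn per sample and reused across its pairs
(unbiased per pair, values across pairs mildly correlated — the standard
trade-off for tractability). Note a consequence of the tie rule: two sparse,
disjoint communities are *not* classified as dissimilar, because the null
itself almost always shares zero taxa.

## ANOSIM and SIMPER

ANOSIM ranks all pairwise Bray–Curtis dissimilarities (ties mid-ranked) and
computes R = (r̄_between − r̄_within)/(n(n−1)/4), in [−1, 1]. P values use
random relabellings with the add-one rule, ties counted as extreme:
P = (1 + #{R_perm ≥ R_obs})/(1 + n_perm); default 9999 permutations, seed
required. For two groups an exhaustive enumeration over all C(n, n₁)
relabellings is provided for exact P on small n.

SIMPER operates on per-sample relative abundances (percent): for each
between-group pair (i, j), taxon k contributes |x_ik − x_jk| / Σ_l(x_il + x_jl);
contributions are averaged over pairs and sum *exactly* to the mean
between-group Bray–Curtis dissimilarity (identity verified to 1e−10 in tests).
Whether published SIMPER tables used raw or relative abundances is typically
unstated; relative is the default and the choice is configurable.

## CCA with Monte-Carlo forward selection

With counts F (n samples × m taxa), grand total f, P = F/f, row weights r and
column weights c, the chi-square standardized matrix is
Q = (P − rcᵀ)/√(rcᵀ); total inertia ‖Q‖² equals the table's chi-square
statistic divided by f. Explanatory variables are weighted-centered,
standardized and scaled by √r; the canonical eigenvalues are the squared
singular values of the projection of Q onto their span. Two-level categorical
variables (sex, phenology) are coded 0/1; age and burden enter as raw numbers.
Rank deficiency is detected by SVD and flagged.

Forward selection adds, at each step, the candidate with the largest additional
constrained inertia, computed via Gram–Schmidt orthogonalization against the
already-selected basis (so the addition is a rank-one update). The candidate is
admitted only if permuting its values across samples (selected variables held
fixed; 1000 permutations by default; add-one P) gives P < α = 0.05. Reported
output carries both the conditional (selection-step) percentage of total
inertia per admitted variable — with the remainder as "undetermined" — and
each candidate's marginal (variable-alone) percentage, since published
percent-variation tables do not always distinguish the two.

## Burden dysbiosis

Hosts are split at the median helminth count; the high group is strictly above
the median. For taxa with reads in both groups the volcano analysis reports
log2(mean relative abundance high / low) (positive = higher under high burden)
and a pooled two-sample t-test on per-sample relative abundances, flagged at
P < 0.05 *without* multiplicity correction — this mirrors the standard volcano
presentation; a Benjamini–Hochberg column is emitted alongside for reference
but does not drive the flags. Taxa with reads in exactly one group (infinite
fold change) are routed to a gained/lost rank-abundance accounting, tagged with
their core/satellite labels. Fold change is reported on the log2 scale for
symmetry, with the raw ratio alongside.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, with
ground-truth labels for recovery testing. Defaults encode the study design it
mirrors: 40 hosts; three gut sites with 38/39/10 samples drawn from random
host subsets; 300-taxon pools; log-normal library sizes (mean 70 000 reads,
σ = 0.65, CV ≈ 0.7).

- **Hosts.** Sex M with probability 22/40; body mass Normal(1896.2, 121.9) g
  for males, Normal(1614.0, 103.1) g for females; nematode burden
  Normal(28, 14.8) / Normal(20, 8.1), rounded and clamped to the observed
  population range [3, 45] (clamping pulls the male–female gap from the
  nominal 8 to ≈7.3 — the tests check against the analytic clamped-normal
  moments); age uniform on 3–17 years; 1–3 chicks fledged; early phenology
  with probability 23/40.
- **Core taxa** (fraction 0.33 of the pool per site) share a log-normal
  (σ = 1.5) site template of relative abundances; each sample's expected
  composition is d·template + (1−d)·ε with per-sample log-normal noise ε and
  site determinism d (defaults 0.95 / 0.8 / 0.5 for
  proventriculus / cloaca / faeces). Counts are negative-binomial
  (dispersion k = 5) around library × composition, giving variance-to-mean
  ratios ≫ 1 and near-total occupancy, and concentrating ≈99.9% of reads in
  the core group.
- **Satellite taxa** are independent Poisson with low per-sample rates
  (log-uniform on [0.05, 0.8], site-scaled 0.5 / 1.0 / 1.5 to create the
  downstream alpha-diversity gradient); rates are deliberately *not* scaled by
  library depth, since a log-normal depth factor would turn them into
  over-dispersed Poisson mixtures and break the I ≈ 1 contract. A fraction
  (0.35) of satellites is placed in exactly one sample with a small count.
- **Responders** (10 per site) have expected counts multiplied by
  exp(β·z) where z is the host's standardized burden and β is the site's
  signed effect (defaults 0.3 / 0.8 / 1.5 growing away from the infection
  site, mirroring the downstream strengthening of burden associations).

One `numpy.random.Generator` drives everything: a fixed seed reproduces tables
bit-for-bit.

What the generator does *not* emulate: phylogenetic or co-occurrence structure
among taxa, sequencing error and chimeras, compositional coupling beyond the
shared library total, taxon sharing structure between sites beyond independent
site templates over a common pool, and zero-inflation mechanisms other than
low Poisson rates. Passing recovery tests therefore demonstrates that the
implementations measure what they claim under the assumed statistical
structure — not that real gut communities satisfy those assumptions.

## Numerical choices and problem sizes

- χ² quantiles via `scipy.stats.chi2.isf` (accurate for extreme tails);
  dispersion undefined (NaN) at zero mean; all-zero taxa are dropped from a
  metacommunity before partitioning.
- Fisher's alpha bracketing starts at [1e−12, 1] and grows the upper bracket
  tenfold until it straddles the root.
- Permutation P values always use the add-one rule and count ties as extreme
  (conservative); every Monte-Carlo routine takes an explicit seed.
- Degenerate t-tests (both groups constant) return t = 0, P = 1 when means
  agree and P = 0 otherwise, rather than NaN.
- Test-suite and acceptance problem sizes (e.g. 200-replicate type-I
  calibrations at 199 permutations, 500 null Raup–Crick pairs at 1000
  randomizations, 10⁵ randomizations for the enumeration check) were chosen so
  the whole suite completes in well under a minute of compute while keeping
  3-s.e. binomial bands around the 5% nominal rates informative.

## Known limitations

- The Raup–Crick matrix reuses per-sample null draws across pairs; pair values
  are individually unbiased but not independent. Use `raup_crick_pair` directly
  when independence across pairs matters.
- SIMPER and ANOSIM assume two groups for the exact/decomposition paths;
  multi-group comparisons are performed pairwise.
- Forward selection tests permute the raw candidate; conditioning is via
  orthogonalization against selected variables, not restricted permutations
  within blocks.
- `anosim_exact` enumerates C(n, n₁) relabellings and is intended for n ≲ 15.
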