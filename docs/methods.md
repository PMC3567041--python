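# Methods

This note documents the statistical procedures, conventions and tunable
parameters of `trflp`, the design choices taken where several
conventions exist, and what the synthetic-data validation does and does
not establish.

## Profile processing

A T-RFLP profile is a per-sample mapping of fragment length to
fluorescence intensity. Processing steps and their conventions:

* **Binning.** Fragment sizes are rounded to the nearest integer base
  pair, *halves away from zero* (113.5 → 114). Peaks outside the
  retained range (default 34–600 bp, configurable) are dropped after
  rounding; peaks of one sample rounding to the same integer are summed,
  so binning conserves total in-range fluorescence exactly. The
  intensity column may be peak height or area; both are treated
  identically.
* **Alignment.** Instrument drift makes the same fragment appear at
  ±1 bp across runs. As a deterministic surrogate for manual curation,
  columns are merged greedily in descending total-intensity order (ties
  broken toward smaller bp): each unvisited column absorbs all other
  unvisited columns within `tolerance_bp` (default 1) and the merged
  column keeps the seed's length (the intensity-weighted mode). A column
  joins at most one group, which breaks chains like 100–101–102
  deterministically. `tolerance_bp=0` disables merging.
* **VPT noise filtering.** For each candidate percentage *q* in a grid
  (default 0.01–5% in steps of 0.01), peaks below *q*% of their sample's
  total fluorescence are removed and the Pearson correlation between
  per-sample total fluorescence and retained-peak count is computed.
  True peaks' counts should not depend on how bright a run was; noise
  peak counts do. The chosen *q* minimizes |r|; a zero-variance count
  vector is defined as r = 0 so fully uniform grids stay eligible, and
  ties are broken toward the smaller *q* (retain more data). Samples
  left with fewer than 2 T-RFs at the chosen threshold are dropped with
  a warning rather than failing the run; an error is raised only when no
  sample survives.

## Distances

* Community: Bray–Curtis on **within-sample rank-transformed**
  abundances — inside each sample, nonzero intensities are replaced by
  ascending average-tie ranks and zeros stay zero. This reading of
  "Spearman rank-transformed" keeps Bray–Curtis inside [0, 1], keeps the
  per-sample interpretation, and makes the distance depend only on
  abundance *order* (hence invariant to any monotone rescaling of
  intensities). The alternative convention — ranking each T-RF across
  samples — is available via `rank_transform(mode="per-trf")` but is not
  the default.
* Environment: Euclidean distance on variables standardized to mean 0,
  SD 1 (sample SD, n−1). Rows with any missing selected variable are
  excluded with a log message before standardization; pairwise-complete
  handling is deliberately not used (simplicity and determinism).

## Permutation tests

All tests fix the distance matrix and permute labels; p-values use
(1 + exceedances)/(1 + n_perm) with an inclusive ≥, so p > 0 and the
identity permutation is effectively always counted. Default n_perm is
999. Tied distances always receive average ranks. `method="exact"`
(ANOSIM, two-way ANOSIM, RELATE) enumerates every distinct labeling and
reports the exact proportion — feasible for n ≲ 8 and used by the test
suite against brute-force oracles.

* **ANOSIM**: R = (r̄_B − r̄_W)/(M/2) over ranks of all M pairwise
  distances. Requires ≥ 2 groups of ≥ 2 samples.
* **Two-way crossed ANOSIM**: the statistic for a factor is the
  unweighted mean of one-way R computed within each level of the other
  factor, with ranks recomputed inside each stratum; permutations are
  constrained within strata. Strata where the tested factor has no
  within- and between-group pairs contribute nothing; the test errors
  only when no stratum is usable.
* **PERMANOVA**: SS_total = Σd²/n over all pairs, SS_within summed per
  group with its own n, pseudo-F = (SS_B/df_B)/(SS_W/df_W). On
  univariate Euclidean input this reproduces the classical one-way
  ANOVA F to 1e-9, which the tests assert.
* **RELATE**: Spearman correlation of the two upper triangles, one
  matrix's rows/columns permuted simultaneously; one-sided (ρ ≥ observed).

## Resistance ratio

ratio = |R_com|/|R_env|, computed per station from storm vs. non-storm
ANOSIM on the community and environmental matrices restricted to that
station.

* **Absolute-value convention.** ANOSIM R can be slightly negative under
  the null; the published per-station table prints positive ratios for
  stations with negative R of either sign, and |R_com|/|R_env| — not the
  signed quotient — reproduces every printed row. The signed variant
  exists behind `signed=True` but is not the default.
* **Class boundaries.** high < 0.5 ≤ intermediate ≤ 1.5 < low. The 1.5
  edge is the explicitly stated one; 0.5 is a midpoint convention for
  "close to zero" vs "around 1". Both configurable.
* **Caution flag.** Raised when max(|R_env|, |R_com|) < 0.2 — the unique
  simple round threshold consistent with all published flagged/unflagged
  rows (flagged maximum 0.155, unflagged minimum 0.217) — or when the
  ratio is infinite. A large ratio with a tiny |R_env| can reflect
  dispersal-driven turnover under near-constant conditions rather than
  low resistance, hence the flag rather than a hard error.
* **Degenerate denominators.** R_env = 0 with R_com ≠ 0 yields +inf with
  caution forced; both zero yields 0 with caution.
* Ratios are kept as exact quotients internally and rounded (half-up,
  2 dp) only at presentation.
* Stations lacking 2 storm and 2 non-storm samples with complete
  environmental data are skipped with a logged reason, not errored.

## Ordination and clustering

* **NMDS** uses non-metric SMACOF (iterative majorization with isotonic
  monotone regression, primary/weak tie treatment) with `n_starts`
  random initializations (default 20); the configuration with the lowest
  Kruskal stress-1, √(Σ(d − d̂)²/Σd²), is returned, centered. The
  per-start stresses are exposed so "best of starts" is checkable.
* **Station K-means** vectorizes each station as the concatenation of
  its relative-abundance profiles over a common date set (default: every
  date observed anywhere; stations missing any date are excluded and
  logged, mirroring surveys where only a subset of sites gets dense
  storm sampling). Clustering uses scikit-learn's KMeans (Lloyd/Elkan)
  with multiple starts rather than the Hartigan–Wong variant named in
  the original analysis: no installed Python implementation of
  Hartigan–Wong exists, the choice of update rule is immaterial for the
  well-separated-regime use the package validates (Adjusted Rand = 1),
  and results are seeded and reproducible.
* **UPGMA on pairwise ANOSIM R**: between-site R values can be negative,
  so the matrix is shifted by max(0, −min R) before average-linkage
  clustering and the shift is reported with the dendrogram. Heights are
  non-decreasing and match a naive O(n³) implementation on test
  fixtures.

## Environment linkage

* **BIO-ENV** enumerates every nonempty subset of ≤ 15 variables (up to
  `max_subset_size`), standardizes, builds the Euclidean matrix, and
  ranks subsets by Spearman ρ against the community matrix (ties:
  smaller subset, then lexicographic). A RELATE p is attached only for
  the winning subset and is labeled a-posteriori: testing a subset
  selected for its correlation is biased, and the package surfaces that
  rather than hiding it.
* **SIMPER** decomposes each between-group pair's Bray–Curtis distance
  into per-T-RF terms δᵢ(j,k) = |yᵢⱼ−yᵢₖ|/Σₛ(yₛⱼ+yₛₖ) — an exact
  identity, asserted to 1e-12 — then averages over pairs and expresses
  contributions as % of the overall average dissimilarity. It operates
  on whatever transform the caller applied; the pipeline feeds it
  relative abundances (the source convention is unstated; rank-transform
  input is equally valid and available). Identical groups return zero
  contributions with a degenerate flag.

## In-silico fragment prediction

Coordinates are 0-based half-open internally; reported lengths are
1-based biological lengths including the full labeled primer. The
restriction-site search starts at the primer match itself, so a site
overlapping the primer 3' end is counted. Sequences failing the forward
scan are scanned on the reverse complement (clones insert in either
orientation) and the orientation is reported. Primer matching allows
`max_mismatches` positions (default 0) outside the IUPAC sets; an
ambiguous base in the sequence matches nothing without mismatch budget.
Because empirical fragment sizes drift by about a base pair against
predictions (capillary migration), lineage matching takes a
`tolerance_bp` (default 1).

## Synthetic scenarios

The generator states a world and every downstream validation measures
against it. The default (`kaneohe_like`) scenario: 23 stations in three
regimes (6 offshore, 15 coastal, 2 freshwater), 12 sampled densely
through the storm window; routine sampling every 21 days Feb–Sep 2006
plus post-storm days +1, +4, +7, +10, +18, +21 (day +10 at every
station); storm window Mar 3–12.

Mechanics, with defaults and why:

* Taxon baseline intensities are log-normal (log-mean 5.5, log-SD 1.2 in
  fluorescence units) with regime-level composition shifts (log-SD 1.0),
  station individuality (log-SD 0.25) and per-sample noise (log-SD 0.4);
  per-sample total-signal scale varies with log-SD 0.2. A detection
  floor (25 units) zeroes faint taxa, and spurious noise peaks (mean 15
  per sample, 0.05–0.3% of total signal, count scaling with signal
  strength) give the VPT filter a true optimum.
* The environmental pulse peaks on day 1 and decays exponentially with
  τ = recovery/3 so nutrients are back within ~5% of baseline by day 10;
  amplitudes default to the published peak storm deviations at the most
  affected station (N+N +12, NH₄⁺ +12.5, H₂SiO₄ +58 µmol/L, SRP +0.9,
  salinity −13, chlorophyll +16 µg/L lagged). The community response is
  a mixture of an immediate wash-in component (weight 0.3, on the
  pulse's time course — runoff physically imports organisms on day 1)
  and a bloom component that is zero until a 3-day lag and decays with
  τ = (18 − 3)/3, so the community signal has essentially recovered by
  day 18.
* Responder taxa (12 of 120) bloom ×80 at peak exposure; dominant taxa
  (5, baseline ×8) gain only ×1.6 at peak. Because abundances are
  simulated absolutely and normalized downstream, the dominants' share
  of the community *falls* during the storm even as their absolute
  signal rises — the compositional paradox emerges from the arithmetic.
  Effect magnitudes are not recoverable from any publication; they are
  stated once here, sized so that the power/calibration checks are
  meaningful, and deliberately not revisited.
* Exposure is 1.0 at five near-shore coastal stations, 0 offshore, 0.3
  at the partially sheltered and freshwater sites, 0.5 at non-dense
  coastal sites. Ground truth: `true_disturbed` = exposure > 0;
  planted resistance class high/intermediate/low for exposure
  < 0.2 / ≤ 0.7 / > 0.7 (a generator convention, not an estimate).
* Randomness derives from one seed through named substreams keyed by a
  stable hash of each station's name, so adding a station never changes
  any other station's data, and identical (config, seed) regenerates
  identical datasets.

What a green synthetic validation establishes: correct null calibration
of the permutation machinery (type-I error inside the exact binomial 99%
band over 1000 null station-tests), power ≥ 0.9 to detect the planted
community shift at fully exposed stations, exact regime recovery by
K-means, and correct identification of the planted responders by SIMPER.
What it does not establish: realism of hydrodynamics, seasonality,
taxon–taxon interactions, PCR/primer bias, or electropherogram-level
artifacts — none of which the generator attempts; nor does it reproduce
any dataset-dependent published statistic (total T-RF richness, global
ANOSIM R, matrix-level BIO-ENV correlations), which would require the
original raw profiles.

## Numerical conventions

* Distance matrices are validated symmetric to 1e-12 with an exactly
  zero diagonal; Bray–Curtis requires positive row sums and errors
  naming the offending samples.
* Monte-Carlo comparisons use a 1e-12 slack on ≥ so ties with the
  observed statistic count as exceedances on both sides of the
  convention.
* All stochastic routines (permutation tests, NMDS, K-means, the
  generator) take seeds; derived sub-seeds are simple offsets or named
  spawn keys, documented at each call site.
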