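# Methods

This note documents the models behind hydrobiome, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions a user relying on the outputs should know.

## The inference problem

Given a taxa × samples count table, a rooted phylogeny with branch lengths,
and per-sample metadata (habitat group, coordinates, environmental
variables), the package asks three questions about how the communities were
assembled: (1) how diverse and how different are the habitats
(alpha/beta diversity, ordination, PERMANOVA, SIMPER, overlap); (2) which
ecological processes — selection, dispersal, drift — structured them
(neutral-model fit, βNTI/RC_bray partitioning, distance decay); (3) how are
the dominant taxa organized and how fragile is that organization
(co-occurrence networks, keystone roles, removal experiments).

## Diversity conventions

- **Shannon** uses the natural log (nats), the convention of the common R
  implementations; divide by ln 2 for bits.
- **Faith's PD** sums branch lengths of the minimal *rooted* subtree
  spanning the observed taxa, root path included. The convention matters
  for single-tip samples: here a lone taxon contributes its full
  root-to-tip path, never zero.
- **β-MNTD** between samples k and l is
  0.5·[Σᵢ f_ik·min_{j∈l} d_ij + Σ_j f_jl·min_{i∈k} d_ij] with patristic
  distances d and weights f; abundance-weighted by default (unweighted =
  1/richness is a flag). A taxon shared by both samples has nearest-taxon
  distance zero, which is why β-MNTD-based inference is only sensitive to
  membership turnover (see the generator discussion below).
- **Rarefaction** is a single seeded multivariate-hypergeometric draw
  (sampling without replacement), matching the common one-table workflow;
  rows that become empty are kept and flagged so taxon indices stay stable.
- **PERMANOVA** uses the adonis-style pseudo-F on squared distances. When
  the number of distinct labelings is within the permutation budget the
  null is enumerated exhaustively and the p-value is exact; otherwise p =
  (1 + #{F_perm ≥ F_obs})/(1 + n_perm), so p is never zero.
- **Mantel** is Spearman by default, one-sided on r ≥ r_obs, permuting
  rows/columns of the first matrix jointly. The partial variant
  rank-transforms all three triangles, residualizes both on the control by
  least squares and correlates residuals; residuals numerically at zero
  (control ≡ matrix) give r = 0 by convention.
- **Geographic distance** is haversine with Earth radius 6371.0088 km;
  sub-km geodesic refinements are irrelevant at transect scale. The
  distance-decay Mantel correlates distance with *dissimilarity* (so decay
  is a positive r); the reported regression line is similarity vs distance
  (decay is a negative slope per km).

## Sloan neutral community model

Occurrence frequency of taxon i is predicted from its regional mean
relative abundance pᵢ as Fᵢ = 1 − I(d; Nm·pᵢ, Nm·(1 − pᵢ)) with
I the regularized incomplete beta CDF, N the mean reads per sample and
d = 1/N the detection limit. m is fitted by least squares on frequencies
(the lineage of the widely used implementations), via a dense log-grid scan
over m ∈ [10⁻⁴, 1] plus bounded scalar refinement — deterministic and
robust to the flat plateaus the SSE surface develops when most frequencies
saturate. R² = 1 − SSE/SST may be negative; that is a result, not an
error: the neutral curve then predicts occurrence worse than the mean
frequency does, the signature of deterministic assembly. 95% bands are
Wilson score intervals on Fᵢ at n = number of samples; taxa are classed
above/within/below.

## Null-model process partitioning

- **βNTI** = (βMNTD_obs − mean βMNTD_null)/sd βMNTD_null with the null
  generated by shuffling taxon identities across the pooled patristic
  matrix — a regional-pool randomization shared by all sample pairs in one
  iteration (999 shuffles by default, 99 for fast runs). Pairs whose null
  has zero spread (a star phylogeny, or two identical samples) are
  undefined: they are returned as NaN, counted, and excluded from the
  partition denominators rather than imputed.
- **RC_bray**: per iteration each sample of a pair is rebuilt with its
  observed richness (membership drawn ∝ occupancy across all samples, each
  member seeded with one individual) and its observed total (remaining
  individuals ∝ regional relative abundance). RC = 2·[(#{null BC < obs} +
  0.5·#{null BC = obs})/n_null] − 1; ties get half weight.
- **Classification**: βNTI > 2 → heterogeneous selection; βNTI < −2 →
  homogeneous selection; otherwise RC > 0.95 → dispersal limitation;
  RC < −0.95 → homogenizing dispersal; else undominated. Fractions are
  reported over within-group pairs in two normalizations: over all
  classifiable pairs, and the selection split over |βNTI| > 2 pairs only,
  because habitat studies quote either denominator.

## Synthetic-data generator

The generator emulates a multi-habitat 16S census on a salinity gradient:

- **Phylogeny/trait**: a Yule tree scaled to root height 1; salinity optima
  evolve by Brownian motion from a root value of 0 and are min–max rescaled
  to [0, 35] (a g/L-like scale) so niche breadths mean the same thing
  across seeds. Rescaling makes the trait pattern invariant to `sigma_bm`
  except in the degenerate zero-spread case (collapsed to 17.5 with a
  warning).
- **Metacommunity**: lognormal relative abundances; at `lognormal_sigma` = 2
  and 1000 taxa ≳40% of the pool sits below 10⁻⁴ — the long rare tail of
  real amplicon surveys.
- **niche** regime: counts ~ Multinomial(depth, w), wᵢ ∝ pᵢ·exp(−(optᵢ −
  e)²/2σ²) for the sample's environment e. An optional
  `sample_pool_sigma` multiplies w by iid lognormal noise per sample
  (demographic stochasticity). This matters: with a shared pool and no
  noise, similar-environment samples contain nearly identical taxon sets,
  and since shared taxa contribute zero to β-MNTD under both the observed
  and shuffled tree, βNTI cannot see the (real) phylogenetic clustering.
  Homogeneous selection is detectable exactly when selection is combined
  with membership turnover among close relatives — which is also the
  ecological claim the index encodes.
- **neutral** regime: a Hubbell-type zero-sum community of size N: per
  event one individual dies (uniform) and is replaced by an immigrant
  (probability m, drawn ∝ p) or a local birth (∝ local abundance). The
  kernel is numba-compiled; burn-in is 10·N events starting from a
  Multinomial draw of the analytic stationary composition Dirichlet(N·m·p)
  of the Moran-with-immigration model, so the burn-in refines an already
  correctly dispersed state instead of fighting a distant initial
  condition.
- **drifted_pools** regime: each group's pool is first Dirichlet-perturbed
  around p (concentration `pool_concentration`·p), then sampled neutrally —
  dispersal limitation between and, at low m, within groups.
- **Space**: samples sit on a 1-D west-to-east transect (group blocks in
  listed order, jittered even spacing), converted to lat/lon near 39°N.
  One spatial dimension is the simplest structure that produces distance
  decay.
- All randomness flows from one seed through named SeedSequence streams
  (tree, traits, env, pools, sampling, coords), so components are
  individually reproducible and a dataset is byte-identical under
  regeneration.

### Reference regime scenarios

`simulate.regime_scenario(name, seed)` freezes one study design per
process. Sizes (300–400 taxa, 7–8 samples per group, depths 100–2000) are
desk-scale: the full four-regime recovery experiment (20 replicates each,
n_null = 99) runs in ~1 minute. The choices that matter:

- *homogeneous_selection*: two groups filtered at the same salinity
  (mean 5, sd 1, σ_niche 2) over a flat 400-taxon pool, with
  `sample_pool_sigma` = 2 and depth 100 — the flat pool puts many
  co-dominant members in the salinity band, and low depth plus demographic
  noise turn membership over among those close relatives, the regime's
  signature.
- *heterogeneous_selection*: one group spanning env sd 10 — pairs
  experience divergent filters, βNTI > 2.
- *dispersal_limitation*: drifted pools with m = 0.02, N = 1000,
  depth 2000. The balance is deliberate: occupancy must stay high (so the
  Raup–Crick null builds overlapping memberships) while abundances drift
  far apart; extreme drift collapses richness and paradoxically
  de-saturates RC.
- *undominated*: well-mixed neutral community (m = 0.5, N = 2000); observed
  turnover matches the null, |RC| ≤ 0.95 and |βNTI| ≤ 2.

What passing these recovery tests shows: the indices respond to the
processes they claim to measure, at effect sizes a strong gradient can
produce. What it does not show: sensitivity at the weaker, mixed regimes of
real surveys, robustness to sequencing error or compositional artifacts
(the generator emits clean multinomial reads), or performance when the
regional pool is mis-specified — the generator's pool is the truth, a
luxury field data never has. Effect sizes were chosen for detectability,
not estimated from any particular system.

## Co-occurrence networks

Taxa are ranked by mean relative abundance and the top `top_n` (500 by
default) are correlated (Spearman, average-rank ties). Edges require
|ρ| > 0.6 and adjusted p < 0.05; adjustment is Benjamini–Hochberg by
default (raw-p mode available — both thresholds circulate in the
literature, and FDR is the stricter choice). Constant rows are excluded
with a warning; isolated nodes are dropped and counted.

Topology: shortest-path metrics on the largest connected component (its
node share is reported); density 2E/N(N−1); mean local clustering with
degree<2 nodes contributing 0; Freeman centralizations normalized by their
theoretical maxima (a star scores 1 on all three). Modules come from
seeded Louvain; relative modularity RM = (M_obs − mean M_ER)/mean M_ER over
100 Erdős–Rényi graphs with the same node and edge counts — RM > 1 means
more than twice the modularity of a density-matched random graph.

Zi–Pi roles use the standard cutoffs (module hub Zi ≥ 2.5; connector
Pi ≥ 0.62); a module whose within-degree has zero spread gets Zi = 0 for
its members, flagged. Keystones = non-peripheral nodes.

Stability: robustness is the fraction of taxa remaining after removing
⌈f·N⌉ nodes — random (uniform, replicated) or targeted (module hubs by
decreasing Zi, then random) — followed by cascading deletion of newly
isolated nodes (an association-free taxon is counted as lost; a no-cascade
flag exists). Natural connectivity λ̄ = ln[(1/N)Σ exp(λᵢ)] is computed via
symmetric eigendecomposition with a log-sum-exp guard, tracked along random
removal orders.

## Numerical and degenerate-input conventions

- Permutation p-values never return 0 (the +1 estimator); exhaustive
  enumeration is exact.
- Bray–Curtis on two all-zero samples, Shannon/PD of empty samples, Mantel
  on a constant triangle, PERMANOVA without residual df: all raise with the
  offending samples named, rather than returning NaN silently.
- Undefined βNTI pairs and undefined Spearman cells (constant vectors) are
  flagged and excluded, with counts, never imputed.
- Text outputs serialize reals at 6 significant digits; all comparisons in
  tests use numeric tolerances, never string equality.
- The NCM fit, Louvain, ER nulls, and all removal experiments are seeded;
  the pipeline derives per-stage seeds from one master seed via named
  streams and writes per-file checksums to its manifest.

## Known limitations

- βNTI/RC inference is only as good as the tree and the assumption that
  niches are phylogenetically conserved; the generator builds that
  conservation in (Brownian trait), so recovery rates here are an upper
  bound for clades with weak signal.
- The RC null conditions on occupancy and regional abundance estimated from
  the data themselves; with few samples those estimates are noisy.
- Compositionality is not modeled: correlations are computed on relative
  abundances without a log-ratio transform, matching the common workflow
  this package mirrors; SparCC-style inference is out of scope.
- The Hubbell kernel is a local Moran model with a fixed pool — no
  speciation, no time-varying environment.
- BIOM support is the JSON dialect, read-only.
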