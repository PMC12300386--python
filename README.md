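# hydrobiome

Community-ecology inference for microbial census data (16S ASV/OTU tables)
along environmental gradients: diversity and dissimilarity, neutral- and
null-model assembly-process inference, distance–decay analysis, and
co-occurrence network topology and stability. It is aimed at microbial
ecologists comparing habitats — e.g. coastal groundwater zones against a
surface reservoir along a salinity gradient — who want the full analysis
stack as tested, scriptable Python rather than a patchwork of R snippets.

Every method ships with a synthetic-data generator whose assembly regime is
known exactly, so the inferential machinery is validated against ground
truth, not just against itself.

## What it computes

**Diversity** (`hydrobiome.diversity`) — rarefaction; Shannon–Wiener
*H* = −Σ qᵢ ln qᵢ (nats); Faith's PD (branch-length sum of the rooted
subtree spanning a sample's taxa); Bray–Curtis; abundance-weighted β-MNTD;
PCoA; one-way PERMANOVA (pseudo-F, with exact enumeration for small
designs); plain and partial Spearman Mantel tests; haversine distance–decay
regression; SIMPER; presence-overlap counts; BH-corrected taxon–environment
correlation screens.

**Assembly inference** (`hydrobiome.assembly`) — the Sloan neutral community
model: a taxon with regional mean relative abundance *pᵢ* is predicted to
occur in a sample with frequency *Fᵢ = 1 − I(1/N; Nm·pᵢ, Nm·(1 − pᵢ))*
(regularized incomplete beta), with migration probability *m* fitted by
bounded least squares and fit quality *R²* (negative values flag
deterministic structure). Null-model process partitioning per sample pair:
βNTI (standardized β-MNTD against taxon shuffles across the phylogeny) and
RC_bray (Raup–Crick on Bray–Curtis under a richness- and abundance-
preserving null), classified as heterogeneous selection (βNTI > 2),
homogeneous selection (βNTI < −2), dispersal limitation (RC > 0.95),
homogenizing dispersal (RC < −0.95) or undominated.

**Networks** (`hydrobiome.network`) — Spearman co-occurrence graphs
(|ρ| > 0.6, FDR < 0.05 by default) over the most abundant taxa; topology
reports (degree, path length, diameter, density, clustering, Freeman
centralizations, Louvain modularity, relative modularity against
Erdős–Rényi nulls); Zi–Pi keystone classification (module hubs Zi ≥ 2.5,
connectors Pi ≥ 0.62); robustness under random vs targeted hub removal with
cascading isolation; natural connectivity λ̄ = ln[(1/N)·Σ exp(λᵢ)].

**Synthetic data** (`hydrobiome.simulate`) — Yule phylogenies with
Brownian-motion salinity optima, lognormal metacommunities, and per-group
local communities assembled under niche filtering, Hubbell neutral
dynamics, or drifted pools, placed on a 1-D transect.

## Worked example

```python
from hydrobiome import assembly as asm
from hydrobiome.simulate import regime_scenario, simulate_dataset

ds = simulate_dataset(regime_scenario("homogeneous_selection", seed=1))
groups = {s: str(ds.metadata.frame.loc[s, "group"]) for s in ds.counts.sample_ids}

fit = asm.fit_ncm(ds.counts)
bnti = asm.compute_bnti(ds.counts, ds.tree, n_null=99, seed=1)
rc = asm.compute_rcbray(ds.counts, n_null=99, seed=2)
part = asm.partition_processes(bnti, rc, groups)
print(f"NCM R2 = {fit.r2:.2f}")
print(part.fractions.round(2))
```

prints

```
NCM R2 = 0.45
    heterogeneous_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  undominated
g1                      0.0                   0.81                  0.10                     0.0         0.10
g2                      0.0                   0.81                  0.05                     0.0         0.14
```

The data were generated under shared-environment filtering, and the
partition attributes ~80% of within-group pairs to homogeneous selection —
the modest neutral-model fit (R² = 0.45) is consistent with a community
structured by selection rather than drift. `examples/` holds one short
narrative script per capability (simulation, diversity/ordination, assembly
inference, networks, full pipeline).

A thin CLI mirrors the stages:

```bash
hydrobiome all --config cfg.yaml --seed 1 --out run/
```

writing per-stage TSV/GraphML outputs plus a manifest with per-file
checksums; identical config + seed reproduce identical checksums.

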