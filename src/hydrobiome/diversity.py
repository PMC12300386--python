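"""Alpha/beta diversity, ordination, permutation tests and association screens.

Conventions used throughout:

* Shannon entropy is in nats (natural log), the R-ecosystem default.
* Faith's PD includes the path to the root, matching the 'pd' convention of
  the picante lineage; a single-tip sample therefore has PD equal to its
  root-to-tip distance.
* β-MNTD defaults to the abundance-weighted variant.
* Permutation p-values use the (1 + #extreme)/(1 + n_perm) estimator, so a
  permutation p-value is never exactly zero; PERMANOVA switches to exhaustive
  enumeration when the number of distinct labelings is within the permutation
  budget.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io import CountTable, DistanceMatrix, PhyloTree, SampleMetadata

__all__ = [
    "rarefy",
    "shannon",
    "faith_pd",
    "bray_curtis",
    "beta_mntd",
    "pcoa",
    "OrdinationResult",
    "permanova",
    "PermanovaResult",
    "mantel",
    "MantelResult",
    "haversine_km",
    "distance_decay",
    "DistanceDecayResult",
    "simper",
    "community_overlap",
    "taxon_env_correlation",
    "diversity_summary",
]

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Rarefaction


def rarefy(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    A single seeded draw (one rarefied table, not an average over draws).
    Taxa whose rows become all-zero are retained and reported via a warning.
    """
    sums = table.sample_sums()
    shallow = [s for s, t in zip(table.sample_ids, sums) if t < depth]
    if shallow:
        raise ValueError(
            f"rarefaction depth {depth} exceeds total reads of samples: {shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    n_empty = int((out.sum(axis=1) == 0).sum())
    if n_empty:
        warnings.warn(f"{n_empty} taxa have zero counts after rarefaction (retained)")
    return CountTable(list(table.taxon_ids), list(table.sample_ids), out, table.taxonomy)


# ---------------------------------------------------------------------------
# Alpha diversity


def shannon(column: np.ndarray) -> float:
    """Shannon–Wiener index H = −Σ q ln q in nats."""
    column = np.asarray(column, dtype=float)
    total = column.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    q = column[column > 0] / total
    return float(-(q * np.log(q)).sum())


def faith_pd(column: np.ndarray, taxon_ids: list[str], tree: PhyloTree) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    rooted subtree spanning the sample's taxa (root path included)."""
    column = np.asarray(column)
    present = {t for t, c in zip(taxon_ids, column) if c > 0}
    if not present:
        raise ValueError("Faith's PD undefined for an all-zero sample")
    tip_names = set(tree.tip_names)
    missing = sorted(present - tip_names)
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:10]}")
    root = tree.tree
    # mark all nodes on a root-to-present-tip path, sum their branch lengths
    counted = set()
    total = 0.0
    for tip in root.tips():
        if tip.name not in present:
            continue
        node = tip
        while node is not root and id(node) not in counted:
            counted.add(id(node))
            total += node.length
            node = node.parent
    return float(total)


# ---------------------------------------------------------------------------
# Beta diversity


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between sample columns."""
    x = table.counts.astype(float)
    sums = x.sum(axis=0)
    n = table.n_samples
    vals = np.zeros((n, n))
    for k in range(n):
        for l in range(k + 1, n):
            denom = sums[k] + sums[l]
            if denom == 0:
                raise ValueError(
                    f"Bray–Curtis undefined for all-zero pair "
                    f"({table.sample_ids[k]}, {table.sample_ids[l]})"
                )
            d = np.abs(x[:, k] - x[:, l]).sum() / denom
            vals[k, l] = vals[l, k] = d
    return DistanceMatrix(list(table.sample_ids), vals, metric="braycurtis")


def _bmntd_from_dist(freq: np.ndarray, present: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Vectorized β-MNTD for all sample pairs.

    freq: taxa × samples weights (rows of absent taxa are 0 and ignored);
    present: boolean taxa × samples; dist: taxa × taxa patristic distances.
    """
    n_taxa, n_samples = freq.shape
    # mins[i, l] = distance from taxon i to its nearest present taxon of sample l
    big = np.inf
    mins = np.empty((n_taxa, n_samples))
    for l in range(n_samples):
        cols = dist[:, present[:, l]]
        mins[:, l] = cols.min(axis=1)
    half = freq.T @ mins  # half[k, l] = Σ_i f_ik · min_{j∈l} d_ij
    out = 0.5 * (half + half.T)
    np.fill_diagonal(out, 0.0)
    return out


def beta_mntd(
    table: CountTable,
    tree: PhyloTree,
    weighted: bool = True,
    patristic: np.ndarray | None = None,
) -> DistanceMatrix:
    """Between-sample mean nearest taxon distance (β-MNTD).

    For samples k, l:
    ``0.5·[Σ_i f_ik·min_{j∈l} d_ij + Σ_j f_jl·min_{i∈k} d_ij]`` with ``f``
    the relative abundances among present taxa (weighted) or 1/richness
    (unweighted) and ``d`` patristic distance.  Nearest-taxon distances to
    the *paired* community include a shared taxon at distance 0.
    """
    present = table.counts > 0
    if (~present.any(axis=0)).any():
        raise ValueError("sample with no present taxa")
    if patristic is None:
        patristic = tree.patristic_matrix(table.taxon_ids)
    if weighted:
        freq = table.counts / table.counts.sum(axis=0, keepdims=True)
    else:
        freq = present / present.sum(axis=0, keepdims=True)
    vals = _bmntd_from_dist(freq.astype(float), present, patristic)
    return DistanceMatrix(list(table.sample_ids), vals, metric="beta_mntd")


# ---------------------------------------------------------------------------
# Ordination


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray  # n_samples × k
    eigenvalues: np.ndarray  # all n, descending (negatives reported)
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical scaling (principal coordinates analysis).

    Negative eigenvalues (non-Euclidean input) are reported, never dropped;
    coordinates are only built on axes with positive eigenvalues.
    """
    n = dist.n
    if k > n - 1:
        raise ValueError(f"k = {k} exceeds n − 1 = {n - 1}")
    d2 = dist.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.clip(eigval, 0, None)
    coords = eigvec[:, :k] * np.sqrt(pos[:k])
    total = pos.sum()
    prop = pos / total if total > 0 else np.zeros(n)
    return OrdinationResult(list(dist.ids), coords, eigval, prop)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int
    exhaustive: bool


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray):
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    g = len(uniq)
    if n - g == 0 or ss_within == 0 and ss_between == 0:
        f = np.nan
    else:
        f = (ss_between / (g - 1)) / (ss_within / (n - g)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else np.nan
    return f, r2


def _count_labelings(counts) -> int:
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def permanova(
    dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA (adonis-style pseudo-F) on a distance matrix.

    When the number of distinct group labelings does not exceed ``n_perm``
    the null distribution is enumerated exhaustively and the p-value is the
    exact fraction of labelings with F ≥ observed F.
    """
    if isinstance(groups, dict):
        labels = np.asarray([groups[s] for s in dist.ids])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != dist.n:
            raise ValueError("group labels must align with distance matrix ids")
    uniq, counts = np.unique(labels, return_counts=True)
    n, g = dist.n, len(uniq)
    if g < 2:
        raise ValueError("PERMANOVA needs ≥2 groups")
    if n == g:
        raise ValueError("no residual degrees of freedom (every group has 1 sample)")
    d2 = dist.values**2
    f_obs, r2 = _permanova_stats(d2, labels, uniq)

    n_distinct = _count_labelings(counts)
    if n_distinct <= n_perm:
        # enumerate all assignments of samples to group slots
        idx = np.arange(n)
        count_ge = 0
        total = 0
        for combo in _distinct_labelings(labels):
            f_p, _ = _permanova_stats(d2, combo, uniq)
            total += 1
            if f_p >= f_obs - 1e-12:
                count_ge += 1
        return PermanovaResult(f_obs, r2, count_ge / total, total, True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f_p, _ = _permanova_stats(d2, perm, uniq)
        if f_p >= f_obs - 1e-12:
            count += 1
    return PermanovaResult(f_obs, r2, (1 + count) / (1 + n_perm), n_perm, False)


def _distinct_labelings(labels):
    """Yield every distinct multiset permutation of the label vector."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = len(labels)

    def rec(prefix, remaining):
        if len(prefix) == n:
            yield np.asarray(prefix, dtype=labels.dtype)
            return
        for i, u in enumerate(uniq):
            if remaining[i] > 0:
                remaining[i] -= 1
                yield from rec(prefix + [u], remaining)
                remaining[i] += 1

    yield from rec([], list(counts))


# ---------------------------------------------------------------------------
# Mantel


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    partial: str | None = None


def _rank_triangle(dm: DistanceMatrix) -> np.ndarray:
    return rankdata(dm.condensed())


def mantel(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    partial_control: DistanceMatrix | None = None,
) -> MantelResult:
    """(Partial) Mantel test with Spearman correlation, one-sided on r ≥ r_obs.

    The partial variant rank-transforms all three triangles, residualizes A
    and B on the control by least squares, and correlates the residuals.
    Permutations jointly shuffle rows/columns of ``dist_a``.
    """
    if dist_a.ids != dist_b.ids:
        dist_b = dist_b.filter(dist_a.ids)
    if partial_control is not None and partial_control.ids != dist_a.ids:
        partial_control = partial_control.filter(dist_a.ids)
    n = dist_a.n
    if n < 4:
        raise ValueError("Mantel test needs ≥4 samples")

    b_rank = _rank_triangle(dist_b)
    c_rank = _rank_triangle(partial_control) if partial_control is not None else None
    if np.ptp(dist_a.condensed()) == 0 or np.ptp(dist_b.condensed()) == 0:
        raise ValueError("constant distance triangle: Mantel r undefined")

    def statistic(a_vals: np.ndarray) -> float:
        a_rank = rankdata(a_vals)
        if c_rank is None:
            return float(stats.pearsonr(a_rank, b_rank)[0])
        ra = a_rank - np.polyval(np.polyfit(c_rank, a_rank, 1), c_rank)
        rb = b_rank - np.polyval(np.polyfit(c_rank, b_rank, 1), c_rank)
        # residuals that are numerically zero mean the control explains the
        # matrix entirely; the partial correlation is 0 by convention
        if np.std(ra) < 1e-8 or np.std(rb) < 1e-8:
            return 0.0
        return float(stats.pearsonr(ra, rb)[0])

    r_obs = statistic(dist_a.condensed())
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        a_perm = dist_a.values[np.ix_(perm, perm)][iu]
        if statistic(a_perm) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(
        r_obs, p, n_perm, partial=partial_control.metric if partial_control is not None else None
    )


# ---------------------------------------------------------------------------
# Distance decay


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance (km), Earth radius 6371.0088 km."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(metadata: SampleMetadata) -> DistanceMatrix:
    coords = metadata.coordinates()
    n = len(coords)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(coords[i, 0], coords[i, 1], coords[j, 0], coords[j, 1])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(metadata.sample_ids, vals, metric="geographic_km")


@dataclass
class DistanceDecayResult:
    mantel: MantelResult
    slope: float  # similarity per km
    intercept: float
    r2: float


def distance_decay(
    table: CountTable,
    metadata: SampleMetadata,
    n_perm: int = 999,
    seed: int = 0,
    partial_control: DistanceMatrix | None = None,
) -> DistanceDecayResult:
    """Similarity (1 − Bray–Curtis) versus geographic distance.

    The Mantel test correlates distance with *dissimilarity* (positive r
    means decay); the fitted line is similarity vs distance, so decay shows
    as a negative slope (per km).
    """
    geo = geographic_distance_matrix(metadata)
    geo = geo.filter(table.sample_ids)
    bc = bray_curtis(table)
    mr = mantel(geo, bc, n_perm=n_perm, seed=seed, partial_control=partial_control)
    x = geo.condensed()
    y = 1.0 - bc.condensed()
    slope, intercept, r, _, _ = stats.linregress(x, y)
    return DistanceDecayResult(mr, float(slope), float(intercept), float(r**2))


# ---------------------------------------------------------------------------
# SIMPER


def simper(
    table: CountTable,
    groups,
    pair: tuple[str, str],
    family_level: bool = False,
) -> pd.DataFrame:
    """Per-taxon contribution to mean between-group Bray–Curtis dissimilarity.

    Contributions sum exactly to the mean between-group Bray–Curtis (the
    SIMPER conservation identity).  With ``family_level=True`` counts are
    first summed over taxa sharing the family field (5th rank) of their
    taxonomy string.
    """
    if isinstance(groups, dict):
        labels = {s: groups[s] for s in table.sample_ids}
    else:
        labels = dict(zip(table.sample_ids, groups))
    g1, g2 = pair
    s1 = [s for s in table.sample_ids if labels[s] == g1]
    s2 = [s for s in table.sample_ids if labels[s] == g2]
    if not s1 or not s2:
        raise ValueError(f"unknown or empty group in pair {pair}")

    work = table
    if family_level:
        if not table.taxonomy:
            raise ValueError("family-level SIMPER requires taxonomy strings")
        fam = {}
        for t in table.taxon_ids:
            ranks = (table.taxonomy.get(t) or "").split(";")
            fam[t] = ranks[4].strip() if len(ranks) > 4 and ranks[4].strip() else "unclassified"
        df = table.to_dataframe()
        df["__family"] = [fam[t] for t in table.taxon_ids]
        agg = df.groupby("__family").sum()
        work = CountTable(list(agg.index), list(table.sample_ids), agg.to_numpy())

    x = work.counts.astype(float)
    idx1 = [work.sample_ids.index(s) for s in s1]
    idx2 = [work.sample_ids.index(s) for s in s2]
    contrib = np.zeros(work.n_taxa)
    n_pairs = 0
    for i in idx1:
        for j in idx2:
            denom = x[:, i].sum() + x[:, j].sum()
            contrib += np.abs(x[:, i] - x[:, j]) / denom
            n_pairs += 1
    contrib /= n_pairs
    total = contrib.sum()
    df = pd.DataFrame(
        {
            "contribution": contrib,
            "percent": 100 * contrib / total if total > 0 else 0.0,
        },
        index=pd.Index(work.taxon_ids, name="taxon_id"),
    )
    df = df.sort_values("contribution", ascending=False, kind="mergesort")
    df["cumulative_percent"] = df["percent"].cumsum()
    return df


# ---------------------------------------------------------------------------
# Presence overlap across groups


def community_overlap(table: CountTable, groups) -> dict:
    """Presence/absence overlap between habitat groups.

    A taxon is 'present' in a group if it has a nonzero count in at least
    one of the group's samples.  Returns every intersection cardinality over
    non-empty group subsets plus the shared fraction |∩ all| / |∪ all|.
    """
    if isinstance(groups, dict):
        labels = [groups[s] for s in table.sample_ids]
    else:
        labels = list(groups)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("overlap needs ≥2 groups")
    sets = {}
    for g in uniq:
        idx = [j for j, lab in enumerate(labels) if lab == g]
        present = table.counts[:, idx].sum(axis=1) > 0
        sets[g] = {t for t, pr in zip(table.taxon_ids, present) if pr}
    union = set().union(*sets.values())
    inter_all = set.intersection(*sets.values())
    intersections = {}
    for r in range(1, len(uniq) + 1):
        for combo in itertools.combinations(uniq, r):
            inter = set.intersection(*(sets[g] for g in combo))
            intersections["&".join(combo)] = len(inter)
    return {
        "group_richness": {g: len(s) for g, s in sets.items()},
        "intersections": intersections,
        "union_size": len(union),
        "shared_all": len(inter_all),
        "shared_fraction": len(inter_all) / len(union) if union else 0.0,
    }


# ---------------------------------------------------------------------------
# Taxon–environment association screen


def taxon_env_correlation(
    table: CountTable,
    metadata: SampleMetadata,
    taxa: list[str] | None = None,
    env_vars: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlations between taxon relative abundance and
    environmental variables, BH-adjusted across the whole screen.

    Returns a long-format frame with rho, p, p_adj, slope, intercept, r2
    per (taxon, variable); undefined correlations (constant vector) are
    flagged with NaN rho rather than failing.
    """
    taxa = taxa or list(table.taxon_ids)
    env_vars = env_vars or metadata.env_columns
    rel = table.relative_abundance()
    rows = []
    for t in taxa:
        ti = table.taxon_ids.index(t)
        for v in env_vars:
            env = metadata.frame.loc[table.sample_ids, v].to_numpy(float)
            ok = ~np.isnan(env)
            x, y = env[ok], rel[ti][ok]
            if ok.sum() < 4:
                raise ValueError(f"fewer than 4 samples with values for {v!r}")
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((t, v, np.nan, np.nan, np.nan, np.nan, np.nan, True))
                continue
            rho, p = stats.spearmanr(x, y)
            slope, intercept, r, _, _ = stats.linregress(x, y)
            rows.append((t, v, rho, p, slope, intercept, r**2, False))
    df = pd.DataFrame(
        rows,
        columns=["taxon_id", "variable", "rho", "p", "slope", "intercept", "r2", "undefined"],
    )
    valid = df["p"].notna()
    padj = np.full(len(df), np.nan)
    if valid.any():
        padj[valid.to_numpy()] = stats.false_discovery_control(
            df.loc[valid, "p"].to_numpy(), method="bh"
        )
    df["p_adj"] = padj
    return df


# ---------------------------------------------------------------------------
# Summary convenience


def diversity_summary(
    table: CountTable, tree: PhyloTree, metadata: SampleMetadata
) -> pd.DataFrame:
    """Per-sample Shannon (nats) and Faith's PD with group labels."""
    rows = []
    for j, s in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rows.append(
            {
                "sample_id": s,
                "group": metadata.frame.loc[s, "group"],
                "shannon": shannon(col),
                "faith_pd": faith_pd(col, table.taxon_ids, tree),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
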