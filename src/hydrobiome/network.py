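"""Co-occurrence networks: construction, topology, keystone roles, stability.

A network is built from Spearman correlations between the most abundant
taxa; edges require both a strong correlation (|rho| above a threshold,
0.6 by default) and significance after multiple-testing adjustment.
Topology metrics follow the igraph conventions used in microbial network
studies: shortest-path metrics on the largest connected component, Freeman
centralizations, Louvain modules, and a relative modularity index against
density-matched Erdős–Rényi graphs.  Stability is probed by node-removal
experiments (robustness = fraction of taxa remaining after cascading
isolation) and by natural connectivity, a spectral robustness measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .io import CountTable

__all__ = [
    "build_network",
    "TopologyReport",
    "topology_report",
    "NodeRole",
    "zi_pi_roles",
    "keystone_nodes",
    "StabilityCurves",
    "robustness_curve",
    "natural_connectivity",
    "natural_connectivity_curve",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# Construction


def build_network(
    table: CountTable,
    top_n: int = 500,
    rho_threshold: float = 0.6,
    alpha: float = 0.05,
    adjust: str = "bh",
    seed: int = 0,
) -> nx.Graph:
    """Spearman co-occurrence network over the ``top_n`` most abundant taxa.

    Taxa are ranked by mean relative abundance; edges keep pairs with
    |rho| > ``rho_threshold`` and (adjusted) p < ``alpha``.  Isolated nodes
    are dropped (count recorded in ``G.graph['n_isolated']``); the summed
    relative abundance of the selected taxa is ``G.graph['coverage']``.
    """
    if table.n_samples < 5:
        raise ValueError("network construction needs ≥5 samples")
    if adjust not in ("bh", "none"):
        raise ValueError("adjust must be 'bh' or 'none'")
    rel = table.relative_abundance()
    mean_rel = rel.mean(axis=1)
    top_n = min(top_n, table.n_taxa)
    order = np.argsort(-mean_rel, kind="stable")[:top_n]
    coverage = float(mean_rel[order].sum())
    sub = table.counts[order].astype(float)
    taxa = [table.taxon_ids[i] for i in order]

    constant = np.ptp(sub, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxon row(s) excluded from correlation"
        )
    keep = ~constant
    sub, taxa_k = sub[keep], [t for t, k in zip(taxa, keep) if k]
    mean_k = mean_rel[order][keep]

    nk = len(taxa_k)
    rho, pval = stats.spearmanr(sub, axis=1)
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)
    iu = np.triu_indices(nk, k=1)
    p_raw = pval[iu]
    if adjust == "bh":
        p_adj = stats.false_discovery_control(p_raw, method="bh")
    else:
        p_adj = p_raw

    g = nx.Graph()
    g.graph.update(
        coverage=coverage,
        top_n=top_n,
        rho_threshold=rho_threshold,
        alpha=alpha,
        adjust=adjust,
    )
    taxonomy = table.taxonomy or {}
    for t, ab in zip(taxa_k, mean_k):
        g.add_node(
            t, mean_relative_abundance=float(ab), taxonomy=taxonomy.get(t, "")
        )
    for (i, j), pr, pa in zip(zip(*iu), p_raw, p_adj):
        r = rho[i, j]
        if abs(r) > rho_threshold and pa < alpha:
            g.add_edge(
                taxa_k[i],
                taxa_k[j],
                rho=float(r),
                sign="+" if r > 0 else "-",
                p_raw=float(pr),
                p_adj=float(pa),
            )
    isolated = [n for n, d in g.degree() if d == 0]
    g.graph["n_isolated"] = len(isolated)
    g.remove_nodes_from(isolated)
    return g


# ---------------------------------------------------------------------------
# Topology


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    average_degree: float
    average_path_length: float
    diameter: float
    density: float
    clustering_coefficient: float
    centralization_degree: float
    centralization_betweenness: float
    centralization_closeness: float
    modularity: float
    relative_modularity: float
    modules: dict[str, int]
    lcc_fraction: float

    def to_series(self) -> pd.Series:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "modules"
        }
        return pd.Series(d)


def _freeman_centralizations(g: nx.Graph, lcc: nx.Graph):
    n = g.number_of_nodes()
    if n < 3:
        return 0.0, 0.0, 0.0
    deg = np.array([d for _, d in g.degree()], dtype=float)
    c_deg = float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))
    # betweenness/closeness on the largest component with normalized scores
    nl = lcc.number_of_nodes()
    if nl < 3:
        return c_deg, 0.0, 0.0
    btw = np.array(list(nx.betweenness_centrality(lcc, normalized=True).values()))
    c_btw = float((btw.max() - btw).sum() / (nl - 1))
    clo = np.array(list(nx.closeness_centrality(lcc).values()))
    c_clo = float((clo.max() - clo).sum() / ((nl - 2) * (nl - 1) / (2 * nl - 3)))
    return c_deg, c_btw, c_clo


def louvain_modules(g: nx.Graph, seed: int = 0) -> dict[str, int]:
    comms = nx.community.louvain_communities(g, seed=seed)
    return {n: k for k, comm in enumerate(comms) for n in comm}


def topology_report(
    g: nx.Graph,
    n_random: int = 100,
    seed: int = 0,
    modules: dict[str, int] | None = None,
) -> TopologyReport:
    """Standard topology metrics plus relative modularity.

    Shortest-path metrics are computed on the largest connected component
    (its node share is reported as ``lcc_fraction``).  Relative modularity
    RM = (M_obs − mean M_ER)/mean M_ER over ``n_random`` Erdős–Rényi graphs
    with identical node and edge counts.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n, e = g.number_of_nodes(), g.number_of_edges()
    signs = [d.get("sign", "+") for _, _, d in g.edges(data=True)]
    n_pos = sum(1 for s in signs if s == "+")
    comps = list(nx.connected_components(g))
    lcc_nodes = max(comps, key=len)
    lcc = g.subgraph(lcc_nodes)
    apl = (
        nx.average_shortest_path_length(lcc) if lcc.number_of_nodes() > 1 else 0.0
    )
    diam = nx.diameter(lcc) if lcc.number_of_nodes() > 1 else 0.0
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    clustering = float(np.mean(list(nx.clustering(g).values())))
    c_deg, c_btw, c_clo = _freeman_centralizations(g, lcc)

    if modules is None:
        modules = louvain_modules(g, seed=seed)
    comm_sets: dict[int, set] = {}
    for node, k in modules.items():
        comm_sets.setdefault(k, set()).add(node)
    mod = nx.community.modularity(g, list(comm_sets.values()))

    rng = np.random.default_rng(seed)
    er_mods = []
    for _ in range(n_random):
        er = nx.gnm_random_graph(n, e, seed=int(rng.integers(2**31 - 1)))
        er_comms = nx.community.louvain_communities(
            er, seed=int(rng.integers(2**31 - 1))
        )
        er_mods.append(nx.community.modularity(er, er_comms))
    mean_er = float(np.mean(er_mods)) if er_mods else np.nan
    rm = (mod - mean_er) / mean_er if er_mods and mean_er != 0 else np.nan

    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        n_positive=n_pos,
        n_negative=e - n_pos,
        average_degree=2 * e / n,
        average_path_length=float(apl),
        diameter=float(diam),
        density=float(density),
        clustering_coefficient=clustering,
        centralization_degree=c_deg,
        centralization_betweenness=c_btw,
        centralization_closeness=c_clo,
        modularity=float(mod),
        relative_modularity=float(rm),
        modules=modules,
        lcc_fraction=len(lcc_nodes) / n,
    )


# ---------------------------------------------------------------------------
# Zi–Pi roles


@dataclass
class NodeRole:
    node: str
    module: int
    zi: float
    pi: float
    role: str  # peripheral | connector | module_hub | network_hub
    zi_flagged: bool = False  # module had zero within-degree spread


def zi_pi_roles(g: nx.Graph, modules: dict[str, int]) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Role thresholds: peripheral (Zi < 2.5, Pi < 0.62), connector
    (Zi < 2.5, Pi ≥ 0.62), module hub (Zi ≥ 2.5, Pi < 0.62), network hub
    (Zi ≥ 2.5, Pi ≥ 0.62).  Modules whose within-degree has zero spread get
    Zi = 0 for all members (flagged).
    """
    missing = [n for n in g.nodes if n not in modules]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing[:5]}")
    within = {}
    for node in g.nodes:
        within[node] = sum(1 for nb in g[node] if modules[nb] == modules[node])
    by_mod: dict[int, list] = {}
    for node in g.nodes:
        by_mod.setdefault(modules[node], []).append(node)
    stats_mod = {}
    for k, members in by_mod.items():
        w = np.array([within[n] for n in members], dtype=float)
        stats_mod[k] = (w.mean(), w.std())

    rows = []
    for node in g.nodes:
        k = modules[node]
        mu, sd = stats_mod[k]
        flagged = sd == 0
        zi = 0.0 if flagged else (within[node] - mu) / sd
        deg = g.degree(node)
        if deg == 0:
            pi = 0.0
        else:
            shares = {}
            for nb in g[node]:
                shares[modules[nb]] = shares.get(modules[nb], 0) + 1
            pi = 1.0 - sum((c / deg) ** 2 for c in shares.values())
        if zi >= ZI_THRESHOLD:
            role = "network_hub" if pi >= PI_THRESHOLD else "module_hub"
        else:
            role = "connector" if pi >= PI_THRESHOLD else "peripheral"
        rows.append((node, k, zi, pi, role, flagged))
    return pd.DataFrame(
        rows, columns=["node", "module", "zi", "pi", "role", "zi_flagged"]
    ).set_index("node")


def keystone_nodes(roles: pd.DataFrame) -> list[str]:
    """Connectors, module hubs and network hubs."""
    return list(roles.index[roles["role"] != "peripheral"])


# ---------------------------------------------------------------------------
# Stability


@dataclass
class StabilityCurves:
    fractions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    strategy: str
    measure: str  # robustness | natural_connectivity


def _cascade_robustness(g: nx.Graph, remove: list) -> float:
    """Remove the listed nodes, then iteratively drop newly isolated nodes."""
    h = g.copy()
    h.remove_nodes_from(remove)
    while True:
        isolated = [n for n, d in h.degree() if d == 0]
        if not isolated:
            break
        h.remove_nodes_from(isolated)
    return h.number_of_nodes() / g.number_of_nodes()


def robustness_curve(
    g: nx.Graph,
    strategy: str = "random",
    fractions=None,
    n_rep: int = 100,
    seed: int = 0,
    roles: pd.DataFrame | None = None,
    cascade: bool = True,
) -> StabilityCurves:
    """Fraction of taxa remaining after removing a fraction of nodes.

    ``random`` removes uniformly without replacement; ``targeted`` removes
    module hubs in decreasing Zi order first, then random nodes among the
    rest.  With ``cascade`` (default) nodes left without any association are
    also counted as lost.
    """
    if strategy not in ("random", "targeted"):
        raise ValueError("strategy must be 'random' or 'targeted'")
    fractions = np.asarray(
        np.linspace(0, 0.8, 17) if fractions is None else fractions, dtype=float
    )
    if ((fractions < 0) | (fractions > 1)).any():
        raise ValueError("removal fractions must lie in [0, 1]")
    nodes = list(g.nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)

    hubs: list = []
    if strategy == "targeted":
        if roles is None:
            raise ValueError("targeted removal requires node roles")
        hub_rows = roles[roles["role"].isin(["module_hub", "network_hub"])]
        hubs = list(hub_rows.sort_values("zi", ascending=False).index)
        if not hubs:
            warnings.warn("no module hubs; targeted removal degenerates to random")

    def remaining(frac, rep_rng):
        n_remove = int(np.ceil(frac * n))
        if n_remove == 0:
            return 1.0
        if strategy == "targeted" and hubs:
            first = hubs[:n_remove]
            rest_pool = [x for x in nodes if x not in set(first)]
            extra = n_remove - len(first)
            rest = (
                list(rep_rng.choice(rest_pool, size=extra, replace=False))
                if extra > 0
                else []
            )
            removal = first + rest
        else:
            removal = list(rep_rng.choice(nodes, size=n_remove, replace=False))
        if cascade:
            return _cascade_robustness(g, removal)
        return (n - n_remove) / n

    mean = np.empty(len(fractions))
    sd = np.empty(len(fractions))
    for i, f in enumerate(fractions):
        vals = [remaining(f, rng) for _ in range(n_rep)]
        mean[i] = np.mean(vals)
        sd[i] = np.std(vals)
    return StabilityCurves(fractions, mean, sd, strategy, "robustness")


def natural_connectivity(g: nx.Graph) -> float:
    """λ̄ = ln[(1/N)·Σ exp(λ_i)] over adjacency eigenvalues (binary graph)."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity undefined for an empty graph")
    a = nx.to_numpy_array(g, weight=None)
    eig = np.linalg.eigvalsh(a)
    return float(logsumexp(eig) - np.log(n))


def natural_connectivity_curve(
    g: nx.Graph,
    max_fraction: float = 0.8,
    n_rep: int = 50,
    seed: int = 0,
) -> StabilityCurves:
    """Natural connectivity after each random single-node removal.

    Removal orders are uniformly random; the curve is averaged over
    ``n_rep`` orders and truncated once fewer than two nodes remain.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need ≥2 nodes")
    n_steps = min(int(np.floor(max_fraction * n)), n - 1)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_rep, n_steps + 1))
    nodes = list(g.nodes)
    for r in range(n_rep):
        order = rng.permutation(n)
        h = g.copy()
        curves[r, 0] = natural_connectivity(h)
        for s in range(1, n_steps + 1):
            h.remove_node(nodes[order[s - 1]])
            curves[r, s] = natural_connectivity(h)
    fractions = np.arange(n_steps + 1) / n
    return StabilityCurves(
        fractions, curves.mean(axis=0), curves.std(axis=0), "random",
        "natural_connectivity",
    )
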