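"""Community assembly inference: Sloan neutral model and βNTI/RCbray nulls.

Two complementary lines of evidence are implemented:

* **Sloan neutral community model (NCM)** — predicts a taxon's occurrence
  frequency across samples from its mean regional relative abundance
  ``p_i`` under pure migration–drift dynamics with community size ``N``
  and migration probability ``m``.  The predicted frequency is
  ``F_i = 1 − I(d; N·m·p_i, N·m·(1 − p_i))`` with ``I`` the regularized
  incomplete beta CDF and ``d = 1/N`` the detection limit.  A good fit
  (R² approaching 1) indicates stochastic assembly; a poor or negative R²
  indicates deterministic structuring.

* **Null-model partitioning** — per sample pair, the phylogenetic turnover
  null (βNTI, a standardized effect size of β-MNTD under taxon shuffles
  across the phylogeny) and the taxonomic turnover null (RCbray, a
  Raup–Crick index on Bray–Curtis under a richness- and abundance-
  preserving null) classify the pair into one of five assembly processes:
  heterogeneous selection (βNTI > 2), homogeneous selection (βNTI < −2),
  dispersal limitation (|βNTI| ≤ 2, RC > 0.95), homogenizing dispersal
  (|βNTI| ≤ 2, RC < −0.95), or undominated (|βNTI| ≤ 2, |RC| ≤ 0.95).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .io import CountTable, DistanceMatrix, PairMatrix, PhyloTree
from .diversity import _bmntd_from_dist

__all__ = [
    "NCMFit",
    "fit_ncm",
    "compute_bnti",
    "compute_rcbray",
    "PairwiseAssembly",
    "AssemblyPartition",
    "partition_processes",
    "PROCESSES",
    "classify_pair",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# Sloan neutral community model


@dataclass
class NCMFit:
    m: float
    N: float
    r2: float
    taxa: pd.DataFrame  # p, observed_freq, predicted_freq, ci_lower, ci_upper, class
    degenerate: bool = False

    @property
    def class_counts(self) -> dict[str, int]:
        return self.taxa["class"].value_counts().to_dict()


def _ncm_predicted(p: np.ndarray, N: float, m: float) -> np.ndarray:
    Nm = N * m
    a = Nm * p
    b = Nm * (1.0 - p)
    d = 1.0 / N
    return 1.0 - special.betainc(a, b, d)


def _wilson(f: np.ndarray, n: int, z: float = 1.959963984540054):
    denom = 1.0 + z**2 / n
    center = (f + z**2 / (2 * n)) / denom
    half = z * np.sqrt(f * (1 - f) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def fit_ncm(table: CountTable) -> NCMFit:
    """Fit the Sloan neutral model to occurrence frequencies.

    ``N`` is the mean sample total; ``m`` is estimated by bounded nonlinear
    least squares of predicted against observed occurrence frequencies
    (multi-start over a log grid on (1e-4, 1]).  R² = 1 − SSE/SST may be
    negative — worse than predicting the mean frequency — which is itself
    the diagnostic for deterministic assembly.  95% bands are Wilson score
    intervals on the predicted frequency with n = number of samples.
    """
    if table.n_samples < 5:
        raise ValueError("NCM fit needs at least 5 samples")
    n_samples = table.n_samples
    N = float(table.sample_sums().mean())
    rel = table.relative_abundance()
    p = rel.mean(axis=1)
    obs = (table.counts > 0).mean(axis=1)
    keep = p > 0
    p, obs = p[keep], obs[keep]
    taxa_ids = [t for t, k in zip(table.taxon_ids, keep) if k]

    sst = float(((obs - obs.mean()) ** 2).sum())
    degenerate = sst == 0.0
    if degenerate:
        warnings.warn("no variation in occurrence frequency; NCM fit degenerate")

    def sse(log_m):
        pred = _ncm_predicted(p, N, float(np.exp(log_m)))
        return float(((obs - pred) ** 2).sum())

    # dense log-grid scan guards against plateaus/multimodality, then a
    # bounded scalar refinement in the bracket around the best grid point
    grid = np.log(np.geomspace(1e-4, 1.0, 200))
    grid_sse = np.array([sse(g) for g in grid])
    k = int(np.argmin(grid_sse))
    lo_b = grid[max(k - 1, 0)]
    hi_b = grid[min(k + 1, len(grid) - 1)]
    if lo_b == hi_b:
        best_log_m = grid[k]
    else:
        res = optimize.minimize_scalar(
            sse, bounds=(lo_b, hi_b), method="bounded", options={"xatol": 1e-10}
        )
        best_log_m = res.x if res.fun <= grid_sse[k] else grid[k]
    m_hat = float(np.exp(best_log_m))
    pred = _ncm_predicted(p, N, m_hat)
    sse_val = float(((obs - pred) ** 2).sum())
    r2 = np.nan if degenerate else 1.0 - sse_val / sst
    lo, hi = _wilson(pred, n_samples)
    cls = np.where(obs > hi, "above", np.where(obs < lo, "below", "within"))
    taxa = pd.DataFrame(
        {
            "p": p,
            "observed_freq": obs,
            "predicted_freq": pred,
            "ci_lower": lo,
            "ci_upper": hi,
            "class": cls,
        },
        index=pd.Index(taxa_ids, name="taxon_id"),
    )
    return NCMFit(m=m_hat, N=N, r2=float(r2) if not degenerate else float("nan"),
                  taxa=taxa, degenerate=degenerate)


# ---------------------------------------------------------------------------
# βNTI


def compute_bnti(
    table: CountTable,
    tree: PhyloTree,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> PairMatrix:
    """Standardized effect size of β-MNTD under regional-pool taxon shuffles.

    The null permutes taxon identities across the pooled patristic distance
    matrix (one shuffle per iteration, shared by all pairs); abundances are
    untouched.  βNTI = (βMNTD_obs − mean_null) / sd_null.  Pairs whose null
    has zero spread (e.g. a star phylogeny) are undefined and returned as
    NaN with a warning; downstream partitioning excludes them.
    """
    if n_null < 99:
        raise ValueError("n_null must be ≥ 99")
    rng = np.random.default_rng(seed)
    dist = tree.patristic_matrix(table.taxon_ids)
    present = table.counts > 0
    if weighted:
        freq = (table.counts / table.counts.sum(axis=0, keepdims=True)).astype(float)
    else:
        freq = (present / present.sum(axis=0, keepdims=True)).astype(float)

    obs = _bmntd_from_dist(freq, present, dist)
    n = table.n_samples
    null_sum = np.zeros((n, n))
    null_sq = np.zeros((n, n))
    n_taxa = table.n_taxa
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        d_null = dist[np.ix_(perm, perm)]
        b = _bmntd_from_dist(freq, present, d_null)
        null_sum += b
        null_sq += b * b
    mean = null_sum / n_null
    var = null_sq / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = (obs - mean) / sd
    bnti[sd < 1e-12] = np.nan
    np.fill_diagonal(bnti, 0.0)
    n_undef = int(np.isnan(bnti[np.triu_indices(n, k=1)]).sum())
    if n_undef:
        warnings.warn(f"{n_undef} sample pair(s) have undefined βNTI (zero null spread)")
    return PairMatrix(list(table.sample_ids), bnti, metric="bnti")


# ---------------------------------------------------------------------------
# RCbray


def _rc_null_sample(rng, richness, total, occ_w, pool_p):
    """One null community: observed richness, membership ∝ occupancy,
    abundance ∝ regional relative abundance (each member seeded with one
    individual)."""
    n_taxa = len(occ_w)
    if richness > n_taxa:
        raise ValueError("sample richness exceeds taxon pool")
    members = rng.choice(n_taxa, size=richness, replace=False, p=occ_w)
    counts = np.zeros(n_taxa)
    counts[members] = 1.0
    remaining = total - richness
    if remaining > 0:
        w = pool_p[members]
        w = w / w.sum()
        counts[members] += rng.multinomial(remaining, w)
    return counts


def _bc_pair(a, b):
    return np.abs(a - b).sum() / (a.sum() + b.sum())


def compute_rcbray(
    table: CountTable, n_null: int = 999, seed: int = 0
) -> PairMatrix:
    """Raup–Crick index on Bray–Curtis with a richness/abundance null.

    Per iteration each sample of a pair is rebuilt: it keeps its observed
    richness and total, membership is drawn ∝ occupancy across all samples,
    and individuals are allocated ∝ regional relative abundance.  Ties
    between null and observed Bray–Curtis get half weight:
    ``RC = 2·[(#{null < obs} + 0.5·#{null = obs}) / n_null] − 1``.
    """
    if n_null < 99:
        raise ValueError("n_null must be ≥ 99")
    rng = np.random.default_rng(seed)
    x = table.counts.astype(float)
    n = table.n_samples
    totals = x.sum(axis=0)
    richness = (x > 0).sum(axis=0).astype(int)
    occ = (x > 0).mean(axis=1)
    occ_w = occ / occ.sum()
    pool_p = (x / totals).mean(axis=1)
    pool_p = pool_p / pool_p.sum()

    obs_bc = np.zeros((n, n))
    for k in range(n):
        for l in range(k + 1, n):
            obs_bc[k, l] = obs_bc[l, k] = _bc_pair(x[:, k], x[:, l])

    rc = np.zeros((n, n))
    for k in range(n):
        for l in range(k + 1, n):
            less = equal = 0
            for _ in range(n_null):
                a = _rc_null_sample(rng, richness[k], int(totals[k]), occ_w, pool_p)
                b = _rc_null_sample(rng, richness[l], int(totals[l]), occ_w, pool_p)
                bc = _bc_pair(a, b)
                if bc < obs_bc[k, l] - 1e-12:
                    less += 1
                elif abs(bc - obs_bc[k, l]) <= 1e-12:
                    equal += 1
            rc_val = 2.0 * ((less + 0.5 * equal) / n_null) - 1.0
            rc[k, l] = rc[l, k] = rc_val
    return PairMatrix(list(table.sample_ids), rc, metric="rcbray")


# ---------------------------------------------------------------------------
# Process partitioning


def classify_pair(bnti: float, rc: float) -> str:
    """Five-process rule from the βNTI / RCbray thresholds."""
    if np.isnan(bnti):
        raise ValueError("undefined βNTI cannot be classified")
    if bnti > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


@dataclass
class PairwiseAssembly:
    pairs: pd.DataFrame  # sample_a, sample_b, group, bnti, rcbray, process


@dataclass
class AssemblyPartition:
    fractions: pd.DataFrame  # groups × 5 processes, over all valid pairs
    deterministic_fractions: pd.DataFrame  # selection split over |βNTI|>2 pairs only
    n_pairs: pd.Series
    n_undefined: pd.Series
    pairs: pd.DataFrame


def partition_processes(
    bnti: PairMatrix,
    rcbray: PairMatrix,
    groups,
    within_groups_only: bool = True,
) -> AssemblyPartition:
    """Turn per-pair (βNTI, RCbray) values into per-group process fractions.

    ``fractions`` normalizes over all classifiable pairs of a group;
    ``deterministic_fractions`` reports the two selection processes as
    shares of the |βNTI| > 2 pairs only (both normalizations are reported
    because habitat studies quote either).  Pairs with undefined βNTI are
    excluded and counted in ``n_undefined``.
    """
    if bnti.ids != rcbray.ids:
        rcbray = rcbray.filter(bnti.ids)
    if isinstance(groups, dict):
        labels = [groups[s] for s in bnti.ids]
    else:
        labels = list(groups)
    n = len(bnti.ids)
    rows = []
    for k in range(n):
        for l in range(k + 1, n):
            same = labels[k] == labels[l]
            if within_groups_only and not same:
                continue
            group = labels[k] if same else f"{labels[k]}|{labels[l]}"
            b = bnti.values[k, l]
            r = rcbray.values[k, l]
            proc = None if np.isnan(b) else classify_pair(b, r)
            rows.append((bnti.ids[k], bnti.ids[l], group, b, r, proc))
    pairs = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "group", "bnti", "rcbray", "process"]
    )
    if pairs.empty or pairs["process"].notna().sum() == 0:
        raise ValueError("no classifiable sample pairs")

    frac_rows, det_rows, n_pairs, n_undef = {}, {}, {}, {}
    for g, sub in pairs.groupby("group"):
        valid = sub.dropna(subset=["process"])
        n_pairs[g] = len(valid)
        n_undef[g] = int(sub["process"].isna().sum())
        if len(valid) == 0:
            continue
        counts = valid["process"].value_counts()
        frac_rows[g] = {p: counts.get(p, 0) / len(valid) for p in PROCESSES}
        det = valid[valid["process"].isin(PROCESSES[:2])]
        if len(det):
            det_rows[g] = {
                p: (det["process"] == p).sum() / len(det) for p in PROCESSES[:2]
            }
        else:
            det_rows[g] = {p: np.nan for p in PROCESSES[:2]}
    fractions = pd.DataFrame(frac_rows).T.reindex(columns=list(PROCESSES)).fillna(0.0)
    det_fractions = pd.DataFrame(det_rows).T.reindex(columns=list(PROCESSES[:2]))
    return AssemblyPartition(
        fractions=fractions,
        deterministic_fractions=det_fractions,
        n_pairs=pd.Series(n_pairs),
        n_undefined=pd.Series(n_undef),
        pairs=pairs,
    )
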