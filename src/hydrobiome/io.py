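"""Core data containers and readers/writers for the standard flat-file formats.

The pipeline's universal currency is a taxa × samples integer count table
(ASV/OTU abundances), a rooted phylogeny with branch lengths, and a sample
metadata table carrying habitat group labels, coordinates and environmental
measurements.  Everything here validates aggressively: silent axis swaps and
malformed matrices are the classic failure mode of community-ecology scripts.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CountTable",
    "PhyloTree",
    "SampleMetadata",
    "DistanceMatrix",
    "PairMatrix",
    "FormatError",
    "ValidationError",
    "read_count_table",
    "write_count_table",
    "read_tree_newick",
    "write_tree_newick",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_network_graphml",
    "write_network_edgelist",
    "write_table_tsv",
]


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


class ValidationError(ValueError):
    """Raised when parsed data violate a container invariant."""


def _check_unique(ids, what):
    seen = set()
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValidationError(f"duplicate {what} id(s): {sorted(set(dups))}")


# ---------------------------------------------------------------------------
# CountTable


@dataclass
class CountTable:
    """Non-negative integer abundance matrix, taxa as rows, samples as columns.

    A relative-abundance view is always derived on demand
    (:meth:`relative_abundance`), never stored, so the raw counts stay the
    single source of truth.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix (taxa × samples)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating):
                if np.isnan(self.counts).any():
                    bad = np.argwhere(np.isnan(self.counts))
                    cells = [(self.taxon_ids[i], self.sample_ids[j]) for i, j in bad[:5]]
                    raise ValidationError(f"NaN count cells: {cells}")
                if not np.allclose(self.counts, np.round(self.counts)):
                    bad = np.argwhere(~np.isclose(self.counts, np.round(self.counts)))
                    cells = [(self.taxon_ids[i], self.sample_ids[j]) for i, j in bad[:5]]
                    raise ValidationError(f"non-integer count cells: {cells}")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa × {len(self.sample_ids)} samples"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if len(self.taxon_ids) < 1 or len(self.sample_ids) < 2:
            raise ValidationError("need ≥1 taxon and ≥2 samples")
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)
            cells = [(self.taxon_ids[i], self.sample_ids[j]) for i, j in bad[:5]]
            raise ValidationError(f"negative count cells: {cells}")
        colsum = self.counts.sum(axis=0)
        if (colsum == 0).any():
            empty = [self.sample_ids[j] for j in np.flatnonzero(colsum == 0)]
            raise ValidationError(f"sample column(s) with zero total: {empty}")

    # -- convenience views -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalized matrix; every column sums to 1."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def select_samples(self, sample_ids) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(
            list(self.taxon_ids), list(sample_ids), self.counts[:, idx], self.taxonomy
        )

    def select_taxa(self, taxon_ids) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        tax = (
            {t: self.taxonomy[t] for t in taxon_ids if t in self.taxonomy}
            if self.taxonomy
            else None
        )
        return CountTable(list(taxon_ids), list(self.sample_ids), self.counts[idx], tax)

    def drop_empty_taxa(self) -> "CountTable":
        keep = self.counts.sum(axis=1) > 0
        return CountTable(
            [t for t, k in zip(self.taxon_ids, keep) if k],
            list(self.sample_ids),
            self.counts[keep],
            self.taxonomy,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def __eq__(self, other):
        return (
            isinstance(other, CountTable)
            and self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


_TAXON_PREFIXES = ("asv", "otu", "feature", "sp", "taxon")


def _looks_like_taxon_ids(names) -> bool:
    hits = sum(1 for n in names if str(n).lower().startswith(_TAXON_PREFIXES))
    return hits >= max(1, int(0.8 * len(names)))


def read_count_table(path, dialect: str = "tsv") -> tuple[CountTable, dict]:
    """Read a count table from TSV (taxa rows, sample columns) or BIOM-JSON.

    Returns the validated table and a small parse report
    (``n_taxa``, ``n_samples``, ``total_reads``).
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        taxonomy = None
        if "taxonomy" in df.columns:
            taxonomy = {str(t): str(v) for t, v in df["taxonomy"].items()}
            df = df.drop(columns=["taxonomy"])
        # transposed-input heuristic: header rows that look like taxon ids, or
        # an implausibly wide table, point at samples-as-rows input
        if _looks_like_taxon_ids(df.columns) and not _looks_like_taxon_ids(df.index):
            raise FormatError(
                "header row looks like taxon ids — the table appears transposed "
                "(samples as rows); supply taxa as rows, samples as columns"
            )
        if df.shape[1] > 20 and df.shape[1] > 4 * df.shape[0]:
            raise FormatError(
                f"table is {df.shape[0]} rows × {df.shape[1]} columns; this looks "
                "transposed (samples as rows) — supply taxa as rows"
            )
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                raise ValidationError(f"non-numeric cells in sample column {col!r}")
        table = CountTable(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(),
            taxonomy,
        )
    elif dialect == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_element_type") not in ("int", None):
            raise FormatError("only integer BIOM matrices are supported")
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat[:] = np.asarray(doc["data"])
        taxonomy = None
        if doc["rows"] and (doc["rows"][0].get("metadata") or {}).get("taxonomy"):
            taxonomy = {
                r["id"]: ";".join(r["metadata"]["taxonomy"])
                for r in doc["rows"]
                if r.get("metadata") and r["metadata"].get("taxonomy")
            }
        table = CountTable(taxa, samples, mat, taxonomy)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    report = {
        "n_taxa": table.n_taxa,
        "n_samples": table.n_samples,
        "total_reads": int(table.counts.sum()),
    }
    return table, report


def write_count_table(table: CountTable, path) -> None:
    df = table.to_dataframe()
    if table.taxonomy:
        df["taxonomy"] = [table.taxonomy.get(t, "") for t in table.taxon_ids]
    df.to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# PhyloTree


@dataclass
class PhyloTree:
    """Rooted phylogeny with branch lengths, backed by a scikit-bio TreeNode."""

    tree: TreeNode

    def __post_init__(self):
        tips = [t.name for t in self.tree.tips()]
        _check_unique(tips, "tip")
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                raise ValidationError(
                    f"branch leading to {node.name or 'internal node'} has no "
                    "length; branch lengths are required for PD/β-MNTD"
                )
            if node.length < 0:
                raise ValidationError(f"negative branch length at {node.name!r}")
        if self.tree.length is None:
            self.tree.length = 0.0

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def patristic_matrix(self, taxa: list[str] | None = None) -> np.ndarray:
        """Tip-to-tip path-length distance matrix, ordered as ``taxa``."""
        dm = self.tree.tip_tip_distances()
        order = taxa if taxa is not None else list(dm.ids)
        missing = [t for t in order if t not in set(dm.ids)]
        if missing:
            raise ValidationError(f"taxa not in tree: {missing[:10]}")
        return dm.filter(order).data.copy()

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()


def read_tree_newick(path) -> PhyloTree:
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"could not parse newick: {exc}") from exc
    return PhyloTree(tree)


def write_tree_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# SampleMetadata


@dataclass
class SampleMetadata:
    """Per-sample group labels, coordinates and environmental measurements.

    ``env`` holds one column per measured variable (TDS, Na+, Cl-, ... in
    mg/L, or a synthetic salinity driver); missing values stay as NaN and are
    flagged in :attr:`missing`, never silently dropped.
    """

    frame: pd.DataFrame  # indexed by sample_id; columns: group, latitude, longitude, env...

    def __post_init__(self):
        if "group" not in self.frame.columns:
            raise ValidationError("metadata requires a 'group' column")
        _check_unique(list(self.frame.index), "sample")
        if "latitude" in self.frame.columns:
            lat = self.frame["latitude"].dropna()
            bad = lat[(lat < -90) | (lat > 90)]
            if len(bad):
                raise ValidationError(f"latitude out of [-90, 90]: {dict(bad)}")
        if "longitude" in self.frame.columns:
            lon = self.frame["longitude"].dropna()
            bad = lon[(lon < -180) | (lon > 180)]
            if len(bad):
                raise ValidationError(f"longitude out of [-180, 180]: {dict(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    @property
    def groups(self) -> pd.Series:
        return self.frame["group"]

    @property
    def env_columns(self) -> list[str]:
        reserved = {"group", "latitude", "longitude"}
        return [c for c in self.frame.columns if c not in reserved]

    @property
    def missing(self) -> dict[str, list[str]]:
        """env column → samples with a missing value."""
        out = {}
        for c in self.env_columns:
            na = self.frame.index[self.frame[c].isna()]
            if len(na):
                out[c] = [str(s) for s in na]
        return out

    def coordinates(self) -> np.ndarray:
        if not {"latitude", "longitude"} <= set(self.frame.columns):
            raise ValidationError("metadata has no latitude/longitude columns")
        missing = self.frame.index[
            self.frame[["latitude", "longitude"]].isna().any(axis=1)
        ]
        if len(missing):
            raise ValidationError(f"samples without coordinates: {list(missing)}")
        return self.frame[["latitude", "longitude"]].to_numpy(float)

    def group_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.frame["group"].items():
            out.setdefault(str(g), []).append(str(s))
        return out


def read_sample_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("metadata must have a 'sample_id' column")
    df = df.set_index("sample_id")
    reserved = {"group"}
    for c in df.columns:
        if c in reserved:
            continue
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# DistanceMatrix


@dataclass
class DistanceMatrix:
    """Square symmetric non-negative dissimilarity matrix with sample ids."""

    ids: list[str]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n},{n})")
        _check_unique(self.ids, "sample")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            i, j = np.unravel_index(
                np.argmax(np.abs(self.values - self.values.T)), self.values.shape
            )
            raise ValidationError(
                f"matrix not symmetric at ({self.ids[i]}, {self.ids[j]})"
            )
        if not np.allclose(np.diag(self.values), 0, atol=1e-12):
            k = int(np.argmax(np.abs(np.diag(self.values))))
            raise ValidationError(f"nonzero diagonal at {self.ids[k]}")
        finite = self.values[np.isfinite(self.values)]
        if (finite < -1e-12).any():
            raise ValidationError("negative distance value")
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy 'condensed' order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def filter(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric)


@dataclass
class PairMatrix:
    """Symmetric square matrix of signed per-pair statistics (βNTI, RCbray).

    Unlike :class:`DistanceMatrix` values may be negative or NaN (undefined
    pairs); the diagonal is not meaningful and is stored as 0.
    """

    ids: list[str]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n},{n})")
        _check_unique(self.ids, "sample")
        a, b = self.values, self.values.T
        both = np.isfinite(a) & np.isfinite(b)
        if not np.allclose(a[both], b[both], atol=1e-10) or not np.array_equal(
            np.isnan(a), np.isnan(b)
        ):
            raise ValidationError("matrix not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def filter(self, ids) -> "PairMatrix":
        idx = [self.ids.index(s) for s in ids]
        return PairMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric)


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise FormatError("distance matrix row and column ids differ")
    return DistanceMatrix([str(i) for i in df.index], df.to_numpy(float))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", float_format="%.6g", index_label="sample_id"
    )


# ---------------------------------------------------------------------------
# Generic writers (bit-stable text output)


def _fmt(x):
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def write_table_tsv(df: pd.DataFrame, path, sort_rows: bool = False) -> None:
    """UTF-8 TSV, '.' decimal, 6 significant digits, optional lexicographic sort."""
    out = df.copy()
    if sort_rows:
        out = out.sort_index(axis=0, key=lambda idx: idx.astype(str))
    out.to_csv(path, sep="\t", float_format="%.6g", encoding="utf-8")


def write_network_graphml(graph, path) -> None:
    import networkx as nx

    g = graph.copy()
    # GraphML cannot hold arbitrary python objects; stringify non-scalars
    for _, d in g.nodes(data=True):
        for k, v in list(d.items()):
            if not isinstance(v, (str, int, float, bool)):
                d[k] = str(v)
    for _, _, d in g.edges(data=True):
        for k, v in list(d.items()):
            if not isinstance(v, (str, int, float, bool)):
                d[k] = str(v)
    nx.write_graphml(g, path)


def write_network_edgelist(graph, path) -> None:
    rows = sorted(
        (min(u, v), max(u, v), graph.edges[u, v].get("rho", 1.0))
        for u, v in graph.edges
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\trho\n")
        for u, v, rho in rows:
            fh.write(f"{u}\t{v}\t{_fmt(rho)}\n")
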