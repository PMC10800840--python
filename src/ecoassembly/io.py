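"""Shared data model and readers/writers for the standard formats.

The pipeline's universal inputs are a sample x taxon abundance table (TSV),
a rooted phylogenetic tree with branch lengths (Newick), and a sample
metadata table (TSV with group labels, coordinates and environmental
variables).  Everything downstream consumes the validated containers defined
here; the canonical orientation is samples as rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("ecoassembly")

GROUPS = ("surface", "middle", "bottom", "sediment")

__all__ = [
    "CommunityTable",
    "SampleMetadata",
    "PhyloTree",
    "PairwiseMatrix",
    "AlignedBundle",
    "read_community_table",
    "write_community_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "to_relative_abundance",
    "align_inputs",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CommunityTable:
    """Sample x taxon abundance matrix (rows = samples, columns = taxa)."""

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n, s = self.counts.shape
        if n != len(self.sample_ids) or s != len(self.taxon_ids):
            raise ValueError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        if not np.isfinite(self.counts).all():
            raise ValueError("counts contain non-finite values")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CommunityTable":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def is_integer(self) -> bool:
        return bool(np.allclose(self.counts, np.round(self.counts), atol=1e-9))

    def select_samples(self, sample_ids: Iterable[str]) -> "CommunityTable":
        keep = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in keep]
        return CommunityTable(self.counts[idx], keep, list(self.taxon_ids))

    def select_taxa(self, taxon_ids: Iterable[str]) -> "CommunityTable":
        keep = list(taxon_ids)
        idx = [self.taxon_ids.index(t) for t in keep]
        return CommunityTable(self.counts[:, idx], list(self.sample_ids), keep)


@dataclass
class SampleMetadata:
    """Per-sample annotations: habitat group, coordinates, environment.

    ``env`` maps variable names (NH4-N, NO2-N, NO3-N, PO4-P, pH, ...) to
    values; missing values are allowed only there (NaN).
    """

    sample_id: str
    group: str
    latitude: float
    longitude: float
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


def metadata_frame(meta: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Tabular view of a metadata collection (env vars as columns)."""
    rows = []
    for m in meta:
        row = {"sample_id": m.sample_id, "group": m.group,
               "latitude": m.latitude, "longitude": m.longitude}
        row.update(m.env)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


class PhyloTree:
    """Rooted tree with branch lengths; leaf labels are taxon ids."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        _check_unique(leaves, "leaf")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length in tree")
        self.leaf_labels: list[str] = sorted(leaves)

    @classmethod
    def from_newick(cls, newick: str, missing_length: float | None = None) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:
            raise ValueError(f"could not parse Newick: {exc}") from exc
        n_missing = sum(1 for e in tree.preorder_edge_iter()
                        if e.head_node.parent_node is not None and e.length is None)
        if n_missing:
            if missing_length is None:
                raise ValueError(
                    f"{n_missing} branch(es) lack lengths; pass missing_length "
                    "to substitute a value"
                )
            for e in tree.preorder_edge_iter():
                if e.length is None:
                    e.length = missing_length
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick",
                                    suppress_rooting=True).strip()

    def cophenetic(self, taxa: Sequence[str] | None = None) -> "PairwiseMatrix":
        """Leaf-to-leaf patristic distance matrix, rows/cols ordered by ``taxa``."""
        labels = list(taxa) if taxa is not None else self.leaf_labels
        missing = set(labels) - set(self.leaf_labels)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        pdm = self._tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in self._tree.taxon_namespace
               if t.label in set(labels)}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(tax[labels[i]], tax[labels[j]])
        return PairwiseMatrix(d, labels, "patristic")

    def retain_taxa(self, taxa: Iterable[str]) -> "PhyloTree":
        keep = set(taxa)
        tree = self._tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(keep))
        return PhyloTree(tree)


@dataclass
class PairwiseMatrix:
    """Square symmetric matrix over ordered labels (samples or taxa)."""

    values: np.ndarray
    labels: list[str]
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        _check_unique(self.labels, "label")
        finite = np.isfinite(self.values)
        if not np.allclose(np.where(finite, self.values, 0.0),
                           np.where(finite.T, self.values.T, 0.0), atol=1e-10):
            raise ValueError("matrix is not symmetric within 1e-10")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy condensed order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def subset(self, labels: Sequence[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(x) for x in labels]
        return PairwiseMatrix(self.values[np.ix_(idx, idx)], list(labels),
                              self.metric_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class AlignedBundle:
    """Jointly validated inputs restricted to shared samples/taxa."""

    table: CommunityTable
    metadata: list[SampleMetadata]
    tree: PhyloTree | None
    dropped_samples: list[str]
    dropped_taxa: list[str]

    def groups(self) -> dict[str, str]:
        return {m.sample_id: m.group for m in self.metadata}


# ---------------------------------------------------------------------------
# readers / writers

def read_community_table(path, orientation: str = "samples_as_rows") -> CommunityTable:
    """Read a TSV abundance table (one header row, one id column).

    ``orientation='taxa_as_rows'`` transposes to the canonical layout.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty community table: {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nonnum = bad.isna() & df[col].notna()
        if nonnum.any():
            row = df.index[np.argmax(nonnum.to_numpy())]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
        neg = bad < 0
        if neg.any():
            row = df.index[np.argmax(neg.to_numpy())]
            raise ValueError(f"negative cell at row {row!r}, column {col!r}")
        df[col] = bad
    if df.isna().any().any():
        raise ValueError("community table contains missing cells")
    if orientation == "taxa_as_rows":
        df = df.T
    return CommunityTable.from_frame(df)


def write_community_table(table: CommunityTable, path) -> None:
    table.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata(path) -> list[SampleMetadata]:
    """Read sample metadata TSV: sample_id, group, latitude, longitude, env..."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "group", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    env_cols = [c for c in df.columns if c not in required]
    _check_unique(list(df["sample_id"]), "sample")
    out = []
    for _, r in df.iterrows():
        env = {c: float(r[c]) for c in env_cols}
        out.append(SampleMetadata(str(r["sample_id"]), str(r["group"]),
                                  float(r["latitude"]), float(r["longitude"]), env))
    return out


def write_metadata(meta: Sequence[SampleMetadata], path) -> None:
    metadata_frame(meta).reset_index().to_csv(path, sep="\t", index=False)


def read_tree(path, missing_length: float | None = None) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read(), missing_length=missing_length)


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# transforms

def to_relative_abundance(table: CommunityTable) -> CommunityTable:
    """Total-sum scaling: every row sums to one."""
    sums = table.counts.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValueError(f"all-zero sample rows: {bad}")
    return CommunityTable(table.counts / sums[:, None],
                          list(table.sample_ids), list(table.taxon_ids))


def align_inputs(table: CommunityTable,
                 meta: Sequence[SampleMetadata],
                 tree: PhyloTree | None = None) -> AlignedBundle:
    """Restrict to shared samples (and tree taxa), canonically sorted.

    Returns the aligned bundle plus a report of dropped ids.  Raises on an
    empty sample intersection.
    """
    meta_ids = {m.sample_id for m in meta}
    shared = sorted(set(table.sample_ids) & meta_ids)
    if not shared:
        raise ValueError("no samples shared between table and metadata")
    dropped_samples = sorted((set(table.sample_ids) | meta_ids) - set(shared))
    sub = table.select_samples(shared)

    dropped_taxa: list[str] = []
    taxa = sorted(sub.taxon_ids)
    if tree is not None:
        on_tree = set(tree.leaf_labels)
        dropped_taxa = sorted(set(taxa) - on_tree)
        taxa = [t for t in taxa if t in on_tree]
        if not taxa:
            raise ValueError("no taxa shared between table and tree")
    sub = sub.select_taxa(taxa)

    if dropped_samples:
        logger.warning("align_inputs dropped %d sample(s): %s",
                       len(dropped_samples), dropped_samples)
    if dropped_taxa:
        logger.warning("align_inputs dropped %d taxa absent from tree",
                       len(dropped_taxa))
    meta_by_id = {m.sample_id: m for m in meta}
    return AlignedBundle(sub, [meta_by_id[s] for s in shared], tree,
                         dropped_samples, dropped_taxa)
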