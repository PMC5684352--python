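"""Data model and I/O for two-layer bipartite networks sharing both species sets.

A layer is a binary incidence matrix between two guilds (e.g. Lepidoptera x
plants); a multilayer pair holds two such layers over identical, aligned
species universes.  Species recorded in only one layer are carried as
zero-degree rows/columns in the other, so that downstream degree and module
analyses see the full species pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BipartiteLayer",
    "MultilayerPair",
    "LayerSummary",
    "read_edge_list",
    "read_incidence",
    "write_edge_list",
    "full_adjacency",
    "layer_adjacency",
    "layer_summary",
    "export_graphml",
]


class ParseError(ValueError):
    """Raised when an input file violates the edge-list/incidence contract."""


@dataclass(frozen=True)
class BipartiteLayer:
    """One binary bipartite interaction layer.

    Parameters
    ----------
    name
        Label of the layer (e.g. ``"herbivory"``).
    rows
        Ordered guild-A species labels (m entries).
    cols
        Ordered guild-B species labels (p entries).
    incidence
        m x p matrix; entry 1 marks an interaction.
    """

    name: str
    rows: tuple[str, ...]
    cols: tuple[str, ...]
    incidence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence, dtype=np.int8)
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "cols", tuple(self.cols))
        object.__setattr__(self, "incidence", inc)
        if inc.ndim != 2 or inc.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.rows)} row / {len(self.cols)} column labels"
            )
        if len(self.rows) < 1 or len(self.cols) < 1:
            raise ValueError("a layer needs at least one row and one column species")
        if not np.isin(inc, (0, 1)).all():
            bad = inc[~np.isin(inc, (0, 1))].flat[0]
            raise ValueError(f"incidence entries must be 0 or 1 (found {bad!r})")
        if len(set(self.rows)) != len(self.rows):
            raise ValueError("duplicate row labels")
        if len(set(self.cols)) != len(self.cols):
            raise ValueError("duplicate column labels")
        inc.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.incidence.shape

    def row_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=1)

    def col_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=0)

    def node_labels(self) -> tuple[str, ...]:
        """All m+p node labels in (rows, cols) order."""
        return self.rows + self.cols


@dataclass(frozen=True)
class MultilayerPair:
    """Two aligned bipartite layers over identical species universes."""

    layer1: BipartiteLayer
    layer2: BipartiteLayer

    def __post_init__(self) -> None:
        if self.layer1.rows != self.layer2.rows or self.layer1.cols != self.layer2.cols:
            raise ValueError("layers are not aligned: row/column label lists differ")
        overlap = set(self.layer1.rows) & set(self.layer1.cols)
        if overlap:
            raise ValueError(
                f"bipartite violation: labels in both guilds: {sorted(overlap)[:5]}"
            )

    @property
    def rows(self) -> tuple[str, ...]:
        return self.layer1.rows

    @property
    def cols(self) -> tuple[str, ...]:
        return self.layer1.cols

    @property
    def layer_names(self) -> tuple[str, str]:
        return (self.layer1.name, self.layer2.name)


@dataclass(frozen=True)
class LayerSummary:
    n_rows: int
    n_cols: int
    n_links: int
    connectance: float
    n_zero_degree_rows: int
    n_zero_degree_cols: int


def layer_summary(layer: BipartiteLayer) -> LayerSummary:
    """Basic descriptors: link count L, connectance C = L/(m*p), zero-degree counts."""
    links = int(layer.incidence.sum())
    m, p = layer.shape
    return LayerSummary(
        n_rows=m,
        n_cols=p,
        n_links=links,
        connectance=links / (m * p),
        n_zero_degree_rows=int((layer.row_degrees() == 0).sum()),
        n_zero_degree_cols=int((layer.col_degrees() == 0).sum()),
    )


def _norm(label: str, normalize: bool) -> str:
    return label.strip().lower() if normalize else label


def _build_pair(
    edges1: Iterable[tuple[str, str]],
    edges2: Iterable[tuple[str, str]],
    layer_names: tuple[str, str],
) -> MultilayerPair:
    edges1, edges2 = list(edges1), list(edges2)
    rows = sorted({a for a, _ in edges1} | {a for a, _ in edges2})
    cols = sorted({b for _, b in edges1} | {b for _, b in edges2})
    both = set(rows) & set(cols)
    if both:
        raise ParseError(
            f"bipartite violation: species appear in both guilds: {sorted(both)[:5]}"
        )
    ri = {s: i for i, s in enumerate(rows)}
    ci = {s: i for i, s in enumerate(cols)}
    layers = []
    for name, edges in zip(layer_names, (edges1, edges2)):
        inc = np.zeros((len(rows), len(cols)), dtype=np.int8)
        for a, b in edges:
            inc[ri[a], ci[b]] = 1
        layers.append(BipartiteLayer(name, rows, cols, inc))
    return MultilayerPair(*layers)


def read_edge_list(
    path: str | Path,
    layer_names: tuple[str, str],
    delimiter: str | None = None,
    normalize_labels: bool = False,
) -> MultilayerPair:
    """Read a long-format edge list with columns (species_a, species_b, layer).

    An optional fourth ``weight`` column is binarized at > 0 with a warning;
    ``#`` comment lines are skipped.  Duplicate edges collapse to a single 1.
    The row/column universes are the union of species seen in either layer,
    ordered lexicographically.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    edges: dict[str, list[tuple[str, str]]] = {n: [] for n in layer_names}
    saw_weight = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            a, b, lab = parts[0], parts[1], parts[2]
            if lineno == 1 and lab not in layer_names and lab.lower() == "layer":
                continue  # header row
            if lab not in layer_names:
                raise ParseError(
                    f"{path}:{lineno}: unknown layer label {lab!r} "
                    f"(expected one of {layer_names})"
                )
            if len(parts) >= 4 and parts[3] not in ("", "weight"):
                saw_weight = True
                if float(parts[3]) <= 0:
                    continue
            edges[lab].append((_norm(a, normalize_labels), _norm(b, normalize_labels)))
    if saw_weight:
        warnings.warn(
            "weight column found; interactions binarized at weight > 0",
            stacklevel=2,
        )
    return _build_pair(edges[layer_names[0]], edges[layer_names[1]], tuple(layer_names))


def _read_incidence_frame(path: Path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        bad = vals[~np.isin(vals, (0, 1))].flat[0]
        raise ParseError(f"{path}: non-binary cell value {bad!r}")
    return df

def read_incidence(
    path1: str | Path,
    path2: str | Path,
    layer_names: tuple[str, str] = ("layer1", "layer2"),
    delimiter: str | None = None,
    normalize_labels: bool = False,
) -> MultilayerPair:
    """Read two labelled 0/1 incidence matrices and align them by label union.

    First row = column labels, first column = row labels.  Species present in
    one file only are zero-padded into the other layer.
    """
    frames = [_read_incidence_frame(Path(p), delimiter) for p in (path1, path2)]
    if normalize_labels:
        for df in frames:
            df.index = [str(s).strip().lower() for s in df.index]
            df.columns = [str(s).strip().lower() for s in df.columns]
    edge_sets = [
        [
            (str(r), str(c))
            for r in df.index
            for c in df.columns
            if df.at[r, c] > 0
        ]
        for df in frames
    ]
    # keep zero-degree species recorded only as labels in either file
    rows = sorted({str(r) for df in frames for r in df.index})
    cols = sorted({str(c) for df in frames for c in df.columns})
    pair = _build_pair(edge_sets[0], edge_sets[1], tuple(layer_names))
    if tuple(rows) != pair.rows or tuple(cols) != pair.cols:
        ri = {s: i for i, s in enumerate(rows)}
        ci = {s: i for i, s in enumerate(cols)}
        layers = []
        for name, edges in zip(layer_names, edge_sets):
            inc = np.zeros((len(rows), len(cols)), dtype=np.int8)
            for a, b in edges:
                inc[ri[a], ci[b]] = 1
            layers.append(BipartiteLayer(name, rows, cols, inc))
        pair = MultilayerPair(*layers)
    return pair


def write_edge_list(pair: MultilayerPair, path: str | Path, delimiter: str = "\t") -> None:
    """Write the pair as a long-format edge list (round-trips with read_edge_list)."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(("species_a", "species_b", "layer")) + "\n")
        for layer in (pair.layer1, pair.layer2):
            ii, jj = np.nonzero(layer.incidence)
            for i, j in zip(ii, jj):
                fh.write(delimiter.join((layer.rows[i], layer.cols[j], layer.name)) + "\n")


def layer_adjacency(layer: BipartiteLayer) -> np.ndarray:
    """Symmetric (m+p) x (m+p) adjacency [[0, B], [B^T, 0]] of one layer."""
    m, p = layer.shape
    adj = np.zeros((m + p, m + p), dtype=np.int8)
    adj[:m, m:] = layer.incidence
    adj[m:, :m] = layer.incidence.T
    return adj


def full_adjacency(pair: MultilayerPair) -> np.ndarray:
    """Symmetric (m+p+m) x (m+p+m) adjacency of the whole multilayer system.

    Node blocks are ordered (guild-A of layer1, shared guild, guild-A of
    layer2): e.g. adult lepidopterans, plants, caterpillars.  Off-diagonal
    blocks hold the two incidence matrices and their transposes; all other
    blocks are zero.
    """
    b = pair.layer1.incidence
    c = pair.layer2.incidence
    m, p = b.shape
    adj = np.zeros((2 * m + p, 2 * m + p), dtype=np.int8)
    adj[:m, m : m + p] = b
    adj[m : m + p, :m] = b.T
    adj[m + p :, m : m + p] = c
    adj[m : m + p, m + p :] = c.T
    return adj


def export_graphml(pair: MultilayerPair, path: str | Path) -> None:
    """Export the full multilayer adjacency as GraphML for external viewers."""
    import networkx as nx

    g = nx.Graph()
    n1, n2 = pair.layer_names
    for s in pair.rows:
        g.add_node(f"{n1}:{s}", guild="A", layer=n1, species=s)
        g.add_node(f"{n2}:{s}", guild="A", layer=n2, species=s)
    for s in pair.cols:
        g.add_node(f"shared:{s}", guild="B", layer="shared", species=s)
    for layer, prefix in ((pair.layer1, n1), (pair.layer2, n2)):
        ii, jj = np.nonzero(layer.incidence)
        for i, j in zip(ii, jj):
            g.add_edge(f"{prefix}:{layer.rows[i]}", f"shared:{layer.cols[j]}", layer=layer.name)
    nx.write_graphml(g, path)
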