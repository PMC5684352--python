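"""Similarity of module composition between two partitions of the same species.

The confusion matrix N counts species shared by module i of one partition and
module j of the other; the normalized mutual information

    I(H, V) = -2 sum_ij N_ij log(N_ij N / (N_i. N_.j))
              / [sum_i N_i. log(N_i./N) + sum_j N_.j log(N_.j/N)]

is 1 when the two classifications coincide and 0 when they are statistically
independent (N_ij = N_i. N_.j / N for every cell).  Natural logarithms are
used; the base cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .module_detection import Partition
from .net_model_io import MultilayerPair

__all__ = ["ConfusionMatrix", "confusion", "nmi", "nmi_partitions", "costructure_graph"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of species shared between modules of two partitions."""

    n_ij: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.n_ij, dtype=np.int64)
        object.__setattr__(self, "n_ij", counts)
        if counts.ndim != 2 or (counts < 0).any():
            raise ValueError("confusion matrix must be a non-negative 2-d array")

    @property
    def total(self) -> int:
        return int(self.n_ij.sum())

    def row_sums(self) -> np.ndarray:
        return self.n_ij.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.n_ij.sum(axis=0)


def confusion(partition_h: Partition, partition_v: Partition) -> ConfusionMatrix:
    """Cross-tabulate the two module assignments over the shared node set.

    Raises if the node sets differ, listing the symmetric difference.
    """
    if set(partition_h.node_labels) != set(partition_v.node_labels):
        diff = sorted(set(partition_h.node_labels) ^ set(partition_v.node_labels))
        raise ValueError(f"partitions cover different node sets: {diff[:10]}")
    pv = partition_v.relabel(partition_h.node_labels)
    counts = np.zeros((partition_h.n_modules, pv.n_modules), dtype=np.int64)
    np.add.at(counts, (partition_h.membership, pv.membership), 1)
    return ConfusionMatrix(counts)


def nmi(conf: ConfusionMatrix) -> float:
    """Normalized mutual information of the two classifications, in [0, 1].

    Zero-count cells are skipped (0 log 0 = 0).  When both partitions are the
    trivial single-module classification the normalizer vanishes; the two
    classifications then coincide and 1.0 is returned.
    """
    counts = conf.n_ij.astype(float)
    n = counts.sum()
    if n < 1:
        raise ValueError("empty confusion matrix")
    ni = counts.sum(axis=1)
    nj = counts.sum(axis=0)
    nz_i = ni > 0
    nz_j = nj > 0
    denom = float(
        ni[nz_i] @ np.log(ni[nz_i] / n) + nj[nz_j] @ np.log(nj[nz_j] / n)
    )
    if denom == 0.0:
        # both margins trivial: single module on each side -> identical
        return 1.0
    mask = counts > 0
    ii, jj = np.nonzero(mask)
    numer = -2.0 * float(
        counts[mask] @ np.log(counts[mask] * n / (ni[ii] * nj[jj]))
    )
    return numer / denom


def nmi_partitions(partition_h: Partition, partition_v: Partition) -> float:
    """Convenience: NMI straight from two aligned partitions."""
    return nmi(confusion(partition_h, partition_v))


def costructure_graph(
    partition_h: Partition,
    partition_v: Partition,
    path: str | Path | None = None,
    pair: MultilayerPair | None = None,
):
    """Module-level bipartite graph: nodes are modules, edges carry shared counts.

    Edge weight n_ij is the number of species shared by module i of the first
    partition and module j of the second; module nodes are annotated with
    their size and, when the underlying pair is given, whether they consist
    solely of species without interactions in that layer.  When ``path`` is
    given both GraphML and a TSV edge table are written.
    """
    import networkx as nx

    conf = confusion(partition_h, partition_v)

    zero_h = zero_v = None
    if pair is not None:
        from .degree_codistribution import degrees

        deg = {}
        for which, layer in (("h", pair.layer1), ("v", pair.layer2)):
            d = {}
            d.update(degrees(layer, "rows").to_dict())
            d.update(degrees(layer, "cols").to_dict())
            deg[which] = d
        zero_h = [
            all(deg["h"][s] == 0 for s in partition_h.members(i))
            for i in range(partition_h.n_modules)
        ]
        zero_v = [
            all(deg["v"][s] == 0 for s in partition_v.members(j))
            for j in range(partition_v.n_modules)
        ]

    g = nx.Graph()
    sizes_h = partition_h.module_sizes()
    sizes_v = partition_v.module_sizes()
    for i in range(conf.n_ij.shape[0]):
        attrs = {"layer": "H", "size": int(sizes_h[i])}
        if zero_h is not None:
            attrs["only_zero_degree"] = bool(zero_h[i])
        g.add_node(f"H{i}", **attrs)
    for j in range(conf.n_ij.shape[1]):
        attrs = {"layer": "V", "size": int(sizes_v[j])}
        if zero_v is not None:
            attrs["only_zero_degree"] = bool(zero_v[j])
        g.add_node(f"V{j}", **attrs)
    ii, jj = np.nonzero(conf.n_ij)
    for i, j in zip(ii, jj):
        g.add_edge(f"H{i}", f"V{j}", weight=int(conf.n_ij[i, j]))

    if path is not None:
        path = Path(path)
        nx.write_graphml(g, path)
        with open(path.with_suffix(".tsv"), "w") as fh:
            fh.write("module_h\tmodule_v\tshared_species\n")
            for i, j in zip(ii, jj):
                fh.write(f"H{i}\tV{j}\t{conf.n_ij[i, j]}\n")
    return g
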