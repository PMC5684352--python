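"""Seeded generators of paired bipartite layers for testing and benchmarking.

``planted_pair`` draws two layers from a k-block stochastic bipartite block
model with tunable between-layer congruence of the block assignments and an
optional fraction of rows silenced (all-zero) in the second layer — mimicking
sparse empirical two-layer networks where many species interact in only one
layer.  ``degree_matched_pair`` realizes prescribed degree sequences exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .module_detection import Partition, canonical_membership
from .net_model_io import BipartiteLayer, MultilayerPair
from .null_model import curveball_randomize

__all__ = ["PlantedPair", "planted_pair", "degree_matched_pair"]


@dataclass(frozen=True)
class PlantedPair:
    pair: MultilayerPair
    planted1: Partition
    planted2: Partition


def _block_assignment(n: int, k: int) -> np.ndarray:
    """Blocks as equal as possible; the remainder goes to the first blocks."""
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return np.repeat(np.arange(k), sizes)


def _planted_partition(
    labels: tuple[str, ...], blocks: np.ndarray, incidence_degrees: np.ndarray
) -> Partition:
    """Planted block labels, with zero-degree nodes pulled into singletons."""
    mem = blocks.copy().astype(np.int64)
    nxt = mem.max() + 1
    for v in np.flatnonzero(incidence_degrees == 0):
        mem[v] = nxt
        nxt += 1
    return Partition(labels, canonical_membership(labels, mem))


def planted_pair(
    n_rows: int = 60,
    n_cols: int = 60,
    k_modules: int = 4,
    p_in: float = 0.4,
    p_out: float = 0.02,
    congruence: float = 0.9,
    zero_frac_rows_l2: float = 0.0,
    seed: int | np.random.Generator | None = None,
    layer_names: tuple[str, str] = ("layer1", "layer2"),
) -> PlantedPair:
    """Draw an aligned two-layer pair with planted, partially congruent modules.

    Layer 1 comes from a k-block bipartite stochastic block model: a link
    appears with probability ``p_in`` when row and column share a block and
    ``p_out`` otherwise.  For layer 2 each species keeps its block with
    probability ``congruence`` and is reassigned uniformly at random
    otherwise; a fraction ``zero_frac_rows_l2`` of rows is then zeroed in
    layer 2, emulating species active in only one layer.

    Returns the pair plus both planted partitions (over all m+p nodes of each
    layer; species left with no links are singleton modules, matching the
    convention of the module detector).
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if k_modules < 1 or k_modules > min(n_rows, n_cols):
        raise ValueError("k_modules must be in [1, min(n_rows, n_cols)]")
    if not 0 <= congruence <= 1 or not 0 <= zero_frac_rows_l2 <= 1:
        raise ValueError("congruence and zero_frac_rows_l2 must be in [0, 1]")
    rng = np.random.default_rng(seed)

    rows = tuple(f"r{i:04d}" for i in range(n_rows))
    cols = tuple(f"c{j:04d}" for j in range(n_cols))
    row_b1 = _block_assignment(n_rows, k_modules)
    col_b1 = _block_assignment(n_cols, k_modules)

    def redraw(blocks: np.ndarray) -> np.ndarray:
        keep = rng.random(len(blocks)) < congruence
        out = blocks.copy()
        out[~keep] = rng.integers(0, k_modules, size=(~keep).sum())
        return out

    row_b2 = redraw(row_b1)
    col_b2 = redraw(col_b1)

    def sample(row_b: np.ndarray, col_b: np.ndarray) -> np.ndarray:
        same = row_b[:, None] == col_b[None, :]
        prob = np.where(same, p_in, p_out)
        return (rng.random((len(row_b), len(col_b))) < prob).astype(np.int8)

    inc1 = sample(row_b1, col_b1)
    inc2 = sample(row_b2, col_b2)
    if zero_frac_rows_l2 > 0:
        n_zero = int(round(zero_frac_rows_l2 * n_rows))
        silenced = rng.choice(n_rows, size=n_zero, replace=False)
        inc2[silenced, :] = 0

    layer1 = BipartiteLayer(layer_names[0], rows, cols, inc1)
    layer2 = BipartiteLayer(layer_names[1], rows, cols, inc2)
    pair = MultilayerPair(layer1, layer2)
    labels = rows + cols
    planted1 = _planted_partition(
        labels, np.concatenate([row_b1, col_b1]),
        np.concatenate([inc1.sum(axis=1), inc1.sum(axis=0)]),
    )
    planted2 = _planted_partition(
        labels, np.concatenate([row_b2, col_b2]),
        np.concatenate([inc2.sum(axis=1), inc2.sum(axis=0)]),
    )
    return PlantedPair(pair, planted1, planted2)


def _gale_ryser_ok(row_deg: np.ndarray, col_deg: np.ndarray) -> bool:
    """Gale-Ryser condition for a binary matrix with the given margins."""
    r = np.sort(row_deg)[::-1]
    c = np.asarray(col_deg)
    if r.sum() != c.sum():
        return False
    for k in range(1, len(r) + 1):
        if r[:k].sum() > np.minimum(c, k).sum():
            return False
    return True


def _realize_bipartite(row_deg: np.ndarray, col_deg: np.ndarray) -> np.ndarray:
    """Constructive fill (Havel-Hakimi style): greedily satisfy the largest row."""
    m, p = len(row_deg), len(col_deg)
    inc = np.zeros((m, p), dtype=np.int8)
    remaining_col = col_deg.astype(np.int64).copy()
    for i in np.argsort(-row_deg, kind="stable"):
        d = int(row_deg[i])
        if d == 0:
            continue
        targets = np.argsort(-remaining_col, kind="stable")[:d]
        if remaining_col[targets[-1]] <= 0:
            raise ValueError("sequences not realizable (Gale-Ryser violated)")
        inc[i, targets] = 1
        remaining_col[targets] -= 1
    return inc


def degree_matched_pair(
    row_degrees_1,
    col_degrees_1,
    row_degrees_2,
    col_degrees_2,
    seed: int | np.random.Generator | None = None,
    layer_names: tuple[str, str] = ("layer1", "layer2"),
    shuffle: bool = True,
) -> MultilayerPair:
    """Build a pair whose layers realize the given degree sequences exactly.

    Each layer is constructed deterministically, then (by default) uniformized
    with curveball shuffles so repeated calls with different seeds explore the
    fixed-margin ensemble.  Sequences must satisfy the Gale-Ryser condition.
    """
    rng = np.random.default_rng(seed)
    seqs = [
        (np.asarray(row_degrees_1, dtype=np.int64), np.asarray(col_degrees_1, dtype=np.int64)),
        (np.asarray(row_degrees_2, dtype=np.int64), np.asarray(col_degrees_2, dtype=np.int64)),
    ]
    if len(seqs[0][0]) != len(seqs[1][0]) or len(seqs[0][1]) != len(seqs[1][1]):
        raise ValueError("both layers must have the same numbers of rows and columns")
    rows = tuple(f"r{i:04d}" for i in range(len(seqs[0][0])))
    cols = tuple(f"c{j:04d}" for j in range(len(seqs[0][1])))
    layers = []
    for name, (rd, cd) in zip(layer_names, seqs):
        if rd.sum() != cd.sum():
            raise ValueError(
                f"layer {name!r}: row degree sum {rd.sum()} != column degree sum {cd.sum()}"
            )
        if (rd < 0).any() or (cd < 0).any() or (rd > len(cd)).any() or (cd > len(rd)).any():
            raise ValueError(f"layer {name!r}: degree out of range")
        if not _gale_ryser_ok(rd, cd):
            raise ValueError(f"layer {name!r}: sequences fail the Gale-Ryser condition")
        layer = BipartiteLayer(name, rows, cols, _realize_bipartite(rd, cd))
        if shuffle and layer.incidence.sum() > 0:
            layer = curveball_randomize(layer, rng=rng)
        layers.append(layer)
    return MultilayerPair(*layers)
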