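"""Curveball randomization: degree-preserving shuffles of an incidence matrix.

A single trade picks two rows, keeps the column partners they share, and
randomly re-splits the union of their exclusive partners between them while
preserving each row's partner count.  Repeated trades sample (asymptotically
uniformly) from the ensemble of binary matrices with both margins fixed — the
configuration-model null for a bipartite network.
"""

from __future__ import annotations

import numpy as np

from .net_model_io import BipartiteLayer

__all__ = ["curveball_trade", "curveball_randomize", "default_n_trades", "rowsets_from_layer"]


def rowsets_from_layer(layer: BipartiteLayer) -> list[set[int]]:
    """Per-row sets of column partner indices."""
    return [set(np.flatnonzero(row).tolist()) for row in layer.incidence]


def curveball_trade(
    rowsets: list[set[int]],
    i: int,
    j: int,
    rng: np.random.Generator,
) -> list[set[int]]:
    """One curveball trade between rows i and j, in place.

    Shared partners never move; the exclusive partners of the two rows are
    pooled, shuffled, and re-dealt so each row keeps its original set size.
    Rows with no exclusive partners make the trade a no-op.
    """
    if i == j:
        raise ValueError("trade requires two distinct rows")
    si, sj = rowsets[i], rowsets[j]
    shared = si & sj
    only_i = sorted(si - shared)
    only_j = sorted(sj - shared)
    if not only_i or not only_j:
        return rowsets
    pool = np.array(only_i + only_j)
    pool = pool[rng.permutation(len(pool))]
    rowsets[i] = shared | set(pool[: len(only_i)].tolist())
    rowsets[j] = shared | set(pool[len(only_i):].tolist())
    return rowsets


def default_n_trades(layer: BipartiteLayer) -> int:
    """Mixing default: five trades per row of the traded guild."""
    return 5 * layer.shape[0]


def curveball_randomize(
    layer: BipartiteLayer,
    n_trades: int | None = None,
    rng: int | np.random.Generator | None = None,
) -> BipartiteLayer:
    """Randomize a layer under fixed row and column sums.

    Trades act on rows (the same fixed-margin ensemble is sampled whichever
    guild is traded).  Zero-degree rows and columns are preserved as zero.
    Deterministic for a fixed (layer, n_trades, seed).
    """
    if n_trades is None:
        n_trades = default_n_trades(layer)
    if n_trades < 1:
        raise ValueError("n_trades must be >= 1")
    rng = np.random.default_rng(rng)
    m = layer.shape[0]
    rowsets = rowsets_from_layer(layer)
    if m >= 2:
        for _ in range(n_trades):
            i, j = rng.choice(m, size=2, replace=False)
            curveball_trade(rowsets, int(i), int(j), rng)
    inc = np.zeros(layer.shape, dtype=np.int8)
    for r, partners in enumerate(rowsets):
        if partners:
            inc[r, sorted(partners)] = 1
    return BipartiteLayer(layer.name, layer.rows, layer.cols, inc)
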