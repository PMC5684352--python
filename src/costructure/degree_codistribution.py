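"""Paired-degree contingency analysis across two layers.

For one guild (say the shared plants), each species has a degree u in layer 1
and a degree w in layer 2.  The contingency table K[u, w] counts species per
degree combination; under independence of the two layers the expected count is
n * p_u * p_w from the table margins.  A Pearson chi-square test quantifies
the overall association and per-cell Pearson residuals identify over- and
under-represented degree combinations, exportable as a mosaic-plot table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .net_model_io import BipartiteLayer, MultilayerPair

__all__ = [
    "DegreeCoTable",
    "CoDistributionResult",
    "degrees",
    "co_table",
    "independence_test",
    "shading_code",
    "mosaic_export",
    "mosaic_plot",
]

Guild = Literal["rows", "cols"]

#: |residual| thresholds for the two shading tiers (approx. alpha = 0.05, 0.0001)
SHADING_MODERATE = 2.0
SHADING_STRONG = 4.0


def degrees(layer: BipartiteLayer, guild: Guild) -> pd.Series:
    """Degree of every species of one guild, zero-degree species included."""
    if guild == "rows":
        return pd.Series(layer.row_degrees(), index=list(layer.rows), name=layer.name)
    if guild == "cols":
        return pd.Series(layer.col_degrees(), index=list(layer.cols), name=layer.name)
    raise ValueError(f"guild must be 'rows' or 'cols', got {guild!r}")


@dataclass(frozen=True)
class DegreeCoTable:
    """Contingency table K[u, w] of paired degrees for one guild."""

    guild: Guild
    u_levels: tuple[int, ...]  # degrees attained in layer1
    w_levels: tuple[int, ...]  # degrees attained in layer2
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.u_levels), len(self.w_levels)):
            raise ValueError("counts shape does not match level lists")
        if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
            raise ValueError("empty degree level in the table")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def margin_u(self) -> np.ndarray:
        """Empirical degree probabilities p_u in layer 1 (row margin / n)."""
        return self.counts.sum(axis=1) / self.n

    def margin_w(self) -> np.ndarray:
        return self.counts.sum(axis=0) / self.n


def co_table(pair: MultilayerPair, guild: Guild) -> DegreeCoTable:
    """Tabulate the joint degree distribution of one guild across the two layers.

    Species with no interaction in either layer count in the (0, 0) cell;
    only degree values attained by at least one species become table levels.
    """
    d1 = degrees(pair.layer1, guild).to_numpy()
    d2 = degrees(pair.layer2, guild).to_numpy()
    u_levels, u_idx = np.unique(d1, return_inverse=True)
    w_levels, w_idx = np.unique(d2, return_inverse=True)
    counts = np.zeros((len(u_levels), len(w_levels)), dtype=np.int64)
    np.add.at(counts, (u_idx, w_idx), 1)
    return DegreeCoTable(
        guild=guild,
        u_levels=tuple(int(u) for u in u_levels),
        w_levels=tuple(int(w) for w in w_levels),
        counts=counts,
    )


@dataclass(frozen=True)
class CoDistributionResult:
    table: DegreeCoTable
    expected: np.ndarray = field(repr=False)
    chi2: float
    df: int
    p_value: float
    p_method: str
    residuals: np.ndarray = field(repr=False)

    def shading(self) -> np.ndarray:
        """Per-cell shading codes derived from the Pearson residuals."""
        return np.vectorize(shading_code)(self.residuals)

    def to_dict(self) -> dict:
        r = self.residuals
        return {
            "guild": self.table.guild,
            "n_species": self.table.n,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "p_method": self.p_method,
            "residual_min": float(r.min()),
            "residual_max": float(r.max()),
            "n_cells": int(r.size),
        }


def shading_code(residual: float) -> str:
    """Map a Pearson residual to a mosaic shading tier.

    |r| >= 4 marks the stricter tier (approx. alpha = 0.0001), 2 <= |r| < 4
    the moderate tier (approx. alpha = 0.05); the sign says whether the degree
    combination is over- or under-represented.
    """
    if residual >= SHADING_STRONG:
        return "strong-positive"
    if residual >= SHADING_MODERATE:
        return "positive"
    if residual <= -SHADING_STRONG:
        return "strong-negative"
    if residual <= -SHADING_MODERATE:
        return "negative"
    return "neutral"


def independence_test(
    table: DegreeCoTable,
    p_method: Literal["asymptotic", "simulate"] = "asymptotic",
    n_sim: int = 1999,
    seed: int | None = None,
) -> CoDistributionResult:
    """Pearson chi-square test of independence of the two degree margins.

    Expected counts are n * p_u * p_w from the observed margins; the statistic
    is the plain Pearson chi-square (no continuity correction) with
    df = (levels_u - 1)(levels_w - 1).  ``p_method="simulate"`` replaces the
    asymptotic p-value by a Monte-Carlo one over tables drawn with both
    margins fixed (Patefield sampling), recommended for the sparse tables that
    raw degree levels typically produce.
    """
    counts = table.counts
    n = table.n
    if n < 1:
        raise ValueError("empty table")
    expected = np.outer(table.margin_u(), table.margin_w()) * n
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    if df == 0 and p_method == "asymptotic":
        raise ValueError(
            "degenerate table (a single degree level on one side): the "
            "asymptotic chi-square is undefined; use p_method='simulate' "
            "or report the table descriptively"
        )
    residuals = (counts - expected) / np.sqrt(expected)
    chi2 = float((residuals**2).sum())

    if p_method == "asymptotic":
        if (expected < 5).mean() > 0.2:
            warnings.warn(
                "more than 20% of expected cell counts are below 5; the "
                "asymptotic chi-square p-value is unreliable, consider "
                "p_method='simulate'",
                stacklevel=2,
            )
        p_value = float(stats.chi2.sf(chi2, df))
    elif p_method == "simulate":
        rng = np.random.default_rng(seed)
        sampler = stats.random_table(counts.sum(axis=1), counts.sum(axis=0))
        sims = sampler.rvs(n_sim, random_state=rng)
        sim_chi2 = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
        p_value = (1.0 + float((sim_chi2 >= chi2 - 1e-9).sum())) / (n_sim + 1.0)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")

    return CoDistributionResult(
        table=table,
        expected=expected,
        chi2=chi2,
        df=df,
        p_value=p_value,
        p_method=p_method,
        residuals=residuals,
    )


def result_frame(result: CoDistributionResult) -> pd.DataFrame:
    """Long-format mosaic table: one row per (u, w) cell."""
    t = result.table
    uu, ww = np.meshgrid(t.u_levels, t.w_levels, indexing="ij")
    return pd.DataFrame(
        {
            "u": uu.ravel(),
            "w": ww.ravel(),
            "count": t.counts.ravel(),
            "expected": result.expected.ravel(),
            "residual": result.residuals.ravel(),
            "shading": result.shading().ravel(),
            "zero_count": t.counts.ravel() == 0,
        }
    )


def mosaic_export(result: CoDistributionResult, path: str | Path) -> pd.DataFrame:
    """Write the long-format mosaic table as TSV and a JSON sidecar of the test."""
    frame = result_frame(result)
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    return frame


_SHADE_COLORS = {
    "strong-positive": "#08519c",
    "positive": "#9ecae1",
    "neutral": "#d9d9d9",
    "negative": "#fcae91",
    "strong-negative": "#a50f15",
}


def mosaic_plot(result: CoDistributionResult, path: str | Path) -> None:
    """Render a simple mosaic: column widths by u-margin, heights by w | u.

    Cells are coloured by residual shading tier; zero-count cells get a bullet.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    t = result.table
    n = t.n
    gap = 0.004
    fig, ax = plt.subplots(figsize=(8, 8))
    x = 0.0
    shades = result.shading()
    for i, u in enumerate(t.u_levels):
        width = t.counts[i].sum() / n
        y = 0.0
        col_total = t.counts[i].sum()
        for j, w in enumerate(t.w_levels):
            height = t.counts[i, j] / col_total if col_total else 0.0
            ax.add_patch(
                Rectangle(
                    (x + gap, y + gap),
                    max(width - 2 * gap, 0),
                    max(height - 2 * gap, 0),
                    facecolor=_SHADE_COLORS[shades[i, j]],
                    edgecolor="black",
                    linewidth=0.3,
                )
            )
            if t.counts[i, j] == 0:
                ax.plot(x + width / 2, y + 1e-3, marker=".", color="black", ms=2)
            y += height
        x += width
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel(f"degree in layer 1 ({t.guild})")
    ax.set_ylabel("degree in layer 2 (conditional)")
    ax.set_title(
        f"degree co-distribution, chi2={result.chi2:.1f}, df={result.df}"
    )
    fig.savefig(path, dpi=150)
    plt.close(fig)
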