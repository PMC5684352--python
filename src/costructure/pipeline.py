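"""End-to-end co-structure analysis of a two-layer bipartite network pair.

The headline test asks whether the module composition of the two layers is
more (or less) similar than expected from networks with the same species and
the same degree sequences: the observed normalized mutual information I of the
two module classifications is compared against I recomputed on replicate pairs
in which both layers were independently curveball-randomized and re-clustered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import degree_codistribution as dc
from .module_detection import Partition, detect_modules, write_partition
from .module_similarity import confusion, costructure_graph, nmi, nmi_partitions
from .net_model_io import (
    MultilayerPair,
    layer_summary,
    read_edge_list,
    read_incidence,
)
from .null_model import curveball_randomize, default_n_trades

__all__ = ["NullDistributionSummary", "nmi_null_test", "AnalysisConfig", "run_full_analysis"]

logger = logging.getLogger("costructure")


@dataclass(frozen=True)
class NullDistributionSummary:
    """Observed NMI against its configuration-model null distribution.

    Empirical p-values use the add-one permutation convention
    p = (1 + #{extreme}) / (1 + n_replicates); ties count as extreme in both
    tails, so p_ge + p_le >= 1 + 1/(n+1).
    """

    i_observed: float
    i_null: tuple[float, ...] = field(repr=False)
    seed: int | None

    @property
    def n_replicates(self) -> int:
        return len(self.i_null)

    def quantiles(self) -> dict[str, float]:
        arr = np.asarray(self.i_null)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        return {
            "min": float(arr.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(arr.max()),
        }

    @property
    def p_ge(self) -> float:
        """Is module similarity HIGHER than the degree-constrained expectation?"""
        arr = np.asarray(self.i_null)
        return (1.0 + float((arr >= self.i_observed).sum())) / (self.n_replicates + 1.0)

    @property
    def p_le(self) -> float:
        arr = np.asarray(self.i_null)
        return (1.0 + float((arr <= self.i_observed).sum())) / (self.n_replicates + 1.0)

    @property
    def p_two(self) -> float:
        return min(1.0, 2.0 * min(self.p_ge, self.p_le))

    def to_dict(self) -> dict:
        return {
            "i_observed": self.i_observed,
            "n_replicates": self.n_replicates,
            **{f"null_{k}": v for k, v in self.quantiles().items()},
            "p_ge": self.p_ge,
            "p_le": self.p_le,
            "p_two": self.p_two,
            "seed": self.seed,
        }


def nmi_null_test(
    pair: MultilayerPair,
    n_replicates: int = 999,
    n_trades: int | None = None,
    seed: int | None = None,
    tol: float = 1e-10,
    fine_tune: bool = False,
    partitions: tuple[Partition, Partition] | None = None,
) -> NullDistributionSummary:
    """Test the observed module-composition NMI against the curveball null.

    Per replicate, BOTH layers are independently degree-preservingly
    randomized, modules are re-detected on each randomized layer with the same
    options as the observed run, and I is recomputed over the full node set.
    Pre-computed observed partitions can be passed to avoid re-detection.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if partitions is None:
        partitions = (
            detect_modules(pair.layer1, tol=tol, fine_tune=fine_tune),
            detect_modules(pair.layer2, tol=tol, fine_tune=fine_tune),
        )
    i_obs = nmi_partitions(*partitions)

    trades = (default_n_trades(pair.layer1), default_n_trades(pair.layer2))
    if n_trades is not None:
        trades = (n_trades, n_trades)
    ss = np.random.SeedSequence(seed)
    i_null = []
    for r, child in enumerate(ss.spawn(n_replicates)):
        rng1, rng2 = (np.random.default_rng(s) for s in child.spawn(2))
        try:
            r1 = curveball_randomize(pair.layer1, n_trades=trades[0], rng=rng1)
            r2 = curveball_randomize(pair.layer2, n_trades=trades[1], rng=rng2)
            assert (r1.row_degrees() == pair.layer1.row_degrees()).all()
            assert (r1.col_degrees() == pair.layer1.col_degrees()).all()
            assert (r2.row_degrees() == pair.layer2.row_degrees()).all()
            assert (r2.col_degrees() == pair.layer2.col_degrees()).all()
            p1 = detect_modules(r1, tol=tol, fine_tune=fine_tune)
            p2 = detect_modules(r2, tol=tol, fine_tune=fine_tune)
        except Exception:
            logger.error("null replicate %d failed", r)
            raise
        i_null.append(nmi_partitions(p1, p2))
    return NullDistributionSummary(
        i_observed=i_obs, i_null=tuple(i_null), seed=seed
    )


@dataclass
class AnalysisConfig:
    """Configuration of a full co-structure run.

    Exactly one of ``edges`` or ``incidence`` must point at input files; all
    randomness flows from ``seed``.
    """

    edges: str | None = None
    incidence: tuple[str, str] | None = None
    layer_names: tuple[str, str] = ("layer1", "layer2")
    guilds: tuple[str, ...] = ("cols", "rows")
    p_method: str = "asymptotic"
    n_replicates: int = 999
    n_trades: int | None = None
    seed: int = 0
    tol: float = 1e-10
    fine_tune: bool = False
    restrict_interacting: bool = False
    mosaic_png: bool = False
    outdir: str = "costructure_out"
    normalize_labels: bool = False

    def validate(self) -> None:
        problems = []
        if (self.edges is None) == (self.incidence is None):
            problems.append("exactly one of 'edges' or 'incidence' must be set")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        if self.n_trades is not None and self.n_trades < 1:
            problems.append("n_trades must be >= 1")
        if self.p_method not in ("asymptotic", "simulate"):
            problems.append(f"unknown p_method {self.p_method!r}")
        for g in self.guilds:
            if g not in ("rows", "cols"):
                problems.append(f"unknown guild {g!r}")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))


def _restricted(partition: Partition, keep: set[str]) -> Partition:
    labels = tuple(l for l in partition.node_labels if l in keep)
    idx = [i for i, l in enumerate(partition.node_labels) if l in keep]
    from .module_detection import canonical_membership

    mem = canonical_membership(labels, partition.membership[idx])
    return Partition(labels, mem)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole analysis and write a reproducible report bundle.

    Outputs under ``config.outdir``: report.json, degrees_<guild>.tsv,
    mosaic_<guild>.tsv(+json), modules_<layer>.tsv(+json),
    module_graph.graphml(+tsv), null_i.tsv and run.log.  Identical configs
    (including the seed) produce byte-identical report.json.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config: %s", json.dumps(asdict(config), default=list, sort_keys=True))
        if config.edges is not None:
            pair = read_edge_list(
                config.edges, tuple(config.layer_names),
                normalize_labels=config.normalize_labels,
            )
        else:
            pair = read_incidence(
                *config.incidence, layer_names=tuple(config.layer_names),
                normalize_labels=config.normalize_labels,
            )
        report: dict = {"config": asdict(config)}
        report["layers"] = {
            layer.name: asdict(layer_summary(layer))
            for layer in (pair.layer1, pair.layer2)
        }

        # degree co-distribution per guild
        report["degree_codistribution"] = {}
        for guild in config.guilds:
            table = dc.co_table(pair, guild)
            res = dc.independence_test(
                table, p_method=config.p_method, seed=config.seed
            )
            dc.mosaic_export(res, outdir / f"mosaic_{guild}.tsv")
            if config.mosaic_png:
                dc.mosaic_plot(res, outdir / f"mosaic_{guild}.png")
            d1 = dc.degrees(pair.layer1, guild)
            d2 = dc.degrees(pair.layer2, guild)
            with open(outdir / f"degrees_{guild}.tsv", "w") as fh:
                fh.write(f"species\tdegree_{pair.layer1.name}\tdegree_{pair.layer2.name}\n")
                for s in d1.index:
                    fh.write(f"{s}\t{d1[s]}\t{d2[s]}\n")
            report["degree_codistribution"][guild] = res.to_dict()
            logger.info("guild %s: chi2=%.4f df=%d p=%.3g", guild, res.chi2, res.df, res.p_value)

        # module detection per layer
        parts = []
        for layer in (pair.layer1, pair.layer2):
            part = detect_modules(layer, tol=config.tol, fine_tune=config.fine_tune)
            write_partition(part, outdir / f"modules_{layer.name}.tsv")
            sizes = part.module_sizes()
            report.setdefault("modules", {})[layer.name] = {
                "n_modules": part.n_modules,
                "n_multispecies_modules": int((sizes > 1).sum()),
                "n_singletons": int((sizes == 1).sum()),
                "q": part.q,
            }
            parts.append(part)
            logger.info("layer %s: %d modules, Q=%.4f", layer.name, part.n_modules, part.q)
        part1, part2 = parts

        if config.restrict_interacting:
            interacting = {
                s for s, d in dc.degrees(pair.layer1, "rows").items() if d > 0
            } | {s for s, d in dc.degrees(pair.layer1, "cols").items() if d > 0}
            interacting &= {
                s for s, d in dc.degrees(pair.layer2, "rows").items() if d > 0
            } | {s for s, d in dc.degrees(pair.layer2, "cols").items() if d > 0}
            part1_use = _restricted(part1, interacting)
            part2_use = _restricted(part2, interacting)
        else:
            part1_use, part2_use = part1, part2

        conf = confusion(part1_use, part2_use)
        costructure_graph(part1_use, part2_use, outdir / "module_graph.graphml", pair=pair if not config.restrict_interacting else None)
        report["module_similarity"] = {
            "i_observed": nmi(conf),
            "m_h": int(conf.n_ij.shape[0]),
            "m_v": int(conf.n_ij.shape[1]),
            "n_species": conf.total,
        }

        null = nmi_null_test(
            pair,
            n_replicates=config.n_replicates,
            n_trades=config.n_trades,
            seed=config.seed,
            tol=config.tol,
            fine_tune=config.fine_tune,
            partitions=(part1, part2) if not config.restrict_interacting else None,
        )
        with open(outdir / "null_i.tsv", "w") as fh:
            fh.write("replicate\ti_null\n")
            for r, v in enumerate(null.i_null):
                fh.write(f"{r}\t{v:.12g}\n")
        report["null_test"] = null.to_dict()
        logger.info(
            "null test: I=%.4f, p_ge=%.3f, p_le=%.3f", null.i_observed, null.p_ge, null.p_le
        )

        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=list)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
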