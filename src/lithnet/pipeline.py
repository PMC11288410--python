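"""End-to-end orchestration: classify, bin, network, test, bootstrap.

``run_pipeline`` chains the stages — typology -> calibration/binning ->
similarity -> per-bin networks and metrics -> small-world test ->
bootstrap — and writes every table the analysis reports on, plus the
graphs, a structured log and a manifest echoing all settings and seeds
so a rerun with the same manifest reproduces all outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chrono, io, netmetrics, sampling, similarity, smallworld, typology
from .chrono import make_bins

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of the pipeline, with the study's default settings."""

    assemblages: str = ""
    dates: str = ""
    curve: str = ""
    outdir: str = "lithnet_out"

    bin_oldest: int = 8600
    bin_youngest: int = 6801
    bin_width: int = 200
    mass_threshold: float = 0.35
    restrict_two_sigma: bool = True
    combine_dates: str = "any"
    sd_cutoff: float = 100.0

    per_bin_min_count: int | None = None  # per-bin type-frequency filter, off by default
    normalise: bool = True

    leiden_resolution: float = 0.02
    leiden_iterations: int = 1000
    leiden_restarts: int = 100

    null_replicates: int = 1000
    bootstrap_replicates: int = 1000
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline produced."""

    config: RunConfig
    inventory: pd.DataFrame
    dated_contexts: list
    assemblages: dict[str, similarity.BinAssemblage]
    matrices: dict[str, similarity.SimilarityMatrix]
    networks: dict
    metrics: pd.DataFrame
    ntr: pd.DataFrame
    smallworld: pd.DataFrame
    bootstrap: pd.DataFrame
    outdir: Path = field(default=None)


def _metrics_table(per_bin: dict[str, netmetrics.NetworkMetrics]) -> pd.DataFrame:
    """Wide table, one column per bin, mirroring the study's layout."""
    rows = ["n_nodes", "n_edges", "density", "clustering_coefficient", "apl",
            "leiden_n_clusters", "leiden_quality", "filter"]
    data = {}
    for label, m in per_bin.items():
        data[label] = [
            m.n_nodes, m.n_edges, round(m.density, 3), round(m.clustering_global, 3),
            round(m.apl, 3) if np.isfinite(m.apl) else float("nan"),
            m.n_communities, round(m.leiden_quality, 3) if np.isfinite(m.leiden_quality) else float("nan"),
            "NO" if not m.edge_filter_applied else "YES",
        ]
    return pd.DataFrame(data, index=rows)


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute every stage and (optionally) write the output bundle."""
    outdir = Path(config.outdir)
    handler = None
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logging.getLogger("lithnet").addHandler(handler)

    try:
        # -- typology ----------------------------------------------------
        records = io.read_assemblage_csv(config.assemblages)
        inventory = typology.build_type_inventory(records)
        kept_inventory, kept_records = typology.filter_shared_types(inventory, records)
        logger.info(
            "typology: %d records in %d types; %d records in %d shared types kept",
            len(records), len(inventory), len(kept_records), len(kept_inventory),
        )

        # -- chronology --------------------------------------------------
        curve = chrono.read_curve(config.curve)
        dates = chrono.filter_dates(io.read_dates_csv(config.dates), config.sd_cutoff)
        bins = make_bins(config.bin_oldest, config.bin_youngest, config.bin_width)
        by_context: dict[tuple[str, str], list] = {}
        for d in dates:
            by_context.setdefault(d.context, []).append(d)
        dated_contexts = []
        for ctx, ds in sorted(by_context.items()):
            dd = [(d, chrono.calibrate(d, curve)) for d in ds]
            dated_contexts.append(
                chrono.assign_bins(
                    ctx, dd, bins,
                    threshold=config.mass_threshold,
                    restrict_two_sigma=config.restrict_two_sigma,
                    combine=config.combine_dates,
                )
            )
        members: dict[str, list[tuple[str, str]]] = {b.label: [] for b in bins}
        for dc in dated_contexts:
            for label in dc.bin_memberships:
                members[label].append(dc.context)

        # -- similarity --------------------------------------------------
        assemblages = {}
        J_by_bin = {}
        n_types = {}
        for b in bins:
            asm = similarity.build_bin_assemblage(
                b.label, members[b.label], kept_records,
                per_bin_min_count=config.per_bin_min_count,
            )
            if len(asm.freq) < 2:
                logger.warning("bin %s: fewer than two contexts; skipped", b.label)
                continue
            assemblages[b.label] = asm
            J_by_bin[b.label] = similarity.jaccard_matrix(asm.binary)
            n_types[b.label] = asm.n_types
        matrices = similarity.normalise_across_bins(J_by_bin, n_types, enabled=config.normalise)

        # -- networks, metrics, small world, bootstrap -------------------
        networks = {}
        per_bin_metrics = {}
        sw_rows = []
        boot_frames = []
        for label, sim in matrices.items():
            G = netmetrics.build_network(sim.J_norm, label)
            networks[label] = G
            m = netmetrics.network_metrics(
                G,
                resolution=config.leiden_resolution,
                iterations=config.leiden_iterations,
                restarts=config.leiden_restarts,
                seed=config.seed,
            )
            per_bin_metrics[label] = m
            sw = smallworld.small_world_test(
                G, replicates=config.null_replicates, seed=config.seed
            )
            sw_rows.append(
                {
                    "bin": label,
                    "observed_cc": sw.observed_cc,
                    "mean_null_cc": sw.mean_null_cc,
                    "observed_apl": sw.observed_apl,
                    "mean_null_apl": sw.mean_null_apl,
                    "sigma": sw.sigma,
                    "verdict": sw.verdict,
                }
            )
            report = sampling.bootstrap_bin(
                assemblages[label],
                replicates=config.bootstrap_replicates,
                seed=config.seed,
            )
            boot_frames.append(report.to_frame())
            if write:
                netdir = outdir / "networks"
                netdir.mkdir(exist_ok=True)
                part = netmetrics.leiden_cpm(
                    G, config.leiden_resolution, config.leiden_iterations,
                    config.leiden_restarts, config.seed,
                )
                io.export_graph(
                    G, netdir / label,
                    node_attrs={
                        "community": part.membership,
                        "betweenness": m.betweenness,
                        "eigenvector": m.eigenvector,
                    },
                )

        metrics = _metrics_table(per_bin_metrics)
        node_sets = [(label, set(G.nodes)) for label, G in networks.items()]
        ntr_table = netmetrics.ntr(node_sets) if len(node_sets) >= 2 else pd.DataFrame()
        sw_table = pd.DataFrame(sw_rows)
        boot_table = pd.concat(boot_frames, ignore_index=True) if boot_frames else pd.DataFrame()
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        if handler is not None:
            handler.close()
            logging.getLogger("lithnet").removeHandler(handler)

    result = PipelineResult(
        config=config,
        inventory=inventory,
        dated_contexts=dated_contexts,
        assemblages=assemblages,
        matrices=matrices,
        networks=networks,
        metrics=metrics,
        ntr=ntr_table,
        smallworld=sw_table,
        bootstrap=boot_table,
        outdir=outdir if write else None,
    )
    if write:
        io.write_type_inventory(inventory, outdir / "type_inventory.csv")
        io.write_bin_membership(dated_contexts, outdir / "bin_membership.csv")
        io.write_similarity_long(matrices, outdir / "similarity_long.csv")
        metrics.to_csv(outdir / "metrics.csv")
        ntr_table.to_csv(outdir / "ntr.csv", index=False)
        sw_table.to_csv(outdir / "smallworld.csv", index=False)
        boot_table.to_csv(outdir / "bootstrap.csv", index=False)
        manifest = {"lithnet_version": __version__, "config": config.to_dict()}
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        logger.info("outputs written to %s", outdir)
    return result
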