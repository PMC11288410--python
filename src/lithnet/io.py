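"""CSV ingest and emit helpers for the pipeline's tabular interfaces."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .chrono import DatedContext, RadiocarbonDate
from .typology import MicrolithRecord, VocabularyError, encode_type

__all__ = [
    "read_assemblage_csv",
    "read_dates_csv",
    "write_type_inventory",
    "write_bin_membership",
    "write_similarity_long",
    "export_graph",
]

ASSEMBLAGE_COLUMNS = [
    "site_id", "level_id", "shape", "symmetry", "edge_form",
    "retouch_mode", "retouch_direction",
]
DATE_COLUMNS = ["lab_code", "site_id", "level_id", "c14_age", "sigma", "material_class"]


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_assemblage_csv(path: str | Path) -> list[MicrolithRecord]:
    """Read one-artefact-per-row assemblage CSV into records.

    Trait codes are validated at ingest; an out-of-vocabulary code
    raises naming the row and dimension.  ``source_note`` is optional.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    _require(df, ASSEMBLAGE_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        traits = (row.shape, row.symmetry, row.edge_form,
                  row.retouch_mode, row.retouch_direction)
        try:
            encode_type(traits, row=i)
        except VocabularyError:
            raise
        records.append(
            MicrolithRecord(row.site_id, row.level_id, traits,
                            getattr(row, "source_note", ""))
        )
    return records


def read_dates_csv(path: str | Path) -> list[RadiocarbonDate]:
    """Read one-date-per-row radiocarbon CSV into date objects."""
    df = pd.read_csv(path)
    _require(df, DATE_COLUMNS, path)
    dates = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            dates.append(
                RadiocarbonDate(
                    str(row.lab_code), str(row.site_id), str(row.level_id),
                    float(row.c14_age), float(row.sigma), str(row.material_class),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return dates


def write_type_inventory(inventory: pd.DataFrame, path: str | Path) -> None:
    inventory.to_csv(path, index=False)


def write_bin_membership(contexts: Iterable[DatedContext], path: str | Path) -> None:
    """Per-context bin memberships, semicolon-separated labels."""
    rows = [
        {"site_id": c.site_id, "level_id": c.level_id,
         "bins": ";".join(c.bin_memberships)}
        for c in contexts
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_similarity_long(
    matrices: Mapping[str, "object"], path: str | Path
) -> None:
    """Long-format pairwise similarities over all bins.

    ``matrices`` maps bin label -> SimilarityMatrix; emits one row per
    unordered context pair with raw and normalised Jaccard.
    """
    rows = []
    for label, sim in matrices.items():
        J, Jn = sim.J, sim.J_norm
        ctxs = list(J.index)
        for a in range(len(ctxs)):
            for b in range(a + 1, len(ctxs)):
                rows.append(
                    {
                        "bin": label,
                        "context_a": ctxs[a],
                        "context_b": ctxs[b],
                        "jaccard": J.iloc[a, b],
                        "jaccard_norm": Jn.iloc[a, b],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def export_graph(
    G: nx.Graph,
    basepath: str | Path,
    node_attrs: Mapping[str, Mapping] | None = None,
) -> tuple[Path, Path]:
    """Write a bin network as GraphML and GEXF with node attributes.

    ``node_attrs`` maps attribute name -> {node: value} (community,
    betweenness, eigenvector, ...).  Site and level are derived from the
    ``site|level`` node labels.
    """
    H = G.copy()
    for v in H:
        site, _, level = str(v).partition("|")
        H.nodes[v]["site"] = site
        H.nodes[v]["level"] = level
    if node_attrs:
        for name, mapping in node_attrs.items():
            nx.set_node_attributes(H, {k: _plain(v) for k, v in mapping.items()}, name)
    basepath = Path(basepath)
    graphml = basepath.with_suffix(".graphml")
    gexf = basepath.with_suffix(".gexf")
    nx.write_graphml(H, graphml)
    nx.write_gexf(H, gexf)
    return graphml, gexf


def _plain(v):
    """Coerce numpy scalars to built-ins for the XML graph writers."""
    try:
        return v.item()
    except AttributeError:
        return v
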