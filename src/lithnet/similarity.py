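"""Per-bin assemblage tables and normalised Jaccard similarity.

Each time bin collects the artefact records of the contexts assigned to
it into a contexts x types contingency table.  Counts are then binarised
to presence/absence — frequency differences between contexts reflect
excavation extent, preservation and site function as much as culture —
and pairwise similarity is the Jaccard index on type sets:

    J(a, b) = |T_a intersect T_b| / |T_a union T_b|

Because the number of types in circulation differs strongly between
bins, raw Jaccard values are not comparable across bins: a bin with few
types yields high similarity by chance.  The matrices are therefore
rescaled to the most type-diverse bin, multiplying each bin's matrix by
n_types(bin) / max_b n_types(b).  The scaling is strictly monotone, so
within-bin structure is untouched; the scale factor is carried in the
output for transparency, and can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .typology import MicrolithRecord

__all__ = [
    "BinAssemblage",
    "SimilarityMatrix",
    "build_bin_assemblage",
    "jaccard_matrix",
    "normalise_across_bins",
    "context_label",
]


def context_label(context: tuple[str, str]) -> str:
    """Stable node label for a (site, level) context."""
    return f"{context[0]}|{context[1]}"


@dataclass
class BinAssemblage:
    """Contexts x types count and presence/absence tables for one bin."""

    bin_label: str
    freq: pd.DataFrame  # index: context labels, columns: type codes, values: counts

    @property
    def binary(self) -> pd.DataFrame:
        return (self.freq >= 1).astype(int)

    @property
    def contexts(self) -> list[str]:
        return list(self.freq.index)

    @property
    def n_types(self) -> int:
        return int((self.freq.sum(axis=0) >= 1).sum())

    @property
    def n_sample(self) -> int:
        return int(self.freq.to_numpy().sum())


def build_bin_assemblage(
    bin_label: str,
    contexts: Sequence[tuple[str, str]],
    records: Sequence[MicrolithRecord],
    per_bin_min_count: int | None = None,
) -> BinAssemblage:
    """Build the contingency table for one bin.

    ``contexts`` are the (site, level) pairs assigned to the bin; their
    records are cross-tabulated against observed type codes.  Levels of
    the same site stay separate rows, so a site's own diachrony is
    preserved.  Rows with no records are dropped.  ``per_bin_min_count``
    optionally re-applies a frequency filter within the bin (types whose
    total bin count is below it are removed); by default only the global
    shared-type filter applied upstream is in force.
    """
    wanted = set(contexts)
    rows = [
        (context_label(r.context), r.type_code) for r in records if r.context in wanted
    ]
    if not rows:
        return BinAssemblage(bin_label, pd.DataFrame())
    df = pd.DataFrame(rows, columns=["context", "type_code"])
    freq = pd.crosstab(df["context"], df["type_code"])
    freq = freq.loc[freq.sum(axis=1) > 0]
    if per_bin_min_count is not None:
        freq = freq.loc[:, freq.sum(axis=0) >= per_bin_min_count]
        freq = freq.loc[freq.sum(axis=1) > 0]
    freq.index.name = "context"
    freq.columns.name = "type_code"
    return BinAssemblage(bin_label, freq)


def jaccard_matrix(binary: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard similarity between the rows of a 0/1 table.

    Diagonal is 1; a pair whose type sets are both empty has an empty
    union and is defined to be 0.
    """
    if len(binary) < 2:
        raise ValueError("need at least two contexts for a similarity matrix")
    b = (binary.to_numpy() >= 1).astype(int)
    inter = b @ b.T
    sizes = b.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(jac, 1.0)
    return pd.DataFrame(jac, index=binary.index, columns=binary.index)


@dataclass
class SimilarityMatrix:
    """Raw and cross-bin-normalised Jaccard matrices for one bin."""

    bin_label: str
    J: pd.DataFrame
    scale_factor: float = 1.0

    @property
    def J_norm(self) -> pd.DataFrame:
        return self.J * self.scale_factor


def normalise_across_bins(
    J_by_bin: Mapping[str, pd.DataFrame],
    n_types_by_bin: Mapping[str, int],
    enabled: bool = True,
) -> dict[str, SimilarityMatrix]:
    """Rescale each bin's Jaccard matrix by its relative type diversity.

    ``scale_factor(bin) = n_types(bin) / max_b n_types(b)``; the most
    diverse bin(s) are unchanged.  With ``enabled=False`` all factors
    are 1 (sensitivity mode).
    """
    if not J_by_bin:
        return {}
    for label in J_by_bin:
        if n_types_by_bin.get(label, 0) < 1:
            raise ValueError(f"bin {label}: no types present")
    max_types = max(n_types_by_bin[label] for label in J_by_bin)
    out = {}
    for label, J in J_by_bin.items():
        factor = n_types_by_bin[label] / max_types if enabled else 1.0
        out[label] = SimilarityMatrix(label, J, factor)
    return out
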