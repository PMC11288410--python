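"""Paradigmatic classification of geometric microliths.

A paradigmatic typology treats an artefact type as the unordered
cross-product of independent trait dimensions, with no hierarchy among
the traits: every observed combination of trait states is a type.  For
geometric microliths (trapeze/triangle/segment projectile inserts) the
five dimensions are shape, symmetry, edge form, retouch mode and retouch
direction, spanning a paradigm of 3 * 2 * 6 * 3 * 5 = 540 cells, of
which only observed combinations become types.

Because the downstream similarity analysis is about *shared* culture,
types observed exactly once in the whole dataset carry no information
about contact between contexts and are filtered out
(:func:`filter_shared_types`).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TRAIT_DIMENSIONS",
    "PARADIGM_SIZE",
    "SEPARATOR",
    "VocabularyError",
    "MicrolithRecord",
    "encode_type",
    "decode_type",
    "iter_paradigm",
    "build_type_inventory",
    "filter_shared_types",
]

#: Ordered trait dimensions and their closed code vocabularies.
TRAIT_DIMENSIONS: dict[str, tuple[str, ...]] = {
    "shape": ("Tra", "Tri", "Seg"),
    "symmetry": ("S", "As"),
    "edge_form": ("R", "Cc", "Cv", "RCc", "RCv", "CcCv"),
    "retouch_mode": ("A", "S", "AS"),
    "retouch_direction": ("D", "Al", "B", "Db", "I"),
}

#: Number of cells in the full paradigmatic space.
PARADIGM_SIZE = 540

#: Separator used in composite type codes.
SEPARATOR = "-"



class VocabularyError(ValueError):
    """An artefact record uses a code outside the closed trait vocabulary."""


@dataclass(frozen=True)
class MicrolithRecord:
    """One artefact: its context link and its five categorical traits.

    ``traits`` is an ordered 5-tuple following :data:`TRAIT_DIMENSIONS`
    order (shape, symmetry, edge_form, retouch_mode, retouch_direction).
    """

    site_id: str
    level_id: str
    traits: tuple[str, str, str, str, str]
    source_note: str = field(default="", compare=False)

    @property
    def context(self) -> tuple[str, str]:
        return (self.site_id, self.level_id)

    @property
    def type_code(self) -> str:
        return encode_type(self.traits)


def _validate(traits: Sequence[str], row: int | None = None) -> None:
    where = "" if row is None else f" (row {row})"
    if len(traits) != len(TRAIT_DIMENSIONS):
        raise VocabularyError(
            f"expected {len(TRAIT_DIMENSIONS)} trait values, got {len(traits)}{where}"
        )
    for value, (dim, vocab) in zip(traits, TRAIT_DIMENSIONS.items()):
        if value not in vocab:
            raise VocabularyError(f"unknown {dim} code {value!r}{where}")


def encode_type(traits: Sequence[str], row: int | None = None) -> str:
    """Encode a trait 5-tuple into its composite type code.

    The code is the order-fixed, hyphen-joined concatenation of the
    trait states, e.g. ``('Tra', 'As', 'RCc', 'A', 'D')`` ->
    ``'Tra-As-RCc-A-D'``.  Codes are case-sensitive and the vocabulary
    is closed: any out-of-vocabulary state raises
    :class:`VocabularyError` naming the offending dimension (and the
    input row, if given).
    """
    _validate(traits, row)
    return SEPARATOR.join(traits)


def decode_type(type_code: str) -> tuple[str, str, str, str, str]:
    """Invert :func:`encode_type`; round-trip is the identity."""
    parts = tuple(type_code.split(SEPARATOR))
    _validate(parts)
    return parts  # type: ignore[return-value]


def iter_paradigm() -> Iterable[tuple[str, str, str, str, str]]:
    """Iterate over all 540 cells of the paradigmatic space."""
    return itertools.product(*TRAIT_DIMENSIONS.values())


def build_type_inventory(records: Sequence[MicrolithRecord]) -> pd.DataFrame:
    """Count each distinct observed type over the whole dataset.

    Returns a DataFrame with columns ``type_code``, ``count`` and
    ``shared`` (``count > 1``), sorted by descending count then code.
    Counts conserve the record total.
    """
    if len(records) == 0:
        raise ValueError("cannot build a type inventory from zero records")
    counts = Counter(r.type_code for r in records)
    inv = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["type_code", "count"],
    )
    inv["shared"] = inv["count"] > 1
    return inv


def filter_shared_types(
    inventory: pd.DataFrame, records: Sequence[MicrolithRecord]
) -> tuple[pd.DataFrame, list[MicrolithRecord]]:
    """Keep only types observed more than once, and their records.

    Contexts whose records are all globally-singleton types drop out of
    all downstream matrices as a consequence.  Applying the filter twice
    is the same as applying it once.
    """
    kept_inventory = inventory.loc[inventory["shared"]].reset_index(drop=True)
    shared_codes = set(kept_inventory["type_code"])
    kept_records = [r for r in records if r.type_code in shared_codes]
    return kept_inventory, kept_records
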