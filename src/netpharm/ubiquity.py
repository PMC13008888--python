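"""Ubiquity flagging of natural products against a reference compound.

A phytochemical found in many plant species says little about the distinct
effect of any one plant, so compounds whose occurrence count (number of
species in a natural-product occurrence database) reaches that of a chosen
reference compound are flagged ubiquitous and deprioritized. The canonical
reference is quinic acid — a shikimate-pathway precursor present in
essentially all plants — but the reference count is always an input, never
a built-in constant, since it depends on the database snapshot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

DEFAULT_REFERENCE = "quinic acid"


class MissingReferenceError(KeyError):
    pass


@dataclass
class UbiquityTable:
    """compound_id → occurrence count, plus the reference compound id.

    ``counts`` may contain None/NaN for compounds the databases did not
    resolve; those are flagged ``unknown`` and retained downstream rather
    than silently dropped.
    """

    counts: dict[str, int | None]
    reference_compound_id: str = DEFAULT_REFERENCE

    def reference_count(self) -> int:
        count = self.counts.get(self.reference_compound_id)
        if count is None or pd.isna(count):
            raise MissingReferenceError(
                f"reference compound {self.reference_compound_id!r} has no "
                "occurrence count"
            )
        if count <= 0:
            raise MissingReferenceError(
                f"reference compound count must be positive, got {count}"
            )
        return int(count)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, reference_compound_id: str = DEFAULT_REFERENCE
    ) -> "UbiquityTable":
        counts = {
            str(r["compound_id"]): (None if pd.isna(r["occurrence_count"]) else int(r["occurrence_count"]))
            for _, r in frame.iterrows()
        }
        return cls(counts=counts, reference_compound_id=reference_compound_id)


def flag_ubiquitous(table: UbiquityTable) -> dict[str, str]:
    """Flag each compound: ubiquitous iff count ≥ reference count,
    non_ubiquitous otherwise, unknown when the count is missing."""
    ref = table.reference_count()
    flags: dict[str, str] = {}
    unknown = 0
    for cid, count in table.counts.items():
        if count is None or pd.isna(count):
            flags[cid] = "unknown"
            unknown += 1
        elif int(count) >= ref:
            flags[cid] = "ubiquitous"
        else:
            flags[cid] = "non_ubiquitous"
    if unknown:
        warnings.warn(
            f"{unknown} compounds have no occurrence count; flagged unknown and "
            "retained",
            stacklevel=2,
        )
    return flags


def rank_by_occurrence(table: UbiquityTable) -> list[str]:
    """Compound ids ordered by descending occurrence count; ties broken
    alphabetically; compounds without a count sort last (also alphabetical)."""
    known = [(cid, c) for cid, c in table.counts.items() if c is not None and not pd.isna(c)]
    unknown = sorted(cid for cid, c in table.counts.items() if c is None or pd.isna(c))
    ranked = sorted(known, key=lambda kv: (-int(kv[1]), kv[0]))
    return [cid for cid, _ in ranked] + unknown
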