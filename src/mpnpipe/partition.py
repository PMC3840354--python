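"""Sequential read-class partitioning: rRNA > sRNA > protein > unassigned.

Each read in a library is placed in exactly one class by precedence: any
qualifying rRNA hit makes it an rRNA read regardless of other matches, then
sRNA, then protein (hits against either the protein/taxonomy catalog or the
KEGG catalog count as protein evidence).  Reads whose hits all fall below
the bit-score threshold, and reads that never appear in any hit table, are
unassigned.  The default threshold of 50 bits is applied inclusively
(``>=``); the comparison operator is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .catalog import LibraryManifest

__all__ = ["READ_CLASSES", "PartitionError", "PartitionResult", "partition"]

#: Assignment precedence order (first match wins), then the fallback class.
READ_CLASSES = ("rRNA", "sRNA", "protein", "unassigned")

#: Which hit-table catalogs provide evidence for each read class.
_CLASS_CATALOGS = {"rRNA": ("rRNA",), "sRNA": ("sRNA",), "protein": ("protein", "kegg")}


class PartitionError(ValueError):
    pass


@dataclass
class PartitionResult:
    """Per-library read classification and class counts."""

    library_id: str
    class_of_read: dict[str, str]
    n_total: int
    n_rRNA: int
    n_sRNA: int
    n_protein: int
    n_unassigned: int

    def counts(self) -> dict[str, int]:
        return {
            "rRNA": self.n_rRNA,
            "sRNA": self.n_sRNA,
            "protein": self.n_protein,
            "unassigned": self.n_unassigned,
        }

    def reads_in_class(self, cls: str) -> set[str]:
        return {r for r, c in self.class_of_read.items() if c == cls}

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "library_id": self.library_id,
                "read_class": list(READ_CLASSES),
                "count": [self.n_rRNA, self.n_sRNA, self.n_protein, self.n_unassigned],
            }
        )


def _qualifying_reads(hits: pd.DataFrame, threshold: float, inclusive: bool) -> set[str]:
    if hits is None or hits.empty:
        return set()
    mask = hits["bit_score"] >= threshold if inclusive else hits["bit_score"] > threshold
    return set(hits.loc[mask, "read_id"])


def partition(
    hits_by_catalog: Mapping[str, pd.DataFrame],
    manifest: LibraryManifest,
    threshold: float = 50.0,
    inclusive: bool = True,
) -> PartitionResult:
    """Classify every read of a library into exactly one class.

    Parameters
    ----------
    hits_by_catalog
        Map of catalog name ("rRNA", "sRNA", "protein", "kegg") to slim hit
        DataFrame; missing catalogs are treated as empty.
    manifest
        Library metadata; ``manifest.total_reads`` fixes the library size so
        reads absent from every hit table are counted as unassigned.
    threshold
        Bit-score significance gate (default 50).
    inclusive
        If True (default) a hit qualifies at ``bit_score >= threshold``,
        otherwise strictly above.
    """
    if threshold <= 0:
        raise PartitionError("threshold must be positive")

    seen: set[str] = set()
    for df in hits_by_catalog.values():
        if df is not None and not df.empty:
            seen.update(df["read_id"])
    if len(seen) > manifest.total_reads:
        raise PartitionError(
            f"library {manifest.library_id!r}: {len(seen)} distinct reads in hit "
            f"tables exceed manifest total_reads={manifest.total_reads}"
        )

    assigned: dict[str, str] = {}
    for cls in ("rRNA", "sRNA", "protein"):
        qualifying: set[str] = set()
        for cat in _CLASS_CATALOGS[cls]:
            qualifying |= _qualifying_reads(hits_by_catalog.get(cat), threshold, inclusive)
        for read in qualifying:
            assigned.setdefault(read, cls)

    class_of_read = {r: assigned.get(r, "unassigned") for r in seen}
    n_r = sum(1 for c in class_of_read.values() if c == "rRNA")
    n_s = sum(1 for c in class_of_read.values() if c == "sRNA")
    n_p = sum(1 for c in class_of_read.values() if c == "protein")
    n_u = manifest.total_reads - n_r - n_s - n_p
    return PartitionResult(
        library_id=manifest.library_id,
        class_of_read=class_of_read,
        n_total=manifest.total_reads,
        n_rRNA=n_r,
        n_sRNA=n_s,
        n_protein=n_p,
        n_unassigned=n_u,
    )
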