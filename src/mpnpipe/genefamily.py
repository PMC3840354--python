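"""recA-normalized gene-family abundance and taxonomic attribution.

The headline metagenomic statistic: for a gene family *f* with reference
protein length L_f and qualifying hit count c_f, and the single-copy
reference gene (recA by default, L = 353 aa for the E. coli protein),

    percent_of_bacteria(f) = 100 * (c_f / L_f) / (c_ref / L_ref)

interpreting the length-normalized count relative to recA as the percent of
genomes that carry the family, on the assumption that recA is present
exactly once per genome.  The reference family normalizes itself to 100 by
construction in every library with at least one reference hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog

__all__ = [
    "DEFAULT_RECA_LENGTH",
    "FamilyAbundance",
    "family_abundance",
    "family_group_mean",
    "attribute_families",
    "family_table",
]

#: Length (aa) assumed for the recA reference when a catalog does not
#: provide one; overridable wherever it is consumed.
DEFAULT_RECA_LENGTH = 353


@dataclass
class FamilyAbundance:
    library_id: str
    family: str
    raw_count: int
    query_length: int
    percent_of_bacteria: float

    @property
    def length_normalized(self) -> float:
        return self.raw_count / self.query_length


class ReferenceFamilyError(ValueError):
    """The reference family has no qualifying hits; the statistic is undefined."""


def _family_lengths(catalog: Catalog, families: Sequence[str]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for fam in families:
        entries = [e for e in catalog.by_family(fam) if e.protein_length]
        if not entries:
            raise ValueError(f"family {fam!r} has no catalog entry with a protein length")
        lengths[fam] = int(median(e.protein_length for e in entries))
    return lengths


def _best_hit_family_counts(
    hits: pd.DataFrame,
    catalog: Catalog,
    threshold: float,
    min_identity: float | None,
) -> pd.Series:
    """Per-family read counts, attributing each read to its single
    best-scoring family (cross-family score ties go to the alphabetically
    first family so the count is deterministic; same-family ties are moot)."""
    q = hits[hits["bit_score"] >= threshold]
    if min_identity is not None:
        q = q[q["percent_identity"] >= min_identity]
    if q.empty:
        return pd.Series(dtype=int)
    fam_of_subject = catalog.subject_column("family")
    q = q.assign(family=q["subject_id"].map(fam_of_subject)).dropna(subset=["family"])
    if q.empty:
        return pd.Series(dtype=int)
    top = q.groupby("read_id", sort=False)["bit_score"].transform("max")
    q = q[q["bit_score"] == top]
    fam_per_read = q.sort_values("family").groupby("read_id", sort=False)["family"].first()
    return fam_per_read.value_counts()


def family_abundance(
    hits: pd.DataFrame,
    catalog: Catalog,
    families: Sequence[str],
    reference_family: str = "recA",
    threshold: float = 50.0,
    min_identity: float | None = None,
    library_id: str = "",
    reference_length: int | None = None,
) -> dict[str, FamilyAbundance]:
    """Length-normalized family abundances as percent of bacteria.

    Returns one :class:`FamilyAbundance` per requested family plus the
    reference family itself (always exactly 100).  ``min_identity`` adds a
    percent-identity gate (e.g. 95 for assigning reads to near-identical
    recovered clusters).  Raises :class:`ReferenceFamilyError` when the
    reference has no qualifying hit.
    """
    wanted = list(dict.fromkeys([*families, reference_family]))
    lengths = _family_lengths(catalog, [f for f in wanted if catalog.by_family(f)])
    for fam in wanted:
        if fam not in lengths:
            raise ValueError(f"family {fam!r} is not in the catalog")
    if reference_length is not None:
        lengths[reference_family] = reference_length

    counts = _best_hit_family_counts(hits, catalog, threshold, min_identity)
    ref_count = int(counts.get(reference_family, 0))
    if ref_count == 0:
        raise ReferenceFamilyError(
            f"library {library_id!r}: no qualifying {reference_family!r} hits; "
            "percent-of-bacteria is undefined"
        )
    ref_rate = ref_count / lengths[reference_family]

    out: dict[str, FamilyAbundance] = {}
    for fam in wanted:
        c = int(counts.get(fam, 0))
        pct = 100.0 * (c / lengths[fam]) / ref_rate
        out[fam] = FamilyAbundance(
            library_id=library_id,
            family=fam,
            raw_count=c,
            query_length=lengths[fam],
            percent_of_bacteria=pct,
        )
    return out


def family_group_mean(
    abundances: Mapping[str, FamilyAbundance] | Mapping[str, float],
    group: Sequence[str],
) -> float:
    """Unweighted arithmetic mean of percent-of-bacteria over ``group``."""
    if not group:
        raise ValueError("empty family group")
    vals = []
    for fam in group:
        if fam not in abundances:
            raise KeyError(f"family {fam!r} missing from abundances")
        v = abundances[fam]
        vals.append(v.percent_of_bacteria if isinstance(v, FamilyAbundance) else float(v))
    return float(np.mean(vals))


def attribute_families(
    hits: pd.DataFrame,
    catalog: Catalog,
    family_group: Sequence[str],
    threshold: float = 50.0,
    min_identity: float | None = None,
    rank: str = "order",
) -> dict[str, float]:
    """Taxonomic attribution of a family group's hits (percent of hits).

    Each qualifying read is attributed via its single top-scoring hit's
    taxon, aggregated to ``rank``; reads whose top hits tie across taxa go
    to an explicit ``"ambiguous"`` bucket rather than being assigned
    arbitrarily.
    """
    q = hits[hits["bit_score"] >= threshold]
    if min_identity is not None:
        q = q[q["percent_identity"] >= min_identity]
    fam_of_subject = catalog.subject_column("family")
    q = q.assign(family=q["subject_id"].map(fam_of_subject))
    q = q[q["family"].isin(set(family_group))]
    if q.empty:
        return {}
    top = q.groupby("read_id", sort=False)["bit_score"].transform("max")
    q = q[q["bit_score"] == top]
    taxon_of_subject = catalog.subject_column("taxon_id")
    q = q.assign(taxon_id=q["subject_id"].map(taxon_of_subject))
    rank_of_taxon = {e.taxon_id: e.rank_name(rank) for e in catalog.entries.values()}
    per_read = q.groupby("read_id", sort=False)["taxon_id"].agg(["nunique", "first"])
    labels = per_read["first"].map(rank_of_taxon).where(per_read["nunique"] == 1, "ambiguous")
    counts = labels.value_counts()
    total = int(counts.sum())
    return {str(k): 100.0 * int(v) / total for k, v in counts.items()}


def family_table(
    per_library: Mapping[str, Mapping[str, FamilyAbundance]],
    families: Sequence[str],
) -> pd.DataFrame:
    """Families x libraries table of percent-of-bacteria, rounded to
    integers for reporting."""
    data = {
        lib: [round(ab[f].percent_of_bacteria) if f in ab else 0 for f in families]
        for lib, ab in per_library.items()
    }
    return pd.DataFrame(data, index=list(families))
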