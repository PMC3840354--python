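"""Best-hit taxonomic profiling of uniquely assignable reads.

A read's taxon is decided by its top-bit-score hit(s): if every tied top hit
points to the same taxon id the read counts for that taxon (ties among
genes of one organism do not disqualify it); if the top hits span several
taxon ids the read is excluded as ambiguous and counted, never silently
dropped.  Abundance is reported as percent of assigned reads.  Assignment
always happens at the taxon-id level; the requested lineage rank only
controls aggregation for reporting, so a species-level profile aggregated
to order level equals profiling at order level directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import Catalog, LINEAGE_RANKS

__all__ = ["TaxonProfile", "profile_taxa", "binned_abundance"]


@dataclass
class TaxonProfile:
    """Per-library taxonomic abundance at one lineage rank (percent)."""

    library_id: str
    rank: str
    abundance: dict[str, float]
    n_assigned: int
    n_ambiguous_excluded: int
    mean_identity: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        taxa = sorted(self.abundance)
        return pd.DataFrame(
            {
                "library_id": self.library_id,
                "rank": self.rank,
                "taxon": taxa,
                "percent": [self.abundance[t] for t in taxa],
                "mean_identity": [self.mean_identity.get(t, np.nan) for t in taxa],
            }
        )


def _top_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Rows achieving the per-read maximum bit score (exact float equality;
    BLAST reports scores at fixed precision so no epsilon is applied)."""
    top = hits.groupby("read_id", sort=False)["bit_score"].transform("max")
    return hits[hits["bit_score"] == top]


def profile_taxa(
    protein_hits: pd.DataFrame,
    catalog: Catalog,
    rank: str = "order",
    threshold: float = 50.0,
    library_id: str = "",
    restrict_reads: set[str] | None = None,
) -> TaxonProfile:
    """Build a taxonomic abundance profile from one library's hits.

    Works identically for protein/taxonomy hits and for rRNA hits (the rRNA
    profile is the same operation applied to the rRNA partition).

    Parameters
    ----------
    protein_hits
        Slim hit DataFrame (already or not yet threshold-filtered).
    catalog
        Reference catalog resolving ``subject_id`` to taxon and lineage.
    rank
        Reporting rank from :data:`~mpnpipe.catalog.LINEAGE_RANKS`.
    threshold
        Bit-score gate applied before top-hit selection.
    restrict_reads
        Optional read-id whitelist (e.g. the protein class of a partition).
    """
    if rank not in LINEAGE_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {LINEAGE_RANKS}")

    hits = protein_hits[protein_hits["bit_score"] >= threshold]
    if restrict_reads is not None:
        hits = hits[hits["read_id"].isin(restrict_reads)]
    if hits.empty:
        return TaxonProfile(library_id, rank, {}, 0, 0)

    unknown = set(hits["subject_id"]) - set(catalog.entries)
    if unknown:
        some = sorted(unknown)[:5]
        raise KeyError(f"hits reference subjects missing from catalog: {some}")

    top = _top_hits(hits)
    taxon_of_subject = catalog.subject_column("taxon_id")
    top = top.assign(taxon_id=top["subject_id"].map(taxon_of_subject))

    per_read = top.groupby("read_id", sort=False)["taxon_id"].agg(["nunique", "first"])
    unique_mask = per_read["nunique"] == 1
    n_ambiguous = int((~unique_mask).sum())
    assigned = per_read.loc[unique_mask, "first"]
    n_assigned = int(len(assigned))
    if n_assigned == 0:
        return TaxonProfile(library_id, rank, {}, 0, n_ambiguous)

    rank_of_taxon = {
        e.taxon_id: e.rank_name(rank) for e in catalog.entries.values()
    }
    groups = assigned.map(rank_of_taxon)
    counts = groups.value_counts()
    abundance = {t: 100.0 * c / n_assigned for t, c in counts.items()}

    # mean percent identity of the counting reads' top hits, per group
    top_assigned = top[top["read_id"].isin(assigned.index)]
    top_assigned = top_assigned.assign(group=top_assigned["taxon_id"].map(rank_of_taxon))
    mean_id = top_assigned.groupby("group")["percent_identity"].mean().to_dict()

    return TaxonProfile(
        library_id=library_id,
        rank=rank,
        abundance=abundance,
        n_assigned=n_assigned,
        n_ambiguous_excluded=n_ambiguous,
        mean_identity={k: float(v) for k, v in mean_id.items()},
    )


def binned_abundance(profile: TaxonProfile, min_report_fraction: float) -> dict[str, float]:
    """Reporting view: taxa below ``min_report_fraction`` percent are pooled
    into an ``"other"`` bin (mirrors >1% / >3% reporting cutoffs)."""
    out: dict[str, float] = {}
    other = 0.0
    for taxon, pct in profile.abundance.items():
        if pct > min_report_fraction:
            out[taxon] = pct
        else:
            other += pct
    if other > 0:
        out["other"] = other
    return out
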