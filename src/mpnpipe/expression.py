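"""Per-gene RNA/DNA expression ratios for genes on recovered clusters.

For gene *g* with RNA count r_g (out of R total non-rRNA non-sRNA reads)
and DNA count d_g (out of D total gDNA reads),

    ratio(g) = (r_g / R) / (d_g / D)

Counts include only hits passing both the bit-score gate (default 50) and
the percent-identity gate (default 95, appropriate for assigning short
reads to near-identical recovered sequences).  A read matching two genes
counts once, for its best-scoring gene.  Genes with zero DNA counts have an
explicitly undefined ratio and never enter group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog

__all__ = [
    "CP_LYASE_FAMILIES",
    "ExpressionRatio",
    "GroupComparison",
    "expression_ratios",
    "group_ratio_comparison",
]

#: Families counted as C-P lyase cluster genes for grouped comparisons
#: (the phn operon components plus the phnP-analogous rcsF phosphoesterase).
CP_LYASE_FAMILIES = frozenset(
    {
        "phnC", "phnD", "phnE", "phnF", "phnG", "phnH", "phnI", "phnJ",
        "phnK", "phnL", "phnM", "phnN", "phnO", "phnP", "rcsF",
    }
)


@dataclass
class ExpressionRatio:
    gene_id: str
    group: str                  # "cp_lyase" or "other"
    rna_count: int
    dna_count: int
    rna_total: int
    dna_total: int

    @property
    def defined(self) -> bool:
        return self.dna_count > 0

    @property
    def ratio(self) -> float:
        if not self.defined:
            return float("nan")
        return (self.rna_count / self.rna_total) / (self.dna_count / self.dna_total)


def _best_gene_counts(
    hits: pd.DataFrame,
    gene_ids: set[str],
    score_threshold: float,
    id_threshold: float,
) -> pd.Series:
    q = hits[
        (hits["bit_score"] >= score_threshold)
        & (hits["percent_identity"] >= id_threshold)
        & hits["subject_id"].isin(gene_ids)
    ]
    if q.empty:
        return pd.Series(dtype=int)
    top = q.groupby("read_id", sort=False)["bit_score"].transform("max")
    q = q[q["bit_score"] == top]
    gene_per_read = q.sort_values("subject_id").groupby("read_id", sort=False)["subject_id"].first()
    return gene_per_read.value_counts()


def expression_ratios(
    fosmid_hits_rna: pd.DataFrame,
    fosmid_hits_dna: pd.DataFrame,
    gene_table: Catalog,
    rna_total: int,
    dna_total: int,
    id_threshold: float = 95.0,
    score_threshold: float = 50.0,
    cp_families: frozenset[str] = CP_LYASE_FAMILIES,
) -> list[ExpressionRatio]:
    """Per-gene RNA/DNA expression ratios.

    ``rna_total`` is the library's non-rRNA non-sRNA read total and
    ``dna_total`` the gDNA library total; both must be positive.  Genes are
    grouped into ``cp_lyase`` vs ``other`` by their catalog family tag.
    """
    if rna_total <= 0 or dna_total <= 0:
        raise ValueError("library totals must be positive")
    gene_ids = set(gene_table.entries)
    rna_counts = _best_gene_counts(fosmid_hits_rna, gene_ids, score_threshold, id_threshold)
    dna_counts = _best_gene_counts(fosmid_hits_dna, gene_ids, score_threshold, id_threshold)
    out = []
    for gene_id in sorted(gene_ids):
        fam = gene_table.entry(gene_id).family
        out.append(
            ExpressionRatio(
                gene_id=gene_id,
                group="cp_lyase" if fam in cp_families else "other",
                rna_count=int(rna_counts.get(gene_id, 0)),
                dna_count=int(dna_counts.get(gene_id, 0)),
                rna_total=rna_total,
                dna_total=dna_total,
            )
        )
    return out


@dataclass
class GroupComparison:
    mean_ratio: dict[str, float]
    median_ratio: dict[str, float]
    n_defined: dict[str, int]
    n_undefined: dict[str, int]
    fold: float                      # mean(cp_lyase) / mean(other)


def group_ratio_comparison(ratios: Sequence[ExpressionRatio]) -> GroupComparison:
    """Arithmetic mean (and median, for robustness) of defined ratios per
    group, and the cp_lyase / other fold between the means."""
    groups: dict[str, list[float]] = {"cp_lyase": [], "other": []}
    undefined: dict[str, int] = {"cp_lyase": 0, "other": 0}
    for r in ratios:
        if r.defined:
            groups[r.group].append(r.ratio)
        else:
            undefined[r.group] += 1
    for g, vals in groups.items():
        if not vals:
            raise ValueError(f"group {g!r} has no gene with a defined ratio")
    mean_ratio = {g: float(np.mean(v)) for g, v in groups.items()}
    median_ratio = {g: float(np.median(v)) for g, v in groups.items()}
    return GroupComparison(
        mean_ratio=mean_ratio,
        median_ratio=median_ratio,
        n_defined={g: len(v) for g, v in groups.items()},
        n_undefined=undefined,
        fold=mean_ratio["cp_lyase"] / mean_ratio["other"],
    )


def ratios_frame(ratios: Sequence[ExpressionRatio]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in ratios],
            "group": [r.group for r in ratios],
            "rna_count": [r.rna_count for r in ratios],
            "dna_count": [r.dna_count for r in ratios],
            "rna_total": [r.rna_total for r in ratios],
            "dna_total": [r.dna_total for r in ratios],
            "ratio": [r.ratio for r in ratios],
            "defined": [r.defined for r in ratios],
        }
    )
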