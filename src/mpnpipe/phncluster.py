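"""Rule-based annotation of C-P lyase (phn) gene clusters.

Canonical role assignment for the phosphonate-utilization operon:
phnC/phnD/phnE form the phosphonate ABC transporter; phnG through phnM are
the catalytic core required for C-P bond cleavage; phnF is regulatory;
phnN, phnO, phnP and the phnP-analogous phosphoesterase rcsF are
accessory.  Genes outside the known nomenclature are carried with the
``novel`` role.  Substrate-growth predictions are a pure function of gene
content, and substrates for which no cluster-intrinsic genetic rule is
known are reported ``indeterminate`` rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ROLES",
    "SUBSTRATES",
    "PhnCluster",
    "CompletenessReport",
    "assess_completeness",
    "predict_substrates",
]

ROLES = ("transporter", "catalytic_core", "regulatory", "accessory", "novel")

#: Substrate panel columns for growth predictions.
SUBSTRATES = (
    "no_P", "MPn", "AMPn", "2AEPn", "1AEPn", "EPn", "PnAc",
    "PnAla", "3PnP", "3APPn", "HPt", "Pt", "Pi",
)

_ROLE_OF = {
    "phnC": "transporter", "phnD": "transporter", "phnE": "transporter",
    "phnG": "catalytic_core", "phnH": "catalytic_core", "phnI": "catalytic_core",
    "phnJ": "catalytic_core", "phnK": "catalytic_core", "phnL": "catalytic_core",
    "phnM": "catalytic_core",
    "phnF": "regulatory",
    "phnN": "accessory", "phnO": "accessory", "phnP": "accessory", "rcsF": "accessory",
}

CATALYTIC_CORE = ("phnG", "phnH", "phnI", "phnJ", "phnK", "phnL", "phnM")
TRANSPORTER = ("phnC", "phnD", "phnE")

#: Substrates whose use follows from a catalytically complete, PRcP-capable
#: cluster (the cyclic-phosphate product must be hydrolyzable by phnP or
#: its rcsF analog).
_CORE_SUBSTRATES = ("MPn", "EPn", "2AEPn", "3PnP", "3APPn")
#: 1-aminoalkylphosphonates additionally require the phnO N-acetyltransferase.
_PHNO_SUBSTRATES = ("AMPn", "1AEPn")

# canonical casing for known names plus cluster-specific synonyms
_CANONICAL = {name.lower(): name for name in _ROLE_OF}
_CANONICAL.update({"rcsf": "rcsF", "phnm1": "phnM1", "phne2": "phnE2"})


def normalize_gene_name(name: str) -> str:
    """Case-insensitive normalization against the phn nomenclature."""
    return _CANONICAL.get(name.strip().lower(), name.strip())


@dataclass(frozen=True)
class PhnCluster:
    """A C-P lyase gene cluster as an ordered (gene, role) list."""

    cluster_id: str
    genes: tuple[tuple[str, str], ...]   # (name, role)

    @classmethod
    def from_genes(
        cls, cluster_id: str, names: Iterable[str], allow_novel: bool = True
    ) -> "PhnCluster":
        genes = []
        for raw in names:
            name = normalize_gene_name(raw)
            role = _ROLE_OF.get(name)
            if role is None:
                if not allow_novel:
                    raise ValueError(
                        f"cluster {cluster_id!r}: unrecognized gene {raw!r} "
                        "(pass allow_novel=True to keep it with role 'novel')"
                    )
                role = "novel"
            genes.append((name, role))
        return cls(cluster_id=cluster_id, genes=tuple(genes))

    def gene_names(self) -> set[str]:
        return {name for name, _ in self.genes}

    def has(self, gene: str) -> bool:
        return normalize_gene_name(gene) in self.gene_names()


@dataclass(frozen=True)
class CompletenessReport:
    cluster_id: str
    catalytically_complete: bool
    transporter_complete: bool
    prcp_capable: bool
    missing_catalytic: tuple[str, ...]
    missing_transporter: tuple[str, ...]


def assess_completeness(cluster: PhnCluster) -> CompletenessReport:
    """Completeness on three axes: catalytic core (phnG-M), transporter
    (phnC-E), and PRcP hydrolysis (phnP or rcsF)."""
    present = cluster.gene_names()
    missing_cat = tuple(g for g in CATALYTIC_CORE if g not in present)
    missing_tra = tuple(g for g in TRANSPORTER if g not in present)
    return CompletenessReport(
        cluster_id=cluster.cluster_id,
        catalytically_complete=not missing_cat,
        transporter_complete=not missing_tra,
        prcp_capable=("phnP" in present) or ("rcsF" in present),
        missing_catalytic=missing_cat,
        missing_transporter=missing_tra,
    )


def predict_substrates(cluster: PhnCluster) -> dict[str, str]:
    """Growth predictions over the substrate panel.

    Phosphonate substrates with a stated genetic rule get ``growth`` /
    ``no_growth``; the remaining columns (phosphonoacetate, phosphonoalanine,
    phosphite, hypophosphite, phosphate, no-P control) have no
    cluster-intrinsic rule and stay ``indeterminate``.
    """
    rep = assess_completeness(cluster)
    functional = rep.catalytically_complete and rep.prcp_capable
    has_phnO = cluster.has("phnO")
    out: dict[str, str] = {}
    for sub in SUBSTRATES:
        if sub in _CORE_SUBSTRATES:
            out[sub] = "growth" if functional else "no_growth"
        elif sub in _PHNO_SUBSTRATES:
            out[sub] = "growth" if (functional and has_phnO) else "no_growth"
        else:
            out[sub] = "indeterminate"
    return out


def annotation_report(cluster: PhnCluster) -> dict:
    """JSON-ready annotation: roles, completeness, and predictions."""
    rep = assess_completeness(cluster)
    return {
        "cluster_id": cluster.cluster_id,
        "genes": [{"name": n, "role": r} for n, r in cluster.genes],
        "catalytically_complete": rep.catalytically_complete,
        "transporter_complete": rep.transporter_complete,
        "prcp_capable": rep.prcp_capable,
        "missing_catalytic": list(rep.missing_catalytic),
        "missing_transporter": list(rep.missing_transporter),
        "substrate_predictions": predict_substrates(cluster),
    }
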