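"""Bundled reference fixtures for the methylphosphonate microcosm study
system.

These small tables describe the published endpoint of a nutrient-amendment
microcosm experiment in North Pacific surface seawater: gene-frequency
estimates for phosphonate-utilization genes in the genomic DNA libraries
(percent of bacteria, recA-normalized), the phosphonate growth-substrate
panel of the three C-P lyase clusters recovered by functional screening,
and the gene content of those clusters.  The cluster gene lists are
reconstructions from the clusters' published descriptions (complete
phnC-F + phnG-M in all three; no phnO anywhere; phnP absent from MPn_2,
which instead carries the analogous rcsF phosphoesterase plus several
novel ORFs); the exact ordered gene lists were not printed, so these
fixtures are synthetic reconstructions faithful to every stated rule.
"""

from __future__ import annotations

import io

import pandas as pd

from .phncluster import PhnCluster

__all__ = [
    "CP_LYASE_SIX",
    "phn_gene_frequencies",
    "substrate_panel",
    "fosmid_clusters",
    "ecoli_phn_operon",
]

#: The six C-P lyase genes whose frequencies were averaged to estimate
#: cluster carriage.
CP_LYASE_SIX = ("phnG", "phnH", "phnI", "phnJ", "phnM", "phnN")

# percent of bacteria carrying each gene (recA-normalized), per gDNA library
_PHN_FREQ_TSV = """\
family	T0	TF_control	TF_GlcN	TF_GlcN_MPn
phnG	0	0	0	47
phnH	0	0	0	15
phnI	0	0	4	38
phnJ	0	1	1	53
phnM	0	0	2	67
phnN	0	0	3	24
phnA	2	6	4	7
phnW	6	5	25	5
phnX	0	0	31	5
phnY	0	3	0	0
phnZ	0	0	4	9
recA	100	100	100	100
"""

# growth (+) / no growth (-) of E. coli hosts carrying each cluster, per P source
_SUBSTRATE_TSV = """\
clone	no_P	MPn	AMPn	2AEPn	1AEPn	EPn	PnAc	PnAla	3PnP	3APPn	HPt	Pt	Pi
CC1FOS	-	-	-	-	-	-	-	-	-	-	-	-	+
B3_TF_MPn_1	-	+	-	+	-	+	+	+	+	+	-	+	+
B3_TF_MPn_2	-	+	-	+	-	+	-	-	+	+	-	-	+
B3_TF_MPn_8	-	+	-	+	-	+	+	-	+	+	-	+	+
"""

_CLUSTER_GENES = {
    # Alteromonadales-like cluster; carries phnP and a hexapeptide-repeat ORF
    "B3_TF_MPn_1": [
        "phnC", "phnD", "phnE", "phnF", "phnG", "phnH", "phnI", "phnJ",
        "phnK", "phnL", "phnM", "phnN", "phnP", "hpt_transferase",
    ],
    # Rhodobacteraceae-like cluster; no phnP, rcsF instead, plus duplicated
    # phnE/phnM-like ORFs and a GNAT acetyltransferase
    "B3_TF_MPn_2": [
        "phnC", "phnD", "phnE", "phnE2", "phnF", "phnG", "phnH", "phnI",
        "phnJ", "phnK", "phnL", "phnM", "phnM1", "phnN", "rcsF",
        "gnat_acetyltransferase", "hpt_transferase",
    ],
    # V. nigripulchritudo-like cluster
    "B3_TF_MPn_8": [
        "phnC", "phnD", "phnE", "phnF", "phnG", "phnH", "phnI", "phnJ",
        "phnK", "phnL", "phnM", "phnN", "phnP",
    ],
}


def phn_gene_frequencies() -> pd.DataFrame:
    """Percent-of-bacteria table for phosphonate genes in the four gDNA
    libraries (families as index, libraries as columns)."""
    return pd.read_csv(io.StringIO(_PHN_FREQ_TSV), sep="\t", index_col="family")


def substrate_panel() -> pd.DataFrame:
    """Observed growth panel for the recovered clusters (and the empty-vector
    control), '+'/'-' coded, clones as index."""
    return pd.read_csv(io.StringIO(_SUBSTRATE_TSV), sep="\t", index_col="clone")


def fosmid_clusters() -> dict[str, PhnCluster]:
    """The three recovered marine C-P lyase clusters as annotated objects."""
    return {
        cid: PhnCluster.from_genes(cid, genes)
        for cid, genes in _CLUSTER_GENES.items()
    }


def ecoli_phn_operon() -> PhnCluster:
    """The canonical 14-gene E. coli phnC..phnP operon."""
    names = [
        "phnC", "phnD", "phnE", "phnF", "phnG", "phnH", "phnI",
        "phnJ", "phnK", "phnL", "phnM", "phnN", "phnO", "phnP",
    ]
    return PhnCluster.from_genes("Ecoli_phn_operon", names)
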