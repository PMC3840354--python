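"""KO- and pathway-level functional profiles with tie splitting and sample
clustering.

Reads tied between several equal-bit-score subjects are split
proportionally: each of the k KO-bearing top hits contributes weight 1/k,
so every KEGG-assigned read contributes total weight exactly 1 (mass
conservation).  KO weights are normalized to the number of KEGG-assigned
reads (non-rRNA, non-sRNA reads with a significant KEGG match).  Pathway
abundance is the sum of its member-KO percents; a KO belonging to several
pathways counts fully in each, so the pathway column sums may exceed 100%.

Samples are clustered by unweighted average linkage on 1 - Pearson r over
retained pathway vectors.  The agglomeration is written here rather than
delegated, because deterministic tie-breaking (merge the lexicographically
smallest pair among equidistant candidates) is part of the contract;
scipy's hierarchical clustering is used as an independent cross-check in
the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, Pathway
from .partition import PartitionResult

__all__ = [
    "KOProfile",
    "PathwayMatrix",
    "SampleClustering",
    "profile_kos",
    "aggregate_pathways",
    "cluster_samples",
    "profile_srna",
]


@dataclass
class KOProfile:
    """Per-library KO weights and percent abundances."""

    library_id: str
    weight: dict[str, float]
    n_kegg_assigned: int
    n_no_ko: int = 0

    @property
    def normalized(self) -> dict[str, float]:
        """KO percent of KEGG-assigned reads."""
        if self.n_kegg_assigned == 0:
            return {k: 0.0 for k in self.weight}
        return {k: 100.0 * w / self.n_kegg_assigned for k, w in self.weight.items()}

    def to_frame(self) -> pd.DataFrame:
        kos = sorted(self.weight)
        norm = self.normalized
        return pd.DataFrame(
            {
                "library_id": self.library_id,
                "ko_id": kos,
                "weight": [self.weight[k] for k in kos],
                "percent": [norm[k] for k in kos],
            }
        )


def profile_kos(
    kegg_hits: pd.DataFrame,
    catalog: Catalog,
    partition: PartitionResult | None = None,
    threshold: float = 50.0,
    library_id: str = "",
) -> KOProfile:
    """Tie-splitting KO profile of one library.

    Reads classed rRNA or sRNA by ``partition`` are excluded.  Among each
    read's top-bit-score hits, only KO-bearing subjects receive weight; a
    read whose top hits all lack a KO is counted as KEGG-unassigned
    (``n_no_ko``) and contributes nothing.
    """
    hits = kegg_hits[kegg_hits["bit_score"] >= threshold]
    if partition is not None:
        rna_like = partition.reads_in_class("rRNA") | partition.reads_in_class("sRNA")
        if rna_like:
            hits = hits[~hits["read_id"].isin(rna_like)]
    lib = library_id or (partition.library_id if partition is not None else "")
    if hits.empty:
        return KOProfile(lib, {}, 0, 0)

    top_score = hits.groupby("read_id", sort=False)["bit_score"].transform("max")
    top = hits[hits["bit_score"] == top_score]
    ko_of_subject = catalog.subject_column("ko_id")
    top = top.assign(ko_id=top["subject_id"].map(ko_of_subject))

    n_reads_with_top = top["read_id"].nunique()
    with_ko = top.dropna(subset=["ko_id"])
    n_assigned = with_ko["read_id"].nunique()
    n_no_ko = int(n_reads_with_top - n_assigned)
    if n_assigned == 0:
        return KOProfile(lib, {}, 0, n_no_ko)

    k_per_read = with_ko.groupby("read_id", sort=False)["ko_id"].transform("size")
    with_ko = with_ko.assign(w=1.0 / k_per_read)
    weight = with_ko.groupby("ko_id")["w"].sum().to_dict()
    return KOProfile(lib, {k: float(v) for k, v in weight.items()}, int(n_assigned), n_no_ko)


@dataclass
class PathwayMatrix:
    """Pathways x libraries percent matrix plus the clustering view."""

    values: pd.DataFrame            # all pathways, percent of KEGG-assigned reads
    retained: list[str]             # pathways above min_fraction somewhere
    min_fraction: float

    @property
    def clustering_view(self) -> pd.DataFrame:
        return self.values.loc[self.retained]

    @property
    def row_normalized_view(self) -> pd.DataFrame:
        """Per-row z-scored display matrix (rows of zero variance map to 0);
        monotone in each row, so row orderings are preserved."""
        view = self.clustering_view
        mu = view.mean(axis=1)
        sd = view.std(axis=1, ddof=0).replace(0.0, np.nan)
        return view.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


def aggregate_pathways(
    profiles: Sequence[KOProfile],
    pathways: Mapping[str, Pathway],
    min_fraction: float = 1.0,
    on_empty_pathway: str = "keep",
) -> PathwayMatrix:
    """Sum member-KO percents into a pathway x library matrix.

    ``min_fraction`` (percent) controls which pathways enter the clustering
    view: a pathway is retained if it exceeds the cutoff in at least one
    library; the full matrix always keeps every pathway.  A pathway none of
    whose member KOs occur in any profile is kept at zero by default, or
    rejected with ``on_empty_pathway="error"``.
    """
    lib_ids = [p.library_id for p in profiles]
    if len(set(lib_ids)) != len(lib_ids):
        raise ValueError("duplicate library ids among KO profiles")
    norm = {p.library_id: p.normalized for p in profiles}
    seen_kos = set().union(*(p.weight.keys() for p in profiles)) if profiles else set()

    data: dict[str, list[float]] = {}
    for pw_id, pw in pathways.items():
        if on_empty_pathway == "error" and not (pw.member_kos & seen_kos):
            raise ValueError(
                f"pathway {pw_id!r} has no member KO present in any profile"
            )
        # summation in sorted KO order keeps the floats identical across
        # processes (set iteration order is hash-randomized)
        data[pw_id] = [
            sum(norm[lib].get(ko, 0.0) for ko in sorted(pw.member_kos))
            for lib in lib_ids
        ]
    values = pd.DataFrame.from_dict(data, orient="index", columns=lib_ids)
    retained = [pw for pw in values.index if (values.loc[pw] > min_fraction).any()]
    return PathwayMatrix(values=values, retained=retained, min_fraction=min_fraction)


# ---------------------------------------------------------------------------
# Hierarchical clustering (unweighted average linkage, Pearson distance)


@dataclass
class SampleClustering:
    """Merge tree of libraries: heights, member sets, leaf order, Newick."""

    labels: list[str]
    merges: list[tuple[float, tuple[str, ...], tuple[str, ...]]]
    leaf_order: list[str]
    newick: str

    def smallest_cluster_containing(self, members: set[str]) -> set[str]:
        """Members of the smallest merge-tree cluster covering ``members``."""
        clusters = [frozenset([l]) for l in self.labels]
        for _, a, b in self.merges:
            clusters.append(frozenset(a) | frozenset(b))
        covering = [c for c in clusters if members <= c]
        return set(min(covering, key=len))


def _pearson_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """d = 1 - Pearson r between library columns; errors on zero variance."""
    flat = matrix.std(axis=0, ddof=0)
    dead = [str(c) for c in flat.index[flat == 0.0]]
    if dead:
        raise ValueError(
            f"Pearson distance undefined: zero-variance profile for librar"
            f"{'y' if len(dead) == 1 else 'ies'} {dead}"
        )
    corr = np.corrcoef(matrix.to_numpy().T)
    return pd.DataFrame(1.0 - corr, index=matrix.columns, columns=matrix.columns)


def cluster_samples(
    matrix: PathwayMatrix | pd.DataFrame,
    tol: float = 1e-12,
) -> SampleClustering:
    """Agglomerate library columns by unweighted average linkage.

    Inter-cluster distance is the mean of all pairwise 1 - Pearson r values
    between members.  When two candidate merges are equidistant (within
    ``tol``), the pair with the lexicographically smallest member ids is
    merged, which makes the tree deterministic and invariant to input
    column order.
    """
    view = matrix.clustering_view if isinstance(matrix, PathwayMatrix) else matrix
    if view.shape[1] < 2:
        raise ValueError("need at least 2 libraries to cluster")
    if view.shape[0] < 2:
        raise ValueError("need at least 2 retained pathways to cluster")

    dist = _pearson_distance_matrix(view)
    labels = sorted(str(c) for c in view.columns)

    # active clusters keyed by their sorted member tuple
    clusters: dict[tuple[str, ...], list[str]] = {(l,): [l] for l in labels}
    newick_of: dict[tuple[str, ...], str] = {(l,): l for l in labels}
    height_of: dict[tuple[str, ...], float] = {(l,): 0.0 for l in labels}
    merges: list[tuple[float, tuple[str, ...], tuple[str, ...]]] = []

    def cluster_dist(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        sub = dist.loc[list(clusters[a]), list(clusters[b])]
        return float(sub.to_numpy().mean())

    while len(clusters) > 1:
        keys = sorted(clusters)
        best: tuple[float, tuple, tuple] | None = None
        best_d = np.inf
        for a, b in itertools.combinations(keys, 2):
            d = cluster_dist(a, b)
            if d < best_d - tol:
                best_d = d
                best = (d, a, b)
            # ties resolved by the sorted-pair iteration order of `keys`
        assert best is not None
        d, a, b = best
        merged = tuple(sorted(a + b))
        members = clusters.pop(a) + clusters.pop(b)
        clusters[merged] = sorted(members)
        la = max(d / 2.0 - height_of[a] / 2.0, 0.0)
        lb = max(d / 2.0 - height_of[b] / 2.0, 0.0)
        newick_of[merged] = f"({newick_of[a]}:{la:.6g},{newick_of[b]}:{lb:.6g})"
        height_of[merged] = d
        merges.append((d, a, b))

    root = next(iter(clusters))

    # leaf order follows the nested merge structure
    def leaves(key: tuple[str, ...]) -> list[str]:
        for d, a, b in reversed(merges):
            if tuple(sorted(a + b)) == key:
                return leaves(a) + leaves(b)
        return [key[0]]

    leaf_order = leaves(root)
    return SampleClustering(
        labels=labels,
        merges=merges,
        leaf_order=leaf_order,
        newick=newick_of[root] + ";",
    )


# ---------------------------------------------------------------------------
# sRNA family profile


def profile_srna(
    srna_hits: pd.DataFrame,
    partition: PartitionResult,
    catalog: Catalog,
    threshold: float = 50.0,
) -> dict[str, float]:
    """sRNA family abundance as percent of *non-rRNA* reads.

    Note the denominator deliberately differs from the KO profiles: it is
    all reads of the library except the rRNA class, not the KEGG-assigned
    subset.
    """
    denom = partition.n_total - partition.n_rRNA
    families = sorted(
        {e.family for e in catalog.entries.values() if e.entry_class == "sRNA" and e.family}
    )
    out = {f: 0.0 for f in families}
    if denom <= 0:
        return out
    hits = srna_hits[srna_hits["bit_score"] >= threshold]
    # only reads actually classed sRNA (rRNA precedence already applied)
    hits = hits[hits["read_id"].isin(partition.reads_in_class("sRNA"))]
    if hits.empty:
        return out
    fam_of_subject = catalog.subject_column("family")
    top_score = hits.groupby("read_id", sort=False)["bit_score"].transform("max")
    top = hits[hits["bit_score"] == top_score]
    fam_per_read = (
        top.assign(family=top["subject_id"].map(fam_of_subject))
        .groupby("read_id", sort=False)["family"]
        .first()
    )
    for fam, n in fam_per_read.value_counts().items():
        out[str(fam)] = 100.0 * int(n) / denom
    return out
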