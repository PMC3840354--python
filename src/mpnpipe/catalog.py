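"""Reference catalogs, library manifests, and alignment hit tables.

Everything downstream of the aligner speaks the vocabulary defined here:
*subjects* (reference genes) carrying an explicit taxonomic lineage, an
optional KEGG ortholog (KO) id, pathway memberships, a protein length and a
gene-family tag; *libraries* with treatment / timepoint / molecule metadata;
and alignment *hits* in the 12-column BLAST tabular layout
(``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore``).  Extra trailing columns in hit tables are ignored.

Hit tables are held in memory as :class:`pandas.DataFrame` objects with the
slim column set :data:`HIT_COLUMNS`; :class:`HitRecord` is the row-level
view used for validation and small fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "BLAST_COLUMNS",
    "HIT_COLUMNS",
    "CATALOGS",
    "ENTRY_CLASSES",
    "TREATMENTS",
    "MOLECULES",
    "LINEAGE_RANKS",
    "CatalogError",
    "HitTableError",
    "HitRecord",
    "Pathway",
    "CatalogEntry",
    "LibraryManifest",
    "Catalog",
    "read_hit_table",
    "write_hit_table",
    "hits_to_frame",
    "read_catalog",
    "write_catalog",
    "read_manifests",
    "write_manifests",
]

#: BLAST tabular ("outfmt 6") column order; bit score is column 12.
BLAST_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

#: Slim in-memory hit-table columns.
HIT_COLUMNS = ("read_id", "subject_id", "percent_identity", "bit_score", "catalog")

#: Catalogs a hit table can be searched against.
CATALOGS = ("rRNA", "sRNA", "protein", "kegg", "fosmid")

#: Classes a reference gene can belong to.
ENTRY_CLASSES = ("rRNA", "sRNA", "protein")

TREATMENTS = ("control", "GlcN", "GlcN_MPn")
MOLECULES = ("DNA", "RNA")

#: Ordered lineage ranks stored per catalog entry (domain -> species/strain).
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "species")


class CatalogError(ValueError):
    """Invalid catalog, manifest, or pathway-table content."""


class HitTableError(ValueError):
    """Malformed hit-table input; message names the offending line(s)."""


@dataclass(frozen=True)
class HitRecord:
    """One read-vs-subject alignment from one catalog search."""

    read_id: str
    subject_id: str
    percent_identity: float
    bit_score: float
    catalog: str

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise HitTableError(f"negative bit score for read {self.read_id!r}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise HitTableError(
                f"percent identity {self.percent_identity} outside [0, 100] "
                f"for read {self.read_id!r}"
            )
        if self.catalog not in CATALOGS:
            raise HitTableError(f"unknown catalog {self.catalog!r}")


@dataclass(frozen=True)
class Pathway:
    """A named set of KEGG orthologs; ``custom`` marks locally curated pathways."""

    pathway_id: str
    name: str
    member_kos: frozenset[str]
    custom: bool = False

    def __post_init__(self) -> None:
        if not self.member_kos:
            raise CatalogError(f"pathway {self.pathway_id!r} has no member KOs")


@dataclass(frozen=True)
class CatalogEntry:
    """A reference gene: taxonomy, orthology, length, and family tag."""

    subject_id: str
    taxon_id: str
    lineage: tuple[str, ...]
    entry_class: str
    ko_id: str | None = None
    pathways: frozenset[str] = frozenset()
    protein_length: int | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if self.entry_class not in ENTRY_CLASSES:
            raise CatalogError(
                f"entry {self.subject_id!r}: unknown class {self.entry_class!r}"
            )
        if self.ko_id is not None and self.entry_class != "protein":
            raise CatalogError(
                f"entry {self.subject_id!r}: KO id on non-protein entry "
                f"(class {self.entry_class!r})"
            )
        if self.entry_class == "protein":
            if self.protein_length is None or self.protein_length <= 0:
                raise CatalogError(
                    f"entry {self.subject_id!r}: protein entries need a "
                    f"positive protein_length, got {self.protein_length!r}"
                )

    def rank_name(self, rank: str) -> str:
        """Lineage name at ``rank`` (one of :data:`LINEAGE_RANKS`)."""
        idx = LINEAGE_RANKS.index(rank)
        if idx >= len(self.lineage):
            return self.lineage[-1] if self.lineage else self.taxon_id
        return self.lineage[idx]


@dataclass(frozen=True)
class LibraryManifest:
    """Metadata for one sequencing library."""

    library_id: str
    treatment: str
    timepoint_h: int
    molecule: str
    total_reads: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise CatalogError(f"unknown treatment {self.treatment!r}")
        if self.molecule not in MOLECULES:
            raise CatalogError(f"unknown molecule {self.molecule!r}")
        if self.timepoint_h < 0:
            raise CatalogError("timepoint_h must be non-negative")
        if self.total_reads <= 0:
            raise CatalogError("total_reads must be positive")


class Catalog:
    """A validated collection of :class:`CatalogEntry` plus its pathway table."""

    def __init__(
        self,
        entries: Iterable[CatalogEntry],
        pathways: Iterable[Pathway] = (),
    ) -> None:
        self.pathways: dict[str, Pathway] = {}
        for pw in pathways:
            if pw.pathway_id in self.pathways:
                raise CatalogError(f"duplicate pathway id {pw.pathway_id!r}")
            self.pathways[pw.pathway_id] = pw
        self.entries: dict[str, CatalogEntry] = {}
        for entry in entries:
            if entry.subject_id in self.entries:
                raise CatalogError(f"duplicate subject_id {entry.subject_id!r}")
            for pw_id in entry.pathways:
                if pw_id not in self.pathways:
                    raise CatalogError(
                        f"entry {entry.subject_id!r} references unknown "
                        f"pathway {pw_id!r}"
                    )
            self.entries[entry.subject_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self.entries

    def entry(self, subject_id: str) -> CatalogEntry:
        try:
            return self.entries[subject_id]
        except KeyError:
            raise CatalogError(f"unknown subject_id {subject_id!r}") from None

    def by_family(self, family: str) -> list[CatalogEntry]:
        return [e for e in self.entries.values() if e.family == family]

    def families(self) -> set[str]:
        return {e.family for e in self.entries.values() if e.family is not None}

    def subject_column(self, attr: str) -> pd.Series:
        """Series mapping subject_id -> ``attr`` over all entries."""
        return pd.Series(
            {sid: getattr(e, attr) for sid, e in self.entries.items()},
            name=attr,
            dtype=object,
        )

    def with_pathway_memberships(self) -> "Catalog":
        """Return a copy whose entries' ``pathways`` are derived from the
        pathway table via KO membership."""
        ko_to_pw: dict[str, set[str]] = {}
        for pw in self.pathways.values():
            for ko in pw.member_kos:
                ko_to_pw.setdefault(ko, set()).add(pw.pathway_id)
        new_entries = []
        for e in self.entries.values():
            pw_ids = frozenset(ko_to_pw.get(e.ko_id, ())) if e.ko_id else frozenset()
            new_entries.append(replace(e, pathways=pw_ids))
        return Catalog(new_entries, self.pathways.values())


# ---------------------------------------------------------------------------
# Hit tables


def _parse_hit_lines(lines: Iterable[str], catalog: str, source: str) -> pd.DataFrame:
    read_ids: list[str] = []
    subject_ids: list[str] = []
    pidents: list[float] = []
    scores: list[float] = []
    bad: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            bad.append(f"line {lineno}: expected >=12 tab-separated columns, got {len(parts)}")
            continue
        try:
            pident = float(parts[2])
            score = float(parts[11])
        except ValueError:
            bad.append(f"line {lineno}: non-numeric identity/score column")
            continue
        if score < 0 or not 0.0 <= pident <= 100.0:
            bad.append(f"line {lineno}: identity/score out of range")
            continue
        read_ids.append(parts[0])
        subject_ids.append(parts[1])
        pidents.append(pident)
        scores.append(score)
    if bad:
        shown = "; ".join(bad[:10])
        more = f" (+{len(bad) - 10} more)" if len(bad) > 10 else ""
        raise HitTableError(f"{source}: {shown}{more}")
    return pd.DataFrame(
        {
            "read_id": pd.Series(read_ids, dtype=object),
            "subject_id": pd.Series(subject_ids, dtype=object),
            "percent_identity": pd.Series(pidents, dtype=float),
            "bit_score": pd.Series(scores, dtype=float),
            "catalog": pd.Series([catalog] * len(read_ids), dtype=object),
        }
    )


def read_hit_table(path: str | Path, catalog: str) -> pd.DataFrame:
    """Read a BLAST-tabular hit table into a slim hit DataFrame.

    ``percent_identity`` is taken from column 3 and ``bit_score`` from
    column 12.  Malformed rows raise :class:`HitTableError` naming their
    line numbers; an empty file yields an empty table.
    """
    if catalog not in CATALOGS:
        raise HitTableError(f"unknown catalog {catalog!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rt", encoding="utf-8") as fh:
        return _parse_hit_lines(fh, catalog, str(path))


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    """Write a slim hit DataFrame as 12-column BLAST tabular.

    Positional columns not represented in the slim frame (alignment length,
    mismatches, coordinates, e-value) are filled with fixed placeholders, so
    a write/read round trip reproduces the slim records exactly.
    """
    n = len(hits)
    out = pd.DataFrame(
        {
            "qseqid": hits["read_id"].to_numpy(),
            "sseqid": hits["subject_id"].to_numpy(),
            "pident": hits["percent_identity"].to_numpy(),
            "length": [100] * n,
            "mismatch": [0] * n,
            "gapopen": [0] * n,
            "qstart": [1] * n,
            "qend": [100] * n,
            "sstart": [1] * n,
            "send": [100] * n,
            "evalue": ["1e-10"] * n,
            "bitscore": hits["bit_score"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.1f")


def hits_to_frame(records: Iterable[HitRecord]) -> pd.DataFrame:
    """Build a slim hit DataFrame from :class:`HitRecord` objects."""
    records = list(records)
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "subject_id": [r.subject_id for r in records],
            "percent_identity": [r.percent_identity for r in records],
            "bit_score": [r.bit_score for r in records],
            "catalog": [r.catalog for r in records],
        },
        columns=list(HIT_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Catalog / pathway / manifest TSV IO (headers, UTF-8, no quoting)

_ENTRY_FIELDS = (
    "subject_id", "taxon_id", "lineage", "entry_class",
    "ko_id", "protein_length", "family",
)


def write_catalog(catalog: Catalog, entries_path: str | Path, pathways_path: str | Path) -> None:
    rows = []
    for e in catalog.entries.values():
        rows.append(
            {
                "subject_id": e.subject_id,
                "taxon_id": e.taxon_id,
                "lineage": ";".join(e.lineage),
                "entry_class": e.entry_class,
                "ko_id": e.ko_id or "",
                "protein_length": "" if e.protein_length is None else e.protein_length,
                "family": e.family or "",
            }
        )
    pd.DataFrame(rows, columns=list(_ENTRY_FIELDS)).to_csv(entries_path, sep="\t", index=False)
    pw_rows = [
        {
            "pathway_id": p.pathway_id,
            "name": p.name,
            "member_kos": ";".join(sorted(p.member_kos)),
            "custom": int(p.custom),
        }
        for p in catalog.pathways.values()
    ]
    pd.DataFrame(
        pw_rows, columns=["pathway_id", "name", "member_kos", "custom"]
    ).to_csv(pathways_path, sep="\t", index=False)


def read_catalog(entries_path: str | Path, pathways_path: str | Path) -> Catalog:
    """Read catalog + pathway TSVs, validating cross-references."""
    pw_df = pd.read_csv(pathways_path, sep="\t", dtype=str).fillna("")
    pathways = [
        Pathway(
            pathway_id=row["pathway_id"],
            name=row["name"],
            member_kos=frozenset(k for k in row["member_kos"].split(";") if k),
            custom=bool(int(row["custom"])),
        )
        for _, row in pw_df.iterrows()
    ]
    df = pd.read_csv(entries_path, sep="\t", dtype=str).fillna("")
    missing = set(_ENTRY_FIELDS) - set(df.columns)
    if missing:
        raise CatalogError(f"{entries_path}: missing columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            CatalogEntry(
                subject_id=row["subject_id"],
                taxon_id=row["taxon_id"],
                lineage=tuple(x for x in row["lineage"].split(";") if x),
                entry_class=row["entry_class"],
                ko_id=row["ko_id"] or None,
                protein_length=int(row["protein_length"]) if row["protein_length"] else None,
                family=row["family"] or None,
            )
        )
    return Catalog(entries, pathways).with_pathway_memberships()


def write_manifests(manifests: Sequence[LibraryManifest], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "library_id": m.library_id,
                "treatment": m.treatment,
                "timepoint_h": m.timepoint_h,
                "molecule": m.molecule,
                "total_reads": m.total_reads,
            }
            for m in manifests
        ]
    ).to_csv(path, sep="\t", index=False)


def read_manifests(path: str | Path) -> list[LibraryManifest]:
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    return [
        LibraryManifest(
            library_id=row["library_id"],
            treatment=row["treatment"],
            timepoint_h=int(row["timepoint_h"]),
            molecule=row["molecule"],
            total_reads=int(row["total_reads"]),
        )
        for _, row in df.iterrows()
    ]
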