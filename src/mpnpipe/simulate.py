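"""Generative model of the nutrient-amendment microcosm experiment.

The simulator emits per-library BLAST-tabular hit tables (never sequences:
the pipeline's computation begins at hit tables, so simulating reads would
add nothing testable) together with the ground truth that produced them.

Model
-----
A community is a set of taxa, each carrying a genome of reference genes
(protein-coding, rRNA, and sRNA entries) and following a per-treatment
abundance trajectory over the sampled timepoints.  For a DNA library, read
counts per gene are multinomial with weights proportional to taxon
abundance x gene length.  For an RNA library, reads are first split into
rRNA / sRNA / other classes at the scenario's fixed fractions; within the
sRNA and protein classes, gene weights are additionally scaled by regulon
induction multipliers (treatment- and time-dependent), which is how
P-starvation, PTS/PHA, csrB, and alkylphosphonate responses are expressed.

Two noise processes mimic alignment reality: with probability
``ambiguity_rate`` a protein read receives k=2 equal-bit-score top hits to
same-KO genes of two distinct taxa (KO-assignable but taxonomically
ambiguous, so tie-split KO counting and unique-taxon profiling disagree in
a controlled way); with probability ``unassigned_rate`` a read receives
only sub-threshold hits (bit score < 50).  Reads may also carry a weaker
secondary hit to exercise top-hit selection.

Each library draws from its own pseudo-random stream derived from
(seed, library_id), so any library can be regenerated independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    Catalog,
    CatalogEntry,
    LibraryManifest,
    Pathway,
    write_catalog,
    write_hit_table,
    write_manifests,
)
from .functional import KOProfile

__all__ = [
    "ScenarioError",
    "Regulon",
    "TaxonSpec",
    "CommunityScenario",
    "SimulationResult",
    "build_catalog",
    "simulate",
    "default_scenario",
    "carriage_scenario",
    "null_ko_profiles",
    "load_scenario",
    "save_scenario",
]

_CATALYTIC_CORE = frozenset({"phnG", "phnH", "phnI", "phnJ", "phnK", "phnL", "phnM"})


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class Regulon:
    """A co-regulated gene-family set with induction multipliers.

    ``induction[treatment][timepoint]`` multiplies the RNA sampling weight
    of member genes; unlisted (treatment, timepoint) combinations fall back
    to ``baseline`` (1 = constitutive, <1 = repressed)."""

    name: str
    families: frozenset[str]
    induction: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    baseline: float = 1.0

    def multiplier(self, treatment: str, timepoint_h: int) -> float:
        return float(self.induction.get(treatment, {}).get(timepoint_h, self.baseline))


@dataclass(frozen=True)
class TaxonSpec:
    """One taxon: genome, abundance trajectory, regulons, carriage flag."""

    taxon_id: str
    lineage: tuple[str, ...]
    genes: tuple[CatalogEntry, ...]
    abundance_trajectory: Mapping[str, Mapping[int, float]]
    regulons: tuple[Regulon, ...] = ()
    carries_cp_lyase: bool = False

    def validate(self) -> None:
        if not self.genes:
            raise ScenarioError(f"taxon {self.taxon_id!r} has an empty genome")
        families = {g.family for g in self.genes if g.family}
        if self.carries_cp_lyase != (_CATALYTIC_CORE <= families):
            raise ScenarioError(
                f"taxon {self.taxon_id!r}: carries_cp_lyase={self.carries_cp_lyase} "
                "inconsistent with phnG..phnM gene content"
            )
        n_reca = sum(1 for g in self.genes if g.family == "recA")
        if n_reca != 1:
            raise ScenarioError(
                f"taxon {self.taxon_id!r}: expected exactly one recA gene, found {n_reca}"
            )

    def abundance(self, treatment: str, timepoint_h: int) -> float:
        try:
            return float(self.abundance_trajectory[treatment][timepoint_h])
        except KeyError:
            raise ScenarioError(
                f"taxon {self.taxon_id!r}: no abundance for "
                f"({treatment!r}, {timepoint_h} h)"
            ) from None

    def induction(self, family: str | None, treatment: str, timepoint_h: int) -> float:
        m = 1.0
        for reg in self.regulons:
            if family in reg.families:
                m *= reg.multiplier(treatment, timepoint_h)
        return m


@dataclass
class CommunityScenario:
    """Complete, seedable description of a simulated microcosm experiment."""

    taxa: tuple[TaxonSpec, ...]
    timepoints_h: tuple[int, ...]
    treatments: tuple[str, ...]
    pathways: tuple[Pathway, ...]
    seed: int = 0
    reads_per_library: int = 20000
    rRNA_fraction_rna: float = 0.40
    sRNA_fraction_rna: float = 0.05
    ambiguity_rate: float = 0.05
    unassigned_rate: float = 0.10
    secondary_hit_rate: float = 0.30
    name: str = "scenario"

    def validate(self) -> None:
        for frac in (
            self.rRNA_fraction_rna, self.sRNA_fraction_rna,
            self.ambiguity_rate, self.unassigned_rate, self.secondary_hit_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ScenarioError(f"fraction {frac} outside [0, 1]")
        if self.rRNA_fraction_rna + self.sRNA_fraction_rna >= 1.0:
            raise ScenarioError("rRNA + sRNA fractions must be < 1")
        if self.reads_per_library <= 0:
            raise ScenarioError("reads_per_library must be positive")
        for taxon in self.taxa:
            taxon.validate()
        for trt in self.treatments:
            for tp in self.timepoints_h:
                total = sum(t.abundance(trt, tp) for t in self.taxa)
                if abs(total - 1.0) > 1e-9:
                    raise ScenarioError(
                        f"abundances at ({trt!r}, {tp} h) sum to {total!r}, not 1"
                    )

    def library_id(self, treatment: str, timepoint_h: int, molecule: str) -> str:
        return f"{treatment}_{timepoint_h:02d}h_{molecule}"

    def libraries(self) -> list[tuple[str, int, str]]:
        return [
            (trt, tp, mol)
            for trt in self.treatments
            for tp in self.timepoints_h
            for mol in ("DNA", "RNA")
        ]

    def carriage(self, treatment: str, timepoint_h: int) -> float:
        """True fraction of cells carrying a complete C-P lyase core."""
        return sum(
            t.abundance(treatment, timepoint_h) for t in self.taxa if t.carries_cp_lyase
        )


def build_catalog(scenario: CommunityScenario) -> Catalog:
    """Union reference catalog over all taxa, with pathway memberships."""
    entries: list[CatalogEntry] = []
    for taxon in scenario.taxa:
        entries.extend(taxon.genes)
    return Catalog(entries, scenario.pathways).with_pathway_memberships()


# ---------------------------------------------------------------------------
# Simulation core


def _lib_rng(seed: int, library_id: str) -> np.random.Generator:
    digest = hashlib.sha256(library_id.encode("utf-8")).digest()
    stream = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


class _GeneArrays:
    """Column-oriented view of the catalog for vectorized sampling."""

    def __init__(self, scenario: CommunityScenario, catalog: Catalog) -> None:
        subjects, lengths, classes, taxon_idx, families, kos = [], [], [], [], [], []
        self.taxa = list(scenario.taxa)
        for ti, taxon in enumerate(self.taxa):
            for gene in taxon.genes:
                subjects.append(gene.subject_id)
                lengths.append(gene.protein_length or 1)
                classes.append(gene.entry_class)
                taxon_idx.append(ti)
                families.append(gene.family or "")
                kos.append(gene.ko_id or "")
        self.subjects = np.array(subjects, dtype=object)
        self.lengths = np.array(lengths, dtype=float)
        self.classes = np.array(classes, dtype=object)
        self.taxon_idx = np.array(taxon_idx, dtype=int)
        self.families = np.array(families, dtype=object)
        self.kos = np.array(kos, dtype=object)
        self.is_protein = self.classes == "protein"
        self.protein_indices = np.flatnonzero(self.is_protein)

        # same-KO, different-taxon tie partners per gene
        by_ko: dict[str, list[int]] = {}
        for gi, ko in enumerate(self.kos):
            if ko and self.is_protein[gi]:
                by_ko.setdefault(ko, []).append(gi)
        self.partners: dict[int, np.ndarray] = {}
        for ko, idxs in by_ko.items():
            for gi in idxs:
                cands = [j for j in idxs if self.taxon_idx[j] != self.taxon_idx[gi]]
                if cands:
                    self.partners[gi] = np.array(cands, dtype=int)

    def abundance_vector(self, treatment: str, tp: int) -> np.ndarray:
        a = np.array([t.abundance(treatment, tp) for t in self.taxa])
        return a[self.taxon_idx]

    def induction_vector(self, treatment: str, tp: int) -> np.ndarray:
        out = np.ones(len(self.subjects))
        for gi in range(len(self.subjects)):
            taxon = self.taxa[self.taxon_idx[gi]]
            fam = self.families[gi] or None
            out[gi] = taxon.induction(fam, treatment, tp)
        return out


def _hit_frame(read_ids, subject_ids, pident, score, catalog_name) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(read_ids, dtype=object),
            "subject_id": pd.Series(subject_ids, dtype=object),
            "percent_identity": np.asarray(pident, dtype=float),
            "bit_score": np.asarray(score, dtype=float),
            "catalog": catalog_name,
        }
    )


def _scores(rng, n, lo, hi):
    return np.round(rng.uniform(lo, hi, n), 1)


def _idents(rng, n, mu, sd, lo=30.0, hi=100.0):
    return np.round(np.clip(rng.normal(mu, sd, n), lo, hi), 1)


@dataclass
class SimulationResult:
    scenario: CommunityScenario
    catalog: Catalog
    manifests: list[LibraryManifest]
    hit_tables: dict[str, dict[str, pd.DataFrame]]
    ground_truth: dict

    def manifest(self, library_id: str) -> LibraryManifest:
        for m in self.manifests:
            if m.library_id == library_id:
                return m
        raise KeyError(library_id)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib_id, tables in self.hit_tables.items():
            for cat, df in tables.items():
                write_hit_table(df, outdir / f"{lib_id}.{cat}.tsv")
        write_manifests(self.manifests, outdir / "manifests.tsv")
        write_catalog(
            self.catalog, outdir / "catalog_entries.tsv", outdir / "catalog_pathways.tsv"
        )
        with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True)


def _simulate_library(
    scenario: CommunityScenario,
    arrays: _GeneArrays,
    treatment: str,
    tp: int,
    molecule: str,
) -> tuple[dict[str, pd.DataFrame], dict]:
    lib_id = scenario.library_id(treatment, tp, molecule)
    rng = _lib_rng(scenario.seed, lib_id)
    n_reads = scenario.reads_per_library
    counter = 0

    def next_ids(n: int) -> np.ndarray:
        nonlocal counter
        ids = np.array([f"{lib_id}:r{counter + i:06d}" for i in range(n)], dtype=object)
        counter += n
        return ids

    abund = arrays.abundance_vector(treatment, tp)

    if molecule == "DNA":
        n_unassigned = int(rng.binomial(n_reads, scenario.unassigned_rate))
        n_assigned = n_reads - n_unassigned
        weights = abund * arrays.lengths
        counts = rng.multinomial(n_assigned, weights / weights.sum())
        n_rrna = int(counts[arrays.classes == "rRNA"].sum())
        n_srna = int(counts[arrays.classes == "sRNA"].sum())
    else:
        p_r, p_s = scenario.rRNA_fraction_rna, scenario.sRNA_fraction_rna
        n_rrna, n_srna, n_rest = rng.multinomial(n_reads, [p_r, p_s, 1.0 - p_r - p_s])
        n_unassigned = int(rng.binomial(n_rest, scenario.unassigned_rate))
        n_prot = int(n_rest) - n_unassigned
        induction = arrays.induction_vector(treatment, tp)
        counts = np.zeros(len(arrays.subjects), dtype=int)
        for cls, n_cls in (("rRNA", int(n_rrna)), ("sRNA", int(n_srna)), ("protein", n_prot)):
            mask = arrays.classes == cls
            w = abund[mask] * arrays.lengths[mask]
            if cls != "rRNA":
                w = w * induction[mask]
            if n_cls > 0:
                if w.sum() <= 0:
                    # class requested but no gene can emit it: those reads
                    # fall through as sub-threshold/unassigned
                    n_unassigned += n_cls
                else:
                    counts[np.flatnonzero(mask)] = rng.multinomial(n_cls, w / w.sum())
        n_rrna = int(counts[arrays.classes == "rRNA"].sum())
        n_srna = int(counts[arrays.classes == "sRNA"].sum())

    tables: dict[str, pd.DataFrame] = {}

    # rRNA and sRNA hit tables
    for cls, cat, (lo, hi), (mu, sd) in (
        ("rRNA", "rRNA", (60.0, 800.0), (96.0, 2.0)),
        ("sRNA", "sRNA", (55.0, 200.0), (94.0, 3.0)),
    ):
        idx = np.flatnonzero(arrays.classes == cls)
        expanded = np.repeat(idx, counts[idx])
        rng.shuffle(expanded)
        ids = next_ids(len(expanded))
        tables[cat] = _hit_frame(
            ids,
            arrays.subjects[expanded],
            _idents(rng, len(expanded), mu, sd),
            _scores(rng, len(expanded), lo, hi),
            cat,
        )

    # protein reads: primary hit + optional tie partner or secondary hit
    pidx = arrays.protein_indices
    expanded = np.repeat(pidx, counts[pidx])
    rng.shuffle(expanded)
    n_p = len(expanded)
    ids = next_ids(n_p)
    score = _scores(rng, n_p, 60.0, 400.0)
    pident = _idents(rng, n_p, 96.5, 2.0, lo=80.0)

    ambiguous = rng.random(n_p) < scenario.ambiguity_rate
    partner = np.full(n_p, -1, dtype=int)
    for i in np.flatnonzero(ambiguous):
        cands = arrays.partners.get(int(expanded[i]))
        if cands is None:
            ambiguous[i] = False
        else:
            partner[i] = int(cands[rng.integers(len(cands))])
    n_tied = int(ambiguous.sum())

    secondary = (rng.random(n_p) < scenario.secondary_hit_rate) & ~ambiguous
    sec_subject = np.full(n_p, -1, dtype=int)
    sec_idx = np.flatnonzero(secondary)
    if len(sec_idx) and len(pidx) > 1:
        draw = pidx[rng.integers(0, len(pidx), len(sec_idx))]
        clash = draw == expanded[sec_idx]
        draw[clash] = pidx[(np.searchsorted(pidx, draw[clash]) + 1) % len(pidx)]
        sec_subject[sec_idx] = draw
    sec_score = np.round(np.maximum(score - rng.uniform(6.0, 60.0, n_p), 25.0), 1)

    rows_ids = [ids]
    rows_subj = [arrays.subjects[expanded]]
    rows_pid = [pident]
    rows_score = [score]
    amb_idx = np.flatnonzero(ambiguous)
    if len(amb_idx):
        rows_ids.append(ids[amb_idx])
        rows_subj.append(arrays.subjects[partner[amb_idx]])
        rows_pid.append(pident[amb_idx])
        rows_score.append(score[amb_idx])
    if len(sec_idx):
        rows_ids.append(ids[sec_idx])
        rows_subj.append(arrays.subjects[sec_subject[sec_idx]])
        rows_pid.append(_idents(rng, len(sec_idx), 85.0, 5.0))
        rows_score.append(sec_score[sec_idx])

    # sub-threshold ("unassigned") reads
    u_ids = next_ids(n_unassigned)
    if n_unassigned and len(pidx):
        u_subj = arrays.subjects[pidx[rng.integers(0, len(pidx), n_unassigned)]]
        rows_ids.append(u_ids)
        rows_subj.append(u_subj)
        rows_pid.append(_idents(rng, n_unassigned, 70.0, 8.0))
        rows_score.append(_scores(rng, n_unassigned, 25.0, 49.4))

    protein_df = _hit_frame(
        np.concatenate(rows_ids) if rows_ids else [],
        np.concatenate(rows_subj) if rows_subj else [],
        np.concatenate(rows_pid) if rows_pid else [],
        np.concatenate(rows_score) if rows_score else [],
        "protein",
    )
    tables["protein"] = protein_df
    tables["kegg"] = protein_df.assign(catalog="kegg")

    assert counter == n_reads, (counter, n_reads)

    taxon_ab = {t.taxon_id: t.abundance(treatment, tp) for t in scenario.taxa}
    fam_weight: dict[str, float] = {}
    w_prot = abund[arrays.is_protein] * arrays.lengths[arrays.is_protein]
    if molecule == "RNA":
        w_prot = w_prot * arrays.induction_vector(treatment, tp)[arrays.is_protein]
    total_w = float(w_prot.sum())
    for fam, w in zip(arrays.families[arrays.is_protein], w_prot):
        if fam:
            fam_weight[fam] = fam_weight.get(fam, 0.0) + float(w) / total_w

    truth = {
        "library_id": lib_id,
        "treatment": treatment,
        "timepoint_h": tp,
        "molecule": molecule,
        "n_reads": n_reads,
        "taxon_abundance": taxon_ab,
        "carriage_cp_lyase": scenario.carriage(treatment, tp),
        "n_tied_reads": n_tied,
        "realized_class_counts": {
            "rRNA": n_rrna,
            "sRNA": n_srna,
            "protein": n_p,
            "unassigned": n_unassigned,
        },
        "expected_protein_family_fraction": fam_weight,
    }
    return tables, truth


def simulate(scenario: CommunityScenario) -> SimulationResult:
    """Run the generative model for every (treatment, timepoint, molecule).

    Returns in-memory hit tables, manifests, the union catalog, and the
    ground truth; byte-identical across runs for a fixed scenario + seed.
    """
    scenario.validate()
    catalog = build_catalog(scenario)
    arrays = _GeneArrays(scenario, catalog)
    manifests: list[LibraryManifest] = []
    hit_tables: dict[str, dict[str, pd.DataFrame]] = {}
    truths: dict[str, dict] = {}
    for trt, tp, mol in scenario.libraries():
        lib_id = scenario.library_id(trt, tp, mol)
        tables, truth = _simulate_library(scenario, arrays, trt, tp, mol)
        hit_tables[lib_id] = tables
        truths[lib_id] = truth
        manifests.append(
            LibraryManifest(
                library_id=lib_id,
                treatment=trt,
                timepoint_h=tp,
                molecule=mol,
                total_reads=scenario.reads_per_library,
            )
        )
    ground_truth = {
        "scenario_name": scenario.name,
        "seed": scenario.seed,
        "libraries": truths,
    }
    return SimulationResult(scenario, catalog, manifests, hit_tables, ground_truth)


# ---------------------------------------------------------------------------
# Bundled gene rosters


def _entries(taxon_id, lineage, specs, entry_class="protein") -> list[CatalogEntry]:
    out = []
    for name, ko, length in specs:
        out.append(
            CatalogEntry(
                subject_id=f"{taxon_id}|{name}",
                taxon_id=taxon_id,
                lineage=lineage,
                entry_class=entry_class,
                ko_id=ko,
                protein_length=length,
                family=name,
            )
        )
    return out


_HOUSEKEEPING = [
    ("rplA", "K02863", 232), ("rplB", "K02886", 273), ("rplM", "K02871", 142),
    ("rplN", "K02874", 122), ("rplO", "K02876", 144), ("rplV", "K02890", 110),
    ("glk", "K00845", 321), ("pgi", "K01810", 549), ("pfkA", "K00850", 320),
    ("fba", "K01623", 359), ("gap", "K00134", 331), ("pyk", "K00873", 470),
    ("gltA", "K01647", 427), ("acnA", "K01681", 891), ("icd", "K00031", 416),
    ("sucD", "K01902", 289), ("sdhA", "K00239", 588), ("fumA", "K01676", 548),
    ("nuoA", "K00330", 147), ("coxA", "K02274", 530), ("atpA", "K02111", 513),
    ("atpB", "K02112", 460),
]
_RECA = [("recA", "K03553", 353)]
_PHO = [
    ("pstS", "K02040", 346), ("pstC", "K02037", 319), ("pstB", "K02036", 257),
    ("phoA", "K01077", 471), ("phoX", "K07093", 583), ("phoB", "K07657", 229),
    ("phoR", "K07636", 431),
]
_PTS = [
    ("ptsI", "K08483", 575), ("ptsH", "K02784", 85),
    ("crr", "K02777", 169), ("ptsG", "K02779", 477),
]
_PHA = [("phbA", "K00626", 394), ("phbB", "K00023", 246), ("phbC", "K03821", 589)]
_PHN_OPERON = [
    ("phnC", "K02041", 262), ("phnD", "K02044", 338), ("phnE", "K02042", 277),
    ("phnF", "K02043", 241), ("phnG", "K06166", 150), ("phnH", "K06165", 194),
    ("phnI", "K06164", 354), ("phnJ", "K06163", 281), ("phnK", "K05781", 252),
    ("phnL", "K05780", 226), ("phnM", "K06162", 378), ("phnN", "K05774", 185),
    ("phnP", "K06167", 252),
]
_PHOSPHONATASE = [("phnW", "K03430", 333), ("phnX", "K05306", 267)]
_MOTILITY = [
    ("cheA", "K03407", 654), ("cheY", "K03413", 129), ("fliC", "K02406", 498),
    ("motA", "K02556", 295), ("barA", "K07678", 918), ("uvrY", "K07689", 214),
]
_PHOTO = [("psbA", "K02703", 360), ("psaA", "K02689", 750), ("rbcL", "K01601", 472)]


def _kos(specs) -> frozenset[str]:
    return frozenset(ko for _, ko, _ in specs)


def _fams(specs) -> frozenset[str]:
    return frozenset(name for name, _, _ in specs)


def default_pathways() -> tuple[Pathway, ...]:
    return (
        Pathway("path:ribosome", "Ribosome", _kos(_HOUSEKEEPING[:6])),
        Pathway("path:glycolysis", "Glycolysis / gluconeogenesis", _kos(_HOUSEKEEPING[6:12])),
        Pathway("path:tca", "Citrate cycle (TCA)", _kos(_HOUSEKEEPING[12:18])),
        Pathway("path:oxphos", "Oxidative phosphorylation", _kos(_HOUSEKEEPING[18:22])),
        Pathway("path:photosynthesis", "Photosynthesis", _kos(_PHOTO)),
        Pathway("path:pts", "Phosphotransferase system (PTS)", _kos(_PTS)),
        Pathway(
            "path:two_component", "Two-component system",
            frozenset({"K07657", "K07636", "K07678", "K07689", "K03407", "K03413"}),
        ),
        Pathway("path:flagellar", "Flagellar assembly", frozenset({"K02406", "K02556"})),
        Pathway(
            "path:abc_transporters", "ABC transporters",
            frozenset({"K02040", "K02037", "K02036", "K02041", "K02044", "K02042"}),
        ),
        Pathway(
            "path:phosphonatase", "Phosphonate and phosphinate metabolism",
            _kos(_PHOSPHONATASE),
        ),
        Pathway("path:recombination", "Homologous recombination", _kos(_RECA)),
        Pathway("path:alkylphosphonate", "Alkylphosphonate metabolism",
                _kos(_PHN_OPERON), custom=True),
        Pathway("path:phosphate", "Phosphate metabolism", _kos(_PHO), custom=True),
        Pathway("path:pha", "Polyhydroxyalkanoate biosynthesis", _kos(_PHA), custom=True),
    )


def _rna_genes(taxon_id, lineage, srna_families) -> list[CatalogEntry]:
    out = [
        CatalogEntry(
            subject_id=f"{taxon_id}|16S", taxon_id=taxon_id, lineage=lineage,
            entry_class="rRNA", protein_length=1500, family="16S",
        ),
        CatalogEntry(
            subject_id=f"{taxon_id}|23S", taxon_id=taxon_id, lineage=lineage,
            entry_class="rRNA", protein_length=2900, family="23S",
        ),
    ]
    lengths = {"csrB": 350, "glycine_riboswitch": 110}
    for fam in srna_families:
        out.append(
            CatalogEntry(
                subject_id=f"{taxon_id}|{fam}", taxon_id=taxon_id, lineage=lineage,
                entry_class="sRNA", protein_length=lengths[fam], family=fam,
            )
        )
    return out


def default_scenario(seed: int = 13, reads_per_library: int = 20000) -> CommunityScenario:
    """The packaged "microcosm succession" scenario.

    Six taxa in three arms (unamended control, Glc+N, Glc+N+MPn) sampled at
    0/12/24/36/48 h.  A V. splendidus-like opportunist blooms at 24 h in
    both amended arms carrying the PTS/PHA/csrB response; the community is
    driven into P starvation (Pho regulon rising to 48 h); and two C-P
    lyase carriers (V. nigripulchritudo-like and a Rhodobacterales
    representative) rise only in the MPn arm at 48 h with the
    alkylphosphonate regulon strongly induced, so roughly 45% of cells
    carry C-P lyase clusters at the MPn endpoint.
    """
    amended = ("GlcN", "GlcN_MPn")
    pho = Regulon(
        "pho", _fams(_PHO),
        {trt: {24: 3.0, 36: 4.0, 48: 5.0} for trt in amended},
    )
    pts = Regulon(
        "pts", _fams(_PTS),
        {trt: {12: 2.0, 24: 5.0, 36: 3.0, 48: 2.0} for trt in amended},
    )
    pha = Regulon(
        "pha", _fams(_PHA),
        {trt: {12: 1.5, 24: 3.0, 36: 2.0, 48: 1.5} for trt in amended},
    )
    motility = Regulon(
        "motility", _fams(_MOTILITY),
        {trt: {24: 3.0, 36: 3.0, 48: 2.0} for trt in amended},
    )
    alkyl = Regulon(
        "alkylphosphonate", _fams(_PHN_OPERON) | {"rcsF"},
        {"GlcN_MPn": {48: 12.0}},
        baseline=0.05,
    )
    phosphonatase = Regulon("phosphonatase", _fams(_PHOSPHONATASE), {}, baseline=0.1)
    csrb = Regulon(
        "csrB", frozenset({"csrB"}),
        {trt: {24: 30.0, 36: 60.0, 48: 25.0} for trt in amended},
        baseline=0.02,
    )

    def traj(control, glcn, mpn):
        return {
            "control": {tp: control for tp in (0, 12, 24, 36, 48)},
            "GlcN": dict(zip((0, 12, 24, 36, 48), glcn)),
            "GlcN_MPn": dict(zip((0, 12, 24, 36, 48), mpn)),
        }

    pro_lin = ("Bacteria", "Cyanobacteria", "Cyanophyceae", "Prochlorales",
               "Prochlorococcus marinus MIT9301")
    pel_lin = ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales",
               "Pelagibacter ubique HTCC1062")
    vspl_lin = ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Vibrionales",
                "Vibrio splendidus 12B01")
    vnig_lin = ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Vibrionales",
                "Vibrio nigripulchritudo ATCC27043")
    rose_lin = ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhodobacterales",
                "Roseobacter sp. B3TF")
    alt_lin = ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Alteromonadales",
               "Alteromonas macleodii ATCC27126")

    def genome(tid, lineage, extra_specs, srnas=("glycine_riboswitch",)):
        genes = _entries(tid, lineage, _HOUSEKEEPING + _RECA + extra_specs)
        genes += _rna_genes(tid, lineage, srnas)
        return tuple(genes)

    pro = TaxonSpec(
        "Prochlorococcus_MIT9301", pro_lin,
        genome("Prochlorococcus_MIT9301", pro_lin, _PHOTO),
        traj(0.45, (0.45, 0.35, 0.15, 0.13, 0.12), (0.45, 0.35, 0.15, 0.12, 0.14)),
    )
    pel = TaxonSpec(
        "Pelagibacter_HTCC1062", pel_lin,
        genome("Pelagibacter_HTCC1062", pel_lin, []),
        traj(0.39, (0.39, 0.31, 0.13, 0.11, 0.12), (0.39, 0.31, 0.13, 0.10, 0.12)),
    )
    vspl = TaxonSpec(
        "Vibrio_splendidus_12B01", vspl_lin,
        genome(
            "Vibrio_splendidus_12B01", vspl_lin,
            _PHO + _PTS + _PHA + _PHOSPHONATASE + _MOTILITY,
            srnas=("glycine_riboswitch", "csrB"),
        ),
        traj(0.05, (0.05, 0.25, 0.59, 0.56, 0.55), (0.05, 0.25, 0.59, 0.55, 0.20)),
        regulons=(pho, pts, pha, motility, phosphonatase, csrb),
    )
    vnig_genes = genome(
        "Vibrio_nigripulchritudo_ATCC27043", vnig_lin,
        _PHO + _PTS + _PHN_OPERON + _MOTILITY,
        srnas=("glycine_riboswitch", "csrB"),
    )
    vnig = TaxonSpec(
        "Vibrio_nigripulchritudo_ATCC27043", vnig_lin, vnig_genes,
        traj(0.005, (0.005, 0.005, 0.01, 0.02, 0.03), (0.005, 0.005, 0.01, 0.03, 0.24)),
        regulons=(pho, pts, motility, alkyl, csrb),
        carries_cp_lyase=True,
    )
    rose_extra = _PHO + [s for s in _PHN_OPERON if s[0] != "phnP"]
    rose_genes = list(
        genome("Roseobacter_B3TF", rose_lin, rose_extra)
    )
    rose_genes.append(
        CatalogEntry(
            subject_id="Roseobacter_B3TF|rcsF", taxon_id="Roseobacter_B3TF",
            lineage=rose_lin, entry_class="protein", ko_id=None,
            protein_length=181, family="rcsF",
        )
    )
    rose = TaxonSpec(
        "Roseobacter_B3TF", rose_lin, tuple(rose_genes),
        traj(0.015, (0.015, 0.015, 0.02, 0.05, 0.04), (0.015, 0.015, 0.02, 0.05, 0.22)),
        regulons=(pho, alkyl),
        carries_cp_lyase=True,
    )
    alt = TaxonSpec(
        "Alteromonas_macleodii_ATCC27126", alt_lin,
        genome("Alteromonas_macleodii_ATCC27126", alt_lin, _PHO),
        traj(0.09, (0.09, 0.07, 0.10, 0.13, 0.14), (0.09, 0.07, 0.10, 0.15, 0.08)),
        regulons=(pho,),
    )

    return CommunityScenario(
        taxa=(pro, pel, vspl, vnig, rose, alt),
        timepoints_h=(0, 12, 24, 36, 48),
        treatments=("control", "GlcN", "GlcN_MPn"),
        pathways=default_pathways(),
        seed=seed,
        reads_per_library=reads_per_library,
        name="microcosm_succession",
    )


def carriage_scenario(
    carriage: float, seed: int = 0, reads_per_library: int = 6000
) -> CommunityScenario:
    """Minimal two-taxon scenario with a known C-P lyase carriage fraction,
    for calibration of the recA-normalized statistic."""
    if not 0.0 < carriage < 1.0:
        raise ScenarioError("carriage must be in (0, 1)")
    lin_a = ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Vibrionales",
             "Carrier sp. A")
    lin_b = ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales",
             "Noncarrier sp. B")
    carrier = TaxonSpec(
        "Carrier_A", lin_a,
        tuple(
            _entries("Carrier_A", lin_a, _HOUSEKEEPING + _RECA + _PHN_OPERON)
            + _rna_genes("Carrier_A", lin_a, ("glycine_riboswitch",))
        ),
        {"control": {0: carriage}},
        carries_cp_lyase=True,
    )
    noncarrier = TaxonSpec(
        "Noncarrier_B", lin_b,
        tuple(
            _entries("Noncarrier_B", lin_b, _HOUSEKEEPING + _RECA)
            + _rna_genes("Noncarrier_B", lin_b, ("glycine_riboswitch",))
        ),
        {"control": {0: 1.0 - carriage}},
    )
    return CommunityScenario(
        taxa=(carrier, noncarrier),
        timepoints_h=(0,),
        treatments=("control",),
        pathways=default_pathways(),
        seed=seed,
        reads_per_library=reads_per_library,
        ambiguity_rate=0.0,
        secondary_hit_rate=0.0,
        name=f"carriage_{carriage:g}",
    )


def null_ko_profiles(
    n_features: int, depth: int, seed: int
) -> tuple[KOProfile, KOProfile]:
    """Two KO profiles drawn from one multinomial distribution (null pair).

    Feature probabilities follow a seeded lognormal rank-abundance curve,
    so most features have small expected counts, as in real KO tables.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x6E756C6C)))
    probs = rng.lognormal(0.0, 1.5, n_features)
    probs /= probs.sum()
    kos = [f"K{i:05d}" for i in range(n_features)]
    profiles = []
    for lib in ("null_A", "null_B"):
        counts = rng.multinomial(depth, probs)
        weight = {kos[i]: float(c) for i, c in enumerate(counts) if c > 0}
        profiles.append(KOProfile(lib, weight, depth, 0))
    return profiles[0], profiles[1]


# ---------------------------------------------------------------------------
# Scenario (de)serialization


def scenario_to_dict(scenario: CommunityScenario) -> dict:
    def entry_d(e: CatalogEntry) -> dict:
        return {
            "subject_id": e.subject_id,
            "taxon_id": e.taxon_id,
            "lineage": list(e.lineage),
            "entry_class": e.entry_class,
            "ko_id": e.ko_id,
            "protein_length": e.protein_length,
            "family": e.family,
        }

    def regulon_d(r: Regulon) -> dict:
        return {
            "name": r.name,
            "families": sorted(r.families),
            "induction": {
                trt: {int(tp): float(m) for tp, m in d.items()}
                for trt, d in r.induction.items()
            },
            "baseline": r.baseline,
        }

    return {
        "name": scenario.name,
        "seed": scenario.seed,
        "reads_per_library": scenario.reads_per_library,
        "timepoints_h": list(scenario.timepoints_h),
        "treatments": list(scenario.treatments),
        "rRNA_fraction_rna": scenario.rRNA_fraction_rna,
        "sRNA_fraction_rna": scenario.sRNA_fraction_rna,
        "ambiguity_rate": scenario.ambiguity_rate,
        "unassigned_rate": scenario.unassigned_rate,
        "secondary_hit_rate": scenario.secondary_hit_rate,
        "pathways": [
            {
                "pathway_id": p.pathway_id,
                "name": p.name,
                "member_kos": sorted(p.member_kos),
                "custom": p.custom,
            }
            for p in scenario.pathways
        ],
        "taxa": [
            {
                "taxon_id": t.taxon_id,
                "lineage": list(t.lineage),
                "carries_cp_lyase": t.carries_cp_lyase,
                "genes": [entry_d(g) for g in t.genes],
                "abundance_trajectory": {
                    trt: {int(tp): float(a) for tp, a in d.items()}
                    for trt, d in t.abundance_trajectory.items()
                },
                "regulons": [regulon_d(r) for r in t.regulons],
            }
            for t in scenario.taxa
        ],
    }


def scenario_from_dict(data: Mapping) -> CommunityScenario:
    pathways = tuple(
        Pathway(p["pathway_id"], p["name"], frozenset(p["member_kos"]), bool(p["custom"]))
        for p in data["pathways"]
    )
    taxa = []
    for td in data["taxa"]:
        genes = tuple(
            CatalogEntry(
                subject_id=g["subject_id"],
                taxon_id=g["taxon_id"],
                lineage=tuple(g["lineage"]),
                entry_class=g["entry_class"],
                ko_id=g.get("ko_id"),
                protein_length=g.get("protein_length"),
                family=g.get("family"),
            )
            for g in td["genes"]
        )
        regulons = tuple(
            Regulon(
                r["name"],
                frozenset(r["families"]),
                {trt: {int(tp): float(m) for tp, m in d.items()}
                 for trt, d in r["induction"].items()},
                float(r.get("baseline", 1.0)),
            )
            for r in td.get("regulons", ())
        )
        taxa.append(
            TaxonSpec(
                taxon_id=td["taxon_id"],
                lineage=tuple(td["lineage"]),
                genes=genes,
                abundance_trajectory={
                    trt: {int(tp): float(a) for tp, a in d.items()}
                    for trt, d in td["abundance_trajectory"].items()
                },
                regulons=regulons,
                carries_cp_lyase=bool(td.get("carries_cp_lyase", False)),
            )
        )
    return CommunityScenario(
        taxa=tuple(taxa),
        timepoints_h=tuple(int(t) for t in data["timepoints_h"]),
        treatments=tuple(data["treatments"]),
        pathways=pathways,
        seed=int(data.get("seed", 0)),
        reads_per_library=int(data.get("reads_per_library", 20000)),
        rRNA_fraction_rna=float(data.get("rRNA_fraction_rna", 0.40)),
        sRNA_fraction_rna=float(data.get("sRNA_fraction_rna", 0.05)),
        ambiguity_rate=float(data.get("ambiguity_rate", 0.05)),
        unassigned_rate=float(data.get("unassigned_rate", 0.10)),
        secondary_hit_rate=float(data.get("secondary_hit_rate", 0.30)),
        name=str(data.get("name", "scenario")),
    )


def save_scenario(scenario: CommunityScenario, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)


def load_scenario(path: str | Path) -> CommunityScenario:
    with open(path, "r", encoding="utf-8") as fh:
        return scenario_from_dict(yaml.safe_load(fh))
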