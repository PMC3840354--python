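"""End-to-end orchestration: simulate -> partition -> profiles ->
differential abundance -> gene families / expression ratios / cluster
annotation, with every stage's output persisted so any stage can be re-run
independently.  Re-running with the same configuration reproduces
byte-identical outputs (no stage reads wall-clock or environment state).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import Catalog, LibraryManifest, read_hit_table, read_catalog, read_manifests
from .datasets import fosmid_clusters
from .diffabund import compare_libraries
from .expression import expression_ratios, group_ratio_comparison, ratios_frame
from .functional import aggregate_pathways, cluster_samples, profile_kos, profile_srna
from .genefamily import attribute_families, family_abundance, family_group_mean, family_table
from .partition import partition
from .phncluster import annotation_report
from .simulate import SimulationResult, default_scenario, load_scenario, simulate
from .taxonomy import profile_taxa

__all__ = ["RunConfig", "PipelineError", "run_all", "load_run"]

log = logging.getLogger("mpnpipe")

#: Gene families tabulated by the gene-family stage (those present in the
#: default scenario's catalog).
DEFAULT_FAMILIES = ("phnG", "phnH", "phnI", "phnJ", "phnM", "phnN", "phnW", "phnX")
CP_LYASE_SIX = ("phnG", "phnH", "phnI", "phnJ", "phnM", "phnN")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Thresholds default to the study's stated values: bit score 50,
    identity 95%, FDR alpha 0.05, pathway retention 1%, taxon report 3%."""

    outdir: str = "pipeline_out"
    scenario: str = "default"          # "default" or a scenario YAML path
    hits_dir: str | None = None        # pre-simulated run directory instead
    seed: int = 13
    reads_per_library: int | None = None
    bit_score_threshold: float = 50.0
    identity_threshold: float = 95.0
    alpha: float = 0.05
    min_pathway_fraction: float = 1.0
    min_report_fraction: float = 3.0
    rank: str = "order"


def load_run(run_dir: str | Path) -> tuple[Catalog, list[LibraryManifest], dict]:
    """Load a persisted simulation directory (manifests, catalog, hit tables)."""
    run_dir = Path(run_dir)
    if not run_dir.is_dir():
        raise PipelineError(f"hits directory not found: {run_dir}")
    catalog = read_catalog(run_dir / "catalog_entries.tsv", run_dir / "catalog_pathways.tsv")
    manifests = read_manifests(run_dir / "manifests.tsv")
    tables: dict[str, dict[str, pd.DataFrame]] = {}
    for m in manifests:
        tables[m.library_id] = {}
        for cat in ("rRNA", "sRNA", "protein", "kegg"):
            path = run_dir / f"{m.library_id}.{cat}.tsv"
            if not path.exists():
                raise PipelineError(f"missing hit table: {path}")
            tables[m.library_id][cat] = read_hit_table(path, cat)
    return catalog, manifests, tables


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_all(config: RunConfig) -> dict:
    """Run every stage and return (and persist) the output manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict[str, str] = {}

    try:
        log.info("mpnpipe %s seed=%s thresholds: b>=%s id>=%s alpha=%s",
                 __version__, config.seed, config.bit_score_threshold,
                 config.identity_threshold, config.alpha)

        # ------------------------------------------------------------ inputs
        if config.hits_dir is not None:
            catalog, manifests, tables = load_run(config.hits_dir)
        else:
            if config.scenario == "default":
                scenario = default_scenario(seed=config.seed)
            else:
                scenario = load_scenario(config.scenario)
                scenario.seed = config.seed
            if config.reads_per_library:
                scenario.reads_per_library = config.reads_per_library
            sim = _stage("simulate")(simulate)(scenario)
            sim_dir = outdir / "sim"
            sim.write(sim_dir)
            outputs["simulation"] = str(sim_dir)
            catalog, manifests, tables = sim.catalog, sim.manifests, sim.hit_tables

        thr = config.bit_score_threshold

        # --------------------------------------------------------- partition
        parts = {}
        for m in manifests:
            parts[m.library_id] = _stage("partition")(partition)(
                tables[m.library_id], m, threshold=thr
            )
        part_df = pd.concat([p.summary_frame() for p in parts.values()], ignore_index=True)
        part_df.to_csv(outdir / "partition_summary.tsv", sep="\t", index=False)
        outputs["partition_summary"] = "partition_summary.tsv"

        # ---------------------------------------------------------- taxonomy
        tax_frames = []
        for m in manifests:
            prof = _stage("tax-profile")(profile_taxa)(
                tables[m.library_id]["protein"], catalog, rank=config.rank,
                threshold=thr, library_id=m.library_id,
                restrict_reads=parts[m.library_id].reads_in_class("protein"),
            )
            tax_frames.append(prof.to_frame())
        pd.concat(tax_frames, ignore_index=True).to_csv(
            outdir / "taxonomic_profiles.tsv", sep="\t", index=False
        )
        outputs["taxonomic_profiles"] = "taxonomic_profiles.tsv"

        # ------------------------------------------------------- KO profiles
        rna_libs = [m for m in manifests if m.molecule == "RNA"]
        ko_profiles = {}
        for m in rna_libs:
            ko_profiles[m.library_id] = _stage("ko-profile")(profile_kos)(
                tables[m.library_id]["kegg"], catalog,
                partition=parts[m.library_id], threshold=thr,
                library_id=m.library_id,
            )
        pd.concat(
            [p.to_frame() for p in ko_profiles.values()], ignore_index=True
        ).to_csv(outdir / "ko_profiles.tsv", sep="\t", index=False)
        outputs["ko_profiles"] = "ko_profiles.tsv"

        # ------------------------------------------------- pathways + tree
        matrix = _stage("pathway-aggregate")(aggregate_pathways)(
            list(ko_profiles.values()), catalog.pathways,
            min_fraction=config.min_pathway_fraction,
        )
        matrix.values.to_csv(outdir / "pathway_matrix.tsv", sep="\t")
        matrix.row_normalized_view.to_csv(outdir / "pathway_matrix_rownorm.tsv", sep="\t")
        tree = _stage("pathway-cluster")(cluster_samples)(matrix)
        (outdir / "dendrogram.nwk").write_text(tree.newick + "\n", encoding="utf-8")
        outputs["pathway_matrix"] = "pathway_matrix.tsv"
        outputs["dendrogram"] = "dendrogram.nwk"

        # ------------------------------------------------------ sRNA profile
        srna_rows = []
        for m in rna_libs:
            fams = profile_srna(
                tables[m.library_id]["sRNA"], parts[m.library_id], catalog, threshold=thr
            )
            for fam, pct in sorted(fams.items()):
                srna_rows.append(
                    {"library_id": m.library_id, "family": fam,
                     "percent_of_non_rRNA": pct}
                )
        pd.DataFrame(srna_rows).to_csv(outdir / "srna_profiles.tsv", sep="\t", index=False)
        outputs["srna_profiles"] = "srna_profiles.tsv"

        # --------------------------------------------- differential abundance
        diff_rows = []
        control_rna = {
            m.timepoint_h: m for m in rna_libs if m.treatment == "control"
        }
        for m in rna_libs:
            if m.treatment == "control" or m.timepoint_h not in control_rna:
                continue
            ctrl = control_rna[m.timepoint_h]
            comp = _stage("diff")(compare_libraries)(
                ko_profiles[m.library_id], ko_profiles[ctrl.library_id],
                alpha=config.alpha,
            )
            name = f"diff_{m.treatment}_vs_control_{m.timepoint_h:02d}h.tsv"
            comp.results.to_csv(outdir / name, sep="\t", index=False)
            diff_rows.append(
                {"treatment": m.treatment, "timepoint_h": m.timepoint_h,
                 "n_tested": comp.n_tested,
                 "significant_fraction": comp.significant_fraction}
            )
        pd.DataFrame(diff_rows).to_csv(
            outdir / "significant_fractions.tsv", sep="\t", index=False
        )
        outputs["significant_fractions"] = "significant_fractions.tsv"

        # ----------------------------------------------------- gene families
        dna_libs = [m for m in manifests if m.molecule == "DNA"]
        families = [f for f in DEFAULT_FAMILIES if catalog.by_family(f)]
        per_lib = {}
        for m in dna_libs:
            try:
                per_lib[m.library_id] = _stage("gene-family")(family_abundance)(
                    tables[m.library_id]["protein"], catalog, families,
                    threshold=thr, library_id=m.library_id,
                )
            except PipelineError:
                raise
        if per_lib:
            ftab = family_table(per_lib, [*families, "recA"])
            ftab.to_csv(outdir / "family_table.tsv", sep="\t")
            outputs["family_table"] = "family_table.tsv"
            six = [f for f in CP_LYASE_SIX if f in families]
            mean_rows = [
                {"library_id": lib,
                 "cp_lyase_mean_percent": family_group_mean(ab, six)}
                for lib, ab in per_lib.items()
            ]
            pd.DataFrame(mean_rows).to_csv(
                outdir / "cp_lyase_means.tsv", sep="\t", index=False
            )
            outputs["cp_lyase_means"] = "cp_lyase_means.tsv"

        # ------------------------------------------------------- attribution
        final_dna = [m for m in dna_libs if m.treatment == "GlcN_MPn"]
        if final_dna:
            m = max(final_dna, key=lambda x: x.timepoint_h)
            attr = attribute_families(
                tables[m.library_id]["protein"], catalog, list(CP_LYASE_SIX),
                threshold=thr, rank=config.rank,
            )
            pd.DataFrame(
                sorted(attr.items()), columns=["taxon", "percent_of_hits"]
            ).to_csv(outdir / "cp_lyase_attribution.tsv", sep="\t", index=False)
            outputs["cp_lyase_attribution"] = "cp_lyase_attribution.tsv"

        # ------------------------------------------------- expression ratios
        exp = _expression_stage(config, catalog, manifests, tables, parts, outdir)
        outputs.update(exp)

        # ------------------------------------------------ cluster annotation
        reports = {cid: annotation_report(c) for cid, c in fosmid_clusters().items()}
        with open(outdir / "cluster_annotations.json", "w", encoding="utf-8") as fh:
            json.dump(reports, fh, indent=2, sort_keys=True)
        outputs["cluster_annotations"] = "cluster_annotations.json"

        manifest = {
            "tool": "mpnpipe",
            "version": __version__,
            "config": asdict(config),
            "outputs": dict(sorted(outputs.items())),
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()


# families standing in for the non-phosphonate genes carried on recovered
# cluster fragments (operon flanks)
_FLANK_FAMILIES = frozenset(
    {"rplA", "rplB", "rplM", "rplN", "rplO", "rplV",
     "glk", "pgi", "pfkA", "fba", "gap", "pyk",
     "gltA", "acnA", "icd", "sucD", "sdhA", "fumA"}
)
_PHN_FAMILIES = frozenset(
    {"phnC", "phnD", "phnE", "phnF", "phnG", "phnH", "phnI", "phnJ",
     "phnK", "phnL", "phnM", "phnN", "phnO", "phnP", "rcsF"}
)


def _expression_stage(config, catalog, manifests, tables, parts, outdir) -> dict:
    rna = [m for m in manifests if m.molecule == "RNA" and m.treatment == "GlcN_MPn"]
    dna = [m for m in manifests if m.molecule == "DNA" and m.treatment == "GlcN_MPn"]
    if not rna or not dna:
        return {}
    m_rna = max(rna, key=lambda m: m.timepoint_h)
    m_dna = max(dna, key=lambda m: m.timepoint_h)

    carrier_taxa = set()
    for e in catalog.entries.values():
        if e.family in _PHN_FAMILIES and e.entry_class == "protein":
            carrier_taxa.add(e.taxon_id)
    gene_entries = [
        e for e in catalog.entries.values()
        if e.taxon_id in carrier_taxa and e.entry_class == "protein"
        and (e.family in _PHN_FAMILIES or e.family in _FLANK_FAMILIES)
    ]
    if not gene_entries:
        return {}
    from dataclasses import replace
    gene_table = Catalog([replace(e, pathways=frozenset()) for e in gene_entries])

    part = parts[m_rna.library_id]
    rna_total = part.n_total - part.n_rRNA - part.n_sRNA
    ratios = _stage("expr-ratio")(expression_ratios)(
        tables[m_rna.library_id]["protein"], tables[m_dna.library_id]["protein"],
        gene_table, rna_total=rna_total, dna_total=m_dna.total_reads,
        id_threshold=config.identity_threshold,
        score_threshold=config.bit_score_threshold,
    )
    ratios_frame(ratios).to_csv(outdir / "expression_ratios.tsv", sep="\t", index=False)
    comp = group_ratio_comparison(ratios)
    with open(outdir / "expression_groups.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "rna_library": m_rna.library_id,
                "dna_library": m_dna.library_id,
                "mean_ratio": comp.mean_ratio,
                "median_ratio": comp.median_ratio,
                "n_defined": comp.n_defined,
                "n_undefined": comp.n_undefined,
                "fold_cp_lyase_over_other": comp.fold,
            },
            fh, indent=2, sort_keys=True,
        )
    return {
        "expression_ratios": "expression_ratios.tsv",
        "expression_groups": "expression_groups.json",
    }
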