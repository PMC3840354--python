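import numpy as np
import pandas as pd
import pytest

from mpnpipe.catalog import CatalogEntry
from mpnpipe.simulate import (
    CommunityScenario,
    ScenarioError,
    TaxonSpec,
    build_catalog,
    carriage_scenario,
    default_pathways,
    default_scenario,
    load_scenario,
    save_scenario,
    simulate,
)
from mpnpipe.taxonomy import profile_taxa

from conftest import make_entry


def _mini_scenario(**kwargs):
    lin = ("Bacteria", "PhylumX", "ClassX", "OrderA", "Solo sp.")
    genes = tuple(
        [
            CatalogEntry("Solo|recA", "Solo", lin, "protein", "K03553", frozenset(), 353, "recA"),
            CatalogEntry("Solo|gap", "Solo", lin, "protein", "K00134", frozenset(), 331, "gap"),
            CatalogEntry("Solo|16S", "Solo", lin, "rRNA", None, frozenset(), 1500, "16S"),
            CatalogEntry("Solo|gly", "Solo", lin, "sRNA", None, frozenset(), 110,
                         "glycine_riboswitch"),
        ]
    )
    taxon = TaxonSpec("Solo", lin, genes, {"control": {0: 1.0}})
    defaults = dict(
        taxa=(taxon,),
        timepoints_h=(0,),
        treatments=("control",),
        pathways=default_pathways(),
        seed=5,
        reads_per_library=2000,
        ambiguity_rate=0.0,
        unassigned_rate=0.0,
        secondary_hit_rate=0.0,
    )
    defaults.update(kwargs)
    return CommunityScenario(**defaults)


class TestScenarioValidation:
    def test_abundances_must_sum_to_one(self):
        lin = ("Bacteria", "P", "C", "O", "S")
        genes = (make_entry("T|recA", taxon="T", family="recA", length=353),)
        taxon = TaxonSpec("T", lin, genes, {"control": {0: 0.7}})
        sc = _mini_scenario(taxa=(taxon,))
        with pytest.raises(ScenarioError, match="sum to"):
            sc.validate()

    def test_empty_genome_rejected(self):
        taxon = TaxonSpec("T", ("B",), (), {"control": {0: 1.0}})
        with pytest.raises(ScenarioError, match="empty genome"):
            _mini_scenario(taxa=(taxon,)).validate()

    def test_carriage_flag_must_match_gene_content(self):
        lin = ("B", "P", "C", "O", "S")
        genes = (make_entry("T|recA", taxon="T", family="recA", length=353),)
        taxon = TaxonSpec("T", lin, genes, {"control": {0: 1.0}}, carries_cp_lyase=True)
        with pytest.raises(ScenarioError, match="carries_cp_lyase"):
            _mini_scenario(taxa=(taxon,)).validate()

    def test_fraction_bounds(self):
        with pytest.raises(ScenarioError):
            _mini_scenario(rRNA_fraction_rna=0.7, sRNA_fraction_rna=0.4).validate()

    def test_default_scenario_is_valid(self):
        default_scenario().validate()


class TestSimulate:
    def test_same_seed_is_byte_identical(self, tmp_path):
        sc = _mini_scenario()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate(sc).write(d1)
        simulate(_mini_scenario()).write(d2)
        for p1 in sorted(d1.iterdir()):
            assert (d2 / p1.name).read_bytes() == p1.read_bytes()

    def test_different_seed_differs(self):
        t1 = simulate(_mini_scenario(seed=1)).hit_tables["control_00h_DNA"]["protein"]
        t2 = simulate(_mini_scenario(seed=2)).hit_tables["control_00h_DNA"]["protein"]
        assert not t1.equals(t2)

    def test_reads_per_library_conserved_exactly(self):
        sim = simulate(_mini_scenario(unassigned_rate=0.2))
        for lib, tables in sim.hit_tables.items():
            read_ids = set()
            for df in tables.values():
                read_ids.update(df["read_id"])
            assert len(read_ids) == sim.scenario.reads_per_library

    def test_single_taxon_profile_is_pure(self):
        sim = simulate(_mini_scenario())
        prof = profile_taxa(
            sim.hit_tables["control_00h_RNA"]["protein"], sim.catalog, rank="order"
        )
        assert prof.abundance == {"OrderA": 100.0}

    def test_rna_class_fractions_near_targets(self):
        sim = simulate(_mini_scenario(reads_per_library=20000))
        truth = sim.ground_truth["libraries"]["control_00h_RNA"]["realized_class_counts"]
        assert truth["rRNA"] / 20000 == pytest.approx(0.40, abs=0.02)
        assert truth["sRNA"] / 20000 == pytest.approx(0.05, abs=0.01)

    def test_sub_threshold_reads_respect_rate(self):
        sim = simulate(_mini_scenario(unassigned_rate=0.25, reads_per_library=20000))
        truth = sim.ground_truth["libraries"]["control_00h_DNA"]["realized_class_counts"]
        assert truth["unassigned"] / 20000 == pytest.approx(0.25, abs=0.02)
        df = sim.hit_tables["control_00h_DNA"]["protein"]
        weak = df[df["bit_score"] < 50.0]
        assert len(weak) == truth["unassigned"]

    def test_ambiguous_reads_are_same_ko_cross_taxon_pairs(self, default_sim):
        lib = "GlcN_24h_RNA"
        df = default_sim.hit_tables[lib]["protein"]
        cat = default_sim.catalog
        sizes = df.groupby("read_id").size()
        multi = df[df["read_id"].isin(sizes[sizes > 1].index)]
        n_checked = 0
        for read, grp in multi.groupby("read_id"):
            top = grp[grp["bit_score"] == grp["bit_score"].max()]
            if len(top) < 2:
                continue
            entries = [cat.entry(s) for s in top["subject_id"]]
            assert len({e.ko_id for e in entries}) == 1
            assert len({e.taxon_id for e in entries}) == len(entries)
            n_checked += 1
        assert n_checked == default_sim.ground_truth["libraries"][lib]["n_tied_reads"]


class TestDefaultScenario:
    def test_mpn_arm_endpoint_carriage(self):
        """C-P lyase carriage reaches >=30% of cells at the MPn endpoint but
        stays marginal in the other arms."""
        sc = default_scenario()
        assert sc.carriage("GlcN_MPn", 48) >= 0.3
        assert sc.carriage("control", 48) < 0.05
        assert sc.carriage("GlcN", 48) < 0.10
        assert sc.carriage("GlcN_MPn", 0) < 0.05

    def test_control_abundances_constant_over_time(self):
        sc = default_scenario()
        for taxon in sc.taxa:
            vals = {taxon.abundance("control", tp) for tp in sc.timepoints_h}
            assert len(vals) == 1

    def test_structure(self):
        sc = default_scenario()
        assert len(sc.taxa) >= 6
        assert sc.timepoints_h == (0, 12, 24, 36, 48)
        assert set(sc.treatments) == {"control", "GlcN", "GlcN_MPn"}
        fams = {f for t in sc.taxa for r in t.regulons for f in r.families}
        assert {"pstS", "phoA", "phoX", "phoB", "phoR"} <= fams

    def test_alkylphosphonate_regulon_mpn_arm_only(self):
        sc = default_scenario()
        carriers = [t for t in sc.taxa if t.carries_cp_lyase]
        assert len(carriers) == 2
        for t in carriers:
            assert t.induction("phnJ", "GlcN_MPn", 48) > 5.0
            assert t.induction("phnJ", "GlcN", 48) < 1.0
            assert t.induction("phnJ", "control", 48) < 1.0

    def test_catalog_builds_and_validates(self):
        cat = build_catalog(default_scenario())
        assert "Vibrio_nigripulchritudo_ATCC27043|phnJ" in cat
        assert cat.pathways["path:alkylphosphonate"].custom


class TestScenarioIO:
    def test_yaml_round_trip_reproduces_simulation(self, tmp_path):
        sc = carriage_scenario(0.3, seed=3, reads_per_library=1500)
        path = tmp_path / "scenario.yaml"
        save_scenario(sc, path)
        back = load_scenario(path)
        t1 = simulate(sc).hit_tables["control_00h_DNA"]["protein"]
        t2 = simulate(back).hit_tables["control_00h_DNA"]["protein"]
        pd.testing.assert_frame_equal(t1, t2)

    def test_carriage_scenario_bounds(self):
        with pytest.raises(ScenarioError):
            carriage_scenario(0.0)
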