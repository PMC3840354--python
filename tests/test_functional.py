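import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from mpnpipe.catalog import Catalog, LibraryManifest, Pathway
from mpnpipe.functional import (
    KOProfile,
    aggregate_pathways,
    cluster_samples,
    profile_kos,
    profile_srna,
)
from mpnpipe.partition import partition

from conftest import hits, make_entry


@pytest.fixture
def ko_catalog():
    return Catalog(
        [
            make_entry("A_k1", taxon="TaxonA", ko="K00001"),
            make_entry("B_k2", taxon="TaxonB", ko="K00002"),
            make_entry("C_k2", taxon="TaxonC", ko="K00002"),
            make_entry("D_nok", taxon="TaxonD"),
        ]
    )


class TestProfileKOs:
    def test_two_way_tie_splits_half(self, ko_catalog):
        df = hits([("r1", "A_k1", 60.0), ("r1", "B_k2", 60.0)], catalog="kegg")
        prof = profile_kos(df, ko_catalog)
        assert prof.weight == {"K00001": 0.5, "K00002": 0.5}
        assert prof.n_kegg_assigned == 1

    def test_single_hit_full_weight(self, ko_catalog):
        prof = profile_kos(hits([("r1", "A_k1", 60.0)], catalog="kegg"), ko_catalog)
        assert prof.weight == {"K00001": 1.0}

    def test_hand_enumeration_three_reads(self, ko_catalog):
        """K1-only; K1/K2 tie; same-KO two-subject tie -> K1: 1.5, K2: 1.5."""
        df = hits(
            [
                ("r1", "A_k1", 60.0),
                ("r2", "A_k1", 70.0), ("r2", "B_k2", 70.0),
                ("r3", "B_k2", 90.0), ("r3", "C_k2", 90.0),
            ],
            catalog="kegg",
        )
        prof = profile_kos(df, ko_catalog)
        assert prof.weight["K00001"] == pytest.approx(1.5)
        assert prof.weight["K00002"] == pytest.approx(1.5)
        assert prof.n_kegg_assigned == 3

    def test_top_hit_without_ko_counted_unassigned(self, ko_catalog):
        df = hits([("r1", "D_nok", 90.0), ("r1", "A_k1", 60.0)], catalog="kegg")
        prof = profile_kos(df, ko_catalog)
        assert prof.n_kegg_assigned == 0
        assert prof.n_no_ko == 1

    def test_rrna_reads_excluded_via_partition(self, ko_catalog):
        kegg = hits([("r1", "A_k1", 60.0), ("r2", "A_k1", 60.0)], catalog="kegg")
        rrna = hits([("r1", "A_k1", 99.0)], catalog="rRNA")
        m = LibraryManifest("lib", "control", 0, "RNA", 2)
        part = partition({"rRNA": rrna, "kegg": kegg}, m)
        prof = profile_kos(kegg, ko_catalog, partition=part)
        assert prof.n_kegg_assigned == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        rows=st.lists(
            st.tuples(st.integers(0, 8), st.sampled_from(["A_k1", "B_k2", "C_k2"]),
                      st.sampled_from([55.0, 60.0, 75.0])),
            min_size=1, max_size=40, unique=True,
        )
    )
    def test_tie_splitting_conserves_mass(self, rows):
        catalog = Catalog(
            [
                make_entry("A_k1", taxon="TaxonA", ko="K00001"),
                make_entry("B_k2", taxon="TaxonB", ko="K00002"),
                make_entry("C_k2", taxon="TaxonC", ko="K00002"),
            ]
        )
        df = hits([(f"r{i}", s, b) for i, s, b in rows], catalog="kegg")
        prof = profile_kos(df, catalog)
        assert sum(prof.weight.values()) == pytest.approx(prof.n_kegg_assigned, abs=1e-6)

    def test_mass_conservation_on_simulated_libraries(self, rna_ko_profiles):
        for prof in rna_ko_profiles.values():
            assert sum(prof.weight.values()) == pytest.approx(
                prof.n_kegg_assigned, abs=1e-6
            )


class TestAggregatePathways:
    def _profiles(self):
        # 1000 KEGG-assigned reads; K1 0.4%, K2 0.7%
        return [KOProfile("lib1", {"K1": 4.0, "K2": 7.0, "K3": 989.0}, 1000)]

    def test_member_percent_sum_and_retention(self):
        pws = {
            "pw": Pathway("pw", "two KOs", frozenset({"K1", "K2"})),
            "rest": Pathway("rest", "rest", frozenset({"K3"})),
        }
        mat = aggregate_pathways(self._profiles(), pws, min_fraction=1.0)
        assert mat.values.loc["pw", "lib1"] == pytest.approx(1.1)
        assert "pw" in mat.retained

    def test_absent_pathway_zero_and_excluded(self):
        pws = {
            "gone": Pathway("gone", "absent", frozenset({"K9"})),
            "rest": Pathway("rest", "rest", frozenset({"K3"})),
        }
        mat = aggregate_pathways(self._profiles(), pws, min_fraction=1.0)
        assert mat.values.loc["gone", "lib1"] == 0.0
        assert "gone" not in mat.retained
        with pytest.raises(ValueError, match="no member KO"):
            aggregate_pathways(self._profiles(), pws, on_empty_pathway="error")

    def test_shared_ko_counts_fully_in_each_pathway(self):
        pws = {
            "p1": Pathway("p1", "a", frozenset({"K1"})),
            "p2": Pathway("p2", "b", frozenset({"K1", "K2"})),
        }
        mat = aggregate_pathways(self._profiles(), pws, min_fraction=0.0)
        assert mat.values.loc["p1", "lib1"] == pytest.approx(0.4)
        assert mat.values.loc["p2", "lib1"] == pytest.approx(1.1)

    def test_row_normalized_view_preserves_row_order(self):
        pws = {"p": Pathway("p", "p", frozenset({"K1", "K2", "K3"}))}
        profs = [
            KOProfile("l1", {"K1": 10.0}, 100),
            KOProfile("l2", {"K1": 50.0}, 100),
            KOProfile("l3", {"K1": 30.0}, 100),
        ]
        mat = aggregate_pathways(profs, pws, min_fraction=0.0)
        raw = mat.clustering_view.loc["p"]
        z = mat.row_normalized_view.loc["p"]
        assert list(raw.sort_values().index) == list(z.sort_values().index)


class TestClusterSamples:
    def test_duplicate_libraries_merge_first_at_zero(self):
        mat = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [3.0, 1.0, 2.0]},
            index=["p1", "p2", "p3"],
        )
        tree = cluster_samples(mat)
        d, x, y = tree.merges[0]
        assert d == pytest.approx(0.0, abs=1e-12)
        assert {x[0], y[0]} == {"a", "b"}

    def test_anticorrelated_distance_two(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        tree = cluster_samples(mat)
        assert tree.merges[-1][0] == pytest.approx(2.0)

    def test_matches_scipy_average_linkage(self):
        """Independent oracle: scipy's UPGMA on the same Pearson distances
        yields the same cophenetic structure (tie-free random input)."""
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(
            rng.random((8, 6)), columns=[f"l{i}" for i in range(6)]
        )
        tree = cluster_samples(mat)
        dist = 1.0 - np.corrcoef(mat.to_numpy().T)
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        coph = squareform(cophenet(Z))
        # cophenetic distance between every library pair must agree
        labels = list(mat.columns)
        heights = {}
        for d, a, b in tree.merges:
            for la in a:
                for lb in b:
                    heights[frozenset((la, lb))] = d
        for i in range(6):
            for j in range(i + 1, 6):
                key = frozenset((labels[i], labels[j]))
                assert heights[key] == pytest.approx(coph[i, j], abs=1e-9)

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.random((6, 5)), columns=list("abcde"))
        t1 = cluster_samples(mat)
        t2 = cluster_samples(mat[["d", "b", "e", "a", "c"]])
        assert t1.newick == t2.newick

    def test_invariant_to_row_scaling(self):
        """Pearson distance is scale-invariant per library... and per-row
        rescaling of the matrix leaves correlations over rows unchanged only
        up to weighting; assert invariance to global scaling."""
        rng = np.random.default_rng(11)
        mat = pd.DataFrame(rng.random((6, 5)), columns=list("abcde"))
        assert cluster_samples(mat).newick == cluster_samples(mat * 7.5).newick

    def test_zero_variance_profile_names_library(self):
        mat = pd.DataFrame({"good": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            cluster_samples(mat)

    def test_needs_two_libraries_and_two_pathways(self):
        with pytest.raises(ValueError):
            cluster_samples(pd.DataFrame({"a": [1.0, 2.0]}))


class TestProfileSrna:
    def _setup(self, srna_rows, total=1000, n_rrna=0):
        cat = Catalog(
            [
                make_entry("csrB_1", taxon="TaxonA", entry_class="sRNA",
                           family="csrB", length=350, ko=None),
                make_entry("gly_1", taxon="TaxonA", entry_class="sRNA",
                           family="glycine_riboswitch", length=110, ko=None),
                make_entry("A_16S", taxon="TaxonA", entry_class="rRNA",
                           family="16S", length=1500, ko=None),
            ]
        )
        tables = {"sRNA": hits(srna_rows, catalog="sRNA")}
        if n_rrna:
            tables["rRNA"] = hits(
                [(f"rr{i}", "A_16S", 60.0) for i in range(n_rrna)], catalog="rRNA"
            )
        m = LibraryManifest("lib", "control", 0, "RNA", total)
        part = partition(tables, m)
        return tables, part, cat

    def test_no_hits_all_zero(self):
        tables, part, cat = self._setup([])
        assert profile_srna(tables["sRNA"], part, cat) == {
            "csrB": 0.0, "glycine_riboswitch": 0.0,
        }

    def test_csrb_percent_of_non_rrna(self):
        """40 csrB reads among 1000 non-rRNA reads -> 4%."""
        rows = [(f"r{i}", "csrB_1", 60.0) for i in range(40)]
        tables, part, cat = self._setup(rows, total=1000)
        assert profile_srna(tables["sRNA"], part, cat)["csrB"] == pytest.approx(4.0)

    def test_rrna_reads_excluded_from_denominator(self):
        rows = [(f"r{i}", "csrB_1", 60.0) for i in range(40)]
        tables, part, cat = self._setup(rows, total=1200, n_rrna=200)
        assert profile_srna(tables["sRNA"], part, cat)["csrB"] == pytest.approx(4.0)

    def test_csrb_induction_pattern_in_default_scenario(self, default_sim, default_parts):
        """csrB rises above 4% of non-rRNA reads at 36 h in the amended arms
        but stays near zero in the control."""
        cat = default_sim.catalog
        def csrb(lib):
            return profile_srna(
                default_sim.hit_tables[lib]["sRNA"], default_parts[lib], cat
            )["csrB"]
        assert csrb("GlcN_36h_RNA") > 4.0
        assert csrb("GlcN_MPn_36h_RNA") > 4.0
        assert csrb("control_36h_RNA") < 0.5
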