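"""Target-set intersection, interaction filtering, subnetwork extraction,
B-miR-net assembly, integrity partitioning and GO enrichment."""

import itertools
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bmirnet.datasets import bgene_integrity_records, load_bgene_integrity_table
from bmirnet.network import (
    ALLOWED_MI,
    GeneIntegrityRecord,
    InteractionRecord,
    assemble_bmirnet,
    enrich_terms,
    exclusive_terms,
    extract_subnetwork,
    filter_interactions,
    integrity_partition,
    intersect_target_sets,
    parse_mi_code,
)


def rec(a, b, ta=9606, tb=9606, mi="MI:0004"):
    return InteractionRecord(a, b, ta, tb, mi)


# ---------------------------------------------------------------------------
# intersect_target_sets
# ---------------------------------------------------------------------------

class TestIntersect:
    def test_three_group_intersection(self):
        shared, venn = intersect_target_sets(
            {"g1": {"A", "B", "C"}, "g2": {"B", "C"}, "g3": {"B", "C", "D"}}
        )
        assert shared == {"B", "C"}
        assert venn["g1+g2+g3"] == 2

    def test_identical_sets(self):
        s = {"X", "Y"}
        shared, _ = intersect_target_sets({"a": set(s), "b": set(s)})
        assert shared == s

    def test_empty_group_empty_intersection(self):
        shared, _ = intersect_target_sets({"a": {"X"}, "b": set()})
        assert shared == set()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            intersect_target_sets({"a": {"X"}})

    def test_case_folding(self):
        shared, _ = intersect_target_sets({"a": {"abca1"}, "b": {"ABCA1"}})
        assert shared == {"ABCA1"}


# ---------------------------------------------------------------------------
# filter_interactions
# ---------------------------------------------------------------------------

class TestFilterInteractions:
    def test_allowed_human_row_kept(self):
        edges, report = filter_interactions([rec("TP53", "MDM2")])
        assert edges == {("MDM2", "TP53")}
        assert report.n_edges == 1

    def test_duplicate_orientations_collapse(self):
        edges, report = filter_interactions([rec("A", "B"), rec("B", "A")])
        assert edges == {("A", "B")}
        assert report.n_duplicates == 1

    def test_foreign_taxid_removed(self):
        edges, report = filter_interactions([rec("A", "B", tb=10090, mi="MI:0018")])
        assert edges == set() and report.n_bad_taxid == 1

    def test_disallowed_mi_removed(self):
        edges, report = filter_interactions([rec("A", "B", mi="MI:0428")])
        assert edges == set() and report.n_bad_mi == 1

    @pytest.mark.parametrize("mi", sorted(ALLOWED_MI))
    def test_every_allowed_method_code(self, mi):
        edges, _ = filter_interactions([rec("A", "B", mi=mi)])
        assert edges == {("A", "B")}

    def test_self_loop_removed(self):
        edges, report = filter_interactions([rec("A", "A")])
        assert edges == set() and report.n_self_loops == 1

    def test_mi_token_extracted_from_free_text(self):
        assert parse_mi_code('psi-mi:"MI:0018"(two hybrid)') == "MI:0018"
        assert parse_mi_code("two hybrid") is None

    def test_idempotent(self):
        rows = [rec("A", "B"), rec("B", "A"), rec("C", "C"), rec("B", "C", mi="MI:0018")]
        edges, _ = filter_interactions(rows)
        again, report = filter_interactions(
            [rec(a, b) for a, b in edges]
        )
        assert again == edges
        assert report.n_duplicates == 0 and report.n_self_loops == 0

    def test_dataframe_input(self):
        df = pd.DataFrame(
            [("A", "B", 9606, 9606, "MI:0004"), ("A", "B", 9606, 9606, "MI:0004")],
            columns=["symbol_a", "symbol_b", "taxid_a", "taxid_b", "mi_code"],
        )
        edges, report = filter_interactions(df)
        assert edges == {("A", "B")} and report.n_duplicates == 1


# ---------------------------------------------------------------------------
# extract_subnetwork
# ---------------------------------------------------------------------------

class TestSubnetwork:
    def test_no_adjacent_seeds_empty(self):
        g = extract_subnetwork({("A", "B"), ("C", "D")}, {"A", "C"})
        assert len(g) == 0

    def test_k4_three_seeds_triangle(self):
        edges = set(itertools.combinations("ABCD", 2))
        g = extract_subnetwork(edges, {"A", "B", "C"})
        assert sorted(g.nodes) == ["A", "B", "C"]
        assert g.number_of_edges() == 3

    def test_isolated_seed_dropped(self):
        g = extract_subnetwork({("A", "B"), ("C", "D")}, {"A", "B", "C"})
        assert sorted(g.nodes) == ["A", "B"]

    def test_neighbor_expansion_mode(self):
        g = extract_subnetwork({("A", "B"), ("B", "C")}, {"A"}, neighbors=True)
        assert sorted(g.nodes) == ["A", "B"]

    def test_idempotent_on_own_nodes(self):
        edges = set(itertools.combinations("ABCDE", 2))
        g1 = extract_subnetwork(edges, {"A", "B", "C"})
        g2 = extract_subnetwork(set(g1.edges), {"A", "B", "C"})
        canon = lambda g: {tuple(sorted(e)) for e in g.edges}
        assert canon(g1) == canon(g2)

    def test_matches_brute_force_edge_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n = int(rng.integers(5, 50))
            nodes = [f"N{i}" for i in range(n)]
            edges = {
                tuple(sorted((nodes[i], nodes[j])))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.15
            }
            seeds = set(rng.choice(nodes, size=max(1, n // 3), replace=False))
            g = extract_subnetwork(edges, seeds)
            oracle_edges = {e for e in edges if e[0] in seeds and e[1] in seeds}
            oracle_nodes = {v for e in oracle_edges for v in e}
            assert set(map(tuple, map(sorted, g.edges))) == oracle_edges
            assert set(g.nodes) == oracle_nodes


# ---------------------------------------------------------------------------
# assemble_bmirnet
# ---------------------------------------------------------------------------

class TestAssemble:
    def make_subgraph(self):
        g = nx.Graph()
        g.add_edges_from([("P1", "P2"), ("P2", "P3")])
        return g

    def test_empty_regulatory_set_is_subgraph(self):
        net = assemble_bmirnet(self.make_subgraph(), [])
        assert net.mirna_nodes == set()
        assert net.n_edges == 2 and net.n_nodes == 3

    def test_edge_and_node_arithmetic(self):
        regulatory = [(m, p) for m in ("mir-a", "mir-b") for p in ("P1", "P2", "P3")]
        net = assemble_bmirnet(self.make_subgraph(), regulatory)
        assert net.n_edges == 2 + 6
        assert net.n_nodes == 3 + 2

    def test_duplicate_regulatory_edges_deduplicated(self):
        net = assemble_bmirnet(
            self.make_subgraph(), [("mir-a", "P1"), ("mir-a", "P1")]
        )
        assert len(net.regulatory_edges) == 1

    def test_unknown_target_dropped(self):
        net = assemble_bmirnet(self.make_subgraph(), [("mir-a", "UNKNOWN")])
        assert net.regulatory_edges == set()
        assert "mir-a" not in net.mirna_nodes

    def test_tissue_target_allowed_and_labeled(self):
        net = assemble_bmirnet(
            self.make_subgraph(),
            [("mir-a", "T1")],
            tissue_specific_targets={"brain": {"T1"}},
            b_genes={"P3"},
            b_related={"P1"},
        )
        assert ("mir-a", "T1") in net.regulatory_edges
        assert net.seed_provenance["T1"] == "tissue-specific target"
        assert net.seed_provenance["P3"] == "B-gene"
        assert net.seed_provenance["P1"] == "B-related"
        assert net.seed_provenance["P2"] == "neighbor"

    def test_degrees_count_both_edge_kinds(self):
        net = assemble_bmirnet(self.make_subgraph(), [("mir-a", "P2")])
        assert net.degrees()["P2"] == 3


# ---------------------------------------------------------------------------
# integrity_partition
# ---------------------------------------------------------------------------

class TestIntegrity:
    def test_bundled_table_splits_18_24(self):
        records = bgene_integrity_records()
        assert len(records) == 42
        above, below = integrity_partition(records, threshold=80.0)
        assert len(above) == 18
        assert len(below) == 24

    def test_boundary_strictly_greater(self):
        records = [
            GeneIntegrityRecord("exact", "EX", 80.0),
            GeneIntegrityRecord("just-above", "JA", 80.25),
            GeneIntegrityRecord("just-below", "JB", 79.90),
        ]
        above, below = integrity_partition(records)
        assert [r.protein_symbol for r in above] == ["JA"]
        assert {r.protein_symbol for r in below} == {"EX", "JB"}

    def test_empty_input(self):
        assert integrity_partition([]) == ([], [])

    def test_partition_is_total(self):
        records = bgene_integrity_records()
        above, below = integrity_partition(records, threshold=70.0)
        assert len(above) + len(below) == len(records)
        assert [r.integrity for r in above] == sorted(
            (r.integrity for r in above), reverse=True
        )

    def test_out_of_range_integrity_rejected(self):
        with pytest.raises(ValueError, match="bad"):
            GeneIntegrityRecord("bad", "BD", 101.0)

    def test_known_borderline_genes(self):
        df = load_bgene_integrity_table()
        by_symbol = df.set_index("protein_symbol")["integrity"]
        assert by_symbol["ABCA1"] == 80.25   # counted as intact
        assert by_symbol["HNRPQ"] == 79.90   # counted as truncated


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

class TestEnrichment:
    def test_selected_equals_background_p_one(self):
        genes = {f"g{i}" for i in range(10)}
        ann = {g: {"T1"} for g in list(genes)[:4]}
        results = enrich_terms(genes, genes, ann)
        assert all(r.p_value == pytest.approx(1.0) for r in results)

    def test_closed_form_full_draw(self):
        """All 5 selected genes carry the term, 5 of 20 in background:
        p = 1 / C(20, 5)."""
        background = {f"g{i}" for i in range(20)}
        selected = {f"g{i}" for i in range(5)}
        ann = {f"g{i}": {"T"} for i in range(5)}
        [r] = enrich_terms(selected, background, ann)
        assert r.p_value == pytest.approx(1 / comb(20, 5), rel=1e-9)
        assert r.p_value == pytest.approx(1 / 15504, rel=1e-9)

    def test_matches_exhaustive_hypergeometric_oracle(self):
        rng = np.random.default_rng(9)
        background = {f"g{i}" for i in range(15)}
        for _ in range(10):
            selected = set(rng.choice(sorted(background), size=6, replace=False))
            marked = set(rng.choice(sorted(background), size=5, replace=False))
            ann = {g: {"T"} for g in marked}
            results = enrich_terms(selected, background, ann)
            k = len(selected & marked)
            if k == 0:
                assert results == []
                continue
            # oracle: enumerate all C(15,6) draws, count those with >= k marked
            n_extreme = sum(
                1
                for draw in itertools.combinations(sorted(background), 6)
                if len(set(draw) & marked) >= k
            )
            [r] = results
            assert r.p_value == pytest.approx(n_extreme / comb(15, 6), rel=1e-9)

    def test_selection_outside_background_error(self):
        with pytest.raises(ValueError):
            enrich_terms({"x"}, {"y"}, {})

    def test_p_monotone_in_k(self):
        from scipy.stats import hypergeom

        ps = [float(hypergeom.sf(k - 1, 50, 10, 8)) for k in range(1, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_untested_terms_absent(self):
        background = {"a", "b", "c", "d"}
        ann = {"a": {"T1"}, "b": {"T2"}}
        results = enrich_terms({"c", "d"}, background, ann)
        assert results == []  # k = 0 for both terms


class TestExclusiveTerms:
    def test_identical_sets_empty(self):
        excl, shared = exclusive_terms({"x", "y"}, {"x", "y"})
        assert excl == set() and shared == {"x", "y"}

    def test_set_difference(self):
        excl, shared = exclusive_terms({"x", "y", "z"}, {"y"})
        assert excl == {"x", "z"} and shared == {"y"}

    def test_planted_exclusive_terms_recovered(self):
        """Terms annotated only on the selected group come out exclusive."""
        background = {f"g{i}" for i in range(30)}
        group_a = {f"g{i}" for i in range(8)}
        group_b = {f"g{i}" for i in range(8, 16)}
        ann = {g: {"COMMON"} for g in background}
        for g in group_a:
            ann[g] = {"COMMON", "A-ONLY"}
        res_a = enrich_terms(group_a, background, ann)
        res_b = enrich_terms(group_b, background, ann)
        terms_a = {r.term_id for r in res_a if r.q_value < 0.05}
        terms_b = {r.term_id for r in res_b if r.q_value < 0.05}
        excl, _ = exclusive_terms(terms_a, terms_b)
        assert excl == {"A-ONLY"}
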