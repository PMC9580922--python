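"""Pair filtering and transitive-link grouping."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsdfind.classify import classify_groups
from hsdfind.core import (
    GeneRecord,
    HsdGroup,
    QualifiedEdge,
    ThresholdConfig,
    build_gene_records,
    cluster_groups,
    copy_number_histogram,
    filter_edges,
)
from hsdfind.simulate import _closure_components
from hsdfind.tabular_io import SignatureRecord, SimilarityHit


def make_hit(q, s, identity=95.0, evalue=1e-40, bit=500.0, aln=300):
    return SimilarityHit(q, s, identity, aln, 5, 1, 1, aln, 1, aln, evalue, bit)


def make_genes(lengths):
    return {g: GeneRecord(g, length) for g, length in lengths.items()}


def sig_row(protein, length, acc, analysis="Pfam", ipr=""):
    return SignatureRecord(protein, "x", length, analysis, acc, f"{acc} desc",
                           1, min(50, length), "1E-20", "T", "15-03-2021",
                           ipr, "ipr desc" if ipr else "")


class TestThresholdConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"identity_min": 0}, {"identity_min": 101},
                   {"length_diff_max": -1}, {"evalue_max": 0}]
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ThresholdConfig(**kwargs)

    def test_label(self):
        assert ThresholdConfig().label == "90%_10aa"
        assert ThresholdConfig(60, 100).label == "60%_100aa"


class TestBuildGeneRecords:
    def test_pfam_profile_collects_accessions(self):
        rows = [sig_row("p1", 300, "PF00504", ipr="IPR001344"),
                sig_row("p1", 300, "PF00078")]
        records = build_gene_records(rows)
        assert records["p1"].pfam_profile == {"PF00504", "PF00078"}
        assert records["p1"].interpro_profile == {"IPR001344"}
        assert records["p1"].length == 300

    def test_non_pfam_analysis_excluded_from_pfam_profile(self):
        rows = [sig_row("p1", 300, "G3DSA:1.10.10", analysis="Gene3D")]
        records = build_gene_records(rows)
        assert records["p1"].pfam_profile == frozenset()

    def test_fasta_only_protein_gets_empty_profile(self):
        records = build_gene_records([], fasta_lengths={"p9": 120})
        assert records["p9"].length == 120
        assert records["p9"].pfam_profile == frozenset()

    def test_conflicting_lengths_name_the_protein(self):
        rows = [sig_row("p1", 300, "PF00504"), sig_row("p1", 299, "PF00078")]
        with pytest.raises(ValueError, match="p1"):
            build_gene_records(rows)

    def test_signature_length_wins_over_fasta_when_consistent(self):
        rows = [sig_row("p1", 300, "PF00504")]
        with pytest.raises(ValueError, match="p1"):
            build_gene_records(rows, fasta_lengths={"p1": 280})

    def test_bundle_profiles_match_generator_ground_truth(self, bundle, bundle_genes):
        for gene_id, info in bundle.manifest["genes"].items():
            assert bundle_genes[gene_id].pfam_profile == set(info["profile"])
            assert bundle_genes[gene_id].length == info["length"]


class TestFilterEdges:
    def test_qualifying_pair_at_defaults(self):
        genes = make_genes({"a": 300, "b": 305})
        edges = filter_edges([make_hit("a", "b", identity=92.0)], genes)
        assert [(e.gene_a, e.gene_b) for e in edges] == [("a", "b")]

    def test_self_hit_excluded(self):
        genes = make_genes({"a": 300})
        edges = filter_edges([make_hit("a", "a", identity=100.0)], genes)
        assert list(edges) == []
        assert edges.self_hits == 1

    def test_identity_threshold_inclusive_and_relaxable(self):
        genes = make_genes({"a": 300, "b": 305})
        hits = [make_hit("a", "b", identity=89.9)]
        assert list(filter_edges(hits, genes, ThresholdConfig())) == []
        assert len(filter_edges(hits, genes, ThresholdConfig(identity_min=80))) == 1
        # boundary: exactly 90 qualifies at the >= 90 default
        assert len(filter_edges([make_hit("a", "b", identity=90.0)], genes)) == 1

    def test_length_difference_boundary_inclusive(self):
        hits = [make_hit("a", "b")]
        assert len(filter_edges(hits, make_genes({"a": 300, "b": 310}),
                                ThresholdConfig())) == 1
        assert list(filter_edges(hits, make_genes({"a": 300, "b": 311}),
                                 ThresholdConfig())) == []

    def test_evalue_cutoff_inclusive(self):
        genes = make_genes({"a": 300, "b": 300})
        assert len(filter_edges([make_hit("a", "b", evalue=1e-5)], genes)) == 1
        assert list(filter_edges([make_hit("a", "b", evalue=2e-5)], genes)) == []

    def test_best_hit_by_bit_score_decides(self):
        genes = make_genes({"a": 300, "b": 305})
        hits = [make_hit("a", "b", identity=85.0, bit=400.0),
                make_hit("b", "a", identity=95.0, bit=450.0)]
        edges = filter_edges(hits, genes)
        assert len(edges) == 1 and edges[0].best_identity == 95.0
        # swap bit scores: the failing hit wins, pair no longer qualifies
        hits = [make_hit("a", "b", identity=85.0, bit=450.0),
                make_hit("b", "a", identity=95.0, bit=400.0)]
        assert list(filter_edges(hits, genes)) == []

    def test_unknown_length_skipped_and_reported(self):
        genes = {"a": GeneRecord("a", 300), "b": GeneRecord("b", None)}
        edges = filter_edges([make_hit("a", "b")], genes)
        assert list(edges) == []
        assert edges.skipped_no_length == (("a", "b"),)

    def test_symmetry_under_query_subject_swap(self, bundle_hits, bundle_genes):
        swapped = [
            SimilarityHit(h.subject_id, h.query_id, h.percent_identity,
                          h.alignment_length, h.mismatches, h.gap_opens,
                          h.subject_start, h.subject_end, h.query_start,
                          h.query_end, h.e_value, h.bit_score)
            for h in bundle_hits
        ]
        forward = filter_edges(bundle_hits, bundle_genes)
        backward = filter_edges(swapped, bundle_genes)
        assert {(e.gene_a, e.gene_b) for e in forward} == {
            (e.gene_a, e.gene_b) for e in backward
        }

    def test_brute_force_rescan_agrees(self, bundle_hits, bundle_genes):
        """Qualifying pairs equal an independent full re-scan of all rows."""
        cfg = ThresholdConfig()
        best = {}
        for h in bundle_hits:
            if h.query_id == h.subject_id:
                continue
            pair = tuple(sorted((h.query_id, h.subject_id)))
            if pair not in best or h.bit_score > best[pair].bit_score:
                best[pair] = h
        expected = set()
        for (a, b), h in best.items():
            la, lb = bundle_genes[a].length, bundle_genes[b].length
            if (h.e_value <= cfg.evalue_max and h.percent_identity >= cfg.identity_min
                    and la is not None and lb is not None
                    and abs(la - lb) <= cfg.length_diff_max):
                expected.add((a, b))
        got = {(e.gene_a, e.gene_b) for e in filter_edges(bundle_hits, bundle_genes, cfg)}
        assert got == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_count_monotone_in_thresholds(self, seed):
        rng = random.Random(seed)
        genes = make_genes({f"g{i}": rng.randint(100, 400) for i in range(40)})
        hits = []
        names = sorted(genes)
        for _ in range(200):
            q, s = rng.sample(names, 2)
            hits.append(make_hit(q, s, identity=round(rng.uniform(50, 100), 1),
                                 evalue=10 ** -rng.randint(3, 60),
                                 bit=round(rng.uniform(50, 900), 1)))
        for ldiff in (10, 50):
            counts = [len(filter_edges(hits, genes, ThresholdConfig(i, ldiff)))
                      for i in (60, 70, 80, 90)]
            assert counts == sorted(counts, reverse=True)
        for ident in (60, 90):
            counts = [len(filter_edges(hits, genes, ThresholdConfig(ident, l)))
                      for l in (10, 30, 50, 100)]
            assert counts == sorted(counts)


class TestClusterGroups:
    def test_transitive_link_merges_a_b_c(self):
        """A~B and A~C place A, B, C in one group even without a B~C edge."""
        edges = [QualifiedEdge("A", "B", 95.0, 1e-40),
                 QualifiedEdge("A", "C", 95.0, 1e-40)]
        (group,) = cluster_groups(edges)
        assert group.members == ("A", "B", "C")
        assert group.group_id == "A"

    def test_disjoint_edges_make_two_groups(self):
        edges = [QualifiedEdge("A", "B", 95.0, 1e-40),
                 QualifiedEdge("C", "D", 95.0, 1e-40)]
        groups = cluster_groups(edges)
        assert [g.members for g in groups] == [("A", "B"), ("C", "D")]

    def test_no_edges_no_groups(self):
        assert cluster_groups([]) == []

    def test_group_id_is_smallest_member_and_sorted(self):
        edges = [QualifiedEdge("z9", "m5", 95.0, 1e-40),
                 QualifiedEdge("m5", "a1", 95.0, 1e-40)]
        (group,) = cluster_groups(edges)
        assert group.group_id == "a1"
        assert group.members == ("a1", "m5", "z9")

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_transitive_closure_oracle(self, seed):
        """Component partition equals naive iterated-closure on random graphs."""
        rng = random.Random(seed)
        n = rng.randint(5, 120)
        nodes = [f"n{i:03d}" for i in range(n)]
        m = rng.randint(0, min(400, 2 * n))
        pairs = []
        for _ in range(m):
            a, b = rng.sample(nodes, 2)
            pairs.append(tuple(sorted((a, b))))
        edges = [QualifiedEdge(a, b, 95.0, 1e-40) for a, b in pairs]
        groups = cluster_groups(edges)
        assert sorted(g.members for g in groups) == _closure_components(pairs)

    @given(st.lists(
        st.tuples(st.integers(0, 60), st.integers(0, 60)).filter(lambda t: t[0] != t[1]),
        max_size=120,
    ))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_partition_property(self, int_pairs):
        """Every incident gene lands in exactly one group; no singletons."""
        edges = [QualifiedEdge(f"g{a}", f"g{b}", 95.0, 1e-40) for a, b in int_pairs]
        groups = cluster_groups(edges)
        seen = [m for g in groups for m in g.members]
        assert len(seen) == len(set(seen))
        assert set(seen) == {x for e in edges for x in (e.gene_a, e.gene_b)}
        assert all(g.size >= 2 for g in groups)


class TestCopyNumberHistogram:
    def test_direct_count(self):
        groups = [HsdGroup(f"g{i}", tuple(f"g{i}m{j}" for j in range(size)))
                  for i, size in enumerate([2, 2, 3, 5])]
        hist = copy_number_histogram(groups)
        assert hist["groups"] == {"2": 2, "3": 1, "4plus": 1}
        assert hist["copies"] == {"2": 4, "3": 3, "4plus": 5}

    def test_empty_input_all_zero(self):
        hist = copy_number_histogram([])
        assert hist == {"groups": {"2": 0, "3": 0, "4plus": 0},
                        "copies": {"2": 0, "3": 0, "4plus": 0}}

    def test_bins_sum_to_totals(self, bundle_hits, bundle_genes):
        edges = filter_edges(bundle_hits, bundle_genes)
        groups = cluster_groups(edges)
        hist = copy_number_histogram(groups)
        assert sum(hist["groups"].values()) == len(groups)
        assert sum(hist["copies"].values()) == sum(g.size for g in groups)
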