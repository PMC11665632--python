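"""Countables, grouping, subsetting, coverage, and the histogram h(i)."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pangrowth import abacus, gfa_io
from pangrowth.abacus import (
    CountableKind,
    ExclusionSpec,
    SubsetSpec,
    build_histogram,
    canonical_edge,
    compute_coverage,
    group_paths,
    itemize_path,
    restrict_path,
)
from pangrowth.gfa_io import PathRecord, Step, parse_gfa


def parse(text: str) -> gfa_io.PangenomeGraph:
    return parse_gfa(io.StringIO(text))


def make_path(steps, name="p", coord=None):
    base, parsed = gfa_io.parse_path_name(name)
    return PathRecord(name, base, coord if coord is not None else parsed,
                      tuple(Step(s, o) for s, o in steps), "P")


class TestCanonicalEdge:
    def test_reverse_complement_traversals_share_a_key(self):
        fwd = canonical_edge(Step("s1", "+"), Step("s2", "+"))
        rev = canonical_edge(Step("s2", "-"), Step("s1", "-"))
        assert fwd == rev

    def test_self_loop_canonicalizes_to_one_key(self):
        assert canonical_edge(Step("s1", "+"), Step("s1", "+")) == \
            canonical_edge(Step("s1", "-"), Step("s1", "-"))

    def test_orientation_distinguishes_edges(self):
        assert canonical_edge(Step("s1", "+"), Step("s2", "-")) != \
            canonical_edge(Step("s1", "+"), Step("s2", "+"))

    @given(
        st.sampled_from(["s1", "s2", "s3"]), st.sampled_from("+-"),
        st.sampled_from(["s1", "s2", "s3"]), st.sampled_from("+-"),
    )
    def test_canonicalization_is_an_involution(self, a, oa, b, ob):
        flip = {"+": "-", "-": "+"}
        assert canonical_edge(Step(a, oa), Step(b, ob)) == \
            canonical_edge(Step(b, flip[ob]), Step(a, flip[oa]))


class TestItemize:
    def test_repeated_traversal_contributes_once(self):
        path = make_path([("g", "+"), ("x", "+"), ("g", "+")])
        assert itemize_path(path, CountableKind.node) == {"g", "x"}

    def test_single_step_path_has_no_edges(self):
        path = make_path([("s1", "+")])
        assert itemize_path(path, CountableKind.node) == {"s1"}
        assert itemize_path(path, CountableKind.edge) == set()

    def test_edge_keys_of_a_zigzag_path(self):
        # consecutive pairs (s1+,s2+), (s2+,s1-), (s1-,s2-) are three
        # distinct adjacencies under reverse-complement canonicalization:
        # the reverse complement of (s1-)->(s2-) is (s2+)->(s1+), which is
        # not the first pair.
        path = make_path([("s1", "+"), ("s2", "+"), ("s1", "-"), ("s2", "-")])
        edges = itemize_path(path, CountableKind.edge)
        assert edges == {
            canonical_edge(Step("s1", "+"), Step("s2", "+")),
            canonical_edge(Step("s2", "+"), Step("s1", "-")),
            canonical_edge(Step("s1", "-"), Step("s2", "-")),
        }

    def test_duplicated_edge_traversal_contributes_once(self):
        path = make_path([("s1", "+"), ("s2", "+"), ("s1", "+"), ("s2", "+")])
        edges = itemize_path(path, CountableKind.edge)
        # (s2+,s1+) and the repeated (s1+,s2+) give exactly two keys
        assert len(edges) == 2


PANSN_GFA = (
    "S\ts1\tA\n"
    "P\tHG002#1#chr1\ts1+\t*\n"
    "P\tHG002#2#chr1\ts1+\t*\n"
    "P\tHG003#1#chr1\ts1+\t*\n"
)


class TestGrouping:
    def test_sample_mode_merges_haplotypes(self):
        g = parse(PANSN_GFA)
        grp = group_paths(g, "sample")
        assert grp.groups == ["HG002", "HG003"]
        assert grp.n == 2

    def test_haplotype_mode_keeps_haplotypes_apart(self):
        g = parse(PANSN_GFA)
        grp = group_paths(g, "haplotype")
        assert grp.n == 3
        assert grp.groups == ["HG002#1", "HG002#2", "HG003#1"]

    def test_none_mode_gives_one_group_per_path(self):
        g = parse(PANSN_GFA)
        assert group_paths(g, "none").n == 3

    def test_table_mode_orders_by_table_and_checks_completeness(self):
        g = parse(PANSN_GFA)
        table = {"HG003#1#chr1": "B", "HG002#1#chr1": "A",
                 "HG002#2#chr1": "A"}
        grp = group_paths(g, "table", table)
        assert grp.groups == ["B", "A"]
        with pytest.raises(gfa_io.GfaError, match="HG003#1#chr1"):
            group_paths(g, "table", {"HG002#1#chr1": "A",
                                     "HG002#2#chr1": "A"})


class TestRestrictPath:
    LENGTHS = {"x": 5, "y": 5, "z": 5}

    def test_bed_interval_straddling_two_nodes(self):
        path = make_path([("x", "+"), ("y", "+"), ("z", "+")])
        spec = SubsetSpec(intervals={"p": [(4, 6)]})
        res = restrict_path(path, self.LENGTHS, spec)
        assert res.nodes == {"x", "y"}
        assert res.node_bp == {"x": 1, "y": 1}
        # x and y are consecutive retained steps -> their edge survives
        assert res.edges == {canonical_edge(Step("x", "+"), Step("y", "+"))}

    def test_empty_spec_keeps_everything(self):
        path = make_path([("x", "+"), ("y", "+"), ("z", "+")])
        res = restrict_path(path, self.LENGTHS, SubsetSpec())
        assert res.nodes == {"x", "y", "z"}
        assert res.node_bp == {"x": 5, "y": 5, "z": 5}
        assert len(res.edges) == 2

    def test_whole_name_match_keeps_everything(self):
        path = make_path([("x", "+"), ("y", "+")])
        res = restrict_path(path, self.LENGTHS, SubsetSpec(names={"p"}))
        assert res.nodes == {"x", "y"}

    def test_unmatched_path_loses_everything(self):
        path = make_path([("x", "+"), ("y", "+")])
        spec = SubsetSpec(intervals={"other": [(0, 3)]})
        res = restrict_path(path, self.LENGTHS, spec)
        assert res.nodes == set() and res.edges == set()

    def test_nonadjacent_retained_steps_form_no_edge(self):
        path = make_path([("x", "+"), ("y", "+"), ("z", "+")])
        spec = SubsetSpec(intervals={"p": [(0, 3), (12, 15)]})
        res = restrict_path(path, self.LENGTHS, spec)
        assert res.nodes == {"x", "z"}
        assert res.edges == set()

    def test_path_coord_suffix_offsets_spec_coordinates(self):
        # the path spells out bases 100..115 of "p"; a BED interval at
        # 105-107 lands inside the second node
        path = make_path([("x", "+"), ("y", "+"), ("z", "+")],
                         name="p:100-115", coord=(100, 115))
        spec = SubsetSpec(intervals={"p": [(105, 107)]})
        res = restrict_path(path, self.LENGTHS, spec)
        assert res.nodes == {"y"}
        assert res.node_bp == {"y": 2}

    def test_interval_beyond_path_is_clipped_with_warning(self, caplog):
        path = make_path([("x", "+")])
        spec = SubsetSpec(intervals={"p": [(3, 99)]})
        with caplog.at_level("WARNING"):
            res = restrict_path(path, self.LENGTHS, spec)
        assert res.node_bp == {"x": 2}
        assert any("clipped" in r.message for r in caplog.records)

    @given(st.integers(1, 14))
    @settings(max_examples=25, deadline=None)
    def test_subset_complementarity_of_bp_weights(self, cut):
        # a partition of the path's coordinate space splits every node's bp
        # weight exactly in two
        path = make_path([("x", "+"), ("y", "+"), ("z", "+")])
        left = restrict_path(path, self.LENGTHS,
                             SubsetSpec(intervals={"p": [(0, cut)]}))
        right = restrict_path(path, self.LENGTHS,
                              SubsetSpec(intervals={"p": [(cut, 15)]}))
        full = restrict_path(path, self.LENGTHS, SubsetSpec())
        for seg in full.nodes:
            assert left.node_bp.get(seg, 0) + right.node_bp.get(seg, 0) \
                == full.node_bp[seg]


FIVE_PATH_GFA = (
    "S\ts1\tAC\nS\ts2\tGGG\nS\ts3\tT\n"
    "L\ts1\t+\ts2\t+\t0M\n"
    "P\tp1\ts1+,s2+\t*\n"
    "P\tp2\ts1+,s2+\t*\n"
    "P\tp3\ts1+,s2+\t*\n"
    "P\tp4\ts2-,s1-\t*\n"  # same edge, reverse traversal
    "P\tp5\ts3+\t*\n"
)


class TestCoverage:
    def test_edge_coverage_counts_distinct_paths_direction_blind(self):
        g = parse(FIVE_PATH_GFA)
        table = compute_coverage(g, CountableKind.edge, group_paths(g))
        key = canonical_edge(Step("s1", "+"), Step("s2", "+"))
        assert table.coverage[key] == 4

    def test_same_group_paths_count_once(self, tiny_graph):
        g = parse(PANSN_GFA)
        table = compute_coverage(g, CountableKind.node, group_paths(g, "sample"))
        assert table.coverage["s1"] == 2  # HG002 (two haplotypes) + HG003

    def test_uncovered_countables_are_absent_from_the_table(self):
        g = parse("S\ts1\tA\nS\ts2\tC\nP\tp\ts1+\t*\n")
        table = compute_coverage(g, CountableKind.node, group_paths(g))
        assert "s2" not in table.coverage
        assert table.universe_weight == 2

    def test_tiny_graph_histogram(self, tiny_graph):
        table = compute_coverage(tiny_graph, CountableKind.node,
                                 group_paths(tiny_graph))
        hist = build_histogram(table, tiny_graph)
        assert list(hist.h) == [0, 2, 1, 1]

    def test_bp_mode_weights_by_segment_length(self):
        g = parse(FIVE_PATH_GFA)
        table = compute_coverage(g, CountableKind.bp, group_paths(g))
        hist = build_histogram(table, g)
        # s1 (2 bp) and s2 (3 bp) covered by 4 paths; s3 (1 bp) by one
        assert hist.h[4] == 5 and hist.h[1] == 1
        assert hist.total == g.total_bp

    def test_exclusion_deletes_countables_globally(self, tiny_graph):
        grp = group_paths(tiny_graph)
        excl = ExclusionSpec(names={"p3"})  # p3 = {d}: d leaves the universe
        table = compute_coverage(tiny_graph, CountableKind.node, grp,
                                 exclusion=excl)
        assert "d" not in table.coverage
        assert table.universe_weight == 3
        hist = build_histogram(table, tiny_graph)
        assert list(hist.h) == [0, 2, 1, 0]

    def test_coverage_never_exceeds_group_count(self, tiny_graph):
        grp = group_paths(tiny_graph)
        table = compute_coverage(tiny_graph, CountableKind.node, grp)
        assert all(1 <= c <= grp.n for c in table.coverage.values())


class TestInvariants:
    @pytest.mark.parametrize("kind", list(CountableKind))
    def test_duplicating_a_step_never_changes_coverage(self, kind):
        # repeating a traversal adds no coverage; in edge mode the splice
        # necessarily creates a NEW adjacency (s2+ -> s1+), whose presence
        # is correct — the coverage of every pre-existing countable must
        # still be unchanged
        base = "S\ts1\tAC\nS\ts2\tGT\nP\tp1\ts1+,s2+\t*\nP\tp2\ts2+\t*\n"
        dup = "S\ts1\tAC\nS\ts2\tGT\nP\tp1\ts1+,s2+,s1+,s2+\t*\nP\tp2\ts2+\t*\n"
        t1 = compute_coverage(parse(base), kind, group_paths(parse(base)))
        t2 = compute_coverage(parse(dup), kind, group_paths(parse(dup)))
        for key, cov in t1.coverage.items():
            assert t2.coverage[key] == cov
        if kind != CountableKind.edge:
            assert t1.coverage == t2.coverage

    def test_merging_groups_never_increases_coverage(self, tiny_graph):
        separate = group_paths(tiny_graph, "none")
        merged = group_paths(
            tiny_graph, "table",
            {"p1": "g1", "p2": "g1", "p3": "g2"},
        )
        t_sep = compute_coverage(tiny_graph, CountableKind.node, separate)
        t_mrg = compute_coverage(tiny_graph, CountableKind.node, merged)
        assert t_mrg.n == t_sep.n - 1
        for key, cov in t_mrg.coverage.items():
            assert cov <= t_sep.coverage[key]

    @pytest.mark.parametrize("kind", list(CountableKind))
    def test_conservation_of_total_weight(self, kind):
        from pangrowth.fixtures import FixtureSpec, generate_gfa

        text, _ = generate_gfa(FixtureSpec(n_paths=5, n_segments=10, seed=11))
        g = parse(text)
        table = compute_coverage(g, kind, group_paths(g))
        hist = build_histogram(table, g)
        if kind == CountableKind.node:
            assert hist.total == len(g.segments)
        elif kind == CountableKind.bp:
            assert hist.total == g.total_bp
        else:
            assert hist.total == len(abacus.edge_universe(g))


class TestTableIO:
    def test_coverage_table_tsv_has_membership_columns(self, tiny_graph):
        grp = group_paths(tiny_graph)
        table = compute_coverage(tiny_graph, CountableKind.node, grp)
        buf = io.StringIO()
        abacus.write_coverage_table_tsv(table, buf, grp.groups)
        lines = buf.getvalue().strip().split("\n")
        assert lines[0] == "countable\tweight\tcoverage\tp1\tp2\tp3"
        rows = {ln.split("\t")[0]: ln.split("\t") for ln in lines[1:]}
        assert rows["d"][2:] == ["3", "1", "1", "1"]
        assert rows["a"][2:] == ["1", "1", "0", "0"]

    def test_histogram_tsv_round_trip(self, tiny_graph, tmp_path):
        table = compute_coverage(tiny_graph, CountableKind.node,
                                 group_paths(tiny_graph))
        hist = build_histogram(table, tiny_graph)
        p = tmp_path / "h.tsv"
        with open(p, "w") as fh:
            abacus.write_histogram_tsv(hist, fh)
        back = abacus.read_histogram_tsv(str(p))
        assert back.n == hist.n
        assert np.allclose(back.h, hist.h)
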