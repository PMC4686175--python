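"""Detection test, vertex matching/classification and edge-error counting."""

import numpy as np
import pytest

from aogm import (
    LineageParams,
    Marker,
    classify_vertices,
    compare,
    compare_graphs,
    compute_edge_errors,
    detection_test,
    generate_reference,
    induced_subgraph,
    match_vertices,
    tracks_to_graph,
)

from conftest import build_result, square


def strip(cy, x0, n):
    """Horizontal 1-pixel strip of n pixels starting at (cy, x0)."""
    return frozenset((cy, x0 + i) for i in range(n))


class TestDetectionTest:
    @pytest.mark.parametrize(
        "ref_n, overlap_n, expected",
        [(10, 6, True), (10, 5, False), (1, 1, True), (4, 2, False), (3, 2, True)],
    )
    def test_strict_majority(self, ref_n, overlap_n, expected):
        ref = Marker(label=1, frame=0, pixels=strip(0, 0, ref_n))
        comp = Marker(label=2, frame=0, pixels=strip(0, 0, overlap_n))
        assert detection_test(ref, comp) is expected

    def test_frames_must_agree(self):
        ref = Marker(label=1, frame=0, pixels=strip(0, 0, 3))
        comp = Marker(label=2, frame=1, pixels=strip(0, 0, 3))
        with pytest.raises(ValueError, match="frames"):
            detection_test(ref, comp)

    def test_dot_inside_large_region_matches(self):
        # an expert dot fully covered by a big segmented region
        dot = Marker(label=1, frame=0, pixels=frozenset({(5, 5)}))
        region = Marker(label=9, frame=0, pixels=square(5, 5, r=3))
        assert detection_test(dot, region)


class TestMatchVertices:
    def test_identical_results_match_one_to_one(self, two_track_result):
        graph = tracks_to_graph(two_track_result)
        matching = match_vertices(graph, graph)
        assert all(cid == rid for rid, cid in matching.assignment.items())

    def test_empty_computed_graph_matches_nothing(self, two_track_result):
        ref = tracks_to_graph(two_track_result)
        comp = tracks_to_graph(build_result(3, [], []))
        matching = match_vertices(ref, comp)
        assert all(cid is None for cid in matching.assignment.values())

    def test_blob_covering_two_dots_collects_both(self):
        ref = tracks_to_graph(
            build_result(
                1,
                [(1, 0, 0, None), (2, 0, 0, None)],
                [(1, 0, square(2, 2)), (2, 0, square(8, 2))],
            )
        )
        blob = square(2, 2).union(square(8, 2))
        comp = tracks_to_graph(build_result(1, [(5, 0, 0, None)], [(5, 0, blob)]))
        matching = match_vertices(ref, comp)
        assert matching.fibers[(5, 0)] == ((1, 0), (2, 0))


@pytest.mark.parametrize("seed", range(200))
def test_matching_agrees_with_brute_force_oracle(seed):
    """Exhaustive pairwise detection testing reproduces match_vertices."""
    rng = np.random.default_rng(seed)
    still = dict(division_prob=0.0, disappearance_prob=0.0, appearance_prob=0.0)
    ref = generate_reference(
        LineageParams(n_frames=3, n_initial=int(rng.integers(1, 5)), shape=(64, 64),
                      seed=seed, **still)
    )
    comp = generate_reference(
        LineageParams(n_frames=3, n_initial=int(rng.integers(1, 5)), shape=(64, 64),
                      max_step=5, seed=seed + 1000, **still)
    )
    rg, cg = tracks_to_graph(ref), tracks_to_graph(comp)
    assert rg.n_vertices <= 12 and cg.n_vertices <= 12
    matching = match_vertices(rg, cg)
    for rid, rmark in rg.nodes.items():
        winners = [
            cid
            for cid, cmark in cg.nodes.items()
            if cmark.frame == rmark.frame and detection_test(rmark, cmark)
        ]
        assert len(winners) <= 1
        assert matching.assignment[rid] == (winners[0] if winners else None)


class TestClassification:
    def test_fiber_arithmetic(self):
        # one computed marker absorbing three references, two matched 1:1
        refs = [(i, 0, 0, None) for i in range(1, 6)]
        ref_markers = [(i, 0, square(4 * i, 4)) for i in range(1, 6)]
        ref = tracks_to_graph(build_result(1, refs, ref_markers))
        blob = square(4, 4) | square(8, 4) | square(12, 4)
        comp = tracks_to_graph(
            build_result(
                1,
                [(21, 0, 0, None), (22, 0, 0, None), (23, 0, 0, None)],
                [(21, 0, blob), (22, 0, square(16, 4)), (23, 0, square(20, 4))],
            )
        )
        cls = classify_vertices(match_vertices(ref, comp), ref, comp)
        assert cls.tp == 5
        assert cls.matched_comp == 3
        assert cls.ns == 2
        assert cls.vs == 1

    def test_identity_classification(self, two_track_result):
        graph = tracks_to_graph(two_track_result)
        cls = classify_vertices(match_vertices(graph, graph), graph, graph)
        assert (cls.fn, cls.fp, cls.vs, cls.ns) == (0, 0, 0, 0)
        assert cls.tp == graph.n_vertices


class TestInducedSubgraphAndEdges:
    def test_identity_keeps_all_edges(self, two_track_result):
        graph = tracks_to_graph(two_track_result)
        cls = classify_vertices(match_vertices(graph, graph), graph, graph)
        assert induced_subgraph(graph, cls) == dict(graph.edges)

    def test_edges_touching_non_split_vertices_are_excluded(self):
        # comp chain a->b->c where b swallows two reference markers
        ref = tracks_to_graph(
            build_result(
                3,
                [(1, 0, 2, None), (2, 1, 1, None)],
                [(1, 0, square(2, 2)), (1, 1, square(2, 2)), (1, 2, square(2, 2)),
                 (2, 1, square(8, 2))],
            )
        )
        blob = square(2, 2) | square(8, 2)
        comp = tracks_to_graph(
            build_result(
                3,
                [(9, 0, 2, None)],
                [(9, 0, square(2, 2)), (9, 1, blob), (9, 2, square(2, 2))],
            )
        )
        cls = classify_vertices(match_vertices(ref, comp), ref, comp)
        assert cls.comp_non_split == {(9, 1)}
        assert induced_subgraph(comp, cls) == {}

    def test_wrong_semantics_edge_is_not_missing(self):
        """A reference parent link matched by a computed track link counts
        once as a semantics error, never as a missing edge."""
        ref = tracks_to_graph(
            build_result(
                2,
                [(1, 0, 0, None), (2, 1, 1, 1)],
                [(1, 0, square(2, 2)), (2, 1, square(2, 2))],
            )
        )
        comp = tracks_to_graph(
            build_result(
                2,
                [(9, 0, 1, None)],
                [(9, 0, square(2, 2)), (9, 1, square(2, 2))],
            )
        )
        matching = match_vertices(ref, comp)
        cls = classify_vertices(matching, ref, comp)
        errors = compute_edge_errors(ref, induced_subgraph(comp, cls), matching)
        assert (errors.ed, errors.ea, errors.ec) == (0, 0, 1)
        assert errors.wrong_semantics == {((9, 0), (9, 1))}


class TestCompare:
    def test_identity_is_all_zero(self, small_reference):
        counts = compare(small_reference, small_reference).counts
        assert counts.as_tuple() == (0, 0, 0, 0, 0, 0)

    def test_empty_computed_result(self, two_track_result):
        empty = build_result(3, [], [])
        report = compare(two_track_result, empty)
        c = report.counts
        assert c.fn == report.n_ref_vertices == 6
        assert c.ea == report.n_ref_edges == 4
        assert (c.ns, c.fp, c.ed, c.ec) == (0, 0, 0, 0)

    def test_empty_reference_result(self, two_track_result):
        empty = build_result(3, [], [])
        c = compare(empty, two_track_result).counts
        assert c.fp == 6
        assert (c.ns, c.fn, c.ed, c.ea, c.ec) == (0, 0, 0, 0, 0)


@pytest.mark.parametrize("seed", range(60))
def test_partition_and_counting_identities(seed):
    """The vertex partition identities hold on random lineage pairs."""
    ref = generate_reference(LineageParams(n_frames=6, n_initial=4, seed=seed))
    comp = generate_reference(
        LineageParams(n_frames=6, n_initial=4, division_prob=0.1, seed=seed + 5000)
    )
    rg, cg = tracks_to_graph(ref), tracks_to_graph(comp)
    report = compare_graphs(rg, cg)
    cls = report.classification
    assert cls.tp + cls.fn == rg.n_vertices
    assert len(cls.comp_true_positive) + cls.fp + cls.vs == cg.n_vertices
    assert cls.ref_true_positive | cls.ref_false_negative == set(rg.nodes)
    assert not cls.ref_true_positive & cls.ref_false_negative
    assert (
        cls.comp_true_positive | cls.comp_false_positive | cls.comp_non_split
        == set(cg.nodes)
    )
    # NS equals the total fiber excess over non-split vertices, and is >= VS
    fibers = report.matching.fibers
    assert cls.ns == sum(len(fibers[cid]) - 1 for cid in cls.comp_non_split)
    assert cls.ns >= cls.vs >= 0
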