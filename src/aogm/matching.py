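"""Matching of reference and computed tracking graphs and error counting.

The comparison is anchored by a *detection test*: a computed marker detects a
reference marker when it covers the strict majority of the reference pixels,

    |R ∩ C| > 0.5 |R|.

Because computed markers within one frame are pairwise disjoint, at most one
computed marker can cover a majority of any reference marker, so the
reference-to-computed assignment is unique and needs no optimization.  A
computed marker may collect several reference markers (an undetected division
or cluster); such *non-split* vertices must be split ``m - 1`` times.

On top of the vertex matching, six error tallies are derived:

* ``NS`` — split operations: TP minus the number of computed vertices with at
  least one reference marker assigned,
* ``FN`` — reference markers detected by nothing (add-vertex operations),
* ``FP`` — computed markers detecting nothing (delete-vertex operations),
* ``ED`` — redundant edges of the induced subgraph on uniquely matched
  computed vertices (delete-edge operations),
* ``EA`` — reference edges with no counterpart in that induced subgraph
  (add-edge operations),
* ``EC`` — matched edge pairs whose track/parent semantics differ
  (alter-semantics operations).

Edges attached to false-positive or non-split computed vertices never count
toward ``ED``/``EC``: deleting or splitting the vertex removes them for free,
which is why the edge stage works on the induced subgraph only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .model import (
    EdgeKind,
    Marker,
    NodeId,
    TrackingGraph,
    TrackingResult,
    tracks_to_graph,
)

__all__ = [
    "detection_test",
    "VertexMatching",
    "match_vertices",
    "VertexClassification",
    "classify_vertices",
    "induced_subgraph",
    "EdgeErrors",
    "compute_edge_errors",
    "ErrorCounts",
    "ErrorReport",
    "compare",
    "compare_graphs",
]


def detection_test(ref: Marker, comp: Marker) -> bool:
    """Strict majority-overlap test deciding whether ``comp`` detects ``ref``.

    Exactly half fails: ``|R ∩ C| > 0.5 |R|`` with a strict inequality, so a
    computed marker covering precisely 50 % of a reference marker does not
    detect it.
    """
    if ref.frame != comp.frame:
        raise ValueError(
            f"detection test requires equal frames, got {ref.frame} and {comp.frame}"
        )
    return 2 * len(ref.pixels & comp.pixels) > len(ref.pixels)


@dataclass(frozen=True)
class VertexMatching:
    """Unique assignment of reference markers to computed markers.

    ``assignment`` maps every reference vertex to the computed vertex that
    detects it, or ``None``; ``fibers`` is the exact inverse multi-map,
    listing for each computed vertex the reference vertices assigned to it.
    """

    assignment: Mapping[NodeId, Optional[NodeId]]
    fibers: Mapping[NodeId, tuple[NodeId, ...]]


def match_vertices(ref: TrackingGraph, comp: TrackingGraph) -> VertexMatching:
    """Run the detection test frame by frame and build the unique matching.

    Uniqueness per reference marker is mathematically guaranteed by the strict
    majority rule plus within-frame disjointness of computed markers, and is
    re-verified here: a second positive test for one reference marker signals
    overlapping computed markers that slipped past validation.
    """
    comp_by_frame: dict[int, list[Marker]] = {}
    for marker in comp.nodes.values():
        comp_by_frame.setdefault(marker.frame, []).append(marker)
    # pixel -> computed vertex lookup per frame makes the overlap count linear
    # in |ref.pixels| instead of quadratic in markers per frame
    pixel_owner: dict[int, dict[tuple[int, ...], NodeId]] = {}
    for frame, markers in comp_by_frame.items():
        owner: dict[tuple[int, ...], NodeId] = {}
        for m in markers:
            for px in m.pixels:
                owner[px] = m.node_id
        pixel_owner[frame] = owner

    assignment: dict[NodeId, Optional[NodeId]] = {}
    fibers: dict[NodeId, list[NodeId]] = {m.node_id: [] for m in comp.nodes.values()}
    for rid, rmark in ref.nodes.items():
        owner = pixel_owner.get(rmark.frame)
        winner: Optional[NodeId] = None
        if owner:
            overlap: dict[NodeId, int] = {}
            for px in rmark.pixels:
                cid = owner.get(px)
                if cid is not None:
                    overlap[cid] = overlap.get(cid, 0) + 1
            hits = [cid for cid, n in overlap.items() if 2 * n > len(rmark.pixels)]
            if len(hits) > 1:
                raise RuntimeError(
                    f"reference marker {rid} passes the majority test against "
                    f"{len(hits)} computed markers; computed markers overlap "
                    "within a frame"
                )
            if hits:
                winner = hits[0]
        assignment[rid] = winner
        if winner is not None:
            fibers[winner].append(rid)
    return VertexMatching(
        assignment=assignment,
        fibers={cid: tuple(sorted(refs)) for cid, refs in fibers.items()},
    )


@dataclass(frozen=True)
class VertexClassification:
    """Partition of both vertex sets induced by the matching.

    Reference vertices split into true positives and false negatives; computed
    vertices into true positives (exactly one reference assigned), false
    positives (none) and non-split vertices (two or more).  ``ns`` is the
    number of split operations: TP minus the number of computed vertices with
    at least one reference marker assigned.
    """

    ref_true_positive: frozenset[NodeId]
    ref_false_negative: frozenset[NodeId]
    comp_true_positive: frozenset[NodeId]
    comp_false_positive: frozenset[NodeId]
    comp_non_split: frozenset[NodeId]

    @property
    def tp(self) -> int:
        return len(self.ref_true_positive)

    @property
    def fn(self) -> int:
        return len(self.ref_false_negative)

    @property
    def fp(self) -> int:
        return len(self.comp_false_positive)

    @property
    def vs(self) -> int:
        """Number of non-split vertices."""
        return len(self.comp_non_split)

    @property
    def matched_comp(self) -> int:
        """Computed vertices with at least one reference marker assigned."""
        return len(self.comp_true_positive) + len(self.comp_non_split)

    @property
    def ns(self) -> int:
        return self.tp - self.matched_comp


def classify_vertices(
    matching: VertexMatching, ref: TrackingGraph, comp: TrackingGraph
) -> VertexClassification:
    """Partition both vertex sets according to the matching."""
    ref_tp = frozenset(rid for rid, cid in matching.assignment.items() if cid is not None)
    ref_fn = frozenset(ref.nodes) - ref_tp
    comp_tp = frozenset(cid for cid, fiber in matching.fibers.items() if len(fiber) == 1)
    comp_fp = frozenset(cid for cid, fiber in matching.fibers.items() if len(fiber) == 0)
    comp_ns = frozenset(cid for cid, fiber in matching.fibers.items() if len(fiber) >= 2)
    return VertexClassification(
        ref_true_positive=ref_tp,
        ref_false_negative=ref_fn,
        comp_true_positive=comp_tp,
        comp_false_positive=comp_fp,
        comp_non_split=comp_ns,
    )


def induced_subgraph(
    comp: TrackingGraph, cls: VertexClassification
) -> dict[tuple[NodeId, NodeId], EdgeKind]:
    """Computed edges whose both endpoints are uniquely matched vertices.

    Edges touching a false-positive or non-split vertex are excluded: they are
    inherently removed when the vertex is deleted or split, so they never
    count as redundant or wrong-semantics edges.
    """
    keep = cls.comp_true_positive
    return {
        (u, v): kind
        for (u, v), kind in comp.edges.items()
        if u in keep and v in keep
    }


@dataclass(frozen=True)
class EdgeErrors:
    """Edge-level error sets and tallies.

    ``redundant`` and ``wrong_semantics`` contain induced-subgraph edges;
    ``missing`` contains reference edges.
    """

    redundant: frozenset[tuple[NodeId, NodeId]]
    missing: frozenset[tuple[NodeId, NodeId]]
    wrong_semantics: frozenset[tuple[NodeId, NodeId]]

    @property
    def ed(self) -> int:
        return len(self.redundant)

    @property
    def ea(self) -> int:
        return len(self.missing)

    @property
    def ec(self) -> int:
        return len(self.wrong_semantics)


def compute_edge_errors(
    ref: TrackingGraph,
    induced: Mapping[tuple[NodeId, NodeId], EdgeKind],
    matching: VertexMatching,
) -> EdgeErrors:
    """Classify edges of the induced subgraph against the reference edges.

    An edge pair matches iff both endpoint detection tests hold with identical
    frame indices at both ends; since every induced endpoint carries exactly
    one reference marker, each induced edge maps to exactly one reference
    vertex pair.  Induced edges whose pair is not a reference edge are
    *redundant*; reference edges matched by no induced edge are *missing*;
    matched pairs with differing track/parent semantics are *wrong-semantics*
    edges (counted on the computed side, never also as missing).
    """
    # induced comp edge -> the reference vertex pair it covers
    comp_pair_to_edge: dict[tuple[NodeId, NodeId], tuple[NodeId, NodeId]] = {}
    redundant = set()
    for (cu, cv), kind in induced.items():
        ru = matching.fibers[cu][0]
        rv = matching.fibers[cv][0]
        if (ru, rv) in ref.edges:
            comp_pair_to_edge[(ru, rv)] = (cu, cv)
        else:
            redundant.add((cu, cv))

    missing = set()
    wrong = set()
    for (ru, rv), rkind in ref.edges.items():
        hit = comp_pair_to_edge.get((ru, rv))
        if hit is None:
            missing.add((ru, rv))
        elif induced[hit] is not rkind:
            wrong.add(hit)
    return EdgeErrors(
        redundant=frozenset(redundant),
        missing=frozenset(missing),
        wrong_semantics=frozenset(wrong),
    )


@dataclass(frozen=True)
class ErrorCounts:
    """The six error tallies plus the context sizes needed downstream.

    ``n_ref_vertices``/``n_ref_edges`` feed the normalized rates and
    ``m_star`` (the largest fiber over non-split vertices, 1 if there is
    none) feeds the minimality condition on weights.
    """

    ns: int = 0
    fn: int = 0
    fp: int = 0
    ed: int = 0
    ea: int = 0
    ec: int = 0
    n_ref_vertices: int = 0
    n_ref_edges: int = 0
    m_star: int = 1

    def __post_init__(self) -> None:
        for name in ("ns", "fn", "fp", "ed", "ea", "ec"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be >= 0")
        if self.m_star < 1:
            raise ValueError("m_star must be >= 1")

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (self.ns, self.fn, self.fp, self.ed, self.ea, self.ec)


@dataclass(frozen=True)
class ErrorReport:
    """Full outcome of one reference/computed comparison."""

    counts: ErrorCounts
    matching: VertexMatching
    classification: VertexClassification
    edge_errors: EdgeErrors
    n_ref_vertices: int
    n_ref_edges: int
    n_comp_vertices: int
    n_comp_edges: int


def compare_graphs(ref: TrackingGraph, comp: TrackingGraph) -> ErrorReport:
    """Deterministic composition of the four matching stages on graphs."""
    matching = match_vertices(ref, comp)
    cls = classify_vertices(matching, ref, comp)
    induced = induced_subgraph(comp, cls)
    edge_errors = compute_edge_errors(ref, induced, matching)
    m_star = max(
        (len(matching.fibers[cid]) for cid in cls.comp_non_split), default=1
    )
    counts = ErrorCounts(
        ns=cls.ns,
        fn=cls.fn,
        fp=cls.fp,
        ed=edge_errors.ed,
        ea=edge_errors.ea,
        ec=edge_errors.ec,
        n_ref_vertices=ref.n_vertices,
        n_ref_edges=ref.n_edges,
        m_star=m_star,
    )
    return ErrorReport(
        counts=counts,
        matching=matching,
        classification=cls,
        edge_errors=edge_errors,
        n_ref_vertices=ref.n_vertices,
        n_ref_edges=ref.n_edges,
        n_comp_vertices=comp.n_vertices,
        n_comp_edges=comp.n_edges,
    )


def compare(ref: TrackingResult, comp: TrackingResult) -> ErrorReport:
    """Compare two tracking results (validates both, then matches graphs)."""
    return compare_graphs(tracks_to_graph(ref), tracks_to_graph(comp))
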