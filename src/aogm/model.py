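"""Domain model for cell-lineage tracking results.

A tracking result over an ``N``-frame time-lapse series is the quadruple
(Theta, P, I, T): a forest of *tracks* (gap-free temporal series of labelled
*markers*), a parent function linking each daughter track to the track it
descends from, and the initial/terminal frame indices of every track.  Any
such quadruple maps one-to-one onto an acyclic oriented graph whose vertices
are the markers and whose edges are either *track links* (consecutive markers
of one track) or *parent links* (terminal marker of a track to the initial
marker of a descendant track, covering both cell division and re-appearance
after a temporal gap).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "Marker",
    "Track",
    "TrackingResult",
    "EdgeKind",
    "TrackingGraph",
    "Violation",
    "TrackingError",
    "validate_tracking_result",
    "tracks_to_graph",
    "restrict_to_frames",
]

#: vertex identifier inside a :class:`TrackingGraph`: ``(label, frame)``
NodeId = tuple[int, int]


class TrackingError(ValueError):
    """A tracking result violates the structural contract."""


@dataclass(frozen=True)
class Marker:
    """The set of pixels (or voxels) carrying one object's label in one frame.

    Parameters
    ----------
    label
        Positive integer object label, shared by all markers of one track.
    frame
        Zero-based frame index.
    pixels
        Non-empty frozenset of integer coordinate tuples, all of one
        dimensionality (2-D or 3-D).  Connectivity is not required: a marker
        is the full support of its label in the frame.
    """

    label: int
    frame: int
    pixels: frozenset[tuple[int, ...]]

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise TrackingError(f"marker label must be positive, got {self.label}")
        if self.frame < 0:
            raise TrackingError(f"marker frame must be >= 0, got {self.frame}")
        if not self.pixels:
            raise TrackingError(f"marker ({self.label}, {self.frame}) has no pixels")
        ndims = {len(p) for p in self.pixels}
        if len(ndims) != 1 or next(iter(ndims)) not in (2, 3):
            raise TrackingError(
                f"marker ({self.label}, {self.frame}) mixes coordinate "
                f"dimensionalities {sorted(ndims)}"
            )

    @property
    def node_id(self) -> NodeId:
        return (self.label, self.frame)

    @property
    def ndim(self) -> int:
        return len(next(iter(self.pixels)))


@dataclass(frozen=True)
class Track:
    """A maximal gap-free temporal series of markers sharing one label."""

    label: int
    t_init: int
    t_end: int
    parent: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise TrackingError(f"track label must be positive, got {self.label}")
        if self.parent is not None and self.parent == self.label:
            raise TrackingError(f"track {self.label} cannot be its own parent")

    @property
    def frames(self) -> range:
        return range(self.t_init, self.t_end + 1)


@dataclass(frozen=True)
class TrackingResult:
    """The quadruple (Theta, P, I, T) plus the markers realizing each track.

    ``markers`` maps ``(label, frame)`` to the :class:`Marker` occupying that
    slot; a well-formed result has exactly one marker for every frame of every
    track's span and none elsewhere (see :func:`validate_tracking_result`).
    """

    n_frames: int
    tracks: Mapping[int, Track]
    markers: Mapping[NodeId, Marker]

    def marker(self, label: int, frame: int) -> Marker:
        return self.markers[(label, frame)]

    def markers_in_frame(self, frame: int) -> list[Marker]:
        return [m for m in self.markers.values() if m.frame == frame]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def children_of(self, label: int) -> list[Track]:
        return [t for t in self.tracks.values() if t.parent == label]


class EdgeKind(enum.Enum):
    """Edge semantics: the function S mapping each edge to {TRACK, PARENT}."""

    TRACK = "T"
    PARENT = "P"


@dataclass(frozen=True)
class TrackingGraph:
    """Acyclic oriented graph of a tracking result.

    Vertices are markers addressed by ``(label, frame)``; every edge points
    forward in time, which forces acyclicity.
    """

    nodes: Mapping[NodeId, Marker]
    edges: Mapping[tuple[NodeId, NodeId], EdgeKind]

    @property
    def n_vertices(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes_in_frame(self, frame: int) -> list[Marker]:
        return [m for m in self.nodes.values() if m.frame == frame]

    @property
    def max_frame(self) -> int:
        """Largest frame index present, or -1 for an empty graph."""
        return max((m.frame for m in self.nodes.values()), default=-1)


@dataclass(frozen=True)
class Violation:
    """One structural defect found by :func:`validate_tracking_result`."""

    kind: str
    label: Optional[int] = None
    frame: Optional[int] = None
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        site = []
        if self.label is not None:
            site.append(f"track {self.label}")
        if self.frame is not None:
            site.append(f"frame {self.frame}")
        where = ", ".join(site)
        return f"[{self.kind}] {where}: {self.detail}" if where else f"[{self.kind}] {self.detail}"


def validate_tracking_result(result: TrackingResult) -> list[Violation]:
    """Check every structural invariant; return all violations found.

    Validation never raises: loaders and pipelines decide whether a non-empty
    report aborts.  An empty list certifies that

    * every track span lies within ``[0, n_frames - 1]``,
    * every track has exactly one marker per frame of its span and no marker
      outside it (no temporal gaps, no strays),
    * marker keys agree with marker label/frame fields,
    * within any single frame the pixel sets of distinct markers are disjoint,
    * every non-NONE parent exists, differs from the child, and terminates
      strictly before the child's initial frame.
    """
    out: list[Violation] = []
    if result.n_frames <= 0:
        out.append(Violation("n_frames", detail=f"n_frames must be positive, got {result.n_frames}"))

    for label, track in result.tracks.items():
        if label != track.label:
            out.append(Violation("key_mismatch", label=label,
                                 detail=f"track keyed {label} carries label {track.label}"))
        if not (0 <= track.t_init <= track.t_end <= result.n_frames - 1):
            out.append(Violation("span", label=label,
                                 detail=f"span [{track.t_init}, {track.t_end}] outside "
                                        f"[0, {result.n_frames - 1}]"))
            continue
        for t in track.frames:
            if (label, t) not in result.markers:
                out.append(Violation("temporal_gap", label=label, frame=t,
                                     detail="no marker inside the track span"))
        if track.parent is not None:
            parent = result.tracks.get(track.parent)
            if parent is None:
                out.append(Violation("dangling_parent", label=label,
                                     detail=f"parent {track.parent} does not exist"))
            elif parent.t_end >= track.t_init:
                out.append(Violation("parent_order", label=label,
                                     detail=f"parent {track.parent} terminates at "
                                            f"{parent.t_end} >= child start {track.t_init}"))

    for (label, frame), marker in result.markers.items():
        if (marker.label, marker.frame) != (label, frame):
            out.append(Violation("key_mismatch", label=label, frame=frame,
                                 detail=f"marker keyed ({label}, {frame}) carries "
                                        f"({marker.label}, {marker.frame})"))
        track = result.tracks.get(label)
        if track is None:
            out.append(Violation("stray_marker", label=label, frame=frame,
                                 detail="marker has no track"))
        elif not (track.t_init <= frame <= track.t_end):
            out.append(Violation("stray_marker", label=label, frame=frame,
                                 detail=f"marker outside span [{track.t_init}, {track.t_end}]"))

    # pairwise pixel disjointness, frame by frame
    by_frame: dict[int, dict[tuple[int, ...], int]] = {}
    for marker in result.markers.values():
        seen = by_frame.setdefault(marker.frame, {})
        for px in marker.pixels:
            other = seen.get(px)
            if other is not None and other != marker.label:
                out.append(Violation("overlap", label=marker.label, frame=marker.frame,
                                     detail=f"pixel {px} shared with marker {other}"))
            else:
                seen[px] = marker.label
    return out


def tracks_to_graph(result: TrackingResult) -> TrackingGraph:
    """Transform a valid tracking result into its acyclic oriented graph.

    Vertices are all markers.  ``(M_i^t1, M_j^t2)`` is an edge iff either
    ``i == j and t2 == t1 + 1`` (a TRACK link) or ``i != j``, ``t1 < t2``,
    ``t1`` is the terminal frame of track *i*, ``t2`` the initial frame of
    track *j*, and *i* is the parent of *j* (a PARENT link).

    Raises
    ------
    TrackingError
        If the result fails validation (the first violation is reported).
    """
    violations = validate_tracking_result(result)
    if violations:
        raise TrackingError(f"invalid tracking result: {violations[0]}")

    edges: dict[tuple[NodeId, NodeId], EdgeKind] = {}
    for track in result.tracks.values():
        for t in range(track.t_init, track.t_end):
            edges[((track.label, t), (track.label, t + 1))] = EdgeKind.TRACK
        if track.parent is not None:
            parent = result.tracks[track.parent]
            edges[((parent.label, parent.t_end), (track.label, track.t_init))] = EdgeKind.PARENT
    return TrackingGraph(nodes=dict(result.markers), edges=edges)


def restrict_to_frames(graph: TrackingGraph, t_max: int) -> TrackingGraph:
    """Subgraph induced by the vertices of frames ``0..t_max``, semantics kept."""
    if t_max < 0:
        raise ValueError(f"t_max must be >= 0, got {t_max}")
    nodes = {nid: m for nid, m in graph.nodes.items() if m.frame <= t_max}
    edges = {
        (u, v): kind
        for (u, v), kind in graph.edges.items()
        if u in nodes and v in nodes
    }
    return TrackingGraph(nodes=nodes, edges=edges)
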