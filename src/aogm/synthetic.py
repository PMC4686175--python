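"""Seeded synthetic lineage generation and controlled error injection.

:func:`generate_reference` simulates a lineage forest the way a time-lapse
series of motile cells produces one: square markers random-walk across a 2-D
field, divide into two daughters, disappear (death or leaving the field), and
appear (entering the field).  Placement enforces a minimum separation, so
markers never overlap within a frame and every generated result is valid.

:func:`inject_errors` applies an :class:`EditScript` of spatio-temporally
disjoint edits to a reference, producing a corrupted "computed" result
together with the error counts the comparison must find.  Each edit type maps
one-to-one onto one of the six error types, and its predicted count delta is
derived combinatorially from the local lineage topology (which reference
edges lose their counterpart), independently of the matching machinery that
is later checked against it:

* :class:`DeleteVertex` (interior marker) — FN+1, EA+2 (both incident track
  links lose their counterpart; the orphaned tail keeps its own links);
* :class:`AddSpurious` — FP+1;
* :class:`Merge` (two span-identical tracks fused into one) — NS+f over the
  f merged frames; EA+ every reference edge incident to a merged marker
  (2(f-1) internal links, plus one per parent or child of either track),
  since all edges touching non-split vertices are excluded from the induced
  subgraph;
* :class:`CutEdge` — EA+1 (the severed link's tail becomes an orphan track);
* :class:`AddFalseEdge` — ED+1 (an orphan track gains a fabricated parent);
* :class:`FlipSemantics` — EC+1 (one daughter continues under the mother's
  label, turning the parent link into a track link), EA+1 per sibling whose
  parent link must be dropped to keep the result well-formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .matching import ErrorCounts
from .model import (
    Marker,
    Track,
    TrackingResult,
    tracks_to_graph,
    validate_tracking_result,
)

__all__ = [
    "LineageParams",
    "GenerationError",
    "generate_reference",
    "DeleteVertex",
    "AddSpurious",
    "Merge",
    "CutEdge",
    "AddFalseEdge",
    "FlipSemantics",
    "Edit",
    "EditScript",
    "ScriptError",
    "inject_errors",
    "random_edit_script",
]


class GenerationError(RuntimeError):
    """Marker placement failed; the field is too crowded for the parameters."""


class ScriptError(ValueError):
    """An edit script is inapplicable or its sites are not disjoint."""


@dataclass(frozen=True)
class LineageParams:
    """Knobs of the synthetic lineage generator.

    Markers are axis-aligned squares of side ``2 * radius + 1`` pixels, so
    overlap arithmetic in tests is exact.  Probabilities are per active cell
    per frame transition; ``appearance_prob`` is the per-frame chance of one
    new cell entering the field.  Centers keep a Chebyshev separation of at
    least ``2 * radius + 1 + min_gap`` pixels, which guarantees disjoint
    markers.
    """

    n_frames: int = 12
    shape: tuple[int, int] = (96, 96)
    n_initial: int = 6
    radius: int = 2
    division_prob: float = 0.04
    disappearance_prob: float = 0.02
    appearance_prob: float = 0.1
    max_step: int = 3
    min_gap: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("division_prob", "disappearance_prob", "appearance_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if self.n_frames < 1 or self.n_initial < 0:
            raise ValueError("n_frames must be >= 1 and n_initial >= 0")


def _square(center: tuple[int, int], radius: int) -> frozenset[tuple[int, int]]:
    cy, cx = center
    return frozenset(
        (y, x)
        for y in range(cy - radius, cy + radius + 1)
        for x in range(cx - radius, cx + radius + 1)
    )


def _separated(center, others, min_sep) -> bool:
    cy, cx = center
    return all(max(abs(cy - oy), abs(cx - ox)) >= min_sep for oy, ox in others)


def _place(rng, params, occupied, near=None, tries=200):
    """Random center respecting bounds and separation, or None."""
    lo_y, lo_x = params.radius, params.radius
    hi_y = params.shape[0] - 1 - params.radius
    hi_x = params.shape[1] - 1 - params.radius
    min_sep = 2 * params.radius + 1 + params.min_gap
    for _ in range(tries):
        if near is None:
            center = (int(rng.integers(lo_y, hi_y + 1)), int(rng.integers(lo_x, hi_x + 1)))
        else:
            reach = max(params.max_step, min_sep)
            center = (
                int(np.clip(near[0] + rng.integers(-reach, reach + 1), lo_y, hi_y)),
                int(np.clip(near[1] + rng.integers(-reach, reach + 1), lo_x, hi_x)),
            )
        if _separated(center, occupied, min_sep):
            return center
    return None


def generate_reference(params: LineageParams) -> TrackingResult:
    """Simulate a valid lineage forest; identical seeds give identical output.

    Divisions terminate the mother and start two daughter tracks with parent
    links; disappearing tracks simply end; appearing cells start parentless
    tracks.  Re-appearance after a gap is not generated.

    Raises
    ------
    GenerationError
        If a marker cannot be placed after bounded retries; lower the density
        (fewer cells, smaller radius, larger field).
    """
    rng = np.random.default_rng(params.seed)
    tracks: dict[int, dict] = {}  # label -> {t0, t1, parent, centers: {frame: center}}
    next_label = 1

    def start_track(frame, center, parent=None):
        nonlocal next_label
        label = next_label
        next_label += 1
        tracks[label] = {"t0": frame, "t1": frame, "parent": parent, "centers": {frame: center}}
        return label

    occupied: list[tuple[int, int]] = []
    for _ in range(params.n_initial):
        center = _place(rng, params, occupied)
        if center is None:
            raise GenerationError(
                "cannot place initial cells; reduce n_initial or radius, or enlarge shape"
            )
        occupied.append(center)
        start_track(0, center)

    active = [lbl for lbl in tracks]
    for frame in range(1, params.n_frames):
        placed: list[tuple[int, int]] = []
        survivors: list[int] = []
        # iterate in label order for determinism
        for label in sorted(active):
            info = tracks[label]
            u = rng.random()
            if u < params.disappearance_prob:
                continue  # track terminates at frame - 1
            if u < params.disappearance_prob + params.division_prob:
                mother = info["centers"][frame - 1]
                daughters = []
                for _ in range(2):
                    c = _place(rng, params, placed, near=mother)
                    if c is None:
                        break
                    placed.append(c)
                    daughters.append(c)
                if len(daughters) == 2:
                    for c in daughters:
                        survivors.append(start_track(frame, c, parent=label))
                    continue
                # no room to divide: fall through to a plain move
                placed = [p for p in placed if p not in daughters]
            c = _place(rng, params, placed, near=info["centers"][frame - 1])
            if c is None:
                # boxed in by already-moved neighbours: allow a long jump
                c = _place(rng, params, placed)
            if c is None:
                raise GenerationError(
                    "cannot move a cell without collision; reduce density"
                )
            placed.append(c)
            info["centers"][frame] = c
            info["t1"] = frame
            survivors.append(label)
        if rng.random() < params.appearance_prob:
            c = _place(rng, params, placed)
            if c is not None:
                placed.append(c)
                survivors.append(start_track(frame, c))
        active = survivors

    track_objs = {
        lbl: Track(label=lbl, t_init=info["t0"], t_end=info["t1"], parent=info["parent"])
        for lbl, info in tracks.items()
    }
    markers = {
        (lbl, frame): Marker(label=lbl, frame=frame, pixels=_square(center, params.radius))
        for lbl, info in tracks.items()
        for frame, center in info["centers"].items()
    }
    result = TrackingResult(n_frames=params.n_frames, tracks=track_objs, markers=markers)
    assert not validate_tracking_result(result)
    return result


# ---------------------------------------------------------------------------
# edits


@dataclass(frozen=True)
class DeleteVertex:
    """Remove one interior marker of a track; the tail becomes an orphan."""

    label: int
    frame: int


@dataclass(frozen=True)
class AddSpurious:
    """Add a single-marker track at an empty location."""

    frame: int
    center: tuple[int, int]
    radius: int = 2


@dataclass(frozen=True)
class Merge:
    """Fuse two span-identical tracks into one whose markers are the unions."""

    label_a: int
    label_b: int


@dataclass(frozen=True)
class CutEdge:
    """Sever the track link between ``frame`` and ``frame + 1``."""

    label: int
    frame: int


@dataclass(frozen=True)
class AddFalseEdge:
    """Give a parentless track a fabricated parent."""

    child_label: int
    new_parent_label: int


@dataclass(frozen=True)
class FlipSemantics:
    """Report a division as plain continuation of the mother's label."""

    parent_label: int
    child_label: int


Edit = Union[DeleteVertex, AddSpurious, Merge, CutEdge, AddFalseEdge, FlipSemantics]


@dataclass(frozen=True)
class EditScript:
    """An ordered list of pairwise disjoint edits."""

    edits: tuple[Edit, ...] = ()


class _Workspace:
    """Mutable copy of a tracking result during edit application."""

    def __init__(self, ref: TrackingResult):
        self.n_frames = ref.n_frames
        self.tracks = {lbl: {"t0": t.t_init, "t1": t.t_end, "parent": t.parent}
                       for lbl, t in ref.tracks.items()}
        self.pixels = {key: m.pixels for key, m in ref.markers.items()}
        self.next_label = max(ref.tracks, default=0) + 1

    def fresh_label(self) -> int:
        label = self.next_label
        self.next_label += 1
        return label

    def to_result(self) -> TrackingResult:
        tracks = {
            lbl: Track(label=lbl, t_init=i["t0"], t_end=i["t1"], parent=i["parent"])
            for lbl, i in self.tracks.items()
        }
        markers = {
            (lbl, frame): Marker(label=lbl, frame=frame, pixels=px)
            for (lbl, frame), px in self.pixels.items()
        }
        return TrackingResult(n_frames=self.n_frames, tracks=tracks, markers=markers)


def _claims(edit: Edit, ref: TrackingResult) -> set[int]:
    """Reference labels whose markers or incident edges the edit touches."""
    def kin(label: int) -> set[int]:
        track = ref.tracks[label]
        out = {label}
        if track.parent is not None:
            out.add(track.parent)
        out.update(c.label for c in ref.children_of(label))
        return out

    if isinstance(edit, DeleteVertex):
        return {edit.label}
    if isinstance(edit, AddSpurious):
        return set()
    if isinstance(edit, Merge):
        return kin(edit.label_a) | kin(edit.label_b)
    if isinstance(edit, CutEdge):
        return {edit.label}
    if isinstance(edit, AddFalseEdge):
        return {edit.child_label, edit.new_parent_label}
    if isinstance(edit, FlipSemantics):
        out = kin(edit.parent_label)
        out.update(c.label for c in ref.children_of(edit.child_label))
        return out
    raise ScriptError(f"unknown edit {edit!r}")


def _apply(edit: Edit, ws: _Workspace, ref: TrackingResult) -> ErrorCounts:
    """Apply one edit to the workspace; return its predicted count delta."""
    if isinstance(edit, DeleteVertex):
        info = ws.tracks.get(edit.label)
        if info is None or not info["t0"] < edit.frame < info["t1"]:
            raise ScriptError(f"{edit}: frame must be strictly inside the track span")
        tail = ws.fresh_label()
        ws.tracks[tail] = {"t0": edit.frame + 1, "t1": info["t1"], "parent": None}
        for t in range(edit.frame + 1, info["t1"] + 1):
            ws.pixels[(tail, t)] = ws.pixels.pop((edit.label, t))
        del ws.pixels[(edit.label, edit.frame)]
        info["t1"] = edit.frame - 1
        for lbl, i in ws.tracks.items():
            if i["parent"] == edit.label and lbl != tail:
                i["parent"] = tail  # keep the parent edge anchored at the true terminal
        return ErrorCounts(fn=1, ea=2)

    if isinstance(edit, AddSpurious):
        label = ws.fresh_label()
        ws.tracks[label] = {"t0": edit.frame, "t1": edit.frame, "parent": None}
        ws.pixels[(label, edit.frame)] = _square(edit.center, edit.radius)
        return ErrorCounts(fp=1)

    if isinstance(edit, Merge):
        a, b = edit.label_a, edit.label_b
        ia, ib = ws.tracks.get(a), ws.tracks.get(b)
        if ia is None or ib is None or (ia["t0"], ia["t1"]) != (ib["t0"], ib["t1"]):
            raise ScriptError(f"{edit}: tracks must exist and have identical spans")
        f = ia["t1"] - ia["t0"] + 1
        for t in range(ia["t0"], ia["t1"] + 1):
            ws.pixels[(a, t)] = ws.pixels[(a, t)] | ws.pixels.pop((b, t))
        del ws.tracks[b]
        for i in ws.tracks.values():
            if i["parent"] == b:
                i["parent"] = a
        # every reference edge incident to a merged marker loses its
        # counterpart: internal track links, parent links into a and b,
        # parent links out to children of a and b
        boundary = 0
        for lbl in (a, b):
            if ref.tracks[lbl].parent is not None:
                boundary += 1
            boundary += len(ref.children_of(lbl))
        return ErrorCounts(ns=f, ea=2 * (f - 1) + boundary, m_star=2)

    if isinstance(edit, CutEdge):
        info = ws.tracks.get(edit.label)
        if info is None or not info["t0"] <= edit.frame < info["t1"]:
            raise ScriptError(f"{edit}: frame must have a successor inside the span")
        tail = ws.fresh_label()
        ws.tracks[tail] = {"t0": edit.frame + 1, "t1": info["t1"], "parent": None}
        for t in range(edit.frame + 1, info["t1"] + 1):
            ws.pixels[(tail, t)] = ws.pixels.pop((edit.label, t))
        info["t1"] = edit.frame
        for lbl, i in ws.tracks.items():
            if i["parent"] == edit.label and lbl != tail:
                i["parent"] = tail
        return ErrorCounts(ea=1)

    if isinstance(edit, AddFalseEdge):
        child = ws.tracks.get(edit.child_label)
        parent = ws.tracks.get(edit.new_parent_label)
        if child is None or parent is None:
            raise ScriptError(f"{edit}: both tracks must exist")
        if child["parent"] is not None or ref.tracks[edit.child_label].parent is not None:
            raise ScriptError(f"{edit}: child must be parentless")
        if parent["t1"] >= child["t0"]:
            raise ScriptError(f"{edit}: parent must terminate before the child starts")
        child["parent"] = edit.new_parent_label
        return ErrorCounts(ed=1)

    if isinstance(edit, FlipSemantics):
        mother = ws.tracks.get(edit.parent_label)
        child = ws.tracks.get(edit.child_label)
        ref_child = ref.tracks.get(edit.child_label)
        if mother is None or child is None or ref_child is None:
            raise ScriptError(f"{edit}: both tracks must exist")
        if ref_child.parent != edit.parent_label or child["t0"] != mother["t1"] + 1:
            raise ScriptError(
                f"{edit}: child must descend from parent and start right after it"
            )
        siblings = [
            c.label for c in ref.children_of(edit.parent_label) if c.label != edit.child_label
        ]
        for t in range(child["t0"], child["t1"] + 1):
            ws.pixels[(edit.parent_label, t)] = ws.pixels.pop((edit.child_label, t))
        mother["t1"] = child["t1"]
        del ws.tracks[edit.child_label]
        for lbl, i in ws.tracks.items():
            if i["parent"] == edit.child_label:
                i["parent"] = edit.parent_label  # terminal marker is unchanged
            elif lbl in siblings:
                i["parent"] = None  # mother no longer terminates before them
        return ErrorCounts(ec=1, ea=len(siblings))

    raise ScriptError(f"unknown edit {edit!r}")


def inject_errors(
    ref: TrackingResult, script: EditScript
) -> tuple[TrackingResult, ErrorCounts]:
    """Apply a script of disjoint edits; return the corrupted result and the
    error counts its comparison against ``ref`` must produce.

    Raises :class:`ScriptError` if two edits claim overlapping lineage
    neighbourhoods (their deltas would interact) or an edit is inapplicable.
    """
    claimed: set[int] = set()
    spurious_sites: list[tuple[int, tuple[int, int], int]] = []
    ref_graph = tracks_to_graph(ref)  # also validates ref
    for edit in script.edits:
        labels = _claims(edit, ref)
        if labels & claimed:
            raise ScriptError(
                f"{edit}: overlaps an earlier edit on labels {sorted(labels & claimed)}"
            )
        claimed |= labels
        if isinstance(edit, AddSpurious):
            spurious_sites.append((edit.frame, edit.center, edit.radius))

    ws = _Workspace(ref)
    totals = dict(ns=0, fn=0, fp=0, ed=0, ea=0, ec=0)
    m_star = 1
    for edit in script.edits:
        delta = _apply(edit, ws, ref)
        for name in totals:
            totals[name] += getattr(delta, name)
        m_star = max(m_star, delta.m_star)

    comp = ws.to_result()
    violations = validate_tracking_result(comp)
    if violations:
        raise ScriptError(f"edits produced an invalid result: {violations[0]}")
    expected = ErrorCounts(
        **totals,
        n_ref_vertices=ref_graph.n_vertices,
        n_ref_edges=ref_graph.n_edges,
        m_star=m_star,
    )
    return comp, expected


def random_edit_script(
    ref: TrackingResult,
    rng: np.random.Generator,
    n_edits: int = 3,
    shape: Optional[tuple[int, int]] = None,
    radius: int = 2,
) -> EditScript:
    """Sample an applicable script of up to ``n_edits`` disjoint edits.

    Edits are drawn uniformly over the applicable sites of all six types;
    fewer edits are returned when the lineage offers no disjoint sites.
    """
    if shape is None:
        maxes = [0, 0]
        for m in ref.markers.values():
            for px in m.pixels:
                maxes = [max(a, c) for a, c in zip(maxes, px)]
        shape = (maxes[0] + 1 + 4 * radius, maxes[1] + 1 + 4 * radius)

    claimed: set[int] = set()
    spurious: dict[int, list[tuple[int, int]]] = {}
    edits: list[Edit] = []

    def free(labels: set[int]) -> bool:
        return not (labels & claimed)

    kinds = ["delete", "spurious", "merge", "cut", "false_edge", "flip"]
    for _ in range(n_edits):
        for kind in rng.permutation(kinds):
            edit = _sample_edit(kind, ref, rng, shape, radius, spurious)
            if edit is None:
                continue
            labels = _claims(edit, ref)
            if not free(labels):
                continue
            claimed |= labels
            if isinstance(edit, AddSpurious):
                spurious.setdefault(edit.frame, []).append(edit.center)
            edits.append(edit)
            break
    return EditScript(edits=tuple(edits))


def _sample_edit(kind, ref, rng, shape, radius, spurious) -> Optional[Edit]:
    tracks = ref.tracks

    def choice(seq):
        return seq[int(rng.integers(len(seq)))] if seq else None

    if kind == "delete":
        sites = [
            (t.label, f)
            for t in tracks.values()
            for f in range(t.t_init + 1, t.t_end)
        ]
        site = choice(sites)
        return DeleteVertex(*site) if site else None
    if kind == "spurious":
        frame = int(rng.integers(ref.n_frames))
        occupied = [
            _center_of(m) for m in ref.markers_in_frame(frame)
        ] + spurious.get(frame, [])
        min_sep = 4 * radius + 2  # clear of every reference marker
        for _ in range(50):
            center = (
                int(rng.integers(radius, shape[0] - radius)),
                int(rng.integers(radius, shape[1] - radius)),
            )
            if _separated(center, occupied, min_sep):
                return AddSpurious(frame=frame, center=center, radius=radius)
        return None
    if kind == "merge":
        by_span: dict[tuple[int, int], list[int]] = {}
        for t in tracks.values():
            by_span.setdefault((t.t_init, t.t_end), []).append(t.label)
        pairs = [
            (a, b)
            for labels in by_span.values()
            for i, a in enumerate(labels)
            for b in labels[i + 1:]
        ]
        pair = choice(pairs)
        return Merge(*pair) if pair else None
    if kind == "cut":
        sites = [
            (t.label, f) for t in tracks.values() for f in range(t.t_init, t.t_end)
        ]
        site = choice(sites)
        return CutEdge(*site) if site else None
    if kind == "false_edge":
        orphans = [t for t in tracks.values() if t.parent is None and t.t_init > 0]
        pairs = [
            (c.label, p.label)
            for c in orphans
            for p in tracks.values()
            if p.label != c.label and p.t_end < c.t_init
        ]
        pair = choice(pairs)
        return AddFalseEdge(*pair) if pair else None
    if kind == "flip":
        sites = [
            (t.parent, t.label)
            for t in tracks.values()
            if t.parent is not None and t.t_init == tracks[t.parent].t_end + 1
        ]
        site = choice(sites)
        return FlipSemantics(*site) if site else None
    raise ValueError(kind)


def _center_of(marker: Marker) -> tuple[int, int]:
    ys = [p[0] for p in marker.pixels]
    xs = [p[1] for p in marker.pixels]
    return (round(sum(ys) / len(ys)), round(sum(xs) / len(xs)))
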