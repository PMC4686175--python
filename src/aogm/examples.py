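"""A synthetic worked example exercising all six error types at once.

:func:`worked_example` builds a 5-frame reference/computed pair of tracking
results whose comparison yields exactly

    NS = 5, FN = 5, FP = 3, ED = 1, EA = 16, EC = 2,

with 20 true-positive reference vertices, 15 computed vertices carrying at
least one reference marker, 25 reference vertices and 18 reference edges.
Under the default challenge weights (5, 10, 1, 1, 1.5, 1) the aggregated
value is 5·5 + 10·5 + 1·3 + 1·1 + 1.5·16 + 1·2 = 105.

The pair is assembled from seven spatially disjoint sub-scenarios, each a
canonical tracking failure:

A. an undetected two-frame division: the mother is tracked but both
   daughters stay merged for two frames (2 non-split vertices -> NS 2; the
   two parent links and two daughter track links are missing -> EA 4);
B. the same with three merged daughter frames (NS 3, EA 6);
C. a detected division reported as plain track continuation (ref parent link
   matched by a computed track link -> EC 1);
D. a plain continuation reported as a division (ref track link matched by a
   computed parent link -> EC 1);
E. an identity swap: the computed track drifts from one object onto an
   unrelated one, creating a link the reference does not have (ED 1) and
   leaving the true continuation unlinked (EA 1);
F. a missed lineage subtree below a detected mother: a three-frame daughter
   and its two children are entirely absent (FN 5, all five incident
   reference edges missing -> EA 5);
G. three spurious detections matching nothing (FP 3).

All markers are axis-aligned squares (or rectangles for merged markers) on a
2-D grid; the sub-scenarios occupy disjoint row bands, so the detection test
can never couple them.
"""

from __future__ import annotations

from itertools import product

from .model import Marker, Track, TrackingResult

__all__ = ["worked_example"]


def _sq(cy: int, cx: int) -> frozenset[tuple[int, int]]:
    """3x3 pixel square centered at (cy, cx)."""
    return frozenset(product(range(cy - 1, cy + 2), range(cx - 1, cx + 2)))


def _rect(y0: int, y1: int, x0: int, x1: int) -> frozenset[tuple[int, int]]:
    """Filled rectangle with inclusive corners."""
    return frozenset(product(range(y0, y1 + 1), range(x0, x1 + 1)))


def worked_example() -> tuple[TrackingResult, TrackingResult]:
    """Return the (reference, computed) pair described in the module docs."""
    n_frames = 5
    ref_tracks: list[Track] = []
    ref_markers: list[Marker] = []
    comp_tracks: list[Track] = []
    comp_markers: list[Marker] = []

    def ref_track(label, t0, t1, parent, positions):
        ref_tracks.append(Track(label=label, t_init=t0, t_end=t1, parent=parent))
        for frame, pixels in zip(range(t0, t1 + 1), positions):
            ref_markers.append(Marker(label=label, frame=frame, pixels=pixels))

    def comp_track(label, t0, t1, parent, positions):
        comp_tracks.append(Track(label=label, t_init=t0, t_end=t1, parent=parent))
        for frame, pixels in zip(range(t0, t1 + 1), positions):
            comp_markers.append(Marker(label=label, frame=frame, pixels=pixels))

    # --- A: division with daughters merged for 2 frames (rows 0-14)
    ref_track(1, 0, 0, None, [_sq(5, 10)])
    ref_track(2, 1, 2, 1, [_sq(3, 10), _sq(3, 10)])
    ref_track(3, 1, 2, 1, [_sq(9, 10), _sq(9, 10)])
    comp_track(101, 0, 2, None,
               [_sq(5, 10), _rect(2, 10, 9, 11), _rect(2, 10, 9, 11)])

    # --- B: division with daughters merged for 3 frames (rows 16-30)
    ref_track(4, 0, 0, None, [_sq(20, 10)])
    ref_track(5, 1, 3, 4, [_sq(18, 10)] * 3)
    ref_track(6, 1, 3, 4, [_sq(24, 10)] * 3)
    comp_track(102, 0, 3, None,
               [_sq(20, 10)] + [_rect(17, 25, 9, 11)] * 3)

    # --- C: ref parent link reported as track continuation (rows 32-38)
    ref_track(7, 0, 0, None, [_sq(35, 10)])
    ref_track(8, 1, 1, 7, [_sq(35, 10)])
    comp_track(103, 0, 1, None, [_sq(35, 10), _sq(35, 10)])

    # --- D: ref track link reported as a division (rows 40-46)
    ref_track(9, 0, 1, None, [_sq(43, 10), _sq(43, 10)])
    comp_track(104, 0, 0, None, [_sq(43, 10)])
    comp_track(105, 1, 1, 104, [_sq(43, 10)])

    # --- E: identity swap onto an unrelated object (rows 48-56)
    ref_track(10, 0, 1, None, [_sq(51, 8), _sq(51, 8)])
    ref_track(11, 1, 1, None, [_sq(51, 14)])
    comp_track(106, 0, 1, None, [_sq(51, 8), _sq(51, 14)])  # drifts onto 11
    comp_track(107, 1, 1, None, [_sq(51, 8)])  # true continuation, unlinked

    # --- F: missed subtree below a detected mother (rows 58-72)
    ref_track(12, 0, 0, None, [_sq(63, 10)])
    ref_track(13, 1, 3, 12, [_sq(63, 10)] * 3)  # entirely missed
    ref_track(14, 4, 4, 13, [_sq(61, 10)])  # missed
    ref_track(15, 4, 4, 13, [_sq(66, 10)])  # missed
    comp_track(108, 0, 0, None, [_sq(63, 10)])

    # --- G: three spurious detections (rows 74-80)
    comp_track(109, 0, 0, None, [_sq(77, 10)])
    comp_track(110, 1, 1, None, [_sq(77, 10)])
    comp_track(111, 2, 2, None, [_sq(77, 10)])

    ref = TrackingResult(
        n_frames=n_frames,
        tracks={t.label: t for t in ref_tracks},
        markers={m.node_id: m for m in ref_markers},
    )
    comp = TrackingResult(
        n_frames=n_frames,
        tracks={t.label: t for t in comp_tracks},
        markers={m.node_id: m for m in comp_markers},
    )
    return ref, comp
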