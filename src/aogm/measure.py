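"""Weighted aggregation of tracking error counts.

The tracking accuracy of a computed lineage is the weighted cost of
transforming its graph into the reference graph,

    AOGM = w_NS NS + w_FN FN + w_FP FP + w_ED ED + w_EA EA + w_EC EC,

with non-negative weights, at least one positive.  Zeroing the edge weights
gives the detection-only variant (AOGM-D); zeroing the vertex weights gives
the association-only variant (AOGM-A); the full value is their sum.

The value equals the *minimum* transformation cost whenever splitting a
non-split vertex with ``m`` assigned reference markers is never costlier than
deleting it and adding ``m`` fresh vertices:

    w_NS (m* - 1) <= w_FP + w_FN m*,

where ``m*`` is the largest fiber over all non-split vertices.  The
input-independent weakened form is ``w_NS <= w_FN``.

Weighted values are computed as exact rationals internally (counts are
integers, weights decimal) and surfaced as floats, so a weight of 1.5 never
introduces rounding surprises.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from fractions import Fraction
from math import nan
from typing import Iterable, Sequence

from .matching import ErrorCounts, compare_graphs
from .model import TrackingGraph, TrackingResult, restrict_to_frames, tracks_to_graph

__all__ = [
    "WeightVector",
    "ErrorCounts",
    "Variant",
    "CHALLENGE_WEIGHTS",
    "aggregate",
    "variant_weights",
    "MinimalityCheck",
    "check_minimality",
    "NormalizedRates",
    "normalized_rates",
    "temporal_evolution",
]

WEIGHT_NAMES = ("ns", "fn", "fp", "ed", "ea", "ec")


@dataclass(frozen=True)
class WeightVector:
    """The six non-negative penalties, at least one positive.

    Defaults are the reference configuration of the first Cell Tracking
    Challenge, reflecting the manual effort of correcting each error type:
    5 per split, 10 per added vertex, 1 per deleted vertex, 1 per deleted
    edge, 1.5 per added edge, 1 per semantics change.
    """

    ns: float = 5.0
    fn: float = 10.0
    fp: float = 1.0
    ed: float = 1.0
    ea: float = 1.5
    ec: float = 1.0

    def __post_init__(self) -> None:
        values = self.as_tuple()
        if any(w < 0 for w in values):
            raise ValueError(f"weights must be non-negative, got {values}")
        if all(w == 0 for w in values):
            raise ValueError("at least one weight must be positive")

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.ns, self.fn, self.fp, self.ed, self.ea, self.ec)

    @classmethod
    def from_sequence(cls, values: Sequence[float]) -> "WeightVector":
        if len(values) != 6:
            raise ValueError(f"expected 6 weights (ns, fn, fp, ed, ea, ec), got {len(values)}")
        return cls(*[float(v) for v in values])


#: the reference weight configuration of the first Cell Tracking Challenge
CHALLENGE_WEIGHTS = WeightVector()


class Variant(enum.Enum):
    """Which error families contribute to the aggregated value."""

    FULL = "full"
    DETECTION = "d"
    ASSOCIATION = "a"


def aggregate(counts: ErrorCounts, w: WeightVector) -> float:
    """The weighted transformation cost of ``counts`` under ``w``.

    Zero iff every positively weighted count is zero.
    """
    total = Fraction(0)
    for name, count in zip(WEIGHT_NAMES, counts.as_tuple()):
        total += Fraction(getattr(w, name)) * count
    return float(total)


def variant_weights(w: WeightVector, variant: Variant) -> WeightVector:
    """Zero out the weight family the variant ignores.

    DETECTION keeps only the vertex-related weights (ns, fn, fp);
    ASSOCIATION keeps only the edge-related weights (ed, ea, ec); FULL is the
    identity.  Raises if the surviving weights are all zero.
    """
    if variant is Variant.FULL:
        return w
    if variant is Variant.DETECTION:
        return WeightVector(ns=w.ns, fn=w.fn, fp=w.fp, ed=0.0, ea=0.0, ec=0.0)
    if variant is Variant.ASSOCIATION:
        return WeightVector(ns=0.0, fn=0.0, fp=0.0, ed=w.ed, ea=w.ea, ec=w.ec)
    raise ValueError(f"unknown variant {variant!r}")


@dataclass(frozen=True)
class MinimalityCheck:
    """Outcome of the minimality condition on a weight vector."""

    holds: bool
    weakened_holds: bool
    m_star: int


def check_minimality(w: WeightVector, m_star: int = 1) -> MinimalityCheck:
    """Does splitting beat delete-plus-add for every fiber up to ``m_star``?

    Checks ``w_NS (m* - 1) <= w_FP + w_FN m*``.  When it holds, the reported
    value is the minimum cost of transforming the computed graph into the
    reference one, not merely the cost of the canonical operation sequence.
    Also reports the input-independent weakened condition ``w_NS <= w_FN``.
    """
    if m_star < 1:
        raise ValueError(f"m_star must be >= 1, got {m_star}")
    holds = w.ns * (m_star - 1) <= w.fp + w.fn * m_star
    return MinimalityCheck(holds=holds, weakened_holds=w.ns <= w.fn, m_star=m_star)


@dataclass(frozen=True)
class NormalizedRates:
    """Error counts normalized per reference vertex (NS, FN, FP) or per
    reference edge (ED, EA, EC).

    Rates with a zero denominator are NaN with the matching ``*_defined``
    flag cleared; no exception is raised.
    """

    ns: float
    fn: float
    fp: float
    ed: float
    ea: float
    ec: float
    vertex_rates_defined: bool
    edge_rates_defined: bool

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.ns, self.fn, self.fp, self.ed, self.ea, self.ec)


def normalized_rates(counts: ErrorCounts) -> NormalizedRates:
    """Normalize the six counts by the reference graph sizes."""
    nv, ne = counts.n_ref_vertices, counts.n_ref_edges
    vdef, edef = nv > 0, ne > 0
    return NormalizedRates(
        ns=counts.ns / nv if vdef else nan,
        fn=counts.fn / nv if vdef else nan,
        fp=counts.fp / nv if vdef else nan,
        ed=counts.ed / ne if edef else nan,
        ea=counts.ea / ne if edef else nan,
        ec=counts.ec / ne if edef else nan,
        vertex_rates_defined=vdef,
        edge_rates_defined=edef,
    )


def temporal_evolution(
    ref: TrackingResult, comp: TrackingResult, w: WeightVector = CHALLENGE_WEIGHTS
) -> list[tuple[int, float]]:
    """Per-prefix measure values: entry ``t`` compares frames ``0..t``.

    Each prefix is compared from scratch — O(N) comparisons, but every entry
    is exactly the measure of the truncated pair and the final entry equals
    the full value.  The series is non-decreasing: extending the prefix never
    removes an error already counted.
    """
    ref_graph = tracks_to_graph(ref)
    comp_graph = tracks_to_graph(comp)
    if ref.n_frames != comp.n_frames:
        raise ValueError(
            f"frame counts differ: reference {ref.n_frames}, computed {comp.n_frames}"
        )
    series = []
    for t in range(ref.n_frames):
        report = compare_graphs(
            restrict_to_frames(ref_graph, t), restrict_to_frames(comp_graph, t)
        )
        series.append((t, aggregate(report.counts, w)))
    return series
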