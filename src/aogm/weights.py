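"""Ranking of algorithms and sensitivity of rankings to the weight choice.

Because the measure is linear in the weights, the weight configurations that
produce one fixed ranking of a set of algorithms form polygonal sectors of
weight space; the borderlines are configurations where at least two
algorithms tie.  This module ranks error-count vectors under a weight
configuration, counts ranking transpositions (Kendall distance), and maps the
sectors over a 2-D rectangle of weight space by grid sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .matching import ErrorCounts
from .measure import WEIGHT_NAMES, WeightVector, aggregate

__all__ = [
    "Ranking",
    "rank_algorithms",
    "transpositions",
    "SectorMap",
    "sector_map",
]


@dataclass(frozen=True)
class Ranking:
    """Ascending-value ranking of algorithms (rank 1 = lowest cost = best).

    ``ranks[i]`` is the rank of algorithm ``i`` in input order.  Exact ties
    share a rank (competition style) and are reported explicitly in
    ``tied_groups``; they are never broken silently.
    """

    ranks: tuple[int, ...]
    values: tuple[float, ...]
    tied_groups: tuple[tuple[int, ...], ...] = ()

    @property
    def has_ties(self) -> bool:
        return bool(self.tied_groups)


def _rank_values(values: Sequence[float]) -> Ranking:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0] * len(values)
    tied: list[tuple[int, ...]] = []
    rank = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        group = order[i:j]
        rank = i + 1
        for idx in group:
            ranks[idx] = rank
        if len(group) > 1:
            tied.append(tuple(sorted(group)))
        i = j
    return Ranking(ranks=tuple(ranks), values=tuple(values), tied_groups=tuple(tied))


def rank_algorithms(
    counts_list: Sequence[ErrorCounts], w: WeightVector
) -> Ranking:
    """Rank algorithms by ascending measure value: higher cost, worse rank."""
    if len(counts_list) < 2:
        raise ValueError("ranking needs at least two algorithms")
    return _rank_values([aggregate(c, w) for c in counts_list])


def transpositions(r: Ranking | Sequence[int], reference: Ranking | Sequence[int]) -> int:
    """Kendall distance: number of algorithm pairs ordered differently.

    Pairs tied in either ranking do not count as discordant.
    """
    a = tuple(r.ranks) if isinstance(r, Ranking) else tuple(r)
    b = tuple(reference.ranks) if isinstance(reference, Ranking) else tuple(reference)
    if len(a) != len(b):
        raise ValueError(f"ranking lengths differ: {len(a)} vs {len(b)}")
    count = 0
    for i, j in combinations(range(len(a)), 2):
        da, db = a[i] - a[j], b[i] - b[j]
        if da * db < 0:
            count += 1
    return count


@dataclass(frozen=True)
class SectorMap:
    """Grid-sampled map of ranking sectors over a 2-D weight rectangle.

    ``ranking_index[iy, ix]`` identifies the ranking at grid cell
    (``axis2`` value ``iy``, ``axis1`` value ``ix``); ``-1`` marks cells lying
    exactly on a tie borderline (a "tie" pseudo-sector, never broken
    arbitrarily).  ``sector_areas`` maps each ranking (and ``None`` for the
    tie cells) to its relative area in percent; ``transposition_areas``
    aggregates those areas by Kendall distance from the ranking at the
    reference point.
    """

    axis_names: tuple[str, str]
    axis1: np.ndarray
    axis2: np.ndarray
    ranking_index: np.ndarray
    rankings: tuple[tuple[int, ...], ...]
    cell_transpositions: np.ndarray
    reference_ranking: tuple[int, ...]
    reference_point: tuple[float, float]
    sector_areas: dict[Optional[tuple[int, ...]], float]
    transposition_areas: dict[Optional[int], float]


def sector_map(
    counts_list: Sequence[ErrorCounts],
    axes: tuple[str, str],
    domain: tuple[tuple[float, float], tuple[float, float]],
    fixed: WeightVector,
    resolution: int = 201,
    reference_point: Optional[tuple[float, float]] = None,
) -> SectorMap:
    """Sample rankings on a uniform grid over a rectangle of weight space.

    The two ``axes`` weights sweep their ``domain`` intervals while the
    remaining four stay at their ``fixed`` values.  The reference ranking is
    taken at ``reference_point`` (domain centre by default, mirroring a
    rectangle centered at the reference configuration).
    """
    name1, name2 = axes
    if name1 == name2:
        raise ValueError("the two axes must be distinct weights")
    for name in axes:
        if name not in WEIGHT_NAMES:
            raise ValueError(f"unknown weight name {name!r}; expected one of {WEIGHT_NAMES}")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    (lo1, hi1), (lo2, hi2) = domain
    if reference_point is None:
        reference_point = ((lo1 + hi1) / 2.0, (lo2 + hi2) / 2.0)
    if not (lo1 <= reference_point[0] <= hi1 and lo2 <= reference_point[1] <= hi2):
        raise ValueError(f"reference point {reference_point} outside domain {domain}")

    counts = np.array([c.as_tuple() for c in counts_list], dtype=float)  # (n_alg, 6)
    idx1, idx2 = WEIGHT_NAMES.index(name1), WEIGHT_NAMES.index(name2)
    fixed_w = np.array(fixed.as_tuple(), dtype=float)
    base_mask = np.ones(6)
    base_mask[[idx1, idx2]] = 0.0
    const = counts @ (fixed_w * base_mask)  # (n_alg,)

    ax1 = np.linspace(lo1, hi1, resolution)
    ax2 = np.linspace(lo2, hi2, resolution)
    w1, w2 = np.meshgrid(ax1, ax2)  # (res, res), rows vary axis2
    # value[a, iy, ix] = const[a] + c1[a] w1 + c2[a] w2
    values = (
        const[:, None, None]
        + counts[:, idx1][:, None, None] * w1[None, :, :]
        + counts[:, idx2][:, None, None] * w2[None, :, :]
    )

    n_alg = len(counts_list)
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    tied = np.any(np.diff(sorted_vals, axis=0) == 0, axis=0)

    # competition ranks from the sort order (ties flagged separately)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, n_alg + 1)[:, None, None], axis=0)

    ref_vals = [
        aggregate(
            c,
            _with_axes(fixed, axes, reference_point),
        )
        for c in counts_list
    ]
    ref_ranking = _rank_values(ref_vals)
    if ref_ranking.has_ties:
        raise ValueError("reference point lies on a tie borderline; move it")

    codes = np.tensordot(
        (n_alg + 1) ** np.arange(n_alg), ranks, axes=([0], [0])
    )  # unique integer per ranking
    codes = np.where(tied, -1, codes)
    unique_codes = sorted(c for c in np.unique(codes) if c >= 0)

    rankings: list[tuple[int, ...]] = []
    ranking_index = np.full(codes.shape, -1, dtype=int)
    cell_trans = np.full(codes.shape, -1, dtype=int)
    sector_areas: dict[Optional[tuple[int, ...]], float] = {}
    trans_areas: dict[Optional[int], float] = {}
    total = codes.size
    for k, code in enumerate(unique_codes):
        mask = codes == code
        iy, ix = np.argwhere(mask)[0]
        ranking = tuple(int(r) for r in ranks[:, iy, ix])
        rankings.append(ranking)
        ranking_index[mask] = k
        t = transpositions(ranking, ref_ranking.ranks)
        cell_trans[mask] = t
        area = 100.0 * mask.sum() / total
        sector_areas[ranking] = sector_areas.get(ranking, 0.0) + area
        trans_areas[t] = trans_areas.get(t, 0.0) + area
    tie_area = 100.0 * (codes == -1).sum() / total
    if tie_area:
        sector_areas[None] = tie_area
        trans_areas[None] = tie_area

    return SectorMap(
        axis_names=(name1, name2),
        axis1=ax1,
        axis2=ax2,
        ranking_index=ranking_index,
        rankings=tuple(rankings),
        cell_transpositions=cell_trans,
        reference_ranking=ref_ranking.ranks,
        reference_point=reference_point,
        sector_areas=sector_areas,
        transposition_areas=trans_areas,
    )


def _with_axes(
    fixed: WeightVector, axes: tuple[str, str], point: tuple[float, float]
) -> WeightVector:
    values = dict(zip(WEIGHT_NAMES, fixed.as_tuple()))
    values[axes[0]] = point[0]
    values[axes[1]] = point[1]
    return WeightVector(**values)
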