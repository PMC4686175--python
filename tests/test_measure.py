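"""Weighted aggregation, variants, minimality and temporal evolution."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aogm import (
    CHALLENGE_WEIGHTS,
    ErrorCounts,
    LineageParams,
    Variant,
    WeightVector,
    aggregate,
    check_minimality,
    compare,
    generate_reference,
    inject_errors,
    normalized_rates,
    random_edit_script,
    temporal_evolution,
    variant_weights,
)
from aogm.synthetic import DeleteVertex, EditScript

import numpy as np

from conftest import build_result, square

EXAMPLE_COUNTS = ErrorCounts(ns=5, fn=5, fp=3, ed=1, ea=16, ec=2,
                             n_ref_vertices=25, n_ref_edges=18, m_star=2)


class TestAggregate:
    def test_challenge_weights_on_example_counts(self):
        # 5*5 + 10*5 + 1*3 + 1*1 + 1.5*16 + 1*2
        assert aggregate(EXAMPLE_COUNTS, CHALLENGE_WEIGHTS) == 105.0

    def test_zero_counts_cost_nothing(self):
        assert aggregate(ErrorCounts(), CHALLENGE_WEIGHTS) == 0.0

    def test_single_term(self):
        counts = ErrorCounts(fn=1)
        assert aggregate(counts, WeightVector(ns=0, fn=10, fp=0, ed=0, ea=0, ec=0)) == 10.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            WeightVector(ns=-1)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightVector(ns=0, fn=0, fp=0, ed=0, ea=0, ec=0)


class TestVariants:
    def test_detection_zeroes_edge_weights(self):
        w = variant_weights(CHALLENGE_WEIGHTS, Variant.DETECTION)
        assert w.as_tuple() == (5, 10, 1, 0, 0, 0)

    def test_association_zeroes_vertex_weights(self):
        w = variant_weights(CHALLENGE_WEIGHTS, Variant.ASSOCIATION)
        assert w.as_tuple() == (0, 0, 0, 1, 1.5, 1)

    def test_full_is_identity(self):
        assert variant_weights(CHALLENGE_WEIGHTS, Variant.FULL) is CHALLENGE_WEIGHTS

    @given(
        counts=st.tuples(*[st.integers(0, 50)] * 6),
    )
    @settings(max_examples=200, deadline=None)
    def test_full_decomposes_into_detection_plus_association(self, counts):
        c = ErrorCounts(*counts)
        full = aggregate(c, CHALLENGE_WEIGHTS)
        d = aggregate(c, variant_weights(CHALLENGE_WEIGHTS, Variant.DETECTION))
        a = aggregate(c, variant_weights(CHALLENGE_WEIGHTS, Variant.ASSOCIATION))
        assert full == d + a


class TestMinimality:
    def test_challenge_weights_always_minimal(self):
        for m in range(1, 20):
            assert check_minimality(CHALLENGE_WEIGHTS, m).holds

    def test_inverted_weights_minimal_only_for_small_fibers(self):
        w = WeightVector(ns=10, fn=1, fp=10, ed=0, ea=0, ec=0)
        small = check_minimality(w, 2)
        assert small.holds and not small.weakened_holds  # 10 <= 12, but 10 > 1
        assert not check_minimality(w, 12).holds  # 110 > 22

    @given(
        ns=st.floats(0, 20), fn=st.floats(0, 20), fp=st.floats(0, 20),
        m_star=st.integers(1, 10),
    )
    @settings(max_examples=300, deadline=None)
    def test_condition_implies_split_never_costlier(self, ns, fn, fp, m_star):
        """Whenever the condition holds, splitting beats delete-plus-add for
        every fiber size up to m_star."""
        try:
            w = WeightVector(ns=ns, fn=fn, fp=fp, ed=1, ea=1, ec=1)
        except ValueError:
            return
        if check_minimality(w, m_star).holds:
            for m in range(2, m_star + 1):
                # the condition at m* bounds every smaller fiber too
                if check_minimality(w, m).holds:
                    assert w.ns * (m - 1) <= w.fp + w.fn * m

    def test_m_star_below_one_rejected(self):
        with pytest.raises(ValueError):
            check_minimality(CHALLENGE_WEIGHTS, 0)


class TestNormalizedRates:
    def test_rates_divide_by_reference_sizes(self):
        counts = ErrorCounts(fn=5, ea=3, n_ref_vertices=10, n_ref_edges=4)
        rates = normalized_rates(counts)
        assert rates.fn == 0.5
        assert rates.ea == 0.75
        assert rates.vertex_rates_defined and rates.edge_rates_defined

    def test_zero_counts_give_zero_rates(self):
        rates = normalized_rates(ErrorCounts(n_ref_vertices=7, n_ref_edges=3))
        assert rates.as_tuple() == (0, 0, 0, 0, 0, 0)

    def test_zero_denominators_flagged_not_raised(self):
        rates = normalized_rates(ErrorCounts(fn=1))
        assert not rates.vertex_rates_defined and not rates.edge_rates_defined
        assert rates.fn != rates.fn  # NaN


class TestTemporalEvolution:
    def test_identity_series_is_zero(self, small_reference):
        series = temporal_evolution(small_reference, small_reference)
        assert [v for _, v in series] == [0.0] * small_reference.n_frames

    def test_single_missed_marker_appears_at_its_frame(self):
        # one track over 3 frames; computed misses the final marker
        tracks = [(1, 0, 2, None)]
        markers = [(1, t, square(2, 2 + t)) for t in range(3)]
        ref = build_result(3, tracks, markers)
        comp = build_result(3, [(1, 0, 1, None)], markers[:2])
        series = temporal_evolution(ref, comp, CHALLENGE_WEIGHTS)
        # before frame 2 the prefixes agree; at frame 2 one FN and one
        # missing track link enter: 10 + 1.5
        assert series == [(0, 0.0), (1, 0.0), (2, 11.5)]

    def test_final_entry_equals_full_measure(self, small_reference):
        rng = np.random.default_rng(3)
        script = random_edit_script(small_reference, rng, n_edits=2)
        comp, _ = inject_errors(small_reference, script)
        series = temporal_evolution(small_reference, comp)
        full = aggregate(compare(small_reference, comp).counts, CHALLENGE_WEIGHTS)
        assert series[-1][1] == full

    @pytest.mark.parametrize("seed", range(20))
    def test_series_is_non_decreasing(self, seed):
        ref = generate_reference(LineageParams(n_frames=8, n_initial=4, seed=seed))
        rng = np.random.default_rng(seed + 100)
        comp, _ = inject_errors(ref, random_edit_script(ref, rng, n_edits=3))
        series = temporal_evolution(ref, comp)
        values = [v for _, v in series]
        assert all(a <= b for a, b in zip(values, values[1:]))


def test_adding_an_error_never_decreases_full_measure(small_reference):
    """Monotonicity: appending one more disjoint edit can only raise the cost."""
    rng = np.random.default_rng(11)
    script = random_edit_script(small_reference, rng, n_edits=1)
    comp1, _ = inject_errors(small_reference, script)
    base = aggregate(compare(small_reference, comp1).counts, CHALLENGE_WEIGHTS)
    # delete one more interior vertex of a track untouched by the first edit
    from aogm import ScriptError

    candidates = [
        (t.label, t.t_init + 1)
        for t in small_reference.tracks.values()
        if t.t_end - t.t_init >= 2
    ]
    comp2 = None
    for site in candidates:
        extended = EditScript(edits=script.edits + (DeleteVertex(*site),))
        try:
            comp2, _ = inject_errors(small_reference, extended)
            break
        except ScriptError:
            continue
    assert comp2 is not None
    worse = aggregate(compare(small_reference, comp2).counts, CHALLENGE_WEIGHTS)
    assert worse >= base
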