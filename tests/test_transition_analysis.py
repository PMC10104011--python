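"""LCS metric and monotone distance-pattern extraction."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hubnet.boolean_network import Trajectory
from hubnet.transition_analysis import (
    distance_increase_counts,
    extract_patterns,
    hamming_distance,
    lcs_distance,
    lcs_length,
    on_probability_at_decrease_initiation,
    tf_pattern_frequencies,
)

binary_vec = st.lists(st.integers(0, 1), min_size=1, max_size=20)


class TestLCS:
    def test_identity(self):
        v = (1, 0, 1, 1, 0)
        assert lcs_length(v, v) == len(v)
        assert lcs_distance(v, v) == 0

    def test_hand_dp_cases(self):
        assert lcs_length((1, 0), (0, 1)) == 1
        assert lcs_length((1, 1), (0, 0)) == 0
        assert lcs_distance((1, 0), (0, 1)) == 2      # 2+2-2*1
        assert lcs_distance((1, 1, 1), (0, 0, 0)) == 6  # A=0
        assert lcs_distance((1, 1), (0, 0)) == 4

    def test_as_printed_form_returns_m_on_identity(self):
        v = (1, 0, 1)
        assert lcs_distance(v, v, form="as-printed") == len(v)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            lcs_length((1,), (1, 0))
        with pytest.raises(ValueError):
            lcs_distance((1,), (1, 0))

    @settings(max_examples=150, derandomize=True)
    @given(binary_vec, st.data())
    def test_metric_axioms(self, v1, data):
        v2 = data.draw(st.lists(st.integers(0, 1), min_size=len(v1),
                                max_size=len(v1)))
        v3 = data.draw(st.lists(st.integers(0, 1), min_size=len(v1),
                                max_size=len(v1)))
        d12 = lcs_distance(v1, v2)
        assert d12 >= 0
        assert d12 <= 2 * len(v1)
        assert d12 == lcs_distance(v2, v1)
        assert (d12 == 0) == (v1 == v2)
        assert lcs_distance(v1, v3) <= d12 + lcs_distance(v2, v3)


class TestHamming:
    def test_cases(self):
        assert hamming_distance((1, 0), (1, 0)) == 0
        assert hamming_distance((1, 0), (0, 1)) == 2
        assert hamming_distance((1, 1, 0), (1, 0, 0)) == 1


def make_traj(distances, updated, hit=False):
    """Trajectory with dummy states (distance analytics only need the series
    and the update labels; states are used for initiation lookups)."""
    states = [(i % 2, 1) for i in range(len(distances))]
    return Trajectory(nodes=["x", "y"], states=states, updated_nodes=updated,
                      distances=list(distances), hit=hit,
                      hit_iteration=len(updated) if hit else None)


class TestExtractPatterns:
    def test_worked_series(self):
        # series 5,5,4,3,3,4,2 with updates x,a,b,c,d,e
        traj = make_traj([5, 5, 4, 3, 3, 4, 2], ["x", "a", "b", "c", "d", "e"])
        pats = extract_patterns(traj)
        assert [(p.direction, [e.node for e in p.events]) for p in pats] == [
            ("decreasing", ["a", "b"]),
            ("increasing", ["d"]),
            ("decreasing", ["e"]),
        ]

    def test_initiation_states(self):
        traj = make_traj([5, 5, 4, 3, 3, 4, 2], ["x", "a", "b", "c", "d", "e"])
        pats = extract_patterns(traj)
        # first decreasing pattern starts at iteration 2 -> state after iter 1
        assert pats[0].initiation_state == traj.states[1]
        assert pats[1].initiation_state == traj.states[4]

    def test_monotone_series_single_pattern(self):
        traj = make_traj([4, 3, 2, 1, 0], list("abcd"))
        pats = extract_patterns(traj)
        assert len(pats) == 1
        assert len(pats[0].events) == 4

    def test_constant_series_no_patterns(self):
        traj = make_traj([3, 3, 3], ["a", "b"])
        assert extract_patterns(traj) == []

    def test_directions_alternate_and_events_partition(self):
        rng = random.Random(8)
        for _ in range(30):
            n = rng.randint(2, 60)
            dists = [rng.randint(0, 6)]
            for _ in range(n):
                dists.append(max(0, dists[-1] + rng.randint(-2, 2)))
            traj = make_traj(dists, [f"n{i}" for i in range(n)])
            pats = extract_patterns(traj)
            for a, b in zip(pats, pats[1:]):
                assert a.direction != b.direction
            n_events = sum(len(p.events) for p in pats)
            n_changes = sum(1 for a, b in zip(dists, dists[1:]) if a != b)
            assert n_events == n_changes


class TestPatternStatistics:
    def test_frequencies_from_worked_series(self):
        traj = make_traj([5, 5, 4, 3, 3, 4, 2], ["x", "a", "b", "c", "d", "e"])
        pats = extract_patterns(traj)
        assert dict(tf_pattern_frequencies(pats, "decreasing")) == \
            {"a": 1, "b": 1, "e": 1}
        assert dict(tf_pattern_frequencies(pats, "increasing")) == {"d": 1}

    def test_increasing_on_monotone_decreasing_is_empty(self):
        traj = make_traj([4, 3, 2, 1], list("abc"))
        pats = extract_patterns(traj)
        assert tf_pattern_frequencies(pats, "increasing") == {}

    def test_counts_conservation(self):
        traj = make_traj([5, 5, 4, 3, 3, 4, 2], ["x", "a", "b", "c", "d", "e"])
        pats = extract_patterns(traj)
        dec = tf_pattern_frequencies(pats, "decreasing")
        n_dec_events = sum(len(p.events) for p in pats
                           if p.direction == "decreasing")
        assert sum(dec.values()) == n_dec_events

    def test_distance_increase_counts(self):
        traj = make_traj([5, 5, 4, 3, 3, 4, 2], ["x", "a", "b", "c", "d", "e"])
        assert dict(distance_increase_counts([traj])) == {"d": 1}
        mono = make_traj([4, 3, 2, 1], list("abc"))
        assert dict(distance_increase_counts([mono])) == {}

    def test_additive_across_trajectories(self):
        t1 = make_traj([3, 2, 3], ["a", "b"])
        t2 = make_traj([3, 2, 3], ["a", "b"])
        both = distance_increase_counts([t1, t2])
        single = distance_increase_counts([t1])
        assert both["b"] == 2 * single["b"]


class TestOnProbabilityAtDecreaseInitiation:
    def test_direct_fraction(self):
        # two decreasing patterns; node x is ON in exactly one initiation state
        t = Trajectory(nodes=["x", "y"],
                       states=[(1, 1), (1, 0), (0, 0), (0, 1), (0, 0)],
                       updated_nodes=["y", "x", "y", "y"],
                       distances=[2, 1, 1, 2, 1], hit=False, hit_iteration=None)
        pats = extract_patterns(t)
        probs = on_probability_at_decrease_initiation(pats, nodes=t.nodes)
        assert probs["x"] == pytest.approx(0.5)
        assert probs["y"] == pytest.approx(1.0)

    def test_requires_decreasing_patterns(self):
        traj = make_traj([1, 2, 3], ["a", "b"])
        with pytest.raises(ValueError, match="no decreasing"):
            on_probability_at_decrease_initiation(extract_patterns(traj))
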