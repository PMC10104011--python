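"""Distance metrics and monotone-pattern analytics of transition trajectories.

The distance between the instantaneous network state and the target state is
based on the longest common subsequence (LCS): with ``A(v1, v2)`` the LCS
length of two binary vectors of length ``m``, the metric form is

    d(v1, v2) = A(v1, v1) + A(v2, v2) - 2 A(v1, v2) = 2 m - 2 A(v1, v2),

which is zero exactly on identical vectors and is sensitive to the *order*
of matches, not only the per-position agreement that Hamming distance sees.
An ``as-printed`` variant without the factor two is kept for fidelity with
the formula as sometimes typeset (it gives ``d(v, v) = m``; see the methods
note).

Along a trajectory the distance-to-target series rises and falls; maximal
runs of consecutive same-sign *change events* are the distance-increasing /
-decreasing patterns.  Counting which node's update produced each change
event, and inspecting the state that initiates each decreasing pattern,
attributes the transition to individual transcription factors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .boolean_network import Trajectory

__all__ = [
    "lcs_length",
    "lcs_distance",
    "hamming_distance",
    "ChangeEvent",
    "Pattern",
    "extract_patterns",
    "tf_pattern_frequencies",
    "distance_increase_counts",
    "on_probability_at_decrease_initiation",
]


def lcs_length(v1: Sequence[int], v2: Sequence[int]) -> int:
    """Longest-common-subsequence length of two equal-length vectors.

    Classic O(m^2) dynamic program over a rolling row.
    """
    if len(v1) != len(v2):
        raise ValueError(f"length mismatch: {len(v1)} vs {len(v2)}")
    m = len(v1)
    prev = [0] * (m + 1)
    for a in v1:
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a == v2[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                pj = prev[j]
                cj = cur[j - 1]
                cur[j] = pj if pj >= cj else cj
        prev = cur
    return prev[m]


def lcs_distance(v1: Sequence[int], v2: Sequence[int],
                 form: str = "standard") -> int:
    """LCS-based distance between two states.

    ``standard`` (default): ``A(v1,v1) + A(v2,v2) - 2 A(v1,v2)`` — a true
    metric with ``d(v, v) = 0``.  ``as-printed``: ``A(v1,v1) + A(v2,v2) -
    A(v1,v2)``, the literal single-count form (``d(v, v) = m``).
    """
    if len(v1) != len(v2):
        raise ValueError(f"length mismatch: {len(v1)} vs {len(v2)}")
    a = lcs_length(v1, v2)
    m = len(v1)
    if form == "standard":
        return 2 * m - 2 * a
    if form == "as-printed":
        return 2 * m - a
    raise ValueError(f"unknown form {form!r}")


def hamming_distance(v1: Sequence[int], v2: Sequence[int]) -> int:
    """Number of positions at which two equal-length vectors differ."""
    if len(v1) != len(v2):
        raise ValueError(f"length mismatch: {len(v1)} vs {len(v2)}")
    return sum(1 for a, b in zip(v1, v2) if a != b)


@dataclass(frozen=True)
class ChangeEvent:
    """One iteration whose update changed the distance to target."""

    iteration: int
    node: str
    delta: int  # signed distance change, never 0


@dataclass(frozen=True)
class Pattern:
    """A maximal run of same-sign change events along one trajectory."""

    direction: str  # "increasing" | "decreasing"
    events: tuple[ChangeEvent, ...]
    initiation_state: tuple[int, ...]  # state just before the first event

    def __post_init__(self) -> None:
        sign = 1 if self.direction == "increasing" else -1
        if any((e.delta > 0) != (sign > 0) for e in self.events):
            raise ValueError("event sign inconsistent with pattern direction")


def extract_patterns(traj: Trajectory) -> list[Pattern]:
    """Split a trajectory's distance series into alternating monotone patterns.

    Only *change events* (iterations where the distance differs from the
    previous value) matter: flat stretches neither extend nor break a
    pattern.  Maximal runs of consecutive same-sign change events become
    patterns whose initiation state is the network state immediately before
    the run's first event.
    """
    dist = traj.distance_series()
    events: list[ChangeEvent] = []
    for t in range(1, len(dist)):
        delta = dist[t] - dist[t - 1]
        if delta != 0:
            events.append(ChangeEvent(t, traj.updated_nodes[t - 1], delta))
    patterns: list[Pattern] = []
    run: list[ChangeEvent] = []
    for ev in events:
        if run and (ev.delta > 0) != (run[-1].delta > 0):
            patterns.append(_close_run(run, traj))
            run = []
        run.append(ev)
    if run:
        patterns.append(_close_run(run, traj))
    return patterns


def _close_run(run: list[ChangeEvent], traj: Trajectory) -> Pattern:
    direction = "increasing" if run[0].delta > 0 else "decreasing"
    return Pattern(
        direction=direction,
        events=tuple(run),
        initiation_state=traj.states[run[0].iteration - 1],
    )


def tf_pattern_frequencies(
    patterns: Iterable[Pattern], direction: str
) -> Counter:
    """How often each node's update appears in patterns of one direction.

    Counts change events, so the totals equal the number of change events of
    that sign (a conservation law the tests verify).
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"unknown direction {direction!r}")
    counts: Counter = Counter()
    for pat in patterns:
        if pat.direction != direction:
            continue
        for ev in pat.events:
            counts[ev.node] += 1
    return counts


def distance_increase_counts(trajectories: Iterable[Trajectory]) -> Counter:
    """Per node: iterations whose update strictly increased the distance."""
    counts: Counter = Counter()
    for traj in trajectories:
        dist = traj.distance_series()
        for t in range(1, len(dist)):
            if dist[t] > dist[t - 1]:
                counts[traj.updated_nodes[t - 1]] += 1
    return counts


def on_probability_at_decrease_initiation(
    patterns: Iterable[Pattern], nodes: Sequence[str] | None = None
) -> dict[str, float]:
    """Per node: fraction of decreasing patterns it is ON in at initiation.

    The initiation state is the network state immediately before the
    pattern's first change event.  Raises ``ValueError`` when there are no
    decreasing patterns.
    """
    dec = [p for p in patterns if p.direction == "decreasing"]
    if not dec:
        raise ValueError("no decreasing patterns")
    if nodes is None:
        m = len(dec[0].initiation_state)
        labels = [f"node{i}" for i in range(m)]
    else:
        labels = list(nodes)
    on_counts = [0] * len(labels)
    for p in dec:
        for i, x in enumerate(p.initiation_state):
            on_counts[i] += x
    return {labels[i]: on_counts[i] / len(dec) for i in range(len(labels))}
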