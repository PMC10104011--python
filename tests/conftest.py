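"""Shared graph builders for the test suite (all generated at test time)."""

from __future__ import annotations

import itertools
import random

import pytest

from hubnet.graph_model import SimpleGraph


def complete_graph(n: int, probs: list[float] | None = None) -> SimpleGraph:
    nodes = [f"v{i}" for i in range(n)]
    edges = list(itertools.combinations(range(n), 2))
    weights = [1.0 - p for p in probs] if probs else None
    return SimpleGraph(nodes=nodes, edges=edges, weights=weights,
                       probabilities=probs)


def path_graph(n: int) -> SimpleGraph:
    return SimpleGraph(nodes=[f"v{i}" for i in range(n)],
                       edges=[(i, i + 1) for i in range(n - 1)])


def star_graph(n: int) -> SimpleGraph:
    return SimpleGraph(nodes=[f"v{i}" for i in range(n)],
                       edges=[(0, i) for i in range(1, n)])


def cycle_graph(n: int) -> SimpleGraph:
    return SimpleGraph(nodes=[f"v{i}" for i in range(n)],
                       edges=[(i, (i + 1) % n) for i in range(n)])


def random_connected_graph(n: int, rng: random.Random,
                           extra_p: float = 0.35,
                           weighted: bool = False) -> SimpleGraph:
    """Random spanning tree (guarantees connectivity) plus extra edges."""
    edges: set[tuple[int, int]] = set()
    order = list(range(n))
    rng.shuffle(order)
    for i in range(1, n):
        a = order[i]
        b = order[rng.randrange(i)]
        edges.add((min(a, b), max(a, b)))
    for u, v in itertools.combinations(range(n), 2):
        if (u, v) not in edges and rng.random() < extra_p:
            edges.add((u, v))
    edge_list = sorted(edges)
    probs = [rng.uniform(0.05, 1.0) for _ in edge_list] if weighted else None
    weights = [1.0 - p for p in probs] if probs else None
    return SimpleGraph(nodes=[f"v{i}" for i in range(n)], edges=edge_list,
                       weights=weights, probabilities=probs)


@pytest.fixture
def k4() -> SimpleGraph:
    return complete_graph(4)
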