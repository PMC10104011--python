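"""Signed regulatory networks and the undirected spanning-tree substrate.

A regulatory network arrives as a directed, signed edge list (transcription
factor interactions, optionally carrying a probability that the interaction
exists).  Spanning-tree analysis works on the undirected simple graph obtained
by dropping directions, self-loops and parallel edges; each undirected edge
carries a weight ``w = 1 - p`` so that high-confidence interactions are cheap
to keep.

Edge indices of the :class:`SimpleGraph` are 1-based and stable (assigned in
first-appearance order after merging), so chromosome vectors of the genetic
optimizer are portable across runs and processes.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "NetworkFormatError",
    "GraphStructureError",
    "SignedEdge",
    "SignedNetwork",
    "SimpleGraph",
    "SpanningTree",
    "InfeasibleSubset",
    "parse_network",
    "to_undirected",
    "total_pairwise_distance",
    "kruskal_from_subset",
    "tree_node_degrees",
]

ACTIVATION = "+"
INHIBITION = "-"

_SIGN_TOKENS = {
    "+": ACTIVATION,
    "activates": ACTIVATION,
    "-": INHIBITION,
    "−": INHIBITION,  # unicode minus, as typeset in many edge lists
    "inhibits": INHIBITION,
}


class NetworkFormatError(ValueError):
    """Malformed or invalid network input."""


class GraphStructureError(ValueError):
    """Graph violates a structural requirement (e.g. not a tree, disconnected)."""


@dataclass(frozen=True)
class SignedEdge:
    source: str
    target: str
    sign: str  # "+" or "-"
    p: float | None = None


@dataclass
class SignedNetwork:
    """Directed, signed, optionally probability-weighted interaction network."""

    nodes: list[str]
    edges: list[SignedEdge]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkFormatError("duplicate node labels")
        declared = set(self.nodes)
        for e in self.edges:
            if e.source not in declared or e.target not in declared:
                raise NetworkFormatError(
                    f"edge {e.source}->{e.target} uses an undeclared node"
                )
            if e.p is not None and not (0.0 <= e.p <= 1.0):
                raise NetworkFormatError(
                    f"edge {e.source}->{e.target}: p={e.p} outside [0, 1]"
                )

    @property
    def has_probabilities(self) -> bool:
        return all(e.p is not None for e in self.edges) and bool(self.edges)

    def regulators_of(self, node: str) -> list[tuple[str, str]]:
        """Incoming (source, sign) pairs of *node*, in edge order."""
        return [(e.source, e.sign) for e in self.edges if e.target == node]


@dataclass
class SimpleGraph:
    """Undirected simple graph with 1-based indexed edges.

    ``edges[i]`` is the unordered node-index pair of edge ``i+1``; ``weights``
    holds ``w = 1 - p`` per edge when the source network carried probabilities,
    else ``None`` (unweighted analysis).
    """

    nodes: list[str]
    edges: list[tuple[int, int]]  # 0-based node indices, u < v
    weights: list[float] | None = None
    probabilities: list[float] | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for u, v in self.edges:
            if u == v:
                raise GraphStructureError("self-loop in simple graph")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise GraphStructureError("parallel edge in simple graph")
            seen.add(key)
        if self.weights is not None and len(self.weights) != len(self.edges):
            raise GraphStructureError("weights length mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def is_weighted(self) -> bool:
        return self.weights is not None

    def edge(self, index: int) -> tuple[int, int]:
        """Node pair of the 1-based edge *index*."""
        if not (1 <= index <= len(self.edges)):
            raise IndexError(f"edge index {index} outside 1..{len(self.edges)}")
        return self.edges[index - 1]

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.nodes]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n_nodes

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for i, (u, v) in enumerate(self.edges, start=1):
            attrs = {"index": i}
            if self.weights is not None:
                attrs["weight"] = self.weights[i - 1]
            g.add_edge(u, v, **attrs)
        return g

    def to_json(self) -> str:
        records = []
        for i, (u, v) in enumerate(self.edges, start=1):
            rec = {"i": i, "u": self.nodes[u], "v": self.nodes[v]}
            if self.probabilities is not None:
                rec["p"] = self.probabilities[i - 1]
            if self.weights is not None:
                rec["w"] = self.weights[i - 1]
            records.append(rec)
        return json.dumps({"nodes": self.nodes, "edges": records}, indent=1)


@dataclass(frozen=True)
class SpanningTree:
    """A spanning tree as a sorted tuple of 1-based edge indices of its graph."""

    graph: SimpleGraph
    edge_indices: tuple[int, ...]
    total_distance: int = field(compare=False)
    weight_sum: float = field(compare=False)

    def degrees(self) -> dict[str, int]:
        return tree_node_degrees(self)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.graph.nodes]
        for i in self.edge_indices:
            u, v = self.graph.edge(i)
            adj[u].append(v)
            adj[v].append(u)
        return adj


@dataclass(frozen=True)
class InfeasibleSubset:
    """Why an edge subset failed to yield a spanning tree."""

    uncovered_nodes: tuple[str, ...]
    components: tuple[tuple[str, ...], ...]

    def __bool__(self) -> bool:  # a report is falsy so `if result:` means success
        return False


def parse_network(path) -> SignedNetwork:
    """Read a TSV edge list ``source<TAB>sign<TAB>target[<TAB>p]``.

    Sign tokens ``+``/``activates`` and ``-``/``inhibits`` are recognized;
    ``#``-prefixed lines and blank lines are skipped.  Nodes are collected from
    edge endpoints in first-appearance order.
    """
    nodes: list[str] = []
    seen: set[str] = set()
    edges: list[SignedEdge] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated rows
                fields = line.split()
            if len(fields) < 3:
                raise NetworkFormatError(
                    f"line {lineno}: expected source<TAB>sign<TAB>target[<TAB>p], got {line!r}"
                )
            src, sign_tok, dst = fields[0], fields[1], fields[2]
            sign = _SIGN_TOKENS.get(sign_tok.strip().lower())
            if sign is None:
                raise NetworkFormatError(
                    f"line {lineno}: unknown sign token {sign_tok!r}"
                )
            p: float | None = None
            if len(fields) >= 4 and fields[3].strip():
                try:
                    p = float(fields[3])
                except ValueError as exc:
                    raise NetworkFormatError(
                        f"line {lineno}: probability {fields[3]!r} is not a number"
                    ) from exc
                if not (0.0 <= p <= 1.0):
                    raise NetworkFormatError(
                        f"line {lineno}: probability {p} outside [0, 1]"
                    )
            for label in (src, dst):
                if label not in seen:
                    seen.add(label)
                    nodes.append(label)
            edges.append(SignedEdge(src, dst, sign, p))
    return SignedNetwork(nodes=nodes, edges=edges)


def write_network(net: SignedNetwork, path) -> None:
    """Write a network back to the TSV edge-list format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# source\tsign\ttarget\tp\n")
        for e in net.edges:
            if e.p is None:
                fh.write(f"{e.source}\t{e.sign}\t{e.target}\n")
            else:
                fh.write(f"{e.source}\t{e.sign}\t{e.target}\t{e.p:.6g}\n")


_MERGE_POLICIES = ("max", "mean", "noisy-or")


def to_undirected(net: SignedNetwork, probability_merge: str = "max") -> SimpleGraph:
    """Collapse a directed signed network onto its undirected simple graph.

    Self-loops are dropped (a spanning tree cannot use them); reciprocal or
    parallel directed edges merge into one undirected edge.  When the network
    carries probabilities, the merged probability follows *probability_merge*:
    ``max`` (default, keeps the strongest evidence), ``mean``, or ``noisy-or``
    (``1 - prod(1 - p)``).  Weight is ``w = 1 - p``.
    """
    if probability_merge not in _MERGE_POLICIES:
        raise ValueError(
            f"unknown merge policy {probability_merge!r}; choose from {_MERGE_POLICIES}"
        )
    index_of = {label: i for i, label in enumerate(net.nodes)}
    merged: dict[tuple[int, int], list[float]] = {}
    order: list[tuple[int, int]] = []
    any_p = any(e.p is not None for e in net.edges)
    for e in net.edges:
        u, v = index_of[e.source], index_of[e.target]
        if u == v:
            continue
        key = (min(u, v), max(u, v))
        if key not in merged:
            merged[key] = []
            order.append(key)
        if e.p is not None:
            merged[key].append(e.p)

    probs: list[float] | None = None
    weights: list[float] | None = None
    if any_p:
        probs = []
        for key in order:
            ps = merged[key]
            if not ps:
                raise NetworkFormatError(
                    "mixed weighted/unweighted edges: "
                    f"no probability for undirected edge {key}"
                )
            if probability_merge == "max":
                p = max(ps)
            elif probability_merge == "mean":
                p = sum(ps) / len(ps)
            else:  # noisy-or
                q = 1.0
                for x in ps:
                    q *= 1.0 - x
                p = 1.0 - q
            probs.append(p)
        weights = [1.0 - p for p in probs]
    return SimpleGraph(nodes=list(net.nodes), edges=order, weights=weights, probabilities=probs)


def _tree_bfs_distance_sum(adj: Sequence[Sequence[int]], start: int) -> tuple[int, int]:
    """(sum of distances from start, number of reached nodes) by BFS."""
    dist = {start: 0}
    q = deque([start])
    total = 0
    while q:
        u = q.popleft()
        du = dist[u]
        for w in adj[u]:
            if w not in dist:
                dist[w] = du + 1
                total += du + 1
                q.append(w)
    return total, len(dist)


def total_pairwise_distance(tree: SpanningTree | None = None, *,
                            adjacency: Sequence[Sequence[int]] | None = None) -> int:
    """Ordered-pair total path distance of a tree: ``sum_{i != j} d(v_i, v_j)``.

    The sum runs over ordered pairs, i.e. twice the unordered (Wiener-index)
    sum.  Computed by BFS from every node; raises :class:`GraphStructureError`
    if the edge set is not a spanning tree of its graph.
    """
    if adjacency is None:
        if tree is None:
            raise ValueError("either a tree or an adjacency list is required")
        n = tree.graph.n_nodes
        if len(tree.edge_indices) != max(n - 1, 0):
            raise GraphStructureError(
                f"{len(tree.edge_indices)} edges cannot span {n} nodes"
            )
        adjacency = tree.adjacency()
    n = len(adjacency)
    if n <= 1:
        return 0
    total = 0
    for start in range(n):
        s, reached = _tree_bfs_distance_sum(adjacency, start)
        if reached != n:
            raise GraphStructureError("edge set is disconnected, not a tree")
        total += s
    return total


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:  # path compression
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def kruskal_from_subset(
    g: SimpleGraph,
    subset: Sequence[int],
    weighted: bool = False,
) -> SpanningTree | InfeasibleSubset:
    """Genotype-to-phenotype map: extract a spanning tree from an edge subset.

    Unweighted mode considers edges in subset order, adding each unless it
    closes a cycle.  Weighted mode sorts the subset ascending by edge weight
    (ties broken by subset position) before the same greedy sweep.  If the
    subset's subgraph does not connect and span all nodes, an
    :class:`InfeasibleSubset` report is returned instead.
    """
    seen_idx: set[int] = set()
    for i in subset:
        if not (1 <= i <= g.n_edges):
            raise NetworkFormatError(f"edge index {i} outside 1..{g.n_edges}")
        if i in seen_idx:
            raise NetworkFormatError(f"duplicate edge index {i} in subset")
        seen_idx.add(i)

    order = list(subset)
    if weighted:
        if g.weights is None:
            raise GraphStructureError("weighted Kruskal requires edge weights")
        w = g.weights
        order.sort(key=lambda i: w[i - 1])  # stable: ties keep subset position
    n = g.n_nodes
    uf = _UnionFind(n)
    chosen: list[int] = []
    for i in order:
        u, v = g.edge(i)
        if uf.union(u, v):
            chosen.append(i)
            if len(chosen) == n - 1:
                break
    if len(chosen) != max(n - 1, 0):
        comps: dict[int, list[int]] = {}
        for x in range(n):
            comps.setdefault(uf.find(x), []).append(x)
        touched = {u for i in subset for u in g.edge(i)}
        uncovered = tuple(g.nodes[x] for x in range(n) if x not in touched)
        return InfeasibleSubset(
            uncovered_nodes=uncovered,
            components=tuple(
                tuple(g.nodes[x] for x in members) for members in comps.values()
            ),
        )
    edge_indices = tuple(sorted(chosen))
    adj: list[list[int]] = [[] for _ in range(n)]
    for i in edge_indices:
        u, v = g.edge(i)
        adj[u].append(v)
        adj[v].append(u)
    dist = total_pairwise_distance(adjacency=adj) if n > 1 else 0
    wsum = 0.0
    if g.weights is not None:
        wsum = sum(g.weights[i - 1] for i in edge_indices)
    return SpanningTree(graph=g, edge_indices=edge_indices,
                        total_distance=dist, weight_sum=wsum)


def tree_node_degrees(tree: SpanningTree) -> dict[str, int]:
    """Per-node degree of a spanning tree, keyed by node label."""
    deg = [0] * tree.graph.n_nodes
    for i in tree.edge_indices:
        u, v = tree.graph.edge(i)
        deg[u] += 1
        deg[v] += 1
    return {tree.graph.nodes[x]: deg[x] for x in range(tree.graph.n_nodes)}
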