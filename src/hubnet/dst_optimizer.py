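"""Genetic-algorithm search for dense spanning trees.

A *dense spanning tree* (DST) of a connected graph minimizes the total
pairwise path distance between all node pairs — equivalently it is the
minimum routing-cost / minimum Wiener-index spanning tree, an NP-hard
objective, which is why a metaheuristic is used.  The *minimum dense spanning
tree* (MDST) extension additionally minimizes the sum of edge weights
``w = 1 - p`` so that the tree keeps the most probable interactions; by
default the two objectives are scalarized lexicographically (distance first,
weight as tie-break).

The genotype is a fixed-length vector of distinct 1-based edge indices; the
phenotype is the spanning tree Kruskal extracts from that subset.  The
archive collects every distinct tree that attains the best objective seen,
mirroring the practice of reporting *all* co-optimal trees rather than one.

Exhaustive enumeration (:func:`enumerate_optimal_bruteforce`) and the
matrix-tree count (:func:`count_spanning_trees`) serve as ground-truth
oracles on small graphs.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .graph_model import (
    GraphStructureError,
    InfeasibleSubset,
    SimpleGraph,
    SpanningTree,
    _UnionFind,
    kruskal_from_subset,
    total_pairwise_distance,
)

__all__ = [
    "GAConfig",
    "ObjectiveValue",
    "TreeArchive",
    "evaluate_dst",
    "evaluate_mdst",
    "ga_search",
    "enumerate_optimal_bruteforce",
    "count_spanning_trees",
]

# weight sums are floats; co-optimality is decided up to this tolerance
_W_TOL = 1e-9


@dataclass(frozen=True)
class ObjectiveValue:
    """Objective of one evaluated chromosome/tree.

    ``distance`` is the ordered-pair total path distance of the extracted
    tree; ``weight`` is the sum of ``w = 1 - p`` over the tree's edges (MDST
    mode only, else ``None``); ``scalar`` is the value the GA minimizes under
    the active scalarization.
    """

    distance: int
    weight: float | None
    scalar: float

    def key(self) -> float:
        # the scalarization already encodes the active ordering (plain
        # distance, lexicographic, or weighted sum); round so that trees with
        # identical (distance, weight) compare equal despite float summation
        return round(self.scalar, 9)


@dataclass
class GAConfig:
    """Knobs of the genetic search; defaults suit desk-scale (<=35 node) graphs."""

    population: int = 80
    generations: int = 250
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    tournament: int = 3
    elitism: int = 2
    restarts: int = 20
    chromosome_length: int | None = None  # default min(M, ceil(1.5 (N-1)))
    seed: int = 0
    mode: str = "dst"  # "dst" | "mdst"
    scalarization: str = "lexicographic"  # or "weighted" with alpha
    alpha: float = 1.0
    # stop a restart after this many generations without improvement
    stall_patience: int = 25
    # score the literal chromosome weight sum instead of the tree's edges
    weight_on_chromosome: bool = False
    # use edge weights inside Kruskal extraction (MDST mode).  Off by
    # default: weight-ordered extraction lets a light slack edge displace a
    # heavier edge of the intended tree, leaving minimum-distance trees
    # unreachable; with subset-order extraction the weight objective still
    # steers selection through the scalarization
    weighted_kruskal: bool = False

    def validate(self, g: SimpleGraph) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mode not in ("dst", "mdst"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.scalarization not in ("lexicographic", "weighted"):
            raise ValueError(f"unknown scalarization {self.scalarization!r}")
        k = self.resolved_k(g)
        if not (g.n_nodes - 1 <= k <= g.n_edges):
            raise ValueError(
                f"chromosome length {k} outside [{g.n_nodes - 1}, {g.n_edges}]"
            )
        if self.mode == "mdst" and g.weights is None:
            raise GraphStructureError(
                "MDST mode requires a probability on every edge"
            )

    def resolved_k(self, g: SimpleGraph) -> int:
        if self.chromosome_length is not None:
            return self.chromosome_length
        if self.mode == "mdst" and self.weighted_kruskal:
            # under weighted extraction a light slack edge can displace a
            # heavier edge of the intended tree, making minimum-distance
            # trees unreachable; with K = N-1 the (repaired) genotype IS the
            # tree, so every spanning tree stays reachable
            return g.n_nodes - 1
        return min(g.n_edges, math.ceil(1.5 * (g.n_nodes - 1)))


@dataclass
class TreeArchive:
    """All distinct optimal trees found, with search provenance."""

    mode: str
    objective: ObjectiveValue | None
    trees: list[SpanningTree] = field(default_factory=list)
    config: GAConfig | None = None
    generations_run: int = 0
    evaluations: int = 0
    # per restart: best scalar seen up to each generation (non-increasing)
    best_history: list[list[float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trees)

    def edge_sets(self) -> set[tuple[int, ...]]:
        return {t.edge_indices for t in self.trees}

    def to_json_dict(self) -> dict:
        obj = None
        if self.objective is not None:
            obj = {
                "distance": self.objective.distance,
                "weight": self.objective.weight,
                "scalar": self.objective.scalar,
            }
        cfg = None
        if self.config is not None:
            cfg = {k: v for k, v in vars(self.config).items()}
        return {
            "mode": self.mode,
            "objective": obj,
            "config": cfg,
            "n_trees": len(self.trees),
            "trees": [list(t.edge_indices) for t in self.trees],
        }


def _scalarize(distance: int, weight: float | None, cfg: GAConfig,
               w_total: float) -> float:
    if weight is None:
        return float(distance)
    if cfg.scalarization == "lexicographic":
        # distance strictly dominates: any distance step outweighs the largest
        # possible weight difference (bounded by the total graph weight)
        return distance * (1.0 + w_total) + weight
    return cfg.alpha * distance + weight


def evaluate_dst(g: SimpleGraph, chromosome) -> ObjectiveValue:
    """Distance objective of a chromosome under unweighted Kruskal extraction."""
    tree = kruskal_from_subset(g, list(chromosome), weighted=False)
    if isinstance(tree, InfeasibleSubset):
        raise GraphStructureError(
            f"infeasible chromosome: uncovered={tree.uncovered_nodes}, "
            f"components={len(tree.components)}"
        )
    return ObjectiveValue(distance=tree.total_distance, weight=None,
                          scalar=float(tree.total_distance))


def evaluate_mdst(g: SimpleGraph, chromosome, cfg: GAConfig | None = None) -> ObjectiveValue:
    """(distance, weight) objectives of a chromosome under the configured
    extraction (subset-order Kruskal by default; weight-ordered behind
    ``cfg.weighted_kruskal``)."""
    if g.weights is None:
        raise GraphStructureError("MDST evaluation requires edge weights")
    cfg = cfg or GAConfig(mode="mdst")
    tree = kruskal_from_subset(g, list(chromosome), weighted=cfg.weighted_kruskal)
    if isinstance(tree, InfeasibleSubset):
        raise GraphStructureError(
            f"infeasible chromosome: uncovered={tree.uncovered_nodes}, "
            f"components={len(tree.components)}"
        )
    if cfg.weight_on_chromosome:
        weight = sum(g.weights[i - 1] for i in chromosome)
    else:
        weight = tree.weight_sum
    w_total = sum(g.weights)
    return ObjectiveValue(
        distance=tree.total_distance,
        weight=weight,
        scalar=_scalarize(tree.total_distance, weight, cfg, w_total),
    )


def _repair(chromosome: list[int], g: SimpleGraph, k: int) -> list[int]:
    """Deterministically make a chromosome feasible and of length k.

    While the chromosome's subgraph has several components, the lowest-index
    graph edge joining two distinct components is appended; then the
    highest-index redundant (cycle-closing) edges are evicted to restore
    length k.  Redundant = not part of the index-order Kruskal tree.
    """
    genes = list(chromosome)
    present = set(genes)
    n = g.n_nodes
    while True:
        uf = _UnionFind(n)
        comps = n
        for i in genes:
            u, v = g.edge(i)
            if uf.union(u, v):
                comps -= 1
        if comps == 1:
            break
        added = False
        for i in range(1, g.n_edges + 1):
            if i in present:
                continue
            u, v = g.edge(i)
            if uf.find(u) != uf.find(v):
                genes.append(i)
                present.add(i)
                added = True
                break
        if not added:  # graph itself disconnected; caller guards against this
            raise GraphStructureError("cannot repair chromosome: graph disconnected")
    if len(genes) > k:
        # tree edges in ascending index order are essential; evict the rest,
        # highest index first
        uf = _UnionFind(n)
        essential = set()
        for i in sorted(genes):
            u, v = g.edge(i)
            if uf.union(u, v):
                essential.add(i)
        removable = sorted((i for i in genes if i not in essential), reverse=True)
        drop = set(removable[: len(genes) - k])
        genes = [i for i in genes if i not in drop]
    return genes


def _evaluate_cached(g: SimpleGraph, genes: list[int], cfg: GAConfig,
                     weighted_kruskal: bool, w_total: float,
                     tree_cache: dict) -> tuple[ObjectiveValue, SpanningTree]:
    tree = kruskal_from_subset(g, genes, weighted=weighted_kruskal)
    assert isinstance(tree, SpanningTree)  # repair guarantees feasibility
    key = tree.edge_indices
    hit = tree_cache.get(key)
    if hit is None:
        hit = tree
        tree_cache[key] = tree
    tree = hit
    if cfg.mode == "mdst":
        if cfg.weight_on_chromosome:
            weight = sum(g.weights[i - 1] for i in genes)
        else:
            weight = tree.weight_sum
    else:
        weight = None
    return (
        ObjectiveValue(tree.total_distance, weight,
                       _scalarize(tree.total_distance, weight, cfg, w_total)),
        tree,
    )


def ga_search(g: SimpleGraph, cfg: GAConfig | None = None) -> TreeArchive:
    """Search for all co-optimal (M)DSTs with a restarted genetic algorithm.

    Tournament selection, uniform index crossover with duplicate repair,
    single-index point mutation, elitism, deterministic feasibility repair.
    Every feasible evaluated tree attaining the best objective seen across all
    restarts is archived (deduplicated on its edge set).  Fully reproducible
    from ``cfg.seed``.
    """
    cfg = cfg or GAConfig()
    if g.n_nodes < 2:
        return TreeArchive(mode=cfg.mode,
                           objective=ObjectiveValue(0, 0.0 if cfg.mode == "mdst" else None, 0.0),
                           trees=[], config=cfg)
    if not g.is_connected():
        raise GraphStructureError("graph is disconnected; no spanning tree exists")
    cfg.validate(g)

    k = cfg.resolved_k(g)
    m = g.n_edges
    weighted_kruskal = cfg.mode == "mdst" and cfg.weighted_kruskal
    w_total = sum(g.weights) if g.weights is not None else 0.0

    best_key: float | None = None
    best_obj: ObjectiveValue | None = None
    archive: dict[tuple[int, ...], SpanningTree] = {}
    tree_cache: dict[tuple[int, ...], SpanningTree] = {}
    total_evals = 0
    total_gens = 0
    histories: list[list[float]] = []

    for restart in range(cfg.restarts):
        rng = random.Random(f"{cfg.seed}:{restart}")
        population = []
        for _ in range(cfg.population):
            genes = _repair(rng.sample(range(1, m + 1), k), g, k)
            population.append(genes)

        scores: list[ObjectiveValue] = []
        trees: list[SpanningTree] = []

        def score_all(pop):
            nonlocal total_evals
            out_s, out_t = [], []
            for genes in pop:
                obj, tree = _evaluate_cached(g, genes, cfg, weighted_kruskal,
                                             w_total, tree_cache)
                total_evals += 1
                out_s.append(obj)
                out_t.append(tree)
            return out_s, out_t

        def absorb(objs, trs):
            """Fold newly scored trees into the global archive."""
            nonlocal best_key, best_obj
            for obj, tree in zip(objs, trs):
                key = obj.key()
                if best_key is None or key < best_key:
                    best_key, best_obj = key, obj
                    archive.clear()
                    archive[tree.edge_indices] = tree
                elif key == best_key:
                    archive.setdefault(tree.edge_indices, tree)

        scores, trees = score_all(population)
        absorb(scores, trees)
        run_best = min(s.scalar for s in scores)
        history = [run_best]
        stall = 0

        for _gen in range(cfg.generations):
            total_gens += 1
            order = sorted(range(len(population)), key=lambda i: scores[i].scalar)
            next_pop = [list(population[i]) for i in order[: cfg.elitism]]
            while len(next_pop) < cfg.population:
                # tournament selection of two parents
                parents = []
                for _ in range(2):
                    contenders = [rng.randrange(len(population))
                                  for _ in range(cfg.tournament)]
                    parents.append(min(contenders, key=lambda i: scores[i].scalar))
                p1, p2 = population[parents[0]], population[parents[1]]
                if rng.random() < cfg.crossover_rate:
                    child = _uniform_crossover(p1, p2, k, m, rng)
                else:
                    child = list(p1)
                if rng.random() < cfg.mutation_rate:
                    _point_mutate(child, m, rng)
                next_pop.append(_repair(child, g, k))
            population = next_pop
            scores, trees = score_all(population)
            absorb(scores, trees)
            gen_best = min(s.scalar for s in scores)
            history.append(min(run_best, gen_best))
            if gen_best < run_best - _W_TOL:
                run_best = gen_best
                stall = 0
            else:
                stall += 1
                if stall >= cfg.stall_patience:
                    break
        histories.append(history)

    result = TreeArchive(
        mode=cfg.mode,
        objective=best_obj,
        trees=sorted(archive.values(), key=lambda t: t.edge_indices),
        config=cfg,
        generations_run=total_gens,
        evaluations=total_evals,
        best_history=histories,
    )
    return result


def _uniform_crossover(p1: list[int], p2: list[int], k: int, m: int,
                       rng: random.Random) -> list[int]:
    """Positionwise gene pick from either parent, repairing duplicates from
    the parents' gene pool (then from the full edge set)."""
    child: list[int] = []
    used: set[int] = set()
    pool = [x for x in p1 + p2]
    for pos in range(k):
        gene = p1[pos] if rng.random() < 0.5 else p2[pos]
        if gene in used:
            gene = next((x for x in pool if x not in used), None)
            if gene is None:
                gene = rng.choice([x for x in range(1, m + 1) if x not in used])
        child.append(gene)
        used.add(gene)
    return child


def _point_mutate(genes: list[int], m: int, rng: random.Random) -> None:
    """Replace one random gene with a random edge index not already present."""
    if m <= len(genes):
        return
    present = set(genes)
    pos = rng.randrange(len(genes))
    while True:
        cand = rng.randint(1, m)
        if cand not in present:
            genes[pos] = cand
            return


def count_spanning_trees(g: SimpleGraph) -> int:
    """Number of spanning trees by the matrix-tree (Kirchhoff) theorem."""
    n = g.n_nodes
    if n <= 1:
        return 1
    lap = np.zeros((n, n))
    for u, v in g.edges:
        lap[u, u] += 1
        lap[v, v] += 1
        lap[u, v] -= 1
        lap[v, u] -= 1
    minor = lap[1:, 1:]
    sign, logdet = np.linalg.slogdet(minor)
    if sign <= 0:
        return 0
    return int(round(math.exp(logdet)))


def enumerate_optimal_bruteforce(
    g: SimpleGraph,
    mode: str = "dst",
    cfg: GAConfig | None = None,
    cap: int = 10**6,
) -> TreeArchive:
    """Ground-truth oracle: evaluate every spanning tree, keep the optimal set.

    Refuses (with the matrix-tree count) when the graph has more than *cap*
    spanning trees.  The MDST mode uses the same scalarization as the GA, so
    the two entry points are comparable tree for tree.
    """
    if mode not in ("dst", "mdst"):
        raise ValueError(f"unknown mode {mode!r}")
    if not g.is_connected():
        raise GraphStructureError("graph is disconnected; no spanning tree exists")
    n_trees = count_spanning_trees(g)
    if n_trees > cap:
        raise GraphStructureError(
            f"graph has ~{n_trees} spanning trees, above the cap of {cap}"
        )
    cfg = cfg or GAConfig(mode=mode)
    w_total = sum(g.weights) if g.weights is not None else 0.0

    import networkx as nx

    gx = g.to_networkx()
    best_key: float | None = None
    best_obj: ObjectiveValue | None = None
    archive: dict[tuple[int, ...], SpanningTree] = {}
    for tree_gx in nx.SpanningTreeIterator(gx):
        idx = tuple(sorted(d["index"] for _, _, d in tree_gx.edges(data=True)))
        adj: list[list[int]] = [[] for _ in range(g.n_nodes)]
        for i in idx:
            u, v = g.edge(i)
            adj[u].append(v)
            adj[v].append(u)
        dist = total_pairwise_distance(adjacency=adj) if g.n_nodes > 1 else 0
        if mode == "mdst":
            weight = sum(g.weights[i - 1] for i in idx)
        else:
            weight = None
        obj = ObjectiveValue(dist, weight, _scalarize(dist, weight, cfg, w_total))
        key = obj.key()
        tree = SpanningTree(graph=g, edge_indices=idx, total_distance=dist,
                            weight_sum=weight or 0.0)
        if best_key is None or key < best_key:
            best_key, best_obj = key, obj
            archive = {idx: tree}
        elif key == best_key:
            archive.setdefault(idx, tree)
    return TreeArchive(
        mode=mode,
        objective=best_obj,
        trees=sorted(archive.values(), key=lambda t: t.edge_indices),
        config=cfg,
        evaluations=n_trees,
    )
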