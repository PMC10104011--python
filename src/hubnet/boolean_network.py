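"""Probabilistic Boolean network with general asynchronous updates.

Each transcription factor is ON (1) or OFF (0) and carries a probabilistic
rule: a table giving P(node ON) for every combination of its regulators'
states (the output format class of Boolean rule-fitting tools that infer such
tables from expression data).  One iteration of the general asynchronous
scheme picks one node uniformly at random and resamples it from its rule;
all other nodes keep their state.  Interventions are modelled as *clamps*:
a clamped node holds its forced value at every iteration ("always ON"),
which is how a candidate pathway is kept active during a subtype-transition
simulation.

A simulation tracks, per iteration, the updated node, the resulting state
and its distance to the nearest target state, and stops at the first exact
hit of a target (the transition event) or at the iteration cap.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

__all__ = [
    "RuleFormatError",
    "BooleanRule",
    "RuleSet",
    "ClampSet",
    "Trajectory",
    "parse_rules",
    "write_rules",
    "parse_state",
    "write_state",
    "async_step",
    "simulate",
    "run_ensemble",
]

State = tuple[int, ...]


class RuleFormatError(ValueError):
    """Malformed rule set or state file."""


@dataclass(frozen=True)
class BooleanRule:
    """One node's probabilistic update rule.

    ``p_on[j]`` is P(node ON) given regulator combination ``j``, where the
    *first* listed regulator is the most significant bit of ``j``.
    """

    node: str
    regulators: tuple[str, ...]
    p_on: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.p_on) != 2 ** len(self.regulators):
            raise RuleFormatError(
                f"rule for {self.node}: table length {len(self.p_on)} != "
                f"2^{len(self.regulators)}"
            )
        for p in self.p_on:
            if not (0.0 <= p <= 1.0):
                raise RuleFormatError(
                    f"rule for {self.node}: probability {p} outside [0, 1]"
                )


class RuleSet:
    """All rules of a network, with a fixed node order for state vectors."""

    def __init__(self, nodes: Sequence[str], rules: Sequence[BooleanRule]) -> None:
        self.nodes: list[str] = list(nodes)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        if len(self.index) != len(self.nodes):
            raise RuleFormatError("duplicate node labels")
        by_node = {r.node: r for r in rules}
        missing = [v for v in self.nodes if v not in by_node]
        if missing:
            raise RuleFormatError(f"nodes without a rule: {missing}")
        unknown = [r.node for r in rules if r.node not in self.index]
        if unknown:
            raise RuleFormatError(f"rules for undeclared nodes: {unknown}")
        for r in rules:
            for reg in r.regulators:
                if reg not in self.index:
                    raise RuleFormatError(
                        f"rule for {r.node}: unknown regulator {reg}"
                    )
        self.rules: list[BooleanRule] = [by_node[v] for v in self.nodes]
        # precompiled per node: regulator indices (MSB first) and table
        self._reg_idx: list[tuple[int, ...]] = [
            tuple(self.index[reg] for reg in r.regulators) for r in self.rules
        ]
        self._tables: list[tuple[float, ...]] = [r.p_on for r in self.rules]

    def __len__(self) -> int:
        return len(self.nodes)

    def table_entry(self, node_i: int, state: Sequence[int]) -> float:
        j = 0
        for ri in self._reg_idx[node_i]:
            j = (j << 1) | state[ri]
        return self._tables[node_i][j]

    def to_json_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "rules": [
                {"node": r.node, "regulators": list(r.regulators),
                 "p_on": list(r.p_on)}
                for r in self.rules
            ],
        }


ClampSet = dict  # node label -> forced value in {0, 1}


def parse_rules(path) -> RuleSet:
    """Load a rule set from the JSON schema
    ``{"nodes": [...], "rules": [{"node", "regulators", "p_on"}...]}``."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        nodes = doc["nodes"]
        rules = [
            BooleanRule(r["node"], tuple(r["regulators"]), tuple(r["p_on"]))
            for r in doc["rules"]
        ]
    except (KeyError, TypeError) as exc:
        raise RuleFormatError(f"bad rules file {path}: {exc}") from exc
    return RuleSet(nodes, rules)


def write_rules(rules: RuleSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(rules.to_json_dict(), fh, indent=1)


def parse_state(path, rules: RuleSet) -> State:
    """Read ``node<TAB>0|1`` lines; node order is taken from the rule set."""
    values: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise RuleFormatError(f"{path}:{lineno}: expected node<TAB>0|1")
            values[parts[0]] = int(parts[1])
    missing = [v for v in rules.nodes if v not in values]
    if missing:
        raise RuleFormatError(f"state file {path} missing nodes: {missing}")
    return tuple(values[v] for v in rules.nodes)


def write_state(state: Sequence[int], rules: RuleSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for v, x in zip(rules.nodes, state):
            fh.write(f"{v}\t{x}\n")


@dataclass
class Trajectory:
    """One asynchronous run: states, updated nodes and distances per iteration.

    ``states[t]`` is the state *after* iteration ``t`` (``states[0]`` is the
    clamped initial state), so ``states`` and ``distances`` have length
    ``iterations + 1`` while ``updated_nodes[t - 1]`` names the node picked at
    iteration ``t``.
    """

    nodes: list[str]
    states: list[State]
    updated_nodes: list[str]
    distances: list[int] | None
    hit: bool
    hit_iteration: int | None
    seed: int | None = None
    clamps: dict = field(default_factory=dict)

    @property
    def iterations(self) -> int:
        return len(self.updated_nodes)

    def distance_series(self) -> list[int]:
        if self.distances is None:
            raise ValueError("trajectory was run without targets/distances")
        return self.distances


def _apply_clamps(state: Sequence[int], clamps: Mapping[str, int],
                  index: Mapping[str, int]) -> State:
    s = list(state)
    for node, val in clamps.items():
        s[index[node]] = int(val)
    return tuple(s)


def async_step(
    state: State,
    rules: RuleSet,
    clamps: Mapping[str, int] | None,
    rng: random.Random,
) -> tuple[State, str]:
    """One general-asynchronous update: pick a node uniformly, resample it.

    A clamped node, when picked, is forced to its clamp value without drawing
    from its rule (the pick still consumes the iteration).  Returns the new
    state and the updated node's label.
    """
    clamps = clamps or {}
    n = len(rules)
    i = rng.randrange(n)
    node = rules.nodes[i]
    if node in clamps:
        value = int(clamps[node])
    else:
        p = rules.table_entry(i, state)
        value = 1 if rng.random() < p else 0
    if state[i] == value:
        return state, node
    new = list(state)
    new[i] = value
    return tuple(new), node


def simulate(
    initial: Sequence[int],
    rules: RuleSet,
    clamps: Mapping[str, int] | None = None,
    targets: Sequence[Sequence[int]] | None = None,
    max_iters: int = 500_000,
    seed: int = 0,
    distance_fn: Callable[[Sequence[int], Sequence[int]], int] | None = None,
) -> Trajectory:
    """Run one asynchronous simulation, optionally until a target is hit.

    Clamps are applied to the initial state before iteration 0.  When
    ``targets`` is given, each iteration records the distance (default: the
    longest-common-subsequence metric of :mod:`hubnet.transition_analysis`)
    to the *nearest* target, and the run stops at the first exact match of
    any target.  Without targets the run always lasts ``max_iters``
    iterations and records no distances.
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    clamps = dict(clamps or {})
    for node in clamps:
        if node not in rules.index:
            raise RuleFormatError(f"clamp on unknown node {node}")
    n = len(rules)
    if len(initial) != n:
        raise RuleFormatError("initial state length does not match rule set")
    targets = [tuple(int(x) for x in t) for t in (targets or [])]
    for t in targets:
        if len(t) != n:
            raise RuleFormatError("target state length does not match rule set")
    track = bool(targets)
    if distance_fn is None:
        from .transition_analysis import lcs_distance

        distance_fn = lcs_distance

    rng = random.Random(seed)
    state = _apply_clamps(tuple(int(x) for x in initial), clamps, rules.index)

    dist_cache: dict[State, int] = {}

    def dist_to_targets(s: State) -> int:
        d = dist_cache.get(s)
        if d is None:
            d = min(distance_fn(s, t) for t in targets)
            dist_cache[s] = d
        return d

    states = [state]
    updated: list[str] = []
    distances: list[int] | None = [dist_to_targets(state)] if track else None
    hit = False
    hit_iter: int | None = None
    if track and distances[0] == 0 and state in targets:
        hit, hit_iter = True, 0
    t = 0
    while t < max_iters and not hit:
        t += 1
        state, node = async_step(state, rules, clamps, rng)
        states.append(state)
        updated.append(node)
        if track:
            distances.append(dist_to_targets(state))
            if state in targets:
                hit, hit_iter = True, t
    return Trajectory(
        nodes=list(rules.nodes),
        states=states,
        updated_nodes=updated,
        distances=distances,
        hit=hit,
        hit_iteration=hit_iter,
        seed=seed,
        clamps=clamps,
    )


def run_ensemble(
    n_runs: int,
    initial: Sequence[int],
    rules: RuleSet,
    clamps: Mapping[str, int] | None = None,
    targets: Sequence[Sequence[int]] | None = None,
    max_iters: int = 500_000,
    base_seed: int = 0,
    on_trajectory: Callable[[int, Trajectory], None] | None = None,
) -> list[Trajectory]:
    """Independent repeated simulations with per-run seeds ``base_seed + i``.

    ``on_trajectory(i, traj)`` — when given — is called as each run finishes,
    so trajectories can be persisted incrementally.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    out = []
    for i in range(n_runs):
        traj = simulate(initial, rules, clamps=clamps, targets=targets,
                        max_iters=max_iters, seed=base_seed + i)
        if on_trajectory is not None:
            on_trajectory(i, traj)
        out.append(traj)
    return out
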