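"""Seeded generators for planted-hub networks, rule sets and a toy fixture.

The real use case — a curated transcription-factor network with
RNA-seq-derived interaction probabilities and fitted probabilistic Boolean
rules — involves external data products.  These generators emulate that class
of inputs so every stage of the pipeline is testable end to end:

* :func:`gen_hub_network` plants hub nodes wired to all other nodes, adds
  sparse peripheral noise edges, draws random activation/inhibition signs
  and Beta-distributed edge probabilities (default Beta(5, 2): curated
  interactions tend to be high-confidence).
* :func:`gen_boolean_rules` builds a probabilistic rule table per node from
  designated attractor states: regulator combinations observed in an
  attractor reproduce the attractor value (softened by a noise level
  ``eps``); unobserved combinations fall back to sign-majority logic.
* :func:`toy_fixture` is a fixed eight-node miniature of the
  clamped-pathway transition experiment: two fixed-point subtype states and
  a clamp set under which the second state becomes reachable from the first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .boolean_network import BooleanRule, RuleSet, State
from .graph_model import ACTIVATION, INHIBITION, SignedEdge, SignedNetwork

__all__ = [
    "SynthesisConfig",
    "AttractorConflictError",
    "gen_hub_network",
    "gen_boolean_rules",
    "toy_fixture",
]


class AttractorConflictError(ValueError):
    """Designated attractors disagree on a node's value for the same
    regulator combination."""


@dataclass
class SynthesisConfig:
    """Parameters of the planted-hub network generator."""

    n_nodes: int = 10
    n_hubs: int = 1
    attachment_p: float = 1.0  # hub-to-node wiring probability
    noise_p: float = 0.1  # peripheral-peripheral edge probability
    beta_a: float = 5.0  # edge-probability Beta shape (skewed high)
    beta_b: float = 2.0
    epsilon: float = 0.0  # rule softening in [0, 0.5]
    seed: int = 0

    def validate(self) -> None:
        if self.n_hubs >= self.n_nodes:
            raise ValueError("need n_hubs < n_nodes")
        if self.n_hubs < 1 or self.n_nodes < 2:
            raise ValueError("need n_nodes >= 2 and n_hubs >= 1")
        for name in ("attachment_p", "noise_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 <= self.epsilon <= 0.5):
            raise ValueError(f"epsilon={self.epsilon} outside [0, 0.5]")


def gen_hub_network(cfg: SynthesisConfig) -> SignedNetwork:
    """Planted-hub signed network, connected by construction, seeded.

    Hubs are labelled ``H1..``, peripherals ``P1..``.  Each hub connects to
    every other node with probability ``attachment_p`` (any node left
    unattached is bridged to the first hub so the graph stays connected);
    peripheral pairs connect independently with probability ``noise_p``.
    Edge directions and signs are drawn at random; probabilities come from
    ``Beta(beta_a, beta_b)``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    hubs = [f"H{i + 1}" for i in range(cfg.n_hubs)]
    periph = [f"P{i + 1}" for i in range(cfg.n_nodes - cfg.n_hubs)]
    nodes = hubs + periph

    pairs: list[tuple[str, str]] = []
    attached: set[str] = set()
    for h in hubs:
        for v in nodes:
            if v == h or (v in hubs and v < h):
                continue
            if rng.random() < cfg.attachment_p:
                pairs.append((h, v))
                attached.add(v)
    for v in periph:
        if v not in attached:  # bridge: keep the graph connected
            pairs.append((hubs[0], v))
    for a, b in itertools.combinations(periph, 2):
        if rng.random() < cfg.noise_p:
            pairs.append((a, b))

    # final connectivity pass (only reachable when attachment_p < 1): bridge
    # every stranded component to the first hub
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for a, b in pairs:
        adj[a].add(b)
        adj[b].add(a)
    seen = {hubs[0]}
    stack = [hubs[0]]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    for v in nodes:
        if v not in seen:
            pairs.append((hubs[0], v))
            seen.add(v)

    edges = []
    for a, b in pairs:
        src, dst = (a, b) if rng.random() < 0.5 else (b, a)
        sign = ACTIVATION if rng.random() < 0.5 else INHIBITION
        p = float(rng.beta(cfg.beta_a, cfg.beta_b))
        edges.append(SignedEdge(src, dst, sign, p))
    return SignedNetwork(nodes=nodes, edges=edges)


def gen_boolean_rules(
    net: SignedNetwork,
    attractors: list[State],
    eps: float = 0.0,
    seed: int = 0,
) -> RuleSet:
    """Rule tables that make the designated attractors fixed points (at eps=0).

    Regulators of a node are its incoming neighbours in the directed signed
    network, in edge order.  For regulator combinations realized in some
    attractor, P(ON) equals the attractor's value for the node, softened
    toward 0.5 by ``eps`` (``p = value (1 - eps) + (1 - value) eps``).
    Combinations never observed get sign-majority logic: count activators ON
    minus inhibitors ON; positive -> ON (1 - eps), negative -> OFF (eps),
    tie -> 0.5.  Attractors that assign conflicting values to the same
    combination raise :class:`AttractorConflictError` naming the node.

    Nodes without regulators are only consistent if every attractor agrees
    on their value.  ``seed`` is accepted for interface symmetry; the
    construction is deterministic.
    """
    if not (0.0 <= eps <= 0.5):
        raise ValueError(f"eps={eps} outside [0, 0.5]")
    for att in attractors:
        if len(att) != len(net.nodes):
            raise ValueError("attractor length does not match node count")
    idx = {v: i for i, v in enumerate(net.nodes)}
    rules = []
    for node in net.nodes:
        regs = net.regulators_of(node)
        reg_names = tuple(r for r, _ in regs)
        signs = tuple(s for _, s in regs)
        k = len(regs)
        observed: dict[int, int] = {}
        for att in attractors:
            j = 0
            for r in reg_names:
                j = (j << 1) | att[idx[r]]
            value = att[idx[node]]
            if j in observed and observed[j] != value:
                raise AttractorConflictError(
                    f"node {node}: attractors disagree on value for regulator "
                    f"combination {j:0{max(k, 1)}b}"
                )
            observed[j] = value
        table = []
        for j in range(2 ** k):
            if j in observed:
                v = observed[j]
                p = v * (1.0 - eps) + (1 - v) * eps
            else:
                score = 0
                for bit, sign in enumerate(signs):
                    on = (j >> (k - 1 - bit)) & 1
                    if on:
                        score += 1 if sign == ACTIVATION else -1
                if score > 0:
                    p = 1.0 - eps
                elif score < 0:
                    p = eps
                else:
                    p = 0.5
            table.append(p)
        rules.append(BooleanRule(node, reg_names, tuple(table)))
    return RuleSet(net.nodes, rules)


# Fixed miniature of the clamped-pathway transition experiment: 8 nodes,
# 14 directed signed interactions, two hubs (H1, H2) joined through the
# intermediate A, and a repressor R that is ON in the resting state S0 and
# OFF in the target state S1.  Probabilities are fixed so the fixture is
# byte-identical across calls.
_FIXTURE_EDGES = [
    # source, sign, target, p
    ("H1", "+", "A", 0.95),
    ("A", "+", "H2", 0.92),
    ("H2", "+", "H1", 0.90),
    ("H1", "+", "P1", 0.85),
    ("A", "+", "P1", 0.70),
    ("H1", "+", "P2", 0.80),
    ("R", "-", "P2", 0.75),
    ("H2", "+", "P3", 0.88),
    ("H2", "+", "P4", 0.82),
    ("R", "-", "P4", 0.65),
    ("H1", "-", "R", 0.78),
    ("H2", "-", "R", 0.72),
    ("P3", "-", "R", 0.60),
    ("P1", "+", "H2", 0.68),
]

_FIXTURE_NODES = ["H1", "A", "H2", "P1", "P2", "P3", "P4", "R"]


def toy_fixture() -> tuple[SignedNetwork, RuleSet, State, State, dict]:
    """Fixed end-to-end fixture: (network, rules, S0, S1, clamps).

    ``S0`` (everything OFF, repressor R ON) and ``S1`` (everything ON, R
    OFF) are both fixed points of the deterministic (eps = 0) asynchronous
    dynamics; they differ in all 8 positions.  Under the clamp set
    ``{"H1": 1, "A": 1}`` — the hub plus the pathway intermediate held
    active — S1 becomes reachable from S0.  Byte-identical across calls.
    """
    edges = [SignedEdge(s, t, sign, p) for s, sign, t, p in _FIXTURE_EDGES]
    net = SignedNetwork(nodes=list(_FIXTURE_NODES), edges=edges)
    s0 = tuple(1 if v == "R" else 0 for v in net.nodes)
    s1 = tuple(0 if v == "R" else 1 for v in net.nodes)
    rules = gen_boolean_rules(net, [s0, s1], eps=0.0)
    clamps = {"H1": 1, "A": 1}
    return net, rules, s0, s1, clamps
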