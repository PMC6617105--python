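"""Markov-Conley chains: response graphs, sink components, pure Nash.

The response graph of a game has every pure strategy profile as a node and a
directed edge for each single-player weakly-improving deviation.  Its sink
strongly connected components — SCCs with no outgoing edge in the
condensation — are the state spaces of the Markov-Conley chains (MCCs), the
discrete solution concept that the profile chain's stationary distribution
concentrates on in the strong-selection limit.  A singleton sink is a pure
Nash equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .games import NormalFormGame, check_symmetric

__all__ = [
    "ResponseGraph",
    "MCCSet",
    "build_response_graph",
    "build_single_population_response_graph",
    "strongly_connected_components",
    "sink_components",
    "mcc_chain",
    "affine_transform_check",
    "response_graph_to_dot",
    "mcc_to_tsv",
]

_REL_TOL = 1e-12


def _compare(a: float, b: float) -> int:
    """-1/0/+1 comparison; ties exact for integers, relative 1e-12 otherwise."""
    if a == b:
        return 0
    if not (float(a).is_integer() and float(b).is_integer()):
        if math.isclose(a, b, rel_tol=_REL_TOL, abs_tol=0.0):
            return 0
    return 1 if a > b else -1


@dataclass(frozen=True)
class ResponseGraph:
    """Directed weakly-better-response graph over pure profiles.

    ``graph`` is a networkx DiGraph whose nodes are profile tuples and whose
    edges carry a boolean attribute ``strict`` (strictly better vs equal
    payoff for the deviating player).  ``labels`` maps nodes to display
    strings.
    """

    graph: nx.DiGraph
    labels: dict
    single_population: bool = False

    @property
    def nodes(self):
        return list(self.graph.nodes)


@dataclass(frozen=True)
class MCCSet:
    """Sink strongly connected components of a response graph.

    ``components`` are frozensets of nodes; ``is_pure_nash[i]`` flags the
    singleton sinks, which are pure Nash equilibria by definition.
    """

    components: tuple
    is_pure_nash: tuple
    graph: ResponseGraph

    def __len__(self):
        return len(self.components)

    @property
    def union(self) -> frozenset:
        out = set()
        for comp in self.components:
            out |= comp
        return frozenset(out)


def build_response_graph(game: NormalFormGame,
                         strict_only: bool = False) -> ResponseGraph:
    """Weakly-better-response graph over all pure profiles.

    An edge s_i -> s_j exists when the profiles differ in one player's
    strategy and that player's payoff at s_j is at least (strictly greater,
    if ``strict_only``) its payoff at s_i.  ``strict_only`` drops the tie
    edges; that variant is non-canonical and only meant for sensitivity
    analysis.
    """
    G = nx.DiGraph()
    labels = {}
    for s in game.profiles():
        G.add_node(s)
        labels[s] = game.profile_label(s)
    for s in game.profiles():
        for k in range(game.num_players):
            base = float(game.payoffs[k][s])
            for tau in range(game.shape[k]):
                if tau == s[k]:
                    continue
                t = s[:k] + (tau,) + s[k + 1:]
                cmp = _compare(float(game.payoffs[k][t]), base)
                if cmp > 0:
                    G.add_edge(s, t, strict=True)
                elif cmp == 0 and not strict_only:
                    G.add_edge(s, t, strict=False)
    return ResponseGraph(G, labels, False)


def build_single_population_response_graph(game: NormalFormGame) -> ResponseGraph:
    """Strategy-level response graph for a 2-player symmetric game.

    Nodes are the shared strategies; an edge sigma -> tau exists when a
    tau-mutant does at least as well against sigma as sigma does against it,
    i.e. M(tau, sigma) >= M(sigma, tau) — the invasion ordering that drives
    the single-population chain.
    """
    if game.num_players != 2 or not check_symmetric(game):
        raise ValueError("single-population response graph requires a "
                         "2-player symmetric game")
    M = game.payoffs[0]
    n = M.shape[0]
    G = nx.DiGraph()
    labels = {}
    for i in range(n):
        G.add_node((i,))
        labels[(i,)] = game.strategy_labels[0][i]
    for sigma in range(n):
        for tau in range(n):
            if tau == sigma:
                continue
            cmp = _compare(float(M[tau, sigma]), float(M[sigma, tau]))
            if cmp >= 0:
                G.add_edge((sigma,), (tau,), strict=cmp > 0)
    return ResponseGraph(G, labels, True)


def strongly_connected_components(graph: ResponseGraph) -> list:
    """SCC partition of the response graph (Tarjan-style linear time)."""
    return [frozenset(c) for c in nx.strongly_connected_components(graph.graph)]


def sink_components(graph: ResponseGraph) -> MCCSet:
    """Sink SCCs of the response graph — the MCC state spaces.

    The condensation of a finite digraph is a DAG, so at least one sink
    always exists.  Singleton sinks (profiles from which every deviation
    strictly hurts the deviator) are flagged as pure Nash equilibria.
    """
    cond = nx.condensation(graph.graph)
    comps = []
    for node in cond.nodes:
        if cond.out_degree(node) == 0:
            comps.append(frozenset(cond.nodes[node]["members"]))
    comps.sort(key=lambda c: sorted(c))
    flags = tuple(len(c) == 1 for c in comps)
    return MCCSet(tuple(comps), flags, graph)


def mcc_chain(component: frozenset, graph: ResponseGraph,
              self_prob: float = 0.5, tie_ratio: float = 0.1) -> np.ndarray:
    """Canonical transition matrix of the MCC on a sink component.

    Each node keeps ``self_prob`` mass; the remainder is split over its
    improving responses inside the component so that every strict
    improvement receives equal probability and every tie edge receives
    ``tie_ratio`` times a strict edge's share.  Component membership — the
    ranking-relevant object — does not depend on these two knobs.
    """
    if not 0 < self_prob < 1:
        raise ValueError("self_prob must lie strictly between 0 and 1")
    if not 0 < tie_ratio < 1:
        raise ValueError("tie_ratio must lie strictly in (0, 1)")
    nodes = sorted(component)
    n = len(nodes)
    if n == 1:
        return np.array([[1.0]])
    index = {v: i for i, v in enumerate(nodes)}
    T = np.zeros((n, n))
    G = graph.graph
    for v in nodes:
        i = index[v]
        strict_succ, tie_succ = [], []
        for _, w, data in G.out_edges(v, data=True):
            if w not in component:
                continue  # cannot happen for a sink SCC
            (strict_succ if data["strict"] else tie_succ).append(w)
        weight = len(strict_succ) + tie_ratio * len(tie_succ)
        if weight == 0:
            raise ValueError(
                f"node {graph.labels.get(v, v)} has no improving response "
                "inside a multi-node component; not a sink SCC"
            )
        unit = (1.0 - self_prob) / weight
        T[i, i] = self_prob
        for w in strict_succ:
            T[i, index[w]] += unit
        for w in tie_succ:
            T[i, index[w]] += tie_ratio * unit
    return T


def affine_transform_check(game: NormalFormGame, scale: float,
                           shift: float) -> bool:
    """True iff positively rescaling/shifting all payoffs preserves the MCCs.

    Positive affine payoff transforms preserve all payoff orderings, so the
    sink components must be identical; exposed as a test utility.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    transformed = NormalFormGame(
        game.num_players,
        game.strategy_labels,
        [scale * M + shift for M in game.payoffs],
    )
    orig = set(sink_components(build_response_graph(game)).components)
    new = set(sink_components(build_response_graph(transformed)).components)
    return orig == new


# ---------------------------------------------------------------------------
# exports


def response_graph_to_dot(graph: ResponseGraph,
                          mccs: MCCSet | None = None) -> str:
    """DOT export: strict edges solid, tie edges dashed, sinks highlighted."""
    sink_nodes = mccs.union if mccs is not None else frozenset()
    idx = {v: i for i, v in enumerate(graph.graph.nodes)}
    lines = ["digraph response {"]
    for v, i in idx.items():
        style = ' style=filled fillcolor=lightblue' if v in sink_nodes else ""
        lines.append(f'  n{i} [label="{graph.labels[v]}"{style}];')
    for u, v, data in graph.graph.edges(data=True):
        style = "solid" if data["strict"] else "dashed"
        lines.append(f"  n{idx[u]} -> n{idx[v]} [style={style}];")
    lines.append("}")
    return "\n".join(lines)


def mcc_to_tsv(mccs: MCCSet) -> str:
    """TSV listing of components: index, size, pure-Nash flag, members."""
    out = ["component\tsize\tpure_nash\tmembers"]
    for i, (comp, nash) in enumerate(zip(mccs.components, mccs.is_pure_nash)):
        members = ";".join(mccs.graph.labels[v] for v in sorted(comp))
        out.append(f"{i}\t{len(comp)}\t{int(nash)}\t{members}")
    return "\n".join(out) + "\n"
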