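"""Random walk on the evidence flow network: streams and proportion contributions.

The flow network for comparison ab is a DAG carrying a unit flow from a to
b.  Normalizing each node's outgoing flows yields the transition matrix
U(ab) of a walker that can only move with the flow.  Every source-to-sink
path pi_i is an *evidence stream* with flow phi_i — the probability that a
walker takes that path, i.e. the product of U entries along it.  The
streams decompose the network estimate into direct and indirect estimates
and define the proportion contribution of each direct comparison cd:

    p_cd(ab) = sum over streams containing cd of phi_i / |pi_i|,

which is non-negative and sums to one over cd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evidence_flow import FlowNetwork, flow_network
from .model import AggregateNetwork, HatMatrix, Label, Pair, comparison_name, label_key

#: guard against exponential path growth on dense networks
DEFAULT_MAX_PATHS = 1_000_000


@dataclass
class FlowWalkModel:
    """Transition matrix U(ab) for the walk on one evidence flow network."""

    comparison: Pair
    nodes: list[Label]
    transition: np.ndarray

    def node_index(self, label: Label) -> int:
        return self.nodes.index(label)

    def step_probability(self, c: Label, d: Label) -> float:
        return float(self.transition[self.node_index(c), self.node_index(d)])


@dataclass
class EvidenceStream:
    """A source-to-sink path together with the evidence flow it carries."""

    path: tuple[Label, ...]
    flow: float

    @property
    def length(self) -> int:
        return len(self.path) - 1

    @property
    def name(self) -> str:
        return "→".join(str(n) for n in self.path)

    @property
    def edges(self) -> list[tuple[Label, Label]]:
        return list(zip(self.path[:-1], self.path[1:]))


@dataclass
class ContributionMatrix:
    """Proportion contributions p_cd(ab): rows are comparisons, columns direct edges."""

    comparisons: list[Pair]
    edges: list[Pair]
    values: np.ndarray

    def to_frame(self):
        import pandas as pd

        names = [comparison_name(p) for p in self.edges]
        return pd.DataFrame(self.values, index=[comparison_name(p) for p in self.comparisons], columns=names)


def flow_transition_matrix(fn: FlowNetwork) -> FlowWalkModel:
    """Normalize outgoing flows into the row-stochastic transition matrix U(ab).

    The sink is absorbing (unit diagonal), and so is any node isolated in
    this comparison's flow network — a walker starting there never moves.
    A non-sink node with inflow but no outflow violates conservation and is
    an error.
    """
    nodes = fn.nodes
    n = len(nodes)
    index = {t: i for i, t in enumerate(nodes)}
    transition = np.zeros((n, n))
    for node in nodes:
        i = index[node]
        if node == fn.sink:
            transition[i, i] = 1.0
            continue
        out = fn.out_flow(node)
        if out > 0:
            for (c, d), f in fn.flows.items():
                if c == node:
                    transition[i, index[d]] = f / out
        elif fn.in_flow(node) > 0:
            raise ValueError(f"conservation violation: node {node!r} has inflow but no outflow")
        else:
            transition[i, i] = 1.0  # isolated for this comparison
    return FlowWalkModel(comparison=fn.comparison, nodes=nodes, transition=transition)


def enumerate_paths(fn: FlowNetwork, max_paths: int = DEFAULT_MAX_PATHS) -> list[tuple[Label, ...]]:
    """All source-to-sink paths of the flow DAG, depth-first, successors label-sorted.

    The DAG property guarantees simple paths and termination.  Deterministic
    order: at every node the successors are visited in label order, so the
    output is reproducible across runs and platforms.
    """
    paths: list[tuple[Label, ...]] = []
    stack: list[Label] = [fn.source]

    def visit(node: Label) -> None:
        if node == fn.sink:
            paths.append(tuple(stack))
            if len(paths) > max_paths:
                raise RuntimeError(
                    f"more than {max_paths} evidence paths for {comparison_name(fn.comparison)}; "
                    "raise max_paths to enumerate them all"
                )
            return
        for successor in fn.successors(node):
            stack.append(successor)
            visit(successor)
            stack.pop()

    visit(fn.source)
    return paths


def stream_flows(model: FlowWalkModel, paths: list[tuple[Label, ...]]) -> list[EvidenceStream]:
    """Assign each path its flow phi_i: the product of U entries along the path."""
    streams = []
    for path in paths:
        phi = 1.0
        for c, d in zip(path[:-1], path[1:]):
            phi *= model.step_probability(c, d)
        streams.append(EvidenceStream(path=path, flow=phi))
    return streams


def evidence_streams(fn: FlowNetwork, max_paths: int = DEFAULT_MAX_PATHS) -> list[EvidenceStream]:
    """Paths and flows for one comparison in a single call."""
    model = flow_transition_matrix(fn)
    return stream_flows(model, enumerate_paths(fn, max_paths=max_paths))


def proportion_contributions(streams: list[EvidenceStream]) -> dict[tuple[Label, Label], float]:
    """Per-edge contribution: sum of phi_i / |pi_i| over streams through the edge.

    The values are non-negative and sum to one whenever the stream flows do.
    """
    contributions: dict[tuple[Label, Label], float] = {}
    for stream in streams:
        share = stream.flow / stream.length
        for edge in stream.edges:
            contributions[edge] = contributions.get(edge, 0.0) + share
    return contributions


def full_contribution_matrix(
    network: AggregateNetwork,
    hat: HatMatrix | None = None,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> ContributionMatrix:
    """Proportion contributions of every direct edge to every observed comparison.

    One row per edge of the aggregate network (hat-matrix rows exist only
    for observed comparisons).  Column order matches the network's edges;
    the directed contribution of either orientation of cd accrues to the
    undirected direct comparison cd.
    """
    if hat is None:
        from .nma_core import hat_matrix

        hat = hat_matrix(network)
    comparisons = network.comparisons
    values = np.zeros((len(comparisons), len(comparisons)))
    col = {pair: j for j, pair in enumerate(comparisons)}
    for i, comparison in enumerate(comparisons):
        fn = flow_network(hat, comparison)
        for (c, d), p in proportion_contributions(evidence_streams(fn, max_paths=max_paths)).items():
            pair = (c, d) if label_key(c) <= label_key(d) else (d, c)
            values[i, col[pair]] += p
    return ContributionMatrix(comparisons=comparisons, edges=comparisons, values=values)
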