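"""Directed evidence flow networks derived from hat-matrix rows.

For the comparison ab, the ab row of the hat matrix defines a directed
acyclic graph: a positive entry in column cd is a flow of evidence from c
to d, a negative entry a flow from d to c.  A unit of evidence leaves the
source a, arrives at the sink b, and is conserved at every intermediate
node — exactly the pattern of a unit electrical current injected at a and
extracted at b.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model import HatMatrix, Label, Pair, canonical_pair, comparison_name, label_key

#: hat-matrix entries with |H| below this are structural zeros, not flow edges
FLOW_TOL = 1e-12


@dataclass
class FlowNetwork:
    """Unit evidence flow from ``source`` to ``sink`` on a DAG.

    ``flows`` maps directed edges ``(c, d)`` to strictly positive flow
    values.  ``nodes`` keeps every treatment of the underlying network, so
    treatments isolated for this particular comparison remain represented.
    """

    comparison: Pair
    nodes: list[Label]
    flows: dict[tuple[Label, Label], float]

    @property
    def source(self) -> Label:
        return self.comparison[0]

    @property
    def sink(self) -> Label:
        return self.comparison[1]

    def successors(self, node: Label) -> list[Label]:
        return sorted((d for (c, d) in self.flows if c == node), key=label_key)

    def out_flow(self, node: Label) -> float:
        return sum(f for (c, _), f in self.flows.items() if c == node)

    def in_flow(self, node: Label) -> float:
        return sum(f for (_, d), f in self.flows.items() if d == node)

    def to_digraph(self) -> nx.DiGraph:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.nodes)
        for (c, d), f in self.flows.items():
            graph.add_edge(c, d, flow=f)
        return graph


@dataclass
class ConservationReport:
    """Outcome of the three flow-conservation checks with the worst deviation."""

    source_ok: bool
    sink_ok: bool
    intermediate_ok: bool
    max_deviation: float

    @property
    def ok(self) -> bool:
        return self.source_ok and self.sink_ok and self.intermediate_ok


def flow_network(hat: HatMatrix, comparison: Pair, tol: float = FLOW_TOL) -> FlowNetwork:
    """Build the evidence flow network for one comparison from its hat-matrix row.

    Entries within ``tol`` of zero are omitted.  The result is checked to be
    acyclic by topological sort; a cycle would signal numerical corruption
    upstream, since hat-matrix rows are currents of a unit-injection problem.
    """
    a, b = canonical_pair(comparison[0], comparison[1])[0]
    row = hat.row(a, b)
    flows: dict[tuple[Label, Label], float] = {}
    for (c, d), value in zip(hat.comparisons, row):
        if value > tol:
            flows[(c, d)] = float(value)
        elif value < -tol:
            flows[(d, c)] = float(-value)
    nodes = sorted({t for pair in hat.comparisons for t in pair}, key=label_key)
    fn = FlowNetwork(comparison=(a, b), nodes=nodes, flows=flows)
    if not nx.is_directed_acyclic_graph(fn.to_digraph()):
        raise ValueError(f"evidence flow network for {comparison_name((a, b))} contains a cycle")
    return fn


def check_conservation(fn: FlowNetwork, tol: float = 1e-10) -> ConservationReport:
    """Verify unit outflow at the source, unit inflow at the sink, and balance elsewhere."""
    deviations = [abs(fn.out_flow(fn.source) - 1.0), abs(fn.in_flow(fn.sink) - 1.0)]
    source_ok = deviations[0] <= tol and fn.in_flow(fn.source) == 0
    sink_ok = deviations[1] <= tol and fn.out_flow(fn.sink) == 0
    intermediate_dev = 0.0
    for node in fn.nodes:
        if node in (fn.source, fn.sink):
            continue
        intermediate_dev = max(intermediate_dev, abs(fn.in_flow(node) - fn.out_flow(node)))
    deviations.append(intermediate_dev)
    return ConservationReport(
        source_ok=source_ok,
        sink_ok=sink_ok,
        intermediate_ok=intermediate_dev <= tol,
        max_deviation=float(np.max(deviations)),
    )
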