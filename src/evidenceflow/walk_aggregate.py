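"""Random walks on the undirected aggregate network.

A walker at node c hops to a neighbour d with probability proportional to
the edge weight w_cd (the conductance of the electrical analogue).  For a
comparison ab the walk starts at a and node b is made absorbing.  The
expected *net* number of times the walker crosses edge cd equals the
electrical current through cd when a unit current is driven from a to b —
and therefore equals the hat-matrix element H_cd(ab).  The analytic route
(Laplacian pseudoinverse potentials) is exact and is the default for all
downstream computation; the Monte Carlo simulator exists to validate it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import AggregateNetwork, Label, Pair, comparison_name


@dataclass
class CrossingEstimate:
    """Expected net crossings per canonical edge, with Monte Carlo standard errors.

    ``mean[k]`` is the expected net number of crossings along edge
    ``edges[k]`` in its canonical direction; crossings in the opposite
    direction count negatively (antisymmetry: the estimate for the reversed
    edge is the negated value).  ``se`` is None for the analytic result.
    """

    edges: list[Pair]
    mean: np.ndarray
    se: np.ndarray | None = None


def transition_matrix(network: AggregateNetwork) -> np.ndarray:
    """Row-stochastic transition matrix T_cd = w_cd / sum_x w_cx, zero diagonal."""
    n = network.n_treatments
    adjacency = np.zeros((n, n))
    for edge in network.edges:
        i, j = network.node_index(edge.treat_a), network.node_index(edge.treat_b)
        adjacency[i, j] = adjacency[j, i] = edge.weight
    row_sums = adjacency.sum(axis=1)
    if np.any(row_sums == 0):
        isolated = [t for t, s in zip(network.treatments, row_sums) if s == 0]
        raise ValueError(f"isolated nodes have no transitions: {isolated}")
    return adjacency / row_sums[:, None]


def make_absorbing(transition: np.ndarray, b_index: int) -> np.ndarray:
    """Copy of ``transition`` with row ``b_index`` replaced by the unit vector at b."""
    absorbing = transition.copy()
    absorbing[b_index, :] = 0.0
    absorbing[b_index, b_index] = 1.0
    return absorbing


def path_probability(transition_ab: np.ndarray, path: Sequence[int]) -> float:
    """Probability of a node-index path under the absorbing walk: product of steps.

    The path must not continue past an absorbing state (a visit to an
    absorbing node anywhere but the final position is an error: the walk
    would have stopped there).
    """
    if len(path) < 2:
        raise ValueError("a path needs at least two nodes")
    for node in path[:-1]:
        if transition_ab[node, node] == 1.0:
            raise ValueError(f"path continues past absorbing node index {node}")
    prob = 1.0
    for c, d in zip(path[:-1], path[1:]):
        prob *= transition_ab[c, d]
    return float(prob)


def expected_net_crossings_analytic(network: AggregateNetwork, a: Label, b: Label) -> CrossingEstimate:
    """Exact expected net crossings via the electrical-current identity.

    Solves the unit-injection problem: potentials ``v = L+ (e_a - e_b)``,
    currents ``I_cd = w_cd (v_c - v_d)`` per canonical edge.  The result is
    elementwise identical to the ab row of the hat matrix.
    """
    if a == b:
        raise ValueError("source and sink must differ")
    injection = np.zeros(network.n_treatments)
    injection[network.node_index(a)] = 1.0
    injection[network.node_index(b)] = -1.0
    potentials = network.laplacian_pinv @ injection
    currents = np.array(
        [
            e.weight * (potentials[network.node_index(e.treat_a)] - potentials[network.node_index(e.treat_b)])
            for e in network.edges
        ]
    )
    return CrossingEstimate(edges=network.comparisons, mean=currents, se=None)


def simulate_walkers(
    network: AggregateNetwork,
    a: Label,
    b: Label,
    n_walkers: int = 100_000,
    seed: int | None = None,
    max_steps: int = 1_000_000,
    batch_steps: int = 256,
) -> CrossingEstimate:
    """Monte Carlo estimate of expected net crossings for the comparison ab.

    Releases ``n_walkers`` independent walkers at a under the absorbing
    transition matrix and accumulates, per walker, the signed number of
    crossings of every edge until absorption at b.  Returns per-edge means
    and standard errors of the mean.  Absorption is certain on a connected
    network; a walker exceeding ``max_steps`` raises ("non-absorbing walk").

    Walkers advance in lock-step numpy batches for speed; the per-walker
    counts (needed for standard errors) are kept in an
    ``n_walkers x n_edges`` integer array.
    """
    if n_walkers < 1:
        raise ValueError("n_walkers must be at least 1")
    transition = make_absorbing(transition_matrix(network), network.node_index(b))
    cumulative = np.cumsum(transition, axis=1)
    a_idx, b_idx = network.node_index(a), network.node_index(b)
    if a_idx == b_idx:
        raise ValueError("source and sink must differ")

    n_nodes, n_edges = network.n_treatments, network.n_edges
    edge_of = -np.ones((n_nodes, n_nodes), dtype=np.int64)
    sign_of = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    for k, e in enumerate(network.edges):
        i, j = network.node_index(e.treat_a), network.node_index(e.treat_b)
        edge_of[i, j] = edge_of[j, i] = k
        sign_of[i, j], sign_of[j, i] = 1, -1

    rng = np.random.default_rng(seed)
    position = np.full(n_walkers, a_idx, dtype=np.int64)
    crossings = np.zeros((n_walkers, n_edges), dtype=np.int32)
    walker_ids = np.arange(n_walkers)

    steps = 0
    active = position != b_idx
    while np.any(active):
        if steps >= max_steps:
            raise RuntimeError(f"non-absorbing walk: {int(active.sum())} walkers still active after {max_steps} steps")
        current = position[active]
        draws = rng.random(current.size)
        nxt = (draws[:, None] < cumulative[current]).argmax(axis=1)
        ids = walker_ids[active]
        crossings[ids, edge_of[current, nxt]] += sign_of[current, nxt]
        position[active] = nxt
        active = position != b_idx
        steps += 1

    mean = crossings.mean(axis=0)
    se = crossings.std(axis=0, ddof=1) / np.sqrt(n_walkers) if n_walkers > 1 else np.zeros(n_edges)
    return CrossingEstimate(edges=network.comparisons, mean=mean, se=se)
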