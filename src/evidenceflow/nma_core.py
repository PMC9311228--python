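"""Aggregate NMA model: multi-arm adjustment, pooling, Laplacian, hat matrix.

The aggregate (two-step) model first converts every trial into an
equivalent set of two-arm comparisons, then pools comparisons edge by edge
with inverse-variance weights, and finally solves the network by weighted
least squares on the graph.  The key objects are the signed incidence
matrix ``B``, the diagonal weight matrix ``W``, the graph Laplacian
``L = B.T W B`` and the hat matrix ``H = B L+ B.T W``, which projects
direct estimates onto the consistent subspace.

The variance <-> resistance correspondence drives the multi-arm
adjustment: the matrix of pairwise total variances of an n-arm trial is a
matrix of resistance distances, whose double-centered form is (-2 times) a
Laplacian pseudoinverse.  Pseudo-inverting recovers the trial Laplacian,
whose negated off-diagonal entries are the adjusted two-arm weights.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import networkx as nx
import numpy as np

from .model import (
    AggregateEdge,
    AggregateNetwork,
    HatMatrix,
    Label,
    ModelSpec,
    Pair,
    Trial,
    canonical_pair,
    comparison_name,
    label_key,
)

#: adjusted weights more negative than this raise; values in (-NEG_TOL, 0) clip to 0
NEG_TOL = 1e-10

#: relative eigenvalue cutoff for the Laplacian pseudoinverse
PINV_CUTOFF = 1e-12


def pinv_psd(matrix: np.ndarray, cutoff: float = PINV_CUTOFF) -> np.ndarray:
    """Moore-Penrose pseudoinverse of a symmetric PSD matrix via eigendecomposition.

    Eigenvalues below ``cutoff`` times the largest eigenvalue are treated as
    exact zeros, which keeps explicit control over the rank-(N-1) null space
    of a connected-graph Laplacian.
    """
    sym = 0.5 * (matrix + matrix.T)
    eigval, eigvec = np.linalg.eigh(sym)
    scale = np.max(np.abs(eigval)) if eigval.size else 0.0
    inv = np.where(np.abs(eigval) > cutoff * scale, 1.0 / np.where(eigval == 0, 1.0, eigval), 0.0)
    return (eigvec * inv) @ eigvec.T


def adjust_multiarm(trial: Trial, model: ModelSpec | None = None) -> Trial:
    """Fill the trial's adjusted per-comparison weights, in place, and return it.

    For a two-arm trial the weight is exactly ``1 / (se**2 + tau2)``.  For an
    n-arm trial the pairwise total variances (heterogeneity added *before*
    adjustment) form a resistance-distance matrix ``V``; with the centering
    matrix ``C = I - J/n`` the trial Laplacian is ``pinv(-0.5 * C V C)`` and
    the adjusted weights are its negated off-diagonal entries.

    Raises
    ------
    ValueError
        If the trial is missing a pairwise contrast ("incomplete multi-arm
        trial") or an adjusted weight is negative beyond round-off
        ("inadmissible variance pattern").
    """
    model = model or ModelSpec()
    if not trial.is_complete:
        raise ValueError(
            f"incomplete multi-arm trial {trial.study_id!r}: "
            f"{trial.n_arms} arms require {trial.n_arms * (trial.n_arms - 1) // 2} contrasts, "
            f"got {len(trial.contrasts)}"
        )
    arms = trial.treatments
    n = len(arms)

    if n == 2:
        contrast = trial.contrasts[0]
        trial.adjusted_weights = {contrast.pair: 1.0 / (contrast.se**2 + model.tau2)}
        return trial

    index = {t: i for i, t in enumerate(arms)}
    variances = np.zeros((n, n))
    for contrast in trial.contrasts:
        i, j = index[contrast.treat_a], index[contrast.treat_b]
        variances[i, j] = variances[j, i] = contrast.se**2 + model.tau2

    centering = np.eye(n) - np.ones((n, n)) / n
    lap_pinv = -0.5 * centering @ variances @ centering
    lap = pinv_psd(lap_pinv)

    weights: dict[Pair, float] = {}
    for contrast in trial.contrasts:
        i, j = index[contrast.treat_a], index[contrast.treat_b]
        w = -lap[i, j]
        if w < -NEG_TOL:
            raise ValueError(
                f"inadmissible variance pattern in trial {trial.study_id!r}: "
                f"adjusted weight for {comparison_name(contrast.pair)} is {w:.3g}"
            )
        weights[contrast.pair] = max(w, 0.0)
    trial.adjusted_weights = weights
    return trial


def _connected_or_raise(edges: Sequence[Pair], treatments: Sequence[Label]) -> None:
    graph = nx.Graph()
    graph.add_nodes_from(treatments)
    graph.add_edges_from(edges)
    if not nx.is_connected(graph):
        components = [sorted(c, key=label_key) for c in nx.connected_components(graph)]
        raise ValueError(f"network is disconnected; components: {components}")


def pool_direct(trials: Sequence[Trial], model: ModelSpec | None = None) -> AggregateNetwork:
    """Pool adjusted per-trial comparisons into the aggregate network.

    Each distinct treatment pair becomes one edge with weight equal to the
    sum of the adjusted per-trial weights and direct estimate equal to the
    weighted mean of the (canonically oriented) observed effects.  Trials
    without adjusted weights are adjusted first.  Edges whose pooled weight
    is zero (infinite variance) are dropped.
    """
    model = model or ModelSpec()
    weight_sum: dict[Pair, float] = defaultdict(float)
    effect_sum: dict[Pair, float] = defaultdict(float)
    for trial in trials:
        if not trial.adjusted_weights:
            adjust_multiarm(trial, model)
        for contrast in trial.contrasts:
            w = trial.adjusted_weights[contrast.pair]
            weight_sum[contrast.pair] += w
            effect_sum[contrast.pair] += w * contrast.canonical_effect()

    # drop zero-weight edges (infinite variance); "zero" is relative to the
    # largest pooled weight so degenerate adjustments cannot leave a
    # numerically disconnected Laplacian behind
    w_max = max(weight_sum.values(), default=0.0)
    pairs = sorted(
        (p for p, w in weight_sum.items() if w > 1e-12 * w_max),
        key=lambda p: (label_key(p[0]), label_key(p[1])),
    )
    if not pairs:
        raise ValueError("no comparisons with positive weight")
    edges = [
        AggregateEdge(p[0], p[1], weight=weight_sum[p], direct_estimate=effect_sum[p] / weight_sum[p])
        for p in pairs
    ]
    treatments = sorted({t for p in pairs for t in p}, key=label_key)
    return build_network(treatments, edges)


def network_from_weights(
    edge_weights: dict[Pair, float] | Sequence[tuple[Label, Label, float]],
    direct_estimates: dict[Pair, float] | None = None,
) -> AggregateNetwork:
    """Build an aggregate network directly from pooled edge weights.

    Convenience constructor for worked examples and fixtures where the
    pooled weights (rather than trial-level data) are given.
    """
    if isinstance(edge_weights, dict):
        items = [(a, b, w) for (a, b), w in edge_weights.items()]
    else:
        items = list(edge_weights)
    direct_estimates = direct_estimates or {}
    edges = []
    for a, b, w in items:
        pair, sign = canonical_pair(a, b)
        theta = direct_estimates.get(pair, sign * direct_estimates.get((b, a) if sign > 0 else (a, b), 0.0))
        edges.append(AggregateEdge(pair[0], pair[1], weight=float(w), direct_estimate=float(theta)))
    edges.sort(key=lambda e: (label_key(e.treat_a), label_key(e.treat_b)))
    treatments = sorted({t for e in edges for t in e.pair}, key=label_key)
    return build_network(treatments, edges)


def build_network(treatments: list[Label], edges: list[AggregateEdge]) -> AggregateNetwork:
    """Assemble incidence matrix, Laplacian and pseudoinverse; require connectivity."""
    for e in edges:
        if e.weight <= 0:
            raise ValueError(f"edge {comparison_name(e.pair)} has non-positive weight {e.weight}")
    _connected_or_raise([e.pair for e in edges], treatments)
    incidence = _incidence(treatments, edges)
    weights = np.array([e.weight for e in edges])
    laplacian = incidence.T @ (weights[:, None] * incidence)
    laplacian_pinv = pinv_psd(laplacian)
    return AggregateNetwork(
        treatments=list(treatments),
        edges=list(edges),
        incidence=incidence,
        weights=weights,
        laplacian=laplacian,
        laplacian_pinv=laplacian_pinv,
    )


def _incidence(treatments: Sequence[Label], edges: Sequence[AggregateEdge]) -> np.ndarray:
    index = {t: i for i, t in enumerate(treatments)}
    incidence = np.zeros((len(edges), len(treatments)))
    for k, e in enumerate(edges):
        incidence[k, index[e.treat_a]] = 1.0  # baseline treatment of the comparison
        incidence[k, index[e.treat_b]] = -1.0
    return incidence


def incidence_matrix(network: AggregateNetwork) -> np.ndarray:
    """The K x N signed edge-incidence matrix B (+1 at each edge's baseline)."""
    return network.incidence.copy()


def hat_matrix(network: AggregateNetwork) -> HatMatrix:
    """The K x K hat matrix ``H = B (B.T W B)+ B.T W`` of the aggregate model.

    ``H`` is idempotent and projects any vector of direct estimates onto the
    space of consistent effects (potential differences on the graph).  Row
    ab, split by sign, is the evidence flow network for comparison ab.
    """
    if np.linalg.matrix_rank(network.laplacian, tol=1e-10) < network.n_treatments - 1:
        raise ValueError("Laplacian rank below N-1: network is disconnected or degenerate")
    b = network.incidence
    values = b @ network.laplacian_pinv @ b.T @ network.weight_diag
    return HatMatrix(comparisons=network.comparisons, values=values)


def network_estimates(hat: HatMatrix, direct: np.ndarray | Sequence[float]) -> np.ndarray:
    """Network estimates ``theta_net = H theta_dir`` (consistent inputs are fixed points)."""
    direct = np.asarray(direct, dtype=float)
    if direct.shape != (len(hat.comparisons),):
        raise ValueError(f"expected {len(hat.comparisons)} direct estimates, got shape {direct.shape}")
    return hat.values @ direct
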