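"""Iterative stream-extraction algorithm (Shortest / Random / Average variants).

Predecessor of the random-walk construction: repeatedly pick a remaining
source-to-sink path, assign it the minimum residual flow along its edges,
subtract, and drop exhausted edges.  The outcome depends on the order of
path selection and some paths may receive no flow at all; the variants
differ only in how paths are picked.  Kept for comparison with the
analytical walk result, which is order-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evidence_flow import FlowNetwork
from .model import Label, label_key
from .streams import EvidenceStream, enumerate_paths, evidence_streams

RESIDUAL_TOL = 1e-10

VARIANTS = ("shortest", "random", "average")


@dataclass
class LegacyResult:
    streams: list[EvidenceStream]
    variant: str
    seed: int | None = None
    n_iter: int = 1

    @property
    def total_flow(self) -> float:
        return sum(s.flow for s in self.streams)


def _feasible_paths(fn: FlowNetwork, residual: dict[tuple[Label, Label], float]) -> list[tuple[Label, ...]]:
    # enumerate source->sink paths restricted to edges with residual flow
    live = FlowNetwork(comparison=fn.comparison, nodes=fn.nodes, flows=dict(residual))
    return enumerate_paths(live)


def _single_run(fn: FlowNetwork, variant: str, rng: np.random.Generator | None) -> dict[tuple[Label, ...], float]:
    residual = dict(fn.flows)
    assigned: dict[tuple[Label, ...], float] = {}
    while True:
        paths = _feasible_paths(fn, residual)
        if not paths:
            leftover = sum(residual.values())
            if leftover > RESIDUAL_TOL * max(1, len(fn.flows)):
                raise RuntimeError(f"residual flow {leftover:.3g} remains with no source-sink path")
            break
        if variant == "shortest":
            # shortest first; ties broken by lexicographic node sequence
            path = min(paths, key=lambda p: (len(p), [label_key(x) for x in p]))
        else:
            path = paths[rng.integers(len(paths))]
        phi = min(residual[edge] for edge in zip(path[:-1], path[1:]))
        assigned[path] = assigned.get(path, 0.0) + phi
        for edge in zip(path[:-1], path[1:]):
            residual[edge] -= phi
            if residual[edge] <= RESIDUAL_TOL:
                del residual[edge]
    return assigned


def legacy_streams(
    fn: FlowNetwork,
    variant: str = "shortest",
    seed: int | None = None,
    n_iter: int = 1000,
) -> LegacyResult:
    """Run the iterative algorithm on one evidence flow network.

    variant="shortest": deterministic, paths picked shortest-first.
    variant="random":   one run with uniformly random path selection.
    variant="average":  per-path flows averaged over n_iter seeded random
    runs; paths never selected are listed with flow 0.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    rng = np.random.default_rng(seed)
    all_paths = enumerate_paths(fn)

    if variant in ("shortest", "random"):
        assigned = _single_run(fn, variant, rng if variant == "random" else None)
        streams = [EvidenceStream(path=p, flow=f) for p, f in sorted(assigned.items(), key=lambda kv: kv[0])]
        return LegacyResult(streams=streams, variant=variant, seed=seed, n_iter=1)

    totals = {p: 0.0 for p in all_paths}
    for _ in range(n_iter):
        for path, phi in _single_run(fn, "random", rng).items():
            totals[path] += phi
    streams = [EvidenceStream(path=p, flow=totals[p] / n_iter) for p in all_paths]
    return LegacyResult(streams=streams, variant="average", seed=seed, n_iter=n_iter)


def compare_methods(fn: FlowNetwork, n_iter: int = 1000, seed: int | None = None):
    """Side-by-side per-path flows: analytical walk vs the three legacy variants.

    Paths a variant never assigns flow to are NaN in its column (rendered as
    "-" in text output, matching the conventional presentation).
    """
    import pandas as pd

    walk = {s.path: s.flow for s in evidence_streams(fn)}
    shortest = {s.path: s.flow for s in legacy_streams(fn, "shortest").streams}
    random_ = {s.path: s.flow for s in legacy_streams(fn, "random", seed=seed).streams}
    average = {s.path: s.flow for s in legacy_streams(fn, "average", seed=seed, n_iter=n_iter).streams}

    paths = sorted(walk, key=lambda p: [label_key(x) for x in p])
    names = ["→".join(str(x) for x in p) for p in paths]
    table = pd.DataFrame(
        {
            "walk": [walk[p] for p in paths],
            "shortest": [shortest.get(p, np.nan) for p in paths],
            "random": [random_.get(p, np.nan) for p in paths],
            "average": [average.get(p, np.nan) for p in paths],
        },
        index=names,
    )
    return table
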