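"""Core containers for the aggregate NMA model.

Treatment labels may be integers or strings.  All edges are stored in a
canonical orientation: the treatment that sorts first (numerically when the
label is an integer or an integer-like string, lexicographically otherwise)
is the baseline of the comparison and receives the ``+1`` entry in the
incidence matrix.  Fixing the orientation makes every derived matrix
reproducible; reversing an orientation only flips signs consistently and
leaves flow networks unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

Label = Hashable
Pair = tuple[Label, Label]


def label_key(label: Label):
    """Sort key placing integer-like labels in numeric order before others."""
    try:
        return (0, int(label), "")
    except (TypeError, ValueError):
        return (1, 0, str(label))


def canonical_pair(a: Label, b: Label) -> tuple[Pair, int]:
    """Return the canonically oriented pair and the sign of the reorientation.

    The sign is +1 if ``(a, b)`` is already canonical and -1 if the pair had
    to be flipped (an effect measured on the flipped pair changes sign).
    """
    if a == b:
        raise ValueError(f"self-comparison {a!r}-{b!r} is not a valid edge")
    if label_key(a) <= label_key(b):
        return (a, b), 1
    return (b, a), -1


def comparison_name(pair: Pair) -> str:
    return f"{pair[0]}-{pair[1]}"


@dataclass(frozen=True)
class TrialContrast:
    """One observed relative treatment effect within a study.

    ``effect`` is the observed effect of ``treat_b`` relative to ``treat_a``
    on the analysis scale (e.g. a log odds ratio) and ``se`` its standard
    error.
    """

    study_id: Label
    treat_a: Label
    treat_b: Label
    effect: float
    se: float

    def __post_init__(self):
        if self.treat_a == self.treat_b:
            raise ValueError(f"study {self.study_id!r}: contrast compares {self.treat_a!r} with itself")
        if not np.isfinite(self.se) or self.se <= 0:
            raise ValueError(f"study {self.study_id!r}: standard error must be positive, got {self.se!r}")

    @property
    def pair(self) -> Pair:
        return canonical_pair(self.treat_a, self.treat_b)[0]

    def canonical_effect(self) -> float:
        """Effect oriented so that the canonical baseline comes first."""
        pair, sign = canonical_pair(self.treat_a, self.treat_b)
        return sign * self.effect


@dataclass
class Trial:
    """A study contributing ``q = n(n-1)/2`` pairwise contrasts.

    A two-arm trial has one contrast; an ``n``-arm trial reports all
    pairwise contrasts among its arms.  ``adjusted_weights`` maps canonical
    treatment pairs to the per-trial weights of the equivalent network of
    two-arm trials; it is filled by :func:`evidenceflow.nma_core.adjust_multiarm`.
    """

    study_id: Label
    contrasts: list[TrialContrast]
    adjusted_weights: dict[Pair, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.contrasts:
            raise ValueError(f"study {self.study_id!r} has no contrasts")
        pairs = [c.pair for c in self.contrasts]
        if len(set(pairs)) != len(pairs):
            raise ValueError(f"study {self.study_id!r} has duplicate contrasts")

    @property
    def treatments(self) -> list[Label]:
        labels = {t for c in self.contrasts for t in (c.treat_a, c.treat_b)}
        return sorted(labels, key=label_key)

    @property
    def n_arms(self) -> int:
        return len(self.treatments)

    @property
    def is_complete(self) -> bool:
        n = self.n_arms
        return len(self.contrasts) == n * (n - 1) // 2


@dataclass(frozen=True)
class ModelSpec:
    """Analysis settings: common heterogeneity variance and effect-scale label."""

    tau2: float = 0.0
    effect_scale: str = "effect"

    def __post_init__(self):
        if self.tau2 < 0 or not np.isfinite(self.tau2):
            raise ValueError(f"tau2 must be a finite non-negative number, got {self.tau2!r}")


@dataclass(frozen=True)
class AggregateEdge:
    """A pooled direct comparison: canonical pair, weight w_ab, direct estimate."""

    treat_a: Label
    treat_b: Label
    weight: float
    direct_estimate: float

    @property
    def pair(self) -> Pair:
        return (self.treat_a, self.treat_b)


@dataclass
class AggregateNetwork:
    """The aggregate two-arm-equivalent network.

    Holds the N treatments, the K pooled edges, the signed K x N incidence
    matrix B (one +1 and one -1 per row), the diagonal weight matrix W, the
    graph Laplacian ``L = B.T W B`` and its Moore-Penrose pseudoinverse.
    """

    treatments: list[Label]
    edges: list[AggregateEdge]
    incidence: np.ndarray
    weights: np.ndarray
    laplacian: np.ndarray
    laplacian_pinv: np.ndarray

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def weight_diag(self) -> np.ndarray:
        return np.diag(self.weights)

    @property
    def comparisons(self) -> list[Pair]:
        return [e.pair for e in self.edges]

    @property
    def direct_estimates(self) -> np.ndarray:
        return np.array([e.direct_estimate for e in self.edges])

    def node_index(self, label: Label) -> int:
        try:
            return self.treatments.index(label)
        except ValueError:
            raise KeyError(f"unknown treatment {label!r}") from None

    def edge_index(self, a: Label, b: Label) -> int:
        pair, _ = canonical_pair(a, b)
        for k, e in enumerate(self.edges):
            if e.pair == pair:
                return k
        raise KeyError(f"no direct comparison {comparison_name(pair)} in the network")


@dataclass
class HatMatrix:
    """K x K hat matrix of the aggregate model: rows map direct to network estimates."""

    comparisons: list[Pair]
    values: np.ndarray

    def row(self, a: Label, b: Label) -> np.ndarray:
        """Row for comparison ab, sign-corrected when (a, b) is anti-canonical."""
        pair, sign = canonical_pair(a, b)
        try:
            k = self.comparisons.index(pair)
        except ValueError:
            raise KeyError(
                f"{comparison_name(pair)} is not an observed comparison; "
                "hat-matrix rows exist only for direct edges of the aggregate network"
            ) from None
        return sign * self.values[k]

    @property
    def names(self) -> list[str]:
        return [comparison_name(p) for p in self.comparisons]
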