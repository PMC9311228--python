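"""Seeded generator of synthetic contrast-format NMA data with known truth.

True relative effects are consistent by construction: each treatment gets a
latent "potential" and every true contrast is a potential difference.
Observed contrasts add Gaussian noise generated at *arm level* — one latent
draw per arm — so that the pairwise contrasts of a multi-arm trial carry
exactly the within-trial covariance structure the multi-arm adjustment
assumes (contrast variances sum the two arm variances, and contrasts
sharing an arm covary through it).  Common heterogeneity tau2 is emulated
the same way, as an extra tau2/2 variance per arm.

Defaults mirror a typical published network of this kind: 11 treatments,
26 trials of which roughly a third are multi-arm (up to four arms), binary
outcome on the log odds-ratio scale with contrast standard errors of
roughly 0.2-0.8, fixed-effect analysis (tau2 = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import Trial, TrialContrast


@dataclass
class SyntheticSpec:
    n_treatments: int = 11
    n_trials: int = 26
    multiarm_fraction: float = 9 / 26
    max_arms: int = 4
    sigma_range: tuple[float, float] = (0.2, 0.8)
    tau2: float = 0.0
    seed: int = 0
    potential_scale: float = 1.0
    max_retries: int = 100

    def __post_init__(self):
        if self.n_treatments < 2:
            raise ValueError("need at least two treatments")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if not (0 <= self.multiarm_fraction <= 1):
            raise ValueError("multiarm_fraction must be a probability")
        if self.max_arms < 2 or self.max_arms > self.n_treatments:
            raise ValueError("max_arms must be between 2 and n_treatments")
        lo, hi = self.sigma_range
        if lo <= 0 or hi < lo:
            raise ValueError("sigma_range must be a positive interval")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


def _sample_trials(spec: SyntheticSpec, potentials: np.ndarray, rng: np.random.Generator) -> list[Trial]:
    treatments = list(range(1, spec.n_treatments + 1))
    trials = []
    for i in range(1, spec.n_trials + 1):
        if spec.max_arms > 2 and rng.random() < spec.multiarm_fraction:
            n_arms = int(rng.integers(3, spec.max_arms + 1))
        else:
            n_arms = 2
        arms = sorted(rng.choice(treatments, size=n_arms, replace=False).tolist())

        # one latent value per arm: truth plus arm-level noise
        sigma = rng.uniform(*spec.sigma_range, size=n_arms)
        arm_sd = np.sqrt(sigma**2 / 2.0 + spec.tau2 / 2.0)
        latent = np.array([potentials[a - 1] for a in arms]) + rng.normal(0.0, arm_sd)
        # reported within-trial variance of contrast (a,b): sum of the two
        # sigma^2/2 arm components (heterogeneity is the analyst's input)
        contrasts = []
        for x in range(n_arms):
            for y in range(x + 1, n_arms):
                se = float(np.sqrt(sigma[x] ** 2 / 2.0 + sigma[y] ** 2 / 2.0))
                contrasts.append(
                    TrialContrast(
                        study_id=f"study_{i:03d}",
                        treat_a=arms[x],
                        treat_b=arms[y],
                        effect=float(latent[y] - latent[x]),
                        se=se,
                    )
                )
        trials.append(Trial(study_id=f"study_{i:03d}", contrasts=contrasts))
    return trials


def _is_connected(trials: list[Trial], n_treatments: int) -> bool:
    graph = nx.Graph()
    graph.add_nodes_from(range(1, n_treatments + 1))
    for t in trials:
        for c in t.contrasts:
            graph.add_edge(c.treat_a, c.treat_b)
    return nx.is_connected(graph)


def generate_synthetic(spec: SyntheticSpec) -> tuple[list[Trial], dict]:
    """Generate trials plus ground truth; regenerates until connected.

    Returns ``(trials, truth)`` where ``truth`` holds the per-treatment
    potentials (centered to mean zero) so that the true effect of b relative
    to a is ``potentials[b] - potentials[a]``.
    """
    rng = np.random.default_rng(spec.seed)
    potentials = rng.normal(0.0, spec.potential_scale, size=spec.n_treatments)
    potentials -= potentials.mean()
    for _ in range(spec.max_retries):
        trials = _sample_trials(spec, potentials, rng)
        if _is_connected(trials, spec.n_treatments):
            truth = {
                "potentials": {a + 1: float(potentials[a]) for a in range(spec.n_treatments)},
                "tau2": spec.tau2,
                "seed": spec.seed,
            }
            return trials, truth
    raise RuntimeError(f"could not generate a connected network in {spec.max_retries} attempts")
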