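"""Scikit-learn style front end for the aggregate NMA evidence-flow analysis.

``EvidenceFlowNMA`` is fit on contrast-format data (a DataFrame in the
netmeta convention or a list of :class:`~evidenceflow.model.Trial`).  The
fit builds the aggregate network and hat matrix; ``transform`` applies the
hat-matrix projection to vectors of direct estimates.  Flow networks,
evidence streams and proportion contributions for any observed comparison
are available from the fitted estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import legacy as _legacy
from .evidence_flow import FlowNetwork, flow_network
from .io import trials_from_frame
from .model import Label, ModelSpec, Trial, comparison_name
from .nma_core import hat_matrix, pool_direct
from .streams import DEFAULT_MAX_PATHS, EvidenceStream, evidence_streams, full_contribution_matrix


class EvidenceFlowNMA(TransformerMixin, BaseEstimator):
    """Aggregate network meta-analysis with evidence flow decomposition.

    Parameters
    ----------
    tau2 : float, default 0.0
        Common heterogeneity variance added to every contrast variance
        before the multi-arm adjustment (0 gives a fixed-effect analysis).
    max_paths : int, default 1_000_000
        Guard on the number of evidence paths enumerated per comparison.

    Attributes
    ----------
    network_ : AggregateNetwork
        Pooled two-arm-equivalent network (incidence, weights, Laplacian).
    treatments_ : list
        Treatment labels in canonical order.
    comparisons_ : list of tuple
        The K observed direct comparisons (canonical orientation).
    hat_matrix_ : pandas.DataFrame
        K x K hat matrix, labelled by comparison.
    direct_estimates_ : pandas.Series
        Pooled direct estimates per comparison.
    network_estimates_ : pandas.Series
        Network estimates ``H @ direct``.
    """

    def __init__(self, tau2: float = 0.0, max_paths: int = DEFAULT_MAX_PATHS):
        self.tau2 = tau2
        self.max_paths = max_paths

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            trials = trials_from_frame(X)
        elif isinstance(X, (list, tuple)) and all(isinstance(t, Trial) for t in X):
            trials = list(X)
        else:
            raise TypeError("X must be a contrast-format DataFrame or a list of Trial records")
        model = ModelSpec(tau2=self.tau2)
        for trial in trials:
            trial.adjusted_weights = {}
        self.network_ = pool_direct(trials, model)
        self.treatments_ = list(self.network_.treatments)
        self.comparisons_ = list(self.network_.comparisons)
        hat = hat_matrix(self.network_)
        self._hat = hat
        names = hat.names
        self.hat_matrix_ = pd.DataFrame(hat.values, index=names, columns=names)
        self.direct_estimates_ = pd.Series(self.network_.direct_estimates, index=names)
        self.network_estimates_ = pd.Series(hat.values @ self.network_.direct_estimates, index=names)
        return self

    def transform(self, X):
        """Project direct-estimate vectors onto consistent network estimates.

        ``X`` has shape (K,) or (m, K) with columns ordered as
        ``comparisons_``.  Consistent inputs are returned unchanged.
        """
        check_is_fitted(self, "hat_matrix_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        rows = np.atleast_2d(X)
        if rows.shape[1] != len(self.comparisons_):
            raise ValueError(f"expected {len(self.comparisons_)} columns, got {rows.shape[1]}")
        out = rows @ self._hat.values.T
        return out[0] if single else out

    def flow_network(self, a: Label, b: Label) -> FlowNetwork:
        """Evidence flow network for the observed comparison ab."""
        check_is_fitted(self, "hat_matrix_")
        return flow_network(self._hat, (a, b))

    def streams(self, a: Label, b: Label, method: str = "walk", seed: int | None = None, n_iter: int = 1000) -> list[EvidenceStream]:
        """Evidence streams for comparison ab by the analytical walk or a legacy variant."""
        fn = self.flow_network(a, b)
        if method == "walk":
            return evidence_streams(fn, max_paths=self.max_paths)
        return _legacy.legacy_streams(fn, variant=method, seed=seed, n_iter=n_iter).streams

    def contributions(self, a: Label, b: Label, method: str = "walk", seed: int | None = None, n_iter: int = 1000) -> pd.Series:
        """Proportion contribution of each direct comparison to the ab estimate."""
        from .streams import proportion_contributions

        streams = self.streams(a, b, method=method, seed=seed, n_iter=n_iter)
        contrib = proportion_contributions(streams)
        values = {}
        for (c, d), p in contrib.items():
            pair = (c, d) if (c, d) in self.comparisons_ else (d, c)
            key = comparison_name(pair)
            values[key] = values.get(key, 0.0) + p
        names = [comparison_name(p) for p in self.comparisons_]
        return pd.Series([values.get(n, 0.0) for n in names], index=names, name=comparison_name((a, b)))

    def contribution_matrix(self) -> pd.DataFrame:
        """Full proportion-contribution matrix over all observed comparisons."""
        check_is_fitted(self, "hat_matrix_")
        return full_contribution_matrix(self.network_, self._hat, max_paths=self.max_paths).to_frame()
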