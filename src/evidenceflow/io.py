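"""Contrast-data IO, matrix/graph export, and the in-package worked examples.

Input follows the contrast convention of the netmeta R package: one row per
pairwise comparison per study with columns ``studlab, treat1, treat2, TE,
seTE`` (treatment effect of ``treat2`` relative to ``treat1`` and its
standard error).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .evidence_flow import FlowNetwork
from .model import AggregateNetwork, HatMatrix, Trial, TrialContrast, comparison_name
from .nma_core import network_from_weights

REQUIRED_COLUMNS = ["studlab", "treat1", "treat2", "TE", "seTE"]


def _arms_from_contrasts(q: int) -> int:
    # invert q = n(n-1)/2
    n = (1 + math.isqrt(1 + 8 * q)) // 2
    if n * (n - 1) // 2 != q:
        raise ValueError(f"{q} rows is not a triangular number of contrasts")
    return n


def trials_from_frame(frame: pd.DataFrame) -> list[Trial]:
    """Group contrast rows by study label into Trial records."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if frame.empty:
        raise ValueError("no contrast rows found")
    trials = []
    for study, group in frame.groupby("studlab", sort=False):
        contrasts = [
            TrialContrast(
                study_id=study,
                treat_a=row.treat1,
                treat_b=row.treat2,
                effect=float(row.TE),
                se=float(row.seTE),
            )
            for row in group.itertuples()
        ]
        trial = Trial(study_id=study, contrasts=contrasts)
        try:
            expected_arms = _arms_from_contrasts(len(contrasts))
        except ValueError as err:
            raise ValueError(f"inconsistent contrast count for study {study!r}: {err}") from None
        if trial.n_arms != expected_arms or not trial.is_complete:
            raise ValueError(
                f"inconsistent contrast count for study {study!r}: {len(contrasts)} rows "
                f"over {trial.n_arms} treatments (expected all pairwise contrasts)"
            )
        trials.append(trial)
    return trials


def read_contrast_data(path: str | Path, sep: str | None = None) -> list[Trial]:
    """Read a delimited contrast file (CSV by default, TSV for .tsv) into trials."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return trials_from_frame(frame)


def write_contrast_data(trials: list[Trial], path: str | Path, sep: str = ",") -> None:
    rows = [
        {"studlab": c.study_id, "treat1": c.treat_a, "treat2": c.treat_b, "TE": c.effect, "seTE": c.se}
        for t in trials
        for c in t.contrasts
    ]
    # %.17g keeps the write -> read round trip bit-exact for float64 values
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# worked-example fixtures

#: five-treatment example network: edge -> pooled inverse-variance weight
FIG2_WEIGHTS = {
    (1, 2): 1.0,
    (1, 3): 3.0,
    (1, 5): 4.0,
    (2, 3): 6.0,
    (2, 4): 5.0,
    (3, 5): 2.0,
    (4, 5): 7.0,
}

#: four-treatment topical-antibiotics example: directed evidence flows for
#: the comparison 1-2 (1 no treatment, 2 quinolone antibiotic, 3 antiseptic,
#: 4 non-quinolone antibiotic), as printed to three decimals
MACFADYEN_FLOWS = {
    (1, 2): 0.635,
    (1, 3): 0.365,
    (3, 2): 0.251,
    (3, 4): 0.114,
    (4, 2): 0.114,
}


def fixture(name: str) -> AggregateNetwork | FlowNetwork:
    """Built-in worked examples: ``"fig2"`` (aggregate) or ``"macfadyen_flow"``."""
    if name == "fig2":
        return network_from_weights(FIG2_WEIGHTS)
    if name == "macfadyen_flow":
        return FlowNetwork(comparison=(1, 2), nodes=[1, 2, 3, 4], flows=dict(MACFADYEN_FLOWS))
    raise KeyError(f"unknown fixture {name!r}; available: 'fig2', 'macfadyen_flow'")


# ---------------------------------------------------------------------------
# exports


def matrix_to_frame(values: np.ndarray, row_labels, col_labels) -> pd.DataFrame:
    return pd.DataFrame(values, index=list(map(str, row_labels)), columns=list(map(str, col_labels)))


def hat_to_frame(hat: HatMatrix) -> pd.DataFrame:
    return matrix_to_frame(hat.values, hat.names, hat.names)


def network_to_json(network: AggregateNetwork) -> str:
    payload = {
        "treatments": [str(t) for t in network.treatments],
        "edges": [
            {
                "treat_a": str(e.treat_a),
                "treat_b": str(e.treat_b),
                "weight": e.weight,
                "direct_estimate": e.direct_estimate,
            }
            for e in network.edges
        ],
    }
    return json.dumps(payload, indent=2)


def flow_to_frame(fn: FlowNetwork) -> pd.DataFrame:
    rows = [
        {"comparison": comparison_name(fn.comparison), "from": c, "to": d, "flow": f}
        for (c, d), f in sorted(fn.flows.items(), key=lambda kv: str(kv[0]))
    ]
    return pd.DataFrame(rows, columns=["comparison", "from", "to", "flow"])


def flow_to_dot(fn: FlowNetwork, digits: int = 3) -> str:
    """Graphviz DOT text for a flow network, edges labelled by flow."""
    lines = [f'digraph "{comparison_name(fn.comparison)}" {{']
    for node in fn.nodes:
        lines.append(f'  "{node}";')
    for (c, d), f in sorted(fn.flows.items(), key=lambda kv: str(kv[0])):
        lines.append(f'  "{c}" -> "{d}" [label="{f:.{digits}f}"];')
    lines.append("}")
    return "\n".join(lines)


def network_to_graphml(network: AggregateNetwork, path: str | Path) -> None:
    graph = nx.Graph()
    graph.add_nodes_from(str(t) for t in network.treatments)
    for e in network.edges:
        graph.add_edge(str(e.treat_a), str(e.treat_b), weight=e.weight, direct_estimate=e.direct_estimate)
    nx.write_graphml(graph, str(path))


def flow_to_graphml(fn: FlowNetwork, path: str | Path) -> None:
    graph = nx.DiGraph()
    graph.add_nodes_from(str(n) for n in fn.nodes)
    for (c, d), f in fn.flows.items():
        graph.add_edge(str(c), str(d), flow=f)
    nx.write_graphml(graph, str(path))
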