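"""Expected influence, bridge expected influence, and network descriptors.

One-step expected influence (EI) of a node is the signed sum of its edge
weights; nodes with high EI can activate the rest of the network.  Bridge
expected influence (BEI) restricts the sum to edges ending in a different
community, so a large positive BEI marks a node that activates the other
cluster and a large negative BEI one that deactivates it.  Whole-network
descriptors follow the structural-zero convention of the glasso stage: an
edge exists iff its precision entry is structurally non-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError


def _check_weights(weights: np.ndarray) -> np.ndarray:
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise EstimationError("weights must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise EstimationError("weights must be symmetric")
    if np.any(np.diag(W) != 0.0):
        raise EstimationError("weights diagonal must be zero")
    return W


def expected_influence(weights: np.ndarray,
                       node: int | None = None) -> np.ndarray | float:
    """One-step EI: signed row sum of the edge-weight matrix.  Returns the
    full vector, or a scalar when ``node`` is given."""
    W = _check_weights(weights)
    ei = W.sum(axis=1)
    return float(ei[node]) if node is not None else ei


def bridge_expected_influence(weights: np.ndarray, communities: list[str],
                              node: int | None = None
                              ) -> np.ndarray | float:
    """One-step BEI: signed sum of a node's edges into other communities."""
    W = _check_weights(weights)
    comm = np.asarray(communities)
    if comm.shape[0] != W.shape[0]:
        raise EstimationError("one community label per node required")
    if len(set(communities)) < 2:
        raise EstimationError(
            "bridge expected influence requires at least 2 communities")
    other = comm[:, None] != comm[None, :]
    bei = (W * other).sum(axis=1)
    return float(bei[node]) if node is not None else bei


@dataclass
class NetworkDescriptors:
    density: float
    mean_weight: float
    mean_abs_weight: float
    n_edges: int
    n_positive: int
    n_negative: int
    strongest_positive: tuple[tuple[int, int], float] | None
    strongest_negative: tuple[tuple[int, int], float] | None


def network_descriptors(weights: np.ndarray) -> NetworkDescriptors:
    """Density, mean weight and signed extreme edges.

    Density is ``n_edges / (p (p-1) / 2)``; ``mean_weight`` averages signed
    weights over ALL pairs including structural zeros (the density-adjusted
    convention); ``mean_abs_weight`` is the same average of absolute
    weights, exposed for transparency since summaries in the literature are
    ambiguous on this point.
    """
    W = _check_weights(weights)
    p = W.shape[0]
    iu = np.triu_indices(p, k=1)
    vals = W[iu]
    n_pairs = vals.size
    nz = vals != 0.0
    n_edges = int(nz.sum())
    n_positive = int((vals > 0).sum())
    n_negative = int((vals < 0).sum())
    strongest_pos = strongest_neg = None
    if n_positive:
        k = int(np.argmax(vals))
        strongest_pos = ((int(iu[0][k]), int(iu[1][k])), float(vals[k]))
    if n_negative:
        k = int(np.argmin(vals))
        strongest_neg = ((int(iu[0][k]), int(iu[1][k])), float(vals[k]))
    return NetworkDescriptors(
        density=n_edges / n_pairs,
        mean_weight=float(vals.mean()),
        mean_abs_weight=float(np.abs(vals).mean()),
        n_edges=n_edges,
        n_positive=n_positive,
        n_negative=n_negative,
        strongest_positive=strongest_pos,
        strongest_negative=strongest_neg,
    )


def centrality_table(weights: np.ndarray, labels: list[str],
                     communities: list[str]) -> pd.DataFrame:
    """Per-node EI and BEI as a DataFrame indexed by node label."""
    ei = expected_influence(weights)
    bei = bridge_expected_influence(weights, communities)
    return pd.DataFrame(
        {"community": communities, "ei": ei, "bei": bei},
        index=pd.Index(labels, name="node"))


def rank_nodes(table: pd.DataFrame, by: str = "ei"
               ) -> tuple[list[str], bool]:
    """Node labels in descending order of the chosen metric.

    Ties are broken lexicographically by label and flagged (second return
    value) — reproducibility over aesthetics.
    """
    metric = by.lower()
    if metric not in ("ei", "bei"):
        raise EstimationError(f"unknown metric {by!r}; use 'ei' or 'bei'")
    values = table[metric]
    has_ties = bool(values.duplicated().any())
    order = table.sort_index().sort_values(
        metric, ascending=False, kind="stable")
    return list(order.index), has_ties
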