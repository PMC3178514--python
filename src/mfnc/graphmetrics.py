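"""Graph metrics of a thresholded causal network: causal density and flow."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GraphMetrics:
    causal_density_count: int
    causal_density_normalized: float
    causal_flow: np.ndarray  # out-degree minus in-degree, per node
    roles: list[str]  # "source" / "sink" / "neutral"


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    A = np.asarray(adjacency, dtype=bool)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(np.diag(A)):
        raise ValueError("self-edges are not allowed")
    return A


def causal_density(adjacency: np.ndarray) -> tuple[int, float]:
    """Number of significant directed links and its normalized value
    (count / n(n-1))."""
    A = _check_adjacency(adjacency)
    n = A.shape[0]
    count = int(A.sum())
    norm = count / (n * (n - 1)) if n > 1 else 0.0
    return count, norm


def causal_flow(adjacency: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Per-node out-degree minus in-degree; positive flow marks a causal
    source, negative a sink, zero neutral.

    Convention: adjacency[i, j] is the edge j -> i.
    """
    A = _check_adjacency(adjacency)
    out_deg = A.sum(axis=0)  # column j: edges leaving node j
    in_deg = A.sum(axis=1)
    flow = (out_deg - in_deg).astype(int)
    roles = ["source" if f > 0 else "sink" if f < 0 else "neutral" for f in flow]
    return flow, roles


def graph_metrics(adjacency: np.ndarray) -> GraphMetrics:
    count, norm = causal_density(adjacency)
    flow, roles = causal_flow(adjacency)
    return GraphMetrics(
        causal_density_count=count,
        causal_density_normalized=norm,
        causal_flow=flow,
        roles=roles,
    )
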