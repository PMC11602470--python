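"""Closeness centrality of multiplex networks and inter-layer heterogeneity.

Edge distance is the inverse of the (normalized) connection strength; a
zero-weight edge is absent (infinite distance). Within a layer the closeness
of node i is the inverse of its mean shortest-path distance to all other
nodes, and 0 when any node is unreachable. The overlapping closeness of a
node averages its per-layer closenesses. An alternative convention in which
shortest paths may hop between a node's replicas at zero cost (equivalent,
for two layers, to distances on the elementwise-maximum-weight graph) is
available through ``interlayer='zero-cost'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import MultiplexNetwork
from .preprocess import ValidationError

__all__ = [
    "CentralityMatrix",
    "layer_closeness",
    "overlapping_closeness",
    "centrality_matrix",
    "interlayer_heterogeneity",
]


@dataclass
class CentralityMatrix:
    """Per-layer node closeness centralities plus the overlapping vector."""

    values: np.ndarray  # [n_nodes x n_layers]
    overlapping: np.ndarray  # [n_nodes]
    node_labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_layers(self) -> int:
        return self.values.shape[1]


def _distance_matrix(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        dist = 1.0 / weights
    np.fill_diagonal(dist, 0.0)
    return dist


def _closeness_from_weights(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    if n < 2:
        raise ValidationError("closeness needs at least 2 nodes")
    d = shortest_path(_distance_matrix(weights), method="D", directed=False)
    c = np.zeros(n)
    for i in range(n):
        row = np.delete(d[i], i)
        if np.all(np.isfinite(row)):
            mean_d = row.mean()
            c[i] = 1.0 / mean_d if mean_d > 0 else 0.0
    return c


def layer_closeness(
    net: MultiplexNetwork, layer: int, interlayer: str = "within"
) -> np.ndarray:
    """Closeness centrality of every node within one layer.

    With ``interlayer='zero-cost'`` paths may traverse the other layers'
    copies of any intermediate node free of charge, i.e. each hop uses the
    best edge available in any layer.
    """
    if not net.normalized:
        raise ValidationError("network must be normalized before centrality")
    if not 0 <= layer < net.n_layers:
        raise ValidationError(f"layer {layer} out of range")
    if interlayer == "within":
        w = net.layer_weights[layer]
    elif interlayer == "zero-cost":
        w = np.maximum.reduce(net.layer_weights)
    else:
        raise ValidationError(f"unknown interlayer convention {interlayer!r}")
    return _closeness_from_weights(w)


def overlapping_closeness(
    net: MultiplexNetwork, interlayer: str = "within"
) -> np.ndarray:
    """Overlapping closeness: the mean of a node's per-layer closenesses."""
    cols = [layer_closeness(net, l, interlayer) for l in range(net.n_layers)]
    return np.mean(cols, axis=0)


def centrality_matrix(
    net: MultiplexNetwork, interlayer: str = "within"
) -> CentralityMatrix:
    """Full centrality matrix (nodes x layers) with the overlapping vector."""
    cols = [layer_closeness(net, l, interlayer) for l in range(net.n_layers)]
    values = np.column_stack(cols)
    return CentralityMatrix(
        values=values,
        overlapping=values.mean(axis=1),
        node_labels=list(net.node_labels),
    )


def interlayer_heterogeneity(net: MultiplexNetwork) -> float:
    """Pearson correlation between the two layers' off-diagonal edge weights.

    Near 1 the layers share structure; near 0 they are unrelated. Returns NaN
    with a warning when either layer's edges have zero variance.
    """
    if net.n_layers != 2:
        raise ValidationError("heterogeneity is defined for two layers")
    iu = np.triu_indices(net.n_nodes, k=1)
    if iu[0].size < 3:
        raise ValidationError("need at least 3 distinct edge positions")
    a = net.layer_weights[0][iu]
    b = net.layer_weights[1][iu]
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero edge variance; heterogeneity undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
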