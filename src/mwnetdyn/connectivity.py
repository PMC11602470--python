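"""Two-layer multiplex functional connectivity for one data segment.

Layer 1 is amplitude envelope correlation (AEC): the absolute Pearson
correlation between Hilbert amplitude envelopes of two channels. Layer 2 is
the imaginary phase-locking value (IPLV):

    IPLV_ij = (1/N) | Im sum_n exp(i (phi_i(n) - phi_j(n))) |

with ``phi`` the analytic (Hilbert) phase. Taking only the imaginary part
makes the measure blind to zero-lag coupling, the dominant signature of
volume conduction at the electrode level. Each layer's edge weights are
min-max normalized over its off-diagonal entries so the two layers share a
common [0, 1] scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .preprocess import ValidationError

__all__ = [
    "MultiplexNetwork",
    "aec",
    "iplv",
    "normalize_layer",
    "build_multiplex",
]

LAYER_LABELS = ("AEC", "IPLV")


@dataclass
class MultiplexNetwork:
    """Weighted two-layer multiplex network for one time segment.

    ``layer_weights[l]`` is a symmetric nonnegative matrix with zero diagonal;
    when ``normalized`` all off-diagonal weights lie in [0, 1]. Interlayer
    edges link each node only to its own replica and carry no traversal cost.
    """

    n_nodes: int
    layer_weights: list[np.ndarray]
    layer_labels: tuple[str, ...] = LAYER_LABELS
    segment_span: tuple[float, float] = (0.0, 0.0)
    normalized: bool = False
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_labels:
            self.node_labels = [f"ch{i}" for i in range(self.n_nodes)]
        for w in self.layer_weights:
            if w.shape != (self.n_nodes, self.n_nodes):
                raise ValidationError("layer matrix shape mismatch")
            if not np.allclose(w, w.T, atol=1e-12):
                raise ValidationError("layer matrix must be symmetric")
            if np.any(np.diag(w) != 0):
                raise ValidationError("layer diagonal must be zero")

    @property
    def n_layers(self) -> int:
        return len(self.layer_weights)


def _check_segment(segment: np.ndarray) -> np.ndarray:
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 2 or segment.shape[0] < 2:
        raise ValidationError("segment must be a channels x samples matrix, >= 2 channels")
    if segment.shape[1] < 8:
        raise ValidationError("segment too short (< 8 samples)")
    if not np.all(np.isfinite(segment)):
        raise ValidationError("segment contains non-finite values")
    return segment


def aec(segment: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between Hilbert amplitude envelopes.

    Returns a symmetric matrix with zero diagonal and values in [0, 1]. Pairs
    involving a constant-envelope channel are set to 0 with a warning
    (correlation undefined).
    """
    segment = _check_segment(segment)
    env = np.abs(hilbert(segment, axis=1))
    sd = env.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("constant envelope channel(s); their AEC set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(env)
    r = np.abs(r)
    r[~np.isfinite(r)] = 0.0
    if degenerate.any():
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.fill_diagonal(r, 0.0)
    return np.clip(r, 0.0, 1.0)


def iplv(segment: np.ndarray) -> np.ndarray:
    """Imaginary phase-locking value between all channel pairs.

    ``(1/N) |Im sum_n exp(i(phi_i - phi_j))|`` with the analytic phase from
    the Hilbert transform of each channel over the whole segment.
    """
    segment = _check_segment(segment)
    analytic = hilbert(segment, axis=1)
    amp = np.abs(analytic)
    degenerate = np.all(amp == 0, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = analytic / amp
    z[~np.isfinite(z)] = 0.0
    n = segment.shape[1]
    m = np.abs(np.imag(z @ z.conj().T)) / n
    if degenerate.any():
        warnings.warn("all-zero channel(s); their IPLV set to 0", stacklevel=2)
        m[degenerate, :] = 0.0
        m[:, degenerate] = 0.0
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2  # symmetrize away float asymmetry
    return np.clip(m, 0.0, 1.0)


def normalize_layer(weights: np.ndarray) -> np.ndarray:
    """Min-max normalize a layer's off-diagonal weights to [0, 1].

    If all off-diagonal weights are equal, every edge maps to 1 (keeping the
    layer connected for shortest-path centrality) and a warning is emitted.
    """
    w = np.asarray(weights, dtype=np.float64)
    off = ~np.eye(w.shape[0], dtype=bool)
    vals = w[off]
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite edge weights")
    lo, hi = vals.min(), vals.max()
    out = np.zeros_like(w)
    if hi == lo:
        warnings.warn("degenerate layer (all edges equal); normalized to 1", stacklevel=2)
        out[off] = 1.0
        return out
    out[off] = (w[off] - lo) / (hi - lo)
    return out


def build_multiplex(
    segment: np.ndarray,
    span: tuple[float, float] = (0.0, 0.0),
    node_labels: list[str] | None = None,
) -> MultiplexNetwork:
    """Assemble the normalized two-layer (AEC, IPLV) multiplex network."""
    segment = _check_segment(segment)
    layers = [normalize_layer(aec(segment)), normalize_layer(iplv(segment))]
    return MultiplexNetwork(
        n_nodes=segment.shape[0],
        layer_weights=layers,
        segment_span=(float(span[0]), float(span[1])),
        normalized=True,
        node_labels=list(node_labels) if node_labels else [],
    )
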