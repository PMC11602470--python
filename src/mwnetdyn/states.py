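"""Recurring multilayer network states via Louvain clustering of segments.

Every segment is summarized by its normalized overlapping closeness vector.
Vectors are min-max normalized per participant and per node component over
all of that participant's segments and trials, then pooled across
participants into a complete segment-similarity graph whose edge weights are
Spearman rank correlations (negatives clamped to 0, since modularity assumes
nonnegative weights). Louvain communities of that graph are the network
states, labeled A, B, C, ... in order of descending time coverage; states
holding under 1% of total time are merged into their most-correlated
neighbor so they cannot destabilize downstream observation alphabets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.stats import rankdata

from .preprocess import ValidationError

__all__ = [
    "StateCatalog",
    "normalize_centralities",
    "build_similarity_graph",
    "detect_states",
    "state_centroids",
    "cross_band_state_correlation",
]


@dataclass
class StateCatalog:
    """Clustering result: per-segment state labels, centroids and coverage."""

    state_labels: list[str]
    assignment: np.ndarray  # state index per segment (graph node order)
    centroids: dict[str, np.ndarray] = field(default_factory=dict)
    coverage_ratio: dict[str, float] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_labels)


def normalize_centralities(
    vectors_by_participant: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Per-participant, per-component min-max normalization to [0, 1].

    The min and max are taken over all of a participant's segments and trials
    (rows), independently per node component, removing inter-individual
    scale differences before pooling. Zero-range components map to 0.
    """
    out = {}
    for pid, v in vectors_by_participant.items():
        v = np.asarray(v, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 2:
            raise ValidationError(f"participant {pid}: need >= 2 vectors")
        lo = v.min(axis=0)
        hi = v.max(axis=0)
        rng = hi - lo
        zero = rng == 0
        if zero.any():
            warnings.warn(
                f"participant {pid}: zero-range component(s) set to 0", stacklevel=2
            )
        safe = np.where(zero, 1.0, rng)
        norm = (v - lo) / safe
        norm[:, zero] = 0.0
        out[pid] = norm
    return out


def build_similarity_graph(
    vectors: np.ndarray,
    durations: np.ndarray | None = None,
) -> nx.Graph:
    """Complete graph over segments; weights are clamped Spearman correlations.

    Node i carries its normalized vector (``vec``) and segment duration
    (``duration``) as attributes for downstream state detection.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[0] < 10 or vectors.shape[1] < 3:
        raise ValidationError("need >= 10 vectors of length >= 3")
    n = vectors.shape[0]
    ranks = rankdata(vectors, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn("constant vector(s); their similarity edges set to 0", stacklevel=2)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1))
    denom[denom == 0] = 1.0
    z = centered / denom[:, None]
    corr = z @ z.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    w = np.clip(corr, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)

    if durations is None:
        durations = np.ones(n)
    g = nx.Graph()
    for i in range(n):
        g.add_node(i, vec=vectors[i], duration=float(durations[i]))
    iu, ju = np.triu_indices(n, k=1)
    g.add_weighted_edges_from(
        (int(i), int(j), float(w[i, j])) for i, j in zip(iu, ju) if w[i, j] > 0
    )
    return g


def detect_states(
    graph: nx.Graph,
    seed: int,
    resolution: float = 1.0,
    min_coverage: float = 0.01,
) -> StateCatalog:
    """Louvain communities of the similarity graph, labeled by coverage.

    Communities covering less than ``min_coverage`` of total segment time are
    merged into the community whose centroid correlates most with theirs.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValidationError("graph must have at least 2 nodes")
    total_w = sum(d.get("weight", 0) for _, _, d in graph.edges(data=True))
    if total_w == 0:
        warnings.warn("all-zero weights; single community returned", stacklevel=2)
        comms = [set(graph.nodes)]
    else:
        comms = nx.community.louvain_communities(
            graph, weight="weight", resolution=resolution, seed=seed
        )
    durations = np.array([graph.nodes[i]["duration"] for i in range(n)])
    vectors = np.array([graph.nodes[i]["vec"] for i in range(n)])
    total_t = durations.sum()

    comms = [sorted(c) for c in comms]
    cov = [durations[list(c)].sum() / total_t for c in comms]

    # merge tiny communities into their most-correlated neighbor
    def centroid(c):
        return vectors[list(c)].mean(axis=0)

    merged = True
    while merged and len(comms) > 1:
        merged = False
        for k, c in enumerate(comms):
            if cov[k] < min_coverage:
                cen = centroid(c)
                best, best_r = None, -np.inf
                for k2, c2 in enumerate(comms):
                    if k2 == k:
                        continue
                    r = np.corrcoef(cen, centroid(c2))[0, 1]
                    if np.isfinite(r) and r > best_r:
                        best, best_r = k2, r
                if best is None:
                    best = int(np.argmax([cv if k2 != k else -1 for k2, cv in enumerate(cov)]))
                comms[best] = sorted(set(comms[best]) | set(c))
                del comms[k]
                cov = [durations[list(c2)].sum() / total_t for c2 in comms]
                merged = True
                break

    order = np.argsort(cov)[::-1]
    labels = [chr(ord("A") + r) for r in range(len(comms))]
    assignment = np.empty(n, dtype=int)
    centroids = {}
    coverage = {}
    for rank, k in enumerate(order):
        for node in comms[k]:
            assignment[node] = rank
        centroids[labels[rank]] = centroid(comms[k])
        coverage[labels[rank]] = float(cov[k])
    return StateCatalog(
        state_labels=labels,
        assignment=assignment,
        centroids=centroids,
        coverage_ratio=coverage,
    )


def state_centroids(
    catalog: StateCatalog, vectors: np.ndarray, durations: np.ndarray | None = None
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Recompute per-state mean vectors and time-coverage ratios."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.shape[0] != catalog.assignment.size:
        raise ValidationError("assignment does not cover the vector collection")
    if durations is None:
        durations = np.ones(vectors.shape[0])
    total = durations.sum()
    cents, cov = {}, {}
    for k, label in enumerate(catalog.state_labels):
        members = catalog.assignment == k
        if not members.any():
            warnings.warn(f"state {label} is empty; excluded", stacklevel=2)
            continue
        cents[label] = vectors[members].mean(axis=0)
        cov[label] = float(durations[members].sum() / total)
    return cents, cov


def cross_band_state_correlation(
    centroids: dict[tuple[str, str], np.ndarray],
) -> "pd.DataFrame":
    """Pearson correlations between state centroids across bands and states.

    ``centroids`` maps (band, state) to a centroid vector; the result is a
    symmetric DataFrame indexed by those pairs, with rows of constant
    centroids marked NaN.
    """
    import pandas as pd

    keys = list(centroids)
    mat = np.array([centroids[k] for k in keys], dtype=np.float64)
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat)
    r = np.asarray(r, dtype=np.float64)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))
    idx = pd.MultiIndex.from_tuples(keys, names=["band", "state"])
    return pd.DataFrame(r, index=idx, columns=idx)
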