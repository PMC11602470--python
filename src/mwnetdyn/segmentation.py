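"""Network-structure-driven segmentation of a band-limited recording (EDMCC).

The recording is scanned with a trailing reference window and an advancing
candidate window of equal length W_r. For each candidate position the
multiplex networks of the two windows are built and the Euclidean distance
between their layer-averaged closeness-centrality profiles is computed
(``edmcc_distance``). A Gaussian kernel density estimate is maintained over
the trailing collection of distances; when the current distance exceeds the
p_KDE upper quantile of that density, a boundary is declared at the candidate
start and the reference window resets there. Segments respect minimum and
maximum lengths and never span artifact-masked samples.

``p_diff`` scores a segmentation by the fraction of adjacent segment pairs
whose between-segment structure distance strictly exceeds both segments'
within-segment (first half vs second half) distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .centrality import CentralityMatrix, centrality_matrix
from .connectivity import build_multiplex
from .preprocess import BandedRecording, ValidationError

__all__ = [
    "SegmentationConfig",
    "Segmentation",
    "edmcc_distance",
    "segment",
    "sliding_window_segment",
    "p_diff",
]


@dataclass
class SegmentationConfig:
    reference_window_s: float = 2.0
    p_kde: float = 0.96
    step_s: float = 0.25
    min_segment_s: float = 0.5
    max_segment_s: float = 10.0
    min_history: int = 30  # distances observed before outlier calls start
    min_persist_s: float = 1.0  # outlier excursion length required for a boundary

    def __post_init__(self) -> None:
        if not 0 < self.p_kde < 1:
            raise ValidationError("p_kde must lie in (0, 1)")
        if not self.min_segment_s <= self.reference_window_s <= self.max_segment_s:
            raise ValidationError("require min_segment <= reference window <= max_segment")
        if self.step_s <= 0:
            raise ValidationError("step_s must be positive")


@dataclass
class Segmentation:
    """Half-open segments [start, end) in sample indices, plus second spans."""

    boundaries: list[tuple[int, int]]
    sampling_rate: float

    @property
    def spans(self) -> list[tuple[float, float]]:
        r = self.sampling_rate
        return [(b0 / r, b1 / r) for b0, b1 in self.boundaries]

    @property
    def n_segments(self) -> int:
        return len(self.boundaries)


def edmcc_distance(c1: CentralityMatrix, c2: CentralityMatrix) -> float:
    """Euclidean distance between layer-averaged centrality profiles."""
    if c1.values.shape != c2.values.shape:
        raise ValidationError("centrality matrices must share shape")
    diff = c1.values.mean(axis=1) - c2.values.mean(axis=1)
    return float(np.sqrt(np.sum(diff**2)))


def _kde_quantile(samples: np.ndarray, p: float) -> float:
    """Upper ``p`` quantile of a Gaussian KDE with Scott's-rule bandwidth."""
    x = np.asarray(samples, dtype=np.float64)
    sd = x.std()
    if sd == 0:
        return float(x[0])
    h = sd * x.size ** (-1 / 5)

    def cdf(t: float) -> float:
        return float(ndtr((t - x) / h).mean())

    lo, hi = x.min() - 6 * h, x.max() + 6 * h
    return float(brentq(lambda t: cdf(t) - p, lo, hi, xtol=1e-10))


def _valid_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of the validity mask as half-open index pairs."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def _window_centrality(data: np.ndarray, i0: int, i1: int, rate: float) -> CentralityMatrix:
    net = build_multiplex(data[:, i0:i1], span=(i0 / rate, i1 / rate))
    return centrality_matrix(net)


def segment(rec: BandedRecording, cfg: SegmentationConfig | None = None) -> Segmentation:
    """EDMCC segmentation of all valid stretches of a recording.

    At each candidate position the trailing reference window (the W_r of data
    just before it) is compared with the advancing candidate window (the W_r
    just after). A position is an outlier when its distance exceeds the p_KDE
    quantile of the kernel density fitted to previously observed distances; a
    boundary is declared at the distance peak of every outlier excursion that
    persists for at least ``min_persist_s`` (a genuine structure change keeps
    the two windows mismatched for about W_r, while isolated noise outliers do
    not persist). Segments longer than ``max_segment_s`` are force-split.
    """
    cfg = cfg or SegmentationConfig()
    rate = rec.sampling_rate
    w = int(round(cfg.reference_window_s * rate))
    step = max(1, int(round(cfg.step_s * rate)))
    min_len = int(round(cfg.min_segment_s * rate))
    max_len = int(round(cfg.max_segment_s * rate))
    persist = max(1, int(round(cfg.min_persist_s / cfg.step_s)))
    runs = _valid_runs(rec.valid_mask)
    if sum(max(0, e - s) for s, e in runs) < 2 * w:
        raise ValidationError("recording too short: need >= 2 reference windows of valid data")

    boundaries: list[tuple[int, int]] = []
    history: list[float] = []
    for run_start, run_end in runs:
        if run_end - run_start < 2 * w:
            continue  # stretch too short to compare two windows
        cache: dict[tuple[int, int], CentralityMatrix] = {}

        def cent(i0: int, i1: int) -> CentralityMatrix:
            key = (i0, i1)
            if key not in cache:
                cache[key] = _window_centrality(rec.data, i0, i1, rate)
            return cache[key]

        cands = list(range(run_start + w, run_end - w + 1, step))
        dist = np.empty(len(cands))
        flags = np.zeros(len(cands), dtype=bool)
        for i, c in enumerate(cands):
            dist[i] = edmcc_distance(cent(c - w, c), cent(c, c + w))
            if len(history) >= cfg.min_history:
                flags[i] = dist[i] > _kde_quantile(np.asarray(history), cfg.p_kde)
            history.append(float(dist[i]))

        # boundaries at the peaks of persistent outlier excursions
        bnds: list[int] = []
        i = 0
        while i < len(cands):
            if flags[i]:
                j = i
                while j < len(cands) and flags[j]:
                    j += 1
                if j - i >= persist:
                    c = cands[i + int(np.argmax(dist[i:j]))]
                    prev = bnds[-1] if bnds else run_start
                    if c - prev >= min_len and run_end - c >= min_len:
                        bnds.append(c)
                i = j
            else:
                i += 1

        # assemble segments, force-splitting any stretch beyond max_segment_s
        edges = [run_start] + bnds + [run_end]
        for b0, b1 in zip(edges, edges[1:]):
            s = b0
            while b1 - s > max_len:
                # avoid leaving a sub-minimum tail after the forced split
                if b1 - (s + max_len) < min_len:
                    break
                boundaries.append((s, s + max_len))
                s += max_len
            if b1 - s > 0:
                boundaries.append((s, b1))
    return Segmentation(boundaries=boundaries, sampling_rate=rate)


def sliding_window_segment(rec: BandedRecording, length_s: float = 2.0) -> Segmentation:
    """Uniform non-overlapping windows over valid data; remainders dropped."""
    if length_s <= 0:
        raise ValidationError("window length must be positive")
    win = int(round(length_s * rec.sampling_rate))
    boundaries = []
    for run_start, run_end in _valid_runs(rec.valid_mask):
        n_win = (run_end - run_start) // win
        for k in range(n_win):
            boundaries.append((run_start + k * win, run_start + (k + 1) * win))
    if not boundaries:
        warnings.warn("recording shorter than one window; empty segmentation", stacklevel=2)
    return Segmentation(boundaries=boundaries, sampling_rate=rec.sampling_rate)


def p_diff(rec: BandedRecording, seg: Segmentation) -> float:
    """Between- vs within-segment structure contrast in [0, 1].

    For every adjacent segment pair, compare the distance between the two
    whole-segment networks against each segment's first-half/second-half
    distance; return the fraction of pairs where the between distance strictly
    dominates both. NaN when fewer than two segments.
    """
    if seg.n_segments < 2:
        warnings.warn("p_diff undefined for < 2 segments", stacklevel=2)
        return float("nan")
    rate = rec.sampling_rate
    whole = []
    within = []
    for b0, b1 in seg.boundaries:
        whole.append(_window_centrality(rec.data, b0, b1, rate))
        mid = (b0 + b1) // 2
        d_w = edmcc_distance(
            _window_centrality(rec.data, b0, mid, rate),
            _window_centrality(rec.data, mid, b1, rate),
        )
        within.append(d_w)
    wins = 0
    pairs = 0
    for i in range(seg.n_segments - 1):
        # only compare truly adjacent segments (no artifact gap between them)
        if seg.boundaries[i][1] != seg.boundaries[i + 1][0]:
            continue
        between = edmcc_distance(whole[i], whole[i + 1])
        pairs += 1
        if between > within[i] and between > within[i + 1]:
            wins += 1
    if pairs == 0:
        return float("nan")
    return wins / pairs
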