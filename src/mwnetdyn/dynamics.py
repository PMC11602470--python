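"""State-sequence dynamics: run metrics, transition structure, randomness test.

Adjacent segments sharing a state are consolidated into runs, so
self-transitions are impossible by construction. Observed transition
probabilities are joint frequencies over all ordered state pairs; the
frequencies-only expectation under the no-memory null is

    P*_{X->Y} = P_Y * P_X / (1 - P_X),

whose off-diagonal grand total is 1 (an identity verified in tests). The
chi-square distance between observed and expected matrices is tested against
a permutation null that pools the two matrices' off-diagonal cells and
randomly reassigns them; p-values use the tie-inclusive (m+1)/(n+1) form so
that observed == expected yields p = 1 rather than 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import ValidationError

__all__ = [
    "StateSequence",
    "TransitionStats",
    "build_state_sequence",
    "sequence_metrics",
    "observed_transitions",
    "expected_transitions",
    "chi_square_distance",
    "transition_randomness_test",
]


@dataclass
class StateSequence:
    """Run-length-encoded state labels for one trial and band."""

    participant_id: str
    trial_label: str
    band: str
    runs: list[tuple[str, float]]  # (state label, duration s)
    n_gaps: int = 0  # artifact gaps that break runs without transitions
    run_breaks: list[bool] = field(default_factory=list)  # run preceded by a gap?

    def __post_init__(self) -> None:
        for _, d in self.runs:
            if d <= 0:
                raise ValidationError("run durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.runs))

    @property
    def labels(self) -> list[str]:
        return [s for s, _ in self.runs]


def build_state_sequence(
    assignment: list[tuple[float, float, str]],
    *,
    participant_id: str = "unknown",
    trial_label: str = "unknown",
    band: str = "unknown",
    gap_tol: float = 1e-9,
) -> StateSequence:
    """Consolidate per-segment (start, end, state) triples into runs.

    Adjacent same-state segments merge; a time gap (masked stretch) between
    segments breaks the run without creating a transition across it.
    """
    segs = sorted(assignment, key=lambda x: x[0])
    for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
        if s1 < e0 - gap_tol:
            raise ValidationError("overlapping segments")
    runs: list[tuple[str, float]] = []
    run_breaks: list[bool] = []  # True if preceded by a gap
    n_gaps = 0
    for i, (s, e, st) in enumerate(segs):
        gap = i > 0 and s > segs[i - 1][1] + gap_tol
        if gap:
            n_gaps += 1
        if runs and not gap and runs[-1][0] == st:
            runs[-1] = (st, runs[-1][1] + (e - s))
        else:
            runs.append((st, e - s))
            run_breaks.append(gap)
    return StateSequence(
        participant_id=participant_id,
        trial_label=trial_label,
        band=band,
        runs=runs,
        n_gaps=n_gaps,
        run_breaks=run_breaks,
    )


def _transition_pairs(seq: StateSequence) -> list[tuple[str, str]]:
    breaks = seq.run_breaks if seq.run_breaks else [False] * len(seq.runs)
    pairs = []
    for i in range(1, len(seq.runs)):
        if breaks[i]:
            continue
        pairs.append((seq.runs[i - 1][0], seq.runs[i][0]))
    return pairs


def sequence_metrics(
    seq: StateSequence, states: list[str] | None = None
) -> dict[str, dict[str, float]]:
    """Frequency (/s), mean run duration (s) and coverage per state."""
    total = seq.total_duration
    if total <= 0:
        raise ValidationError("total duration must be positive")
    if states is None:
        states = sorted({s for s, _ in seq.runs})
    out = {}
    for st in states:
        durs = [d for s, d in seq.runs if s == st]
        out[st] = {
            "frequency": len(durs) / total,
            "mean_duration": float(np.mean(durs)) if durs else float("nan"),
            "coverage": float(sum(durs) / total),
        }
    return out


def _resolve_states(
    seqs: list[StateSequence], states: list[str] | None
) -> list[str]:
    if states is None:
        states = sorted({s for q in seqs for s, _ in q.runs})
    return states


def observed_transitions(
    seq: StateSequence | list[StateSequence], states: list[str] | None = None
) -> np.ndarray:
    """Joint transition probabilities P_{X->Y}; zero diagonal; sums to 1."""
    seqs = [seq] if isinstance(seq, StateSequence) else list(seq)
    states = _resolve_states(seqs, states)
    idx = {s: i for i, s in enumerate(states)}
    k = len(states)
    counts = np.zeros((k, k))
    for q in seqs:
        for a, b in _transition_pairs(q):
            counts[idx[a], idx[b]] += 1
    total = counts.sum()
    if total == 0:
        warnings.warn("no transitions observed", stacklevel=2)
        return np.full((k, k), np.nan)
    return counts / total


def expected_transitions(
    seq: StateSequence | list[StateSequence], states: list[str] | None = None
) -> np.ndarray:
    """Frequencies-only expectation P*_{X->Y} = P_Y P_X / (1 - P_X)."""
    seqs = [seq] if isinstance(seq, StateSequence) else list(seq)
    states = _resolve_states(seqs, states)
    idx = {s: i for i, s in enumerate(states)}
    k = len(states)
    occ = np.zeros(k)
    for q in seqs:
        for s, _ in q.runs:
            occ[idx[s]] += 1
    p = occ / occ.sum()
    if np.any(p >= 1.0):
        warnings.warn("single-state sequence; expectation undefined", stacklevel=2)
        return np.full((k, k), np.nan)
    exp = np.outer(p / (1.0 - p), p)
    np.fill_diagonal(exp, 0.0)
    return exp


def chi_square_distance(observed: np.ndarray, expected: np.ndarray) -> float:
    """d = sum over off-diagonal cells of (P - P*)^2 / P*."""
    o = np.asarray(observed, dtype=np.float64)
    e = np.asarray(expected, dtype=np.float64)
    if o.shape != e.shape:
        raise ValidationError("shape mismatch")
    off = ~np.eye(o.shape[0], dtype=bool)
    ov, ev = o[off], e[off]
    bad = (ev == 0) & (ov > 0)
    if bad.any():
        raise ValidationError("expected cell is 0 where observed > 0")
    keep = ev > 0
    return float(np.sum((ov[keep] - ev[keep]) ** 2 / ev[keep]))


@dataclass
class TransitionStats:
    observed: np.ndarray
    expected: np.ndarray
    chi_square_d: float
    p_value: float
    n_permutations: int
    states: list[str] = field(default_factory=list)


def transition_randomness_test(
    observed_avg: np.ndarray,
    expected_avg: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    states: list[str] | None = None,
) -> TransitionStats:
    """Permutation test of transition structure beyond state frequencies.

    Pools the off-diagonal cells of the observed and expected matrices,
    randomly reassigns them into two pseudo-matrices of the original shapes,
    and recomputes the chi-square distance; cells whose pseudo-expected value
    is 0 contribute nothing. p = (m + 1) / (n_perm + 1) with m the count of
    permuted distances >= the actual one (tie-inclusive).
    """
    if n_perm < 100:
        raise ValidationError("need at least 100 permutations")
    o = np.asarray(observed_avg, dtype=np.float64)
    e = np.asarray(expected_avg, dtype=np.float64)
    k = o.shape[0]
    off = ~np.eye(k, dtype=bool)
    d0 = chi_square_distance(o, e)
    pool = np.concatenate([o[off], e[off]])
    rng = np.random.default_rng(seed)
    if np.allclose(pool, pool[0]):
        warnings.warn("degenerate pooled cell values; p = 1", stacklevel=2)
        return TransitionStats(o, e, d0, 1.0, n_perm, states or [])
    perm = rng.permuted(np.tile(pool, (n_perm, 1)), axis=1)
    half = pool.size // 2
    po, pe = perm[:, :half], perm[:, half:]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (po - pe) ** 2 / pe
    terms[pe == 0] = 0.0
    d_perm = terms.sum(axis=1)
    m = int(np.sum(d_perm >= d0))
    p = (m + 1) / (n_perm + 1)
    return TransitionStats(o, e, d0, float(p), n_perm, states or [])
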