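"""Synthetic band-limited EEG with planted coupling motifs.

Each planted network state is a pair of edge sets. Every connected component
of an edge set shares ONE source, so coupling strength is independent of
motif size: amplitude-coupled channels receive a common envelope-modulated
narrowband source at zero lag (loads on the AEC layer, invisible to IPLV),
and phase-coupled channels receive copies of a shared source rotated by
incremental analytic phase lags (default pi/4, keeping the imaginary part of
the phase-locking phasor large — and, since a phase rotation preserves the
envelope, a phase module synchronizes envelopes too). A trial switches
between states according to a condition-specific Markov chain with
exponential dwell times; all remaining signal is independent noise.
Everything is rendered as white noise and then passed through the same
windowed-Hamming FIR band-pass as the analysis pipeline, so generator and
analyzer agree spectrally.

Coupling strength ``amp_strength`` is the mixing weight: a channel carrying a
source is ``sqrt(1-a^2) * noise + a * sqrt(snr) * source`` with unit-variance
components, so at ``a=0`` every channel is pure independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.signal import hilbert

from .preprocess import BANDS, DEFAULT_CHANNELS, BandedRecording, Recording, ValidationError, bandpass_filter

__all__ = [
    "PlantedState",
    "ConditionSpec",
    "GroundTruth",
    "make_state_library",
    "simulate_trial",
    "simulate_participant",
    "benchmark_condition_specs",
]


@dataclass(frozen=True)
class PlantedState:
    """A recurring coupling motif: which pairs co-vary in amplitude or phase."""

    state_id: str
    amp_edges: tuple[tuple[int, int], ...]
    phase_edges: tuple[tuple[int, int], ...]
    amp_strength: float = 0.9
    phase_lag: float = np.pi / 4

    def __post_init__(self) -> None:
        for a, b in (*self.amp_edges, *self.phase_edges):
            if a == b:
                raise ValidationError("self-pairs are not allowed in edge sets")
        if not 0.0 <= self.amp_strength <= 1.0:
            raise ValidationError("amp_strength must lie in [0, 1]")
        if not 0.0 < self.phase_lag < np.pi:
            raise ValidationError("phase_lag must lie in (0, pi)")


@dataclass
class ConditionSpec:
    """Markov switching dynamics of one experimental condition."""

    condition: str  # "FL" or "MW"
    state_transition_matrix: np.ndarray
    dwell_mean: float = 2.0
    snr: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.state_transition_matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("transition matrix must be square")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("transition matrix rows must sum to 1")
        if self.dwell_mean <= 0:
            raise ValidationError("dwell_mean must be positive")
        self.state_transition_matrix = m


@dataclass
class GroundTruth:
    """Hidden state path and change points of one simulated trial."""

    change_points: np.ndarray  # interior switch times, seconds
    path: list[tuple[float, float, str]]  # (onset s, offset s, state_id)

    def state_at(self, t: float) -> str:
        for onset, offset, sid in self.path:
            if onset <= t < offset:
                return sid
        return self.path[-1][2]


def _tagged_edges(state: PlantedState) -> set:
    return {("a", e) for e in state.amp_edges} | {("p", e) for e in state.phase_edges}


def _jaccard(s1: set, s2: set) -> float:
    u = len(s1 | s2)
    return len(s1 & s2) / u if u else 1.0


def make_state_library(
    n_states: int,
    n_channels: int,
    seed: int,
    amp_strength: float = 0.9,
    phase_lag: float = np.pi / 4,
) -> list[PlantedState]:
    """Draw ``n_states`` motifs with mutually distinct edge sets.

    States are redrawn until every pair of states differs both in its tagged
    edge set and in the channels its phase module recruits (Jaccard overlap
    < 0.5 for each), so no two states elevate the same centrality profile.
    """
    if n_states < 2 or n_channels < 3:
        raise ValidationError("need n_states >= 2 and n_channels >= 3")
    pairs = list(combinations(range(n_channels), 2))
    # Each state plants one phase-coupled module (a clique whose channels share
    # a single source under incremental phase lags, so it loads on both the
    # envelope and the phase layer) plus one amplitude-only pair on channels
    # outside the module. A single source per module keeps pairwise coupling
    # undiluted regardless of module size.
    module = min(4, n_channels // 2)
    rng = np.random.default_rng(seed)
    states: list[PlantedState] = []
    modules: list[set[int]] = []
    labels = [chr(ord("A") + i) for i in range(n_states)]
    for label in labels:
        for attempt in range(4000):
            if n_channels >= 6:
                if len(states) == 1 and n_channels >= 2 * module:
                    # the second module avoids the first one's channels
                    # entirely, guaranteeing one fully disjoint state pair
                    free = [c for c in range(n_channels) if c not in modules[0]]
                    free = [int(c) for c in rng.permutation(free)]
                    rest = [int(c) for c in rng.permutation(sorted(modules[0]))]
                    chans = free + rest
                else:
                    chans = [int(c) for c in rng.permutation(n_channels)]
                mod = sorted(chans[:module])
                amp = (tuple(sorted(chans[module : module + 2])),)
                phase = tuple(combinations(mod, 2))
            else:  # too few channels for a disjoint module; fall back to pairs
                idx = rng.choice(len(pairs), size=2, replace=False)
                amp = (pairs[idx[0]],)
                phase = (pairs[idx[1]],)
                mod = sorted(set(pairs[idx[1]]))
            cand = PlantedState(
                state_id=label,
                amp_edges=amp,
                phase_edges=phase,
                amp_strength=amp_strength,
                phase_lag=phase_lag,
            )
            tags = _tagged_edges(cand)
            distinct = all(_jaccard(tags, _tagged_edges(s)) < 0.5 for s in states)
            # modules must also differ in the channels they recruit, otherwise
            # two states would elevate nearly the same centrality profile
            distinct = distinct and all(
                _jaccard(set(mod), m2) < 0.5 for m2 in modules
            )
            if distinct:
                states.append(cand)
                modules.append(set(mod))
                break
        else:
            raise ValidationError(
                f"cannot draw {n_states} distinct states over {n_channels} channels"
            )
    return states


def draw_state_path(
    library: list[PlantedState],
    spec: ConditionSpec,
    duration: float,
    rng: np.random.Generator,
) -> list[tuple[float, float, int]]:
    """Sample a dwell path (onset, offset, state index) covering ``duration``."""
    n = len(library)
    if spec.state_transition_matrix.shape[0] != n:
        raise ValidationError("transition matrix size must match library size")
    cur = int(rng.integers(n))
    t = 0.0
    path = []
    while t < duration:
        dwell = float(rng.exponential(spec.dwell_mean))
        dwell = max(dwell, 0.1)  # avoid zero-length dwells
        end = min(t + dwell, duration)
        path.append((t, end, cur))
        t = end
        row = spec.state_transition_matrix[cur].copy()
        row[cur] = 0.0  # a switch must change state
        if row.sum() == 0:
            row = np.ones(n)
            row[cur] = 0.0
        row /= row.sum()
        cur = int(rng.choice(n, p=row))
    return path


def _components(edges: tuple[tuple[int, int], ...]) -> list[list[int]]:
    """Connected components of an edge set, each sorted by channel index."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    comps: dict[int, list[int]] = {}
    for node in parent:
        comps.setdefault(find(node), []).append(node)
    return [sorted(c) for c in comps.values()]


def _smooth_envelope(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Slowly varying positive amplitude envelope, mean ~1."""
    win = max(int(rate / 2), 2)
    g = np.convolve(rng.standard_normal(n + win), np.ones(win) / win, mode="valid")[:n]
    sd = g.std()
    if sd > 0:
        g = g / sd
    # shallow modulation: deep dips would make window-level envelope
    # correlations collapse during low-amplitude stretches
    return 1.0 + 0.3 * np.tanh(g)


def _phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    """Rotate the analytic phase of ``x`` by ``lag`` radians (all-pass)."""
    return np.real(hilbert(x) * np.exp(-1j * lag))


def simulate_trial(
    library: list[PlantedState],
    spec: ConditionSpec,
    duration: float,
    band: str,
    rate: float,
    seed: int,
    *,
    n_channels: int = 8,
    participant_id: str = "sim",
    trial_label: str | None = None,
    forced_path: list[tuple[float, float, int]] | None = None,
) -> tuple[BandedRecording, GroundTruth]:
    """Render one band-limited trial with Markov-switching planted coupling."""
    if duration < 10:
        raise ValidationError("duration must be at least 10 s")
    if band not in BANDS:
        raise ValidationError(f"unknown band {band!r}")
    import warnings as _w

    if duration < 2 * spec.dwell_mean:
        _w.warn("duration < 2 dwell means: too few switches for dynamics tests", stacklevel=2)
    rng = np.random.default_rng(seed)
    path = forced_path if forced_path is not None else draw_state_path(library, spec, duration, rng)
    n = int(round(duration * rate))
    noise = rng.standard_normal((n_channels, n))
    coupled = np.zeros((n_channels, n))
    counts = np.zeros((n_channels, n))

    for onset, offset, sidx in path:
        st = library[sidx]
        i0, i1 = int(round(onset * rate)), int(round(offset * rate))
        L = i1 - i0
        if L < 4:
            continue
        # one source per connected coupling module: every edge's two channels
        # share a common source, and modules larger than a pair stay undiluted
        for comp in _components(st.amp_edges):
            src = _smooth_envelope(L, rate, rng) * rng.standard_normal(L)
            sd = src.std()
            if sd > 0:
                src = src / sd
            for ch in comp:
                coupled[ch, i0:i1] += src
                counts[ch, i0:i1] += 1
        for comp in _components(st.phase_edges):
            src = rng.standard_normal(L)
            for pos, ch in enumerate(comp):
                coupled[ch, i0:i1] += src if pos == 0 else _phase_shift(src, pos * st.phase_lag)
                counts[ch, i0:i1] += 1

    # unit-variance coupled component per channel where present
    scale = np.sqrt(np.maximum(counts, 1))
    coupled = coupled / scale
    amp = library[0].amp_strength if library else 0.0
    data = np.sqrt(max(0.0, 1.0 - amp**2)) * noise + amp * np.sqrt(spec.snr) * coupled
    data *= 20.0  # scale to tens of microvolts

    names = list(DEFAULT_CHANNELS) if n_channels == 8 else [f"ch{i}" for i in range(n_channels)]
    rec = Recording(
        participant_id=participant_id,
        trial_label=trial_label or f"{spec.condition}-1",
        sampling_rate=rate,
        channel_names=names,
        data=data,
    )
    banded = bandpass_filter(rec, band)
    cps = np.array([offset for _, offset, _ in path[:-1]])
    gt = GroundTruth(
        change_points=cps,
        path=[(on, off, library[s].state_id) for on, off, s in path],
    )
    return banded, gt


def simulate_participant(
    library: list[PlantedState],
    fl_spec: ConditionSpec,
    mw_spec: ConditionSpec,
    n_trials_per_condition: int,
    duration: float,
    seed: int,
    *,
    bands: tuple[str, ...] = ("alpha",),
    rate: float = 256.0,
    n_channels: int = 8,
    participant_id: str = "sim",
) -> list[dict]:
    """Simulate FL-k / MW-k trials; one state path per trial, rendered per band.

    Returns one dict per trial with keys ``trial_label``, ``condition``,
    ``ground_truth`` and ``recordings`` (band -> BandedRecording). All
    per-trial seeds derive deterministically from the master seed.
    """
    if n_trials_per_condition < 1:
        raise ValidationError("need at least one trial per condition")
    ss = np.random.SeedSequence(seed)
    trials = []
    specs = [("FL", fl_spec), ("MW", mw_spec)]
    children = ss.spawn(2 * n_trials_per_condition * (1 + len(bands)))
    ci = 0
    for cond, spec in specs:
        for k in range(1, n_trials_per_condition + 1):
            path_rng = np.random.default_rng(children[ci]); ci += 1
            path = draw_state_path(library, spec, duration, path_rng)
            recs = {}
            gt = None
            for band in bands:
                band_seed = int(children[ci].generate_state(1)[0] % (2**31)); ci += 1
                rec, gt = simulate_trial(
                    library, spec, duration, band, rate, band_seed,
                    n_channels=n_channels, participant_id=participant_id,
                    trial_label=f"{cond}-{k}", forced_path=path,
                )
                recs[band] = rec
            trials.append(
                {
                    "trial_label": f"{cond}-{k}",
                    "condition": cond,
                    "recordings": recs,
                    "ground_truth": gt,
                }
            )
    return trials


def benchmark_condition_specs(dwell_mean: float = 2.0, snr: float = 1.0) -> tuple[ConditionSpec, ConditionSpec]:
    """Four-state FL/MW benchmark: same states, different switching structure.

    Focused learning favors A<->B exchanges; mind wandering favors C<->D,
    mirroring a condition contrast carried purely by transition dynamics.
    """
    fl = np.array(
        [
            [0.0, 0.8, 0.1, 0.1],
            [0.8, 0.0, 0.1, 0.1],
            [0.4, 0.4, 0.0, 0.2],
            [0.4, 0.4, 0.2, 0.0],
        ]
    )
    mw = np.array(
        [
            [0.0, 0.2, 0.4, 0.4],
            [0.2, 0.0, 0.4, 0.4],
            [0.1, 0.1, 0.0, 0.8],
            [0.1, 0.1, 0.8, 0.0],
        ]
    )
    return (
        ConditionSpec("FL", fl, dwell_mean=dwell_mean, snr=snr),
        ConditionSpec("MW", mw, dwell_mean=dwell_mean, snr=snr),
    )
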