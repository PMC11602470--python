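"""Synthetic benchmark studies exercising the full pipeline.

These are the package's standard evaluation experiments: change-point
recovery and segmentation quality, recurring-state recovery, transition-test
calibration and power, HMM parameter recovery, and end-to-end within-
participant condition discrimination. Problem sizes are chosen so each study
runs in minutes on one core while leaving comfortable statistical margins.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from . import (
    build_multiplex,
    build_similarity_graph,
    build_state_sequence,
    centrality_matrix,
    crossvalidate_participant,
    detect_states,
    fit_hmm,
    make_state_library,
    normalize_centralities,
    segment,
    simulate_participant,
    simulate_trial,
    sliding_window_segment,
)
from .dynamics import (
    StateSequence,
    expected_transitions,
    observed_transitions,
    transition_randomness_test,
)
from .segmentation import SegmentationConfig, p_diff
from .synthetic import ConditionSpec, benchmark_condition_specs

BENCH_BAND = "gamma"  # widest band: most envelope/phase samples per window
BENCH_RATE = 256.0


# ---------------------------------------------------------------- segmentation

def _most_distinct_pair(library) -> tuple[int, int]:
    """Indices of the two states with the least shared coupling structure."""
    def tags(s):
        return {("a", e) for e in s.amp_edges} | {("p", e) for e in s.phase_edges}

    def chans(s):
        return {c for e in (*s.amp_edges, *s.phase_edges) for c in e}

    best, best_ov = (0, 1), np.inf
    for i in range(len(library)):
        for j in range(i + 1, len(library)):
            ov = len(tags(library[i]) & tags(library[j])) + len(
                chans(library[i]) & chans(library[j])
            )
            if ov < best_ov:
                best, best_ov = (i, j), ov
    return best


def segmentation_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Single planted switch at 30 s in 60 s trials: recovery and p_diff.

    The switch is planted between the library's two most distinct motifs (a
    boundary-detection benchmark needs a genuine structure change). Returns
    the fraction of seeds with a detected boundary within +-1 s of the
    switch, the stationary-trial segment counts, and mean p_diff for the
    EDMCC and 2 s sliding-window segmentations of the switching trials.
    """
    lib = make_state_library(4, 8, seed + 1)
    fl, _ = benchmark_condition_specs()
    i, j = _most_distinct_pair(lib)
    hits = 0
    null_counts = []
    pd_edmcc, pd_slide = [], []
    for s in range(n_seeds):
        rec, _ = simulate_trial(
            lib, fl, 60, BENCH_BAND, BENCH_RATE, seed + 100 + s,
            forced_path=[(0.0, 30.0, i), (30.0, 60.0, j)],
        )
        sg = segment(rec)
        interior = [t for t, _ in sg.spans][1:]
        hits += any(abs(b - 30.0) <= 1.0 for b in interior)
        pd_edmcc.append(p_diff(rec, sg))
        pd_slide.append(p_diff(rec, sliding_window_segment(rec, 2.0)))
        null_rec, _ = simulate_trial(
            lib, fl, 60, BENCH_BAND, BENCH_RATE, seed + 200 + s,
            forced_path=[(0.0, 60.0, 0)],
        )
        null_counts.append(segment(null_rec).n_segments)
    return {
        "recovery_rate": hits / n_seeds,
        "null_segment_counts": null_counts,
        "p_diff_edmcc": float(np.nanmean(pd_edmcc)),
        "p_diff_sliding": float(np.nanmean(pd_slide)),
    }


def oracle_segmentation_p_diff(n_seeds: int = 20, seed: int = 0) -> float:
    """Mean p_diff when segmenting exactly at the planted state switches."""
    from .segmentation import Segmentation

    lib = make_state_library(4, 8, seed + 1)
    fl, _ = benchmark_condition_specs()
    vals = []
    for s in range(n_seeds):
        rec, gt = simulate_trial(lib, fl, 60, BENCH_BAND, BENCH_RATE, seed + 300 + s)
        cuts = [0] + [
            int(t * BENCH_RATE) for t in gt.change_points if 0.5 <= t <= 59.5
        ] + [rec.n_samples]
        seg = Segmentation(
            boundaries=[(a, b) for a, b in zip(cuts, cuts[1:]) if b - a >= 128],
            sampling_rate=BENCH_RATE,
        )
        vals.append(p_diff(rec, seg))
    return float(np.nanmean(vals))


# ---------------------------------------------------------------- state recovery

def draw_distinct_profiles(
    rng: np.random.Generator, n: int = 4, dim: int = 8, max_abs_spearman: float = 0.4
) -> np.ndarray:
    """Mutually dissimilar centrality profiles, as distinct network states have."""
    profiles: list[np.ndarray] = []
    while len(profiles) < n:
        p = rng.uniform(0, 1, dim)
        if all(abs(spearmanr(p, q).statistic) < max_abs_spearman for q in profiles):
            profiles.append(p)
    return np.array(profiles)


def state_recovery(n_seeds: int = 10, seed: int = 0, sigma: float = 0.1) -> dict:
    """Louvain recovery of 4 planted centrality profiles under additive noise."""
    from sklearn.metrics import adjusted_rand_score

    aris, n_states = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        profiles = draw_distinct_profiles(rng)
        truth = rng.integers(0, 4, 200)
        vecs = profiles[truth] + rng.normal(0, sigma, (200, 8))
        graph = build_similarity_graph(vecs)
        catalog = detect_states(graph, seed=seed + s)
        aris.append(adjusted_rand_score(truth, catalog.assignment))
        n_states.append(catalog.n_states)
    return {
        "mean_ari": float(np.mean(aris)),
        "n_states": n_states,
        "frac_exactly_4": float(np.mean([k == 4 for k in n_states])),
    }


# ---------------------------------------------------------------- transition test

def _null_run_sequence(rng: np.random.Generator, n_runs: int, k: int = 4) -> list[str]:
    """Memoryless consolidated sequence: next state ~ marginal excluding current."""
    labels = [chr(ord("A") + i) for i in range(k)]
    seq = [int(rng.integers(k))]
    for _ in range(n_runs - 1):
        p = np.ones(k) / k
        p[seq[-1]] = 0
        p /= p.sum()
        seq.append(int(rng.choice(k, p=p)))
    return [labels[i] for i in seq]


def _cycle_sequence(rng: np.random.Generator, n_runs: int, k: int = 4) -> list[str]:
    labels = [chr(ord("A") + i) for i in range(k)]
    start = int(rng.integers(k))
    return [labels[(start + i) % k] for i in range(n_runs)]


def _seq_from_labels(labels: list[str]) -> StateSequence:
    return StateSequence("sim", "FL-1", BENCH_BAND, [(s, 1.0) for s in labels])


def transition_test_calibration(
    n_reps: int = 500, n_runs: int = 200, n_perm: int = 999, seed: int = 0
) -> dict:
    """Type-I error and power of the transition randomness permutation test."""
    rng = np.random.default_rng(seed)
    rej_null = 0
    for r in range(n_reps):
        seq = _seq_from_labels(_null_run_sequence(rng, n_runs))
        obs = observed_transitions(seq)
        exp = expected_transitions(seq)
        ts = transition_randomness_test(obs, exp, n_perm=n_perm, seed=seed + 10_000 + r)
        rej_null += ts.p_value < 0.05
    rej_alt = 0
    for r in range(n_reps):
        seq = _seq_from_labels(_cycle_sequence(rng, n_runs))
        obs = observed_transitions(seq)
        exp = expected_transitions(seq)
        ts = transition_randomness_test(obs, exp, n_perm=n_perm, seed=seed + 20_000 + r)
        rej_alt += ts.p_value < 0.05
    return {
        "type_i_error": rej_null / n_reps,
        "power": rej_alt / n_reps,
    }


# ---------------------------------------------------------------- HMM recovery

def hmm_parameter_recovery(n_seeds: int = 10, length: int = 2000, seed: int = 0) -> dict:
    """Recover a known 2-hidden-state, 4-symbol emission matrix from samples."""
    A = np.array([[0.9, 0.1], [0.1, 0.9]])
    B = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7]])
    max_errs, monotone = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        z = [int(rng.integers(2))]
        for _ in range(length - 1):
            z.append(int(rng.choice(2, p=A[z[-1]])))
        obs = np.array([int(rng.choice(4, p=B[h])) for h in z])
        model = fit_hmm(obs, n_hidden=2, seed=seed + s, n_obs=4)
        direct = np.abs(model.B - B).max()
        swapped = np.abs(model.B[::-1] - B).max()
        max_errs.append(min(direct, swapped))
        trace = np.array(model.train_log_likelihood_trace)
        monotone.append(bool(np.all(np.diff(trace) >= -1e-8)))
    return {
        "emission_max_errors": max_errs,
        "frac_recovered": float(np.mean([e <= 0.1 for e in max_errs])),
        "all_traces_monotone": all(monotone),
    }


# ---------------------------------------------------------------- end to end

def analyze_participant_sequences(
    seed: int,
    fl_spec: ConditionSpec,
    mw_spec: ConditionSpec,
    duration: float = 300.0,
    band: str = BENCH_BAND,
    max_segment_s: float = 2.5,
) -> dict:
    """Signals -> segments -> states -> per-trial symbol sequences (one band)."""
    lib = make_state_library(4, 8, seed)
    trials = simulate_participant(
        lib, fl_spec, mw_spec, 2, duration, seed, bands=(band,), rate=BENCH_RATE
    )
    cfg = SegmentationConfig(max_segment_s=max_segment_s)
    vecs, meta = [], []
    for tr in trials:
        rec = tr["recordings"][band]
        sg = segment(rec, cfg)
        for (b0, b1), (t0, t1) in zip(sg.boundaries, sg.spans):
            cm = centrality_matrix(build_multiplex(rec.data[:, b0:b1], (t0, t1)))
            vecs.append(cm.overlapping)
            meta.append((tr["trial_label"], t0, t1))
    normed = normalize_centralities({"sim": np.array(vecs)})["sim"]
    durations = np.array([t1 - t0 for _, t0, t1 in meta])
    catalog = detect_states(build_similarity_graph(normed, durations), seed=seed)
    sym = {s: i for i, s in enumerate(catalog.state_labels)}
    out: dict[str, dict[str, list[np.ndarray]]] = {band: {"FL": [], "MW": []}}
    for tl in sorted({m[0] for m in meta}):
        rows = sorted(
            (meta[i][1], meta[i][2], catalog.state_labels[catalog.assignment[i]])
            for i in range(len(meta))
            if meta[i][0] == tl
        )
        seq = build_state_sequence(rows, trial_label=tl, band=band)
        out[band][tl.split("-")[0]].append(np.array([sym[s] for s, _ in seq.runs]))
    return {"sequences": out, "n_states": catalog.n_states}


def end_to_end_discrimination(
    n_seeds: int = 10, seed: int = 0, null: bool = False, duration: float = 300.0
) -> dict:
    """Within-participant AUC when conditions differ only in switching dynamics."""
    fl, mw = benchmark_condition_specs()
    if null:
        mw = ConditionSpec("MW", fl.state_transition_matrix, dwell_mean=fl.dwell_mean)
    aucs = []
    for s in range(n_seeds):
        bundle = analyze_participant_sequences(seed + s, fl, mw, duration=duration)
        res = crossvalidate_participant(
            bundle["sequences"], k=8, seed=seed + s, windows_per_fold=4
        )
        aucs.append(res.auc_mean)
    return {"aucs": aucs, "mean_auc": float(np.mean(aucs))}
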