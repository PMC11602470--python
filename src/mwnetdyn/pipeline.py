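"""End-to-end pipeline: signals -> networks -> states -> dynamics -> detection.

Drives every stage with a single flat key=value configuration and writes
per-stage delimited tables plus a log of the effective configuration and
seeds. The synthetic mode generates the benchmark conditions (shared planted
states, condition-specific switching); the files mode reads recordings from
disk. All randomness derives from the single ``seed`` key.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import centrality, connectivity, dynamics, group_stats, hmm, segmentation, states, synthetic
from .preprocess import BAND_ORDER, ValidationError, bandpass_filter, load_recording, reject_by_amplitude

__all__ = ["default_config", "load_config", "run_pipeline"]


def default_config() -> dict:
    return {
        "mode": "synthetic",
        "seed": 0,
        "out_dir": "",
        "bands": "alpha",
        "rate": 256.0,
        "n_participants": 2,
        "n_trials_per_condition": 2,
        "duration_s": 120.0,
        "n_states": 4,
        "amp_strength": 0.9,
        "dwell_mean_s": 2.0,
        "snr": 1.0,
        "amplitude_threshold_uv": 100.0,
        "artifact_pad_s": 0.25,
        "reference_window_s": 2.0,
        "p_kde": 0.96,
        "step_s": 0.25,
        "min_segment_s": 0.5,
        "max_segment_s": 10.0,
        "resolution": 1.0,
        "cv_folds": 8,
        "windows_per_fold": 4,
        "n_permutations": 999,
        "classify": True,
        "input_files": "",
    }


def load_config(path: str | Path) -> dict:
    """Parse a flat key=value config file (one pair per line, # comments)."""
    cfg = default_config()
    text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"malformed config line: {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in cfg:
            raise ValidationError(f"unknown config key: {key}")
        ref = cfg[key]
        if isinstance(ref, bool):
            cfg[key] = val.lower() in ("1", "true", "yes")
        elif isinstance(ref, int):
            cfg[key] = int(val)
        elif isinstance(ref, float):
            cfg[key] = float(val)
        else:
            cfg[key] = val
    return cfg


def _validate_config(cfg: dict) -> dict:
    full = default_config()
    missing = [k for k in cfg if k not in full]
    if missing:
        raise ValidationError(f"unknown config keys: {missing}")
    merged = {**full, **cfg}
    if not merged["out_dir"]:
        raise ValidationError("missing config keys: ['out_dir']")
    return merged


def _gather_trials(cfg: dict, bands: list[str]) -> list[dict]:
    """Per-trial dicts with banded recordings, one entry per participant-trial."""
    rng_root = np.random.SeedSequence(int(cfg["seed"]))
    trials = []
    if cfg["mode"] == "synthetic":
        lib_seed = int(rng_root.generate_state(1)[0] % 2**31)
        library = synthetic.make_state_library(
            int(cfg["n_states"]), 8, lib_seed, amp_strength=float(cfg["amp_strength"])
        )
        fl, mw = synthetic.benchmark_condition_specs(
            dwell_mean=float(cfg["dwell_mean_s"]), snr=float(cfg["snr"])
        )
        part_seeds = rng_root.spawn(int(cfg["n_participants"]))
        for p in range(int(cfg["n_participants"])):
            pid = f"P{p + 1:02d}"
            pseed = int(part_seeds[p].generate_state(1)[0] % 2**31)
            for tr in synthetic.simulate_participant(
                library, fl, mw, int(cfg["n_trials_per_condition"]),
                float(cfg["duration_s"]), pseed,
                bands=tuple(bands), rate=float(cfg["rate"]), participant_id=pid,
            ):
                tr["participant_id"] = pid
                trials.append(tr)
    elif cfg["mode"] == "files":
        entries = [e for e in str(cfg["input_files"]).split(";") if e]
        if not entries:
            raise ValidationError("missing config keys: ['input_files']")
        for entry in entries:
            path, pid, label, fmt = entry.split(":")
            rec = load_recording(
                path, fmt, sampling_rate=float(cfg["rate"]),
                participant_id=pid, trial_label=label,
            )
            recs = {band: bandpass_filter(rec, band) for band in bands}
            trials.append(
                {
                    "participant_id": pid,
                    "trial_label": label,
                    "condition": label.split("-")[0],
                    "recordings": recs,
                    "ground_truth": None,
                }
            )
    else:
        raise ValidationError(f"unknown mode {cfg['mode']!r}")
    return trials


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the full analysis; returns the results bundle and writes tables."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else _validate_config(dict(config))
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    bands = [b.strip() for b in str(cfg["bands"]).split(",") if b.strip()]
    bad = [b for b in bands if b not in BAND_ORDER]
    if bad:
        raise ValidationError(f"unknown bands: {bad}")

    seg_cfg = segmentation.SegmentationConfig(
        reference_window_s=float(cfg["reference_window_s"]),
        p_kde=float(cfg["p_kde"]),
        step_s=float(cfg["step_s"]),
        min_segment_s=float(cfg["min_segment_s"]),
        max_segment_s=float(cfg["max_segment_s"]),
    )
    trials = _gather_trials(cfg, bands)

    # segment every trial x band; collect per-segment overlapping centralities
    seg_rows = []
    records = []  # (participant, trial, condition, band, start, end, vector)
    for tr in trials:
        for band in bands:
            rec = reject_by_amplitude(
                tr["recordings"][band],
                threshold=float(cfg["amplitude_threshold_uv"]),
                pad=float(cfg["artifact_pad_s"]),
            )
            seg = segmentation.segment(rec, seg_cfg)
            for (b0, b1), (t0, t1) in zip(seg.boundaries, seg.spans):
                net = connectivity.build_multiplex(
                    rec.data[:, b0:b1], span=(t0, t1), node_labels=rec.channel_names
                )
                cm = centrality.centrality_matrix(net)
                records.append(
                    {
                        "participant_id": tr["participant_id"],
                        "trial_label": tr["trial_label"],
                        "condition": tr["condition"],
                        "band": band,
                        "start_s": t0,
                        "end_s": t1,
                        "vector": cm.overlapping,
                    }
                )
                seg_rows.append(
                    {
                        "participant_id": tr["participant_id"],
                        "trial_label": tr["trial_label"],
                        "band": band,
                        "start_s": t0,
                        "end_s": t1,
                        "heterogeneity": centrality.interlayer_heterogeneity(net),
                    }
                )
    df = pd.DataFrame(records)
    pd.DataFrame(seg_rows).to_csv(out / "segments.csv", index=False)

    # per band: per-participant normalization, similarity graph, Louvain states
    cluster_seed = int(np.random.SeedSequence(int(cfg["seed"]) + 1).generate_state(1)[0] % 2**31)
    assign_rows = []
    centroid_rows = []
    all_centroids: dict[tuple[str, str], np.ndarray] = {}
    sequences: dict[tuple[str, str, str], dynamics.StateSequence] = {}
    for band in bands:
        sub = df[df["band"] == band].reset_index(drop=True)
        by_part = {
            pid: np.vstack(g["vector"].to_numpy())
            for pid, g in sub.groupby("participant_id")
        }
        normed = states.normalize_centralities(by_part)
        pos = {pid: 0 for pid in normed}
        vecs = np.empty((len(sub), len(sub.loc[0, "vector"])))
        for i, row in sub.iterrows():
            pid = row["participant_id"]
            vecs[i] = normed[pid][pos[pid]]
            pos[pid] += 1
        durations = (sub["end_s"] - sub["start_s"]).to_numpy()
        graph = states.build_similarity_graph(vecs, durations)
        catalog = states.detect_states(graph, seed=cluster_seed, resolution=float(cfg["resolution"]))
        sub = sub.assign(state=[catalog.state_labels[k] for k in catalog.assignment])
        for label, cen in catalog.centroids.items():
            all_centroids[(band, label)] = cen
            centroid_rows += [
                {"band": band, "state": label, "node": i, "value": v,
                 "coverage": catalog.coverage_ratio[label]}
                for i, v in enumerate(cen)
            ]
        for (pid, tl), g in sub.groupby(["participant_id", "trial_label"]):
            g = g.sort_values("start_s")
            seq = dynamics.build_state_sequence(
                list(zip(g["start_s"], g["end_s"], g["state"])),
                participant_id=pid, trial_label=tl, band=band,
            )
            sequences[(pid, tl, band)] = seq
        assign_rows.append(sub.drop(columns=["vector"]))
    assign_df = pd.concat(assign_rows, ignore_index=True)
    assign_df.to_csv(out / "state_assignments.csv", index=False)
    pd.DataFrame(centroid_rows).to_csv(out / "state_centroids.csv", index=False)

    seq_rows = []
    for (pid, tl, band), seq in sorted(sequences.items()):
        t = 0.0
        for st, d in seq.runs:
            seq_rows.append(
                {"participant_id": pid, "trial_label": tl, "band": band,
                 "state": st, "onset_s": t, "duration_s": d}
            )
            t += d
    pd.DataFrame(seq_rows).to_csv(out / "state_sequences.csv", index=False)

    # dynamics metrics and per-condition transition randomness tests
    state_labels = sorted({s for q in sequences.values() for s, _ in q.runs})
    metric_rows = []
    for (pid, tl, band), seq in sorted(sequences.items()):
        cond = tl.split("-")[0]
        for st, m in dynamics.sequence_metrics(seq, state_labels).items():
            metric_rows.append(
                {"participant_id": pid, "trial_label": tl, "condition": cond,
                 "band": band, "state": st, **m}
            )
    metrics_df = pd.DataFrame(metric_rows)
    metrics_df.to_csv(out / "dynamics_metrics.csv", index=False)

    test_rows = []
    for band in bands:
        for cond in ("FL", "MW"):
            cond_seqs = [
                q for (pid, tl, b), q in sequences.items()
                if b == band and tl.startswith(cond)
            ]
            if not cond_seqs:
                continue
            obs = np.nanmean(
                [dynamics.observed_transitions(q, state_labels) for q in cond_seqs], axis=0
            )
            exp = np.nanmean(
                [dynamics.expected_transitions(q, state_labels) for q in cond_seqs], axis=0
            )
            obs = obs / np.nansum(obs)
            exp = exp / np.nansum(exp)
            ts = dynamics.transition_randomness_test(
                np.nan_to_num(obs), np.nan_to_num(exp),
                n_perm=int(cfg["n_permutations"]), seed=int(cfg["seed"]) + 2,
                states=state_labels,
            )
            test_rows.append(
                {"band": band, "condition": cond, "chi_square_d": ts.chi_square_d,
                 "p_value": ts.p_value, "n_permutations": ts.n_permutations}
            )
    pd.DataFrame(test_rows).to_csv(out / "transition_tests.csv", index=False)

    # FL vs MW group comparisons of the dynamics metrics
    comp_rows = []
    for band in bands:
        for st in state_labels:
            for metric in ("frequency", "mean_duration", "coverage"):
                sel = metrics_df[(metrics_df["band"] == band) & (metrics_df["state"] == st)]
                a = sel[sel["condition"] == "FL"][metric].dropna().to_numpy()
                b = sel[sel["condition"] == "MW"][metric].dropna().to_numpy()
                if a.size < 3 or b.size < 3:
                    continue
                r = group_stats.compare_groups(a, b, metric=f"{band}:{st}:{metric}")
                comp_rows.append(asdict(r) | {"band": band, "state": st})
    pd.DataFrame(comp_rows).to_csv(out / "group_comparisons.csv", index=False)

    # within-participant HMM classification
    cls_results = []
    if cfg["classify"]:
        label_to_sym = {s: i for i, s in enumerate(state_labels)}
        participants = sorted({pid for pid, _, _ in sequences})
        for pid in participants:
            per_band: dict[str, dict[str, list[np.ndarray]]] = {}
            for band in bands:
                per_band[band] = {"FL": [], "MW": []}
                for (p2, tl, b2), seq in sorted(sequences.items()):
                    if p2 == pid and b2 == band:
                        syms = np.array([label_to_sym[s] for s, _ in seq.runs])
                        per_band[band][tl.split("-")[0]].append(syms)
            try:
                res = hmm.crossvalidate_participant(
                    per_band, k=int(cfg["cv_folds"]), seed=int(cfg["seed"]) + 3,
                    windows_per_fold=int(cfg["windows_per_fold"]), participant_id=pid,
                )
            except ValidationError as exc:
                import warnings

                warnings.warn(f"classification skipped for {pid}: {exc}", stacklevel=2)
                continue
            cls_results.append(res)
        cls_rows = []
        for res in cls_results:
            for fr in res.folds:
                cls_rows.append(
                    {"participant_id": res.participant_id, "fold": fr.fold,
                     "band": fr.band, "auc": fr.auc, "f1": fr.f1}
                )
            cls_rows.append(
                {"participant_id": res.participant_id, "fold": "mean",
                 "band": "", "auc": res.auc_mean, "f1": res.f1_mean}
            )
        pd.DataFrame(cls_rows).to_csv(out / "classification.csv", index=False)

    with open(out / "run_log.txt", "w") as fh:
        fh.write("effective configuration\n")
        for key in sorted(cfg):
            fh.write(f"{key}={cfg[key]}\n")
        fh.write(f"derived_cluster_seed={cluster_seed}\n")

    return {
        "config": cfg,
        "segments": df,
        "assignments": assign_df,
        "sequences": sequences,
        "metrics": metrics_df,
        "transition_tests": pd.DataFrame(test_rows),
        "classification": cls_results,
        "centroids": all_centroids,
    }
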