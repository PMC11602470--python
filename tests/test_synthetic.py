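"""Planted-motif signal generator: coupling, switching and determinism."""

import numpy as np
import pytest
from scipy.signal import hilbert, periodogram
from scipy.stats import mannwhitneyu

from mwnetdyn import (
    BANDS,
    ConditionSpec,
    PlantedState,
    ValidationError,
    aec,
    benchmark_condition_specs,
    make_state_library,
    simulate_participant,
    simulate_trial,
)


def jaccard(s1, s2):
    u = len(s1 | s2)
    return len(s1 & s2) / u if u else 1.0


def tagged(state):
    return {("a", e) for e in state.amp_edges} | {("p", e) for e in state.phase_edges}


class TestPlantedState:
    def test_self_pair_rejected(self):
        with pytest.raises(ValidationError):
            PlantedState("A", ((1, 1),), ())

    @pytest.mark.parametrize("kwargs", [dict(amp_strength=1.2), dict(phase_lag=0.0),
                                        dict(phase_lag=np.pi)])
    def test_parameter_ranges(self, kwargs):
        with pytest.raises(ValidationError):
            PlantedState("A", ((0, 1),), ((2, 3),), **kwargs)


class TestConditionSpec:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            ConditionSpec("FL", np.array([[0.5, 0.4], [0.5, 0.5]]))

    def test_positive_dwell(self):
        with pytest.raises(ValidationError):
            ConditionSpec("FL", np.eye(2), dwell_mean=0.0)


class TestMakeStateLibrary:
    def test_four_states_eight_channels_distinct(self):
        lib = make_state_library(4, 8, seed=1)
        assert [s.state_id for s in lib] == ["A", "B", "C", "D"]
        for i in range(4):
            for j in range(i + 1, 4):
                assert jaccard(tagged(lib[i]), tagged(lib[j])) < 0.5

    def test_minimal_channels(self):
        lib = make_state_library(2, 3, seed=1)
        assert tagged(lib[0]) != tagged(lib[1])

    def test_deterministic(self):
        assert make_state_library(4, 8, seed=1) == make_state_library(4, 8, seed=1)

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(ValidationError):
            make_state_library(1, 8, seed=1)
        with pytest.raises(ValidationError):
            make_state_library(2, 2, seed=1)


class TestSimulateTrial:
    def setup_method(self):
        self.lib = make_state_library(4, 8, seed=7)
        self.fl, _ = benchmark_condition_specs()

    def test_deterministic(self):
        r1, g1 = simulate_trial(self.lib, self.fl, 20, "alpha", 256, seed=3)
        r2, g2 = simulate_trial(self.lib, self.fl, 20, "alpha", 256, seed=3)
        np.testing.assert_array_equal(r1.data, r2.data)
        np.testing.assert_array_equal(g1.change_points, g2.change_points)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValidationError):
            simulate_trial(self.lib, self.fl, 5, "alpha", 256, seed=0)

    @pytest.mark.parametrize("band", ["delta", "theta", "alpha", "beta", "gamma"])
    def test_band_limited(self, band):
        """>= 90% of power inside the band, measured to the FIR half-transition
        points (the filter's own resolution of 'inside')."""
        rec, _ = simulate_trial(self.lib, self.fl, 30, band, 256, seed=1)
        lo, hi = BANDS[band]
        l_tr = min(max(0.25 * lo, 2.0), lo)
        h_tr = min(max(0.25 * hi, 2.0), 128 - hi)
        f, p = periodogram(rec.data, fs=256, axis=1)
        inside = p[:, (f >= lo - l_tr / 2) & (f <= hi + h_tr / 2)].sum()
        assert inside / p.sum() >= 0.9

    def test_path_consistent_with_change_points(self):
        _, gt = simulate_trial(self.lib, self.fl, 60, "alpha", 256, seed=2)
        offsets = [off for _, off, _ in gt.path[:-1]]
        np.testing.assert_allclose(offsets, gt.change_points)
        for (a, b, s1), (c, d, s2) in zip(gt.path, gt.path[1:]):
            assert b == c and s1 != s2

    def test_zero_coupling_indistinguishable_from_noise(self):
        """With amp_strength 0 and no phase edges, planted pairs look like
        any other pair (rank test over seeds)."""
        lib0 = [
            PlantedState(s.state_id, s.amp_edges, (), amp_strength=0.0)
            for s in self.lib
        ]
        planted_vals, other_vals = [], []
        for seed in range(50):
            rec, _ = simulate_trial(
                lib0, self.fl, 12, "gamma", 256, seed, forced_path=[(0.0, 12.0, 0)]
            )
            m = aec(rec.data)
            e = lib0[0].amp_edges[0]
            planted_vals.append(m[e])
            other_vals.append(m[0, 1] if e != (0, 1) else m[6, 7])
        p = mannwhitneyu(planted_vals, other_vals).pvalue
        assert p > 0.01

    def test_strong_amp_edge_beats_noise_quantile(self):
        rec, _ = simulate_trial(
            self.lib, self.fl, 60, "gamma", 256, seed=4, forced_path=[(0.0, 60.0, 0)]
        )
        m = aec(rec.data)
        planted = {tuple(sorted(e)) for e in self.lib[0].amp_edges}
        iu = np.triu_indices(8, 1)
        noise = [m[i, j] for i, j in zip(*iu) if (i, j) not in planted
                 and (i, j) not in {tuple(sorted(e)) for e in self.lib[0].phase_edges}]
        for e in planted:
            assert m[e] > np.quantile(noise, 0.95)

    def test_planted_phase_lag_recoverable(self):
        lib = [
            PlantedState("A", (), ((0, 1),), amp_strength=0.9, phase_lag=np.pi / 4),
            PlantedState("B", (), ((2, 3),), amp_strength=0.9, phase_lag=np.pi / 4),
        ]
        fl = ConditionSpec("FL", np.array([[0.0, 1.0], [1.0, 0.0]]))
        rec, _ = simulate_trial(
            lib, fl, 60, "alpha", 256, seed=5, forced_path=[(0.0, 60.0, 0)]
        )
        an = hilbert(rec.data, axis=1)
        dphi = np.angle(an[0] * np.conj(an[1]))
        circ_mean = np.angle(np.mean(np.exp(1j * dphi)))
        assert abs(circ_mean - np.pi / 4) < 0.2


class TestSimulateParticipant:
    def test_labels_and_determinism(self):
        lib = make_state_library(4, 8, seed=1)
        fl, mw = benchmark_condition_specs()
        trials = simulate_participant(lib, fl, mw, 2, 20, seed=9, bands=("alpha",))
        assert [t["trial_label"] for t in trials] == ["FL-1", "FL-2", "MW-1", "MW-2"]
        trials2 = simulate_participant(lib, fl, mw, 2, 20, seed=9, bands=("alpha",))
        for t1, t2 in zip(trials, trials2):
            np.testing.assert_array_equal(
                t1["recordings"]["alpha"].data, t2["recordings"]["alpha"].data
            )

    def test_same_path_across_bands(self):
        lib = make_state_library(4, 8, seed=1)
        fl, mw = benchmark_condition_specs()
        trials = simulate_participant(
            lib, fl, mw, 1, 20, seed=2, bands=("alpha", "gamma")
        )
        tr = trials[0]
        assert tr["recordings"]["alpha"].band == "alpha"
        assert tr["recordings"]["gamma"].band == "gamma"

    def test_at_least_one_trial_required(self):
        lib = make_state_library(2, 8, seed=1)
        fl, mw = benchmark_condition_specs()
        fl2 = ConditionSpec("FL", fl.state_transition_matrix[:2, :2] * 0 + np.array([[0, 1], [1, 0]]))
        with pytest.raises(ValidationError):
            simulate_participant(lib, fl2, fl2, 0, 20, seed=1)
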