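"""Trace analysis: segmentation, dwell angles, classification, fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from if1kinetics.containers import AngleTrace, PauseSegment
from if1kinetics.rotary_sim import (
    MotorConfig,
    ObservationConfig,
    ground_truth_pauses,
    simulate_trajectory,
)
from if1kinetics.trajectory_analysis import (
    circular_mean,
    classify_pauses,
    detect_pauses,
    fit_dwell_times,
    inhibition_angle,
    reference_binding_angles,
    rotating_time_to_inhibition,
    rotation_episodes,
)


def _flat_trace(angle=50.0, duration=10.0, fps=30.0, noise=0.0, seed=0):
    n = int(duration * fps)
    rng = np.random.default_rng(seed)
    y = np.full(n, angle) + (rng.normal(0, noise, n) if noise else 0.0)
    return AngleTrace(time=np.arange(n) / fps, angle=y, fps=fps)


class TestDetectPauses:
    def test_constant_trace_is_one_full_pause(self):
        tr = _flat_trace(duration=10.0)
        pauses = detect_pauses(tr)
        assert len(pauses) == 1
        assert pauses[0].start == pytest.approx(0.0)
        assert pauses[0].end == pytest.approx(10.0, abs=1 / 30)
        assert pauses[0].terminal

    def test_min_duration_threshold_semantics(self):
        # dwells of 0.5 s and 5 s separated by fast rotation; only the
        # long one survives min_duration = 1 s
        fps = 30.0
        seg = np.concatenate([
            np.full(15, 0.0),                       # 0.5 s at 0
            0.0 + np.arange(1, 31) * 24.0,          # 1 s rotation at 2 rps
            np.full(150, 840.0),                    # 5 s at 840
            840.0 + np.arange(1, 31) * 24.0,        # exit rotation
        ])
        tr = AngleTrace(time=np.arange(seg.size) / fps, angle=seg, fps=fps)
        pauses = detect_pauses(tr, min_duration=1.0, angle_window=30.0)
        assert len(pauses) == 1
        assert pauses[0].mean_angle == pytest.approx(840.0, abs=1e-9)

    def test_round_trip_recovery_on_noisy_simulations(self, fast_rotation_motor):
        for seed, noise in [(0, 5.0), (1, 8.0), (2, 10.0)]:
            obs = ObservationConfig(fps=30, angle_noise_sd=noise, duration=60.0,
                                    seed=seed)
            tr = simulate_trajectory(fast_rotation_motor, obs)
            gt = ground_truth_pauses(tr, min_duration=1.5)
            det = detect_pauses(tr, min_duration=1.0, angle_window=30.0)
            for g in gt:
                cands = [p for p in det if p.start < g.end and p.end > g.start]
                assert cands, f"missed pause at {g.start:.2f}s (seed {seed})"
                p = max(cands, key=lambda p: min(p.end, g.end) - max(p.start, g.start))
                err_frames = max(abs(p.start - g.start), abs(p.end - g.end)) * tr.fps
                assert err_frames <= 2.0 + 1e-6
            # no pauses invented inside rotation episodes
            gt_all = ground_truth_pauses(tr, min_duration=0.6)
            for p in det:
                assert any(p.start < g.end and p.end > g.start for g in gt_all)

    def test_partition_property(self, fast_rotation_motor):
        obs = ObservationConfig(fps=30, angle_noise_sd=5.0, duration=30.0, seed=9)
        tr = simulate_trajectory(fast_rotation_motor, obs)
        pauses = detect_pauses(tr)
        episodes = rotation_episodes(tr, pauses)
        intervals = sorted([(p.start, p.end) for p in pauses] + episodes)
        assert intervals[0][0] == pytest.approx(tr.time[0])
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            assert a1 == pytest.approx(b0)
        assert intervals[-1][1] == pytest.approx(tr.time[-1] + 1 / tr.fps)

    def test_window_below_noise_warns(self):
        tr = _flat_trace(noise=12.0, seed=4)
        with pytest.warns(UserWarning, match="angle_window"):
            detect_pauses(tr, angle_window=20.0)

    def test_equivariance_under_angle_shift(self, fast_rotation_motor):
        obs = ObservationConfig(fps=30, angle_noise_sd=6.0, duration=30.0, seed=13)
        tr = simulate_trajectory(fast_rotation_motor, obs)
        shifted = AngleTrace(time=tr.time, angle=tr.angle + 37.0, fps=tr.fps)
        p0 = detect_pauses(tr)
        p1 = detect_pauses(shifted)
        assert len(p0) == len(p1)
        for a, b in zip(p0, p1):
            assert b.start == a.start and b.end == a.end
            assert b.mean_angle == pytest.approx(a.mean_angle + 37.0, abs=1e-9)


class TestReferenceAngles:
    def _binding_trace(self, noise, seed, duration=120.0):
        motor = MotorConfig(atp_binding_rate_constant=3e7, atp_conc=2.8e-8,
                            catalytic_rate=200.0, adp_entry_prob_per_turn=0,
                            if1_entry_rate=0)
        return simulate_trajectory(
            motor, ObservationConfig(fps=30, angle_noise_sd=noise,
                                     duration=duration, seed=seed)
        )

    def test_noise_free_exact(self):
        tr = self._binding_trace(0.0, 21)
        refs = reference_binding_angles(tr)
        residues = refs % 120.0
        circ_dist = np.minimum(residues, 120.0 - residues)
        assert np.all(circ_dist < 1e-6)

    def test_noisy_recovery_within_cluster_se(self):
        tr = self._binding_trace(8.0, 22)
        refs = reference_binding_angles(tr)
        pauses = detect_pauses(tr)
        n_frames = sum(p.duration for p in pauses) * tr.fps / 3.0
        tol = 3.0 * 8.0 / math.sqrt(n_frames)
        for r in refs:
            assert min(r % 120.0, 120.0 - (r % 120.0)) < tol

    def test_shift_equivariance(self):
        tr = self._binding_trace(5.0, 23)
        refs = reference_binding_angles(tr)
        shifted = AngleTrace(time=tr.time, angle=tr.angle + 37.0, fps=tr.fps)
        refs2 = reference_binding_angles(shifted)
        expected = np.sort((refs + 37.0) % 360.0)
        assert np.allclose(refs2, expected, atol=1e-9)

    def test_insufficient_clusters_rejected(self):
        tr = _flat_trace(duration=30.0)
        with pytest.raises(ValueError):
            reference_binding_angles(tr)


class TestInhibitionAngle:
    def test_exact_offset_with_zero_noise(self):
        pauses = [PauseSegment(0, 5, 80.0 + 120 * k, 0.0) for k in range(4)]
        res = inhibition_angle(pauses, [0.0, 120.0, 240.0])
        assert res.delta_theta_mean == pytest.approx(80.0, abs=1e-9)
        assert res.delta_theta_sd == pytest.approx(0.0, abs=1e-9)

    def test_single_pause_sd_undefined(self):
        res = inhibition_angle([PauseSegment(0, 5, 200.0, 0.0)], [0.0])
        assert res.delta_theta_mean == pytest.approx(80.0)
        assert math.isnan(res.delta_theta_sd)
        assert res.n_pauses == 1

    def test_reduction_always_in_unit_cell(self):
        rng = np.random.default_rng(5)
        pauses = [PauseSegment(0, 5, float(a), 1.0)
                  for a in rng.uniform(-2000, 2000, 50)]
        res = inhibition_angle(pauses, [13.0])
        assert 0.0 <= res.delta_theta_mean < 120.0

    def test_recovery_on_simulated_molecules(self, binding_limited_motor):
        deltas = []
        for seed in range(12):
            obs = ObservationConfig(fps=30, angle_noise_sd=8.0, duration=300.0,
                                    seed=seed)
            tr = simulate_trajectory(binding_limited_motor, obs)
            det = detect_pauses(tr)
            lab = classify_pauses(det, trace_end=float(tr.time[-1] + 1 / tr.fps))
            if1 = [p for p in lab if p.label == "IF1"]
            rest = [p for p in lab if p.label != "IF1"]
            if len(rest) < 3 or not if1:
                continue
            try:
                refs = reference_binding_angles(tr, pauses=rest)
            except ValueError:
                continue
            deltas.append(inhibition_angle(if1, refs).delta_theta_mean)
        deltas = np.asarray(deltas)
        assert len(deltas) >= 5
        se = deltas.std(ddof=1) / math.sqrt(len(deltas))
        assert abs(deltas.mean() - 80.0) < 3 * se

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            inhibition_angle([], [0.0])
        with pytest.raises(ValueError):
            inhibition_angle([PauseSegment(0, 5, 80.0, 0.0)], [])


class TestClassifyPauses:
    def test_rules(self):
        pauses = [
            PauseSegment(0, 600, 80.0, 1.0),           # >= 480 s -> IF1
            PauseSegment(700, 715, 200.0, 1.0),        # 15 s recovered -> ADP
            PauseSegment(800, 802, 320.0, 1.0),        # 2 s -> unclassified
            PauseSegment(900, 960, 440.0, 1.0, terminal=True),  # terminal -> IF1
        ]
        out = classify_pauses(pauses, adp_tau_range=(5.0, 100.0),
                              if1_min_duration=480.0, trace_end=1000.0)
        assert [p.label for p in out] == ["IF1", "ADP", "unclassified", "IF1"]

    def test_labels_always_assigned_and_input_not_mutated(self):
        p = PauseSegment(0, 3, 0.0, 1.0)
        out = classify_pauses([p])
        assert out[0].label in {"IF1", "ADP", "unclassified"}
        assert p.label == "unclassified"


class TestDwellTimeFits:
    def test_constant_durations_give_exact_mean(self):
        f = fit_dwell_times(np.full(10, 7.0), "single")
        assert f.taus[0] == pytest.approx(7.0, rel=1e-12)

    def test_single_recovery_with_censoring(self):
        rng = np.random.default_rng(42)
        t = rng.exponential(19.6, 500)
        obs, cens = np.minimum(t, 480.0), t > 480.0
        f = fit_dwell_times(obs, "single", censored=cens)
        assert abs(f.taus[0] - 19.6) < 3 * f.stderr_taus[0]

    def test_censored_mle_unbiased_where_naive_is_low(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(200.0, 2000)
        obs, cens = np.minimum(t, 480.0), t > 480.0
        naive = fit_dwell_times(obs, "single")
        corrected = fit_dwell_times(obs, "single", censored=cens)
        assert naive.taus[0] < 200.0 - 3 * naive.stderr_taus[0]
        assert abs(corrected.taus[0] - 200.0) < 3 * corrected.stderr_taus[0]

    def test_double_recovery(self):
        rng = np.random.default_rng(3)
        comp = rng.random(500) < 0.5
        t = np.where(comp, rng.exponential(10.0, 500), rng.exponential(250.0, 500))
        f = fit_dwell_times(t, "double")
        assert f.taus[0] < f.taus[1]
        assert abs(f.taus[0] - 10.0) < 3 * f.stderr_taus[0]
        assert abs(f.taus[1] - 250.0) < 3 * f.stderr_taus[1]
        assert not f.unidentifiable

    def test_close_components_flagged_unidentifiable(self):
        rng = np.random.default_rng(8)
        comp = rng.random(400) < 0.5
        t = np.where(comp, rng.exponential(20.0, 400), rng.exponential(30.0, 400))
        f = fit_dwell_times(t, "double")
        assert f.unidentifiable

    def test_histogram_method_agrees_roughly(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(19.6, 1000)
        f = fit_dwell_times(t, "single", method="histogram_ls")
        assert f.taus[0] == pytest.approx(19.6, rel=0.2)
        assert f.loglik is None and f.residual_sum is not None

    @pytest.mark.parametrize("model,n", [("single", 3), ("double", 10)])
    def test_minimum_event_counts(self, model, n):
        with pytest.raises(ValueError):
            fit_dwell_times(np.ones(n), model)


class TestRotatingTime:
    def test_direct_onset(self):
        pauses = [PauseSegment(42.0, 600.0, 80.0, 1.0, label="IF1")]
        rt = rotating_time_to_inhibition(_flat_trace(duration=5.0),
                                         exchange_time=0.0, pauses=pauses)
        assert rt.duration == pytest.approx(42.0)
        assert not rt.censored

    def test_censored_when_no_inhibition(self):
        tr = _flat_trace(duration=5.0)
        rt = rotating_time_to_inhibition(tr, exchange_time=0.0,
                                         pauses=[PauseSegment(1, 3, 0.0, 1.0,
                                                              label="ADP")])
        assert rt.censored
        assert rt.duration == pytest.approx(5.0, abs=0.1)

    def test_ensemble_recovery_of_onset_mean(self):
        motor = MotorConfig(atp_binding_rate_constant=1e8, atp_conc=1e-3,
                            catalytic_rate=100.0, adp_entry_prob_per_turn=0,
                            if1_entry_rate=0.25)
        durations, cens = [], []
        for seed in range(120):
            tr = simulate_trajectory(
                motor, ObservationConfig(angle_noise_sd=4.0, duration=60.0,
                                         seed=seed)
            )
            rt = rotating_time_to_inhibition(tr, exchange_time=0.0)
            durations.append(rt.duration)
            cens.append(rt.censored)
        f = fit_dwell_times(durations, "single", censored=cens)
        from if1kinetics.rotary_sim import expected_rotating_time
        expect = expected_rotating_time(motor)
        assert abs(f.taus[0] - expect) < 3 * f.stderr_taus[0]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(shift=st.floats(-360.0, 360.0),
       angles=st.lists(st.floats(0.0, 359.99), min_size=3, max_size=12))
def test_circular_mean_shift_equivariance(shift, angles):
    m0 = circular_mean(angles)
    m1 = circular_mean([a + shift for a in angles])
    diff = (m1 - m0 - shift) % 360.0
    assert min(diff, 360.0 - diff) < 1e-6
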