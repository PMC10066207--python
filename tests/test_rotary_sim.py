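"""Generative model: trajectories, ensemble curves, manipulations."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from if1kinetics.rotary_sim import (
    EnsembleAssayConfig,
    ManipulationProtocol,
    MotorConfig,
    ObservationConfig,
    _scheme_matrix,
    apply_manipulation,
    expected_rotating_time,
    ground_truth_pauses,
    simulate_ensemble_progress,
    simulate_release_trace,
    simulate_trajectory,
    species_fractions,
)
from if1kinetics.stall_release import ActivationModel, predict_pon


class TestTrajectory:
    def test_noise_free_staircase_is_monotone_120_periodic(self, clean_staircase):
        tr = clean_staircase
        assert np.all(np.diff(tr.angle) >= 0)
        # every latent dwell angle is congruent to 0 or 80 mod 120
        residues = np.unique(np.round(tr.angle % 120.0, 6))
        assert set(residues) <= {0.0, 80.0}

    def test_irreversible_inhibition_ends_at_catalytic_angle(self):
        motor = MotorConfig(adp_entry_prob_per_turn=0, if1_entry_rate=50.0,
                            if1_pause_tau=math.inf)
        obs = ObservationConfig(angle_noise_sd=0.0, duration=10.0, seed=3)
        tr = simulate_trajectory(motor, obs)
        last = tr.segments[-1]
        assert last.kind == "if1"
        assert last.end == pytest.approx(10.0)
        assert (last.latent_angle - 80.0) % 120.0 == pytest.approx(0.0, abs=1e-9)
        assert tr.annotations["terminal_if1"]

    def test_seed_reproducibility(self):
        motor = MotorConfig()
        obs = ObservationConfig(duration=5.0, seed=11)
        a = simulate_trajectory(motor, obs)
        b = simulate_trajectory(motor, obs)
        assert np.array_equal(a.angle, b.angle)
        assert a.segments == b.segments

    def test_mean_rotating_time_matches_competing_risk_expectation(self):
        # oracle: closed-form mean of the geometric/exponential race
        motor = MotorConfig(atp_binding_rate_constant=1e8, atp_conc=1e-3,
                            catalytic_rate=100.0, adp_entry_prob_per_turn=0,
                            if1_entry_rate=0.2)
        expect = expected_rotating_time(motor)
        onsets = []
        for seed in range(500):
            tr = simulate_trajectory(
                motor, ObservationConfig(angle_noise_sd=0, duration=100.0, seed=seed)
            )
            t_if1 = [s.start for s in tr.segments if s.kind == "if1"]
            if t_if1:
                onsets.append(t_if1[0])
        onsets = np.asarray(onsets)
        assert len(onsets) > 450
        se = onsets.std(ddof=1) / math.sqrt(len(onsets))
        assert abs(onsets.mean() - expect) < 3 * se

    def test_ground_truth_pauses_merge_contiguous_same_angle(self):
        motor = MotorConfig(atp_binding_rate_constant=3e7, atp_conc=2.8e-5,
                            catalytic_rate=50.0, adp_entry_prob_per_turn=0.5,
                            adp_exit_taus=(5.0,), if1_entry_rate=0)
        tr = simulate_trajectory(
            motor, ObservationConfig(angle_noise_sd=0, duration=30.0, seed=5)
        )
        gt = ground_truth_pauses(tr, min_duration=1.0)
        # merged intervals are disjoint, ordered, all >= 1 s
        for a, b in zip(gt, gt[1:]):
            assert a.end <= b.start + 1e-12
            assert a.latent_angle != b.latent_angle or b.start > a.end
        assert all(g.duration >= 1.0 for g in gt)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"catalytic_rate": -1.0},
            {"atp_conc": float("nan")},
            {"adp_entry_prob_per_turn": 1.5},
            {"binding_angles": (0.0, 100.0, 240.0)},
            {"if1_pause_tau": 0.0},
        ],
    )
    def test_invalid_motor_config(self, kwargs):
        with pytest.raises(ValueError):
            MotorConfig(**kwargs)

    def test_duration_shorter_than_one_frame_rejected(self):
        with pytest.raises(ValueError):
            ObservationConfig(duration=0.01, fps=30)


class TestEnsemble:
    def test_zero_inhibitor_gives_linear_decrease(self):
        cfg = EnsembleAssayConfig(if1_conc=0.0)
        curve = simulate_ensemble_progress(cfg)
        slopes = np.diff(curve.absorbance) / np.diff(curve.time)
        assert np.allclose(slopes, slopes[0], rtol=1e-9)
        expected = -(cfg.nadh_extinction_coefficient * cfg.path_length
                     * cfg.initial_rate_per_enzyme * cfg.enzyme_conc)
        assert slopes[0] == pytest.approx(expected, rel=1e-9)

    def test_absorbance_non_increasing(self):
        curve = simulate_ensemble_progress(EnsembleAssayConfig(if1_conc=1e-5))
        assert np.all(np.diff(curve.absorbance) <= 1e-12)

    def test_species_fractions_match_matrix_exponential(self):
        # independent oracle: scipy expm on the same rate matrix
        rng = np.random.default_rng(0)
        t = np.array([0.0, 1.0, 10.0, 50.0, 300.0])
        for _ in range(10):
            cfg = EnsembleAssayConfig(
                if1_conc=float(rng.uniform(1e-8, 3e-5)),
                k_on=float(rng.uniform(1e4, 1e7)),
                k_off=float(rng.uniform(1e-4, 0.2)),
                k_lock=float(rng.uniform(1e-3, 0.2)),
            )
            ours = species_fractions(cfg, t)
            K = _scheme_matrix(cfg.k_on * cfg.if1_conc, cfg.k_off, cfg.k_lock)
            oracle = np.array([expm(K * tt) @ [1.0, 0.0, 0.0] for tt in t])
            assert np.abs(ours - oracle).max() < 1e-8

    def test_locking_limit_completes(self):
        # k_off -> 0 and saturating inhibitor: everything ends locked
        cfg = EnsembleAssayConfig(if1_conc=3e-5, k_off=1e-9, k_lock=0.03)
        p = species_fractions(cfg, np.array([2000.0]))[0]
        assert p[2] == pytest.approx(1.0, abs=1e-6)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            EnsembleAssayConfig(if1_conc=-1e-6)


class TestManipulation:
    def test_null_model_never_activates(self):
        model = ActivationModel(k_max=0.0, tau_spont=math.inf)
        proto = ManipulationProtocol(target_angle=-200.0, stall_duration=5.0)
        outcomes = {apply_manipulation(0.0, proto, model, seed=s).outcome
                    for s in range(50)}
        assert outcomes == {"OFF"}

    def test_wildtype_counterclockwise_rotation_rarely_activates(self):
        model = ActivationModel()  # hazard only beyond -180 deg clockwise
        proto = ManipulationProtocol(protocol_kind="full_rotation",
                                     direction_sign=+1, target_angle=360.0,
                                     stall_duration=0.0)
        n_on = sum(apply_manipulation(0.0, proto, model, seed=s).outcome == "ON"
                   for s in range(100))
        assert n_on / 100 < 0.04

    def test_monte_carlo_matches_closed_form(self):
        model = ActivationModel()
        proto = ManipulationProtocol(target_angle=-200.0, stall_duration=2.0)
        n = 1000
        frac = 100.0 * np.mean(
            [apply_manipulation(0.0, proto, model, seed=s).outcome == "ON"
             for s in range(n)]
        )
        pred = predict_pon(model, -200.0, 2.0, ramp_rate=proto.ramp_rate)
        sd = math.sqrt(pred * (100.0 - pred) / n)
        assert abs(frac - pred) < 3 * sd

    def test_off_returns_to_pause_angle(self):
        model = ActivationModel(k_max=0.0)
        proto = ManipulationProtocol(target_angle=-200.0, stall_duration=1.0)
        trial = apply_manipulation(123.0, proto, model, seed=0)
        assert trial.outcome == "OFF"
        assert trial.release_angle == 123.0

    def test_sign_convention_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ManipulationProtocol(direction_sign=+1, target_angle=-200.0)
        with pytest.raises(ValueError):
            ManipulationProtocol(protocol_kind="full_rotation",
                                 direction_sign=-1, target_angle=-200.0)

    def test_release_trace_kinds(self):
        on = simulate_release_trace("ON", 100.0, noise_sd=0.0, seed=1)
        off = simulate_release_trace("OFF", 100.0, noise_sd=0.0, seed=1)
        assert on.angle[-1] - 100.0 > 360.0
        assert np.allclose(off.angle, 100.0)
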