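import warnings

import numpy as np
import pytest

from if1kinetics.rotary_sim import MotorConfig, ObservationConfig, simulate_trajectory


@pytest.fixture(autouse=True)
def _quiet_segmentation_warnings():
    # the high-noise regimes deliberately probe the window/noise warning
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="angle_window")
        yield


@pytest.fixture
def fast_rotation_motor():
    """~5 rps rotation with ~5 s ADP pauses; no inhibitor."""
    return MotorConfig(
        atp_binding_rate_constant=3e7,
        atp_conc=2.8e-5,
        catalytic_rate=50.0,
        adp_entry_prob_per_turn=0.15,
        adp_exit_taus=(5.0,),
        if1_entry_rate=0.0,
    )


@pytest.fixture
def binding_limited_motor():
    """Three-dwell regime (~1.2 s binding dwells) with inhibitor arrest."""
    return MotorConfig(
        atp_binding_rate_constant=3e7,
        atp_conc=2.8e-8,
        catalytic_rate=200.0,
        adp_entry_prob_per_turn=0.0,
        if1_entry_rate=4.0,
        if1_pause_tau=np.inf,
    )


@pytest.fixture
def clean_staircase():
    """Noise-free, inhibition-free trace: a monotone 120-deg staircase."""
    motor = MotorConfig(adp_entry_prob_per_turn=0.0, if1_entry_rate=0.0)
    obs = ObservationConfig(fps=30, angle_noise_sd=0.0, duration=5.0, seed=7)
    return simulate_trajectory(motor, obs)
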