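"""Torque components, the APA cross-fade, and closed-loop behaviour."""

import math
from dataclasses import replace

import numpy as np
import pytest

from leansim import (
    BodyState,
    ControlGains,
    PlanningParams,
    blend_torque,
    feedback_torque,
    feedforward_torque,
    simulate_trial,
)
from leansim.control import blend_weights, min_stable_kp
from leansim.errors import SimulationDivergedError, ValidationError
from leansim.plant import DEG
from leansim.simulate import SimConfig


@pytest.fixture()
def params():
    return PlanningParams(t_r=0.4, t_f=2.0, t_b=1.5, t_APA=0.5, theta_f=2.0)


class TestFeedbackTorque:
    def test_perfect_tracking_gives_zero(self):
        g = ControlGains(K_P=50, K_FF=5)
        assert feedback_torque(g, 1.5, 0.3, BodyState(1.5, 0.3)) == 0.0

    def test_proportional_path(self):
        g = ControlGains(K_P=61.73, K_FF=0)
        assert feedback_torque(g, 1.0, 0.0, BodyState(0.0, 0.0)) == pytest.approx(61.73)

    def test_velocity_path_uses_default_gain(self):
        g = ControlGains(K_P=50, K_FF=0)  # K_I defaults to 5 N·m/(deg/s)
        assert g.K_I == 5.0
        assert feedback_torque(g, 0.0, 1.0, BodyState(0.0, 0.0)) == pytest.approx(5.0)


class TestFeedforwardTorque:
    def test_zero_gain(self, healthy_anthro):
        assert feedforward_torque(0.0, healthy_anthro, 2.0, 50.0) == 0.0

    def test_static_reference_sign(self, healthy_anthro):
        assert feedforward_torque(1.0, healthy_anthro, 1.0, 0.0) < 0

    def test_inertial_term_unit_conversion(self, healthy_anthro):
        # K_FF=1, ddtheta_ref=1 deg/s^2, theta_ref=0 -> J_B converted to rad
        tau = feedforward_torque(1.0, healthy_anthro, 0.0, 1.0)
        assert tau == pytest.approx(healthy_anthro.J_B * DEG, rel=1e-12)
        assert tau == pytest.approx(72.8 * math.pi / 180, abs=0.01)


class TestBlendTorque:
    def test_window_start_is_pure_feedback(self, params):
        cmd = blend_torque(params.t_r, params, tau_FF=10, tau_FB=3, tau_AIS=1,
                           blend_direction="printed")
        assert cmd.tau_total == pytest.approx(3 + 1)
        assert cmd.alpha == 0.0

    def test_window_end_approaches_pure_feedforward_printed(self, params):
        t = params.t_r + params.t_APA * (1 - 1e-9)
        cmd = blend_torque(t, params, tau_FF=10, tau_FB=3, tau_AIS=1,
                           blend_direction="printed")
        assert cmd.tau_total == pytest.approx(10 + 1, rel=1e-6)

    def test_midpoint_average(self, params):
        t = params.t_r + 0.5 * params.t_APA
        cmd = blend_torque(t, params, tau_FF=10, tau_FB=4, tau_AIS=1,
                           blend_direction="printed")
        assert cmd.tau_total == pytest.approx((10 + 4) / 2 + 1)

    def test_narrative_direction_reverses_fade(self, params):
        t = params.t_r + 0.25 * params.t_APA
        printed = blend_torque(t, params, 10, 4, 1, blend_direction="printed")
        narrative = blend_torque(t, params, 10, 4, 1, blend_direction="narrative")
        assert printed.tau_total == pytest.approx(0.25 * 10 + 0.75 * 4 + 1)
        assert narrative.tau_total == pytest.approx(0.75 * 10 + 0.25 * 4 + 1)

    def test_after_window_is_feedback_only(self, params):
        for direction in ("printed", "narrative"):
            cmd = blend_torque(params.t_r + params.t_APA + 0.1, params, 10, 4, 1,
                               blend_direction=direction)
            assert cmd.tau_total == pytest.approx(4 + 1)

    def test_narrative_is_continuous_at_window_end(self, params):
        before = blend_weights(params.t_r + params.t_APA * (1 - 1e-9), params, "narrative")
        after = blend_weights(params.t_r + params.t_APA + 1e-9, params, "narrative")
        assert before[0] == pytest.approx(after[0], abs=1e-6)  # w_ff -> 0

    def test_bad_inputs(self, params):
        with pytest.raises(ValidationError):
            blend_torque(1.0, params, math.inf, 0, 0)
        with pytest.raises(ValidationError):
            blend_torque(1.0, params, 0, 0, 0, blend_direction="sideways")


class TestClosedLoop:
    def test_torque_decomposition_identity(self, healthy_sim):
        recomputed = (
            healthy_sim.w_ff * healthy_sim.tau_ff
            + healthy_sim.w_fb * healthy_sim.tau_fb
            + healthy_sim.tau_ais
        )
        assert np.max(np.abs(recomputed - healthy_sim.tau_total)) < 1e-9

    def test_apa_sign_opposes_target(self, healthy_sim, pd_sim):
        # first post-onset COP extremum is opposite the (positive) target
        for sim in (healthy_sim, pd_sim):
            onset = sim.trial.onset_index
            post = sim.cop_out_cm[onset:]
            first_peak = np.argmax(np.abs(post) > 0.05)
            assert post[first_peak] < 0

    def test_steady_state_matches_static_analysis(
        self, healthy_anthro, healthy_plant, healthy_layout
    ):
        # long hold at the target: theta -> K_P' * theta_f / (K_P'+K_A'-mgl)
        from leansim.plant import RAD

        theta_f = 1.8
        p = PlanningParams(t_r=0.35, t_f=2.0, t_b=1.5, t_APA=0.46, theta_f=theta_f, hold=8.0)
        gaps = []
        for kp in (30.0, 50.0, 80.0, 130.0):
            res = simulate_trial(
                healthy_anthro, healthy_plant, p, ControlGains(K_P=kp, K_FF=5.0)
            )
            i_end_hold = np.searchsorted(res.t_fine, res.trial.target_onset + p.t_r + p.t_f + p.hold) - 2
            theta_ss = res.theta_deg[i_end_hold]
            kp_rad = kp * RAD
            ka_rad = healthy_plant.K_A * RAD
            predicted = kp_rad * theta_f / (kp_rad + ka_rad - healthy_anthro.mgl)
            assert theta_ss == pytest.approx(predicted, rel=1e-3)
            # COP at steady state equals the COM projection
            cop_ss = res.cop_fine_cm[i_end_hold]
            assert cop_ss == pytest.approx(
                healthy_anthro.L_COM * math.radians(theta_ss) * 100, rel=1e-3
            )
            gaps.append(abs(theta_ss - theta_f))
        assert np.all(np.diff(gaps) < 0)  # larger K_P -> smaller offset

    def test_deterministic_given_seed(
        self, healthy_anthro, healthy_plant, healthy_params_t1, healthy_gains
    ):
        cfg = SimConfig(noise_sd_cm=0.05, seed=42)
        r1 = simulate_trial(healthy_anthro, healthy_plant, healthy_params_t1, healthy_gains, config=cfg)
        r2 = simulate_trial(healthy_anthro, healthy_plant, healthy_params_t1, healthy_gains, config=cfg)
        assert np.array_equal(r1.trial.cop_ap, r2.trial.cop_ap)
        assert np.array_equal(r1.trial.cop_ml, r2.trial.cop_ml)

    def test_unstable_gains_rejected_at_setup(self, healthy_anthro, healthy_plant, params):
        kp_min = min_stable_kp(healthy_anthro, healthy_plant)
        with pytest.raises(ValidationError, match="static stability"):
            simulate_trial(
                healthy_anthro, healthy_plant, params,
                ControlGains(K_P=0.5 * kp_min, K_FF=5.0),
            )

    def test_divergence_reports_gains(
        self, healthy_anthro, healthy_plant, healthy_params_t1, healthy_gains
    ):
        cfg = SimConfig(theta_cap_deg=1.0)  # any real lean exceeds a 1-degree cap
        with pytest.raises(SimulationDivergedError) as exc:
            simulate_trial(healthy_anthro, healthy_plant, healthy_params_t1, healthy_gains, config=cfg)
        assert exc.value.k_p == healthy_gains.K_P

    def test_trial_contract(self, healthy_sim):
        trial = healthy_sim.trial
        assert trial.sampling_hz == 80.0
        assert trial.target_onset == 5.0
        assert trial.time[0] == 0.0
        assert np.allclose(np.diff(trial.time), 1 / 80.0)
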