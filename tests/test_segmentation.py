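"""Five-phase segmentation: onset detection, features, aggregation."""

import math

import numpy as np
import pytest

from leansim import (
    COPTrial,
    SegmentationConfig,
    aggregate_subject,
    detect_apa_onset,
    project_onto_direction,
    segment_signal,
    segment_trial,
    target_layout,
)
from leansim.errors import NoAPADetectedError, SegmentationFailedError, ValidationError

FS = 80.0


def make_trial(x_ap, x_ml=None, target_id=1, onset=5.0):
    n = len(x_ap)
    return COPTrial(
        time=np.arange(n) / FS,
        cop_ap=np.asarray(x_ap, float),
        cop_ml=np.zeros(n) if x_ml is None else np.asarray(x_ml, float),
        target_onset=onset,
        target_id=target_id,
    )


def piecewise(vertices, fs=FS):
    """Sample a piecewise-linear curve given (t, x) vertices on a uniform grid."""
    t_end = vertices[-1][0]
    t = np.arange(int(round(t_end * fs)) + 1) / fs
    tv = [v[0] for v in vertices]
    xv = [v[1] for v in vertices]
    return t, np.interp(t, tv, xv)


@pytest.fixture()
def trapezoid():
    """Analytic fixture: 1 cm APA dip, 5 cm peak, small return undershoot."""
    _, x = piecewise([
        (0.0, 0.0), (5.5, 0.0), (6.0, -1.0), (6.5, 0.0),
        (8.5, 5.0), (11.0, 0.0), (11.5, -0.2), (12.0, 0.0), (13.0, 0.0),
    ])
    return x


class TestProjection:
    def test_pure_ap_target_reduces_to_ap_channel(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.1, 900)
        trial = make_trial(x, x_ml=rng.normal(0, 0.1, 900), target_id=1)
        proj = project_onto_direction(trial, target_layout(0.97))
        i0 = trial.onset_index
        assert np.allclose(proj, trial.cop_ap - trial.cop_ap[:i0].mean())

    def test_projection_along_diagonal_recovers_scalar(self):
        lay = target_layout(0.97)
        s = np.concatenate([np.zeros(400), np.linspace(0, 3, 500)])
        for tid in (1, 2, 4, 7):
            u_ap, u_ml = lay[tid].unit_vector
            trial = make_trial(s * u_ap, s * u_ml, target_id=tid)
            assert np.allclose(project_onto_direction(trial, lay), s, atol=1e-12)

    def test_cop_at_target_projects_to_target_distance(self):
        lay = target_layout(0.97)
        rec = lay[2]
        x = np.zeros(800)
        ap = x + 0.0
        ml = x + 0.0
        ap[-1] = rec.ap_distance * 100
        ml[-1] = rec.ml_distance * 100
        proj = project_onto_direction(make_trial(ap, ml, target_id=2), lay)
        assert proj[-1] == pytest.approx(rec.distance * 100, rel=1e-12)

    def test_offset_invariance(self, trapezoid):
        lay = target_layout(0.97)
        r1 = segment_trial(make_trial(trapezoid), lay)
        r2 = segment_trial(make_trial(trapezoid + 3.7), lay)
        assert r1.apa_onset_idx == r2.apa_onset_idx
        assert r1.peak_idx == r2.peak_idx
        assert r2.apa_size == pytest.approx(r1.apa_size, rel=1e-12)
        assert r2.lean_max == pytest.approx(r1.lean_max, rel=1e-12)


class TestDetectOnset:
    def test_noiseless_ramp_detected_at_first_sample(self):
        t, x = piecewise([(0, 0), (6.0, 0), (7.0, -2.0), (9.0, -2.0)])
        t_onset, idx = detect_apa_onset(x, t, target_onset=5.0)
        # ramp starts at 6.0 s; first sample beyond the floor is one later
        assert idx == int(6.0 * FS) + 1

    def test_threshold_scales_with_baseline_sd(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.05, 480)
        ramp = -np.linspace(0, 3, 320)
        x = np.concatenate([noise, ramp + noise[:320][::-1] * 0])
        t = np.arange(800) / FS
        _, idx1 = detect_apa_onset(x, t, target_onset=5.0)
        _, idx2 = detect_apa_onset(3.0 * x, t, target_onset=5.0)
        assert idx1 == idx2

    def test_no_response_raises(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.05, 800)
        with pytest.raises(NoAPADetectedError):
            detect_apa_onset(x, np.arange(800) / FS, target_onset=5.0)

    def test_toward_target_movement_is_not_an_apa(self):
        # deviation toward the target (positive) must not trigger
        t, x = piecewise([(0, 0), (6.0, 0), (7.0, 4.0), (9.0, 4.0)])
        with pytest.raises(NoAPADetectedError):
            detect_apa_onset(x, t, target_onset=5.0)


class TestSegmentTrial:
    def test_trapezoid_features_are_exact(self, trapezoid):
        res = segment_signal(trapezoid, np.arange(trapezoid.size) / FS, 5.0)
        assert res.t_r == pytest.approx(0.5125, abs=1e-12)
        assert res.t_APA == pytest.approx(6.5 - 5.5125, abs=1e-9)
        assert res.apa_size == pytest.approx(1.0, rel=1e-12)
        assert res.lean_max == pytest.approx(5.0, rel=1e-12)
        assert res.t_f == pytest.approx(8.5 - 5.5125, abs=1e-12)
        assert res.t_b == pytest.approx(11.5 - 8.5, abs=1e-12)
        assert res.t_total == res.t_r + res.t_f + res.t_b

    def test_mirrored_target_gives_identical_magnitudes(self, trapezoid):
        lay = target_layout(0.97)
        u2, u3 = lay[2].unit_vector, lay[3].unit_vector
        r2 = segment_trial(make_trial(trapezoid * u2[0], trapezoid * u2[1], 2), lay)
        r3 = segment_trial(make_trial(trapezoid * u3[0], trapezoid * u3[1], 3), lay)
        assert r2 == r3

    def test_monotone_drift_fails(self):
        t, x = piecewise([(0, 0), (6.0, 0), (6.3, -0.5), (6.6, 0.0), (13.0, 8.0)])
        with pytest.raises(SegmentationFailedError):
            segment_signal(x, t, 5.0)

    def test_baseline_window_must_precede_onset(self, trapezoid):
        with pytest.raises(ValidationError):
            segment_signal(trapezoid, np.arange(trapezoid.size) / FS, target_onset=0.0)

    def test_simulated_pd_trial_recovers_planted_times(self, pd_sim, pd_params_t1):
        res = segment_signal(pd_sim.cop_out_cm, pd_sim.trial.time, 5.0)
        assert res.t_r == pytest.approx(pd_params_t1.t_r, abs=1 / FS)  # 1 sample
        # the COP maximum lags/leads the planner times by the model's
        # inertial bias; consistency is at the ~0.3 s level by design
        assert res.t_f == pytest.approx(pd_params_t1.t_f, abs=0.3)
        assert res.t_b == pytest.approx(pd_params_t1.t_b, abs=0.3)
        assert res.t_total == res.t_r + res.t_f + res.t_b

    def test_80hz_features_match_internal_state(self, healthy_sim):
        s80 = segment_signal(healthy_sim.cop_out_cm, healthy_sim.trial.time, 5.0)
        fine = segment_signal(healthy_sim.cop_fine_cm, healthy_sim.t_fine, 5.0)
        assert s80.apa_size == pytest.approx(fine.apa_size, rel=0.01)
        assert s80.lean_max == pytest.approx(fine.lean_max, rel=0.01)

    def test_optional_lowpass_runs(self, trapezoid):
        cfg = SegmentationConfig(lowpass_hz=10.0)
        res = segment_signal(trapezoid, np.arange(trapezoid.size) / FS, 5.0, cfg)
        assert res.lean_max == pytest.approx(5.0, rel=0.02)


class TestAggregateSubject:
    def _seg(self, trapezoid):
        return segment_signal(trapezoid, np.arange(trapezoid.size) / FS, 5.0)

    def test_identical_trials_mean_equals_single(self, trapezoid):
        r = self._seg(trapezoid)
        out = aggregate_subject({1: [r, r, r, r]})
        assert out.loc[0, "n_trials"] == 4
        assert out.loc[0, "apa_size"] == pytest.approx(r.apa_size)
        assert out.loc[0, "t_total"] == pytest.approx(r.t_total)

    def test_flagged_trial_reduces_n(self, trapezoid):
        r = self._seg(trapezoid)
        out = aggregate_subject({1: [r, None, r, r]})
        assert out.loc[0, "n_trials"] == 3
        assert not out.loc[0, "missing"]

    def test_empty_direction_flagged_missing(self, trapezoid):
        r = self._seg(trapezoid)
        out = aggregate_subject({1: [r], 2: [None, None]})
        row = out[out.target_id == 2].iloc[0]
        assert row["missing"] and math.isnan(row["apa_size"])
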