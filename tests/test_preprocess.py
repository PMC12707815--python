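"""Stance detection, smoothing, speed/mass estimation and normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hopdyn.config import G, SmoothingSpec
from hopdyn.errors import PipelineError
from hopdyn.preprocess import (StanceWindow, detect_stance,
                               estimate_body_mass, normalize_grf,
                               smooth_positions, stride_parameters,
                               trial_speed)
from hopdyn.trial_io import ForceRecord, MarkerSet

from test_trial_io import make_forces


def half_sine_forces(peak=1000.0, duration=0.30, rate=1000.0, pad=0.2):
    t = np.arange(int((duration + 2 * pad) * rate) + 1) / rate
    s = (t - pad) / duration
    fy = np.where((s >= 0) & (s <= 1), peak * np.sin(np.pi * np.clip(s, 0, 1)),
                  0.0)
    return make_forces(fy, rate=rate)


class TestDetectStance:
    def test_half_sine_closed_form_duration(self):
        # threshold crossings of P sin(pi t/T) at 0.02 P:
        # duration = T (1 - 2 asin(0.02)/pi)
        T = 0.30
        rec = half_sine_forces(peak=1000.0, duration=T)
        win = detect_stance(rec)
        assert win.threshold == pytest.approx(20.0, rel=1e-6)
        expected = T * (1 - 2 * np.arcsin(0.02) / np.pi)
        assert win.contact_duration == pytest.approx(expected, abs=2e-4)

    def test_all_zero_force_is_no_contact(self):
        with pytest.raises(PipelineError, match="no_contact"):
            detect_stance(make_forces(np.zeros(500)))

    def test_two_separated_contacts_rejected(self):
        t = np.arange(1501) / 1000.0
        fy = np.where(t < 0.3, 500.0, 0.0) + np.where(t > 0.8, 500.0, 0.0)
        with pytest.raises(PipelineError, match="multiple_contacts"):
            detect_stance(make_forces(fy))

    def test_brief_dropout_bridged(self):
        t = np.arange(501) / 1000.0
        fy = np.where((t > 0.1) & (t < 0.4), 500.0, 0.0)
        fy[(t > 0.24) & (t < 0.26)] = 0.0  # 20 ms dropout < 50 ms gap
        win = detect_stance(make_forces(fy))
        assert win.contact_duration == pytest.approx(0.3, abs=5e-3)

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=0.05, max_value=1e3))
    def test_threshold_scales_with_peak(self, scale):
        rec = half_sine_forces()
        scaled = ForceRecord(grf=rec.grf * scale, cop_x=rec.cop_x,
                             rate=rec.rate, time=rec.time)
        a, b = detect_stance(rec), detect_stance(scaled)
        assert a.start_time == pytest.approx(b.start_time, abs=1e-12)
        assert a.end_time == pytest.approx(b.end_time, abs=1e-12)

    def test_generator_contact_within_one_sample(self, noisefree_trial):
        trial, truth = noisefree_trial
        win = detect_stance(trial.forces)
        true_dur = truth.stance_end - truth.stance_start
        assert abs(win.contact_duration - true_dur) <= 1.0 / trial.forces.rate


class TestBodyMass:
    def test_constant_force(self):
        rec = make_forces(np.full(1001, 196.2))
        assert estimate_body_mass(rec, (0.0, 1.0)) == pytest.approx(20.0,
                                                                    rel=1e-6)

    def test_half_sine_closed_form(self):
        P, Tc, Ta = 1200.0, 0.30, 0.25
        rec = half_sine_forces(peak=P, duration=Tc, pad=Ta / 2)
        m = estimate_body_mass(rec, (0.0, Tc + Ta))
        expected = 2 * P * Tc / (np.pi * (Tc + Ta) * G)
        assert m == pytest.approx(expected, rel=1e-4)

    def test_generator_mass_within_one_percent(self, noisefree_trial):
        trial, _ = noisefree_trial
        rec = trial.forces_raw
        m = estimate_body_mass(rec, (rec.time[0], rec.time[-1]))
        assert m == pytest.approx(trial.metadata.body_mass, rel=0.01)

    def test_cycle_shorter_than_stance_rejected(self):
        rec = half_sine_forces()
        win = detect_stance(rec)
        with pytest.raises(PipelineError, match="bad_cycle"):
            estimate_body_mass(rec, (win.start_time, win.start_time + 0.1),
                               stance=win)

    def test_invariant_to_resampling(self, noisefree_trial):
        from hopdyn.trial_io import resample_forces
        trial, _ = noisefree_trial
        raw = trial.forces_raw
        dec = resample_forces(raw, 200.0)
        cycle = (dec.time[0], dec.time[-1])  # common window for both records
        m_raw = estimate_body_mass(raw, cycle)
        m_dec = estimate_body_mass(dec, cycle)
        assert m_dec == pytest.approx(m_raw, rel=2e-3)


class TestSmoothing:
    def make_markers(self, y, rate=200.0):
        n = len(y)
        t = np.arange(n) / rate
        pos = np.column_stack([t * 0.0, y, np.zeros(n)])
        return MarkerSet(positions={"ilium": pos.copy(), "hip": pos.copy(),
                                    "knee": pos.copy(), "ankle": pos.copy(),
                                    "mtp": pos.copy(), "toe": pos.copy(),
                                    "tail": pos.copy()}, rate=rate, time=t)

    def test_linear_trajectory_unchanged(self):
        t = np.arange(100) / 200.0
        mk = self.make_markers(0.5 + 0.3 * t)
        sm = smooth_positions(mk, SmoothingSpec("gcv_spline"))
        np.testing.assert_allclose(sm.position("ankle")[:, 1], 0.5 + 0.3 * t,
                                   atol=1e-9)

    def test_quadratic_second_derivative(self):
        a = 4.0
        t = np.arange(200) / 200.0
        mk = self.make_markers(0.5 * a * t**2)
        sm = smooth_positions(mk, SmoothingSpec("fixed_spline", 0.0))
        acc = sm.acceleration("ankle")[5:-5, 1]
        np.testing.assert_allclose(acc, a, rtol=0.01)

    def test_noise_reduced_below_sigma(self):
        rng = np.random.default_rng(42)
        t = np.arange(300) / 200.0
        clean = 0.05 * np.sin(2 * np.pi * 2.0 * t)
        sigma = 0.002
        mk = self.make_markers(clean + rng.normal(0, sigma, len(t)))
        sm = smooth_positions(mk, SmoothingSpec("gcv_spline"))
        rms = np.sqrt(np.mean((sm.position("ankle")[:, 1] - clean) ** 2))
        assert rms < sigma

    def test_short_series_rejected(self):
        mk = self.make_markers(np.zeros(5))
        with pytest.raises(PipelineError, match="short_series"):
            smooth_positions(mk)


class TestTrialSpeed:
    def test_constant_translation(self, interp_config):
        t = np.arange(200) / 200.0
        v = 3.0
        pos = {m: np.column_stack([v * t, np.full_like(t, 0.7),
                                   np.zeros_like(t)])
               for m in ("ilium", "hip", "knee", "ankle", "mtp", "toe", "tail")}
        mk = MarkerSet(positions=pos, rate=200.0, time=t)
        sm = smooth_positions(mk, interp_config.smoothing)
        win = StanceWindow(0.4, 0.6, 1000.0, 20.0, 0.5)
        assert trial_speed(sm, win) == pytest.approx(3.0, abs=1e-9)

    def test_ballistic_aerial_phases_exact(self, interp_config):
        # projectile flight: constant horizontal velocity, parabolic vertical
        t = np.arange(240) / 200.0
        v = 2.8
        y = 0.9 - 0.5 * G * (t - 0.6) ** 2
        pos = {m: np.column_stack([v * t, y, np.zeros_like(t)])
               for m in ("ilium", "hip", "knee", "ankle", "mtp", "toe", "tail")}
        mk = MarkerSet(positions=pos, rate=200.0, time=t)
        sm = smooth_positions(mk, interp_config.smoothing)
        win = StanceWindow(0.5, 0.7, 1000.0, 20.0, 0.6)
        assert trial_speed(sm, win) == pytest.approx(v, abs=1e-9)

    def test_generator_speed_recovered(self, noisefree_trial, interp_config):
        trial, truth = noisefree_trial
        sm = smooth_positions(trial.markers, interp_config.smoothing)
        win = detect_stance(trial.forces)
        assert trial_speed(sm, win, trial.forward) == pytest.approx(
            truth.speed, abs=0.05)

    def test_no_aerial_samples(self, interp_config):
        t = np.arange(60) / 200.0
        pos = {m: np.column_stack([t, t * 0, t * 0])
               for m in ("ilium", "hip", "knee", "ankle", "mtp", "toe", "tail")}
        sm = smooth_positions(MarkerSet(positions=pos, rate=200.0, time=t),
                              interp_config.smoothing)
        win = StanceWindow(-1.0, 1.0, 100.0, 2.0, 0.0)
        with pytest.raises(PipelineError, match="no_aerial"):
            trial_speed(sm, win)


class TestStrideParameters:
    def test_two_contacts(self):
        t = np.arange(301) / 200.0
        x = 3.0 * t
        pos = {m: np.column_stack([x, np.zeros_like(t), np.zeros_like(t)])
               for m in ("ilium", "hip", "knee", "ankle", "mtp", "toe", "tail")}
        mk = MarkerSet(positions=pos, rate=200.0, time=t)
        # mid-stances 0.45 s apart; MTP advances 3.0 * 0.45 = 1.35 m
        s1 = StanceWindow(0.30, 0.50, 1000.0, 20.0, 0.40)
        s2 = StanceWindow(0.75, 0.95, 1000.0, 20.0, 0.85)
        out = stride_parameters(mk, [s1, s2], speed=3.0)
        assert out.stride_duration == pytest.approx(0.45)
        assert out.stride_frequency == pytest.approx(1 / 0.45)
        assert out.stride_length == pytest.approx(1.35, rel=1e-9)

    def test_single_contact_reports_contact_only(self, noisefree_trial):
        trial, _ = noisefree_trial
        win = detect_stance(trial.forces)
        out = stride_parameters(trial.markers, [win], speed=2.5)
        assert out.stride_length is None and out.stride_duration is None
        assert out.contact_duration == win.contact_duration

    def test_generator_stride_consistent_with_speed(self, noisefree_trial):
        # stitch two cycles of the same hop; length = speed * duration
        trial, truth = noisefree_trial
        t_cyc = len(trial.markers) / trial.markers.rate
        shift = truth.speed * t_cyc
        t = np.concatenate([trial.markers.time,
                            trial.markers.time + t_cyc])
        pos = {n: np.vstack([p, p + [shift, 0, 0]])
               for n, p in trial.markers.positions.items()}
        mk = MarkerSet(positions=pos, rate=trial.markers.rate, time=t)
        f = trial.forces_raw
        t2 = np.concatenate([f.time, f.time + t_cyc])
        rec = ForceRecord(grf=np.vstack([f.grf, f.grf]),
                          cop_x=np.concatenate([f.cop_x, f.cop_x + shift]),
                          rate=f.rate, time=t2)
        w1 = detect_stance(ForceRecord(grf=f.grf, cop_x=f.cop_x, rate=f.rate,
                                       time=f.time))
        w2 = StanceWindow(w1.start_time + t_cyc, w1.end_time + t_cyc,
                          w1.peak_vertical_force, w1.threshold,
                          w1.peak_time + t_cyc)
        out = stride_parameters(mk, [w1, w2], speed=truth.speed)
        assert out.stride_length == pytest.approx(
            truth.speed * out.stride_duration, rel=0.02)


class TestNormalizeGRF:
    def test_peak_arithmetic(self):
        # total (two-leg) peak of 941.8 N at 20 kg: per-leg peak 470.9 N,
        # i.e. 2.40 BW per leg, in the observed 1.4-3.7 BW range
        rec = half_sine_forces(peak=941.76, duration=0.30)
        win = detect_stance(rec)
        out = normalize_grf(rec, win, mass=20.0)
        assert out.peak_vertical_bw == pytest.approx(941.76 / 2 / (20 * G),
                                                     rel=1e-3)
        assert out.peak_vertical_bw == pytest.approx(2.40, abs=0.01)

    def test_zero_lateral_stays_zero(self):
        rec = half_sine_forces()
        win = detect_stance(rec)
        out = normalize_grf(rec, win, mass=20.0)
        assert np.all(out.grf_bw[:, 2] == 0.0)

    def test_generator_peak_recovered(self, noisefree_trial):
        trial, truth = noisefree_trial
        win = detect_stance(trial.forces)
        out = normalize_grf(trial.forces, win, truth.body_mass)
        assert out.peak_vertical_bw == pytest.approx(
            truth.peak_grf_bw_per_leg, abs=0.02)

    def test_mean_per_leg_force_over_cycle_is_half_bw(self, noisefree_trial):
        trial, truth = noisefree_trial
        f = trial.forces_raw
        mean_bw = np.trapezoid(f.fy, f.time) / (f.time[-1] - f.time[0]) / 2 \
            / (truth.body_mass * G)
        assert mean_bw == pytest.approx(0.5, rel=0.01)
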