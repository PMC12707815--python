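"""Limb model construction and Newton-Euler inverse dynamics oracles."""

import numpy as np
import pytest

from hopdyn.config import G, SegmentFractions
from hopdyn.dynamics import (LimbModel, Segment, build_limb_model,
                             cylinder_inertia, inverse_dynamics,
                             newton_euler_planar, normalize_moment)
from hopdyn.errors import PipelineError
from hopdyn.preprocess import StanceWindow, detect_stance, smooth_positions
from hopdyn.trial_io import ForceRecord, MarkerSet

from conftest import static_markers

LENGTHS = {"pelvis": 0.12, "thigh": 0.22, "shank": 0.30,
           "metatarsus": 0.24, "phalanges": 0.11}


class TestBuildLimbModel:
    def test_cylinder_inertia_example(self):
        model = build_limb_model(20.0, LENGTHS)
        shank = model.segments["shank"]
        assert shank.mass == pytest.approx(0.9)
        # I = m (L^2/12 + rho^2/4), rho = 0.1 L = 0.03 m
        assert shank.inertia == pytest.approx(
            0.9 * (0.09 / 12 + 0.0009 / 4), rel=1e-12)

    def test_zero_radius_is_thin_rod(self):
        frac = SegmentFractions(radius_fraction=0.0)
        model = build_limb_model(20.0, LENGTHS, frac)
        shank = model.segments["shank"]
        assert shank.inertia == pytest.approx(shank.mass * 0.3**2 / 12)

    def test_mass_linearity(self):
        a = build_limb_model(20.0, LENGTHS)
        b = build_limb_model(40.0, LENGTHS)
        for seg in a.segments:
            assert b.segments[seg].mass == pytest.approx(
                2 * a.segments[seg].mass)
            assert b.segments[seg].inertia == pytest.approx(
                2 * a.segments[seg].inertia)

    def test_implausible_fractions_rejected(self):
        frac = SegmentFractions(thigh=0.3, shank=0.15, metatarsus=0.04,
                                phalanges=0.01)
        with pytest.raises(PipelineError, match="implausible_fractions"):
            build_limb_model(20.0, LENGTHS, frac)


STATIC_POSE = {"ilium": (0.90, 0.75), "hip": (0.88, 0.63),
               "knee": (1.01, 0.51), "ankle": (0.90, 0.25),
               "mtp": (1.05, 0.06), "toe": (1.16, 0.05),
               "tail": (0.75, 0.80)}


def static_force_record(n, rate, fy, cop_x, fx=0.0):
    t = np.arange(n) / rate
    grf = np.tile([fx, fy, 0.0], (n, 1))
    return ForceRecord(grf=grf, cop_x=np.full(n, cop_x), rate=rate, time=t)


def zero_mass_model():
    frac = SegmentFractions(thigh=0.0, shank=0.0, metatarsus=0.0,
                            phalanges=0.0)
    return build_limb_model(20.0, LENGTHS, frac)


class TestStaticLimits:
    def test_massless_static_ankle_moment_is_force_times_R(self, interp_config):
        mk = static_markers(STATIC_POSE)
        sm = smooth_positions(mk, interp_config.smoothing)
        F, cop = 800.0, 1.00
        forces = static_force_record(len(mk), mk.rate, F, cop)
        win = StanceWindow(0.0, mk.time[-1], F, 0.02 * F, 0.1)
        moments = inverse_dynamics(zero_mass_model(), sm, forces, win,
                                   leg_share=1.0)
        R = abs(STATIC_POSE["ankle"][0] - cop)
        np.testing.assert_allclose(moments.moments["ankle"], F * R, rtol=1e-9)

    def test_plantarflexor_moment_positive_when_cop_ahead(self, interp_config):
        mk = static_markers(STATIC_POSE)
        sm = smooth_positions(mk, interp_config.smoothing)
        forces = static_force_record(len(mk), mk.rate, 800.0, 1.00)
        win = StanceWindow(0.0, mk.time[-1], 800.0, 16.0, 0.1)
        moments = inverse_dynamics(zero_mass_model(), sm, forces, win,
                                   leg_share=1.0)
        assert np.all(moments.moments["ankle"] > 0)

    def test_full_mass_static_torque_balance(self, interp_config):
        """With zero accelerations the ankle moment equals the moment of the
        GRF plus distal segment weights about the ankle (direct oracle)."""
        mk = static_markers(STATIC_POSE)
        sm = smooth_positions(mk, interp_config.smoothing)
        model = build_limb_model(20.0, LENGTHS)
        F, cop = 800.0, 1.00
        forces = static_force_record(len(mk), mk.rate, F, cop)
        win = StanceWindow(0.0, mk.time[-1], F, 16.0, 0.1)
        moments = inverse_dynamics(model, sm, forces, win, leg_share=1.0)
        ankle = np.array(STATIC_POSE["ankle"])
        # oracle: torque balance of the foot free body about the ankle
        tau = (cop - ankle[0]) * F - (0.0 - ankle[1]) * 0.0
        for seg, (pm, dm) in (("metatarsus", ("mtp", "ankle")),
                              ("phalanges", ("toe", "mtp"))):
            prox = np.array(STATIC_POSE[dm]) if seg == "metatarsus" else \
                np.array(STATIC_POSE["mtp"])
            dist = np.array(STATIC_POSE["mtp"]) if seg == "metatarsus" else \
                np.array(STATIC_POSE["toe"])
            com = prox + model.segments[seg].com_fraction * (dist - prox)
            tau += (com[0] - ankle[0]) * (-model.segments[seg].mass * G)
        np.testing.assert_allclose(moments.moments["ankle"], abs(tau),
                                   rtol=1e-9)

    def test_zero_masses_reduce_to_grf_cross_product(self, noisefree_trial,
                                                     interp_config):
        """Quasi-static equivalence on a dynamic trial."""
        trial, _ = noisefree_trial
        sm = smooth_positions(trial.markers, interp_config.smoothing)
        win = detect_stance(trial.forces)
        moments = inverse_dynamics(zero_mass_model(), sm, trial.forces, win,
                                   forward=trial.forward)
        t = moments.time
        fx = np.interp(t, trial.forces.time, trial.forces.grf[:, 0]) / 2
        fy = np.interp(t, trial.forces.time, trial.forces.fy) / 2
        loaded = ~np.isnan(trial.forces.cop_x)
        cop = np.interp(t, trial.forces.time[loaded],
                        trial.forces.cop_x[loaded])
        for joint, marker in (("ankle", "ankle"), ("knee", "knee")):
            p = np.column_stack(
                [np.interp(t, sm.time, trial.markers.positions[marker][:, 0]),
                 np.interp(t, sm.time, trial.markers.positions[marker][:, 1])])
            tau = (cop - p[:, 0]) * fy - (0.0 - p[:, 1]) * fx
            np.testing.assert_allclose(np.abs(moments.moments[joint]),
                                       np.abs(tau), rtol=1e-6, atol=1e-9)


class TestPendulumOracle:
    def test_pinned_rod_closed_form(self):
        """Uniform rod pinned at one end, horizontal, constant angular
        acceleration: pin moment = (m L^2/3) alpha + m g L/2."""
        m_rod, L, alpha = 1.4, 0.30, 12.0
        seg = {name: Segment(length=L, mass=0.0, com_fraction=0.5, inertia=0.0)
               for name in ("phalanges", "metatarsus", "shank", "thigh")}
        seg["shank"] = Segment(length=L, mass=m_rod, com_fraction=0.5,
                               inertia=cylinder_inertia(m_rod, L, 0.0))
        model = LimbModel(segments=seg, body_mass=m_rod)
        n = 5
        # rod horizontal (theta = 0), rotating with omega = 0, alpha > 0;
        # the knee is the pin, the ankle the free end
        pin = np.array([0.0, 0.0])
        pos = {"knee": np.tile(pin, (n, 1)),
               "ankle": np.tile([L, 0.0], (n, 1)),
               "hip": np.tile([-0.1, 0.3], (n, 1)),
               "toe": np.tile([L + 0.2, -0.1], (n, 1)),
               "mtp": np.tile([L + 0.1, 0.0], (n, 1))}
        vel = {k: np.zeros((n, 2)) for k in pos}
        acc = {k: np.zeros((n, 2)) for k in pos}
        # free-end kinematics of rotation about the pin at theta=omega=0:
        # a = alpha x r => (0, alpha L) at the ankle
        acc["ankle"] = np.tile([0.0, alpha * L], (n, 1))
        raw = newton_euler_planar(pos, vel, acc, model,
                                  ext_force=np.zeros((n, 2)),
                                  ext_point=np.tile([L + 0.2, -0.1], (n, 1)))
        expected = (m_rod * L**2 / 3) * alpha + m_rod * G * L / 2
        np.testing.assert_allclose(raw["knee"], expected, rtol=1e-6)


class TestInvariances:
    def test_origin_invariance(self, noisefree_trial, interp_config):
        trial, _ = noisefree_trial
        sm = smooth_positions(trial.markers, interp_config.smoothing)
        win = detect_stance(trial.forces)
        model = build_limb_model(20.0, LENGTHS)
        a = inverse_dynamics(model, sm, trial.forces, win, trial.forward)
        shift = np.array([5.0, 0.0, -3.0])
        mk = MarkerSet(positions={n: p + shift
                                  for n, p in trial.markers.positions.items()},
                       rate=trial.markers.rate, time=trial.markers.time)
        f = trial.forces
        # the CoP shifts with the fore-aft origin
        f2 = ForceRecord(grf=f.grf, cop_x=f.cop_x + shift[0], rate=f.rate,
                         time=f.time)
        sm2 = smooth_positions(mk, interp_config.smoothing)
        b = inverse_dynamics(model, sm2, f2, win, trial.forward)
        for joint in a.moments:
            np.testing.assert_allclose(a.moments[joint], b.moments[joint],
                                       atol=1e-8)

    def test_tendon_force_single_source_of_truth(self, noisefree_trial,
                                                 interp_config, profile):
        """ankle moment / r equals the energetics tendon force."""
        from hopdyn.energetics import tendon_force
        from hopdyn.pipeline import analyze_trial
        trial, _ = noisefree_trial
        res = analyze_trial(trial, interp_config)
        r = np.interp(res.moments.time, res.stance.grid_times(), res.ema.r)
        expected = np.maximum(res.moments.moments["ankle"], 0.0) / r
        np.testing.assert_allclose(res.stress.force_n, expected, rtol=1e-12)


class TestNormalizeMoment:
    def test_worked_example(self):
        from hopdyn.dynamics import JointMomentSeries
        series = JointMomentSeries(time=np.array([0.0]),
                                   moments={"ankle": np.array([40.0])})
        out = normalize_moment(series, 20.0, 0.70)
        assert out["ankle"][0] == pytest.approx(40 / (20 * G * 0.70), rel=1e-9)
        assert out["ankle"][0] == pytest.approx(0.2913, abs=2e-4)

    def test_zero_maps_to_zero(self):
        from hopdyn.dynamics import JointMomentSeries
        series = JointMomentSeries(time=np.array([0.0]),
                                   moments={"hip": np.array([0.0])})
        assert normalize_moment(series, 15.0, 0.8)["hip"][0] == 0.0

    def test_dimensionless_scale_invariance(self):
        """Scaling forces/moments with c m and masses with c leaves the
        dimensionless moment unchanged."""
        from hopdyn.dynamics import JointMomentSeries
        rng = np.random.default_rng(0)
        m_arr = rng.uniform(10, 60, 8)
        for c in (0.5, 2.0, 7.3):
            base = JointMomentSeries(time=np.arange(8.0),
                                     moments={"ankle": m_arr})
            scaled = JointMomentSeries(time=np.arange(8.0),
                                       moments={"ankle": m_arr * c})
            a = normalize_moment(base, 20.0, 0.7)["ankle"]
            b = normalize_moment(scaled, 20.0 * c, 0.7)["ankle"]
            np.testing.assert_allclose(a, b, rtol=1e-12)
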