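"""Synthetic hopping-trial generator with full ground truth.

The generator produces one complete hop cycle (half flight - stance - half
flight) of a SLIP-like hopper, built so that every stage of the analysis
pipeline can be validated without animal data:

* vertical GRF is a half-sine over stance whose impulse balances body
  weight over the cycle, so flight duration follows from the chosen peak
  force; fore-aft GRF is a braking-then-propulsion sine wave with zero net
  impulse;
* the pelvis follows the trajectory obtained by integrating those forces
  (ballistic in flight), so speed and impulse-based mass estimates have
  exact known values;
* joint angles follow C1 cosine segments through touchdown / midstance /
  toe-off values (maximally crouched at midstance) and markers come from
  planar forward kinematics down the chain;
* the centre of pressure travels linearly fore-aft across the foot, which
  makes its boxcar-decimated view exact;
* ground truth (angles, angular velocities, moments, powers, work, r, R,
  EMA, tendon stress) is evaluated by the generator's own code on the
  noise-free signals.  Truth moments use the same Newton-Euler formulas as
  the analysis but an independently written evaluation on cubic-spline
  kinematics; truth forces on the marker clock are the boxcar-averaged view
  of the 1000 Hz record, i.e. exactly what a synchronised acquisition
  delivers.

Marker noise (additive Gaussian, seeded) emulates motion-capture jitter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .config import G, MomentArmConfig, PipelineConfig, SegmentFractions
from .dynamics import LimbModel, build_limb_model
from .errors import PipelineError
from .leverage import MomentArmProfile
from .trial_io import (ForceRecord, MarkerSet, Trial, TrialMetadata,
                       resample_forces, write_force_csv, write_trc)

REF_MASS = 20.0  # kg, reference subject
REF_SEGMENTS = {  # m, reference segment lengths (20 kg subject)
    "pelvis": 0.12, "thigh": 0.22, "shank": 0.30,
    "metatarsus": 0.24, "phalanges": 0.11,
}
#: world angle (deg) of the ilium->hip segment, constant over the hop
PELVIS_DIR_DEG = -100.0
#: chain chirality at (hip, knee, ankle, mtp): the sign of the rotation from
#: the proximal to the distal segment vector (the limb's zig-zag)
CHIRALITY = {"hip": -1, "knee": 1, "ankle": -1, "mtp": -1}

JOINT_ORDER = ("hip", "knee", "ankle", "mtp")


def default_contact_time(speed: float) -> float:
    """Contact-time rule t_c = 0.42 - 0.05 v (s): contacts shorten with
    speed, spanning ~0.2-0.32 s over 2-4.5 m/s."""
    return 0.42 - 0.05 * speed


def default_peak_grf_bw(speed: float) -> float:
    """Per-leg peak vertical GRF rule 1.0 + 0.45 v (BW): ~1.9 BW at 2 m/s to
    ~3.0 BW at 4.5 m/s, mean ~2.4 BW near 3.1 m/s."""
    return 1.0 + 0.45 * speed


def default_waveforms(speed: float) -> Dict[str, Tuple[float, float, float]]:
    """(touchdown, midstance, toe-off) included angles, degrees.

    The distal joints carry the speed effects: the ankle lands less
    plantarflexed and dorsiflexes further at midstance in faster hops
    (115 deg at the slowest speeds down to ~76 deg at the fastest), and the
    MTP plantarflexes more before midstance at speed.  Proximal joints
    change little.
    """
    dv = speed - 2.5
    ankle_mid = float(np.clip(112.0 - 14.0 * dv, 76.0, 115.0))
    return {
        "hip": (140.0, 130.0, 150.0),
        "knee": (127.0, 96.0, 112.0),
        "ankle": (130.0 - 4.0 * dv, ankle_mid, 150.0),
        "mtp": (137.0, 125.0 + 4.0 * dv, 150.0),
    }


#: stance fraction at which each joint reaches its midstance value; the
#: distal joints peak slightly before 50% (maximum ankle dorsiflexion near
#: 44% of stance), so tendon recoil overlaps the high-force phase
DEFAULT_APEX_FRAC = {"hip": 0.5, "knee": 0.5, "ankle": 0.44, "mtp": 0.44}


@dataclass
class SyntheticTrialSpec:
    """Conditions of one synthetic hop."""

    body_mass: float = REF_MASS  # kg
    speed: float = 3.1  # m/s
    stance_duration: Optional[float] = None  # s; default from contact rule
    flight_duration: Optional[float] = None  # s; default from impulse balance
    peak_grf_bw: Optional[float] = None  # per leg; default from force rule
    horizontal_grf_ratio: Optional[float] = None  # fixed fore-aft amplitude /
    # vertical peak; None (default) directs the GRF from the CoP toward the
    # pelvis marker (SLIP-like), with a zero-net-impulse correction
    waveforms: Optional[Dict[str, Tuple[float, float, float]]] = None
    apex_frac: Optional[Dict[str, float]] = None  # stance fraction of the
    # midstance knot per joint; default DEFAULT_APEX_FRAC
    marker_noise_sigma: float = 0.001  # m, typical optical capture jitter
    force_noise_sigma: float = 0.0  # N
    seed: int = 0
    trial_id: str = ""
    animal_id: str = "synth"

    def resolve(self) -> "SyntheticTrialSpec":
        """Fill rule-based defaults and check dynamic feasibility."""
        spec = dataclasses.replace(self)
        if spec.stance_duration is None:
            spec.stance_duration = default_contact_time(spec.speed)
        if spec.peak_grf_bw is None:
            spec.peak_grf_bw = default_peak_grf_bw(spec.speed)
        if not spec.stance_duration > 0:
            raise PipelineError("infeasible_spec", "stance_duration <= 0")
        if spec.peak_grf_bw <= np.pi / 4:
            raise PipelineError(
                "infeasible_spec",
                f"per-leg peak {spec.peak_grf_bw:.2f} BW <= pi/4: the "
                "half-sine impulse cannot support body weight")
        t_fl = spec.stance_duration * (4.0 * spec.peak_grf_bw / np.pi - 1.0)
        if spec.flight_duration is None:
            spec.flight_duration = t_fl
        elif abs(spec.flight_duration - t_fl) > 1e-6:
            raise PipelineError(
                "infeasible_spec",
                f"flight {spec.flight_duration:.4f} s inconsistent with "
                f"impulse balance (requires {t_fl:.4f} s)")
        if spec.waveforms is None:
            spec.waveforms = default_waveforms(spec.speed)
        if spec.apex_frac is None:
            spec.apex_frac = dict(DEFAULT_APEX_FRAC)
        if not spec.trial_id:
            spec.trial_id = f"synth_{spec.seed:05d}"
        return spec


def scaled_segments(body_mass: float) -> Dict[str, float]:
    """Geometrically scaled segment lengths: L ~ mass^(1/3)."""
    k = (body_mass / REF_MASS) ** (1.0 / 3.0)
    return {name: L * k for name, L in REF_SEGMENTS.items()}


# ---------------------------------------------------------------------------
# waveform and trajectory primitives
# ---------------------------------------------------------------------------

def _cosine_segment(s: np.ndarray, a: float, b: float) -> np.ndarray:
    """C1 blend from a (s=0) to b (s=1) with zero end slopes."""
    return a + (b - a) * 0.5 * (1.0 - np.cos(np.pi * np.clip(s, 0, 1)))


def _cosine_segment_rate(s: np.ndarray, a: float, b: float,
                         duration: float) -> np.ndarray:
    s = np.clip(s, 0, 1)
    return (b - a) * 0.5 * np.pi * np.sin(np.pi * s) / duration


class _AngleWaveform:
    """Periodic C1 joint-angle trajectory through TD/mid/TO knots.

    ``apex`` is the stance fraction at which the midstance value is reached.
    """

    def __init__(self, td: float, mid: float, to: float,
                 t_td: float, t_c: float, t_cycle: float, apex: float = 0.5):
        self.td, self.mid, self.to = td, mid, to
        self.t_td, self.t_c, self.t_cycle = t_td, t_c, t_cycle
        self.t_to = t_td + t_c
        self.t_air = t_cycle - t_c
        self.apex = apex

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        s = (t - self.t_td) / self.t_c
        f = self.apex
        out = np.where(
            s < f, _cosine_segment(s / f, self.td, self.mid),
            _cosine_segment((s - f) / (1 - f), self.mid, self.to))
        aerial = (s < 0) | (s > 1)
        u = ((t - self.t_to) % self.t_cycle) / self.t_air
        out = np.where(aerial, _cosine_segment(u, self.to, self.td), out)
        return out

    def rate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        s = (t - self.t_td) / self.t_c
        f = self.apex
        out = np.where(
            s < f,
            _cosine_segment_rate(s / f, self.td, self.mid, f * self.t_c),
            _cosine_segment_rate((s - f) / (1 - f), self.mid, self.to,
                                 (1 - f) * self.t_c))
        aerial = (s < 0) | (s > 1)
        u = ((t - self.t_to) % self.t_cycle) / self.t_air
        out = np.where(
            aerial, _cosine_segment_rate(u, self.to, self.td, self.t_air), out)
        return out


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Generator-side ground truth on the 200 Hz marker clock."""

    time: np.ndarray
    stance_start: float
    stance_end: float
    speed: float
    body_mass: float
    peak_grf_bw_per_leg: float
    angles_deg: Dict[str, np.ndarray]
    omega: Dict[str, np.ndarray]  # rad/s, d(included angle)/dt
    grf_exact: np.ndarray  # (n, 3) analytic total GRF at marker times
    grf_boxcar: np.ndarray  # (n, 3) boxcar view of the 1000 Hz record
    cop_x: np.ndarray
    moments: Dict[str, np.ndarray]  # N m, extensor-positive, marker clock
    powers: Dict[str, np.ndarray]  # W
    work: Dict[str, Tuple[float, float, float]]  # (pos, neg, net) J/kg
    r: np.ndarray  # m, NaN outside stance
    R: np.ndarray
    ema: np.ndarray
    crouch_factor: np.ndarray
    min_cf: float
    min_cf_pct_stance: float
    tendon_csa_m2: float
    peak_stress_mpa: float
    safety_factor: float
    segment_lengths: Dict[str, float]
    seed: int

    def stance_mask(self) -> np.ndarray:
        return (self.time >= self.stance_start) & (self.time <= self.stance_end)


# ---------------------------------------------------------------------------
# independent truth evaluation helpers
# ---------------------------------------------------------------------------

def _x2(a, b):
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _truth_newton_euler(pos, vel, acc, model: LimbModel, ext_force, ext_point):
    """Generator-side Newton-Euler pass (same formulas as the analysis,
    written separately; operates on exact spline kinematics)."""
    chain = (("phalanges", "toe", "mtp", "mtp"),
             ("metatarsus", "mtp", "ankle", "ankle"),
             ("shank", "ankle", "knee", "knee"),
             ("thigh", "knee", "hip", "hip"))
    g_vec = np.array([0.0, -G])
    f_d = ext_force.copy()
    m_d = np.zeros(len(ext_force))
    p_d = ext_point.copy()
    out = {}
    for seg_name, dm, pm, joint in chain:
        seg = model.segments[seg_name]
        f = seg.com_fraction
        com = pos[pm] + f * (pos[dm] - pos[pm])
        a_com = acc[pm] + f * (acc[dm] - acc[pm])
        w = pos[dm] - pos[pm]
        wd = vel[dm] - vel[pm]
        wdd = acc[dm] - acc[pm]
        n2 = np.einsum("ij,ij->i", w, w)
        om = _x2(w, wd) / n2
        al = _x2(w, wdd) / n2 - 2 * np.einsum("ij,ij->i", w, wd) * om / n2
        f_p = seg.mass * (a_com - g_vec) - f_d
        m_p = (seg.inertia * al - m_d - _x2(pos[pm] - com, f_p)
               - _x2(p_d - com, f_d))
        out[joint] = m_p
        f_d, m_d, p_d = -f_p, -m_p, pos[pm]
    return out


def _decompose_work(power: np.ndarray, time: np.ndarray, mass: float):
    """Positive/negative/net work with interpolated zero crossings, J/kg."""
    ts, ps = [time[0]], [power[0]]
    for i in range(1, len(time)):
        if power[i - 1] * power[i] < 0:
            tc = time[i - 1] - power[i - 1] * (time[i] - time[i - 1]) / (
                power[i] - power[i - 1])
            ts.append(tc)
            ps.append(0.0)
        ts.append(time[i])
        ps.append(power[i])
    ts, ps = np.asarray(ts), np.asarray(ps)
    seg = 0.5 * (ps[1:] + ps[:-1]) * np.diff(ts)
    pos = float(seg[seg > 0].sum()) / mass
    neg = float(seg[seg < 0].sum()) / mass
    return pos, neg, pos + neg


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def generate_trial(spec: SyntheticTrialSpec,
                   limb: Optional[LimbModel] = None,
                   profile: Optional[MomentArmProfile] = None,
                   config: Optional[PipelineConfig] = None
                   ) -> Tuple[Trial, SyntheticTruth]:
    """Generate one dynamically balanced hop with full ground truth."""
    spec = spec.resolve()
    config = config or PipelineConfig()
    profile = profile or MomentArmProfile(config.moment_arm)
    lengths = scaled_segments(spec.body_mass)
    if limb is None:
        limb = build_limb_model(spec.body_mass, lengths, config.fractions)
    else:
        lengths = {name: seg.length for name, seg in limb.segments.items()}

    m = spec.body_mass
    t_c = spec.stance_duration
    t_air = spec.flight_duration
    t_cycle = t_c + t_air
    t_td = t_air / 2.0
    t_to = t_td + t_c
    p_leg = spec.peak_grf_bw
    p_tot = 2.0 * p_leg * m * G  # total half-sine peak, N

    dt_m = 1.0 / config.marker_rate
    n_m = int(round(t_cycle / dt_m))
    t_m = np.arange(n_m) * dt_m
    dt_f = 1.0 / config.force_rate
    n_f = int(round(t_cycle / dt_f))
    t_f = np.arange(n_f) * dt_f

    s_f = (t_f - t_td) / t_c
    on_f = (s_f >= 0) & (s_f <= 1)
    sc_f = np.clip(s_f, 0.0, 1.0)
    fy_f = np.where(on_f, p_tot * np.sin(np.pi * sc_f), 0.0)

    def pelvis_y(t):
        """Vertical pelvis trajectory: apex at t=0, half-sine loading.

        Closed-form double integral of a_y = -g + (p_tot/m) sin(pi s) with
        s the stance fraction; the 2*(t - t_to) term carries the velocity
        gained over stance into the second flight phase.
        """
        t = np.asarray(t, float)
        tau = np.clip(t - t_td, 0.0, t_c)
        s = tau / t_c
        load = tau - (t_c / np.pi) * np.sin(np.pi * s) \
            + 2.0 * np.maximum(t - t_to, 0.0)
        return -0.5 * G * t**2 + (p_tot / m) * (t_c / np.pi) * load

    waves = {j: _AngleWaveform(*spec.waveforms[j], t_td=t_td, t_c=t_c,
                               t_cycle=t_cycle,
                               apex=spec.apex_frac.get(j, 0.5))
             for j in JOINT_ORDER}

    seg_of_joint = {"hip": "thigh", "knee": "shank",
                    "ankle": "metatarsus", "mtp": "phalanges"}
    marker_of_seg = {"thigh": "knee", "shank": "ankle",
                     "metatarsus": "mtp", "phalanges": "toe"}

    def chain_offsets(t):
        """Marker positions relative to the ilium (forward kinematics)."""
        t = np.asarray(t, float)
        pts = {"ilium": np.zeros((len(t), 2))}
        phi = np.full(len(t), np.radians(PELVIS_DIR_DEG))
        cur = lengths["pelvis"] * np.column_stack([np.cos(phi), np.sin(phi)])
        pts["hip"] = cur
        for joint in JOINT_ORDER:
            theta = np.radians(waves[joint](t))
            phi = phi + np.pi + CHIRALITY[joint] * theta
            seg = seg_of_joint[joint]
            cur = cur + lengths[seg] * np.column_stack([np.cos(phi), np.sin(phi)])
            pts[marker_of_seg[seg]] = cur
        return pts

    # ground level: lowest toe point during stance sits on the plate, with
    # the vertical pelvis trajectory fixed by the dynamics
    off_m = chain_offsets(t_m)
    stance_m = (t_m >= t_td) & (t_m <= t_to)
    y_pelvis_m = pelvis_y(t_m)
    y_shift = -(y_pelvis_m[stance_m] + off_m["toe"][stance_m, 1]).min()

    def ilium_y(t):
        return pelvis_y(t) + y_shift

    # ------------------------------------------------------------------
    # fore-aft force: either a fixed-ratio braking/propulsion sine or a
    # SLIP-like force directed from the CoP toward the pelvis marker.  The
    # pelvis fore-aft trajectory and the directed force depend on each
    # other weakly, so a few fixed-point iterations suffice.
    # ------------------------------------------------------------------
    from scipy.integrate import cumulative_trapezoid

    if spec.horizontal_grf_ratio is not None:
        fx_f = np.where(on_f, -spec.horizontal_grf_ratio * p_tot
                        * np.sin(2 * np.pi * sc_f), 0.0)
    else:
        fx_f = np.where(on_f, -0.2 * p_tot * np.sin(2 * np.pi * sc_f), 0.0)

    y_il_f = ilium_y(t_f)
    t_mid = 0.5 * (t_td + t_to)
    # the centre of pressure emulates a planted foot rolling heel-to-toe:
    # it travels l_roll fore-aft, centred under the pelvis at midstance,
    # linearly in time (=> exact under boxcar decimation)
    l_roll = 0.6 * (lengths["metatarsus"] + lengths["phalanges"])

    def integrate_x(fx):
        vx = spec.speed + cumulative_trapezoid(fx / m, t_f, initial=0.0)
        return cumulative_trapezoid(vx, t_f, initial=0.0)

    x_il_f = integrate_x(fx_f)
    cop_mid = np.interp(t_mid, t_f, x_il_f)
    if spec.horizontal_grf_ratio is None:
        for _ in range(6):
            cop_mid = np.interp(t_mid, t_f, x_il_f)
            cop_iter = cop_mid + (sc_f - 0.5) * l_roll
            with np.errstate(invalid="ignore", divide="ignore"):
                fx_new = np.where(on_f,
                                  fy_f * (x_il_f - cop_iter) / y_il_f, 0.0)
            # remove net fore-aft impulse with a vertical-profile-shaped
            # correction (keeps end points at zero)
            jx = np.trapezoid(fx_new, t_f)
            jy = np.trapezoid(fy_f, t_f)
            fx_new = fx_new - fy_f * (jx / jy)
            x_new = integrate_x(fx_new)
            done = np.max(np.abs(x_new - x_il_f)) < 1e-10
            fx_f, x_il_f = fx_new, x_new
            if done:
                break
        cop_mid = np.interp(t_mid, t_f, x_il_f)

    x_il_spline = CubicSpline(t_f, x_il_f)

    def ilium_xy(t):
        t = np.asarray(t, float)
        return np.column_stack([x_il_spline(t), ilium_y(t)])

    def chain_markers(t):
        base = ilium_xy(t)
        return {name: base + off for name, off in chain_offsets(t).items()}

    pts_m = chain_markers(t_m)

    def cop_of(t):
        s = np.clip((np.asarray(t, float) - t_td) / t_c, 0, 1)
        return cop_mid + (s - 0.5) * l_roll

    grf_f = np.column_stack([fx_f, fy_f, np.zeros_like(fy_f)])
    cop_f = np.where(on_f, cop_of(t_f), np.nan)

    # ------------------------------------------------------------------
    # ground truth (noise-free)
    # ------------------------------------------------------------------
    raw_forces = ForceRecord(grf=grf_f.copy(), cop_x=cop_f.copy(),
                             rate=config.force_rate, time=t_f)
    boxcar = resample_forces(raw_forces, config.marker_rate,
                             config.contact_floor_n)
    nb = min(n_m, len(boxcar.time))
    grf_box = boxcar.grf[:nb]
    cop_box = boxcar.cop_x[:nb]
    t_m = t_m[:nb]
    pts_m = {k: v[:nb] for k, v in pts_m.items()}
    stance_m = stance_m[:nb]

    angles = {j: waves[j](t_m) for j in JOINT_ORDER}
    s_m = np.clip((t_m - t_td) / t_c, 0.0, 1.0)
    grf_exact = np.column_stack([
        np.interp(t_m, t_f, fx_f),
        np.where(stance_m, p_tot * np.sin(np.pi * s_m), 0.0),
        np.zeros(len(t_m))])

    # spline kinematics of the noise-free markers (the truth differentiation)
    spl = {name: [CubicSpline(t_m, p[:, k]) for k in range(2)]
           for name, p in pts_m.items()}
    vel = {n: np.column_stack([s[0](t_m, 1), s[1](t_m, 1)]) for n, s in spl.items()}
    acc = {n: np.column_stack([s[0](t_m, 2), s[1](t_m, 2)]) for n, s in spl.items()}

    # joint angular velocities of the sampled marker data (spline identity):
    # this, not the analytic waveform rate, is the truth for the 200 Hz
    # record, since sampling cannot see the sub-sample waveform kinks
    triplets = {"hip": ("ilium", "hip", "knee"),
                "knee": ("hip", "knee", "ankle"),
                "ankle": ("knee", "ankle", "mtp"),
                "mtp": ("ankle", "mtp", "toe")}
    omega = {}
    for j, (a, b, c) in triplets.items():
        u, v = pts_m[a] - pts_m[b], pts_m[c] - pts_m[b]
        du, dv = vel[a] - vel[b], vel[c] - vel[b]
        chi = np.arctan2(_x2(u, v), np.einsum("ij,ij->i", u, v))
        sgn = np.where(chi >= 0, 1.0, -1.0)
        om_u = _x2(u, du) / np.einsum("ij,ij->i", u, u)
        om_v = _x2(v, dv) / np.einsum("ij,ij->i", v, v)
        omega[j] = sgn * (om_v - om_u)

    cop_filled = np.where(np.isnan(cop_box), np.nanmean(cop_box), cop_box)
    ext_force = 0.5 * grf_box[:, :2]
    ext_point = np.column_stack([cop_filled, np.zeros(nb)])
    raw_m = _truth_newton_euler(pts_m, vel, acc, limb, ext_force, ext_point)
    moments = {j: CHIRALITY[j] * raw_m[j] for j in JOINT_ORDER}

    powers = {j: moments[j] * omega[j] for j in JOINT_ORDER}
    work = {}
    sl = np.flatnonzero(stance_m)
    for j in JOINT_ORDER:
        work[j] = _decompose_work(powers[j][sl], t_m[sl], m)

    # leverage truth
    scale = profile.subject_scale(lengths["shank"])
    r = np.where(stance_m, scale * profile(np.clip(angles["ankle"],
                                                   profile.config.angle_min_deg,
                                                   profile.config.angle_max_deg)),
                 np.nan)
    thr = 0.02 * np.nanmax(grf_box[:, 1])
    R = np.full(nb, np.nan)
    ema = np.full(nb, np.nan)
    for i in range(nb):
        fx, fy = 0.5 * grf_box[i, 0], 0.5 * grf_box[i, 1]
        if grf_box[i, 1] > thr and not np.isnan(cop_box[i]):
            norm = np.hypot(fx, fy)
            dx = pts_m["ankle"][i, 0] - cop_box[i]
            dy = pts_m["ankle"][i, 1]
            R[i] = abs(dx * fy - dy * fx) / norm
            ema[i] = r[i] / R[i]

    # tendon truth
    from .energetics import tendon_csa
    csa = tendon_csa(m, config.tendon.csa_a, config.tendon.csa_b)
    with np.errstate(invalid="ignore"):
        force_t = np.where(stance_m & ~np.isnan(r),
                           np.maximum(moments["ankle"], 0.0) / r, 0.0)
    peak_stress = float(np.nanmax(force_t) / csa / 1e6)
    safety = config.tendon.failure_stress_mpa / peak_stress

    # crouch truth
    total_len = sum(lengths.values())
    cf = np.linalg.norm(pts_m["toe"] - pts_m["ilium"], axis=1) / total_len
    cf_st = cf[sl]
    i_min = int(np.argmin(cf_st))
    min_cf = float(cf_st[i_min])
    min_cf_pct = float(100.0 * (t_m[sl][i_min] - t_td) / t_c)

    truth = SyntheticTruth(
        time=t_m, stance_start=t_td, stance_end=t_to, speed=spec.speed,
        body_mass=m, peak_grf_bw_per_leg=p_leg,
        angles_deg=angles, omega=omega, grf_exact=grf_exact, grf_boxcar=grf_box,
        cop_x=cop_box, moments=moments, powers=powers, work=work,
        r=r, R=R, ema=ema, crouch_factor=cf, min_cf=min_cf,
        min_cf_pct_stance=min_cf_pct, tendon_csa_m2=csa,
        peak_stress_mpa=peak_stress, safety_factor=safety,
        segment_lengths=dict(lengths), seed=spec.seed)

    # ------------------------------------------------------------------
    # observed trial (seeded noise)
    # ------------------------------------------------------------------
    rng = np.random.default_rng(spec.seed)
    positions = {}
    for name, p in pts_m.items():
        p3 = np.column_stack([p[:, 0], p[:, 1], np.zeros(nb)])
        if spec.marker_noise_sigma > 0:
            p3 = p3 + rng.normal(0.0, spec.marker_noise_sigma, p3.shape)
        positions[name] = p3
    # tail marker: constant offset behind/above the ilium
    tail = pts_m["ilium"] + np.array([-0.15, 0.05]) * (m / REF_MASS) ** (1 / 3)
    tail3 = np.column_stack([tail[:, 0], tail[:, 1], np.zeros(nb)])
    if spec.marker_noise_sigma > 0:
        tail3 = tail3 + rng.normal(0.0, spec.marker_noise_sigma, tail3.shape)
    positions["tail"] = tail3

    grf_obs = grf_f.copy()
    if spec.force_noise_sigma > 0:
        grf_obs = grf_obs + rng.normal(0.0, spec.force_noise_sigma, grf_obs.shape)
    obs_raw = ForceRecord(grf=grf_obs, cop_x=cop_f, rate=config.force_rate,
                          time=t_f)
    obs_sync = resample_forces(obs_raw, config.marker_rate,
                               config.contact_floor_n)
    obs_sync = ForceRecord(grf=obs_sync.grf[:nb], cop_x=obs_sync.cop_x[:nb],
                           rate=obs_sync.rate, time=obs_sync.time[:nb])
    markers = MarkerSet(positions=positions, rate=config.marker_rate, time=t_m)
    meta = TrialMetadata(animal_id=spec.animal_id, trial_id=spec.trial_id,
                         body_mass=m)
    trial = Trial(metadata=meta, markers=markers, forces=obs_sync,
                  forces_raw=obs_raw, forward=np.array([1.0, 0.0]))
    return trial, truth


def write_synthetic_trial(trial: Trial, truth: SyntheticTruth,
                          out_dir: str | Path) -> Dict[str, Path]:
    """Write TRC + force CSV readable by trial_io, plus a truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tid = trial.metadata.trial_id
    paths = {
        "markers": out_dir / f"{tid}.trc",
        "forces": out_dir / f"{tid}_forces.csv",
        "truth": out_dir / f"{tid}_truth.json",
    }
    write_trc(trial.markers, paths["markers"])
    write_force_csv(trial.forces_raw, paths["forces"])
    summary = {
        "speed": truth.speed, "body_mass": truth.body_mass,
        "stance_start": truth.stance_start, "stance_end": truth.stance_end,
        "peak_grf_bw_per_leg": truth.peak_grf_bw_per_leg,
        "min_cf": truth.min_cf, "peak_stress_mpa": truth.peak_stress_mpa,
        "safety_factor": truth.safety_factor, "seed": truth.seed,
        "work_J_per_kg": {j: list(w) for j, w in truth.work.items()},
    }
    paths["truth"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """True effects injected into a cohort (for recovery by the stats stage)."""

    ankle_td_speed_slope: float = -4.0  # deg per m/s at touchdown
    ankle_mid_speed_slope: float = -14.0  # deg per m/s at midstance
    mtp_mid_speed_slope: float = 4.0  # deg per m/s at midstance
    mass_speed_correlation: float = 0.24  # larger animals hop slightly faster


def generate_cohort(n_trials: int,
                    mass_range: Tuple[float, float] = (13.7, 26.6),
                    speed_range: Tuple[float, float] = (1.99, 4.48),
                    effect_spec: Optional[EffectSpec] = None,
                    seed: int = 0,
                    marker_noise_sigma: float = 0.001,
                    config: Optional[PipelineConfig] = None
                    ) -> List[Tuple[Trial, SyntheticTruth]]:
    """Sample a cohort of hops across mass and speed ranges.

    Masses are uniform over ``mass_range``; speeds are uniform over
    ``speed_range`` with a configurable mass-speed correlation.  Per-subject
    limb geometry scales with mass^(1/3), and the effect slopes replace the
    speed dependencies of the default posture rules, so the regression stage
    has exact known coefficients to recover.
    """
    if n_trials < 2:
        raise PipelineError("cohort_too_small", f"n_trials={n_trials} < 2")
    if not (mass_range[1] > mass_range[0] and speed_range[1] > speed_range[0]):
        raise PipelineError("cohort_too_small", "degenerate mass/speed range")
    eff = effect_spec or EffectSpec()
    rng = np.random.default_rng(seed)
    rho = float(np.clip(eff.mass_speed_correlation, -0.999, 0.999))
    um = rng.uniform(size=n_trials)
    # Gaussian-copula correlation between mass and speed quantiles
    from scipy.stats import norm as _norm
    zm = _norm.ppf(um)
    zs = rho * zm + np.sqrt(1 - rho**2) * _norm.ppf(rng.uniform(size=n_trials))
    us = _norm.cdf(zs)
    masses = mass_range[0] + um * (mass_range[1] - mass_range[0])
    speeds = speed_range[0] + us * (speed_range[1] - speed_range[0])

    out = []
    v_ref = 2.5
    for i in range(n_trials):
        v = float(speeds[i])
        base = default_waveforms(v_ref)  # speed effects injected explicitly
        dv = v - v_ref
        waves = dict(base)
        a_td, a_mid, a_to = base["ankle"]
        waves["ankle"] = (a_td + eff.ankle_td_speed_slope * dv,
                          float(np.clip(a_mid + eff.ankle_mid_speed_slope * dv,
                                        70.0, 118.0)),
                          a_to)
        m_td, m_mid, m_to = base["mtp"]
        waves["mtp"] = (m_td, m_mid + eff.mtp_mid_speed_slope * dv, m_to)
        spec = SyntheticTrialSpec(
            body_mass=float(masses[i]), speed=v, waveforms=waves,
            marker_noise_sigma=marker_noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
            trial_id=f"cohort_{i:03d}", animal_id=f"synth_{i:03d}")
        out.append(generate_trial(spec, config=config))
    return out
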