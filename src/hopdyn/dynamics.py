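"""Planar link-segment inverse dynamics for the hindlimb chain.

The limb is modelled as four rigid segments — phalanges, metatarsus, shank,
thigh — joined by hinge joints (MTP, ankle, knee, hip).  Segment inertial
properties follow the uniform-cylinder approximation: mass is a configurable
fraction of body mass, the centre of mass sits at a fixed fraction of
segment length from the proximal end, and the transverse moment of inertia
is I = m (L^2/12 + rho^2/4) with rho a fixed fraction of L.

Net joint moments come from a distal-to-proximal Newton-Euler recursion
starting at the phalanges, where the (per-leg) ground reaction force acts at
the centre of pressure.  All inertial terms are retained.  Moments are
reported extensor/plantarflexor-positive: a positive moment acts to increase
the included joint angle of the distal segment, so extensor moment times
extension velocity is positive power at every joint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .config import G, PipelineConfig, SegmentFractions
from .errors import PipelineError, PipelineWarning
from .kinematics import SEGMENT_MARKERS, sagittal_project
from .preprocess import SmoothedMarkers, StanceWindow, resample_to_pct
from .trial_io import ForceRecord

#: chain order, distal first; (segment, distal marker, proximal marker, joint
#: at the proximal end)
CHAIN = (
    ("phalanges", "toe", "mtp", "mtp"),
    ("metatarsus", "mtp", "ankle", "ankle"),
    ("shank", "ankle", "knee", "knee"),
    ("thigh", "knee", "hip", "hip"),
)


@dataclass
class Segment:
    length: float  # m
    mass: float  # kg
    com_fraction: float  # from the proximal end
    inertia: float  # kg m^2 about the CoM


@dataclass
class LimbModel:
    segments: Dict[str, Segment]
    body_mass: float  # kg

    @property
    def leg_length(self) -> float:
        """Total limb length: chain segments plus the pelvis (ilium-hip)."""
        return float(sum(s.length for s in self.segments.values()))


def cylinder_inertia(mass: float, length: float, radius: float) -> float:
    """Transverse moment of inertia of a uniform cylinder about its CoM."""
    return mass * (length**2 / 12.0 + radius**2 / 4.0)


def build_limb_model(mass: float, lengths: Dict[str, float],
                     fractions: Optional[SegmentFractions] = None) -> LimbModel:
    """Populate segment masses, CoM positions and inertias from config
    fractions.  ``lengths`` may include a ``pelvis`` entry (counted in total
    leg length but carrying no mass in the chain)."""
    fractions = fractions or SegmentFractions()
    if not mass > 0:
        raise PipelineError("bad_metadata", "mass must be > 0")
    frac = {"thigh": fractions.thigh, "shank": fractions.shank,
            "metatarsus": fractions.metatarsus, "phalanges": fractions.phalanges}
    if sum(frac.values()) >= 0.5 - 1e-9:
        raise PipelineError("implausible_fractions",
                            f"hindlimb fractions sum to {sum(frac.values()):.2f}")
    segments = {}
    for name in lengths:
        L = float(lengths[name])
        if not L > 0:
            raise PipelineError("bad_metadata", f"segment {name}: length {L}")
        m = mass * frac.get(name, 0.0)
        rho = fractions.radius_fraction * L
        segments[name] = Segment(length=L, mass=m,
                                 com_fraction=fractions.com_fraction,
                                 inertia=cylinder_inertia(m, L, rho))
    return LimbModel(segments=segments, body_mass=mass)


@dataclass
class JointMomentSeries:
    """Net internal joint moments over stance, extensor-positive, N m."""

    time: np.ndarray
    moments: Dict[str, np.ndarray]  # joint -> N m

    def dimensionless(self, mass: float, leg_length: float) -> Dict[str, np.ndarray]:
        return normalize_moment(self, mass, leg_length)

    def on_pct_grid(self, stance: StanceWindow) -> Dict[str, np.ndarray]:
        return {j: resample_to_pct(self.time, m, stance)
                for j, m in self.moments.items()}


def normalize_moment(moments: JointMomentSeries, mass: float,
                     leg_length: float) -> Dict[str, np.ndarray]:
    """Moments divided by body weight times leg length (dimensionless)."""
    if not (mass > 0 and leg_length > 0):
        raise PipelineError("bad_metadata", "mass and leg length must be > 0")
    scale = mass * G * leg_length
    return {j: m / scale for j, m in moments.moments.items()}


def _cross2(a, b):
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def newton_euler_planar(pos: Dict[str, np.ndarray], vel: Dict[str, np.ndarray],
                        acc: Dict[str, np.ndarray], model: LimbModel,
                        ext_force: np.ndarray, ext_point: np.ndarray,
                        g: float = G) -> Dict[str, np.ndarray]:
    """Distal-to-proximal recursion on sagittal-plane marker kinematics.

    ``pos``/``vel``/``acc`` map marker names to (n, 2) arrays; ``ext_force``
    is the (n, 2) external (per-leg ground reaction) force applied at
    ``ext_point`` (n, 2) on the phalanges.  Returns the raw z-moment at each
    joint acting on its distal segment (no sign convention applied).
    """
    n = len(ext_force)
    f_dist = ext_force.copy()  # force applied on current segment at its distal end
    m_dist = np.zeros(n)  # couple applied at the distal end
    p_dist_pt = ext_point.copy()  # where that force acts
    g_vec = np.array([0.0, -g])
    raw: Dict[str, np.ndarray] = {}
    for seg_name, d_marker, p_marker, joint in CHAIN:
        seg = model.segments[seg_name]
        p_prox, p_distal = pos[p_marker], pos[d_marker]
        # CoM kinematics: linear combination of the two joint markers
        f = seg.com_fraction
        com = p_prox + f * (p_distal - p_prox)
        a_com = acc[p_marker] + f * (acc[d_marker] - acc[p_marker])
        if np.any(np.linalg.norm(a_com, axis=1) > 50 * G):
            warnings.warn(f"{seg_name}: CoM acceleration exceeds 50 g "
                          "(kinematic artifact?)", PipelineWarning)
        # segment angular acceleration from the exact atan2 identities
        w = p_distal - p_prox
        w_dot = vel[d_marker] - vel[p_marker]
        w_ddot = acc[d_marker] - acc[p_marker]
        n2 = np.einsum("ij,ij->i", w, w)
        omega = _cross2(w, w_dot) / n2
        alpha = _cross2(w, w_ddot) / n2 - 2 * np.einsum("ij,ij->i", w, w_dot) * omega / n2
        # force balance: F_prox + F_dist + m g = m a
        f_prox = seg.mass * (a_com - g_vec) - f_dist
        # moment balance about the CoM
        r_p = p_prox - com
        r_d = p_dist_pt - com
        m_prox = (seg.inertia * alpha - m_dist
                  - _cross2(r_p, f_prox) - _cross2(r_d, f_dist))
        raw[joint] = m_prox
        # reaction on the next (more proximal) segment
        f_dist = -f_prox
        m_dist = -m_prox
        p_dist_pt = p_prox
    return raw


def joint_chirality(pos: Dict[str, np.ndarray]) -> Dict[str, int]:
    """Dominant sign of the signed angle from the proximal to the distal
    segment vector at each joint (the chain's zig-zag handedness)."""
    from .kinematics import JOINT_TRIPLETS
    signs = {}
    for joint, (a, b, c) in JOINT_TRIPLETS.items():
        u = pos[a] - pos[b]
        v = pos[c] - pos[b]
        chi = np.arctan2(_cross2(u, v), np.einsum("ij,ij->i", u, v))
        s = int(np.sign(np.sign(chi).sum()))
        signs[joint] = s or 1
    return signs


def inverse_dynamics(model: LimbModel, smoothed: SmoothedMarkers,
                     forces: ForceRecord, stance: StanceWindow,
                     forward: Sequence[float] = (1.0, 0.0),
                     leg_share: float = 0.5,
                     config: Optional[PipelineConfig] = None) -> JointMomentSeries:
    """Net joint moments over the stance phase.

    The measured GRF is multiplied by ``leg_share`` (default 0.5: equal
    sharing between the two legs) and applied at the fore-aft centre of
    pressure on the plate surface.  Output moments are extensor-positive.
    """
    t_all = smoothed.time
    sel = stance.mask(t_all)
    t = t_all[sel]
    if len(t) < 3:
        raise PipelineError("bad_stance", "fewer than 3 stance samples")
    names = ("toe", "mtp", "ankle", "knee", "hip", "ilium")
    pos = {n: sagittal_project(smoothed.position(n, t), forward) for n in names}
    vel = {n: sagittal_project(smoothed.velocity(n, t), forward) for n in names}
    acc = {n: sagittal_project(smoothed.acceleration(n, t), forward) for n in names}

    fx = np.interp(t, forces.time,
                   forces.grf[:, 0] * forward[0] + forces.grf[:, 2] * forward[1])
    fy = np.interp(t, forces.time, forces.fy)
    ext_force = leg_share * np.column_stack([fx, fy])
    loaded = ~np.isnan(forces.cop_x)
    cop = np.interp(t, forces.time[loaded], forces.cop_x[loaded])
    ext_point = np.column_stack([cop, np.zeros_like(cop)])

    raw = newton_euler_planar(pos, vel, acc, model, ext_force, ext_point)
    signs = joint_chirality(pos)
    moments = {j: signs[j] * raw[j] for j in raw}
    return JointMomentSeries(time=t, moments=moments)
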