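"""Planar joint angles, crouch factor and timing metrics.

Joint angles use the included-angle convention: the angle at the middle
marker of each triplet (hip: ilium-hip-knee, knee: hip-knee-ankle, ankle:
knee-ankle-mtp, MTP: ankle-mtp-toe), in degrees, in (0, 180].  Ankle
dorsiflexion therefore decreases the ankle angle and MTP plantarflexion
increases the MTP angle.  Angular velocities come from exact differentiation
identities applied to the smoothing-spline marker velocities, so they are
consistent with the positions to machine precision.

The crouch factor CF is the pelvis(ilium)-to-toe distance divided by the
summed segment lengths of the hindlimb chain: 1 for a fully extended
(collinear) limb, smaller when crouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import PipelineError, PipelineWarning
from .preprocess import SmoothedMarkers, StanceWindow, resample_to_pct
from .trial_io import MarkerSet

#: joint -> (proximal, middle, distal) marker triplet
JOINT_TRIPLETS = {
    "hip": ("ilium", "hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "ankle": ("knee", "ankle", "mtp"),
    "mtp": ("ankle", "mtp", "toe"),
}

#: chain segment -> (proximal marker, distal marker)
SEGMENT_MARKERS = {
    "pelvis": ("ilium", "hip"),
    "thigh": ("hip", "knee"),
    "shank": ("knee", "ankle"),
    "metatarsus": ("ankle", "mtp"),
    "phalanges": ("mtp", "toe"),
}

JOINTS = tuple(JOINT_TRIPLETS)


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _dot2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 0] + a[..., 1] * b[..., 1]


def sagittal_project(points: np.ndarray, forward: Sequence[float]) -> np.ndarray:
    """Project lab-frame (x, y, z) points onto the travel-direction sagittal
    plane; returns (fore-aft, vertical)."""
    points = np.asarray(points, dtype=float)
    x = points[..., 0] * forward[0] + points[..., 2] * forward[1]
    return np.stack([x, points[..., 1]], axis=-1)


def included_angle(u: np.ndarray, v: np.ndarray,
                   u_dot: Optional[np.ndarray] = None,
                   v_dot: Optional[np.ndarray] = None,
                   min_len: float = 1e-3):
    """Included angle between 2D vector series u, v and (optionally) its rate.

    Returns ``(theta_rad, chi_sign, theta_dot)`` where ``chi_sign`` is the
    sign of the signed angle from u to v (the joint's chirality in the
    chain) and ``theta_dot = d|chi|/dt`` from the exact identity
    ``omega_w = cross(w, w_dot)/|w|^2`` for each leg of the triplet.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu = np.hypot(u[..., 0], u[..., 1])
    nv = np.hypot(v[..., 0], v[..., 1])
    if np.any(nu < min_len) or np.any(nv < min_len):
        raise PipelineError("degenerate_triplet",
                            f"markers closer than {min_len * 1e3:.0f} mm")
    chi = np.arctan2(_cross2(u, v), _dot2(u, v))
    sign = np.sign(chi)
    sign[sign == 0] = 1.0
    theta = np.abs(chi)
    theta_dot = None
    if u_dot is not None and v_dot is not None:
        omega_u = _cross2(u, np.asarray(u_dot, float)) / nu**2
        omega_v = _cross2(v, np.asarray(v_dot, float)) / nv**2
        theta_dot = sign * (omega_v - omega_u)
    return theta, sign, theta_dot


@dataclass
class JointAngleSeries:
    """Included joint angles (deg) and angular velocities (rad/s)."""

    time: np.ndarray
    angles_deg: Dict[str, np.ndarray]
    omega: Dict[str, np.ndarray]  # d(included angle)/dt, rad/s
    chirality: Dict[str, int]  # dominant sign of the signed angle u->v

    def on_pct_grid(self, stance: StanceWindow) -> Dict[str, np.ndarray]:
        return {j: resample_to_pct(self.time, a, stance)
                for j, a in self.angles_deg.items()}


def joint_angles(smoothed: SmoothedMarkers,
                 forward: Sequence[float] = (1.0, 0.0),
                 t: Optional[np.ndarray] = None) -> JointAngleSeries:
    """Included angles and angular velocities for hip, knee, ankle, MTP."""
    t = smoothed.time if t is None else np.asarray(t)
    pos = {n: sagittal_project(smoothed.position(n, t), forward)
           for n in smoothed.names}
    vel = {n: sagittal_project(smoothed.velocity(n, t), forward)
           for n in smoothed.names}
    angles, omegas, chir = {}, {}, {}
    for joint, (a, b, c) in JOINT_TRIPLETS.items():
        u, v = pos[a] - pos[b], pos[c] - pos[b]
        du, dv = vel[a] - vel[b], vel[c] - vel[b]
        theta, sign, theta_dot = included_angle(u, v, du, dv)
        angles[joint] = np.degrees(theta)
        omegas[joint] = theta_dot
        chir[joint] = int(np.sign(sign.sum())) or 1
    return JointAngleSeries(time=t, angles_deg=angles, omega=omegas,
                            chirality=chir)


def segment_lengths(markers: MarkerSet | SmoothedMarkers,
                    stance: Optional[StanceWindow] = None,
                    cv_warn: float = 0.10) -> Dict[str, float]:
    """Rigid per-segment lengths: median inter-marker distance over stance.

    The median suppresses skin-movement artefact; a coefficient of variation
    above ``cv_warn`` flags a soft segment.
    """
    if isinstance(markers, SmoothedMarkers):
        markers = markers.as_markerset()
    sel = stance.mask(markers.time) if stance is not None else slice(None)
    lengths = {}
    for seg, (a, b) in SEGMENT_MARKERS.items():
        d = np.linalg.norm(
            markers.positions[a][sel] - markers.positions[b][sel], axis=1)
        med = float(np.median(d))
        if med > 0 and d.std() / med > cv_warn:
            warnings.warn(f"segment {seg}: length CV {d.std() / med:.1%} > "
                          f"{cv_warn:.0%} (skin movement?)", PipelineWarning)
        lengths[seg] = med
    return lengths


def total_limb_length(lengths: Dict[str, float]) -> float:
    return float(sum(lengths[s] for s in SEGMENT_MARKERS))


@dataclass
class ExtremumInfo:
    value: float
    pct_stance: float
    at_boundary: bool = False


def timing_metrics(series: np.ndarray, mode: str = "max",
                   pct: Optional[np.ndarray] = None) -> ExtremumInfo:
    """Extremum value and %-stance timing, refined by quadratic interpolation.

    Exact for a parabola sampled on the grid; a monotone series reports its
    boundary extremum with ``at_boundary`` set.
    """
    y = np.asarray(series, dtype=float)
    if pct is None:
        pct = np.linspace(0.0, 100.0, len(y))
    idx = int(np.nanargmax(y) if mode == "max" else np.nanargmin(y))
    if idx in (0, len(y) - 1):
        return ExtremumInfo(value=float(y[idx]), pct_stance=float(pct[idx]),
                            at_boundary=True)
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = pct[idx + 1] - pct[idx]
    value = y1 - 0.25 * (y0 - y2) * delta
    return ExtremumInfo(value=float(value),
                        pct_stance=float(pct[idx] + delta * step))


@dataclass
class CrouchSeries:
    """Crouch factor over stance: pelvis-to-toe distance / summed limb length."""

    time: np.ndarray
    crouch_factor: np.ndarray
    total_limb_length: float
    min_cf: float
    min_cf_pct_stance: float

    @property
    def pelvis_toe_distance(self) -> np.ndarray:
        return self.crouch_factor * self.total_limb_length


def crouch_factor(smoothed: SmoothedMarkers, lengths: Dict[str, float],
                  stance: StanceWindow,
                  forward: Sequence[float] = (1.0, 0.0)) -> CrouchSeries:
    total = total_limb_length(lengths)
    t = smoothed.time
    toe = sagittal_project(smoothed.position("toe"), forward)
    ilium = sagittal_project(smoothed.position("ilium"), forward)
    cf = np.linalg.norm(toe - ilium, axis=1) / total
    on_grid = resample_to_pct(t, cf, stance)
    ext = timing_metrics(on_grid, mode="min")
    return CrouchSeries(time=t, crouch_factor=cf, total_limb_length=total,
                        min_cf=ext.value, min_cf_pct_stance=ext.pct_stance)
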