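"""Joint power, per-hop work decomposition, tendon force, stress and safety
factor.

Joint power is the product of the (unnormalised) net joint moment and the
joint angular velocity; with the extensor-positive conventions used here,
positive power is energy generation and negative power absorption.  Per-hop
work splits the stance-phase power integral into contiguous positive and
negative periods, delimited by linearly interpolated zero crossings so the
sums are robust to grid resolution, and is normalised to body mass.

Achilles tendon force is the plantarflexor part of the ankle moment divided
by the instantaneous tendon moment arm (the tendon cannot push, so
dorsiflexor-moment samples carry zero tendon force).  Stress is force over
the combined gastrocnemius + plantaris cross-sectional area, obtained from
an area-mass power law; the flexor digitorum longus is excluded.  The
safety factor is the failure stress divided by the peak operating stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .config import TendonConfig
from .errors import PipelineError
from .kinematics import ExtremumInfo, JointAngleSeries, timing_metrics
from .dynamics import JointMomentSeries


def joint_power(moments: JointMomentSeries,
                angles: JointAngleSeries) -> Dict[str, np.ndarray]:
    """P(t) = M(t) * omega(t) per joint, W (extensor x extension > 0)."""
    powers = {}
    for joint, m in moments.moments.items():
        omega = np.interp(moments.time, angles.time, angles.omega[joint])
        powers[joint] = m * omega
    return powers


@dataclass
class WorkSummary:
    """Per-hop work at one joint, J/kg."""

    positive_work: float
    negative_work: float  # <= 0

    @property
    def net_work(self) -> float:
        return self.positive_work + self.negative_work


def work_decomposition(power: np.ndarray, time: np.ndarray,
                       mass: float) -> WorkSummary:
    """Sum positive-period and negative-period work over stance.

    Zero crossings of the power trace are located by linear interpolation
    and inserted as integration break points; each sign-homogeneous period
    is integrated by the trapezoid rule.
    """
    if not mass > 0:
        raise PipelineError("bad_metadata", "mass must be > 0")
    p = np.asarray(power, float)
    t = np.asarray(time, float)
    # augment with exact zero-crossing points
    ts, ps = [t[0]], [p[0]]
    for i in range(1, len(t)):
        if p[i - 1] * p[i] < 0:
            tc = t[i - 1] - p[i - 1] * (t[i] - t[i - 1]) / (p[i] - p[i - 1])
            ts.append(tc)
            ps.append(0.0)
        ts.append(t[i])
        ps.append(p[i])
    ts = np.asarray(ts)
    ps = np.asarray(ps)
    seg = 0.5 * (ps[1:] + ps[:-1]) * np.diff(ts)  # trapezoid per sub-interval
    pos = float(seg[seg > 0].sum()) / mass
    neg = float(seg[seg < 0].sum()) / mass
    return WorkSummary(positive_work=pos, negative_work=neg)


def work_by_joint(powers: Dict[str, np.ndarray], time: np.ndarray,
                  mass: float) -> Dict[str, WorkSummary]:
    return {j: work_decomposition(p, time, mass) for j, p in powers.items()}


# ---------------------------------------------------------------------------
# tendon mechanics
# ---------------------------------------------------------------------------

def tendon_force(ankle_moment: np.ndarray, r: np.ndarray) -> np.ndarray:
    """F(t) = max(M_ankle, 0) / r(t): only plantarflexor moments load the
    Achilles."""
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise PipelineError("bad_moment_arm", "moment arm must be > 0")
    return np.maximum(np.asarray(ankle_moment, float), 0.0) / r


def tendon_csa(mass: float, a: float = TendonConfig.csa_a,
               b: float = TendonConfig.csa_b) -> float:
    """Combined gastrocnemius + plantaris cross-sectional area, m^2:
    csa = a * mass**b."""
    if not mass > 0:
        raise PipelineError("bad_metadata", "mass must be > 0")
    csa = a * mass**b
    if not csa > 0:
        raise PipelineError("bad_regression", f"csa {csa} <= 0")
    return float(csa)


@dataclass
class TendonStressSeries:
    """Tendon force, stress and safety factor over stance."""

    force_n: np.ndarray
    csa_m2: float
    stress_mpa: np.ndarray
    peak_stress_mpa: float
    peak_pct_stance: Optional[float]
    safety_factor: Optional[float]  # None when the tendon is never loaded
    failure_stress_mpa: float


def tendon_stress(force: np.ndarray, csa: float,
                  failure_stress_mpa: float = 100.0,
                  pct: Optional[np.ndarray] = None) -> TendonStressSeries:
    """Stress = force/csa in MPa; safety factor = failure stress / peak."""
    if not csa > 0:
        raise PipelineError("bad_regression", "csa must be > 0")
    force = np.asarray(force, float)
    stress = force / csa / 1e6
    if np.all(force <= 0):
        return TendonStressSeries(force_n=force, csa_m2=csa, stress_mpa=stress,
                                  peak_stress_mpa=0.0, peak_pct_stance=None,
                                  safety_factor=None,
                                  failure_stress_mpa=failure_stress_mpa)
    ext: ExtremumInfo = timing_metrics(stress, mode="max", pct=pct)
    peak = max(ext.value, float(stress.max()))
    return TendonStressSeries(
        force_n=force, csa_m2=csa, stress_mpa=stress, peak_stress_mpa=peak,
        peak_pct_stance=ext.pct_stance,
        safety_factor=failure_stress_mpa / peak,
        failure_stress_mpa=failure_stress_mpa)
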