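"""Muscle and external moment arms and effective mechanical advantage (EMA).

EMA at the ankle is r/R: the Achilles (gastrocnemius + plantaris) tendon
moment arm r divided by the external moment arm R, the perpendicular
distance from the ground reaction force line of action (through the centre
of pressure) to the ankle joint centre.  Small EMA means more muscle force
per unit ground force.

r depends on ankle angle.  The default profile is a symmetric parabola
peaking at 114.4 deg — the configuration in which the calcaneal lever is
most effective — and is fully configurable, including a table-driven form
(angle, r) with monotone-cubic interpolation for profiles exported from a
musculoskeletal model.  Per-subject r scales with shank length relative to
the reference model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize_scalar

from .config import MomentArmConfig, PipelineConfig
from .errors import PipelineError, PipelineWarning
from .kinematics import JointAngleSeries, sagittal_project, timing_metrics
from .preprocess import (SmoothedMarkers, StanceWindow, resample_to_pct)
from .trial_io import ForceRecord


class MomentArmProfile:
    """r(theta): Achilles moment arm (m) as a function of ankle angle (deg)."""

    def __init__(self, config: Optional[MomentArmConfig] = None):
        self.config = config or MomentArmConfig()
        c = self.config
        self._table = None
        if c.table_path is not None:
            df = pd.read_csv(c.table_path)
            self._init_table(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    @classmethod
    def from_table(cls, angles_deg: Sequence[float], r_m: Sequence[float],
                   config: Optional[MomentArmConfig] = None) -> "MomentArmProfile":
        prof = cls(config)
        prof._init_table(np.asarray(angles_deg, float), np.asarray(r_m, float))
        return prof

    def _init_table(self, angles: np.ndarray, r: np.ndarray) -> None:
        order = np.argsort(angles)
        angles, r = angles[order], r[order]
        if np.any(r <= 0):
            raise PipelineError("bad_profile", "moment arm must be positive")
        self._table = PchipInterpolator(angles, r, extrapolate=False)
        self._table_range = (float(angles[0]), float(angles[-1]))

    def __call__(self, theta_deg) -> np.ndarray:
        """Reference-size moment arm; angles clamped to the valid range."""
        c = self.config
        theta = np.asarray(theta_deg, dtype=float)
        lo, hi = ((max(c.angle_min_deg, self._table_range[0]),
                   min(c.angle_max_deg, self._table_range[1]))
                  if self._table is not None
                  else (c.angle_min_deg, c.angle_max_deg))
        if np.any(theta < lo - 1e-9) or np.any(theta > hi + 1e-9):
            warnings.warn(f"ankle angle outside [{lo:g}, {hi:g}] deg clamped",
                          PipelineWarning)
            theta = np.clip(theta, lo, hi)
        if self._table is not None:
            return np.asarray(self._table(theta), dtype=float)
        return c.r_peak * (1.0 - c.curvature * (theta - c.theta_peak_deg) ** 2)

    def argmax_deg(self) -> float:
        """Ankle angle (deg) maximising r over the physiological range."""
        c = self.config
        lo, hi = c.angle_min_deg, c.angle_max_deg
        if self._table is not None:
            lo = max(lo, self._table_range[0])
            hi = min(hi, self._table_range[1])
        res = minimize_scalar(lambda th: -float(self(th)), bounds=(lo, hi),
                              method="bounded",
                              options={"xatol": 1e-8})
        return float(res.x)

    def subject_scale(self, shank_length: float) -> float:
        """Geometric scale factor: subject shank length / reference shank."""
        if not shank_length > 0:
            raise PipelineError("bad_profile", "shank length must be > 0")
        return shank_length / self.config.ref_shank_length


def muscle_moment_arm(ankle_angle_deg, profile: MomentArmProfile,
                      subject_scale: float = 1.0) -> np.ndarray:
    """r = subject_scale * profile(theta)."""
    return subject_scale * profile(ankle_angle_deg)


def external_moment_arm(ankle_pos: Sequence[float], cop_x: float,
                        grf: Sequence[float], min_force_n: float = 1e-6) -> float:
    """Unsigned perpendicular distance from the GRF line to the ankle centre.

    The GRF line passes through (cop_x, 0) with direction (Fx, Fy); the
    distance is |cross(ankle - cop, F)| / |F| in the sagittal plane.
    """
    fx, fy = float(grf[0]), float(grf[1])
    norm = np.hypot(fx, fy)
    if norm <= min_force_n:
        raise PipelineError("undefined_R", "GRF magnitude is ~0")
    dx = float(ankle_pos[0]) - float(cop_x)
    dy = float(ankle_pos[1])
    return abs(dx * fy - dy * fx) / norm


@dataclass
class EMASeries:
    """r, R, EMA and ankle height on the %-stance grid.

    EMA is masked (NaN) where the vertical GRF is at or below the stance
    threshold, where the GRF direction (hence R) is undefined.
    """

    pct: np.ndarray
    r: np.ndarray  # m
    R: np.ndarray  # m
    ema: np.ndarray  # r/R, NaN where masked
    ankle_height: np.ndarray  # m above the plate surface
    cop_x: np.ndarray  # m
    midstance_pct: float
    extras: Dict[str, float] = field(default_factory=dict)

    def _at_pct(self, series: np.ndarray, pct: float) -> float:
        return float(np.interp(pct, self.pct, series))

    @property
    def ema_midstance(self) -> float:
        return self._at_pct(self.ema, self.midstance_pct)

    @property
    def r_midstance(self) -> float:
        return self._at_pct(self.r, self.midstance_pct)

    @property
    def R_midstance(self) -> float:
        return self._at_pct(self.R, self.midstance_pct)

    @property
    def ankle_height_midstance(self) -> float:
        return self._at_pct(self.ankle_height, self.midstance_pct)

    def min_ema(self):
        """Minimum EMA over the loaded part of stance and its timing."""
        valid = ~np.isnan(self.ema)
        return timing_metrics(self.ema[valid], mode="min", pct=self.pct[valid])


def ema_series(angles: JointAngleSeries, smoothed: SmoothedMarkers,
               forces: ForceRecord, stance: StanceWindow,
               profile: MomentArmProfile, subject_scale: float = 1.0,
               forward: Sequence[float] = (1.0, 0.0),
               config: Optional[PipelineConfig] = None) -> EMASeries:
    """Time-varying r, R and EMA = r/R over stance.

    r follows the (scaled) moment-arm profile at the instantaneous ankle
    angle; R is the perpendicular distance from the instantaneous GRF line
    of action to the ankle marker.  R depends only on the force direction,
    so EMA is invariant to uniform force rescaling.
    """
    config = config or PipelineConfig()
    grid_t = stance.grid_times()
    pct = np.linspace(0.0, 100.0, len(grid_t))

    ankle_deg = np.interp(grid_t, angles.time, angles.angles_deg["ankle"])
    r = muscle_moment_arm(ankle_deg, profile, subject_scale)

    ankle_xy = sagittal_project(smoothed.position("ankle", grid_t), forward)
    fx = np.interp(grid_t, forces.time,
                   forces.grf[:, 0] * forward[0] + forces.grf[:, 2] * forward[1])
    fy = np.interp(grid_t, forces.time, forces.fy)
    loaded_src = ~np.isnan(forces.cop_x)
    cop = np.interp(grid_t, forces.time[loaded_src], forces.cop_x[loaded_src])

    # strictly above threshold; the grid endpoints sit exactly at the
    # interpolated crossings, so a relative epsilon keeps them masked
    loaded = fy > stance.threshold * (1.0 + 1e-9)
    R = np.full_like(r, np.nan)
    for i in np.flatnonzero(loaded):
        R[i] = external_moment_arm(ankle_xy[i], cop[i], (fx[i], fy[i]))
    ema = np.where(loaded & (R > 0), r / np.where(R > 0, R, np.nan), np.nan)

    if config.midstance_mode == "peak_grf":
        mid_pct = float(timing_metrics(fy, mode="max", pct=pct).pct_stance)
    else:
        mid_pct = 50.0
    return EMASeries(pct=pct, r=r, R=R, ema=ema,
                     ankle_height=ankle_xy[:, 1], cop_x=cop,
                     midstance_pct=mid_pct)
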