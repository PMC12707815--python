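"""Event detection, smoothing and trial-level normalisations.

Stance is defined by the vertical ground reaction force exceeding 2% of its
peak; crossing times are located by linear interpolation between samples so
contact durations are not quantised to the force sample period.  Marker
trajectories are smoothed with cubic smoothing splines (roughness chosen by
generalised cross-validation by default) and velocities/accelerations are
taken from the same spline, so kinematics and dynamics stay consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .config import G, STANCE_GRID_N, PipelineConfig, SmoothingSpec
from .errors import PipelineError, PipelineWarning
from .trial_io import ForceRecord, MarkerSet

# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


class SmoothedMarkers:
    """Per-marker, per-axis smoothing splines with derivative access."""

    def __init__(self, splines: Dict[str, list], time: np.ndarray, rate: float):
        self._splines = splines
        self.time = time
        self.rate = rate

    @property
    def names(self):
        return list(self._splines)

    def position(self, name: str, t: Optional[np.ndarray] = None) -> np.ndarray:
        t = self.time if t is None else np.asarray(t)
        return np.column_stack([s(t) for s in self._splines[name]])

    def velocity(self, name: str, t: Optional[np.ndarray] = None) -> np.ndarray:
        t = self.time if t is None else np.asarray(t)
        return np.column_stack([s.derivative(1)(t) for s in self._splines[name]])

    def acceleration(self, name: str, t: Optional[np.ndarray] = None) -> np.ndarray:
        t = self.time if t is None else np.asarray(t)
        return np.column_stack([s.derivative(2)(t) for s in self._splines[name]])

    def as_markerset(self) -> MarkerSet:
        return MarkerSet(
            positions={n: self.position(n) for n in self._splines},
            rate=self.rate, time=self.time)


def smooth_positions(markers: MarkerSet,
                     smoothing: Optional[SmoothingSpec] = None) -> SmoothedMarkers:
    """Fit a cubic smoothing spline to every marker coordinate.

    ``gcv_spline`` lets generalised cross-validation choose the roughness
    penalty per coordinate; ``fixed_spline`` uses a fixed penalty (0 gives
    the interpolating natural cubic spline, the right choice for noise-free
    synthetic data).
    """
    smoothing = smoothing or SmoothingSpec()
    if len(markers) < 10:
        raise PipelineError("short_series",
                            f"{len(markers)} samples < 10 required for smoothing")
    lam = None if smoothing.method == "gcv_spline" else float(smoothing.param)
    t = markers.time
    splines = {}
    for name, pos in markers.positions.items():
        splines[name] = [make_smoothing_spline(t, pos[:, ax], lam=lam)
                        for ax in range(pos.shape[1])]
    return SmoothedMarkers(splines, t, markers.rate)


# ---------------------------------------------------------------------------
# stance detection
# ---------------------------------------------------------------------------

@dataclass
class StanceWindow:
    start_time: float
    end_time: float
    peak_vertical_force: float  # N, total (both legs)
    threshold: float  # N
    peak_time: float  # s, time of peak vertical force

    def __post_init__(self):
        if not self.start_time < self.end_time:
            raise PipelineError("bad_stance", "start must precede end")

    @property
    def contact_duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def mid_time(self) -> float:
        return 0.5 * (self.start_time + self.end_time)

    def mask(self, time: np.ndarray) -> np.ndarray:
        return (time >= self.start_time) & (time <= self.end_time)

    def grid_times(self, n: int = STANCE_GRID_N) -> np.ndarray:
        """Absolute times of the uniform %-stance grid."""
        return self.start_time + np.linspace(0.0, 1.0, n) * self.contact_duration


def _cross_time(t0, f0, t1, f1, level):
    return t0 + (level - f0) / (f1 - f0) * (t1 - t0)


def detect_stance(forces: ForceRecord,
                  threshold_frac: float = 0.02,
                  contact_floor_n: float = 10.0,
                  multi_contact_gap_s: float = 0.05) -> StanceWindow:
    """Locate the stance phase from the vertical force.

    The threshold is ``threshold_frac`` (2%) of the peak vertical force, so
    the window is invariant to uniform rescaling of the force trace.
    Sub-threshold dropouts shorter than ``multi_contact_gap_s`` are bridged;
    two genuinely separate loaded regions are an error.
    """
    fy = forces.fy
    t = forces.time
    peak_idx = int(np.nanargmax(fy))
    peak = fy[peak_idx]
    if not peak > contact_floor_n:
        raise PipelineError("no_contact",
                            f"peak vertical force {peak:.1f} N <= {contact_floor_n} N")
    thr = threshold_frac * peak
    above = fy > thr
    # contiguous runs of loaded samples
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(fy))
    runs: List[List[int]] = []
    for s, e in zip(starts, ends):
        if runs and (t[s] - t[runs[-1][1] - 1]) <= multi_contact_gap_s:
            runs[-1][1] = e
        else:
            runs.append([s, e])
    if len(runs) > 1:
        raise PipelineError("multiple_contacts",
                            f"{len(runs)} loaded regions separated by more than "
                            f"{multi_contact_gap_s * 1e3:.0f} ms")
    s, e = runs[0]
    start = (t[s] if s == 0
             else _cross_time(t[s - 1], fy[s - 1], t[s], fy[s], thr))
    end = (t[e - 1] if e == len(fy)
           else _cross_time(t[e - 1], fy[e - 1], t[e], fy[e], thr))
    return StanceWindow(start_time=float(start), end_time=float(end),
                        peak_vertical_force=float(peak), threshold=float(thr),
                        peak_time=float(t[peak_idx]))


# ---------------------------------------------------------------------------
# body mass, speed, stride parameters
# ---------------------------------------------------------------------------

def estimate_body_mass(forces: ForceRecord, cycle: Tuple[float, float],
                       stance: Optional[StanceWindow] = None) -> float:
    """Impulse-based body mass over one constant-velocity hop cycle.

    mass = (integral of vertical force over the cycle) / (cycle time * g).
    """
    t0, t1 = cycle
    if t1 <= t0:
        raise PipelineError("bad_cycle", "cycle end must follow start")
    if stance is not None and (t1 - t0) < stance.contact_duration - 1e-9:
        raise PipelineError("bad_cycle", "cycle shorter than the stance phase")
    tt = forces.time
    inside = (tt > t0) & (tt < t1)
    ts = np.concatenate([[t0], tt[inside], [t1]])
    fs = np.interp(ts, tt, forces.fy)
    impulse = np.trapezoid(fs, ts)
    return float(impulse / ((t1 - t0) * G))


def trial_speed(smoothed: SmoothedMarkers, stance: StanceWindow,
                forward: Sequence[float] = (1.0, 0.0),
                pelvis: str = "ilium", min_aerial: int = 5) -> float:
    """Mean horizontal pelvis velocity over the aerial phases flanking stance."""
    t = smoothed.time
    vel = smoothed.velocity(pelvis)
    vh = vel[:, 0] * forward[0] + vel[:, 2] * forward[1]
    before = t < stance.start_time
    after = t > stance.end_time
    sides = [vh[m] for m in (before, after) if m.sum() >= min_aerial]
    if not sides:
        raise PipelineError("no_aerial", "no aerial samples on either side of stance")
    if len(sides) == 1:
        warnings.warn("aerial phase visible on one side only; speed from a "
                      "single aerial window", PipelineWarning)
    return float(np.mean([s.mean() for s in sides]))


def is_steady(smoothed: SmoothedMarkers, stance: StanceWindow,
              forward: Sequence[float] = (1.0, 0.0), pelvis: str = "ilium",
              tol: float = 0.10) -> bool:
    """True if mean aerial speed before and after stance agree within ``tol``."""
    t = smoothed.time
    vel = smoothed.velocity(pelvis)
    vh = vel[:, 0] * forward[0] + vel[:, 2] * forward[1]
    before, after = t < stance.start_time, t > stance.end_time
    if before.sum() < 3 or after.sum() < 3:
        return True  # cannot judge; do not exclude
    v0, v1 = vh[before].mean(), vh[after].mean()
    vbar = 0.5 * (abs(v0) + abs(v1))
    return bool(vbar == 0 or abs(v1 - v0) / vbar <= tol)


@dataclass
class StrideParameters:
    speed: float  # m/s
    contact_duration: float  # s
    stride_length: Optional[float] = None  # m
    stride_duration: Optional[float] = None  # s

    @property
    def stride_frequency(self) -> Optional[float]:
        return None if self.stride_duration is None else 1.0 / self.stride_duration


def stride_parameters(markers: MarkerSet, stances: Sequence[StanceWindow],
                      speed: float, marker: str = "mtp") -> StrideParameters:
    """Stride length/duration from successive contacts.

    Stride length is the fore-aft displacement of the MTP marker (ankle as
    fallback) between successive mid-stance instants — the most reliably
    detected "equivalent time point" of the stride; duration is the
    contact-to-contact time.
    """
    if not stances:
        raise PipelineError("no_contact", "no stance windows supplied")
    stances = sorted(stances, key=lambda s: s.start_time)
    first = stances[0]
    if len(stances) == 1:
        return StrideParameters(speed=speed,
                                contact_duration=first.contact_duration)
    second = stances[1]
    name = marker if marker in markers.positions else "ankle"
    pos = markers.positions[name]
    x0 = np.interp(first.mid_time, markers.time, pos[:, 0])
    x1 = np.interp(second.mid_time, markers.time, pos[:, 0])
    duration = second.start_time - first.start_time
    return StrideParameters(speed=speed,
                            contact_duration=first.contact_duration,
                            stride_length=float(abs(x1 - x0)),
                            stride_duration=float(duration))


# ---------------------------------------------------------------------------
# GRF normalisation
# ---------------------------------------------------------------------------

@dataclass
class NormalizedGRF:
    """Per-leg GRF in body weights on the uniform %-stance grid.

    Total measured forces are halved (equal sharing between the two legs)
    and divided by body weight m*g.
    """

    pct: np.ndarray  # (n,) 0..100
    grf_bw: np.ndarray  # (n, 3) per-leg, multiples of BW
    cop_x: np.ndarray  # (n,) m
    body_mass: float  # kg

    @property
    def vertical_bw(self) -> np.ndarray:
        return self.grf_bw[:, 1]

    @property
    def peak_vertical_bw(self) -> float:
        return float(np.max(self.grf_bw[:, 1]))


def resample_to_pct(time: np.ndarray, values: np.ndarray,
                    stance: StanceWindow, n: int = STANCE_GRID_N) -> np.ndarray:
    """Linear interpolation of a time series onto the %-stance grid."""
    grid_t = stance.grid_times(n)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return np.interp(grid_t, time, values)
    return np.column_stack(
        [np.interp(grid_t, time, values[:, j]) for j in range(values.shape[1])])


def normalize_grf(forces: ForceRecord, stance: StanceWindow, mass: float,
                  n: int = STANCE_GRID_N) -> NormalizedGRF:
    if not mass > 0:
        raise PipelineError("bad_metadata", "mass must be > 0")
    bw = mass * G
    grf = resample_to_pct(forces.time, forces.grf, stance, n) / 2.0 / bw
    loaded = ~np.isnan(forces.cop_x)
    cop = np.interp(stance.grid_times(n), forces.time[loaded],
                    forces.cop_x[loaded]) if loaded.any() else np.full(n, np.nan)
    return NormalizedGRF(pct=np.linspace(0.0, 100.0, n), grf_bw=grf,
                         cop_x=cop, body_mass=mass)
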