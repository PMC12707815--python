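"""Pipeline configuration.

All tunable constants of the analysis live here so that a run is fully
described by one :class:`PipelineConfig` object (serialisable to YAML, and
written into every results manifest).  Units are strictly SI internally;
angles cross the interface in degrees and tendon stress in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import PipelineError

#: standard gravity used everywhere, m/s^2
G = 9.81

#: number of samples on the percent-stance grid (0..100 inclusive)
STANCE_GRID_N = 101


@dataclass
class SmoothingSpec:
    """Marker smoothing-spline settings.

    method
        ``"gcv_spline"`` — roughness penalty chosen by generalised
        cross-validation (the default, appropriate for noisy capture data);
        ``"fixed_spline"`` — fixed penalty ``param`` (``0`` interpolates,
        appropriate for noise-free synthetic input).
    """

    method: str = "gcv_spline"
    param: float = 0.0

    def __post_init__(self):
        if self.method not in ("gcv_spline", "fixed_spline"):
            raise PipelineError("bad_smoothing", f"unknown method {self.method!r}")
        if self.method == "fixed_spline" and self.param < 0:
            raise PipelineError("bad_smoothing", "penalty must be >= 0")


@dataclass
class MomentArmConfig:
    """Parametric Achilles (gastrocnemius + plantaris) moment-arm profile.

    r(theta) = r_peak * (1 - curvature * (theta - theta_peak_deg)**2), with
    theta the included ankle angle in degrees.  ``r_peak`` is the value for
    the reference model; per-subject values scale with the subject's shank
    length relative to ``ref_shank_length``.
    """

    theta_peak_deg: float = 114.4
    curvature: float = 6.25e-5  # deg^-2; ~10% drop 40 deg away from the peak
    r_peak: float = 0.022  # m at the reference shank length
    ref_shank_length: float = 0.30  # m
    angle_min_deg: float = 60.0
    angle_max_deg: float = 180.0
    table_path: Optional[str] = None  # CSV (angle_deg, r_m) overrides parametric


@dataclass
class TendonConfig:
    """Achilles tendon cross-section and material limits.

    ``csa = csa_a * mass**csa_b`` (m^2) is the combined gastrocnemius +
    plantaris cross-sectional area (the flexor digitorum longus is excluded:
    it is a foot-placement tendon, not an energy store).  The coefficients
    are calibrated so that a 20 kg subject hopping at 2.5 m/s operates near
    50 MPa peak stress; failure at 100 MPa puts that at a safety factor of 2.
    """

    csa_a: float = 5.3e-6  # m^2 kg^-b
    csa_b: float = 0.67
    failure_stress_mpa: float = 100.0


@dataclass
class SegmentFractions:
    """Per-segment body-mass fractions and shape factors for the limb model.

    Mass fractions are configurable placeholders of the right order of
    magnitude for a macropod hindlimb; every quantitative check in the test
    suite is either invariant to them or uses the generator's own model.
    """

    thigh: float = 0.10
    shank: float = 0.045
    metatarsus: float = 0.02
    phalanges: float = 0.005
    com_fraction: float = 0.5  # CoM position from the proximal end
    radius_fraction: float = 0.1  # cylinder radius / segment length


@dataclass
class PipelineConfig:
    marker_rate: float = 200.0  # Hz
    force_rate: float = 1000.0  # Hz
    stance_threshold_frac: float = 0.02  # of peak vertical GRF
    contact_floor_n: float = 10.0  # N; below this there is no contact at all
    multi_contact_gap_s: float = 0.05
    max_gap_frames: int = 5
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    fractions: SegmentFractions = field(default_factory=SegmentFractions)
    moment_arm: MomentArmConfig = field(default_factory=MomentArmConfig)
    tendon: TendonConfig = field(default_factory=TendonConfig)
    baseline_window_s: float = 0.05  # pre-contact window for force zeroing
    steady_speed_tol: float = 0.10  # |v_before - v_after| / v for steady hops
    midstance_mode: str = "pct50"  # or "peak_grf"

    def __post_init__(self):
        if self.midstance_mode not in ("pct50", "peak_grf"):
            raise PipelineError("bad_config", f"midstance_mode {self.midstance_mode!r}")
        if not 0 < self.stance_threshold_frac < 1:
            raise PipelineError("bad_config", "stance_threshold_frac must be in (0,1)")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("smoothing", SmoothingSpec),
            ("fractions", SegmentFractions),
            ("moment_arm", MomentArmConfig),
            ("tendon", TendonConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
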