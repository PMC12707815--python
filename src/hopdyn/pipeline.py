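"""End-to-end analysis of one trial and cohort-level assembly.

``analyze_trial`` runs the full chain — smoothing, stance detection, speed
and mass estimation, joint kinematics, crouch factor, inverse dynamics,
EMA, joint power/work and tendon stress — and returns a ``TrialResult``
whose scalar summary row feeds the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig, STANCE_GRID_N
from .dynamics import (JointMomentSeries, build_limb_model, inverse_dynamics,
                       normalize_moment)
from .energetics import (WorkSummary, joint_power, tendon_csa, tendon_force,
                         tendon_stress, work_by_joint, TendonStressSeries)
from .errors import PipelineError
from .kinematics import (CrouchSeries, JointAngleSeries, crouch_factor,
                         joint_angles, segment_lengths, total_limb_length,
                         timing_metrics)
from .leverage import EMASeries, MomentArmProfile, ema_series
from .preprocess import (NormalizedGRF, SmoothedMarkers, StanceWindow,
                         detect_stance, estimate_body_mass, is_steady,
                         normalize_grf, resample_to_pct, trial_speed)
from .trial_io import ResultBundle, Trial


@dataclass
class TrialResult:
    trial_id: str
    stance: StanceWindow
    speed: float
    body_mass: float
    steady: bool
    lengths: Dict[str, float]
    angles: JointAngleSeries
    crouch: CrouchSeries
    grf_norm: NormalizedGRF
    moments: JointMomentSeries
    powers: Dict[str, np.ndarray]
    work: Dict[str, WorkSummary]
    ema: EMASeries
    stress: TendonStressSeries
    smoothed: SmoothedMarkers = field(repr=False, default=None)

    # -- reporting --------------------------------------------------------
    def scalar_row(self) -> dict:
        ankle = self.work["ankle"]
        min_ema = self.ema.min_ema()
        row = {
            "animal_id": self.trial_id.rsplit("_", 1)[0],
            "body_mass_kg": self.body_mass,
            "speed_m_s": self.speed,
            "steady": self.steady,
            "contact_duration_s": self.stance.contact_duration,
            "peak_grf_bw_per_leg": self.grf_norm.peak_vertical_bw,
            "min_cf": self.crouch.min_cf,
            "min_cf_pct_stance": self.crouch.min_cf_pct_stance,
            "ema_midstance": self.ema.ema_midstance,
            "min_ema": min_ema.value,
            "r_midstance_m": self.ema.r_midstance,
            "R_midstance_m": self.ema.R_midstance,
            "ankle_height_midstance_m": self.ema.ankle_height_midstance,
            "peak_stress_mpa": self.stress.peak_stress_mpa,
            "peak_stress_pct_stance": self.stress.peak_pct_stance,
            "safety_factor": self.stress.safety_factor,
        }
        for joint, w in self.work.items():
            row[f"{joint}_pos_work_j_kg"] = w.positive_work
            row[f"{joint}_neg_work_j_kg"] = w.negative_work
            row[f"{joint}_net_work_j_kg"] = w.net_work
        for joint, a in self.angles.angles_deg.items():
            mask = self.stance.mask(self.angles.time)
            row[f"{joint}_angle_td_deg"] = float(a[mask][0])
            row[f"{joint}_angle_mid_deg"] = float(
                np.interp(self.stance.mid_time, self.angles.time, a))
        return row

    def timeseries_table(self) -> pd.DataFrame:
        """101-point %-stance table of the main time-varying outputs."""
        stance = self.stance
        pct = np.linspace(0.0, 100.0, STANCE_GRID_N)
        data = {"pct_stance": pct}
        for j, a in self.angles.on_pct_grid(stance).items():
            data[f"{j}_angle_deg"] = a
        data["crouch_factor"] = resample_to_pct(
            self.crouch.time, self.crouch.crouch_factor, stance)
        for ax, name in ((0, "fore_aft"), (1, "vertical"), (2, "lateral")):
            data[f"grf_{name}_bw"] = self.grf_norm.grf_bw[:, ax]
        dimless = normalize_moment(self.moments, self.body_mass,
                                   total_limb_length(self.lengths))
        on_grid = self.moments.on_pct_grid(stance)
        for j in on_grid:
            data[f"{j}_moment_nm"] = on_grid[j]
            data[f"{j}_moment_dimless"] = resample_to_pct(
                self.moments.time, dimless[j], stance)
            data[f"{j}_power_w"] = resample_to_pct(
                self.moments.time, self.powers[j], stance)
        data["r_m"] = self.ema.r
        data["R_m"] = self.ema.R
        data["ema"] = self.ema.ema
        data["ankle_height_m"] = self.ema.ankle_height
        data["stress_mpa"] = resample_to_pct(
            self.moments.time, self.stress.stress_mpa, stance)
        return pd.DataFrame(data)


def analyze_trial(trial: Trial, config: Optional[PipelineConfig] = None,
                  profile: Optional[MomentArmProfile] = None) -> TrialResult:
    """Run the full analysis chain on one trial."""
    from .preprocess import smooth_positions

    config = config or PipelineConfig()
    profile = profile or MomentArmProfile(config.moment_arm)
    forward = trial.forward

    smoothed = smooth_positions(trial.markers, config.smoothing)
    stance = detect_stance(trial.forces, config.stance_threshold_frac,
                           config.contact_floor_n, config.multi_contact_gap_s)
    speed = trial_speed(smoothed, stance, forward)
    steady = is_steady(smoothed, stance, forward, tol=config.steady_speed_tol)

    mass = trial.metadata.body_mass
    if mass is None:
        mass = estimate_body_mass(trial.forces,
                                  (trial.forces.time[0], trial.forces.time[-1]),
                                  stance)
    if not mass > 0:
        raise PipelineError("bad_metadata", f"estimated mass {mass:.2f} kg")

    lengths = segment_lengths(smoothed, stance)
    angles = joint_angles(smoothed, forward)
    crouch = crouch_factor(smoothed, lengths, stance, forward)
    grf_norm = normalize_grf(trial.forces, stance, mass)

    model = build_limb_model(mass, lengths, config.fractions)
    moments = inverse_dynamics(model, smoothed, trial.forces, stance, forward,
                               config=config)
    powers = joint_power(moments, angles)
    work = work_by_joint(powers, moments.time, mass)

    ema = ema_series(angles, smoothed, trial.forces, stance, profile,
                     profile.subject_scale(lengths["shank"]), forward, config)

    r_at = np.interp(moments.time, stance.grid_times(), ema.r)
    force = tendon_force(moments.moments["ankle"], r_at)
    csa = tendon_csa(mass, config.tendon.csa_a, config.tendon.csa_b)
    pct_of_t = 100.0 * (moments.time - stance.start_time) / stance.contact_duration
    stress = tendon_stress(force, csa, config.tendon.failure_stress_mpa,
                           pct=pct_of_t)

    return TrialResult(
        trial_id=trial.metadata.trial_id, stance=stance, speed=speed,
        body_mass=mass, steady=steady, lengths=lengths, angles=angles,
        crouch=crouch, grf_norm=grf_norm, moments=moments, powers=powers,
        work=work, ema=ema, stress=stress, smoothed=smoothed)


def analyze_cohort(trials, config: Optional[PipelineConfig] = None,
                   profile: Optional[MomentArmProfile] = None,
                   steady_only: bool = True) -> pd.DataFrame:
    """Analyse a list of trials into a tidy per-hop scalar table."""
    rows = []
    for trial in trials:
        res = analyze_trial(trial, config, profile)
        if steady_only and not res.steady:
            continue
        rows.append(res.scalar_row() | {"trial_id": res.trial_id})
    return pd.DataFrame(rows)


def bundle_results(results, config: Optional[PipelineConfig] = None) -> ResultBundle:
    bundle = ResultBundle(config=config or PipelineConfig())
    for res in results:
        bundle.add(res.trial_id, res.scalar_row(), res.timeseries_table())
    return bundle
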