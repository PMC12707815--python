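"""Generate one synthetic hopping trial and inspect its ground truth.

Builds a 20 kg hopper at 2.5 m/s, writes the marker (TRC) and force-plate
(CSV) files plus a truth summary JSON, and prints the trial's headline
mechanics.  The per-leg peak force is in body weights (BW); the safety
factor is tendon failure stress (100 MPa) over peak operating stress.
"""

from pathlib import Path

import numpy as np

from hopdyn import SyntheticTrialSpec, generate_trial, write_synthetic_trial

spec = SyntheticTrialSpec(body_mass=20.0, speed=2.5, marker_noise_sigma=0.001,
                          seed=1)
trial, truth = generate_trial(spec)
paths = write_synthetic_trial(trial, truth, Path("scratch/example_trial"))

print(f"wrote {paths['markers'].name}, {paths['forces'].name}")
print(f"stance duration : {truth.stance_end - truth.stance_start:.3f} s")
print(f"peak GRF        : {truth.peak_grf_bw_per_leg:.2f} BW per leg")
print(f"min crouch factor: {truth.min_cf:.3f} at "
      f"{truth.min_cf_pct_stance:.1f}% stance (1 = fully extended limb)")
print(f"peak tendon stress: {truth.peak_stress_mpa:.1f} MPa "
      f"(safety factor {truth.safety_factor:.2f})")
mid = np.argmin(np.abs(truth.time - 0.5 * (truth.stance_start
                                           + truth.stance_end)))
print(f"midstance ankle EMA: {truth.ema[mid]:.3f} "
      f"(r = {truth.r[mid] * 1e3:.1f} mm, R = {truth.R[mid] * 1e3:.1f} mm)")
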