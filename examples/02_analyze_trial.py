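"""Run the full analysis pipeline on one trial read from disk.

Generates a noise-free hop, writes it to TRC + CSV, reads it back through
trial_io, and runs the chain: smoothing, stance detection, joint angles,
crouch factor, inverse dynamics, EMA, joint work and tendon stress.  The
printed per-hop scalars are what the cohort statistics consume.
"""

from pathlib import Path

from hopdyn import (PipelineConfig, SmoothingSpec, SyntheticTrialSpec,
                    analyze_trial, generate_trial, read_trial,
                    write_synthetic_trial)

config = PipelineConfig(smoothing=SmoothingSpec("fixed_spline", 0.0))
spec = SyntheticTrialSpec(body_mass=18.0, speed=3.2, marker_noise_sigma=0.0,
                          seed=4)
trial, truth = generate_trial(spec, config=config)
paths = write_synthetic_trial(trial, truth, Path("scratch/example_analysis"))

back = read_trial(paths["markers"], paths["forces"], trial.metadata, config)
res = analyze_trial(back, config)

print(f"speed             : {res.speed:.2f} m/s (true {truth.speed:.2f})")
print(f"contact duration  : {res.stance.contact_duration * 1e3:.0f} ms")
print(f"peak GRF per leg  : {res.grf_norm.peak_vertical_bw:.2f} BW")
print(f"midstance EMA     : {res.ema.ema_midstance:.3f}")
print(f"peak tendon stress: {res.stress.peak_stress_mpa:.1f} MPa at "
      f"{res.stress.peak_pct_stance:.0f}% stance")
print("joint work (J/kg, positive / negative / net):")
for joint, w in res.work.items():
    print(f"  {joint:5s} {w.positive_work:+.2f} / {w.negative_work:+.2f} "
          f"/ {w.net_work:+.2f}")
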