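# Methods

## Scope and model

The package analyses single hops of a bouncing biped (kangaroo-like) in the
sagittal plane. A hop is one foot-contact ("stance") flanked by flight. The
hindlimb is a chain of rigid segments — pelvis (ilium–hip), thigh, shank,
metatarsus, phalanges — joined by hinge joints (hip, knee, ankle,
metatarsophalangeal). Straight-line hopping justifies planarisation: the
travel direction is estimated from the net horizontal pelvis displacement
and all mechanics are computed in the (fore-aft, vertical) plane; the
medial-lateral force component is carried through the I/O layer but ignored
by the mechanics.

## Event detection and preprocessing

Stance is the period with vertical GRF above 2% of its peak; crossing times
are linearly interpolated between samples, so contact durations are not
quantised to the sample period (±5 ms at 200 Hz would be material for
contact-time regressions). Sub-threshold dropouts shorter than 50 ms are
bridged; genuinely separate loaded regions raise an error rather than
guessing.

Forces recorded at 1000 Hz are decimated onto the 200 Hz marker clock by a
centred boxcar average. The boxcar is exact for linear signals and
preserves impulse, which is what the impulse-based body-mass estimate
(`m = ∫F_y dt / (T_cycle · g)`, `g = 9.81 m/s²` exactly) depends on;
waveform fidelity at 200 Hz matters less. The plate baseline is the mean
over a 50 ms unloaded window ending 10 ms before the force first exceeds a
10 N contact floor; the guard keeps the loading ramp out of the baseline.
The centre of pressure is averaged only over loaded samples and is NaN in
flight, where it is undefined.

Marker trajectories are smoothed per coordinate with cubic smoothing
splines; the roughness penalty is chosen by generalised cross-validation by
default, or fixed (zero = interpolating) for noise-free synthetic data.
Velocities and accelerations come from the same spline, so kinematics and
dynamics stay mutually consistent. Marker gaps up to 5 frames are filled by
cubic spline; longer gaps reject the trial. Hop speed is the mean
horizontal pelvis velocity over the aerial windows flanking stance; trials
whose pre- and post-stance aerial speeds differ by more than 10% are
flagged non-steady and excluded from cohort regressions by default.

## Kinematics

Joint angles use the included-angle convention at the middle marker of each
triplet, in (0°, 180°]: ankle dorsiflexion decreases the ankle angle, MTP
plantarflexion increases the MTP angle. Angular velocity is computed from
the exact identity `ω_w = (w × ẇ)/|w|²` applied to spline-derived marker
velocities — algebraically the derivative of the unwrapped angle, without
fitting a second spline. Segment lengths are the median inter-marker
distance over stance (rigid thereafter; a length CV above 10% flags a soft,
skin-movement-affected segment). The crouch factor is pelvis-to-toe
distance over summed segment lengths. Extrema on the uniform 101-point
%-stance grid are refined by three-point quadratic interpolation (exact for
a parabola; monotone series report a flagged boundary extremum).

## Inverse dynamics

Net joint moments come from a planar distal-to-proximal Newton–Euler
recursion starting at the phalanges, where the per-leg GRF (half the plate
total: equal sharing between legs) acts at `(cop_x, 0)`. Segment mass is a
configurable fraction of body mass (defaults: thigh 0.10, shank 0.045,
metatarsus 0.02, phalanges 0.005 — order-of-magnitude placeholders, since
the quantitative checks are either invariant to them or use the generator's
own model), the CoM sits midway along the segment, and the transverse
inertia follows the uniform cylinder `I = m(L²/12 + ρ²/4)` with
`ρ = 0.1 L`. All inertial terms are retained; accelerations are the
smoothing spline's second derivative. Moments are reported
extensor/plantarflexor-positive: the raw z-moment on the distal segment is
multiplied by the joint's chain chirality (the sign of the rotation from
proximal to distal segment vector), which makes extensor moment ×
extension velocity positive power at every joint, and lets the MTP's
absorptive role emerge with the conventional sign.

## Leverage and tendon stress

The Achilles moment arm r(θ) defaults to a symmetric parabola peaking at an
ankle angle of 114.4° with curvature 6.25e-5 deg⁻² (≈10% drop 40° from the
peak) and r_peak = 22 mm for a 0.30 m reference shank; per-subject r scales
with shank length. The exact musculoskeletal-model-derived profile is not
public, so a table-driven profile (CSV of angle, r with monotone-cubic
interpolation) is first-class. R is the point–line distance from the ankle
marker to the GRF line of action in the sagittal plane; EMA = r/R is masked
wherever the vertical force is at or below the stance threshold (R is
direction-only, hence EMA is invariant to force rescaling). Midstance is
50% stance by default; a config switch moves it to the time of peak
vertical GRF (the two coincide on symmetric loading).

Tendon force is `max(M_ankle, 0)/r` — the tendon cannot push, so
dorsiflexor-moment samples carry zero force. The combined gastrocnemius +
plantaris cross-section is `A = a·m^b` with b = 0.67 and a = 5.3e-6
m²·kg⁻ᵇ, calibrated so the 20 kg reference hop at 2.5 m/s peaks near
50 MPa (≈42 mm² at 20 kg, a physiologically sensible area); the failure
stress defaults to 100 MPa, the value consistent with safety factors of 2
at ~50 MPa and 1.67 at ~60 MPa. The flexor digitorum longus is excluded —
it is a foot-placement tendon, not a significant energy store. Work
decomposition integrates power by trapezoid within sign-homogeneous periods
delimited by interpolated zero crossings, so the sums are grid-resolution
robust; stance-only integration is used throughout (net work identities
hold to machine precision by construction).

## Statistics

Each hop is an independent observation. Outcomes are fitted by OLS on
`mass + speed + mass:speed`; the interaction is dropped when its two-sided
p ≥ 0.05 and the additive model refitted (α = 0.05 throughout). The
stress–EMA relation is fitted as a power law by OLS on log–log axes (the
multiplicative-error convention; R² reported on the log scale), with
trial-level points by default and an animal-level aggregation available.
Tertile grouping at the 33.3/66.7 percentiles is for display only.

## Synthetic-trial generator

The generator emulates the structure of real hopping data so every pipeline
stage is testable without animal recordings. Study conditions follow the
observed envelope: masses 13.7–26.6 kg, speeds 1.99–4.48 m/s, contact
durations `t_c = 0.42 − 0.05·v` s (≈0.2–0.32 s, shortening with speed),
per-leg peak vertical GRF `1.0 + 0.45·v` BW (≈1.9–3.0 BW, mean ≈2.4 BW at
3.1 m/s), and a weak positive mass–speed correlation (0.24). Vertical GRF
is a half-sine whose impulse balances body weight over the cycle, which
fixes the flight duration (an inconsistent requested flight time is an
error); the fore-aft force is SLIP-like, directed from the centre of
pressure toward the pelvis marker with a zero-net-impulse correction, the
weak force/trajectory coupling resolved by a few fixed-point iterations.
The CoP emulates a planted foot rolling heel-to-toe: a linear fore-aft
travel of 0.6×(foot length), centred under the pelvis at midstance (linear
in time, hence exact under boxcar decimation).

Joint angles follow C1 cosine segments through touchdown/midstance/toe-off
knots; the distal joints reach their midstance values at 44% of stance
(maximum ankle dorsiflexion slightly before midstance, so tendon recoil
overlaps the high-force phase), the proximal joints at 50%. Default knots
(ankle 130°→112°→150° at 2.5 m/s, midstance dorsiflexion deepening
~14°/(m/s) toward ~76° at the fastest speeds; MTP plantarflexing with
speed; hip and knee nearly speed-invariant) were chosen so the midstance
posture places the ankle ≈9 cm behind the pelvis — giving midstance
EMA ≈ 0.25 with r ≈ 22 mm — while keeping the limb crouch minimal near
midstance and the foot spanning the CoP path. Markers come from planar
forward kinematics down the chain from the pelvis trajectory (obtained by
integrating the forces; ballistic in flight), with optional seeded Gaussian
jitter (1 mm default, typical of optical capture).

Ground truth is evaluated by the generator's own code on the noise-free
signals: truth moments apply the same Newton–Euler formulas through an
independently written pass on cubic-spline kinematics, and truth forces on
the marker clock are the boxcar view of the 1000 Hz record — the quantity a
synchronised acquisition actually delivers. Truth angular velocities are
likewise the spline-consistent rates of the sampled data (sampling cannot
see sub-sample waveform kinks). Recovery tests therefore verify the
pipeline's event detection, resampling, differentiation and bookkeeping,
while formula correctness is covered independently by closed-form oracles
(static torque balance, pinned-rod pendulum, point–line distance,
half-sine event timing).

What the generator does not emulate: a foot that is literally stationary on
the plate (markers sweep smoothly while the CoP models the planted foot),
whole-body angular-momentum balance, skin-movement artefact, and the
empirical covariance structure that produced the published cohort
regression coefficients. Passing recovery tests consequently demonstrates
correctness of the analysis chain on dynamically balanced inputs, not
agreement with any specific animal dataset.

## Numerical choices and problem sizes

Tolerances in the test suite: noise-free end-to-end recovery asserts angles
to 0.1°, moments to 1e-6 of each joint's peak, per-joint work to 1% (with a
0.01 J/kg floor for near-zero hip work, whose relative error is dominated
by the 2%-threshold trimming of the integration window), and EMA to 1e-9 at
the native samples. Recovery and invariant suites run on a 20-trial
noise-free cohort; parameter-recovery uses a 60-hop cohort and type-I-error
control 100 seeded 15-hop null cohorts — sizes chosen to keep the full
suite under a couple of minutes on one core while leaving the statistical
checks well-powered. Ties in tertile grouping keep input order; degenerate
(all-equal) groupings warn. Angles outside the 60–180° moment-arm domain
are clamped with a warning; accelerations above 50 g raise a
kinematic-artefact warning but do not stop the analysis.

## Known limitations

Hip and knee EMA are out of scope (surface markers track proximal joints
poorly). The inverse dynamics models the hindlimb chain only, with the GRF
as sole external load — trunk and tail dynamics are not represented. The
segment mass fractions and tendon CSA coefficients are calibrated
placeholders, and conclusions that depend on their absolute values should
be re-run with measured anatomy via the configuration.
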