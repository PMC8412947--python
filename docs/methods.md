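# Methods

## Scope and data model

`mtulab` analyzes one stance phase of running at a time. A trial is a
uniformly sampled table (`time_s, knee_deg, ankle_deg, fascicle_mm,
pennation_deg, emg_V[, moment_Nm]`); lengths are mm, angles degrees, times
seconds. All stance curves live on a common 101-point 0–100 % grid.
Stance averages are trapezoidal grid means (endpoint samples
half-weighted), i.e. discrete time averages; a plain arithmetic mean over
an inclusive endpoint grid would bias endpoint-vanishing quantities (such
as velocities that are zero at touchdown and toe-off) by O(1/n) ≈ 1 %.

## Event detection and geometry

Touchdown/toe-off are consecutive local minima of the knee angle; among
all consecutive minima pairs the one bracketing the largest knee-flexion
excursion is chosen, which is the stance signature (flexion then
re-extension). Indices are sample-exact; no sub-sample refinement is
attempted.

MTU length is reconstructed incrementally, `ΔL = r(φ_mid)·Δφ` with Δφ in
radians and the lever arm evaluated at the interval midpoint angle when
angle-dependent (supplied as a linear-interpolation table; angles outside
the table raise a range error). Only length *changes* are meaningful; the
initial MTU length is a configuration input. The angle sign convention is
that increasing angle lengthens the MTU (dorsiflexion for plantar flexors,
knee flexion for knee extensors). Belly length accumulates changes of the
fascicle projection `L_f·cos β`; this tracks the projection of the
fascicle onto the MTU line, not the anatomical belly length.

Velocities are central differences (one-sided at the ends, `np.gradient`).
Raw derivatives keep their sign (shortening negative); the muscle-model
boundary negates, so the Hill and efficiency layers see
shortening-positive velocities in `L_0/s`. No smoothing is applied by
default; an optional zero-phase 4th-order low-pass (configurable cutoff,
15 Hz used in the examples and acceptance runs on noisy data) filters the
kinematic channels before detection and differentiation. With raw white
noise on kinematic channels, unsmoothed differentiation is meaningless at
1 kHz, so noisy analyses should always set a cutoff.

## Contractile model

The individual force-length relation is a least-squares quadratic of
tendon force (joint moment / lever arm) against fascicle length; fits with
non-negative curvature (including numerically flat, e.g. collinear data)
are rejected since no force optimum exists. A vertex outside the fitted
length range extended by ±20 % of its span is flagged as extrapolated
(warning, not an error — the threshold is a pragmatic default, not an
empirical fact). `L_0` and `F_max` are the vertex coordinates, and the
force-length potential `F(L)/F_max` is clipped to [0, 1].

Force-velocity uses the Hill hyperbola with normalized constants
`a_rel = 0.1 + 0.4·FT` and `b_rel = a_rel·V_max`. Defaults for the two
muscles studied are shipped both as the formula path and as published
rounded constants (soleus: FT 0.19, a_rel 0.175, b_rel 1.182, V_max
6.77 L_0/s; vastus lateralis: FT 0.63, a_rel 0.351, b_rel 4.042, V_max
11.51 L_0/s). The rounded constants are the reproducibility defaults; they
differ from the formula products in the third decimal, which is why the
potential's zero can sit a hair before/after `V_max` — evaluation is
explicitly floored to 0 for `v ≥ V_max`. For lengthening (v < 0) no
eccentric branch is defined by the concentric Hill relation; the default
policy clamps the potential to 1.0, with a mirrored eccentric hyperbola
(saturating at `1.3 + 0.3·a_rel`) available as a configuration switch.
V_max sensitivity scales `V_max` by a factor, keeps `a_rel`, and scales
`b_rel` by the same factor.

Stance-averaged potentials are averages of the instantaneous potential
over the grid, not potentials of the mean length/velocity — the two differ
whenever the trajectory is not constant.

## Enthalpy efficiency

Efficiency is taken from a load-efficiency table (relative load
`p = P/P_0` vs enthalpy efficiency η at `a/P_0 = 0.25`), transposed to
normalized shortening velocity with `v/V_max = (1 − p)/(1 + p/(a/P_0))`
(derived from `(P + a)(v + b) = (P_0 + a)·b` with `V_max = b·P_0/a`), then
interpolated with a natural cubic spline anchored at (0, 0) and (1, 0).
The peak is located on a 0.001-resolution grid. Efficiency is 0 for
isometric or lengthening states and for `v ≥ V_max`.

The packaged table (`data/load_efficiency_a025_synthetic.csv`) is a
synthetic reconstruction, generated by
`synthesize_load_efficiency_table`: velocity from the Hill relation with
mechanical constant `a/P_0 = 0.25`, and
`η(p) = p·v / (p·v + (0.16 + 0.18·p)·v + a·b)` — work over work plus
shortening heat (load-dependent coefficient 0.16 + 0.18·p) plus a
maintenance-heat rate of `a·b`. Splined, it peaks at η ≈ 0.446 at
v/V_max ≈ 0.19, matching the published curve summary (0.45 at 0.18) within
its tolerance. A user with the historical table can substitute it as a
`LoadEfficiencyTable` without code changes.

By default a trial's efficiency is evaluated at the stance-*mean* fascicle
velocity; an instantaneous-efficiency-then-average mode exists behind
`efficiency_mode="instantaneous"`. The two differ for strongly varying
velocity profiles; group reporting conventions differ on this, so both are
provided.

## Decoupling

`DC_Tendon`, `DC_Belly`, `DC_MTU` are absolute velocity differences
normalized by the subject's *absolute* `V_max` (`V_max·L_0`, mm/s), so
units cancel; they are computed on the normalized stance grid (grid-first,
so group curves share an abscissa — whether decoupling is computed before
or after time normalization is a convention, and grid-first is the one
used throughout). Non-negativity, the triangle inequality
`DC_MTU ≤ DC_Tendon + DC_Belly`, and scale invariance hold by
construction and are property-tested. Gearing ratios (`V_MTU/V_Belly`
etc.) are provided for comparison only, with samples whose denominator is
below a configurable epsilon masked as undefined; they never feed headline
outputs.

## EMG

Processing is 4th-order Butterworth high-pass at 50 Hz, full-wave
rectification, 4th-order low-pass at 20 Hz (the low-pass order mirrors the
high-pass since only cutoffs are conventionally reported), all zero-phase
(forward-backward) so peak-timing metrics are unbiased; residual ringing
is floored at zero. Envelopes are normalized to the maximum of an MVC
envelope processed identically. Peak-activation timing is the earliest
argmax on the stance grid in percent of stance; a flat envelope has no
peak and is reported missing.

## Synthetic data

The generator emulates one stance phase: fascicle length, pennation, and
the MTU profile are cubic smoothstep interpolants (C¹, zero end-velocity)
between endpoint values, so analytic velocities exist everywhere. The MTU
rises by the configured excursion until the shortening onset, then falls
to −0.5× the excursion at toe-off (lengthening-shortening). The joint
driving the MTU is synthesized by inverting the lever-arm relation, the
knee angle carries exact minima at the window boundaries with monotone
swing-like padding outside, EMG is a 150 Hz carrier under a Gaussian burst
envelope, and additive i.i.d. Gaussian noise is drawn per channel in a
fixed order (knee, ankle, fascicle, pennation, EMG, moment) from one
seeded stream — identical config and seed give bit-identical output.

Preset endpoint values are set to the published stance-averaged operating
conditions of the two muscles during moderate-speed running: soleus-like —
stance 304 ms, fascicles 0.994→0.752 `L/L_0` (mean velocity
0.796 `L_0/s`), pennation 19.4→28.4°, MTU excursion 18 mm peaking at 59 %
of stance (stance-averaged DC_Tendon 0.570, DC_Belly 0.017), EMG burst at
41 % of stance; vastus-lateralis-like — stance 290 ms, fascicles
1.066→1.042 (mean 1.054, velocity 0.083 `L_0/s`), pennation 13.2→13.4°,
excursion 22.6 mm peaking at 50 % (DC_Tendon 0.180), burst at 35 %. MVC
datasets are concave-quadratic force samples spanning the vertex; MVC EMG
is a carrier with a smooth ramp-plateau-ramp envelope (an abrupt onset
would put a zero-phase filter transient into the normalization peak).

Ground truth is computed from the analytic trajectories, independently of
the sampled-signal path: smooth integrands by composite Simpson quadrature
on 20 001 points, the absolute-value decoupling integrands piecewise
between sign changes (bracketed by scanning and refined with Brent's
method) with adaptive quadrature. Per-channel default noise (0.1° angles,
0.3 mm fascicle, 0.2° pennation, 0.02 V EMG, 1 N·m moment) reflects
post-tracking measurement scatter, not raw sensor noise.

What passing synthetic tests do *not* show: the generator prescribes
trajectories rather than simulating dynamics, so it cannot validate the
lever-arm model against real joint kinematics, fascicle-tracking errors,
step-to-step variability structure (noise is white and independent), or
eccentric phases (presets shorten monotonically). Results on real data
additionally depend on marker-based angle quality and ultrasound tracking,
which are out of scope.

## Pipeline and numerical choices

`analyze_trial` composes detection → geometry → differentiation →
normalization → potentials/efficiency/decoupling/EMG and is exactly equal
to running the stages manually (tested). Reports are JSON scalars with a
delimited-text curve sidecar; group summaries use sample SD (n−1
denominator, 0 for a single report). Determinism: identical inputs and
configuration give byte-identical reports.

Problem sizes in tests and the acceptance script (1 kHz sampling, ~300 ms
stances, 9 trials per preset group, 200 Monte-Carlo force-length draws,
20 001-point ground-truth quadrature) were chosen as the smallest sizes at
which the quantities of interest are stable to well below their assertion
tolerances.

## Known limitations

* The belly-length contract tracks projection changes; absolute belly
  length is not modeled.
* One efficiency curve is used for both muscles (no fiber-type-specific
  efficiency), and the packaged table is a reconstruction, not the
  historical measurement.
* No activation dynamics, series-elastic force estimation, or
  pennation-dependent force transmission.
* Group inferential statistics (t-tests, SPM) are out of scope; exports
  are designed to feed existing tools.
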