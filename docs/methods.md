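# Methods

## Model and estimator

The system is modeled as rigid statics in the horizontal plane: a segment
S₁ (mass M₁, CoM at CoM₁ relative to its rotation center), a static
remainder S₂ (mass M₂), and a static carrier (board or frame) rest on a
board supported at three non-collinear points. The whole-system CoM
decomposes as CoM·M = CoM₁M₁ + CoM₂M₂ (+ carrier), and rotating only S₁
by θ about the origin turns CoM₁ by the rotation matrix R(θ). Subtracting
the two postures eliminates every static term:

    (CoM_α − CoM_β)·M = (I − R(θ))·CoM₁,α·M₁

`estimate_moment` solves this 2×2 system for v = CoM₁,α·(M₁/M) and returns
M⁽¹⁾ = |v|·M. Because I − R(θ) is a scaled rotation with both singular
values equal to 2 sin(θ/2), the closed scalar form
M⁽¹⁾ = M·|ΔCoM|/(2 sin(θ/2)) is exactly equivalent
(`estimate_moment_scalar`); the test suite asserts the equivalence to
1e−12 over 1,000 random instances.

Assumptions inherited from the measurement principle:

- the rotation is purely horizontal (gravity moments unchanged), about a
  fixed center, and the segment is rigid during a set;
- nothing else moves between the α and β readings (posture drift is a
  simulator noise option, not part of the estimator);
- the CoM difference is origin-free, so the estimator needs the rotation
  center only to report the segment-CoM *bearing*, never for the moment
  magnitude itself — errors in the digitized rotation center therefore do
  not propagate into M⁽¹⁾ under this model.

The estimated moment is a magnitude and is invariant to the rotation
handedness; the counter-clockwise-positive convention (configurable via
`clockwise_positive`) only affects the sign of the reported bearing.

## Units, conventions, tolerances

- Positions in cm, masses in kg, moments in kg·cm, angles in degrees at
  every interface (converted to radians internally). Scale readings are
  ingested in grams, the instrument's native unit.
- Singularity guard: angles within 1° (configurable) of 0°/360° are
  rejected — the chord gain vanishes there and noise amplification is
  unbounded. The admissible domain is (0°, 360°) exclusive; negative
  (mirror-convention) angles are accepted.
- Total mass for the estimate is the mean of the two states' summed
  readings. The two totals must agree within a gate defaulting to 3σ of
  their difference under the reference scale's 1.5 g precision
  (3·√6·1.5 g ≈ 11 g): each state's total is three independent readings,
  so the α−β difference has SD √6·σ. A literal per-reading 3σ gate
  (4.5 g) would reject ~22% of statistically ordinary sessions.
- `check_total_mass` (QC against a *declared* total) keeps the stricter
  3 × 1.5 g = 4.5 g default, since it compares one summed measurement to
  a nominal constant.
- Sample SD uses the n−1 denominator (metrological convention). Relative
  figures are reported against the calibrated reference moment when one
  is supplied, else against the session mean, and are rounded to one
  decimal in rendered reports (full precision in JSON).
- Degenerate inputs: support triangles with area < 1 cm² are rejected;
  all-zero readings raise an empty-load error; a system CoM outside the
  support triangle raises a tipping error (a support load would be
  negative, i.e. the board lifts off).

## Forward simulator and noise model

`simulate_session` defines state α as the segment's reference posture
θ = 0 (no generality lost — only the relative rotation matters) and
state β as the rotated posture. Support loads are the barycentric
coordinates of the system CoM times the total mass — the unique
three-point statics solution, whose inverse is exactly the CoM
computation, so noise-free sessions invert to the true moment to machine
precision ("inverse crime" asserted at 1e−10).

Noise sources, all configurable, applied in this order:

| source | default | emulates |
|---|---|---|
| `scale_sigma_g` | 1.5 g | reference scale's stated precision |
| `scale_quantum_g` | 0.1 g | display resolution, applied after the Gaussian noise |
| `angle_sigma_deg` | 0.5° | manual protractor reading of overlapped photographs |
| `position_sigma_cm` | 0.2 cm | straightedge digitization of support positions |
| `drift_sigma_cm` | 0 (off) | subject posture drift between sequential single-scale readings |

The scale figures are the reference instrument's stated specification;
the angle and position sigmas are engineering estimates for manual
photograph reading (no instrument specification exists for them) and are
deliberately prominent knobs.

Two modeling choices matter for realism:

- **Position noise is common-mode per set.** The supports do not move
  between the α and β weighings and are digitized from the same overhead
  pictures, so the same positional error is attached to both states of a
  set. Only the small *differential* effect (through the change in
  barycentric weights) reaches the moment. Treating the error as
  independent per state would inflate the simulated uncertainty roughly
  sixfold and contradict the precision the physical method demonstrably
  achieves.
- **The carrier is indistinguishable from S₂.** Board and frame masses
  are folded into the static side of the decomposition; a dedicated test
  asserts that adding arbitrary static mass anywhere changes both CoMs
  but not the estimated moment (to 1e−10 relative).

What the simulator does *not* emulate: camera perspective distortion
(argued negligible at the 2.4 m camera distance of the reference setup),
non-rigid segments, out-of-plane motion, rotation-center misestimation
(exposed only through the reported bearing, which the moment does not
use), and any systematic scale bias. Passing tests therefore demonstrate
correctness of the estimator and internal consistency of the pipeline
under this noise family — not that a particular physical campaign's error
budget is fully captured.

## Benchmark presets

- `dummy-bar`: segment = uniform end-pivoted bar, 3.013 kg × 77.2 cm
  (lever 38.6 cm, true moment 116.3018 kg·cm); static block 52.066 kg;
  board 11.627 kg; total 66.706 kg. Campaign: 30 sets, θ spanning
  30–180°.
- `human-leg`: subject 63.460 kg + frame 15.569 kg; the synthetic leg is
  10.0 kg (≈16% of body mass) with a 38.88 cm lever so the true moment
  equals the 388.8 kg·cm benchmark mean; the real subject's leg
  parameters are unknown, so comparisons are qualitative. Campaign: 15
  sets at θ = 48.8°.

Neither benchmark documents its support geometry; both presets use an
equilateral support triangle (circumradius 60 cm / 70 cm) centered near
the system CoM. That choice keeps every load positive across the full
angle range and makes the scale-noise covariance of the CoM nearly
isotropic, so conclusions about angle scaling are clean; conclusions
drawn from presets are conditional on this geometry and on the noise
defaults above.

## Uncertainty propagation

`monte_carlo` repeats simulate→estimate (default 2,000 replicates: SD of
the SD ≈ 1/√(2n) ≈ 1.6%, negligible against the tolerances used), reports
mean/SD/relative SD versus the true moment, counts tipped replicates
(aborting beyond 1%), and optionally attributes the spread per source by
one-factor-at-a-time reruns. Inside the Monte Carlo the estimator's mass
gate is widened well past the sampled noise so the replicate distribution
is not censored.

`analytic_sd` is the independent first-order route through
M⁽¹⁾ = M·|ΔCoM|/(2 sin(θ/2)): scale noise (plus the q/√12 quantization
equivalent) enters via ∂CoM/∂mᵢ = (Pᵢ − CoM)/M for each state, projected
on the ΔCoM direction; common-mode position noise via the difference of
the two states' barycentric weights; drift as equivalent per-reading load
noise; and the angle record via ∂M⁽¹⁾/∂θ = −M|ΔCoM|cos(θ/2)/(4 sin²(θ/2)).
The direction-projected covariance is used rather than an isotropic
approximation, so the scale term is only *approximately* proportional to
1/(2 sin(θ/2)) when the triangle covariance is anisotropic. Tests require
MC/analytic agreement within 15% at default noise, jointly and per
source.

Known estimator bias: |noisy vector| is biased upward, so the MC mean
exceeds the truth at high noise and converges to it as noise → 0. No
bias correction is applied; the bias is quantified by `mc_mean` versus
`true_moment` in the report.

Under the default noise model the single-set relative SD at θ = 90° is
≈0.5%, dominated by the angle record, with digitization second and scale
noise nearly negligible; precision degrades as 1/(2 sin(θ/2)) toward
small angles (≈1.7% at 30°). These figures are produced at run time by
`examples/03_uncertainty_budget.py` and `scripts/acceptance.py`, and are
conditional on the documented noise defaults.

## Problem sizes

Default sizes mirror the benchmark campaigns (30 and 15 sets) and use
2,000 Monte Carlo replicates per uncertainty figure; property tests use
1,000 random instances. The full test suite and the acceptance script
each complete in well under a minute on one CPU.
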