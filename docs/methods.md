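# Methods

This note documents the models behind `pacesense`, the parameter choices and
their rationale, the one-time detector calibration, and what the synthetic
study does and does not demonstrate about real devices.

## Synthetic VF electrograms

Proprietary device-recorded VF episodes cannot be redistributed, so every
experiment runs on a synthetic stand-in. An episode is a train of biphasic
intracardiac deflections: cycle lengths are drawn per cycle from a jittered
dominant frequency (default 4.5 Hz ⇒ 222 ms mean cycle, inside the 140–330 ms
VF band) and realized in whole 256 Hz samples; each cycle carries one
Gaussian-derivative deflection (σ = 5% of the cycle, ≈ 11 ms) whose peak
amplitude is drawn with coefficient of variation 0.2 and rescaled so the mean
per-cycle peak equals the target exactly before band-limited (1–40 Hz) noise
of 0.02 mV RMS is added.

Choices and why:

- **Deflection shape.** A narrow biphasic deflection, not a sinusoid: real
  bipolar VF electrograms contain sharp activations whose energy (≈ 10–30 Hz
  here) passes an ICD sense band nearly unattenuated. The detector's
  behaviour then depends on amplitudes and intervals, which are the modelled
  quantities, rather than on an arbitrary carrier frequency.
- **Amplitude distribution.** Libraries draw target mean amplitudes uniformly
  over 0.15–1.0 mV. The sensed-amplitude range and the 0.86 mV reference mean
  are study conditions; the distribution across episodes is not published, so
  uniform is used as the neutral choice.
- **Durations** uniform in 6–10 s, mirroring the length of device recordings
  that start at arrhythmia detection.
- **8-bit quantization** is available (±8 mV full scale by default, a chosen
  dynamic range) but off by default; it is not needed for any detection
  result.

The per-cycle mean amplitude estimator (`mean_vf_amplitude`) rectifies the
waveform, segments it at crossings of 25% of a 1 s running peak, and averages
the per-segment maxima — the amplitude a sense amplifier effectively responds
to. It is exactly homogeneous of degree one, which the ratio experiments rely
on.

## Episode looping

Episodes are stitched to 60 s: the loop point is the sample of minimal
absolute amplitude within the trailing 250 ms (ties → latest index), and at
each junction a monotone cubic (PCHIP) interpolant replaces ±4 samples,
anchored on three surviving samples per side. Monotone interpolation was
chosen over an unconstrained cubic so the patch can never overshoot its
anchors; outside the ±4-sample neighbourhoods the looped signal is
bit-identical to naive tiling, and the junction jump never exceeds the
unsmoothed jump.

## Pacing artefacts and the pre-amplifier model

Raw pulses are rectangles (optionally followed by a 10%-amplitude,
charge-balancing recharge tail) synthesized at 32 768 Hz — an integer 128×
the device rate; the front-end corners live far below Nyquist at either rate,
so the internal rate is a fidelity knob, not a semantic one. The
pre-amplifier model is a 2nd-order 10 Hz high-pass cascaded with a 2nd-order
95 Hz low-pass (bilinear-discretized Butterworth): it reproduces the
slew-rate reduction, opposite-polarity rebound and AC coupling of a real ICD
front end, whose exact transfer function is proprietary. The filtered train
is decimated to 256 Hz by anti-aliased polyphase resampling and added to the
VF recording; a short monotone-cubic patch smooths the hand-off at the edges
of each artefact's support (where the artefact is ≤ 1% of its peak, so the
pulse shape itself is untouched).

**Amplitude normalization is in the sensed domain.** The experiment's spike
amplitudes are amplitudes *as measured by the sense amplifier* (filtered and
rectified), which is also how the closest-case bench table reports them. A
sub-millisecond pulse is far narrower than one 256 Hz sample, and its
recorded amplitude depends strongly (up to ~3×) on the sub-sample alignment
of the pulse with the sampling grid; at pacing rates whose period is an
integer number of device samples, every pulse in a train shares one
alignment. The overlay therefore normalizes against the mean sensed peak of
the *actual* unit-amplitude train being inserted, making the realized sensed
spike amplitude track the request at any rate and phase while preserving
pulse-to-pulse scatter at incommensurate rates.

A consequence of sensed-domain amplitudes: pulse width influences detection
almost entirely *through* the sensed amplitude (wider pulses pass more energy
through the front end, as the bench table's sensed column shows). At equal
sensed amplitude the residual width effect is small, and the grid experiments
assert only that widening never helps.

## Sensing and detection

The detector is a generic auto-adjusting-sensitivity engine, not the
proprietary algorithm: band-pass (10–95 Hz, shared with the front-end
corners) and full-wave rectification; events fire on upward threshold
crossings outside a 150 ms blanking window; at each event the peak within
blanking restarts the threshold at `min(0.54 × peak, 5 mV)` (never below the
0.15 mV programmed floor, the device default), decaying exponentially with
τ = 450 ms toward the floor; VF is declared when 12 of the last 16 intervals
are below 320 ms, and therapy time adds a fixed 8 s charge.

**Calibration (performed once, then frozen).** The free parameters were tuned
jointly against three anchors on the synthetic library and then fixed at the
values above: (i) baseline detection ≥ 99% on 100 episodes spanning
0.15–1.0 mV with no pacing; (ii) the closest-case table's twelve
detect/no-detect outcomes, which place the decision boundary between sensed
spikes of 2.26 mV (ratio 2.63, detected) and 2.90 mV (ratio 3.37,
undetected) at 80 ppm — verified stable across nine independent episode
seeds; (iii) a ratio-response that is flat for ratios ≤ 2, collapses to
≤ 10% by ratio 7 at 60 ppm, and is uniformly worse at 90 ppm. The restart
fraction is the sharpest lever on the boundary (recovery time
≈ τ·ln(f·r) grows with the spike-to-VF ratio r); the NID choice trades
baseline sensitivity against masking specificity (18-of-24 lost one baseline
percentage point; 12-of-16 restores it at equal boundary placement).

**Known limitation.** A single sensitivity profile cannot simultaneously
reproduce the discrete closest-case boundary (undetected from ratio ≈ 3.4)
and a gentle intermediate slope with ~80% detection still at ratio 4; this
implementation prioritizes the discrete outcomes and the two quantitative
endpoints, so its detection falls off more steeply between ratios 3 and 5
than the reference device's. Rate-dependence, ≤ 2 safety and ratio-7 collapse
are unaffected.

One spec'd invariant was weakened deliberately: lowering the sensitivity
floor cannot guarantee an event-for-event superset in *any* adaptive
detector, because an extra early event shifts blanking and restarts
downstream. What does hold, and is tested, is that a lower floor never senses
fewer events and never senses later.

## Geometry and the volume-conductor model

Implant geometry is Cartesian (mm). The two scalar coordinates of the risk
model are D1 (ICD Ring2 ↔ pacemaker tip) and D2 (ICD Ring1 ↔ pacemaker
ring). `pose_from_distances` constructs a deterministic coplanar pose
realizing a given (D1, D2) exactly, preferring the bridging arrangement (tip
nearest Ring2, ring nearest Ring1) those definitions describe; lead electrode
separation defaults to 40 mm and capsule length to 25 mm.

The pacing field is a point current source/sink pair in an infinite
homogeneous medium of 375 Ω·cm (the tank's saline resistivity), with
programmed volts converted to current through a fixed 500 Ω interface
impedance. Only *orderings* are meaningful in this idealization — sensed
amplitude falls monotonically when the separation is scaled up, tracks the
distance sum D1+D2 across rotation poses far more than the pose itself, and
is largest on the bipolar lead vector when the can sits ≥ 100 mm away out of
the lead plane — never absolute bench values, which depend on boundaries and
tissue inhomogeneity outside the model.

## Population risk

The nine-patient distance set is proprietary; the shipped
`SYNTHETIC_NINE_PAIRS` fixture is synthetic: it contains the three printed
bench positions and six engineered pairs such that the fitted bivariate
normal's rectangle probability P(D1 < 35, D2 < 35) is ≈ 0.07, with no pair
having both coordinates below 35 mm (matching the observed cohort). The Monte
Carlo estimator samples the fitted normal (50 000 draws by default, negative
draws retained; an optional ≥ 10 mm feasibility rejection reflects the
collinear trade-off, off by default because the headline 7% figure is the
untruncated, conservative one) and attaches a Wilson 95% binomial interval.
Multiplying the geometric probability by the programming prevalence assumes
independence of implant geometry and programmed output — an explicit
modelling assumption. The prevalence sampler's default six-point amplitude
distribution is calibrated so its cumulative mass hits the two published
anchors (90.5% ≤ 1 V, 96.5% ≤ 3 V at 0.24 ms); the split within each bin is
otherwise a choice.

## Problem sizes and determinism

The standard experiment library is 100 episodes (the acceptance script's
size); unit and property tests use 10–20 episodes, which resolves detection
percentages to 5–10 points — adequate for the monotonicity and boundary
properties they assert. Every stochastic quantity is a pure function of an
integer seed: episodes hash (seed, index) through NumPy `SeedSequence`,
pacing phases derive one fraction per episode reused across grid cells (so
cells are comparable and amplitude monotonicity is testable), and every
`RiskEstimate` records its seed and sample count.

## What passing tests do and do not show

The synthetic generator reproduces the amplitude and interval statistics the
detector consumes, not fibrillation electrophysiology; the detector is a
calibrated generic engine, not the proprietary algorithm; the field model is
a homogeneous idealization of a saline tank, which is itself an idealization
of a thorax. Results therefore demonstrate the *mechanisms* — ratio-driven
masking, the pulse-width pathway through sensed amplitude, the
distance-not-angle dependence, and the arithmetic of joint risk — under
controlled conditions, and bound their parameter sensitivities; they do not
certify any particular device pairing.
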