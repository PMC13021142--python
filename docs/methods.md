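# Methods

## Scope and model overview

The package simulates closed-loop bidirectional control of heart rate via a
single vagus-nerve electrode that can either stimulate (low-frequency,
activity-increasing, heart-rate-lowering) or block (10 kHz KHFAC,
activity-decreasing, heart-rate-raising). Everything runs against a
synthetic plant; no recorded physiological data are used anywhere.

The closed loop is: plant → R-event stream → rolling heart-rate estimate →
fuzzy controller → calibration-based waveform command → plant. The
controller updates at 2 Hz; the plant integrates at 50 ms substeps.

## The synthetic cardiac-vagal plant

Heart-rate depression ("vagal drive", bpm) is

    D = clamp( min(S_p · f_perturb, max_drop) · T(amp) + S_c · f_stim,
               0, max_drop )

and the instantaneous heart rate relaxes toward `baseline − D` with one
first-order time constant τ (default 3 s). Design points:

* **Effector saturation.** `max_drop` is the span between the resting
  baseline and the heart-rate floor reached under maximal vagal drive — the
  intrinsic/escape rate of the anesthetized rat heart, drawn per animal as
  N(250, 25) bpm (truncated) against a baseline of N(400, 30) bpm, giving
  spans around 150 bpm. The frequency–response is linear at `S_p` bpm/Hz up
  to `f* = max_drop / S_p` (typically 10–25 Hz) and flat beyond, which is
  why the calibration sweep steps frequency only until the drop stops
  growing. Spans much larger than this would be inconsistent with the
  behavior the protocol is designed to expose: at a maximum slew of
  10 bpm/s a controller could never traverse a ±10% band of a ~300 bpm span
  fast enough for band-crossing dynamics to exist at all.
* **Block transmission.** `T(amp)` is 1 up to the per-animal starting block
  amplitude and falls linearly at `S_block / max_drop` per mA beyond it.
  Block multiplies the *post-saturation* perturbation drive (a fraction of
  fibers conducting scales the effective drive), so under a maximal 30 Hz
  perturbation the simulated heart-rate recovery is exactly `S_block`
  bpm/mA starting exactly at the starting block amplitude — the calibration
  procedure identifies the generating parameters operationally.
* **Population model.** Per-animal parameters are truncated normals bounded
  by the observed calibration ranges (stimulation sensitivity 5–12 bpm/Hz,
  starting block amplitude 0.5–3 mA p-p, block sensitivity 14.5–160
  bpm/mA p-p). The location of each underlying normal is solved
  numerically so the mean of the *truncated* distribution equals the
  reported population mean (9.2 bpm/Hz, 1.8 mA, 64.3 bpm/mA); plain
  truncation of a normal centered on the reported mean would bias the
  realized mean (most visibly +15% for the strongly asymmetric block
  sensitivity). The realized spread is necessarily somewhat narrower than
  the reported sd; the means are the quantities the tests pin down.
* **Beats.** R events are emitted where the integral of hr/60 crosses
  integers; each inter-beat interval receives additive Gaussian jitter
  (default sd 2 ms, floored at 20 ms). This is the only stochastic element
  of the plant. At a 2 s estimation window it produces ~0.5–0.7 bpm of
  estimate noise, enough to exercise the estimator and the controller's
  slope input.
* **First-order lag, τ.** One dominant time constant (default 3 s,
  config-exposed) is the minimal effector dynamic. Note a structural
  consequence: a first-order response is monotone, so closed-loop
  overshoot comes only from the estimator-plus-hold delay (~1.25 s), not
  from τ — see Limitations.

## Heart-rate estimation

The measured heart rate at time t is `60 / mean(R–R)` over the intervals
whose **later** R event falls in the half-open window `(t − 2 s, t]`
(mean-of-intervals, then reciprocal). With fewer than two beats in the
window the estimator holds its last valid value and flags a data gap. The
estimator is ticked at 2 Hz continuously — also during open-loop segments
such as calibration sweeps — exactly as a real-time system would run it.

## Controller

Error memberships are sigmoids with midpoints ±5 bpm and steepness
0.8 /bpm (a ≈ ±5 bpm dead zone around the setpoint); slope memberships are
the complementary trapezoid pair saturating at ±1 bpm/s. The rule table is

| error \ slope | Increasing | Decreasing |
| --- | --- | --- |
| Above | +1 | +0.4 |
| Near  | 0 (any slope) | 0 (any slope) |
| Below | −0.4 | −1 |

giving the characteristic four-plateau output surface (large/small change
for each direction) plus a zero region. Defuzzification is the weighted
singleton sum clamped to [−1, 1]; the per-update increment is
`(G / update rate) · ΔCout`, making G exactly the slew bound in bpm/s.
`cout` is clamped to ±200 (windup guard). All of these are config-exposed;
the membership and singleton values are stand-ins chosen for the stated
qualitative shape, since only the shape, not the numbers, is documented
for the original controller. Within the dead zone the output is not
strictly sign-correct (opposing sigmoid tails can produce |ΔCout| up to
~0.04); outside ±1 bpm of error the sign always matches the error.

## Calibration procedure

*Stimulation:* step the control electrode 1→30 Hz in 1 Hz / 10 s steps,
reading the rolling estimate averaged over the last 5 s of each dwell;
stop once a step fails to drop the heart rate by > 1 bpm (the maximal drop
is reached). An ordinary least-squares line through the falling segment
(the flattened knee point is trimmed) gives the sensitivity in bpm/Hz.

*Block:* under a maximal 30 Hz perturbation, raise the 10 kHz block
amplitude in 0.1 mA p-p steps until the estimate recovers to the resting
baseline. The **starting block current** is the largest amplitude whose
reading stayed within 1 bpm of the perturbed plateau — taking the *last*
such reading makes isolated noise blips harmless, and the plateau
reference is refined as the mean of all pre-onset readings. The recovery
slope (bpm/mA) is fitted from the starting current to recovery, cutting
points within one step-rise of baseline (they may be clamped at full
recovery). Finally the starting current is refined by back-extrapolating
the fitted line to the plateau level, clamped inside its 0.1 mA grid
interval; without this, every small block command would be biased by up to
`slope × 0.1 mA` bpm of quantization.

The 1 bpm rise threshold sits between the measurement noise of an averaged
dwell reading (~0.3 bpm) and the smallest per-step rise in the population
(1.45 bpm at 14.5 bpm/mA); a 2 bpm criterion would systematically detect
onset a grid step late for low-sensitivity animals. Both thresholds are
configurable.

Across 100 sampled animals the full pipeline recovers the generating
stimulation slope within 3.1%, the starting amplitude within 0.095 mA, and
the block slope within 4.6% (asserted at the looser 10% / 0.1 mA / 15%
bounds in the acceptance tests).

## Trial protocol

Per trial: ≤ 30 s of maximal 30 Hz control-electrode stimulation (minimum
rolling estimate → 0% anchor), 120 s recovery (resting estimate → 100%
anchor; an anchor span under 20 bpm raises an unresponsive-plant error),
setpoint fixed at the bpm midpoint, then 840 s of closed loop:
120 s quiet, 1→30 Hz perturbation ramp (10 s/Hz), 30→1 Hz ramp down, 120 s
quiet. Logging is at the controller rate (1681 rows, t = 0 at controller
start). `--no-control` runs the same timeline open-loop as the reference
condition.

## Metrics and categorization

Band metrics use the 40–60% normalized band over the controller-on window:
time to band (first sample below 60%), time in band (sample counting at
the 0.5 s grid), and the excursion count — completed above-and-below
pairs, counted by greedy pairing of maximal strictly-above / strictly-below
segments, so repeated exits on one side never count as oscillation.
Categories: **Oscillations** if ≥ 5 pairs, else **Slow** if outside the
band more than half the window, else **Stable** (mutually exclusive,
exhaustive, oscillation check first). Pairwise gain comparisons are
two-sided Wilcoxon rank-sum (Mann-Whitney) tests, exact for ≤ 12 untied
values per group, tie-corrected normal approximation otherwise; the
default significance level is 0.005 (configurable — an unusually strict
printed value, retained as such).

## Reproducibility and numerics

A single global seed fans out to named substreams through fixed spawn
keys, so adding a consumer never shifts existing streams; identical seeds
give bit-identical beat sequences, trials, and files. Problem sizes used
by the test suite: 10,000 population draws for the mean checks, 100
animals for calibration recovery, 20 seeds × 3 gains for the gain study
(and 9 seeds at τ = 6 s for the high-gain stability probe). Text output
uses 6 significant digits.

## What the synthetic bench does and does not show

The bench reproduces: exact protocol arithmetic; the gain-to-slew
correspondence; population calibration statistics; end-to-end parameter
recovery through the calibration procedure; and the ordering of response
speed with gain (median time-to-band ≈ 60/30/18 s at G = 2/5/10, τ = 3 s —
the same ordering and magnitude class as live-animal data).

It does **not** reproduce the in-vivo prevalence of degraded-control
categories. With a perfectly calibrated, linear, first-order plant the
2 bpm/s controller tracks the perturbation ramp with only a few bpm of
error (never approaching the Slow criterion), and no gain/τ combination
produces band-crossing oscillation: a dead-zoned integrating controller on
a monotone first-order plant can overshoot only by (slew × delay) ≈ 5 bpm
at G = 10, far inside a ±10% band. In live preparations those behaviors
plausibly arise from mechanisms deliberately outside this model: slow
block↔stim transition dynamics at the nerve, drift of calibration values
over hours, baseline drift, and reflex/compensatory variability. Mode
switching here is instantaneous (a hysteresis option exists but defaults
off), baseline drift defaults off, and no baroreflex, respiratory sinus
arrhythmia, or sympathetic compensation is modeled. Passing the bench
therefore validates the algorithmic pipeline, not robustness to those
physiological stressors; two acceptance checks encoding the in-vivo
category pattern (low gain mostly Slow; high gain oscillating at τ = 6 s)
are expected to fail against this plant and are retained as documentation
of that boundary.

## Known limitations

* The plant omits effector latency (< 1 s vagal-cardiac delay), nonlinear
  frequency–response curvature near the knee, and any slow adaptation.
* The 2 s estimation window under-samples heart rates below ~60 bpm; the
  estimator then alternates between valid and held values. The default
  population keeps plateaus near 250 bpm, where this is not a factor.
* Block and stimulation share one electrode and are mutually exclusive by
  the sign of cout; simultaneous stimulation-plus-block strategies are out
  of scope.
* Category outcomes depend on the invented plant dynamics; only the
  calibration statistics and protocol arithmetic carry quantitative
  meaning beyond this bench.
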