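# Methods

## The measurement model

A tri-axial accelerometer at the lower back (L3–L4, near the body's centre
of mass) records anterior-posterior (AP), medial-lateral (ML) and vertical
(V) acceleration in g at a nominal 100 Hz. Photo gates at the start and
end lines of a 5-m segment (inside an 8-m walk with 1.5 m for gait
initiation and termination) timestamp the analysis window on the same
clock as the trace; without gates, manually recorded times fill the same
role and all downstream computation is agnostic to the source. The
accelerometer is zeroed at rest, so in-window signals are additionally
zero-meaned in software before RMS and autocorrelation (configurable via
`demean`), removing any residual gravity/offset leakage.

## Step counting

Each initial foot contact produces a dominant AP acceleration peak. For
peak picking only, the AP channel is low-pass filtered (zero-phase
Butterworth, order 4, 10 Hz cutoff): gait energy sits below ~5 Hz, and a
zero-phase filter cannot displace a symmetric peak, while the metrics
(RMS, autocorrelation) always see the raw signal. Peaks must be at least
`min_peak_spacing_s` = 0.25 s apart (capping cadence at 240 steps/min) and
have prominence ≥ 0.5 × SD of the windowed AP signal; both are
configurable and merely bound physiological gait. Peaks falling exactly on
a gate timestamp count as in-window (closed interval).

With contacts t₁ < … < t_K inside the window [t_start, t_end] and mean
step interval T̄ (over all consecutive in-window pairs), the fractional
count is

    total = (K − 1) + (t₁ − t_start)/T̄ + (t_end − t_K)/T̄ .

The integer term is the number of whole steps *between* successive
contacts: the first contact terminates the partial initial step rather
than contributing a whole one. This convention is forced by dimensional
consistency — walking distance d at step length ℓ contains d/ℓ steps, and
the telescoping sum above equals exactly that when detection is exact,
independent of where the gates cut the cycle. It also makes the identities
cadence = 60·total/time and step length = d/total mutually consistent with
speed = d/time, which the alternative (counting every peak as a whole
step) violates by exactly one step. Fractions are *not* clipped at 1; a
fraction above 1 means a contact near a gate line was missed and raises a
quality warning instead of being hidden.

## Trunk-control metrics

Per-axis RMS is computed on the windowed, zero-meaned signal. The RMS
ratio divides one axis RMS by the RMS magnitude √(ΣᵢRMSᵢ²), so the three
ratios satisfy Σ RMSR² = 1 identically; the ML ratio is the
balance-relevant one.

Regularity uses the *unbiased* autocorrelation estimate
Ad(k) = [1/(N−k) Σ xᵢxᵢ₊ₖ] / [1/N Σ xᵢ²], which does not shrink with lag
like the biased form and therefore compares step- and stride-lag peaks
fairly. On near-periodic finite windows the unbiased numerator can
marginally exceed the lag-0 value; coefficients beyond 1 + 1e-9 in
magnitude are clipped to ±1 with a warning. Step regularity is the
dominant local extremum with lag in [0.5, 1.5] × the estimated step
interval, stride regularity in [1.5, 2.5] ×, ties broken toward the
shorter lag; a band with no local extremum reports NaN plus a warning,
never a fabricated value. Because ML trunk sway changes sign between left
and right steps, the ML step-lag extremum is typically negative; its
magnitude is reported by default (`ml_abs`, switchable) so that ML step
regularity is a positive number like the other axes. Symmetry =
100 × stride/step regularity may exceed 100% and is capped in reporting at
999% (warning) to avoid blow-ups near zero step regularity.

## Reliability statistics

For n subjects measured on k = 2 occasions, the two-way mean squares BMS
(between subjects), JMS (between occasions) and EMS (residual) give the
single-measures ICC. The default is the consistency form
(BMS − EMS)/(BMS + (k−1)EMS), invariant under a pure additive occasion
shift, with the F-based 95% CI; the absolute-agreement form, which adds
k(JMS − EMS)/n to the denominator, is available as `variant="agreement"`
with the corresponding Satterthwaite CI. Both are exposed because the
common "two-way mixed, single measures" label is used inconsistently
across the literature for these two coefficients; neither is privileged
here. Both implementations are cross-checked against an independent
library in the test suite. Zero between-subject variance leaves the ICC
undefined (NaN + diagnostic). A tiny residual mean square left by
floating-point cancellation (|EMS| < 1e-12·BMS) is snapped to zero so
duplicated data yield ICC = 1 exactly.

SEM = SD_all · √(1 − ICC) with SD_all the SD (ddof = 1) of the 2n pooled
scores — the literal "all test scores" reading. SDD = 1.96·√2·SEM, and
SDD% divides by the grand mean of the pooled scores (equal to the mean of
the two occasion means for equal n). Note that feeding published
occasion-level SDs (≈0.185 pooled for the velocity example) through this
chain gives SEM ≈ 0.067 where the published table prints 0.065 — a
rounding-path discrepancy on the source side that is documented here, not
reconciled. The SEM chain requires ICC ∈ [0, 1]; a negative ICC leaves
SEM/SDD undefined with a warning.

The normality screen is a one-sample KS test against a normal with the
sample's own mean and SD; estimating parameters from the same sample makes
the p-values conservative (the Lilliefors caveat), which is acceptable for
a screen preceding the paired t-test. No multiple-testing correction is
applied across parameters. Bland-Altman limits are bias ± 1.96 × SD of the
paired differences.

## The simulator

Signals are harmonic sums driven by a step-cycle phase φ(t) that is
integer exactly at each foot contact (piecewise-linear interpolation over
the contact grid, so an alternate-step timing offset stays exact):

* AP: amplitudes (1, 0.5, 0.25)·`ap_amp_g` on harmonics 1–3 of the step
  frequency — a sharp pulse peaking exactly at each contact;
* V: (1, 0.3)·`v_amp_g` on harmonics 1–2, phase-shifted by 0.3π;
* ML: (1, 0.2)·`ml_sway_g` on *odd* harmonics of the stride frequency, so
  the sign alternation between left and right steps is exact;
* asymmetry: AP and V are multiplied by a stride-periodic envelope equal
  to 1 on even contacts and (1 − asymmetry) on odd ones; the envelope's
  extrema coincide with the contacts, so peak positions are untouched;
* white Gaussian noise of SD `noise_sd_g` on every channel, from a single
  seeded generator.

Gate placement makes the step fractions analytically known: t_start is
`start_phase` step intervals before the first in-window contact and
t_end − t_start = true_total · T with true_total = distance/step length.
Defaults (cadence 140.87 steps/min, step length 0.5683 m, hence speed
1.334 m/s and 8.798 steps in 5 m) put the simulator in the healthy-adult
self-selected-speed regime; the axis amplitudes (0.17/0.18/0.26 g) were
chosen once so the closed-form RMS values (≈0.138/0.130/0.192 g) sit near
typical trunk-accelerometry magnitudes for that regime — they are tuning
choices, not measured facts. Noise defaults to 0.01 g (a digitization +
soft-tissue jitter scale); asymmetry defaults to 0 (healthy symmetric
gait).

Cohort simulation draws per-subject latent parameters (cadence SD 11.85
steps/min, step length SD 5.95 cm, smaller amplitude spreads, clamped to
physiological bounds) and re-simulates occasion 2 with independent noise
and configurable parameter perturbations; with all perturbations and noise
zero, the paired walks are bit-identical and every downstream ICC is 1.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: non-stationary cadence within a walk,
gait-initiation/termination transients bleeding into the window, sensor
tilt and axis cross-talk, soft-tissue resonance, non-Gaussian artifacts
(clothing snags, belt slip), and pathological waveform shapes. Tests
demonstrate that the *algorithms* recover known structure, not that the
device-level accuracy claims transfer to arbitrary populations.

## Problem sizes and numerical choices

The accuracy sweep uses 200 simulated walks spanning cadence 90–160
steps/min, step length 0.45–0.70 m, noise 0–0.02 g, asymmetry 0–0.15 and
a uniform gate phase; each walk is ~8 s at 100 Hz, so the sweep runs in
seconds. ICC recovery averages 10 replicate cohorts of 1000 subjects
(Monte-Carlo SE ≈ 0.005 against a 0.02 tolerance); Bland-Altman coverage
uses n = 10 000. Uniform-sampling tolerance is 1e-4 s per step (benign
jitter passes, a dropped 10-ms sample fails). Autocorrelation requires the
window to hold at least twice the maximum lag. The sign convention of the
axes is not fixed by the hardware description; all metrics used here are
insensitive to a global sign flip per axis (RMS, RMSR, squared-based), and
peak detection assumes contacts appear as positive AP peaks — flip the AP
channel if a sensor is mounted inverted.

## Known limitations

* Subject-level published reliability values (means, ICCs, CIs, limits of
  agreement) cannot be recomputed: the underlying per-subject data were
  never deposited. They serve only as regime targets for simulator
  defaults.
* The fractional-count convention assumes the first detected peak closes
  the initial partial step; systems that count every peak as a whole step
  will read one step higher on the same walk.
* The KS normality screen is conservative with estimated parameters; use a
  dedicated Lilliefors or Shapiro-Wilk test for formal inference.
* Symmetry is reported unfolded (values above 100% are kept, not reflected
  to min(r, 1/r)·100); folding conventions differ across the literature.
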