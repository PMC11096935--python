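# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `icpulse`, and what the synthetic-data experiments do and do
not demonstrate.

## 1. Signals and preprocessing

The pipeline operates on concurrent ICP [mmHg], ABP [mmHg] and CBFV [cm/s]
channels sampled at 50 Hz.  Before pulse analysis the ICP and CBFV channels
are upsampled to 200 Hz by linear interpolation (sharper onset timing) and
low-pass filtered at 12 Hz.

* **Filter realization.** The cutoff is the only constrained quantity; the
  family, order and phase are free choices.  We use an order-4 Butterworth
  applied forward–backward (`filtfilt`).  Zero-phase application matters
  because onset *timing* anchors the ICP/CaBV synchronization; a causal
  filter would skew every onset by its group delay.  Forward–backward
  application squares the magnitude response, so the single-pass corner is
  widened by (√2 − 1)^(−1/8) ≈ 1.116 so that the cascade's −3 dB point lands
  on the requested 12 Hz.  Measured: 1 Hz passband amplitude error < 1%,
  40 Hz attenuation ≫ 20 dB, DC gain exactly 1.
* **Moving means.** The 6-s CBFV mean (the venous-outflow proxy of the
  volume model) and the 10-s trend means use a *centered* window, truncated
  (not padded) at the series edges: no invented samples, and no systematic
  lag in the subtracted mean.  Whether the original analyses centered or
  trailed this window is unknown; both the window length and (via
  `frozen_mean`) the per-pulse evaluation policy are configurable.
* The trend-averaging window behind the wave detector (10 s) is likewise a
  free choice; plateau waves evolve over minutes, so the detector is
  insensitive to it within a factor of a few.

## 2. Pulse onset detection

Onsets (the minimum at the start of the ascending slope) are found with a
deterministic multiscale local-minima scalogram, the trough-finding variant
of the automatic multiscale peak detection (AMPD) family.  Within each 6-s
analysis window (50% overlap), sample *i* is *marked* at scale *k* when
`x[i] < x[i−k]` and `x[i] < x[i+k]`, for k = 1..K with K spanning 1.2 s.
The scale γ with the most marks tracks the dominant beat half-period; onsets
are the samples marked at **every** scale 1..γ.  This suppresses dicrotic
and notch minima (which fail at large scales) without any detrending or
random component, so detection is exactly reproducible.  Duplicates within
one sample across overlapping windows are merged.

Two consequences are documented rather than hidden:

* Samples closer than γ (≤ 1.2 s) to a series end cannot be marked at all
  scales, so boundary beats are structurally undetectable; recovery metrics
  therefore score onsets in the interior of the recording.
* The detector reports the minimum of the *filtered* signal.  Its agreement
  with construction-time truth (±2 samples at 200 Hz noise-free; ≥ 98%
  within 10 ms at 5%-amplitude noise) is a property of the whole chain,
  filter included.

## 3. Pulse quality control

Manual visual pulse review is replaced by explicit rules with
machine-readable reason codes, applied per beat (onset-to-onset segment):

| rule | default | reason code |
| --- | --- | --- |
| duration bounds | 0.3–2.0 s | `duration` |
| value range | ICP [−10, 120] mmHg, CBFV [0.5, 250] cm/s, ABP [10, 250] mmHg | `range` |
| finite samples | all | `non_finite` |
| minimum pulsatility | ICP 1 mmHg, CBFV 5 cm/s, ABP 10 mmHg | `amplitude` |
| local extrema count | ≤ 8 | `extrema` |

The extrema count uses a prominence floor of 2% of the pulse amplitude:
band-limited noise riding on the flat diastolic tail would otherwise create
arbitrarily many strict sample-level extrema and reject essentially every
real pulse.  The CBFV lower bound is 0.5 cm/s (not 0): zero velocity in an
insonated artery is a signal dropout, not physiology, and the range rule is
what catches dropout-to-zero artifacts.

ICP and CBFV pulses of the same cardiac cycle are paired by mutual-nearest
onset within 0.25 s (symmetric in the two channels; each pulse used once).
The tolerance reflects that intracranial pressure and flow-velocity systolic
onsets are near-simultaneous relative to a 0.6–1.2 s beat.  The signed
onset lag is kept on every pair so either synchronization convention can be
audited; no transit-time correction is applied.

## 4. The volume pulse and the difference index

`ΔCaBV(n) = Σ_{i=1..n} [CBFV(i) − mean(CBFV)] Δt` is evaluated per CBFV
pulse with the 6-s moving mean read *per sample* (default) or frozen at the
pulse onset (sensitivity variant).  Units are cm — flow normalized by the
(unknown, assumed constant) vessel cross-section — so absolute values are
only comparable within one recording.  The two model assumptions (constant
insonated cross-section; low venous pulsatility) are contracts, not checks;
a heuristic monitor logs a warning when the slow mean varies more than 5%
within one pulse.  ΔCaBV is not re-zeroed after computation; min–max
normalization downstream makes any offset immaterial to DI.

DI is the raw sum of absolute differences between the normalized,
onset-synchronized pulses over the CaBV pulse length M.  When the ICP pulse
is shorter than M its last sample is held (the comparison window follows
the volume pulse to its end; a truncate-to-shorter policy is available).
DI is *not* divided by M, so it scales with beat length; `n_compared` is
stored with every record so users can form a length-normalized variant.
Heart-rate dependence of the raw sum is a known limitation; time-axis
normalization of pulses is deliberately out of scope.

## 5. Plateau-wave detection and period selection

On the trend series, candidate waves are seeded by excursions of mean ICP
above 40 mmHg.  The pre-wave reference level is the median trend ICP over
the 240 s before the rise onset, where the rise onset is the last upward
crossing of reference + 5 mmHg before the peak — reference and rise onset
define each other, so a two-pass fixed point resolves them.  A candidate is
accepted when peak ICP > 40 mmHg, rise ≥ 15 mmHg over the reference, CPP
falls ≥ 10 mmHg below its pre-wave median, and the ≥ 15 mmHg elevation
persists ≥ 3 min contiguously.  The reported wave interval spans the two
reference + 5 mmHg crossings.

Baseline period: the 240 s immediately before the rise onset (shortened
with a warning if the recording starts later; below 60 s the wave is
excluded).  Plateau period: the maximal contiguous interval inside the wave
with trend ICP ≥ 90% of the wave maximum.  Pulse pairs are labeled by the
ICP onset time falling inside either interval; rise/fall pulses stay
unlabeled and unscored.

## 6. Statistics

All summaries are median [Q1–Q3] (linear interpolation between order
statistics).  The baseline-vs-plateau comparison is the two-sided Wilcoxon
signed-rank test: zero differences dropped (Wilcoxon's original rule, the
common clinical-software default), average ranks on ties,
W = min(W⁺, W⁻).  P-values are **exact** up to n = 25 — computed by shift
convolution of the signed-rank distribution on the doubled-rank lattice,
which handles tied (half-integer) ranks exactly — and use a tie- and
continuity-corrected normal approximation beyond.  Exactness is verified
against full 2ⁿ sign-assignment enumeration and against an independent
library implementation.

The primary inference unit is the **wave**: each wave contributes its median
DI per period, and the test pairs the 15-ish medians.  Pooling all pulse
pairs instead would pseudo-replicate (hundreds of correlated pulses per
wave); a pooled mode exists for exploration and warns when used.  Normality
screening is intentionally absent: the pipeline is unconditionally
nonparametric.  The significance level is 0.05; no multiple-testing
correction is applied across the (three) channel-level comparisons.

## 7. The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
cerebrovascular dynamics (no autoregulation, no vasodilatory-cascade model).

**Pulse morphology.** One ICP cycle is a sum of three raised-cosine
components (P1/P2/P3 at latencies 0.16/0.45/0.70 of the cycle, widths 0.30,
amplitudes 1.0/0.8/0.6) over a diastolic mound `0.45·sin(πu)^0.15`.  The
sub-unit power gives every cycle a sharp, deep diastolic trough with
equal-magnitude slopes on both sides of the beat junction, which is what
lets onset minima survive trend slopes, zero-phase filtering and
band-limited noise essentially unmoved.  The `roundness` parameter blends
this saw-tooth linearly toward a single broad mid-cycle hump (the shape a
constant-flow-forward volume pulse itself takes), reproducing the
documented triphasic-to-rounded evolution: 3 strict maxima at roundness 0,
1 at roundness 1, monotone in between (asserted at 0.86 s / 200 Hz
reference settings).  CBFV and ABP cycles have fixed two-phase shapes
(sharp systolic upstroke, dicrotic bump) — only their mean and pulsatility
are modulated, since the analysis manipulates ICP shape, not CBFV shape,
and no consensus CBFV waveform parameterization exists.

**Episodes.**  Default plan (one wave per 780-s recording): baseline /
plateau mean ICP 19.4 / 42.7 mmHg, CBFV 44.2 / 32.9 cm/s, ABP constant at
93.9 mmHg (so CPP falls ~23 mmHg by construction); wave at 270 s with
45 s rise, 300 s plateau, 45 s fall; heart rate 70 bpm, CV 4%.  The 45-s
ramps are a modeling choice consistent with the ~1-min onset of clinical
plateau waves.  ICP pulse amplitude is 4 mmHg at baseline and grows 8% per
mmHg of mean-ICP rise (amplitude–pressure coupling); pulse roundness ramps
from 0.15 to 0.85 in step with the mean-ICP trend; CBFV pulsatility rises
25% during the wave.  Beat lengths are drawn per beat and rounded to whole
samples so every onset lies exactly on the 50-Hz grid; each rendered cycle
is mean-centered and added to the per-sample trend, so windowed channel
means track the programmed levels and each beat's minimum sits exactly on
its onset sample.  Channel noise defaults: ICP 0.15, ABP 0.6, CBFV
0.8 (white Gaussian).  Artifacts (0.2 events/min): additive spikes,
flatlines (1–3 s), CBFV dropout-to-zero — one kind per QC rule — with all
intervals recorded in the ground truth.

**Cohorts.**  Per-recording jitter is multiplicative log-normal with
σ = 5% (≈ ±10% at 2σ) on baseline ICP, ICP rise, CBFV level, ABP, heart
rate and pulse amplitude; draws violating 1-mmHg safety margins on the
wave-defining criteria (plateau ICP ≥ 41 mmHg, rise ≥ 16 mmHg) are redrawn,
so every simulated wave remains detectable in principle — spread without
silently deleting the phenomenon under study.  Child seeds derive from the
cohort seed via `numpy.random.SeedSequence` spawning; everything is
bit-reproducible from one integer.

**What passing tests show — and don't.**  Synthetic experiments demonstrate
that the implementation recovers *programmed* morphology effects through
the full chain under realistic noise, artifact and heart-rate variability,
with correctly calibrated inference.  They cannot validate the
constant-flow-forward model itself, the clinical representativeness of the
pulse shapes, or effect sizes in real patients: the generator builds in the
very coupling (roundness rising with mean ICP) whose physiological origin
is the open scientific question.  Real recordings also contain
non-stationarities the generator omits: respiratory modulation, slow
B-waves, probe repositioning, arrhythmias.

## 8. Numerical choices and degenerate inputs

* Flat pulses (zero peak-to-trough) cannot be normalized; they are excluded
  upstream by the QC amplitude rule and raise a degenerate-pulse error if
  forced through.
* A pulse whose global minimum is not at its onset sample is passed through
  with a warning, never rotated — it usually indicates an upstream problem
  worth auditing (the synthetic fall phase produces a benign version:
  within-beat trend decline puts the segment minimum at the beat's end).
* Recordings are validated on load: shared fs and length across channels, a
  uniform time column (tolerance 1% of the sample interval; the column is
  then discarded), named channels present.
* Constant series yield no onsets (no strict minima) rather than an error.
* All randomness flows from explicit integer seeds; the analysis itself is
  deterministic (the detector has no random component).

## 9. Problem sizes used in the shipped experiments

The shipped tests and the acceptance script use 15-wave cohorts of 780-s
recordings (~900 beats each, ~8700 scored pulse pairs per cohort), 20
waveless control recordings, 1000 random pulse pairs for the DI oracle, and
200 null cohorts for type-I calibration — sizes chosen to mirror a
15-wave clinical cohort while keeping a full run in the order of a minute
on a single CPU.
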