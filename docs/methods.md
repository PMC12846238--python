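# Methods

## Signal model and assumptions

A trial is modeled as two independently clocked uniform streams: a vertical
heel coordinate (metres, nominally 60 Hz) per side and one vertical ground
reaction force (vGRF, newtons, nominally 1000 Hz) per platform. Sample *i*
of a stream lives at `start_time + i / sampling_rate` on that stream's own
clock; synchronization estimates the constant clock offset between the two
streams from one movement event visible in both. The method assumes the
evaluated movement contains exactly one swing-to-contact descent of the
heel (a unique local minimum followed by an ascent) and one quiescent-then-
loaded transition of the vGRF. Non-finite samples (tracking dropouts) are
rejected at container construction rather than silently propagated; gap
interpolation is out of scope.

## Processing chains

**Heel**: min–max normalization, then a cascade of two 4th-order
Butterworth low-passes (3 Hz cut-off) applied bidirectionally, then a
5-sample centered running median. Normalization precedes filtering, so
post-filter values may slightly exceed [0, 1] from ringing; they are not
re-clamped because clamping would distort the slopes the contact detector
uses (tests bound the excursion at ±0.05 on representative traces). The
median's edge policy is a shrinking window (no padding), so no boundary
values are invented. Note that the cascade runs before the median: an
isolated impulse is therefore smeared into a low, smooth bump before the
median sees it, and the median stage removes *pre-filter* impulse noise
only in the sense of bounding its residual footprint (the impulse-removal
property holds exactly for the median operator itself).

**Force**: a single 4th-order 30 Hz low-pass, also zero-phase. The
directionality of this filter is not dictated by the event rules
themselves; zero-phase was chosen because onset timing is the entire point
of the pipeline and a causal filter would bias the detected onset late by
a rate-dependent group delay. The choice is recorded in every report's
provenance block.

**Zero-phase implementation**: each bidirectional pass is forward+backward
filtering with reflective (even) edge padding of `3 × order` samples, so a
signal must exceed 12 samples (order 4) to be filtered; the padding scheme
is fixed so results reproduce bit-for-bit across runs.

## Event detectors

**Heel contact** — `threshold = baseline × k + min`, where `baseline` is
the difference between the maximum after a stabilization period and the
global minimum, and k is 0.6 (single-leg) or 0.2 (bilateral). The event is
the first sample that follows a local minimum, is ascending, and strictly
crosses the threshold (`v[i] > thr ≥ v[i−1]`). Local minima are
first-difference sign changes from − to +, with plateaus resolved to the
plateau's last sample so the ascent starts immediately after. The
stabilization period defaults to 30 samples (0.5 s at 60 Hz): long enough
to exclude setup transients, short enough to keep brief trials usable; it
is config-exposed and logged.

**Force onset** — `threshold = baseline + 0.1 × SD`, with `baseline` the
mean of the first 10 resting samples. The SD term is computed over the full
trace by default (population denominator); a config option computes it over
the resting window instead, because the rule's wording admits either
reading — the full-trace reading is the default and neither is asserted as
uniquely correct. Onset is the first sample at or beyond the baseline
window strictly above the threshold. Strict inequality makes the degenerate
constant-trace case fail loudly (SD = 0 ⇒ threshold = baseline ⇒ no sample
strictly exceeds) instead of firing at sample 0.

Both detectors assert the first-crossing contract post hoc on every call,
and both are continuously checked against independent literal loop
implementations of the rules.

**Bilateral tie-break** — bilateral trials process both heels and align on
the earlier detected contact (the first-contacting limb); if one heel
channel is degenerate the other is used and the failure is counted in QC.

## Offset, shifting, cycle scale

The signed offset is `force-onset time − heel-contact time` (negative ⇔
force leads). Shifting is purely a clock correction of the force stream's
`start_time` by −offset: no rolling, no interpolation, so the native
1000 Hz samples survive intact and the re-detected onset lands exactly on
the contact instant. Resampling to a common grid (linear interpolation) is
an explicit, optional, post-shift step — shift-first is the default order.
Cycle normalization interpolates each channel at 101 equally spaced
instants (0–100 % at 1 % steps, the movement-analysis convention) from the
contact instant to the end of the shorter aligned stream; both boundaries
are config-overridable since no canonical cycle end exists for
non-periodic tasks.

## Extra-step quality control

A preliminary step onto the plate produces a transient force episode that
makes the onset detector fire early. The QC segments above-threshold runs,
merges runs separated by dips shorter than a quiet gap (default 0.25 s,
i.e. the signal never properly returned to baseline), and calls the last
episode of at least 0.5 s the main loading. The trial is flagged when any
episode ends before the main episode starts, and the main episode's start
is reported as the candidate corrected onset for a manual re-run. The flag
is advisory: batch statistics count it but no automatic correction is
applied.

## Synthetic trials

The generator emulates a stationary squat-like task: a heel plateau with a
raised-cosine descent (1.0 s) to a unique minimum at the contact instant
and a partial raised-cosine rise (0.8 s, to 85 % of the drop); a vGRF that
is quiescent (0 N, or a configurable resting load), rises over 0.3 s to
body weight (608 N, a 62 kg subject) and oscillates at squat cadence
(±15 % at 0.5 Hz); white Gaussian noise added before filtering (default
SD 2 % of each channel's range); default 7 s duration, contact at 3 s,
60/1000 Hz rates.

Ground truth injects the offset **between the detectable events**: the
loading is positioned so its continuous threshold-crossing instant falls
exactly `true_offset_s` after the heel detector's crossing instant on the
clean trace (closed-form raised-cosine crossing for the heel; a short
fixed-point iteration for the force, whose threshold depends on the
whole-trace SD). This is what makes "recovered = injected" well-posed:
both detectors have waveform-dependent rise latencies, and defining the
offset between waveform corners instead would contaminate recovery with
those latencies. Consequently noiseless recovery is exact up to sampling
quantization (≲1 ms), and under 2 % noise the residual error is dominated
by the 60 Hz frame quantum.

What the generator does **not** emulate: pose-estimation error structure
(autocorrelated, occlusion-driven), double-peak impact transients of gait,
multi-segment soft-tissue artifacts, or platform drift. Passing tests
therefore demonstrate the algorithm's correctness and noise robustness
under the stated signal structure, not its field performance on arbitrary
recordings.

Banks draw randomized fields from stated ranges with trial *i* seeded
`seed + i`, so banks are reproducible and individual trials can be
regenerated in isolation.

## Numerical choices

- Filters designed via bilinear transform; the closed-form oracle for the
  magnitude response therefore evaluates the Butterworth formula at the
  prewarped frequency ratio `tan(πf/fs)/tan(πfc/fs)`, which is exact for
  this design (the analog-frequency formula differs by ~30 % at 10 Hz on a
  60 Hz stream and is not the response of any realizable digital filter
  here).
- Degenerate inputs fail loudly: constant traces cannot be normalized
  (zero range) and cannot fire the force detector; both surface as typed
  errors that batch mode converts into counted per-trial failures.
- Strict (`>`) crossings everywhere; plateaus at exactly the threshold do
  not fire.
- Summary SDs over repetitions use the sample (n−1) convention; detector
  SDs use the population (n) convention, following the rule's formula.
- Zero-variance curves are excluded from r aggregation but counted and
  reported, never dropped silently.
- Reports contain no wall-clock content and serialize floats at full
  precision, so identical inputs produce byte-identical reports.

## Problem sizes

The shipped checks use 200-trial banks for offset recovery, 1000 random
signals per detector-oracle comparison, 1000 random curve pairs for the
metric oracle, and a 100-trial bank (20 % corrupted) for the QC operating
point; the full suite plus the reproduction script complete in well under
a minute on one CPU. These sizes give binomial 95 % intervals of a few
percent on the reported rates, adequate for the pass bands used.

## Known limitations

- One event per trial: repeated contacts (gait) need windowing before use.
- The offset is quantized to the kinematic frame (16.7 ms at 60 Hz);
  sub-frame interpolation of the event instant is deliberately not done.
- The extra-step QC assumes the main loading is the longest-sustained late
  episode; movements with genuine long pre-loading phases would need the
  quiet-gap and sustained-duration knobs adjusted.
- Cross-correlation alignment is intentionally absent: the event-based
  definition is the method under study, and the two do not agree in the
  presence of waveform distortion.
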