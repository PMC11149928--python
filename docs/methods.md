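# Methods

## Signal model and preprocessing

All analyses operate on uniformly sampled single-channel LFP in arbitrary
voltage units; every reported statistic is z-scored or a ratio, so the
absolute scale cancels. The default sampling rate is 1000 Hz, the lowest
round rate that resolves the ripple band's 220 Hz upper edge with a
comfortable margin; it is configurable everywhere.

Filters are zero-phase throughout (forward–backward application), so event
boundaries and instantaneous phase carry no group delay. The band-pass is a
4th-order Butterworth (applied twice by `filtfilt`, giving an effective
8th-order magnitude response); the 60 Hz notch is a second-order IIR notch
with quality factor 30 (≈ 2 Hz −3 dB width), which removes a line tone by
more than 80 dB while leaving 50 and 70 Hz essentially untouched. Inputs
are reflect-padded by about three time constants of the band's low edge
before filtering to suppress onset transients at trial boundaries.

The filter family and order are conventional choices for ripple-band LFP
work; the tests pin the behavior that matters (in-band gain 0.9–1.05,
≥ 30 dB notch depth, ≥ 20 dB an octave outside the band, zero lag) rather
than the coefficients.

Instantaneous amplitude and phase come from the Hilbert analytic signal.
Phase follows the cosine convention — phase 0 at the band-passed signal's
positive peak — wrapped to (−π, π].

Z-scoring takes an explicit reference window. By default each trial
references itself; the session-pipeline option `zscore_reference='baseline'`
instead standardizes every segment against the baseline trial's envelope
statistics, supporting baseline-referenced conventions without changing the
detector. Which segment defined the normalization in any given published
dataset is rarely stated; surfacing it as a recorded option keeps both
readings auditable.

## SWR detection

The detector runs on the z-scored ripple-band (140–220 Hz) envelope:

1. find maximal runs of samples strictly exceeding `threshold_sd` (3 SD);
2. extend each run outward while the envelope exceeds `boundary_sd`
   (default: equal to the threshold, so the event span is exactly the
   supra-threshold run; setting it lower, e.g. 1 SD, emulates
   envelope-edge conventions);
3. merge runs whose end-to-start gap is ≤ `merge_gap_ms` (15 ms,
   inclusive), transitively;
4. keep merged spans of at least `min_duration_ms` (15 ms).

The minimum-duration filter is applied to the *merged* span: two sub-15 ms
runs that merge into a ≥ 15 ms span count as one event. The alternative
order (filter before merge) would silently discard such pairs; the chosen
order is recorded in run manifests and the brute-force reference
implementation used in the tests applies the same rule.

Intervals are half-open in samples, `[start, end)`, and duration is
`(end − start)/fs`; with the integral defined as the plain sum of z-scored
envelope samples across the span, one sample contributes `1/fs` seconds to
the duration and its z-value to the integral, keeping the two features
consistent. Note that the event *count* is not monotone in the threshold:
lowering the threshold can bridge the valley between two events and fuse
them. The properties that do hold — supra-threshold support shrinks with
threshold, and counts are non-increasing in the merge gap — are tested.

"SWR frequency" is events per second over the entire trial; the raw count
is reported alongside, and per-event feature means are taken over all
events in the trial. Stimulus-trial features are reported as ratios to the
most recent preceding baseline trial in the same session; a zero or
undefined baseline feature flags the ratio as undefined (NaN) rather than
dropping or imputing it.

## Phase-amplitude coupling

Theta phase and gamma envelope are binned into 18 phase bins of 20°, the
convention of the entropy-based Modulation Index; the bin count is
configurable. The MI uses natural logarithms (any base cancels in the
ratio). MI is exactly invariant to uniform amplitude scaling and, up to
floating-point, to rotation of the phase origin.

By default no 60 Hz notch is applied before PAC extraction — the bands are
taken from the raw LFP, and the line frequency sits inside the 50–100 Hz
mid-gamma band, so notching would carve a hole in the amplitude-providing
band. The toggle is surfaced (`apply_notch`) and recorded. Low-gamma
(25–50 Hz) coupling runs through the same machinery by passing a different
amplitude band.

A circular-shift surrogate null (`surrogate_mi`) is provided for chance-level
assessment: shifting the amplitude series in time preserves both series'
autocorrelation while destroying their alignment.

## Synthetic LFP generator

The generator emulates exactly the structure the analysis assumes, with
defaults matching the validation conditions used throughout the tests:

* **Background**: white Gaussian noise shaped in the Fourier domain to
  power ∝ 1/f (exponent 1 by default), rescaled to SD = `rms` (1.0), with
  optional 60 Hz hum. Spectral shaping gives the exact target slope at
  O(n log n) cost.
* **Ripple bursts**: a 180 Hz cosine under a Tukey (α = 0.5) envelope
  spanning `duration_ms` (50 ms), placed by a homogeneous Poisson process
  (rate 0.3 events/s) thinned to a 100 ms minimum gap — the simplest null
  with a controllable rate. Requesting a rate too high for the minimum
  spacing raises an error rather than silently under-delivering.
  The Tukey window was chosen over a Gaussian after measurement: a Gaussian
  with σ = duration/6 holds a 6-SD burst above the 3 SD threshold for only
  ≈ 15 ms — exactly at the minimum-duration cutoff — so ordinary background
  interference pushed ~15% of bursts under the duration criterion. The
  flat-topped Tukey burst holds its calibrated peak for half its duration,
  and recovery is then limited only by amplitude, not by a coincidence of
  envelope shape with the duration rule.
* **Amplitude calibration**: `amplitude_z` is expressed in detector units —
  SD of the burst-free ripple-band envelope. The raw burst amplitude is
  `mean + amplitude_z·SD` of that envelope, divided by the ripple-band
  filter's measured peak-envelope gain on the burst template (≈ 0.95 at
  fs = 1000), so the z-envelope at the burst center lands on `amplitude_z`
  on average (verified: 6.01 measured for a 6.0 target).
* **Coupling**: the deterministic component is
  `θ_amp·cos(2πf_θt) + γ_amp·(1 + m·cos(2πf_θt − φ_pref))/2·sin(2πf_γt)`.
  The theta carrier is a *cosine* so that its Hilbert (cosine-convention)
  phase equals `2πf_θt` directly: the injected preferred phase and the
  measured preferred phase then share one convention, and the
  phase-amplitude profile peaks in the bin containing `φ_pref` with no
  quarter-cycle bookkeeping. Defaults: theta 8 Hz amplitude 1, gamma 70 Hz
  mean amplitude 0.5 — a mid-band carrier and a gamma/theta amplitude
  ratio typical of hippocampal LFP.

Determinism: every generator is a pure function of (parameters, seed) via
`numpy.random.default_rng`.

What the generator does *not* emulate: biophysical ripple waveforms
(sharp-wave deflections, intra-ripple frequency drift), non-stationary
ripple rates, movement artifacts, electrode drift, or cross-channel
correlation. Passing the recovery tests therefore demonstrates that the
analysis chain is correct and well-calibrated on signals satisfying its
assumptions — not that detection performance transfers to any particular
recording quality.

## Session pipeline and cohort simulation

A session is an ordered list of segments with an explicit design: the
social paradigm is a 180 s baseline followed by 300 s stimulus trials, the
nonsocial paradigm 60 s + 120 s. Each stimulus segment is normalized to the
most recent preceding baseline, which covers both one-baseline-per-session
and one-baseline-per-trial layouts. The tidy output keeps one row per
(channel × segment × feature) — channels are never averaged before the
table, so the nesting needed for a mixed-effects fit
(`feature ~ genotype*drug + (1|animal)`) is preserved. Mixed-model
estimation itself is delegated to standard software; the package ships a
permutation two-group test (exact enumeration of label assignments when
there are ≤ 20,000, Monte Carlo otherwise) for recovery experiments, with
channel values averaged per animal first since the animal is the
experimental unit.

The cohort simulator assigns animals round-robin to effect groups, scales
the stimulus-segment ripple rate by a per-group multiplier (and optionally
adds a coupling component), analyzes every segment through the same
pipeline as real data, and returns measured and true values side by side.

## Problem sizes and numerical choices

* Recovery experiments use 60 s segments × 20 seeds (detection) and 300 s
  × 3 seeds (coupling); the replicate-cohort experiments use 100 cohorts of
  10 animals × 2 channels with 90 s baselines and 150 s stimulus segments —
  a scaled-down session that keeps per-animal event counts high enough for
  stable rate ratios while letting the full 100-replicate design run on a
  single CPU in a few minutes.
* Detection comparisons use an absolute slack of 1e-9 samples on gap and
  duration arithmetic so that exact-integer gaps (15 ms at 1000 Hz) are
  inclusive under floating-point division.
* MI of an empty-amplitude distribution is undefined and raises; empty
  phase bins (short recordings) warn and contribute zero mass.
* A constant series cannot be z-scored (zero-variance reference) and
  raises rather than returning infinities.
* Event placement clamps burst supports inside the recording, and a
  recording too short to hold one burst is an error.

## Known limitations

* Detection calibration (`amplitude_z`) is defined against burst-free
  background statistics; in trials dense with large events, self-referenced
  z-scoring inflates the envelope SD and effective peaks sit slightly lower
  (~10% at the default burst load).
* The Modulation Index for sinusoidal envelope modulation is small in
  absolute terms (≈ 0.01 at full depth); it is a relative, not absolute,
  coupling scale, and comparisons are only meaningful at fixed bin count.
* No artifact rejection is implemented; recordings are assumed clean apart
  from line hum.
* The permutation test assumes exchangeable animals under the null; it is
  a recovery-check tool, not a replacement for the mixed-effects analysis
  the tidy table is designed to feed.
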