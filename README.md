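# ripplepac

Sharp-wave-ripple (SWR) detection and theta–gamma phase-amplitude coupling
(PAC) analysis for hippocampal local field potential (LFP) recordings, with
a synthetic-LFP generator that provides ground truth for end-to-end
validation.

## Who this is for

Electrophysiologists analyzing continuous LFP from behavioral sessions
(e.g. a baseline trial followed by a social- or object-exposure trial) who
need, per trial and per electrode:

* SWR events and their features — count, rate, peak amplitude, duration,
  integral — with stimulus trials normalized to the session baseline, and
* theta-phase → gamma-amplitude coupling strength, quantified by the
  Modulation Index,

emitted as tidy tables ready for nested mixed-effects modeling (the animal
is the experimental unit; electrodes stay nested within it).

## The method

**SWR detection.** The LFP is notched at 60 Hz, band-pass filtered to the
ripple band (140–220 Hz, zero-phase 4th-order Butterworth), Hilbert
transformed, and the envelope z-scored. SWRs are events where the z-scored
envelope exceeds **3 SD for at least 15 ms**; events within **15 ms** of
one another are merged into a single event. Per event, the peak z-amplitude,
duration, and integral (the sum of z-scored envelope samples from the start
to the end of the event) are computed; per trial, rates and feature means
are reported raw and as ratios to the same session's baseline trial.

**Phase-amplitude coupling.** Theta (4–12 Hz), low-gamma (25–50 Hz) and
mid-gamma (50–100 Hz) components are extracted from the raw LFP. The
Hilbert theta phase φ and gamma envelope A are binned into N = 18 phase
bins; with p_j the normalized mean envelope per bin, the Modulation Index
is the normalized Kullback–Leibler divergence from uniformity,

    MI = (ln N − H(p)) / ln N,   H(p) = −Σ_j p_j ln p_j,

so MI = 0 means no coupling and MI = 1 means all gamma amplitude
concentrated at one theta phase.

**Synthetic LFP.** 1/f background noise (spectrally shaped white noise),
optional 60 Hz hum, ripple bursts calibrated directly in detector units
(SD of the burst-free ripple-band envelope) and placed by a thinned Poisson
process, and theta-modulated gamma with controllable depth and preferred
phase — every generator is a pure function of its parameters and a seed,
and returns the injected ground truth.

## Worked example

```python
import numpy as np
from ripplepac import (BANDS, NoiseSpec, PacSpec, RippleSpec, analytic,
                       generate_background, generate_pac, inject_ripples,
                       detect_events, summarize_trial, zscore, pac_for_trial)

# 60 s of pink noise with 6-SD ripple bursts at 0.3 Hz
bg = generate_background(60, 1000, NoiseSpec(exponent=1, rms=1), seed=42)
sig, truth = inject_ripples(bg, RippleSpec(rate=0.3, amplitude_z=6), seed=43)
z = zscore(analytic(sig, BANDS["ripple"]))
summary = summarize_trial(detect_events(z), sig.duration_s)
print(f"injected {len(truth.events)} bursts, detected {summary.n_events} events")
print(f"rate {summary.rate_hz:.3f} /s, mean peak {summary.mean_peak_z:.2f} SD, "
      f"mean duration {summary.mean_duration_ms:.1f} ms, mean integral {summary.mean_integral:.1f}")

# theta-gamma coupling, depth 0.8, preferred phase 1.0 rad
rec, _ = generate_pac(120, 1000, PacSpec(coupling=0.8, preferred_phase=1.0),
                      NoiseSpec(rms=0.5), seed=7)
profile = pac_for_trial(rec)
print(f"MI = {profile.mi:.4f}, preferred phase = {profile.preferred_phase:.2f} rad")
```

prints

```
injected 17 bursts, detected 18 events
rate 0.300 /s, mean peak 5.89 SD, mean duration 31.4 ms, mean integral 147.8
MI = 0.0251, preferred phase = 0.87 rad
```

The detector recovers the injected bursts (one extra event is a chance
background excursion, consistent with the measured false-positive rate of
~0.02 events/s); the measured trial rate matches the generating 0.3 Hz; the
preferred phase lands within one 20° bin of the injected 1.0 rad. An
uncoupled control (`coupling=0`) under the same noise gives MI ≈ 4e-6.

The same operations are available from the shell:

```sh
ripplepac simulate ripples --duration-s 60 --seed 42 --out rec.csv
ripplepac detect --in rec.csv --out events.csv
ripplepac pac --in rec.csv --out profile.csv
ripplepac run --config session.toml --out-dir results/
```

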