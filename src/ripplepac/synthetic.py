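"""Synthetic LFP generation with known ground truth.

Emulates the statistical structure the analysis assumes, so detection and
coupling estimation can be validated end-to-end without recordings:

* broadband 1/f ("pink") background, made by spectrally shaping white
  Gaussian noise in the Fourier domain (exact target slope, O(n log n)),
  with optional 60 Hz line contamination;
* transient ripple-band bursts (140-220 Hz sinusoid under a flat-topped
  Tukey envelope) whose amplitude is calibrated in SD units of the burst-free
  ripple-band envelope, placed by a homogeneous Poisson process thinned to
  respect a minimum gap;
* a theta carrier whose mid-gamma amplitude is modulated by theta phase
  with controllable depth and preferred phase.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .filtering import (
    BANDS,
    ContractError,
    LfpRecording,
    SamplingRateError,
    analytic,
)

__all__ = [
    "NoiseSpec",
    "RippleSpec",
    "PacSpec",
    "GroundTruth",
    "GenerationError",
    "generate_background",
    "inject_ripples",
    "generate_pac",
    "DEFAULT_FS",
]

#: Default sampling rate (Hz): resolves the 220 Hz ripple-band upper edge
#: with more than a factor-of-two margin.
DEFAULT_FS = 1000.0

_MIN_FS = 2 * BANDS["ripple"].hi  # ripple band must be resolvable


@dataclass(frozen=True)
class NoiseSpec:
    """Background spectrum: power ~ 1/f**exponent, scaled to ``rms``.

    ``line_amp`` adds a 60 Hz sinusoid of that amplitude (0 = off).
    """

    exponent: float = 1.0
    rms: float = 1.0
    line_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ContractError("exponent must be non-negative")
        if self.rms <= 0:
            raise ContractError("rms must be positive")
        if self.line_amp < 0:
            raise ContractError("line_amp must be non-negative")


@dataclass(frozen=True)
class RippleSpec:
    """Injected ripple-burst family.

    ``amplitude_z`` is the target peak of the ripple-band z-scored envelope
    at the burst center, in SD units of the burst-free background envelope —
    i.e. directly in the detector's units.  ``duration_ms`` is the full
    envelope support (Tukey window, flat top of half the duration).
    """

    rate: float = 0.3
    center_freq: float = 180.0
    duration_ms: float = 50.0
    amplitude_z: float = 6.0
    min_gap_ms: float = 100.0

    def __post_init__(self) -> None:
        band = BANDS["ripple"]
        if not band.lo <= self.center_freq <= band.hi:
            raise ContractError(
                f"center_freq must lie in [{band.lo}, {band.hi}] Hz"
            )
        if self.duration_ms <= 0:
            raise ContractError("duration_ms must be positive")
        if self.rate < 0:
            raise ContractError("rate must be non-negative")
        if self.amplitude_z <= 0:
            raise ContractError("amplitude_z must be positive")
        if self.min_gap_ms < 0:
            raise ContractError("min_gap_ms must be non-negative")


@dataclass(frozen=True)
class PacSpec:
    """Theta-carrier / gamma-amplitude coupling parameters.

    ``coupling`` is the modulation depth m in [0, 1]; ``preferred_phase``
    is the theta phase (radians, cosine convention) at which the gamma
    amplitude is maximal.
    """

    theta_freq: float = 8.0
    gamma_freq: float = 70.0
    theta_amp: float = 1.0
    gamma_amp: float = 0.5
    coupling: float = 0.5
    preferred_phase: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.coupling <= 1:
            raise ContractError("coupling must lie in [0, 1]")
        if not 4 <= self.theta_freq <= 12:
            raise ContractError("theta_freq must lie in [4, 12] Hz")
        if not 50 <= self.gamma_freq <= 100:
            raise ContractError("gamma_freq must lie in [50, 100] Hz")
        if not -np.pi <= self.preferred_phase <= np.pi:
            raise ContractError("preferred_phase must lie in [-pi, pi]")
        if self.gamma_freq <= 2 * self.theta_freq:
            raise ContractError(
                "gamma_freq must exceed twice theta_freq (bands not separable)"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What was actually injected: event intervals, PAC spec, seed."""

    events: Tuple[Tuple[float, float, float], ...] = ()
    pac: Optional[PacSpec] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        starts = [ev[0] for ev in self.events]
        ends = [ev[1] for ev in self.events]
        if starts != sorted(starts):
            raise ContractError("ground-truth events must be sorted")
        if any(e2 < e for (_, e, _), (e2, _, _) in zip(self.events, self.events[1:])):
            raise ContractError("ground-truth events must not overlap")


class GenerationError(ValueError):
    """Requested signal cannot be generated under the given constraints."""


def _check_fs(fs: float) -> None:
    if fs < _MIN_FS:
        raise SamplingRateError(
            f"fs={fs} Hz cannot resolve the ripple band (need >= {_MIN_FS} Hz)"
        )


def generate_background(
    duration_s: float,
    fs: float = DEFAULT_FS,
    noise: NoiseSpec = NoiseSpec(),
    seed: Optional[int] = None,
) -> LfpRecording:
    """Generate 1/f background noise, optionally with 60 Hz line hum.

    White Gaussian noise is shaped in the Fourier domain by
    ``f**(-exponent/2)`` (DC removed) and rescaled so its sample SD equals
    ``noise.rms`` exactly; the line component is added afterwards.
    """
    _check_fs(fs)
    if duration_s <= 0:
        raise ContractError("duration_s must be positive")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-noise.exponent / 2.0)
    x = np.fft.irfft(spectrum * shape, n)
    x *= noise.rms / np.std(x)
    if noise.line_amp > 0:
        t = np.arange(n) / fs
        x = x + noise.line_amp * np.sin(2 * np.pi * 60.0 * t)
    return LfpRecording(samples=x, fs=fs)


def _burst_template(spec: RippleSpec, fs: float, phase: float) -> np.ndarray:
    """Unit-peak ripple burst: center_freq cosine under a Tukey envelope.

    The Tukey (alpha = 0.5) window spans ``duration_ms``: cosine-tapered
    flanks with a flat top of half the duration.  The smooth onset avoids
    filter ringing while the flat top keeps the envelope at its calibrated
    peak long enough for the duration criterion to see the full amplitude.
    """
    from scipy.signal import windows

    n = int(round(spec.duration_ms / 1000.0 * fs))
    n += 1 - n % 2  # odd length, exact center sample
    envelope = windows.tukey(n, alpha=0.5, sym=True)
    t = (np.arange(n) - n // 2) / fs
    return envelope * np.cos(2 * np.pi * spec.center_freq * t + phase)


def _place_bursts(
    n: int, fs: float, spec: RippleSpec, rng: np.random.Generator
) -> List[int]:
    """Poisson burst centers (sample indices), thinned to respect min_gap."""
    duration_s = n / fs
    half_s = spec.duration_ms / 2.0 / 1000.0
    min_spacing_s = spec.min_gap_ms / 1000.0 + 2 * half_s
    if spec.rate * min_spacing_s >= 1.0:
        raise GenerationError(
            f"rate {spec.rate}/s incompatible with min_gap_ms={spec.min_gap_ms} "
            f"and duration_ms={spec.duration_ms}"
        )
    count = rng.poisson(spec.rate * duration_s)
    lo, hi = half_s, duration_s - half_s
    if hi <= lo:
        raise GenerationError("recording too short to hold a single burst")
    centers = np.sort(rng.uniform(lo, hi, size=count))
    kept: List[float] = []
    for c in centers:
        if not kept or c - kept[-1] >= min_spacing_s:
            kept.append(c)
    return [int(round(c * fs)) for c in kept]


def inject_ripples(
    rec: LfpRecording,
    spec: RippleSpec,
    seed: Optional[int] = None,
) -> Tuple[LfpRecording, GroundTruth]:
    """Add ripple bursts to a recording; return the signal and its truth log.

    The burst's raw amplitude is calibrated against the burst-free signal:
    the ripple-band Hilbert envelope's mean and SD are measured on the
    input, and the peak amplitude is set to ``mean + amplitude_z * SD`` so
    that the z-scored envelope at the burst center reaches ``amplitude_z``
    on average.
    """
    _check_fs(rec.fs)
    rng = np.random.default_rng(seed)
    if spec.rate == 0:
        return rec, GroundTruth(events=(), seed=seed)
    env = analytic(rec, BANDS["ripple"]).amplitude
    # ripple-band filtering attenuates the burst slightly (its Gaussian
    # envelope spreads the spectrum); divide out the template's measured
    # peak-envelope gain so the calibration lands on target
    template = _burst_template(spec, rec.fs, 0.0)
    padded = np.concatenate([np.zeros(template.size), template, np.zeros(template.size)])
    gain = float(
        analytic(LfpRecording(padded, rec.fs), BANDS["ripple"]).amplitude.max()
    )
    raw_amp = float(np.mean(env) + spec.amplitude_z * np.std(env)) / gain
    centers = _place_bursts(rec.n_samples, rec.fs, spec, rng)
    samples = rec.samples.copy()
    events = []
    half_s = spec.duration_ms / 2.0 / 1000.0
    for center in centers:
        burst = raw_amp * _burst_template(spec, rec.fs, rng.uniform(0, 2 * np.pi))
        half = burst.size // 2
        lo, hi = center - half, center + half + 1
        blo, bhi = max(0, -lo), burst.size - max(0, hi - samples.size)
        lo, hi = max(lo, 0), min(hi, samples.size)
        samples[lo:hi] += burst[blo:bhi]
        events.append((center / rec.fs - half_s, center / rec.fs + half_s, spec.amplitude_z))
    return rec.with_samples(samples), GroundTruth(events=tuple(events), seed=seed)


def generate_pac(
    duration_s: float,
    fs: float = DEFAULT_FS,
    spec: PacSpec = PacSpec(),
    noise: Optional[NoiseSpec] = NoiseSpec(),
    seed: Optional[int] = None,
) -> Tuple[LfpRecording, GroundTruth]:
    """Generate a theta-modulated gamma signal plus optional background.

    The deterministic part is::

        theta_amp * cos(2 pi f_theta t)
        + gamma_amp * (1 + coupling * cos(2 pi f_theta t - preferred_phase)) / 2
          * sin(2 pi f_gamma t)

    The theta carrier is a cosine so that its Hilbert phase equals
    ``2 pi f_theta t`` directly: the gamma envelope then peaks exactly at
    measured theta phase ``preferred_phase``.  Pass ``noise=None`` for a
    noise-free signal.
    """
    _check_fs(fs)
    if duration_s < 10:
        raise ContractError("duration_s must be >= 10 s for stable phase bins")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    theta_phase = 2 * np.pi * spec.theta_freq * t
    theta = spec.theta_amp * np.cos(theta_phase)
    gamma_env = (
        spec.gamma_amp
        * (1 + spec.coupling * np.cos(theta_phase - spec.preferred_phase))
        / 2.0
    )
    gamma = gamma_env * np.sin(2 * np.pi * spec.gamma_freq * t)
    x = theta + gamma
    if noise is not None:
        x = x + generate_background(duration_s, fs, noise, seed).samples
    rec = LfpRecording(samples=x, fs=fs)
    return rec, GroundTruth(events=(), pac=spec, seed=seed)
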