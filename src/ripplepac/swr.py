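"""Sharp-wave-ripple detection on the z-scored ripple-band envelope.

An SWR is a run of samples where the z-scored 140-220 Hz Hilbert envelope
exceeds ``threshold_sd`` (default 3 SD).  Runs are boundary-extended down to
``boundary_sd``, runs separated by at most ``merge_gap_ms`` (default 15 ms)
are merged into a single event, and merged spans shorter than
``min_duration_ms`` (default 15 ms) are discarded.  Per-event features are
the peak z-amplitude, the duration, and the integral (the sum of z-scored
envelope samples across the event span), plus per-trial aggregates and
baseline-normalized ratios.

All intervals are half-open in samples: ``[start, end)``; duration is
``(end - start) / fs``, which keeps the integral and the duration consistent
with one sample contributing ``1/fs`` seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .filtering import ContractError, ZScoredSeries

__all__ = [
    "DetectionParams",
    "RippleEvent",
    "TrialSwrSummary",
    "NormalizedSwrSummary",
    "detect_events",
    "merge_events",
    "event_features",
    "summarize_trial",
    "normalize_to_baseline",
    "SUMMARY_FEATURES",
]

_EPS = 1e-9


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds, in SD units and milliseconds.

    ``boundary_sd`` sets where an event's start/end are placed once its core
    has crossed ``threshold_sd``; by default it equals the detection
    threshold (the integral covers the supra-threshold span only), but it
    can be lowered (e.g. to 1 SD) to integrate out to the envelope's edges.
    """

    threshold_sd: float = 3.0
    min_duration_ms: float = 15.0
    merge_gap_ms: float = 15.0
    boundary_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ContractError("threshold_sd must be positive")
        if self.min_duration_ms <= 0:
            raise ContractError("min_duration_ms must be positive")
        if self.merge_gap_ms < 0:
            raise ContractError("merge_gap_ms must be non-negative")
        if self.boundary_sd is None:
            object.__setattr__(self, "boundary_sd", self.threshold_sd)
        elif self.boundary_sd > self.threshold_sd:
            raise ContractError("boundary_sd must not exceed threshold_sd")


@dataclass(frozen=True)
class RippleEvent:
    """One detected sharp-wave ripple."""

    start_s: float
    end_s: float
    duration_ms: float
    peak_z: float
    integral_z: float
    peak_time_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ContractError("event end must follow start")


@dataclass(frozen=True)
class TrialSwrSummary:
    """Per-trial SWR aggregates.

    When ``n_events`` is zero the means are undefined and carried as NaN
    with ``means_defined`` False; the rate is 0.
    """

    n_events: int
    rate_hz: float
    mean_peak_z: float
    mean_duration_ms: float
    mean_integral: float
    trial_duration_s: float
    channel_id: Optional[str] = None

    @property
    def means_defined(self) -> bool:
        return self.n_events > 0


#: Feature names reported per trial, in tidy-table order.
SUMMARY_FEATURES = (
    "n_events",
    "rate_hz",
    "mean_peak_z",
    "mean_duration_ms",
    "mean_integral",
)


@dataclass(frozen=True)
class NormalizedSwrSummary:
    """Stimulus-trial features as ratios to the session baseline.

    A ratio is NaN when the baseline feature is zero or undefined; such
    features are flagged rather than dropped.
    """

    ratios: dict
    flagged: tuple

    def __getitem__(self, feature: str) -> float:
        return self.ratios[feature]


def _intervals_above(z: np.ndarray, level: float) -> List[tuple]:
    """Half-open sample intervals where z > level (strict, 'exceeding')."""
    above = z > level
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(z.size)
    return list(zip(starts, ends))


def _union(intervals: Sequence[tuple]) -> List[tuple]:
    out: List[list] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def _merge_gapped(intervals: Sequence[tuple], gap_samples: float) -> List[tuple]:
    """Coalesce sorted intervals whose start-to-previous-end gap <= gap."""
    out: List[list] = []
    for s, e in intervals:
        if out and s - out[-1][1] <= gap_samples + _EPS:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def event_features(
    z_env: "ZScoredSeries | np.ndarray",
    interval: tuple,
    fs: Optional[float] = None,
) -> RippleEvent:
    """Compute the per-event features over a half-open sample interval."""
    z, fs = _as_array(z_env, fs)
    start, end = interval
    if not 0 <= start < end <= z.size:
        raise ContractError(f"interval {interval} outside series of {z.size} samples")
    seg = z[start:end]
    peak_idx = int(np.argmax(seg))
    return RippleEvent(
        start_s=start / fs,
        end_s=end / fs,
        duration_ms=(end - start) * 1000.0 / fs,
        peak_z=float(seg[peak_idx]),
        integral_z=float(np.sum(seg)),
        peak_time_s=(start + peak_idx) / fs,
    )


def _as_array(z_env, fs):
    if isinstance(z_env, ZScoredSeries):
        fs = z_env.fs if fs is None else fs
        z = z_env.z
    else:
        z = np.asarray(z_env, dtype=np.float64)
    if fs is None:
        raise ContractError("sampling rate required (pass fs or a ZScoredSeries with fs)")
    return z, float(fs)


def detect_events(
    z_env: "ZScoredSeries | np.ndarray",
    params: DetectionParams = DetectionParams(),
    fs: Optional[float] = None,
) -> List[RippleEvent]:
    """Detect SWR events on a z-scored ripple-band envelope.

    Pipeline: find maximal runs exceeding ``threshold_sd``; extend each run
    outward while the envelope exceeds ``boundary_sd``; merge runs whose
    gap is at most ``merge_gap_ms``; keep merged spans of at least
    ``min_duration_ms``.  Events are returned sorted and non-overlapping.
    """
    z, fs = _as_array(z_env, fs)
    if z.size == 0:
        return []
    cores = _intervals_above(z, params.threshold_sd)
    extended = []
    for s, e in cores:
        while s > 0 and z[s - 1] > params.boundary_sd:
            s -= 1
        while e < z.size and z[e] > params.boundary_sd:
            e += 1
        extended.append((s, e))
    spans = _merge_gapped(_union(extended), params.merge_gap_ms * fs / 1000.0)
    min_samples = params.min_duration_ms * fs / 1000.0
    kept = [(s, e) for s, e in spans if (e - s) >= min_samples - _EPS]
    return [event_features(z, iv, fs) for iv in kept]


def merge_events(
    events: Sequence[RippleEvent],
    merge_gap_ms: float,
    z_env: "ZScoredSeries | np.ndarray | None" = None,
    fs: Optional[float] = None,
) -> List[RippleEvent]:
    """Merge events whose end-to-start gap is at most ``merge_gap_ms``.

    Merging is transitive.  When the envelope is supplied, peak and
    integral are recomputed over the merged span (the integral then
    includes the sub-threshold gap samples); otherwise the merged peak is
    the max of the parts and the integral their sum.
    """
    if any(
        events[i].start_s > events[i + 1].start_s for i in range(len(events) - 1)
    ):
        raise ContractError("events must be sorted by start time")
    if not events:
        return []
    gap_s = merge_gap_ms / 1000.0
    groups: List[List[RippleEvent]] = [[events[0]]]
    for ev in events[1:]:
        if ev.start_s - groups[-1][-1].end_s <= gap_s + _EPS:
            groups[-1].append(ev)
        else:
            groups.append([ev])
    merged: List[RippleEvent] = []
    for group in groups:
        start_s = group[0].start_s
        end_s = max(ev.end_s for ev in group)
        if z_env is not None:
            z, fs_ = _as_array(z_env, fs)
            iv = (int(round(start_s * fs_)), int(round(end_s * fs_)))
            merged.append(event_features(z, iv, fs_))
        else:
            best = max(group, key=lambda ev: ev.peak_z)
            merged.append(
                RippleEvent(
                    start_s=start_s,
                    end_s=end_s,
                    duration_ms=(end_s - start_s) * 1000.0,
                    peak_z=best.peak_z,
                    integral_z=float(sum(ev.integral_z for ev in group)),
                    peak_time_s=best.peak_time_s,
                )
            )
    return merged


def summarize_trial(
    events: Sequence[RippleEvent],
    trial_duration_s: float,
    channel_id: Optional[str] = None,
) -> TrialSwrSummary:
    """Aggregate per-event features over one trial.

    The event rate ("SWR frequency") uses the full trial duration as
    denominator; the raw event count is reported separately.
    """
    if trial_duration_s <= 0:
        raise ContractError("trial_duration_s must be positive")
    n = len(events)
    if n == 0:
        return TrialSwrSummary(
            n_events=0,
            rate_hz=0.0,
            mean_peak_z=math.nan,
            mean_duration_ms=math.nan,
            mean_integral=math.nan,
            trial_duration_s=trial_duration_s,
            channel_id=channel_id,
        )
    return TrialSwrSummary(
        n_events=n,
        rate_hz=n / trial_duration_s,
        mean_peak_z=float(np.mean([ev.peak_z for ev in events])),
        mean_duration_ms=float(np.mean([ev.duration_ms for ev in events])),
        mean_integral=float(np.mean([ev.integral_z for ev in events])),
        trial_duration_s=trial_duration_s,
        channel_id=channel_id,
    )


def normalize_to_baseline(
    stim: TrialSwrSummary, base: TrialSwrSummary
) -> NormalizedSwrSummary:
    """Feature-wise ratio of a stimulus trial to its session baseline."""
    if (
        stim.channel_id is not None
        and base.channel_id is not None
        and stim.channel_id != base.channel_id
    ):
        raise ContractError(
            f"channel mismatch: {stim.channel_id!r} vs {base.channel_id!r}"
        )
    ratios = {}
    flagged = []
    for feature in SUMMARY_FEATURES:
        s = float(getattr(stim, feature))
        b = float(getattr(base, feature))
        if b == 0.0 or math.isnan(b) or math.isnan(s):
            ratios[feature] = math.nan
            flagged.append(feature)
        else:
            ratios[feature] = s / b
    return NormalizedSwrSummary(ratios=ratios, flagged=tuple(flagged))
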