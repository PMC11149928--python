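"""Session orchestration: run SWR and PAC stages over a session design.

A session is an ordered list of trial segments (baseline and stimulus) per
animal, recorded on one or more electrodes.  The social paradigm is a 3 min
baseline followed by a 5 min social interaction (mother or novel mother);
the nonsocial paradigm is a 1 min baseline followed by a 2 min object
exposure.  Each stimulus segment is normalized to the most recent preceding
baseline in the same session ("the respective baseline trial").

The output is a tidy table with one row per (channel x segment x feature),
never averaged across electrodes, so it feeds directly into a nested
mixed-effects fit (the intended model is ``feature ~ genotype * drug +
(1 | animal)``; the fit itself is delegated to standard mixed-model
software).  A permutation two-group test is provided for recovery
experiments on simulated cohorts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .filtering import (
    BANDS,
    ContractError,
    LfpRecording,
    TrialInfo,
    analytic,
    notch_60hz,
    zscore,
)
from .pac import DEFAULT_N_BINS, PacPair, pac_for_trial
from .swr import (
    SUMMARY_FEATURES,
    DetectionParams,
    TrialSwrSummary,
    detect_events,
    normalize_to_baseline,
    summarize_trial,
)
from .synthetic import (
    GenerationError,
    NoiseSpec,
    PacSpec,
    RippleSpec,
    generate_background,
    generate_pac,
    inject_ripples,
)

__all__ = [
    "TrialSegment",
    "SessionDesign",
    "GroupEffect",
    "MissingSegmentError",
    "MIXED_MODEL_FORMULA",
    "TIDY_COLUMNS",
    "social_session",
    "object_session",
    "run_session",
    "batch_simulate_and_analyze",
    "permutation_test",
    "cohort_rate_test",
]

#: Formula descriptor for the downstream nested mixed-effects fit.
MIXED_MODEL_FORMULA = "feature ~ genotype * drug + (1|animal)"

TIDY_COLUMNS = [
    "animal_id",
    "channel_id",
    "genotype",
    "drug",
    "stimulus",
    "feature_name",
    "raw_value",
    "baseline_normalized_value",
]


class MissingSegmentError(ContractError):
    """A declared segment/channel has no recording."""


@dataclass(frozen=True)
class TrialSegment:
    """One contiguous recording segment within a session."""

    kind: str  # 'baseline' | 'social' | 'object'
    stimulus: str = "none"  # 'mother' | 'novel_mother' | 'object' | 'none'
    duration_s: float = 180.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ContractError("segment duration must be positive")

    @property
    def label(self) -> str:
        return "baseline" if self.kind == "baseline" else self.stimulus


@dataclass(frozen=True)
class SessionDesign:
    """One animal's session: genotype/drug labels, ordered segments, electrodes."""

    animal_id: str
    genotype: str = "cre_only"  # 'cre_only' | 'cre_gi'
    drug: str = "vehicle"  # 'vehicle' | 'cno'
    trials: Tuple[TrialSegment, ...] = ()
    electrodes: Tuple[str, ...] = ("ch0",)

    def __post_init__(self) -> None:
        seen_baseline = False
        for seg in self.trials:
            if seg.kind == "baseline":
                seen_baseline = True
            elif not seen_baseline:
                raise ContractError(
                    f"stimulus segment {seg.label!r} has no preceding baseline"
                )
        if not self.electrodes:
            raise ContractError("at least one electrode required")


def social_session(
    animal_id: str,
    genotype: str = "cre_only",
    drug: str = "vehicle",
    electrodes: Sequence[str] = ("ch0",),
    stimuli: Sequence[str] = ("mother", "novel_mother"),
    baseline_s: float = 180.0,
    stimulus_s: float = 300.0,
) -> SessionDesign:
    """The social paradigm: one baseline then the social stimulus trials."""
    trials = [TrialSegment("baseline", "none", baseline_s)]
    trials += [TrialSegment("social", s, stimulus_s) for s in stimuli]
    return SessionDesign(animal_id, genotype, drug, tuple(trials), tuple(electrodes))


def object_session(
    animal_id: str,
    genotype: str = "cre_only",
    drug: str = "vehicle",
    electrodes: Sequence[str] = ("ch0",),
    baseline_s: float = 60.0,
    stimulus_s: float = 120.0,
) -> SessionDesign:
    """The nonsocial paradigm: 1 min baseline then 2 min object exposure."""
    trials = (
        TrialSegment("baseline", "none", baseline_s),
        TrialSegment("object", "object", stimulus_s),
    )
    return SessionDesign(animal_id, genotype, drug, trials, tuple(electrodes))


def _ripple_envelope(rec: LfpRecording, apply_notch: bool) -> np.ndarray:
    if apply_notch:
        rec = notch_60hz(rec)
    return analytic(rec, BANDS["ripple"]).amplitude


def _swr_summary(
    rec: LfpRecording,
    params: DetectionParams,
    apply_notch: bool,
    ref_stats: Optional[Tuple[float, float]] = None,
) -> TrialSwrSummary:
    """Ripple path: notch -> band-pass -> envelope -> z-score -> detect."""
    env = _ripple_envelope(rec, apply_notch)
    if ref_stats is None:
        z_env = zscore(env, fs=rec.fs)
    else:
        mean_ref, sd_ref = ref_stats
        from .filtering import ZScoredSeries

        z_env = ZScoredSeries(
            z=(env - mean_ref) / sd_ref,
            mean_ref=mean_ref,
            sd_ref=sd_ref,
            reference_window="session_baseline",
            fs=rec.fs,
        )
    events = detect_events(z_env, params)
    return summarize_trial(events, rec.duration_s, channel_id=rec.channel_id)


def run_session(
    design: SessionDesign,
    recordings: Mapping[Tuple[int, str], LfpRecording],
    params: DetectionParams = DetectionParams(),
    pac_pair: PacPair = PacPair(),
    n_bins: int = DEFAULT_N_BINS,
    swr_notch: bool = True,
    pac_notch: bool = False,
    zscore_reference: str = "trial",
    compute_pac: bool = True,
) -> pd.DataFrame:
    """Run both analysis stages over a session; return the tidy table.

    ``recordings`` maps ``(segment_index, channel_id)`` to the recording of
    that segment on that electrode.  ``zscore_reference`` is ``'trial'``
    (each segment's envelope is z-scored against itself, the default) or
    ``'baseline'`` (all segments use the session baseline's envelope
    statistics).  Deterministic: identical inputs give identical tables.
    """
    if zscore_reference not in ("trial", "baseline"):
        raise ContractError("zscore_reference must be 'trial' or 'baseline'")
    rows: List[dict] = []
    for channel in design.electrodes:
        for idx, seg in enumerate(design.trials):
            if (idx, channel) not in recordings:
                raise MissingSegmentError(
                    f"no recording for segment {idx} ({seg.label}) "
                    f"on channel {channel!r} of animal {design.animal_id!r}"
                )
        baseline_summary: Optional[TrialSwrSummary] = None
        ref_stats: Optional[Tuple[float, float]] = None
        for idx, seg in enumerate(design.trials):
            rec = recordings[(idx, channel)]
            if seg.kind == "baseline" and zscore_reference == "baseline":
                env = _ripple_envelope(rec, swr_notch)
                ref_stats = (float(np.mean(env)), float(np.std(env)))
            summary = _swr_summary(
                rec,
                params,
                swr_notch,
                ref_stats if zscore_reference == "baseline" else None,
            )
            if seg.kind == "baseline":
                baseline_summary = summary
                normalized = None
            elif baseline_summary is not None:
                normalized = normalize_to_baseline(summary, baseline_summary)
            else:  # unreachable given SessionDesign validation
                normalized = None
            for feature in SUMMARY_FEATURES:
                rows.append(
                    {
                        "animal_id": design.animal_id,
                        "channel_id": channel,
                        "genotype": design.genotype,
                        "drug": design.drug,
                        "stimulus": seg.label,
                        "feature_name": feature,
                        "raw_value": float(getattr(summary, feature)),
                        "baseline_normalized_value": (
                            normalized[feature] if normalized is not None else math.nan
                        ),
                    }
                )
            if not compute_pac:
                continue
            profile = pac_for_trial(rec, pac_pair, n_bins=n_bins, apply_notch=pac_notch)
            rows.append(
                {
                    "animal_id": design.animal_id,
                    "channel_id": channel,
                    "genotype": design.genotype,
                    "drug": design.drug,
                    "stimulus": seg.label,
                    "feature_name": "pac_mi",
                    "raw_value": profile.mi,
                    "baseline_normalized_value": math.nan,
                }
            )
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)


@dataclass(frozen=True)
class GroupEffect:
    """Group-dependent generator settings for the cohort simulator.

    ``stimulus_rate_multiplier`` scales the ripple rate of stimulus
    segments relative to the baseline rate; ``baseline_coupling`` and
    ``stimulus_coupling`` (when set) add a theta-gamma PAC component with
    the given modulation depths.
    """

    stimulus_rate_multiplier: float = 1.0
    baseline_coupling: Optional[float] = None
    stimulus_coupling: Optional[float] = None

    def __post_init__(self) -> None:
        if self.stimulus_rate_multiplier < 0:
            raise ContractError("stimulus_rate_multiplier must be non-negative")
        for c in (self.baseline_coupling, self.stimulus_coupling):
            if c is not None and not 0 <= c <= 1:
                raise ContractError("coupling must lie in [0, 1]")


def _simulate_segment(
    duration_s: float,
    fs: float,
    rate: float,
    coupling: Optional[float],
    noise: NoiseSpec,
    ripple_template: RippleSpec,
    pac_template: PacSpec,
    seed: int,
    channel_id: str,
) -> Tuple[LfpRecording, int]:
    rec = generate_background(duration_s, fs, noise, seed)
    if coupling is not None:
        pac_spec = replace(pac_template, coupling=coupling)
        pac_rec, _ = generate_pac(duration_s, fs, pac_spec, noise=None)
        rec = rec.with_samples(rec.samples + pac_rec.samples)
    spec = replace(ripple_template, rate=rate)
    if rate > 0:
        rec, truth = inject_ripples(rec, spec, seed=seed + 1)
        n_injected = len(truth.events)
    else:
        n_injected = 0
    return replace(rec, channel_id=channel_id), n_injected


def batch_simulate_and_analyze(
    n_animals: int,
    effects: Mapping[str, GroupEffect],
    seed: int,
    n_channels: int = 2,
    fs: float = 1000.0,
    baseline_s: float = 180.0,
    stimulus_s: float = 300.0,
    base_rate: float = 0.3,
    noise: NoiseSpec = NoiseSpec(),
    ripple_template: RippleSpec = RippleSpec(),
    pac_template: PacSpec = PacSpec(),
    params: DetectionParams = DetectionParams(),
    compute_pac: Optional[bool] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort with group-dependent effects and analyze it.

    Animals are assigned to the effect groups round-robin; the group label
    is carried in the tidy table's ``genotype`` column.  Returns the tidy
    measurement table and a ground-truth table (one row per segment x
    channel with the injected rate, event count, and coupling), so that
    group-level recovery can be tested against what was actually injected.

    PAC profiles are computed only when any group specifies a coupling
    (override with ``compute_pac``), since the ripple-rate recovery
    experiments do not need them.
    """
    if n_animals < 1:
        raise ContractError("n_animals must be >= 1")
    if not effects:
        raise ContractError("at least one effect group required")
    group_names = list(effects)
    if compute_pac is None:
        compute_pac = any(
            e.baseline_coupling is not None or e.stimulus_coupling is not None
            for e in effects.values()
        )
    rng = np.random.default_rng(seed)
    tidy_frames: List[pd.DataFrame] = []
    truth_rows: List[dict] = []
    for a in range(n_animals):
        group = group_names[a % len(group_names)]
        effect = effects[group]
        animal_id = f"sim{a:03d}"
        channels = tuple(f"ch{c}" for c in range(n_channels))
        design = social_session(
            animal_id,
            genotype=group,
            electrodes=channels,
            stimuli=("mother",),
            baseline_s=baseline_s,
            stimulus_s=stimulus_s,
        )
        recordings: Dict[Tuple[int, str], LfpRecording] = {}
        for channel in channels:
            for idx, seg in enumerate(design.trials):
                is_baseline = seg.kind == "baseline"
                rate = base_rate if is_baseline else base_rate * effect.stimulus_rate_multiplier
                coupling = (
                    effect.baseline_coupling if is_baseline else effect.stimulus_coupling
                )
                seg_seed = int(rng.integers(0, 2**31 - 2))
                rec, n_injected = _simulate_segment(
                    seg.duration_s,
                    fs,
                    rate,
                    coupling,
                    noise,
                    ripple_template,
                    pac_template,
                    seg_seed,
                    channel,
                )
                recordings[(idx, channel)] = rec
                truth_rows.append(
                    {
                        "animal_id": animal_id,
                        "group": group,
                        "channel_id": channel,
                        "stimulus": seg.label,
                        "true_rate_hz": rate,
                        "n_injected": n_injected,
                        "true_coupling": math.nan if coupling is None else coupling,
                        "seed": seg_seed,
                    }
                )
        tidy_frames.append(
            run_session(design, recordings, params=params, compute_pac=compute_pac)
        )
    tidy_all = pd.concat(tidy_frames, ignore_index=True)
    return tidy_all, pd.DataFrame(truth_rows)


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> float:
    """Two-sided permutation p-value for a difference in group means.

    Enumerates all label assignments exactly when there are at most 20,000
    of them; otherwise uses ``n_perm`` random permutations (the observed
    assignment counts toward the tail, so p is never zero).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ContractError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = abs(a.mean() - b.mean())
    n_total = pooled.size
    n_comb = math.comb(n_total, n_a)
    if n_comb <= 20000:
        stats = np.empty(n_comb)
        for i, idx in enumerate(itertools.combinations(range(n_total), n_a)):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(idx)] = True
            stats[i] = abs(pooled[mask].mean() - pooled[~mask].mean())
        return float(np.mean(stats >= observed - 1e-12))
    rng = np.random.default_rng(seed)
    hits = 1  # observed assignment
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        stat = abs(pooled[perm[:n_a]].mean() - pooled[perm[n_a:]].mean())
        if stat >= observed - 1e-12:
            hits += 1
    return hits / (n_perm + 1)


def cohort_rate_test(
    tidy: pd.DataFrame,
    group_a: str,
    group_b: str,
    feature: str = "rate_hz",
) -> float:
    """Permutation p-value comparing baseline-normalized ``feature`` between groups.

    Channel values are averaged per animal first (the animal, not the
    electrode, is the experimental unit), then the two groups of per-animal
    means are compared.
    """
    sub = tidy[(tidy["feature_name"] == feature) & tidy["stimulus"].ne("baseline")]
    sub = sub.dropna(subset=["baseline_normalized_value"])
    per_animal = sub.groupby(["genotype", "animal_id"])[
        "baseline_normalized_value"
    ].mean()
    try:
        a = per_animal.loc[group_a].to_numpy()
        b = per_animal.loc[group_b].to_numpy()
    except KeyError as exc:
        raise ContractError(f"group {exc} absent from tidy table") from exc
    return permutation_test(a, b)
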