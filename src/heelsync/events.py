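"""Adaptive-threshold event detectors and the extra-step QC check.

Heel contact
    On the preprocessed (dimensionless) heel trace, a baseline is the
    difference between the maximum observed after a stabilization period
    and the global minimum; the threshold is
    ``baseline * threshold_factor + min``, with factor 0.6 for single-leg
    tasks and 0.2 for bilateral tasks.  Contact is the first sample on an
    ascending portion, after a local minimum, that strictly exceeds the
    threshold while its predecessor does not.

Force onset
    On the filtered vGRF, the baseline is the mean of the first resting
    samples (default 10) and the threshold is
    ``baseline + 0.1 * SD(signal)``; onset is the first sample beyond the
    baseline window strictly above the threshold.

Extra step
    A preliminary step before the main movement produces a transient force
    episode that makes the onset detector fire prematurely.  The QC check
    segments above-threshold episodes and flags the trial when a transient
    episode (one that returns to baseline for a quiet gap) precedes a
    later sustained episode, reporting the sustained episode's start as the
    candidate corrected onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import DegenerateSignalError, NoEventError, ParameterError, SampledSignal

__all__ = [
    "HeelDetectorConfig",
    "ForceDetectorConfig",
    "EventDetection",
    "ExtraStepQC",
    "DETECTOR_PRESETS",
    "detect_heel_contact",
    "detect_force_onset",
    "detect_extra_step",
]


@dataclass(frozen=True)
class HeelDetectorConfig:
    """Heel-contact detector parameters.

    ``threshold_factor`` scales the post-stabilization range (0.6 single-leg,
    0.2 bilateral).  ``stabilization_samples`` excludes setup transients from
    the maximum; 30 samples is 0.5 s at 60 Hz.
    """

    threshold_factor: float = 0.2
    stabilization_samples: int = 30

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_factor < 1.0:
            raise ParameterError(
                f"threshold_factor must lie in (0, 1), got {self.threshold_factor}")
        if self.stabilization_samples < 0:
            raise ParameterError("stabilization_samples must be >= 0")


@dataclass(frozen=True)
class ForceDetectorConfig:
    """Force-onset detector parameters.

    ``sd_scope`` selects which segment the SD term is computed over:
    ``"signal"`` (the full trace, the default reading of the rule) or
    ``"baseline"`` (the resting window only).
    """

    baseline_samples: int = 10
    threshold_factor: float = 0.1
    sd_scope: str = "signal"  # {"signal", "baseline"}

    def __post_init__(self) -> None:
        if self.baseline_samples < 2:
            raise ParameterError("baseline_samples must be >= 2")
        if not self.threshold_factor > 0:
            raise ParameterError("threshold_factor must be > 0")
        if self.sd_scope not in ("signal", "baseline"):
            raise ParameterError(f"sd_scope must be 'signal' or 'baseline', got {self.sd_scope!r}")


DETECTOR_PRESETS: dict[str, HeelDetectorConfig] = {
    "single-leg": HeelDetectorConfig(threshold_factor=0.6),
    "bilateral": HeelDetectorConfig(threshold_factor=0.2),
}


@dataclass(frozen=True)
class EventDetection:
    """A detected event: sample index, time on the source clock, and the
    threshold/baseline that produced it."""

    index: int
    time_s: float
    threshold_value: float
    baseline_value: float
    detector: str  # {"heel_contact", "force_onset"}

    def to_dict(self) -> dict:
        return {
            "index": int(self.index),
            "time_s": float(self.time_s),
            "threshold_value": float(self.threshold_value),
            "baseline_value": float(self.baseline_value),
            "detector": self.detector,
        }


def _local_minima(values: np.ndarray) -> np.ndarray:
    """Indices of local minima: first-difference sign changes from - to +.

    A plateau between a descent and an ascent resolves to the plateau's
    last sample, so the ascent begins immediately after the minimum.
    """
    d = np.diff(values)
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return np.empty(0, dtype=int)
    prev, nxt = nz[:-1], nz[1:]
    mask = (d[prev] < 0) & (d[nxt] > 0)
    return nxt[mask]


def detect_heel_contact(heel: SampledSignal, cfg: HeelDetectorConfig) -> EventDetection:
    """Detect heel contact on a preprocessed heel trace.

    Returns the first sample that (a) follows a local minimum, (b) is on an
    ascending portion, and (c) strictly crosses the adaptive threshold
    (value > threshold while the previous value is <= threshold).

    Raises
    ------
    DegenerateSignalError
        If the post-stabilization maximum does not exceed the global minimum.
    NoEventError
        If no qualifying crossing exists (unsynchronizable trial).
    """
    v = heel.values
    n = v.size
    if n <= cfg.stabilization_samples + 2:
        raise ParameterError(
            f"signal length {n} must exceed stabilization_samples + 2 "
            f"({cfg.stabilization_samples + 2})")
    vmin = float(v.min())
    baseline = float(v[cfg.stabilization_samples:].max()) - vmin
    if baseline <= 0:
        raise DegenerateSignalError(
            "degenerate heel baseline: post-stabilization maximum does not "
            "exceed the global minimum")
    threshold = baseline * cfg.threshold_factor + vmin

    minima = _local_minima(v)
    if minima.size == 0:
        raise NoEventError(
            "no local minimum in heel trace; no contact candidate",
            threshold=threshold, baseline=baseline, detector="heel_contact")
    first_min = int(minima[0])

    ascending = v[1:] > v[:-1]
    crossing = (v[1:] > threshold) & (v[:-1] <= threshold)
    candidates = np.flatnonzero(ascending & crossing) + 1
    candidates = candidates[candidates > first_min]
    if candidates.size == 0:
        raise NoEventError(
            f"heel trace never crosses threshold {threshold:.6g} on an ascent "
            "after a local minimum",
            threshold=threshold, baseline=baseline, detector="heel_contact")
    idx = int(candidates[0])
    # first-crossing contract, asserted post hoc on every call
    assert v[idx] > threshold and v[idx - 1] <= threshold
    return EventDetection(
        index=idx,
        time_s=heel.time_of(idx),
        threshold_value=threshold,
        baseline_value=baseline,
        detector="heel_contact",
    )


def _force_threshold(v: np.ndarray, cfg: ForceDetectorConfig) -> tuple[float, float]:
    baseline = float(v[: cfg.baseline_samples].mean())
    scope = v if cfg.sd_scope == "signal" else v[: cfg.baseline_samples]
    sd = float(np.std(scope))  # population (n) denominator
    return baseline, baseline + sd * cfg.threshold_factor


def detect_force_onset(vgrf: SampledSignal, cfg: ForceDetectorConfig) -> EventDetection:
    """Detect the onset of vertical loading on a filtered vGRF trace.

    Onset is the first sample at or beyond the baseline window strictly
    above ``baseline + SD * threshold_factor``.  A constant trace has
    SD = 0 and never strictly exceeds its own baseline, so it fails loudly.
    """
    v = vgrf.values
    if v.size <= cfg.baseline_samples:
        raise ParameterError(
            f"signal length {v.size} must exceed baseline_samples ({cfg.baseline_samples})")
    baseline, threshold = _force_threshold(v, cfg)
    above = np.flatnonzero(v[cfg.baseline_samples:] > threshold)
    if above.size == 0:
        raise NoEventError(
            f"vGRF never exceeds threshold {threshold:.6g} N",
            threshold=threshold, baseline=baseline, detector="force_onset")
    idx = int(above[0]) + cfg.baseline_samples
    return EventDetection(
        index=idx,
        time_s=vgrf.time_of(idx),
        threshold_value=threshold,
        baseline_value=baseline,
        detector="force_onset",
    )


@dataclass
class ExtraStepQC:
    """Advisory QC flags for the preliminary-step failure mode."""

    extra_step: bool
    episodes: list[tuple[int, int]] = field(default_factory=list)
    alternative_onset: EventDetection | None = None

    def to_dict(self) -> dict:
        return {
            "extra_step": bool(self.extra_step),
            "episodes": [[int(a), int(b)] for a, b in self.episodes],
            "alternative_onset": (
                None if self.alternative_onset is None else self.alternative_onset.to_dict()
            ),
        }


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean mask."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_extra_step(
    vgrf: SampledSignal,
    onset: EventDetection,
    heel_event: EventDetection | None = None,
    *,
    quiet_gap_s: float = 0.25,
    min_sustained_s: float = 0.5,
) -> ExtraStepQC:
    """Flag trials whose vGRF shows a transient loading episode before the
    main, sustained loading (a preliminary step onto the platform).

    Above-threshold runs separated by sub-``quiet_gap_s`` dips are merged
    into one episode (the signal never properly returned to baseline).  The
    main episode is the last merged episode lasting at least
    ``min_sustained_s``; the trial is flagged when any episode ends before
    that episode starts, and the main episode's start is reported as the
    candidate corrected onset for a manual re-run.

    ``heel_event`` is accepted for signature completeness (reserved for
    future plausibility checks); the segmentation depends only on the force
    trace and the onset's threshold.
    """
    v = vgrf.values
    fs = vgrf.sampling_rate
    threshold = onset.threshold_value
    gap_samples = max(1, int(round(quiet_gap_s * fs)))
    sustained_samples = max(1, int(round(min_sustained_s * fs)))

    runs = _runs_above(v > threshold)
    if not runs:
        return ExtraStepQC(extra_step=False)

    merged: list[tuple[int, int]] = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] < gap_samples:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))

    sustained = [ep for ep in merged if ep[1] - ep[0] >= sustained_samples]
    if not sustained:
        return ExtraStepQC(extra_step=False, episodes=merged)
    main_start, _ = sustained[-1]
    has_precursor = any(end <= main_start for _, end in merged if end <= main_start)
    alternative = None
    if has_precursor:
        alternative = EventDetection(
            index=int(main_start),
            time_s=vgrf.time_of(int(main_start)),
            threshold_value=threshold,
            baseline_value=onset.baseline_value,
            detector="force_onset",
        )
    return ExtraStepQC(extra_step=has_precursor, episodes=merged, alternative_onset=alternative)
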