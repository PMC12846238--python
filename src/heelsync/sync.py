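"""Offset computation, force-stream shifting, cycle normalization, and the
model/results objects that orchestrate one trial or a batch.

The signed temporal offset is defined between the two detected events,

    offset = t(force onset) - t(heel contact),

each on its recording's own clock; a negative offset means the force
signal started loading before the kinematically estimated contact.
Shifting is a clock correction — the force stream's ``start_time`` is
adjusted by ``-offset`` so its onset lands exactly on the heel-contact
instant — never an array roll, so the native 1000 Hz samples are kept
intact and any common-grid resampling is an explicit later step.

:class:`TrialSynchronizer` is the model object (trial + configuration);
``fit()`` runs the full pipeline and returns a :class:`SyncResult` carrying
the offset, both events, the shifted force stream, 0-100 % cycle curves,
QC flags and a provenance log, with a ``summary()`` table.  Failures in
batch mode are data (:class:`TrialFailure`), not exceptions, so the
batch success-rate statistic is first-class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .events import (
    EventDetection,
    ExtraStepQC,
    detect_extra_step,
    detect_force_onset,
    detect_heel_contact,
)
from .preprocess import force_preprocess, heel_preprocess
from .signals import (
    DegenerateSignalError,
    HeelSyncError,
    NoEventError,
    ParameterError,
    SampledSignal,
    TrialRecord,
)

__all__ = [
    "compute_offset",
    "shift_force",
    "resample_to",
    "time_normalize",
    "TrialSynchronizer",
    "SyncResult",
    "TrialFailure",
    "synchronize_trial",
    "BatchResult",
    "batch_synchronize",
]


def compute_offset(heel_event: EventDetection, force_event: EventDetection) -> float:
    """Signed offset in seconds: force-onset time minus heel-contact time.

    Negative values mean the force signal occurred earlier than the
    kinematic contact estimate.
    """
    return float(force_event.time_s - heel_event.time_s)


def shift_force(vgrf: SampledSignal, offset_s: float) -> SampledSignal:
    """Re-time the force stream by ``-offset_s`` (clock correction only).

    After shifting, an event at force-clock time ``t`` reads ``t - offset_s``
    on the corrected clock, so the force onset lands exactly on the
    heel-contact instant.  Samples are untouched.
    """
    return vgrf.shifted(-offset_s)


def resample_to(signal: SampledSignal, target_rate: float) -> SampledSignal:
    """Linear interpolation onto a uniform grid at ``target_rate``.

    The grid starts at the signal's ``start_time`` and covers the longest
    span of whole target periods inside the original interval; grid points
    coinciding with original samples (including the first) are preserved
    exactly, and interpolation is exact on linear segments.
    """
    if not target_rate > 0:
        raise ParameterError(f"target_rate must be > 0, got {target_rate}")
    if signal.n_samples < 2:
        raise ParameterError("cannot resample a single-sample signal")
    span = signal.duration
    m = int(np.floor(span * target_rate + 1e-9)) + 1
    t_new = signal.start_time + np.arange(m) / target_rate
    t_old = signal.times()
    v_new = np.interp(t_new, t_old, signal.values)
    return SampledSignal(
        values=v_new,
        sampling_rate=target_rate,
        start_time=signal.start_time,
        label=signal.label,
        units=signal.units,
    )


def time_normalize(
    signal: SampledSignal,
    cycle_start_s: float,
    cycle_end_s: float,
    cycle_points: int = 101,
) -> np.ndarray:
    """Express a signal on a 0-100 % movement-cycle axis.

    Linear interpolation at ``cycle_points`` equally spaced instants from
    ``cycle_start_s`` (0 %) to ``cycle_end_s`` (100 %), both of which must
    lie inside the signal's time span.
    """
    if cycle_points < 2:
        raise ParameterError(f"cycle_points must be >= 2, got {cycle_points}")
    if not cycle_end_s > cycle_start_s:
        raise ParameterError(
            f"cycle_end_s ({cycle_end_s}) must exceed cycle_start_s ({cycle_start_s})")
    eps = 1e-9
    if cycle_start_s < signal.start_time - eps or cycle_end_s > signal.end_time + eps:
        raise ParameterError(
            f"cycle [{cycle_start_s}, {cycle_end_s}] s outside signal span "
            f"[{signal.start_time}, {signal.end_time}] s")
    t = np.linspace(cycle_start_s, cycle_end_s, cycle_points)
    return np.interp(t, signal.times(), signal.values)


# ---------------------------------------------------------------------------
# results


@dataclass
class SyncResult:
    """Outcome of synchronizing one trial."""

    offset_s: float
    heel_event: EventDetection
    force_event: EventDetection
    heel_side: str
    shifted_vgrf: SampledSignal
    cycle_curves: dict[str, np.ndarray]
    cycle_span_s: tuple[float, float]
    qc: ExtraStepQC
    provenance: dict
    trial_name: str = ""
    task: str = ""

    ok: bool = True

    @property
    def success(self) -> bool:
        return True

    def to_dict(self) -> dict:
        """JSON-ready representation (0-based indices, times in seconds)."""
        return {
            "schema": {"indices": "0-based", "times": "seconds"},
            "ok": True,
            "trial": self.trial_name,
            "task": self.task,
            "offset_s": float(self.offset_s),
            "heel_side": self.heel_side,
            "heel_event": self.heel_event.to_dict(),
            "force_event": self.force_event.to_dict(),
            "cycle_span_s": [float(self.cycle_span_s[0]), float(self.cycle_span_s[1])],
            "cycle_curves": {k: [float(x) for x in v] for k, v in self.cycle_curves.items()},
            "qc": self.qc.to_dict(),
            "provenance": self.provenance,
        }

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        lines = [
            "Trial synchronization results",
            "=" * 46,
            f"{'trial':<28}{self.trial_name or '-'}",
            f"{'task':<28}{self.task or '-'}",
            f"{'offset (s)':<28}{self.offset_s:+.4f}",
            f"{'heel side used':<28}{self.heel_side}",
            f"{'heel contact index':<28}{self.heel_event.index}",
            f"{'heel contact time (s)':<28}{self.heel_event.time_s:.4f}",
            f"{'heel threshold':<28}{self.heel_event.threshold_value:.4f}",
            f"{'force onset index':<28}{self.force_event.index}",
            f"{'force onset time (s)':<28}{self.force_event.time_s:.4f}",
            f"{'force threshold (N)':<28}{self.force_event.threshold_value:.4f}",
            f"{'extra-step flag':<28}{self.qc.extra_step}",
            f"{'cycle span (s)':<28}{self.cycle_span_s[0]:.4f} - {self.cycle_span_s[1]:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot of aligned heel and force curves (see plotting)."""
        from .plotting import plot_sync

        return plot_sync(self, ax=ax)


@dataclass
class TrialFailure:
    """A trial the pipeline could not synchronize — data, not an exception."""

    trial_name: str
    task: str
    reason: str
    stage: str
    detail: dict = field(default_factory=dict)

    ok: bool = False

    def to_dict(self) -> dict:
        return {
            "schema": {"indices": "0-based", "times": "seconds"},
            "ok": False,
            "trial": self.trial_name,
            "task": self.task,
            "reason": self.reason,
            "stage": self.stage,
            "detail": self.detail,
        }


def _failure_from_error(trial: TrialRecord, exc: HeelSyncError, stage: str) -> TrialFailure:
    kind = {
        DegenerateSignalError: "degenerate-signal",
        NoEventError: "no-event",
    }.get(type(exc), "error")
    detail: dict = {"message": str(exc)}
    if isinstance(exc, NoEventError):
        if exc.threshold is not None:
            detail["threshold"] = float(exc.threshold)
        if exc.detector is not None:
            detail["detector"] = exc.detector
    return TrialFailure(
        trial_name=trial.name, task=trial.task, reason=kind, stage=stage, detail=detail)


# ---------------------------------------------------------------------------
# model


class TrialSynchronizer:
    """Model object: one trial plus the configuration that governs its fit.

    ``fit()`` runs the full pipeline — heel smoothing chain, contact
    detection, force low-pass, onset detection, offset computation, clock
    shift, optional resampling, extra-step QC and 0-100 % cycle
    normalization — and returns a :class:`SyncResult`.  Detector or
    preprocessing failures raise; use :func:`synchronize_trial` or the
    batch path to receive failures as data instead.
    """

    def __init__(self, trial: TrialRecord, config: RunConfig | None = None):
        self.trial = trial
        self.config = config if config is not None else RunConfig(
            laterality_mode=trial.laterality_mode,
            evaluated_side=trial.evaluated_side,
        )

    @classmethod
    def from_files(cls, trc_path, force_path, config: RunConfig) -> "TrialSynchronizer":
        """Build the model from a TRC file and a force-platform CSV."""
        from .io import load_trial

        return cls(load_trial(trc_path, force_path, config), config)

    # -- pipeline -----------------------------------------------------------

    def _heel_candidates(self) -> list[str]:
        cfg = self.config
        if cfg.laterality_mode == "single_leg":
            side = cfg.evaluated_side
            if side not in ("left", "right"):
                side = self.trial.evaluated_side
            if side not in ("left", "right"):
                raise ParameterError(
                    "single_leg trials need evaluated_side 'left' or 'right'")
            return [side]
        return ["left", "right"]

    def fit(self) -> SyncResult:
        trial, cfg = self.trial, self.config
        heel_cfg = cfg.effective_heel_detector()

        # heel chain; bilateral trials align on the first-contacting heel
        events: dict[str, EventDetection] = {}
        preprocessed: dict[str, SampledSignal] = {}
        errors: list[HeelSyncError] = []
        for side in self._heel_candidates():
            try:
                pre = heel_preprocess(
                    trial.heel(side), cfg.heel_filter, cfg.median_window)
                events[side] = detect_heel_contact(pre, heel_cfg)
                preprocessed[side] = pre
            except (DegenerateSignalError, NoEventError, ParameterError) as exc:
                errors.append(exc)
        if not events:
            raise errors[0]
        heel_side = min(events, key=lambda s: events[s].time_s)
        heel_event = events[heel_side]
        heel_pre = preprocessed[heel_side]

        # force chain
        force_pre = force_preprocess(trial.active_vgrf, cfg.force_filter)
        force_event = detect_force_onset(force_pre, cfg.force_detector)

        offset_s = compute_offset(heel_event, force_event)
        shifted = shift_force(force_pre, offset_s)
        if cfg.resample_hz is not None:
            shifted = resample_to(shifted, cfg.resample_hz)

        qc = detect_extra_step(
            force_pre, force_event, heel_event,
            quiet_gap_s=cfg.quiet_gap_s, min_sustained_s=cfg.min_sustained_s)

        # cycle: contact instant to the end of the shorter aligned stream
        cycle_start = heel_event.time_s
        cycle_end = min(heel_pre.end_time, shifted.end_time)
        if cycle_end <= cycle_start:
            raise ParameterError(
                "no post-contact overlap between heel and shifted force streams")
        curves: dict[str, np.ndarray] = {}
        for side, pre in preprocessed.items():
            end_side = min(cycle_end, pre.end_time)
            curves[f"heel_{side}"] = time_normalize(
                pre, cycle_start, end_side, cfg.cycle_points)
        curves["vgrf"] = time_normalize(shifted, cycle_start, cycle_end, cfg.cycle_points)

        provenance = {
            "config": cfg.to_dict(),
            "heel_events": {s: e.to_dict() for s, e in events.items()},
            "heel_side_selected": heel_side,
            "heel_sides_failed": len(errors),
            "force_sampling_rate": trial.active_vgrf.sampling_rate,
            "kinematic_sampling_rate": trial.heel_left.sampling_rate,
            "offset_s": float(offset_s),
            "cycle": {
                "start_s": float(cycle_start),
                "end_s": float(cycle_end),
                "points": cfg.cycle_points,
            },
        }
        return SyncResult(
            offset_s=offset_s,
            heel_event=heel_event,
            force_event=force_event,
            heel_side=heel_side,
            shifted_vgrf=shifted,
            cycle_curves=curves,
            cycle_span_s=(float(cycle_start), float(cycle_end)),
            qc=qc,
            provenance=provenance,
            trial_name=trial.name,
            task=trial.task,
        )


def synchronize_trial(
    trial: TrialRecord, config: RunConfig | None = None
) -> SyncResult | TrialFailure:
    """Run the full pipeline on one trial; failures come back as data."""
    model = TrialSynchronizer(trial, config)
    try:
        return model.fit()
    except (DegenerateSignalError, NoEventError) as exc:
        return _failure_from_error(trial, exc, stage="event-detection")
    except ParameterError as exc:
        return _failure_from_error(trial, exc, stage="pipeline")


# ---------------------------------------------------------------------------
# batch


@dataclass
class BatchResult:
    """Aggregate of a batch run: per-trial results plus the success-rate
    statistic and a per-task offset table (mean and SD in seconds)."""

    results: list[SyncResult | TrialFailure]

    @property
    def n_trials(self) -> int:
        return len(self.results)

    @property
    def successes(self) -> list[SyncResult]:
        return [r for r in self.results if r.ok]

    @property
    def failures(self) -> list[TrialFailure]:
        return [r for r in self.results if not r.ok]

    @property
    def success_rate(self) -> float:
        """Percentage of trials synchronized."""
        return 100.0 * len(self.successes) / self.n_trials

    def task_table(self) -> pd.DataFrame:
        """Per-task offset mean and sample SD, in seconds."""
        rows = [
            {"task": r.task or "unknown", "offset_s": r.offset_s} for r in self.successes
        ]
        if not rows:
            return pd.DataFrame(columns=["task", "n", "mean_offset_s", "sd_offset_s"])
        df = pd.DataFrame(rows)
        out = (
            df.groupby("task", sort=True)["offset_s"]
            .agg(n="count", mean_offset_s="mean", sd_offset_s=lambda x: x.std(ddof=1))
            .reset_index()
        )
        return out

    def to_dict(self) -> dict:
        table = self.task_table()
        return {
            "n_trials": self.n_trials,
            "n_success": len(self.successes),
            "n_failure": len(self.failures),
            "success_rate_pct": float(self.success_rate),
            "failures": [
                {"trial": f.trial_name, "task": f.task, "reason": f.reason,
                 "stage": f.stage, "detail": f.detail}
                for f in self.failures
            ],
            "offsets_s": {
                r.trial_name or str(i): float(r.offset_s)
                for i, r in enumerate(self.results) if r.ok
            },
            "task_table": [
                {
                    "task": row["task"],
                    "n": int(row["n"]),
                    "mean_offset_s": float(row["mean_offset_s"]),
                    "sd_offset_s": (None if pd.isna(row["sd_offset_s"])
                                    else float(row["sd_offset_s"])),
                }
                for _, row in table.iterrows()
            ],
        }

    def summary(self) -> str:
        lines = [
            "Batch synchronization results",
            "=" * 46,
            f"{'trials':<28}{self.n_trials}",
            f"{'synchronized':<28}{len(self.successes)}",
            f"{'failed':<28}{len(self.failures)}",
            f"{'success rate (%)':<28}{self.success_rate:.1f}",
            "",
            "Per-task offset (s):",
            self.task_table().to_string(index=False),
        ]
        if self.failures:
            lines.append("")
            lines.append("Failures:")
            for f in self.failures:
                lines.append(f"  {f.trial_name or '?'}: {f.reason} ({f.stage})")
        return "\n".join(lines)


def batch_synchronize(
    trials: list[TrialRecord], config: RunConfig | None = None
) -> BatchResult:
    """Synchronize a bank of trials; per-trial failures are recorded, not
    raised, so the success rate is a computed statistic."""
    if not trials:
        raise ParameterError("batch_synchronize requires at least one trial")
    return BatchResult([synchronize_trial(t, config) for t in trials])
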