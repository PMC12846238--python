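"""Core signal containers and the package's exception hierarchy.

A :class:`SampledSignal` is a uniformly sampled 1-D channel: the heel
vertical coordinate from a markerless capture (metres, nominally 60 Hz)
or a force platform's vertical ground reaction force (newtons, nominally
1000 Hz).  Sample *i* lives at ``start_time + i / sampling_rate`` on the
recording's own clock; synchronization is ultimately a correction of
``start_time`` on the force stream.

A :class:`TrialRecord` groups the channels of one movement trial together
with its task metadata (laterality, evaluated side, active platform).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "HeelSyncError",
    "FormatError",
    "ConfigurationError",
    "ParameterError",
    "DegenerateSignalError",
    "NoEventError",
    "SampledSignal",
    "TrialRecord",
]


class HeelSyncError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(HeelSyncError):
    """A file does not conform to its declared format."""


class ConfigurationError(HeelSyncError):
    """A configuration key or mapping is invalid or missing."""


class ParameterError(HeelSyncError):
    """An operation was called with out-of-contract parameters."""


class DegenerateSignalError(HeelSyncError):
    """A signal lacks the structure an operation requires (e.g. constant)."""


class NoEventError(HeelSyncError):
    """No sample satisfied a detector's crossing condition.

    Carries the computed threshold and baseline so a failed trial can be
    reported (this is the unsynchronizable-trial path, counted as data in
    batch mode rather than raised).
    """

    def __init__(self, message: str, *, threshold: float | None = None,
                 baseline: float | None = None, detector: str | None = None):
        super().__init__(message)
        self.threshold = threshold
        self.baseline = baseline
        self.detector = detector


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled 1-D channel.

    Parameters
    ----------
    values : array-like of float
        Sample values. Must be finite; non-finite samples (tracking gaps)
        are rejected loudly rather than propagated silently.
    sampling_rate : float
        Sampling rate in Hz, strictly positive.
    start_time : float, optional
        Time of the first sample, in seconds, on the recording's own clock.
    label, units : str, optional
        Channel name and physical units ("m", "N", or "" once dimensionless).
    """

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ParameterError(f"signal values must be 1-D, got shape {v.shape}")
        if v.size < 1:
            raise ParameterError("signal must contain at least one sample")
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise ParameterError(
                f"non-finite sample at index {bad} in channel "
                f"{self.label!r}; gaps must be handled before constructing a signal"
            )
        if not (self.sampling_rate > 0 and np.isfinite(self.sampling_rate)):
            raise ParameterError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    # -- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + (self.n_samples - 1) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds on the signal's own clock."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def time_of(self, index: int) -> float:
        """Time of sample ``index`` (uniform-sampling contract)."""
        if not 0 <= index < self.n_samples:
            raise ParameterError(f"index {index} out of range [0, {self.n_samples})")
        return self.start_time + index / self.sampling_rate

    def with_values(self, values: np.ndarray, *, units: str | None = None,
                    label: str | None = None) -> "SampledSignal":
        """Copy of this signal with new samples (same clock and rate)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            units=self.units if units is None else units,
            label=self.label if label is None else label,
        )

    def shifted(self, delta_t: float) -> "SampledSignal":
        """Copy with ``start_time`` advanced by ``delta_t`` seconds."""
        return replace(self, start_time=self.start_time + delta_t)


@dataclass
class TrialRecord:
    """One movement trial: heel channels, per-platform vGRF, task metadata."""

    heel_left: SampledSignal
    heel_right: SampledSignal
    vgrf: Mapping[str, SampledSignal]
    task: str = "squat"
    laterality_mode: str = "bilateral"  # {"single_leg", "bilateral"}
    evaluated_side: str = "both"        # {"left", "right", "both"}
    active_platform: str = ""
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.laterality_mode not in ("single_leg", "bilateral"):
            raise ParameterError(
                f"laterality_mode must be 'single_leg' or 'bilateral', got {self.laterality_mode!r}")
        if self.laterality_mode == "bilateral" and self.evaluated_side != "both":
            raise ParameterError("bilateral trials must have evaluated_side='both'")
        if self.evaluated_side not in ("left", "right", "both"):
            raise ParameterError(f"invalid evaluated_side {self.evaluated_side!r}")
        if self.heel_left.sampling_rate != self.heel_right.sampling_rate:
            raise ParameterError("heel channels must share one sampling rate")
        if not self.vgrf:
            raise ParameterError("trial must carry at least one vGRF channel")
        rates = {s.sampling_rate for s in self.vgrf.values()}
        if len(rates) > 1:
            raise ParameterError("all force channels must share one sampling rate")
        if not self.active_platform:
            self.active_platform = next(iter(self.vgrf))
        if self.active_platform not in self.vgrf:
            raise ParameterError(
                f"active_platform {self.active_platform!r} not among platforms "
                f"{sorted(self.vgrf)}")

    @property
    def active_vgrf(self) -> SampledSignal:
        return self.vgrf[self.active_platform]

    def heel(self, side: str) -> SampledSignal:
        if side == "left":
            return self.heel_left
        if side == "right":
            return self.heel_right
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
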