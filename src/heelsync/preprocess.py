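"""Preprocessing: min-max normalization and the two filtering chains.

The heel vertical coordinate is min-max normalized and then smoothed by a
cascade of two 4th-order 3 Hz low-pass Butterworth filters, each applied
bidirectionally (forward + backward, so the net phase shift is zero and
event timing is unbiased), followed by a 5-sample running median that
suppresses residual impulse noise.  Force channels get a single 4th-order
30 Hz zero-phase low-pass.

Zero-phase passes use reflective (even) edge padding of length
``3 * order`` samples per pass; a signal must therefore be longer than
``3 * order`` samples to be filtered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signals import DegenerateSignalError, ParameterError, SampledSignal

__all__ = [
    "FilterSpec",
    "FILTER_PRESETS",
    "minmax_normalize",
    "butterworth_lowpass",
    "median_filter",
    "heel_preprocess",
    "force_preprocess",
]


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth low-pass configuration.

    ``passes`` counts cascaded applications; each bidirectional pass is one
    forward plus one backward run (squaring the magnitude response).
    """

    order: int = 4
    cutoff_hz: float = 3.0
    bidirectional: bool = True
    passes: int = 1

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError(f"filter order must be >= 1, got {self.order}")
        if self.passes < 1:
            raise ParameterError(f"passes must be >= 1, got {self.passes}")
        if not self.cutoff_hz > 0:
            raise ParameterError(f"cutoff_hz must be > 0, got {self.cutoff_hz}")

    def min_length(self) -> int:
        """Minimum signal length the edge-padding scheme supports."""
        return 3 * self.order + 1 if self.bidirectional else self.order + 1

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "cutoff_hz": self.cutoff_hz,
            "bidirectional": self.bidirectional,
            "passes": self.passes,
        }


#: Immutable named defaults for the two chains.
FILTER_PRESETS: dict[str, FilterSpec] = {
    "heel-cascade": FilterSpec(order=4, cutoff_hz=3.0, bidirectional=True, passes=2),
    "force-lowpass": FilterSpec(order=4, cutoff_hz=30.0, bidirectional=True, passes=1),
}


def minmax_normalize(signal: SampledSignal) -> SampledSignal:
    """Linearly rescale a signal so its minimum maps to 0 and maximum to 1.

    Raises
    ------
    DegenerateSignalError
        If the signal is constant (zero range cannot be normalized).
    """
    v = signal.values
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise DegenerateSignalError(
            f"cannot min-max normalize constant signal {signal.label!r} (value {lo})")
    return signal.with_values((v - lo) / (hi - lo), units="")


def butterworth_lowpass(signal: SampledSignal, spec: FilterSpec) -> SampledSignal:
    """Apply a Butterworth low-pass ``spec.passes`` times.

    Bidirectional passes use :func:`scipy.signal.filtfilt` with even
    (reflective) padding of ``3 * order`` samples, giving zero net phase
    shift; causal passes use a plain forward run.
    """
    fs = signal.sampling_rate
    nyq = fs / 2.0
    if not spec.cutoff_hz < nyq:
        raise ParameterError(
            f"cutoff {spec.cutoff_hz} Hz must be below the Nyquist frequency "
            f"{nyq} Hz at fs={fs} Hz")
    need = spec.min_length()
    if signal.n_samples < need:
        raise ParameterError(
            f"signal of length {signal.n_samples} too short for the edge-padding "
            f"scheme; at least {need} samples required")
    b, a = sps.butter(spec.order, spec.cutoff_hz / nyq, btype="low")
    x = signal.values.astype(float)
    for _ in range(spec.passes):
        if spec.bidirectional:
            x = sps.filtfilt(b, a, x, padtype="even", padlen=3 * spec.order)
        else:
            x = sps.lfilter(b, a, x)
    return signal.with_values(x)


def median_filter(signal: SampledSignal, window: int = 5) -> SampledSignal:
    """Centered running median; the window shrinks at the boundaries.

    The shrinking-window edge policy avoids inventing padding values: at
    index *i* the median is taken over ``values[max(0, i-k) : i+k+1]`` with
    ``k = window // 2``.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"median window must be an odd integer >= 3, got {window}")
    out = (
        pd.Series(signal.values)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return signal.with_values(out)


def heel_preprocess(
    heel: SampledSignal,
    filter_spec: FilterSpec | None = None,
    median_window: int = 5,
) -> SampledSignal:
    """Full heel smoothing chain: normalize, Butterworth cascade, median.

    The output is dimensionless; post-filter values may slightly exceed
    [0, 1] because of filter ringing and are deliberately not re-clamped
    (clamping would distort the slopes the contact detector relies on).
    """
    if abs(heel.sampling_rate - 60.0) > 1e-9:
        warnings.warn(
            f"heel channel sampled at {heel.sampling_rate} Hz; the smoothing "
            "chain is tuned for nominal 60 Hz video capture",
            UserWarning,
            stacklevel=2,
        )
    spec = FILTER_PRESETS["heel-cascade"] if filter_spec is None else filter_spec
    out = minmax_normalize(heel)
    out = butterworth_lowpass(out, spec)
    out = median_filter(out, median_window)
    return out


def force_preprocess(vgrf: SampledSignal, filter_spec: FilterSpec | None = None) -> SampledSignal:
    """Force chain: 4th-order 30 Hz zero-phase low-pass, units preserved."""
    spec = FILTER_PRESETS["force-lowpass"] if filter_spec is None else filter_spec
    return butterworth_lowpass(vgrf, spec)
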