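"""Synthetic trial generator with exact ground truth.

Emulates the temporal structure the synchronization algorithm assumes for
a predominantly vertical task (a stationary squat): a heel vertical
trajectory that sits on an elevated plateau, descends smoothly
(raised-cosine) to a unique minimum at ground contact and partially rises
afterwards; and a vGRF trace that is quiescent, rises sigmoidally to body
weight at loading, then oscillates at squat cadence.  White Gaussian noise
is added before any filtering, mirroring the real processing order.  An
optional preliminary-step transient (a short force bump before the main
loading) reproduces the documented failure mode that makes the onset
detector fire prematurely.

Ground truth is exact by construction: the generator places the force
loading so that the *detectable* force-onset instant lands exactly
``true_offset_s`` after the *detectable* heel-contact instant (each
detector's threshold-crossing time, computed in closed form on the clean
waveforms with a short fixed-point step for the SD-dependent force
threshold).  Running the detectors on the noiseless channels therefore
recovers the stored indices, and the recovered offset equals the injected
one up to sampling quantization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .signals import ParameterError, SampledSignal, TrialRecord

__all__ = ["SyntheticTrialSpec", "SyntheticGroundTruth", "generate_trial", "generate_bank"]

#: loading that must remain after the rise so the main episode counts as
#: sustained (margin over the QC default of 0.5 s)
_SUSTAIN_MARGIN_S = 0.7


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Parameters of one synthetic trial.

    Noise SDs are expressed as a fraction of each clean channel's range
    (default 2 %, the noise regime the pipeline is expected to handle).
    Rates default to the nominal acquisition setup: 60 Hz video kinematics,
    1000 Hz force platform.
    """

    true_offset_s: float = -1.38
    fs_kin: float = 60.0
    fs_force: float = 1000.0
    duration_s: float = 7.0
    contact_time_s: float = 3.0          # heel-minimum instant, kinematic clock
    body_weight_n: float = 608.0         # 62 kg participant
    heel_drop_amplitude_m: float = 0.12
    heel_base_height_m: float = 0.02
    descent_duration_s: float = 1.0
    rise_duration_s: float = 0.8
    rise_fraction: float = 0.85          # partial post-contact rise, of drop amplitude
    load_rise_duration_s: float = 0.3
    oscillation_fraction: float = 0.15   # squat-cycle loading oscillation, of body weight
    oscillation_hz: float = 0.5
    resting_load_n: float = 0.0          # nonzero = subject already on the plate
    noise_sd_kin: float = 0.02
    noise_sd_force: float = 0.02
    extra_step: bool = False
    extra_step_time_s: float | None = None  # bump start, force clock; None = derived
    extra_step_lead_s: float = 0.8          # bump start precedes main loading by this
    extra_step_duration_s: float = 0.3
    extra_step_peak_n: float = 200.0
    laterality_mode: str = "bilateral"
    evaluated_side: str = "both"
    task: str = "squat_60"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.contact_time_s < self.duration_s):
            raise ParameterError("contact_time_s must lie inside (0, duration_s)")
        if self.fs_kin <= 0 or self.fs_force <= 0:
            raise ParameterError("sampling rates must be > 0")
        if self.noise_sd_kin < 0 or self.noise_sd_force < 0:
            raise ParameterError("noise fractions must be >= 0")
        if self.laterality_mode not in ("single_leg", "bilateral"):
            raise ParameterError(f"invalid laterality_mode {self.laterality_mode!r}")
        if self.heel_drop_amplitude_m <= 0 or self.rise_fraction <= 0:
            raise ParameterError("heel amplitude and rise_fraction must be > 0")
        if self.body_weight_n <= self.resting_load_n:
            raise ParameterError("body_weight_n must exceed resting_load_n")
        if self.contact_time_s - self.descent_duration_s <= 0.6:
            raise ParameterError(
                "descent must start after the stabilization window "
                "(contact_time_s - descent_duration_s > 0.6 s)")
        if self.contact_time_s + self.rise_duration_s >= self.duration_s:
            raise ParameterError("post-contact rise must finish within the trial")

    def heel_threshold_factor(self) -> float:
        return 0.6 if self.laterality_mode == "single_leg" else 0.2

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Exact event locations stored by the construction."""

    true_offset_s: float
    contact_time_s: float                # heel-minimum instant (kinematic clock)
    heel_contact_index: int              # detectable contact sample, clean trace
    heel_contact_time_s: float
    heel_threshold: float
    force_onset_index: int               # main-loading crossing sample, clean trace
    force_onset_time_s: float
    force_threshold: float
    naive_onset_index: int               # first crossing incl. any preliminary bump
    naive_onset_time_s: float
    extra_step: bool
    spec: SyntheticTrialSpec

    def to_dict(self) -> dict:
        d = {
            "true_offset_s": self.true_offset_s,
            "contact_time_s": self.contact_time_s,
            "heel_contact_index": self.heel_contact_index,
            "heel_contact_time_s": self.heel_contact_time_s,
            "heel_threshold": self.heel_threshold,
            "force_onset_index": self.force_onset_index,
            "force_onset_time_s": self.force_onset_time_s,
            "force_threshold": self.force_threshold,
            "naive_onset_index": self.naive_onset_index,
            "naive_onset_time_s": self.naive_onset_time_s,
            "extra_step": self.extra_step,
            "spec": self.spec.to_dict(),
        }
        return d


# ---------------------------------------------------------------------------
# waveforms


def _heel_waveform(t: np.ndarray, spec: SyntheticTrialSpec) -> np.ndarray:
    """Clean heel height in metres on the kinematic clock."""
    base = spec.heel_base_height_m
    amp = spec.heel_drop_amplitude_m
    tc = spec.contact_time_s
    t0 = tc - spec.descent_duration_s
    tr = spec.rise_duration_s

    h = np.full_like(t, base + amp)
    descent = (t > t0) & (t <= tc)
    h[descent] = base + amp * (1 + np.cos(np.pi * (t[descent] - t0) / spec.descent_duration_s)) / 2
    rising = (t > tc) & (t <= tc + tr)
    h[rising] = base + amp * spec.rise_fraction * (1 - np.cos(np.pi * (t[rising] - tc) / tr)) / 2
    h[t > tc + tr] = base + amp * spec.rise_fraction
    return h


def _force_waveform(tau: np.ndarray, t0: float, spec: SyntheticTrialSpec) -> np.ndarray:
    """Clean vGRF in newtons on the force clock, loading from ``t0``."""
    rest = spec.resting_load_n
    w = spec.body_weight_n
    d = spec.load_rise_duration_s
    f = np.full_like(tau, rest)
    rising = (tau >= t0) & (tau < t0 + d)
    f[rising] = rest + (w - rest) * (1 - np.cos(np.pi * (tau[rising] - t0) / d)) / 2
    loaded = tau >= t0 + d
    osc = spec.oscillation_fraction * w
    f[loaded] = w + osc * np.sin(2 * np.pi * spec.oscillation_hz * (tau[loaded] - t0 - d))
    if spec.extra_step:
        tb = _bump_start(t0, spec)
        db = spec.extra_step_duration_s
        in_bump = (tau >= tb) & (tau <= tb + db)
        f[in_bump] += spec.extra_step_peak_n * (
            1 - np.cos(2 * np.pi * (tau[in_bump] - tb) / db)) / 2
    return f


def _bump_start(t0: float, spec: SyntheticTrialSpec) -> float:
    tb = (spec.extra_step_time_s if spec.extra_step_time_s is not None
          else t0 - spec.extra_step_lead_s)
    if tb + spec.extra_step_duration_s >= t0:
        raise ParameterError("preliminary step must end before the main loading")
    if tb <= 0.05:
        raise ParameterError("preliminary step must start after the resting baseline window")
    return tb


# ---------------------------------------------------------------------------
# literal event scans (construction oracle; intentionally plain loops)


def _scan_heel_contact(values: np.ndarray, factor: float, stabilization: int
                       ) -> tuple[int, float]:
    """Literal rule: threshold crossing on an ascent after a local minimum."""
    vmin = values.min()
    baseline = values[stabilization:].max() - vmin
    thr = baseline * factor + vmin
    # local minima with plateaus resolved to the plateau's last sample
    minima = []
    last_nonzero_sign = 0
    for i in range(1, len(values)):
        d = values[i] - values[i - 1]
        if d > 0 and last_nonzero_sign < 0:
            minima.append(i - 1)
        if d != 0:
            last_nonzero_sign = 1 if d > 0 else -1
    if not minima:
        raise ParameterError("synthetic heel trace has no local minimum")
    first_min = minima[0]
    for i in range(first_min + 1, len(values)):
        if values[i] > values[i - 1] and values[i] > thr and values[i - 1] <= thr:
            return i, thr
    raise ParameterError("synthetic heel trace never crosses its threshold")


def _scan_force_onset(values: np.ndarray, baseline_samples: int, factor: float,
                      start_at: int = 0) -> tuple[int, float]:
    baseline = values[:baseline_samples].mean()
    thr = baseline + values.std() * factor
    for i in range(max(baseline_samples, start_at), len(values)):
        if values[i] > thr:
            return i, thr
    raise ParameterError("synthetic force trace never crosses its threshold")


# ---------------------------------------------------------------------------
# generation


def generate_trial(spec: SyntheticTrialSpec) -> tuple[TrialRecord, SyntheticGroundTruth]:
    """Generate one trial and its exact ground truth.

    Deterministic given ``spec.seed``: the same spec yields bit-identical
    channels on every call.
    """
    n_kin = int(round(spec.duration_s * spec.fs_kin)) + 1
    n_force = int(round(spec.duration_s * spec.fs_force)) + 1
    t_kin = np.arange(n_kin) / spec.fs_kin
    t_force = np.arange(n_force) / spec.fs_force

    # --- heel: clean waveform, detectable contact from a literal scan
    heel_clean = _heel_waveform(t_kin, spec)
    lo, hi = heel_clean.min(), heel_clean.max()
    heel_norm = (heel_clean - lo) / (hi - lo)
    factor = spec.heel_threshold_factor()
    if spec.rise_fraction <= factor:
        raise ParameterError(
            f"rise_fraction {spec.rise_fraction} must exceed the heel threshold "
            f"factor {factor} or contact is undetectable")
    stabilization = min(int(round(0.5 * spec.fs_kin)), n_kin - 3)
    heel_idx, heel_thr = _scan_heel_contact(heel_norm, factor, stabilization)
    heel_time = heel_idx / spec.fs_kin

    # --- force: place the loading so its threshold crossing lands exactly
    # true_offset_s after the detectable heel contact (fixed point on the
    # SD-dependent threshold)
    tau_target = heel_time + spec.true_offset_s
    min_start = (10 + 1) / spec.fs_force + 0.05
    if tau_target <= min_start:
        raise ParameterError(
            f"true_offset_s {spec.true_offset_s} puts the force onset inside "
            "the resting baseline window")
    if tau_target + spec.load_rise_duration_s >= spec.duration_s - _SUSTAIN_MARGIN_S:
        raise ParameterError(
            f"true_offset_s {spec.true_offset_s} leaves no sustained loading "
            "before the end of the trial")

    t0 = tau_target - 0.05 * spec.load_rise_duration_s
    thr = float("nan")
    for _ in range(4):
        force_clean = _force_waveform(t_force, t0, spec)
        baseline = force_clean[:10].mean()
        thr = baseline + force_clean.std() * 0.1
        frac = (thr - spec.resting_load_n) / (spec.body_weight_n - spec.resting_load_n)
        if not 0.0 < frac < 1.0:
            raise ParameterError("force threshold outside the loading rise")
        cross = t0 + (spec.load_rise_duration_s / math.pi) * math.acos(1 - 2 * frac)
        t0 += tau_target - cross
    force_clean = _force_waveform(t_force, t0, spec)

    main_start_idx = int(np.searchsorted(t_force, t0 - 1e-12))
    onset_idx, force_thr = _scan_force_onset(force_clean, 10, 0.1, start_at=main_start_idx)
    naive_idx, _ = _scan_force_onset(force_clean, 10, 0.1)

    # --- noise, drawn in a fixed channel order for determinism
    rng = np.random.default_rng(spec.seed)
    heel_range = hi - lo
    force_range = force_clean.max() - force_clean.min()
    heel_left = heel_clean + rng.normal(0.0, spec.noise_sd_kin * heel_range, n_kin)
    heel_right = heel_clean + rng.normal(0.0, spec.noise_sd_kin * heel_range, n_kin)
    force = force_clean + rng.normal(0.0, spec.noise_sd_force * force_range, n_force)

    evaluated = "both" if spec.laterality_mode == "bilateral" else (
        spec.evaluated_side if spec.evaluated_side in ("left", "right") else "left")
    trial = TrialRecord(
        heel_left=SampledSignal(heel_left, spec.fs_kin, label="LHeel", units="m"),
        heel_right=SampledSignal(heel_right, spec.fs_kin, label="RHeel", units="m"),
        vgrf={"plate1": SampledSignal(force, spec.fs_force, label="Fz1", units="N")},
        task=spec.task,
        laterality_mode=spec.laterality_mode,
        evaluated_side=evaluated,
        active_platform="plate1",
        name=f"synthetic_{spec.seed:05d}",
        meta={"synthetic": True},
    )
    truth = SyntheticGroundTruth(
        true_offset_s=spec.true_offset_s,
        contact_time_s=spec.contact_time_s,
        heel_contact_index=heel_idx,
        heel_contact_time_s=heel_time,
        heel_threshold=float(heel_thr),
        force_onset_index=onset_idx,
        force_onset_time_s=onset_idx / spec.fs_force,
        force_threshold=float(force_thr),
        naive_onset_index=naive_idx,
        naive_onset_time_s=naive_idx / spec.fs_force,
        extra_step=spec.extra_step,
        spec=spec,
    )
    return trial, truth


def generate_bank(
    n: int,
    base_spec: SyntheticTrialSpec | None = None,
    randomize: dict | None = None,
    seed: int = 0,
) -> list[tuple[TrialRecord, SyntheticGroundTruth]]:
    """Generate ``n`` trials with parameters drawn from stated ranges.

    ``randomize`` maps spec field names to ``(low, high)`` uniform ranges
    (numeric fields) or to a list of choices; the special key
    ``extra_step_fraction`` makes that share of trials carry the
    preliminary-step transient (assignment randomized but reproducible).
    Trial ``i`` uses seed ``seed + i``, so a bank at seed 0 spans trial
    seeds ``0 .. n-1``.
    """
    if n < 1:
        raise ParameterError("bank size must be >= 1")
    base = base_spec if base_spec is not None else SyntheticTrialSpec()
    randomize = dict(randomize or {})
    extra_fraction = randomize.pop("extra_step_fraction", None)
    valid = {f.name for f in fields(SyntheticTrialSpec)}
    for key, rng_spec in randomize.items():
        if key not in valid:
            raise ParameterError(f"unknown spec field {key!r} in randomize")
        if isinstance(rng_spec, (tuple, list)) and len(rng_spec) == 0:
            raise ParameterError(f"empty range for randomized field {key!r}")

    rng = np.random.default_rng(seed)
    extra_flags = np.zeros(n, dtype=bool)
    if extra_fraction is not None:
        k = int(round(float(extra_fraction) * n))
        extra_flags[rng.permutation(n)[:k]] = True

    out = []
    for i in range(n):
        updates: dict = {"seed": seed + i}
        for key in sorted(randomize):
            rng_spec = randomize[key]
            if isinstance(rng_spec, tuple) and len(rng_spec) == 2 and all(
                    isinstance(x, (int, float)) for x in rng_spec):
                updates[key] = float(rng.uniform(rng_spec[0], rng_spec[1]))
            else:
                updates[key] = rng_spec[int(rng.integers(len(rng_spec)))]
        if extra_fraction is not None:
            updates["extra_step"] = bool(extra_flags[i])
        out.append(generate_trial(replace(base, **updates)))
    return out
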