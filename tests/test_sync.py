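import dataclasses

import numpy as np
import pytest

from heelsync import (
    EventDetection,
    ForceDetectorConfig,
    ParameterError,
    RunConfig,
    SampledSignal,
    SyntheticTrialSpec,
    TrialSynchronizer,
    batch_synchronize,
    compute_offset,
    detect_force_onset,
    resample_to,
    shift_force,
    synchronize_trial,
    time_normalize,
)
from heelsync.synthetic import generate_bank, generate_trial


def event(t, detector="force_onset", fs=1000.0):
    return EventDetection(index=int(round(t * fs)), time_s=t, threshold_value=0.0,
                          baseline_value=0.0, detector=detector)


class TestComputeOffset:
    @pytest.mark.parametrize("heel_t,force_t,expected", [
        (2.00, 0.62, -1.38),   # force earlier -> negative
        (1.00, 1.00, 0.0),
        (1.00, 1.50, +0.50),
    ])
    def test_sign_convention(self, heel_t, force_t, expected):
        off = compute_offset(event(heel_t, "heel_contact", 60.0), event(force_t))
        assert off == pytest.approx(expected)


class TestShiftForce:
    def test_clock_arithmetic(self):
        sig = SampledSignal(np.arange(10.0), 1000.0, start_time=0.5)
        shifted = shift_force(sig, -1.38)
        assert shifted.start_time == pytest.approx(0.5 + 1.38)
        assert np.array_equal(shifted.values, sig.values)

    def test_zero_offset_is_identity(self):
        sig = SampledSignal(np.arange(10.0), 1000.0)
        assert shift_force(sig, 0.0) == sig

    def test_redetected_onset_lands_on_heel_contact(self, clean_trial):
        trial, _ = clean_trial
        res = synchronize_trial(trial)
        ev = detect_force_onset(res.shifted_vgrf, ForceDetectorConfig())
        assert ev.time_s == pytest.approx(res.heel_event.time_s, abs=1e-12)


class TestResample:
    def test_constant_preserved(self):
        sig = SampledSignal(np.full(1001, 3.5), 1000.0)
        out = resample_to(sig, 60.0)
        assert out.sampling_rate == 60.0
        assert np.allclose(out.values, 3.5)

    def test_linear_ramp_exact(self):
        t = np.arange(1001) / 1000.0
        sig = SampledSignal(2.0 + 5.0 * t, 1000.0)
        out = resample_to(sig, 60.0)
        assert np.allclose(out.values, 2.0 + 5.0 * out.times(), atol=1e-12)

    def test_sinusoid_close_to_analytic(self):
        t = np.arange(2001) / 1000.0
        sig = SampledSignal(np.sin(2 * np.pi * 1.0 * t), 1000.0)
        out = resample_to(sig, 60.0)
        assert np.max(np.abs(out.values - np.sin(2 * np.pi * out.times()))) < 1e-3

    def test_single_sample_rejected(self):
        with pytest.raises(ParameterError):
            resample_to(SampledSignal([1.0], 1000.0), 60.0)


class TestTimeNormalize:
    def test_length_and_linearity(self):
        t = np.arange(1001) / 1000.0
        sig = SampledSignal(1.0 + 3.0 * t, 1000.0)
        curve = time_normalize(sig, 0.2, 0.8, cycle_points=101)
        assert curve.shape == (101,)
        assert curve[0] == pytest.approx(1.0 + 3.0 * 0.2)
        assert curve[-1] == pytest.approx(1.0 + 3.0 * 0.8)
        assert np.allclose(np.diff(curve, 2), 0.0, atol=1e-12)

    def test_bounds_outside_span_rejected(self):
        sig = SampledSignal(np.zeros(100), 60.0)
        with pytest.raises(ParameterError, match="outside"):
            time_normalize(sig, -0.5, 1.0)
        with pytest.raises(ParameterError):
            time_normalize(sig, 0.5, 0.2)


class TestSynchronizeTrial:
    def test_clean_trial_recovers_injected_offset(self, clean_trial):
        trial, truth = clean_trial
        res = synchronize_trial(trial)
        assert res.ok
        assert abs(res.offset_s - truth.true_offset_s) <= 1 / 60.0
        assert res.cycle_curves["vgrf"].shape == (101,)
        assert set(res.cycle_curves) == {"heel_left", "heel_right", "vgrf"}

    def test_flat_heel_yields_failure_result(self, clean_trial):
        trial, _ = clean_trial
        flat = dataclasses.replace(trial)
        flat.heel_left = trial.heel_left.with_values(np.full(trial.heel_left.n_samples, 0.1))
        flat.heel_right = flat.heel_left
        res = synchronize_trial(flat)
        assert not res.ok
        assert res.reason == "degenerate-signal"

    def test_provenance_records_thresholds_and_config(self, clean_trial):
        trial, _ = clean_trial
        res = synchronize_trial(trial)
        prov = res.provenance
        assert prov["config"]["heel_detector_effective"]["threshold_factor"] == 0.2
        assert prov["config"]["force_detector"]["threshold_factor"] == 0.1
        assert prov["offset_s"] == res.offset_s

    def test_single_leg_uses_higher_factor_and_evaluated_side(self):
        spec = SyntheticTrialSpec(laterality_mode="single_leg", evaluated_side="right",
                                  noise_sd_kin=0.0, noise_sd_force=0.0,
                                  true_offset_s=-0.8, seed=11)
        trial, truth = generate_trial(spec)
        cfg = RunConfig(laterality_mode="single_leg", evaluated_side="right")
        res = TrialSynchronizer(trial, cfg).fit()
        assert res.heel_side == "right"
        assert res.provenance["config"]["heel_detector_effective"]["threshold_factor"] == 0.6
        assert abs(res.offset_s - truth.true_offset_s) <= 1 / 60.0

    def test_resample_option_changes_grid_only(self, clean_trial):
        trial, _ = clean_trial
        cfg = RunConfig(resample_hz=60.0)
        res = TrialSynchronizer(trial, cfg).fit()
        assert res.shifted_vgrf.sampling_rate == 60.0

    def test_idempotence_on_aligned_trial(self, clean_trial):
        trial, _ = clean_trial
        first = synchronize_trial(trial)
        aligned = dataclasses.replace(trial)
        aligned.vgrf = {"plate1": first.shifted_vgrf}
        second = synchronize_trial(aligned)
        assert second.ok
        assert abs(second.offset_s) <= 1 / 60.0

    def test_offset_equivariance_under_force_delay(self, clean_trial):
        trial, _ = clean_trial
        base = synchronize_trial(trial).offset_s
        fs = trial.active_vgrf.sampling_rate
        for k in (100, 777):
            delayed = np.concatenate([np.zeros(k), trial.active_vgrf.values])
            t2 = dataclasses.replace(trial)
            t2.vgrf = {"plate1": SampledSignal(delayed, fs)}
            off = synchronize_trial(t2).offset_s
            assert abs((off - base) - k / fs) <= 1 / fs + 1e-9


class TestBatch:
    def _flat(self, trial):
        t = dataclasses.replace(trial)
        t.heel_left = trial.heel_left.with_values(np.full(trial.heel_left.n_samples, 0.2))
        t.heel_right = t.heel_left
        return t

    def test_all_clean_is_100pct(self):
        bank = generate_bank(10, randomize={"true_offset_s": (-1.5, 0.5)}, seed=5)
        report = batch_synchronize([t for t, _ in bank])
        assert report.success_rate == 100.0
        assert report.n_trials == 10

    def test_failure_accounting_80pct(self):
        bank = generate_bank(8, seed=20)
        trials = [t for t, _ in bank]
        trials += [self._flat(trials[0]), self._flat(trials[1])]
        report = batch_synchronize(trials)
        assert report.success_rate == pytest.approx(80.0)
        assert len(report.failures) == 2
        assert all(f.reason == "degenerate-signal" for f in report.failures)

    def test_uniform_offsets_aggregate_per_task(self):
        spec = SyntheticTrialSpec(noise_sd_kin=0.0, noise_sd_force=0.0,
                                  true_offset_s=-1.38)
        bank = generate_bank(6, base_spec=spec, seed=3)
        report = batch_synchronize([t for t, _ in bank])
        table = report.task_table()
        row = table[table["task"] == "squat_60"].iloc[0]
        assert row["mean_offset_s"] == pytest.approx(-1.38, abs=1 / 60.0)
        assert row["sd_offset_s"] <= 1 / 60.0

    def test_empty_batch_rejected(self):
        with pytest.raises(ParameterError):
            batch_synchronize([])

    def test_summary_mentions_rate(self):
        bank = generate_bank(3, seed=30)
        text = batch_synchronize([t for t, _ in bank]).summary()
        assert "success rate" in text
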