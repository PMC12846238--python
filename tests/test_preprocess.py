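import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heelsync import (
    DegenerateSignalError,
    FilterSpec,
    ParameterError,
    SampledSignal,
    butterworth_lowpass,
    force_preprocess,
    heel_preprocess,
    median_filter,
    minmax_normalize,
)
from heelsync.preprocess import FILTER_PRESETS
from heelsync.synthetic import SyntheticTrialSpec, generate_trial

from .oracles import butterworth_magnitude, naive_median_filter

HEEL_SPEC = FILTER_PRESETS["heel-cascade"]
FORCE_SPEC = FILTER_PRESETS["force-lowpass"]

finite_arrays = st.lists(
    st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
    min_size=2, max_size=50,
)


def sine(f_hz, fs, duration_s=60.0):
    t = np.arange(int(duration_s * fs)) / fs
    return SampledSignal(np.sin(2 * np.pi * f_hz * t), fs)


def fitted_amplitude(sig, f_hz):
    """Steady-state amplitude via quadrature projection on the middle half."""
    t = sig.times()
    mid = slice(sig.n_samples // 4, 3 * sig.n_samples // 4)
    c = 2 * np.mean(sig.values[mid] * np.cos(2 * np.pi * f_hz * t[mid]))
    s = 2 * np.mean(sig.values[mid] * np.sin(2 * np.pi * f_hz * t[mid]))
    return float(np.hypot(c, s))


class TestMinmaxNormalize:
    def test_linear_map(self):
        out = minmax_normalize(SampledSignal([2.0, 4.0, 6.0], 60.0))
        assert np.allclose(out.values, [0.0, 0.5, 1.0])
        assert out.sampling_rate == 60.0 and out.units == ""

    def test_constant_signal_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            minmax_normalize(SampledSignal([5.0, 5.0, 5.0], 60.0))

    @given(finite_arrays)
    def test_idempotent(self, values):
        if max(values) <= min(values):
            return
        once = minmax_normalize(SampledSignal(values, 60.0))
        twice = minmax_normalize(once)
        assert np.array_equal(once.values, twice.values)
        assert once.values.min() == 0.0 and once.values.max() == 1.0


class TestButterworth:
    @pytest.mark.parametrize("spec,fs,c", [
        (HEEL_SPEC, 60.0, 0.7),
        (FORCE_SPEC, 1000.0, 600.0),
    ])
    def test_dc_gain_unity(self, spec, fs, c):
        sig = SampledSignal(np.full(500, c), fs)
        out = butterworth_lowpass(sig, spec)
        assert np.max(np.abs(out.values - c)) <= 1e-9 * abs(c)

    def test_heel_cascade_stopband_matches_closed_form(self):
        out = butterworth_lowpass(sine(10.0, 60.0), HEEL_SPEC)
        amp = fitted_amplitude(out, 10.0)
        # bidirectional squares the response; two passes square it again
        analytic = butterworth_magnitude(10.0, 60.0, 3.0, 4) ** 4
        assert amp < 0.01
        assert abs(amp - analytic) <= 0.01 * analytic

    def test_heel_cascade_passband_matches_closed_form(self):
        out = butterworth_lowpass(sine(0.5, 60.0), HEEL_SPEC)
        amp = fitted_amplitude(out, 0.5)
        analytic = butterworth_magnitude(0.5, 60.0, 3.0, 4) ** 4
        assert amp > 0.99
        assert abs(amp - analytic) <= 0.01 * analytic

    def test_zero_phase_preserves_symmetric_pulse_peak(self):
        n = 601
        t = np.arange(n)
        pulse = np.exp(-0.5 * ((t - 300) / 12.0) ** 2)
        out = butterworth_lowpass(SampledSignal(pulse, 60.0), HEEL_SPEC)
        assert int(np.argmax(out.values)) == 300

    def test_causal_pass_lags_a_pulse(self):
        n = 601
        pulse = np.exp(-0.5 * ((np.arange(n) - 300) / 12.0) ** 2)
        causal = FilterSpec(order=4, cutoff_hz=3.0, bidirectional=False, passes=1)
        out = butterworth_lowpass(SampledSignal(pulse, 60.0), causal)
        assert int(np.argmax(out.values)) > 300

    def test_cutoff_must_be_below_nyquist(self):
        with pytest.raises(ParameterError, match="Nyquist"):
            butterworth_lowpass(sine(1.0, 60.0), FilterSpec(order=4, cutoff_hz=30.0))

    def test_short_signal_error_names_minimum(self):
        sig = SampledSignal(np.zeros(10), 60.0)
        with pytest.raises(ParameterError, match="13"):
            butterworth_lowpass(sig, HEEL_SPEC)

    def test_length_preserved(self):
        sig = sine(2.0, 60.0, duration_s=2.0)
        assert butterworth_lowpass(sig, HEEL_SPEC).n_samples == sig.n_samples


class TestMedianFilter:
    def test_single_outlier_removed(self):
        out = median_filter(SampledSignal([0.0, 0.0, 9.0, 0.0, 0.0], 60.0), 5)
        assert np.array_equal(out.values, np.zeros(5))

    def test_monotone_interior_unchanged(self):
        v = np.arange(20.0)
        out = median_filter(SampledSignal(v, 60.0), 5)
        assert np.array_equal(out.values[2:-2], v[2:-2])

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError, match="odd"):
            median_filter(SampledSignal(np.zeros(10), 60.0), 4)

    @given(finite_arrays, st.sampled_from([3, 5, 7]))
    def test_matches_bruteforce_oracle(self, values, window):
        out = median_filter(SampledSignal(values, 60.0), window)
        assert np.allclose(out.values, naive_median_filter(values, window),
                           rtol=0, atol=1e-12)

    def test_matches_oracle_on_many_random_signals(self, rng):
        for _ in range(200):
            v = rng.normal(size=int(rng.integers(5, 60)))
            out = median_filter(SampledSignal(v, 60.0), 5)
            assert np.array_equal(out.values, naive_median_filter(v, 5))


class TestHeelPreprocess:
    def test_output_nearly_in_unit_range_on_squat_trace(self, clean_trial):
        trial, _ = clean_trial
        out = heel_preprocess(trial.heel_left)
        assert out.values.min() >= -0.05 and out.values.max() <= 1.05
        assert out.units == ""

    def test_constant_trace_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            heel_preprocess(SampledSignal(np.full(100, 0.3), 60.0))

    def test_warns_off_nominal_rate(self):
        v = np.sin(np.linspace(0, 3, 100))
        with pytest.warns(UserWarning, match="60 Hz"):
            heel_preprocess(SampledSignal(v, 100.0))

    def test_outlier_impact_bounded(self, clean_spec):
        # an in-range impulse is smeared by the cascade before the median
        # stage; its residual footprint stays small but nonzero
        trial, _ = generate_trial(clean_spec)
        v = trial.heel_left.values.copy()
        k = 40  # mid-plateau
        v_out = v.copy()
        v_out[k] -= 0.5 * (v.max() - v.min())  # stays inside the range
        ref = heel_preprocess(trial.heel_left.with_values(v))
        per = heel_preprocess(trial.heel_left.with_values(v_out))
        assert np.max(np.abs(per.values - ref.values)) < 0.05


class TestForcePreprocess:
    def test_dc_passthrough_600n(self):
        out = force_preprocess(SampledSignal(np.full(2000, 600.0), 1000.0, units="N"))
        assert np.max(np.abs(out.values - 600.0)) <= 1e-9 * 600.0
        assert out.units == "N"

    def test_stopband_and_passband_match_closed_form(self):
        out_hi = force_preprocess(sine(200.0, 1000.0, duration_s=4.0))
        amp_hi = fitted_amplitude(out_hi, 200.0)
        analytic_hi = butterworth_magnitude(200.0, 1000.0, 30.0, 4) ** 2
        assert amp_hi < 0.01
        assert abs(amp_hi - analytic_hi) <= 0.02 * analytic_hi + 1e-12

        out_lo = force_preprocess(sine(1.0, 1000.0, duration_s=8.0))
        amp_lo = fitted_amplitude(out_lo, 1.0)
        assert amp_lo > 0.99
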