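"""Independent reference implementations used as test oracles.

These are deliberately plain, literal loop translations of the detection
rules and metric formulas, kept free of the package's vectorized code
paths so the tests are a genuine dual-route check.
"""

from __future__ import annotations

import math


def naive_heel_contact(values, factor: float, stabilization: int):
    """Literal heel-contact rule: threshold from the post-stabilization
    range, first ascending crossing after a local minimum.

    Returns (index, threshold) or (None, threshold) when no event exists;
    returns (None, None) for a degenerate baseline.
    """
    v = list(values)
    vmin = min(v)
    baseline = max(v[stabilization:]) - vmin
    if baseline <= 0:
        return None, None
    thr = baseline * factor + vmin

    minima = []
    last_sign = 0
    for i in range(1, len(v)):
        d = v[i] - v[i - 1]
        if d > 0 and last_sign < 0:
            minima.append(i - 1)
        if d != 0:
            last_sign = 1 if d > 0 else -1
    if not minima:
        return None, thr
    for i in range(minima[0] + 1, len(v)):
        if v[i] > v[i - 1] and v[i] > thr and v[i - 1] <= thr:
            return i, thr
    return None, thr


def naive_force_onset(values, baseline_samples: int, factor: float,
                      sd_scope: str = "signal"):
    """Literal force-onset rule: resting-mean baseline plus SD-scaled margin,
    first strictly-exceeding sample at or beyond the baseline window."""
    v = list(values)
    baseline = sum(v[:baseline_samples]) / baseline_samples
    scope = v if sd_scope == "signal" else v[:baseline_samples]
    mean = sum(scope) / len(scope)
    sd = math.sqrt(sum((x - mean) ** 2 for x in scope) / len(scope))
    thr = baseline + sd * factor
    for i in range(baseline_samples, len(v)):
        if v[i] > thr:
            return i, thr
    return None, thr


def naive_median_filter(values, window: int):
    """Brute-force centered running median with shrinking edge windows."""
    import statistics

    v = list(values)
    k = window // 2
    out = []
    for i in range(len(v)):
        chunk = v[max(0, i - k): i + k + 1]
        out.append(statistics.median(chunk))
    return out


def naive_curve_metrics(a, b):
    """Two-pass loop Pearson r, RMSE and MAE."""
    n = len(a)
    assert len(b) == n
    mean_a = sum(a) / n
    mean_b = sum(b) / n
    num = sum((a[i] - mean_a) * (b[i] - mean_b) for i in range(n))
    den_a = sum((a[i] - mean_a) ** 2 for i in range(n))
    den_b = sum((b[i] - mean_b) ** 2 for i in range(n))
    denom = math.sqrt(den_a * den_b)
    r = num / denom if denom > 0 else None
    rmse = math.sqrt(sum((a[i] - b[i]) ** 2 for i in range(n)) / n)
    mae = sum(abs(a[i] - b[i]) for i in range(n)) / n
    return r, rmse, mae


def butterworth_magnitude(f_hz: float, fs_hz: float, cutoff_hz: float, order: int) -> float:
    """Closed-form magnitude response of a bilinear-designed digital
    Butterworth low-pass at frequency ``f_hz`` (single forward pass).

    The bilinear transform maps the analog prototype through
    ``ratio = tan(pi f / fs) / tan(pi fc / fs)``; the squared magnitude is
    ``1 / (1 + ratio^(2 order))``.
    """
    ratio = math.tan(math.pi * f_hz / fs_hz) / math.tan(math.pi * cutoff_hz / fs_hz)
    return (1.0 / (1.0 + ratio ** (2 * order))) ** 0.5
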