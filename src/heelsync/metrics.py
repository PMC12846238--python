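"""Curve-agreement metrics for validating a synchronization.

Pairs of time-normalized vGRF curves (e.g. a hardware-synchronized
reference vs the event-synchronized stream) are each amplitude-normalized
to [0, 1] and compared point-by-point with Pearson r, RMSE and MAE, then
aggregated over repetitions as mean +/- sample SD together with the share
of repetitions exceeding r = 0.80.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import DegenerateSignalError, ParameterError

__all__ = [
    "AgreementMetrics",
    "amplitude_normalize",
    "compare_curves",
    "repetition_report",
]


@dataclass(frozen=True)
class AgreementMetrics:
    """Pearson r, RMSE and MAE for one pair of normalized curves.

    ``r`` is NaN (with ``r_defined`` False) when either curve has zero
    variance; RMSE and MAE are always defined.
    """

    r: float
    rmse: float
    mae: float
    n_points: int
    r_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "r": None if not self.r_defined else float(self.r),
            "rmse": float(self.rmse),
            "mae": float(self.mae),
            "n_points": int(self.n_points),
            "r_defined": bool(self.r_defined),
        }


def amplitude_normalize(curve: np.ndarray) -> np.ndarray:
    """Map a curve linearly onto [0, 1] (its own min to 0, max to 1)."""
    c = np.asarray(curve, dtype=float)
    lo, hi = float(c.min()), float(c.max())
    if hi <= lo:
        raise DegenerateSignalError("cannot amplitude-normalize a constant curve")
    return (c - lo) / (hi - lo)


def compare_curves(a: np.ndarray, b: np.ndarray) -> AgreementMetrics:
    """Point-by-point agreement between two equal-length curves.

    r is the sample Pearson correlation; RMSE and MAE are computed on the
    curves as given (dimensionless when the curves are 0-1 normalized).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError(f"curves must be equal-length 1-D, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ParameterError("curves must contain at least 2 points")
    diff = a - b
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt(np.sum(da**2) * np.sum(db**2))
    if denom == 0.0:
        return AgreementMetrics(r=float("nan"), rmse=rmse, mae=mae,
                                n_points=a.size, r_defined=False)
    r = float(np.sum(da * db) / denom)
    return AgreementMetrics(r=r, rmse=rmse, mae=mae, n_points=a.size)


def repetition_report(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    *,
    r_threshold: float = 0.80,
    normalize: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-repetition metrics plus a mean +/- SD summary.

    Degenerate (zero-variance) pairs are excluded from the r aggregation
    but counted and reported rather than hidden.  SDs use the sample
    (n-1) convention of "+/- SD over repetitions".

    Returns
    -------
    (table, summary)
        ``table`` has one row per repetition (columns: repetition, r, rmse,
        mae, r_defined); ``summary`` carries column means/SDs, the share of
        repetitions with r above ``r_threshold``, and the degenerate count.
    """
    if not pairs:
        raise ParameterError("repetition_report requires at least one pair")
    rows = []
    for i, (a, b) in enumerate(pairs):
        if normalize:
            a = amplitude_normalize(a)
            b = amplitude_normalize(b)
        m = compare_curves(a, b)
        rows.append({
            "repetition": i,
            "r": m.r if m.r_defined else np.nan,
            "rmse": m.rmse,
            "mae": m.mae,
            "r_defined": m.r_defined,
        })
    table = pd.DataFrame(rows)
    defined = table[table["r_defined"]]

    def _mean_sd(col: pd.Series) -> tuple[float | None, float | None]:
        if col.empty:
            return None, None
        mean = float(col.mean())
        sd = float(col.std(ddof=1)) if col.size > 1 else None
        return mean, sd

    r_mean, r_sd = _mean_sd(defined["r"])
    rmse_mean, rmse_sd = _mean_sd(table["rmse"])
    mae_mean, mae_sd = _mean_sd(table["mae"])
    summary = {
        "n_pairs": len(pairs),
        "n_degenerate": int((~table["r_defined"]).sum()),
        "r_mean": r_mean,
        "r_sd": r_sd,
        "rmse_mean": rmse_mean,
        "rmse_sd": rmse_sd,
        "mae_mean": mae_mean,
        "mae_sd": mae_sd,
        "pct_r_above_threshold": (
            None if defined.empty
            else float(100.0 * (defined["r"] > r_threshold).mean())
        ),
        "r_threshold": r_threshold,
    }
    return table, summary
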