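"""Basic diagnostic plots for synchronized trials."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_sync"]


def plot_sync(result, ax=None):
    """Plot the preprocessed heel and min-max scaled shifted force on the
    common (kinematic) clock, with the aligned event instant marked.

    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))

    f = result.shifted_vgrf
    fv = f.values
    rng = fv.max() - fv.min()
    fnorm = (fv - fv.min()) / rng if rng > 0 else np.zeros_like(fv)
    ax.plot(f.times(), fnorm, label="vGRF (shifted, scaled 0-1)", color="tab:blue")

    start, end = result.cycle_span_s
    pct = np.linspace(start, end, len(result.cycle_curves["vgrf"]))
    for key, curve in result.cycle_curves.items():
        if key.startswith("heel_"):
            ax.plot(pct, curve, label=f"{key} (preprocessed)", alpha=0.8)

    ax.axvline(result.heel_event.time_s, color="red", linestyle="--",
               label=f"aligned contact ({result.heel_event.time_s:.2f} s)")
    ax.set_xlabel("time (s, kinematic clock)")
    ax.set_ylabel("normalized magnitude")
    ax.set_title(f"offset = {result.offset_s:+.3f} s")
    ax.legend(loc="best", fontsize=8)
    return ax
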