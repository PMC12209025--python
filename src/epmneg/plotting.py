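"""Effect-ribbon plots with the ROPE band marked."""

from __future__ import annotations

import numpy as np

from .effects import DecisionSeries

__all__ = ["plot_decision_series"]


def plot_decision_series(dec: DecisionSeries, ax=None, rope_percent: float = 18.0):
    """Median effect over time with its HDI ribbon and the ROPE band.

    Timepoints where the effect is not practically equivalent to zero are
    drawn in red, undecided stretches in grey, equivalent ones in blue.
    The dashed lines mark the +/- ``rope_percent`` equivalence band on the
    percent-NEG scale.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(dec.times, dec.hdi_low, dec.hdi_high, alpha=0.25, color="0.6", lw=0)
    colours = {"equivalent": "tab:blue", "undecided": "0.4", "not-equivalent": "tab:red"}
    for state, colour in colours.items():
        masked = np.where(dec.decision == state, dec.median, np.nan)
        ax.plot(dec.times, masked, color=colour, lw=2, label=state)
    for bound in (-rope_percent, rope_percent):
        ax.axhline(bound, ls="--", color="k", lw=0.8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("NEG difference (%)")
    ax.set_title(dec.contrast)
    ax.legend(frameon=False, fontsize=8)
    return ax
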