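"""Diagnostic figures: cumulative uEE curve and Morlet spectrogram."""

from __future__ import annotations

import numpy as np

from .core import EventTrain, IctalDischarge, TimeSeries
from .lfp import cumulative_curve, wavelet_spectrogram


def plot_cumulative(events: EventTrain, discharges: list[IctalDischarge] | None = None,
                    bin: float = 1.0, ax=None):
    """Cumulative event count with ictal discharge spans shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid, counts = cumulative_curve(events, bin)
    ax.step(grid, counts, where="post")
    for d in discharges or []:
        ax.axvspan(d.start, d.end, alpha=0.2, color="tab:red")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cumulative uEE count")
    return ax


def plot_spectrogram(sig: TimeSeries, freqs=None, ax=None):
    """Morlet-wavelet power, log-scaled frequency axis."""
    import matplotlib.pyplot as plt

    if freqs is None:
        freqs = np.geomspace(1.0, sig.rate / 2 * 0.8, 60)
    freqs = np.asarray(freqs, dtype=float)
    power = wavelet_spectrogram(sig, freqs)
    if ax is None:
        _, ax = plt.subplots()
    ax.pcolormesh(sig.times, freqs, power, shading="auto")
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return ax
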