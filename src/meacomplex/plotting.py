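"""Minimal plotting helpers (matplotlib optional extra)."""

from __future__ import annotations

import numpy as np


def plot_raster(spikes, ax=None, **kwargs):
    """Raster plot of a SpikeTrainSet (one row per electrode)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for eid in range(spikes.n_electrodes):
        t = spikes.train(eid)
        ax.plot(t, np.full(t.size, eid), "|", markersize=2, color="k",
                **kwargs)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("electrode")
    return ax


def plot_significant_sources(ss, ax=None):
    """Binary activation matrix of a SignificantSourceMatrix."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(ss.matrix, aspect="auto", origin="lower", cmap="Greys",
              interpolation="none")
    ax.set_xlabel("post-stimulus bin")
    ax.set_ylabel("channel (activity-sorted)")
    return ax


def plot_psth(psth, ax=None):
    """Channel-mean PSTH profile in spikes/s."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    t = np.arange(psth.rates.shape[1]) * psth.bin_size * 1e3
    ax.plot(t, psth.rates.mean(axis=0))
    ax.set_xlabel("time after stimulus (ms)")
    ax.set_ylabel("rate (spikes/s)")
    return ax
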