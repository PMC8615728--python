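"""LFP extraction and spectral quantification.

The raw 10 kHz signal is band-passed 1-300 Hz (zero-phase Butterworth) and
decimated to 1 kHz to obtain the LFP.  Spontaneous spectra use Welch's
method with 5 s windows and 50% overlap; band powers are trapezoidal
integrals of the one-sided density over half-open bands:

    delta 1-4 Hz, theta 4-11 Hz, beta 11-30 Hz.

Evoked spectra average the stimulus-locked response (100 ms before to
900 ms after each pulse, first 10 ms after the pulse blanked and linearly
interpolated) over trials on the 20 channels with the highest spontaneous
basal firing rate, then apply Welch with 200 ms windows up to 100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple
import warnings

import numpy as np
from scipy import signal

from .core import AnalogSignalSet, StimulationRecord

__all__ = [
    "BANDS", "BandPowerResult", "extract_lfp", "welch_psd",
    "band_power", "band_powers", "evoked_psd",
]

#: Half-open frequency bands (Hz) from the operative methods definition.
BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 11.0),
    "beta": (11.0, 30.0),
}

#: Alternative band edges quoted in some figure material, kept as a preset.
BANDS_FIGURE: Dict[str, Tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (5.0, 9.0),
    "beta": (10.0, 30.0),
}


@dataclass
class BandPowerResult:
    """Per-channel and channel-averaged band powers (uV^2).

    ``per_channel`` maps band name to an array over channels; ``mean`` maps
    band name to the channel average.  ``normalized`` holds the mean powers
    divided by a reference (typically the basal-phase mean), when one was
    supplied.
    """

    per_channel: Dict[str, np.ndarray]
    mean: Dict[str, float]
    normalized: Optional[Dict[str, float]] = None


def extract_lfp(raw: AnalogSignalSet, band: Tuple[float, float] = (1.0, 300.0),
                order: int = 4) -> AnalogSignalSet:
    """Band-pass the raw signal and decimate x10 to the 1 kHz LFP.

    Zero-phase (forward-backward) Butterworth filtering preserves evoked
    latencies; decimation applies its own anti-alias filter.
    """
    if raw.kind != "raw":
        raise ValueError("extract_lfp expects a raw-kind signal")
    if raw.sampling_rate < 2 * band[1]:
        raise ValueError("sampling rate below Nyquist for the upper cutoff")
    sos = signal.butter(order, band, btype="bandpass", fs=raw.sampling_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, raw.samples, axis=1)
    decimated = signal.decimate(filtered, 10, axis=1, zero_phase=True)
    return AnalogSignalSet(decimated, raw.sampling_rate / 10, raw.t_start,
                           kind="lfp")


def welch_psd(lfp: AnalogSignalSet, window_s: float = 5.0,
              overlap: float = 0.5) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density per channel (uV^2/Hz).

    Returns ``(freqs, psd)`` with ``psd`` of shape (n_channels, n_freqs).
    """
    nperseg = int(round(window_s * lfp.sampling_rate))
    if nperseg > lfp.n_samples:
        raise ValueError("window longer than the signal")
    noverlap = int(round(overlap * nperseg))
    freqs, psd = signal.welch(lfp.samples, fs=lfp.sampling_rate, axis=1,
                              nperseg=nperseg, noverlap=noverlap)
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray,
               band: Tuple[float, float]) -> np.ndarray:
    """Trapezoidal integral of the density over the half-open band [lo, hi).

    Shared band edges (4 Hz, 11 Hz) are attributed to the lower band only,
    so disjoint bands add up to the power of their union.
    """
    lo, hi = band
    if hi <= lo:
        raise ValueError("inverted frequency band")
    if lo < freqs[0] - 1e-9 or hi > freqs[-1] + 1e-9:
        raise ValueError("band outside the PSD frequency range")
    psd = np.atleast_2d(psd)
    # integrate on a grid clipped to [lo, hi); interpolate at the edges
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.vstack([np.interp(grid, freqs, p) for p in psd])
    return np.trapezoid(vals, grid, axis=1)


def band_powers(lfp: AnalogSignalSet,
                bands: Mapping[str, Tuple[float, float]] = BANDS,
                window_s: float = 5.0, overlap: float = 0.5,
                reference_mean: Optional[Mapping[str, float]] = None
                ) -> BandPowerResult:
    """Welch PSD followed by band integration, averaged over channels."""
    freqs, psd = welch_psd(lfp, window_s=window_s, overlap=overlap)
    per_channel = {name: band_power(freqs, psd, b) for name, b in bands.items()}
    mean = {name: float(v.mean()) for name, v in per_channel.items()}
    normalized = None
    if reference_mean is not None:
        normalized = {name: mean[name] / reference_mean[name]
                      for name in mean if reference_mean.get(name, 0) > 0}
    return BandPowerResult(per_channel=per_channel, mean=mean,
                           normalized=normalized)


def evoked_psd(lfp: AnalogSignalSet, stim: StimulationRecord,
               pre: float = 0.100, post: float = 0.900, blank: float = 0.010,
               window_s: float = 0.200, overlap: float = 0.5,
               max_freq: float = 100.0,
               channels: Optional[Sequence[int]] = None
               ) -> Tuple[np.ndarray, np.ndarray]:
    """PSD of the trial-mean evoked LFP response.

    Trial windows run from ``pre`` before to ``post`` after each stimulus;
    the ``blank`` interval after the pulse is linearly interpolated to
    remove the electrical artifact without injecting a broadband step.
    ``channels`` should be the top-20 channels by basal spontaneous firing
    rate; with fewer than 20 available all are used with a warning.

    Returns ``(freqs, psd)`` limited to ``max_freq``, one PSD row per
    selected channel.
    """
    if lfp.kind != "lfp":
        raise ValueError("evoked_psd expects an lfp-kind signal")
    fs = lfp.sampling_rate
    if channels is None:
        channels = list(range(lfp.n_channels))
    channels = list(channels)
    if len(channels) < 20:
        warnings.warn(f"only {len(channels)} channels available for the "
                      "evoked PSD (20 requested)", stacklevel=2)
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    n_win = n_pre + n_post
    means = np.zeros((len(channels), n_win))
    for k, onset in enumerate(stim.onsets):
        i0 = int(round((onset - lfp.t_start) * fs)) - n_pre
        if i0 < 0 or i0 + n_win > lfp.n_samples:
            raise ValueError("trial window extends beyond the signal")
        seg = lfp.samples[np.ix_(channels, range(i0, i0 + n_win))].copy()
        b0, b1 = n_pre, min(n_pre + int(round(blank * fs)), n_win - 1)
        if b1 > b0:
            # linear interpolation across the artifact interval
            left = seg[:, b0 - 1] if b0 > 0 else seg[:, b1]
            right = seg[:, b1]
            ramp = np.linspace(0.0, 1.0, b1 - b0 + 2)[1:-1]
            seg[:, b0:b1] = left[:, None] + (right - left)[:, None] * ramp
        means += seg
    means /= stim.n_trials
    nperseg = int(round(window_s * fs))
    freqs, psd = signal.welch(means, fs=fs, axis=1, nperseg=nperseg,
                              noverlap=int(round(overlap * nperseg)))
    keep = freqs <= max_freq
    return freqs[keep], psd[:, keep]
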