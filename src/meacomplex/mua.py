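"""Multi-unit activity metrics: spike/burst detection, firing statistics,
and pairwise synchrony.

The spike detector thresholds the high-pass (> 300 Hz) signal at
``k`` times the robust noise SD (median(|x|)/0.6745) with a 1 ms dead
time.  Bursts are groups of at least ``min_spikes`` spikes with
inter-spike intervals no larger than ``max_isi`` (defaults 5 spikes /
100 ms, the common MEA convention; the detector is fully configurable).

Synchrony is quantified two ways, and any regime contrast should agree in
sign between them:

* the spike time tiling coefficient (STTC), a firing-rate-robust pairwise
  correlation in [-1, 1];
* the parameter-free SPIKE-synchronization measure in [0, 1], a
  multivariate coincidence rate with an adaptive coincidence window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .core import AnalogSignalSet, SpikeTrainSet, bin_spike_counts

__all__ = [
    "Burst", "BurstSet", "NetworkMetrics",
    "detect_spikes", "detect_bursts", "firing_stats", "burstiness_index",
    "sttc", "sttc_matrix", "mean_sttc", "spike_synchronization",
    "compute_network_metrics",
]


@dataclass(frozen=True)
class Burst:
    start: float
    end: float
    n_spikes: int


@dataclass
class BurstSet:
    """Per-electrode burst lists plus the detector parameters used."""

    bursts: Dict[int, List[Burst]]
    max_isi: float
    min_spikes: int

    def n_bursts(self) -> int:
        return sum(len(b) for b in self.bursts.values())


@dataclass
class NetworkMetrics:
    """Network-level MUA summary for one recording phase.

    mfr_per_electrode : spikes/s per electrode (all layout slots)
    mfr : mean over electrodes
    ibr : percentage of spikes outside any burst, in [0, 100]
    bi : burstiness index in [0, 1] (NaN when there are no spikes)
    cv_mfr : SD/mean of the per-electrode MFRs
    sttc_mean : mean pairwise STTC over electrode pairs with spikes
    spike_sync : multivariate SPIKE-synchronization in [0, 1]
    """

    mfr_per_electrode: np.ndarray
    mfr: float
    ibr: float
    bi: float
    cv_mfr: float
    sttc_mean: float
    spike_sync: float


def detect_spikes(raw: AnalogSignalSet, k: float = 7.0,
                  highpass_hz: float = 300.0, dead_time: float = 0.001,
                  order: int = 4) -> SpikeTrainSet:
    """Threshold-based spike detection on the high-pass filtered signal.

    The threshold is ``k`` times the robust noise SD estimated per channel
    as median(|x|)/0.6745, with a floor of a tenth of the absolute signal
    maximum; peaks of |x| above it, separated by at least ``dead_time``,
    are retained.  A flat channel yields an empty train.
    """
    if raw.kind != "raw":
        raise ValueError("detect_spikes expects a raw-kind signal")
    fs = raw.sampling_rate
    sos = sps.butter(order, highpass_hz, btype="highpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, raw.samples, axis=1)
    distance = max(int(round(dead_time * fs)), 1)
    trains: Dict[int, np.ndarray] = {}
    for ch in range(raw.n_channels):
        x = np.abs(filtered[ch])
        sigma = np.median(x) / 0.6745
        # the floor keeps near-noiseless traces (sigma ~ 0, e.g. clean
        # synthetic fixtures) from thresholding at filter-ringing level
        thr = max(k * sigma, 0.1 * x.max())
        if thr <= 0:
            continue
        peaks, _ = sps.find_peaks(x, height=thr, distance=distance)
        if peaks.size:
            trains[ch] = raw.t_start + peaks / fs
    return SpikeTrainSet(trains, raw.t_start, raw.t_start + raw.duration,
                         layout=_layout_for(raw.n_channels))


def _layout_for(n: int):
    from .core import ElectrodeLayout
    return ElectrodeLayout(n_electrodes=n)


def detect_bursts(spikes: SpikeTrainSet, max_isi: float = 0.100,
                  min_spikes: int = 5) -> BurstSet:
    """ISI-threshold burst detection per electrode.

    A burst is a maximal run of consecutive spikes whose inter-spike
    intervals are all <= ``max_isi``, containing at least ``min_spikes``
    spikes.
    """
    out: Dict[int, List[Burst]] = {}
    for eid, t in spikes.trains.items():
        bursts: List[Burst] = []
        if t.size >= min_spikes:
            gaps = np.where(np.diff(t) > max_isi)[0]
            starts = np.concatenate(([0], gaps + 1))
            ends = np.concatenate((gaps, [t.size - 1]))
            for s, e in zip(starts, ends):
                n = e - s + 1
                if n >= min_spikes:
                    bursts.append(Burst(start=t[s], end=t[e], n_spikes=n))
        out[eid] = bursts
    return BurstSet(bursts=out, max_isi=max_isi, min_spikes=min_spikes)


def firing_stats(spikes: SpikeTrainSet, bursts: Optional[BurstSet] = None
                 ) -> Tuple[np.ndarray, float, float, float]:
    """Per-electrode MFR, mean MFR, IBR (%), and CV(MFR).

    IBR is the percentage of spikes falling outside every detected burst;
    with no burst set supplied, bursts are detected with the defaults.
    CV(MFR) is the SD over electrodes divided by the mean (0 when the mean
    is 0).
    """
    if spikes.duration <= 0:
        raise ValueError("zero-duration phase")
    if bursts is None:
        bursts = detect_bursts(spikes)
    n = spikes.n_electrodes
    mfr = np.zeros(n)
    total = 0
    in_burst = 0
    for eid in range(n):
        t = spikes.train(eid)
        mfr[eid] = t.size / spikes.duration
        total += t.size
        for b in bursts.bursts.get(eid, []):
            in_burst += int(np.sum((t >= b.start) & (t <= b.end)))
    ibr = float("nan") if total == 0 else 100.0 * (total - in_burst) / total
    mean = float(mfr.mean())
    cv = 0.0 if mean == 0 or n < 2 else float(mfr.std(ddof=1) / mean)
    return mfr, mean, ibr, cv


def burstiness_index(spikes: SpikeTrainSet, bin_size: float = 1.0,
                     top_fraction: float = 0.15) -> float:
    """Burstiness index in [0, 1]: 0 = no bursts, 1 = burst-dominated.

    Whole-network spike counts are binned (default 1 s); ``f15`` is the
    fraction of all spikes inside the fullest ``top_fraction`` of bins and
    BI = (f15 - top_fraction)/(1 - top_fraction), clipped to [0, 1].
    Returns NaN when there are no spikes.
    """
    counts = bin_spike_counts(spikes, bin_size).sum(axis=0)
    total = counts.sum()
    if total == 0:
        return float("nan")
    n_top = max(1, int(round(top_fraction * counts.size)))
    f_top = np.sort(counts)[::-1][:n_top].sum() / total
    bi = (f_top - top_fraction) / (1.0 - top_fraction)
    return float(np.clip(bi, 0.0, 1.0))


def _tiled_fraction(t: np.ndarray, dt: float, t0: float, t1: float) -> float:
    """Fraction of [t0, t1] covered by the union of +-dt windows."""
    starts = np.clip(t - dt, t0, t1)
    ends = np.clip(t + dt, t0, t1)
    total = 0.0
    prev_end = t0
    for s, e in zip(starts, ends):
        s = max(s, prev_end)
        if e > s:
            total += e - s
            prev_end = e
        else:
            prev_end = max(prev_end, e)
    return total / (t1 - t0)


def _prop_within(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Fraction of spikes in ``a`` within +-dt of any spike in ``b``."""
    idx = np.searchsorted(b, a)
    left = np.where(idx > 0, np.abs(a - b[np.maximum(idx - 1, 0)]), np.inf)
    right = np.where(idx < b.size, np.abs(b[np.minimum(idx, b.size - 1)] - a),
                     np.inf)
    return float(np.mean(np.minimum(left, right) <= dt))


def sttc(train_a: np.ndarray, train_b: np.ndarray, dt: float = 0.010,
         t_start: float = 0.0, t_stop: float = None) -> float:
    """Spike time tiling coefficient of two trains over [t_start, t_stop].

    STTC = 1/2 [ (P_A - T_B)/(1 - P_A T_B) + (P_B - T_A)/(1 - P_B T_A) ]

    where P_A is the proportion of spikes of A within +-dt of a spike of B
    and T_B the fraction of the recording tiled by +-dt windows around B's
    spikes (edges clipped to the recording).  Symmetric in its arguments;
    returns NaN when either train is empty.
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if a.size == 0 or b.size == 0:
        return float("nan")
    if t_stop is None:
        raise ValueError("t_stop is required")
    ta = _tiled_fraction(a, dt, t_start, t_stop)
    tb = _tiled_fraction(b, dt, t_start, t_stop)
    pa = _prop_within(a, b, dt)
    pb = _prop_within(b, a, dt)
    if pa * tb == 1.0:
        if pb * ta == 1.0:
            return 1.0
        return 0.5 + 0.5 * (pb - ta) / (1.0 - pb * ta)
    if pb * ta == 1.0:
        return 0.5 + 0.5 * (pa - tb) / (1.0 - pa * tb)
    return 0.5 * ((pa - tb) / (1.0 - pa * tb) + (pb - ta) / (1.0 - pb * ta))


def sttc_matrix(spikes: SpikeTrainSet, dt: float = 0.010) -> np.ndarray:
    """Symmetric matrix of pairwise STTCs (NaN for empty-train pairs)."""
    n = spikes.n_electrodes
    out = np.full((n, n), np.nan)
    trains = [spikes.train(e) for e in range(n)]
    for i in range(n):
        if trains[i].size:
            out[i, i] = 1.0
        for j in range(i + 1, n):
            v = sttc(trains[i], trains[j], dt, spikes.t_start, spikes.t_stop)
            out[i, j] = out[j, i] = v
    return out


def mean_sttc(spikes: SpikeTrainSet, dt: float = 0.010) -> float:
    """Mean pairwise STTC; empty-train pairs are excluded, not zero-filled."""
    m = sttc_matrix(spikes, dt)
    iu = np.triu_indices_from(m, k=1)
    vals = m[iu]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def _adjacent_isis(t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Left/right inter-spike interval at each spike (inf at the edges)."""
    isi = np.diff(t)
    left = np.concatenate(([np.inf], isi))
    right = np.concatenate((isi, [np.inf]))
    return left, right


def _pair_coincidences(a: np.ndarray, b: np.ndarray
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-spike coincidence indicators of trains a and b (SPIKE-sync).

    A spike of ``a`` is coincident when its nearest spike in ``b`` lies
    closer than the adaptive window tau = 1/2 min of the four inter-spike
    intervals surrounding the two spikes.
    """
    la, ra = _adjacent_isis(a)
    lb, rb = _adjacent_isis(b)

    def one_way(x, y, lx, rx, ly, ry):
        idx = np.searchsorted(y, x)
        lo = np.maximum(idx - 1, 0)
        hi = np.minimum(idx, y.size - 1)
        d_lo = np.abs(x - y[lo])
        d_hi = np.abs(y[hi] - x)
        nearest = np.where(d_lo <= d_hi, lo, hi)
        d = np.minimum(d_lo, d_hi)
        tau = 0.5 * np.minimum.reduce(
            [lx, rx, ly[nearest], ry[nearest]])
        return (d < tau).astype(float)

    ca = one_way(a, b, la, ra, lb, rb)
    cb = one_way(b, a, lb, rb, la, ra)
    return ca, cb


def spike_synchronization(spikes: SpikeTrainSet,
                          electrodes: Optional[Sequence[int]] = None) -> float:
    """Multivariate SPIKE-synchronization in [0, 1].

    For every spike the coincidence indicator is averaged over all partner
    trains, then over all spikes of all (nonempty) trains.  Returns NaN
    with fewer than two nonempty trains.
    """
    if electrodes is None:
        electrodes = range(spikes.n_electrodes)
    trains = [spikes.train(e) for e in electrodes]
    trains = [t for t in trains if t.size > 0]
    m = len(trains)
    if m < 2:
        return float("nan")
    sums = [np.zeros(t.size) for t in trains]
    for i in range(m):
        for j in range(i + 1, m):
            ci, cj = _pair_coincidences(trains[i], trains[j])
            sums[i] += ci
            sums[j] += cj
    total = sum(s.sum() for s in sums)
    n_spikes = sum(t.size for t in trains)
    return float(total / (n_spikes * (m - 1)))


def compute_network_metrics(spikes: SpikeTrainSet, sttc_dt: float = 0.010,
                            bi_bin: float = 1.0,
                            burst_max_isi: float = 0.100,
                            burst_min_spikes: int = 5) -> NetworkMetrics:
    """All spontaneous-activity MUA metrics of one phase in one call."""
    bursts = detect_bursts(spikes, max_isi=burst_max_isi,
                           min_spikes=burst_min_spikes)
    mfr_pe, mfr, ibr, cv = firing_stats(spikes, bursts)
    return NetworkMetrics(
        mfr_per_electrode=mfr_pe, mfr=mfr, ibr=ibr,
        bi=burstiness_index(spikes, bin_size=bi_bin),
        cv_mfr=cv,
        sttc_mean=mean_sttc(spikes, dt=sttc_dt),
        spike_sync=spike_synchronization(spikes),
    )
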