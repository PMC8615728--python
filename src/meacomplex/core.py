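"""Core domain types and binning primitives for MEA culture recordings.

Conventions used throughout the package:

* Time is in seconds, as floating point, 0-based from the start of the
  recording.  All bins are half-open ``[t, t + dt)`` so that a partition of
  an interval into bins never double-counts a spike.
* Electrode ids are 0-based contiguous integers.  The standard layout is an
  8 x 8 grid with the four corners missing, giving 60 analysis slots (59
  physical recording electrodes plus one reference slot that may stay empty).
* Analog signals are in microvolts; raw acquisitions are sampled at 10 kHz,
  local field potentials (LFPs) at 1 kHz after decimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "SpikeTrainSet",
    "AnalogSignalSet",
    "StimulationRecord",
    "TrialTensor",
    "SessionPhases",
    "bin_spike_counts",
    "align_trials",
]

GRID_SIDE = 8
RAW_RATE_HZ = 10_000.0
LFP_RATE_HZ = 1_000.0


def _default_grid_positions(n: int) -> Dict[int, Tuple[int, int]]:
    """Row-major 8 x 8 grid positions excluding the four corners."""
    corners = {(0, 0), (0, GRID_SIDE - 1), (GRID_SIDE - 1, 0),
               (GRID_SIDE - 1, GRID_SIDE - 1)}
    positions = [(r, c) for r in range(GRID_SIDE) for c in range(GRID_SIDE)
                 if (r, c) not in corners]
    if n > len(positions):
        raise ValueError(f"at most {len(positions)} electrodes fit the grid")
    return {i: positions[i] for i in range(n)}


@dataclass(frozen=True)
class ElectrodeLayout:
    """Planar MEA electrode geometry.

    Parameters
    ----------
    n_electrodes : int
        Number of analysis slots (default 60: an 8 x 8 grid minus corners;
        59 of these carry physical recording electrodes, one is the
        reference).
    grid_positions : mapping of electrode id to (row, col)
        Position of each electrode on the grid.  Defaults to row-major
        enumeration of the corner-free 8 x 8 grid.
    inter_electrode_distance_um : float
        Center-to-center electrode pitch in micrometers.
    """

    n_electrodes: int = 60
    grid_positions: Mapping[int, Tuple[int, int]] = None  # type: ignore[assignment]
    inter_electrode_distance_um: float = 200.0

    def __post_init__(self) -> None:
        if self.grid_positions is None:
            object.__setattr__(self, "grid_positions",
                               _default_grid_positions(self.n_electrodes))
        ids = sorted(self.grid_positions)
        if ids != list(range(self.n_electrodes)):
            raise ValueError("electrode ids must be 0-based and contiguous")
        pos = list(self.grid_positions.values())
        if len(set(pos)) != len(pos):
            raise ValueError("duplicate grid positions")
        corners = {(0, 0), (0, GRID_SIDE - 1), (GRID_SIDE - 1, 0),
                   (GRID_SIDE - 1, GRID_SIDE - 1)}
        if corners & set(pos):
            raise ValueError("corner positions are not recording sites")


@dataclass
class SpikeTrainSet:
    """Per-electrode spike timestamps over a common recording window.

    ``trains`` maps electrode id to a sorted, strictly increasing float array
    of spike times in seconds; electrodes with no entry are silent.
    """

    trains: Dict[int, np.ndarray]
    t_start: float
    t_stop: float
    layout: ElectrodeLayout = field(default_factory=ElectrodeLayout)

    def __post_init__(self) -> None:
        if not self.t_stop > self.t_start:
            raise ValueError("t_stop must exceed t_start")
        clean: Dict[int, np.ndarray] = {}
        for eid, times in self.trains.items():
            eid = int(eid)
            if not 0 <= eid < self.layout.n_electrodes:
                raise ValueError(f"electrode id {eid} outside layout")
            t = np.asarray(times, dtype=float)
            if t.ndim != 1:
                raise ValueError("spike trains must be 1-D")
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"train {eid} not strictly increasing")
            if t.size and (t[0] < self.t_start or t[-1] >= self.t_stop):
                raise ValueError(
                    f"train {eid} has spikes outside [t_start, t_stop)")
            clean[eid] = t
        self.trains = clean

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def n_electrodes(self) -> int:
        return self.layout.n_electrodes

    def train(self, eid: int) -> np.ndarray:
        """Spike times of one electrode (empty array if silent)."""
        return self.trains.get(int(eid), np.empty(0))

    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def slice(self, t0: float, t1: float) -> "SpikeTrainSet":
        """Restrict to the half-open interval [t0, t1)."""
        if not (self.t_start <= t0 < t1 <= self.t_stop):
            raise ValueError("slice interval outside recording")
        out = {eid: t[(t >= t0) & (t < t1)] for eid, t in self.trains.items()}
        return SpikeTrainSet(out, t0, t1, self.layout)


@dataclass
class AnalogSignalSet:
    """Multichannel sampled voltage traces.

    ``samples`` is a (channel, time) array in microvolts.  ``kind`` is
    ``"raw"`` (10 kHz acquisition) or ``"lfp"`` (1 kHz after band-pass and
    decimation).
    """

    samples: np.ndarray
    sampling_rate: float
    t_start: float = 0.0
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.kind not in ("raw", "lfp"):
            raise ValueError("kind must be 'raw' or 'lfp'")
        expected = {"raw": RAW_RATE_HZ, "lfp": LFP_RATE_HZ}[self.kind]
        if not np.isclose(self.sampling_rate, expected):
            raise ValueError(
                f"{self.kind} signals are sampled at {expected:g} Hz")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class StimulationRecord:
    """One electrical-stimulation session from a single site.

    The study protocol delivers biphasic voltage pulses (600 us, 750 mV
    half-amplitude) every 5 s, 120 trials per site.
    """

    site: int
    onsets: np.ndarray
    inter_stimulus_interval: float = 5.0
    pulse: Mapping[str, float] = field(default_factory=lambda: {
        "duration_us": 600.0, "half_amplitude_mV": 750.0})
    jitter_tolerance: float = 0.5

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1 or self.onsets.size == 0:
            raise ValueError("onsets must be a nonempty 1-D array")
        d = np.diff(self.onsets)
        if np.any(d <= 0):
            raise ValueError("onsets must be strictly increasing")
        if d.size and np.any(np.abs(d - self.inter_stimulus_interval)
                             > self.jitter_tolerance):
            raise ValueError("inter-stimulus intervals outside tolerance")

    @property
    def n_trials(self) -> int:
        return self.onsets.size


@dataclass
class TrialTensor:
    """Trial x channel x time-bin array aligned to stimulus onsets.

    ``counts`` holds spike counts (integers) or real values for the LFP
    variant.  Bin ``b`` of trial ``k`` covers
    ``[onset_k - pre + b*bin_size, onset_k - pre + (b+1)*bin_size)``.
    """

    counts: np.ndarray
    bin_size: float
    pre: float
    post: float
    alignment: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be trial x channel x bin")
        n_bins = _exact_bins(self.pre + self.post, self.bin_size)
        if self.counts.shape[2] != n_bins:
            raise ValueError("bin axis inconsistent with window and bin_size")
        if np.issubdtype(self.counts.dtype, np.integer) and np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        self.alignment = np.asarray(self.alignment, dtype=float)
        if self.alignment.size != self.counts.shape[0]:
            raise ValueError("one alignment time per trial required")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def n_pre_bins(self) -> int:
        return _exact_bins(self.pre, self.bin_size) if self.pre > 0 else 0

    @property
    def n_post_bins(self) -> int:
        return self.n_bins - self.n_pre_bins

    def pre_counts(self) -> np.ndarray:
        """Trial x channel x bin slice before stimulus onset."""
        return self.counts[:, :, :self.n_pre_bins]

    def post_counts(self) -> np.ndarray:
        """Trial x channel x bin slice from stimulus onset on."""
        return self.counts[:, :, self.n_pre_bins:]


@dataclass(frozen=True)
class SessionPhases:
    """Experimental phase intervals of one culture session, in seconds.

    The protocol records 30 min of basal activity; after drug administration
    the first 10 min are discarded, the next 30 min form CCh1 and the last
    20 min CCh2.
    """

    basal: Tuple[float, float]
    cch1: Tuple[float, float]
    cch2: Tuple[float, float]
    discard: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        ordered = [self.basal]
        if self.discard is not None:
            ordered.append(self.discard)
        ordered += [self.cch1, self.cch2]
        for lo, hi in ordered:
            if not hi > lo:
                raise ValueError("phase intervals must have positive length")
        for (a0, a1), (b0, b1) in zip(ordered, ordered[1:]):
            if b0 < a1:
                raise ValueError("phase intervals must be disjoint and ordered")

    @classmethod
    def standard(cls, basal_min: float = 30.0, discard_min: float = 10.0,
                 cch1_min: float = 30.0, cch2_min: float = 20.0) -> "SessionPhases":
        """Protocol-standard phases laid out back to back from t = 0."""
        b = basal_min * 60.0
        d = b + discard_min * 60.0
        c1 = d + cch1_min * 60.0
        c2 = c1 + cch2_min * 60.0
        return cls(basal=(0.0, b), discard=(b, d), cch1=(d, c1), cch2=(c1, c2))


def _exact_bins(width: float, bin_size: float) -> int:
    n = width / bin_size
    n_round = round(n)
    if not np.isclose(n, n_round, atol=1e-9):
        raise ValueError(f"window {width} not divisible by bin size {bin_size}")
    return int(n_round)


def bin_spike_counts(spikes: SpikeTrainSet, bin_size: float,
                     interval: Optional[Tuple[float, float]] = None,
                     electrodes: Optional[Sequence[int]] = None) -> np.ndarray:
    """Bin spike trains into a (channel, bin) count matrix.

    Bins are half-open ``[t, t + bin_size)``, so the total count over any
    interval exactly partitioned into bins equals the number of spikes in
    that interval.  A trailing partial bin is dropped.

    Parameters
    ----------
    spikes : SpikeTrainSet
    bin_size : float
        Bin width in seconds; must be positive and no larger than the
        interval.
    interval : (t0, t1), optional
        Half-open analysis window; defaults to the full recording.
    electrodes : sequence of int, optional
        Row order of the output; defaults to all layout slots.

    Returns
    -------
    ndarray of int, shape (n_electrodes, n_bins)
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    t0, t1 = interval if interval is not None else (spikes.t_start, spikes.t_stop)
    if not (spikes.t_start <= t0 < t1 <= spikes.t_stop):
        raise ValueError("interval outside recording or empty")
    n_bins = int(np.floor((t1 - t0) / bin_size + 1e-9))
    if n_bins < 1:
        raise ValueError("bin size larger than the interval")
    if electrodes is None:
        electrodes = range(spikes.n_electrodes)
    edges = t0 + bin_size * np.arange(n_bins + 1)
    out = np.zeros((len(list(electrodes)), n_bins), dtype=np.int64)
    for row, eid in enumerate(electrodes):
        t = spikes.train(eid)
        t = t[(t >= t0) & (t < edges[-1])]
        if t.size:
            idx = np.floor((t - t0) / bin_size + 1e-9).astype(np.int64)
            np.add.at(out[row], np.minimum(idx, n_bins - 1), 1)
    return out


def align_trials(spikes: SpikeTrainSet, stim: StimulationRecord,
                 pre: float = 1.0, post: float = 0.5,
                 bin_size: float = 0.005, blank: float = 0.010,
                 electrodes: Optional[Sequence[int]] = None) -> TrialTensor:
    """Cut stimulus-aligned trial windows and bin spike counts.

    Each trial covers ``[onset - pre, onset + post)``.  Spikes in
    ``[onset, onset + blank)`` are removed before binning to suppress the
    electrical stimulation artifact (default 10 ms, as for the LFP).

    Raises
    ------
    ValueError
        If a trial window extends beyond the recording or consecutive trial
        windows overlap.
    """
    if blank < 0 or blank >= post:
        raise ValueError("blank must lie in [0, post)")
    n_bins = _exact_bins(pre + post, bin_size)
    onsets = stim.onsets
    if onsets[0] - pre < spikes.t_start or onsets[-1] + post > spikes.t_stop:
        raise ValueError("trial windows extend beyond the recording")
    if np.any(np.diff(onsets) < pre + post):
        raise ValueError("overlapping trial windows")
    if electrodes is None:
        electrodes = list(range(spikes.n_electrodes))
    else:
        electrodes = list(electrodes)
    counts = np.zeros((onsets.size, len(electrodes), n_bins), dtype=np.int64)
    for row, eid in enumerate(electrodes):
        t = spikes.train(eid)
        for k, onset in enumerate(onsets):
            w = t[(t >= onset - pre) & (t < onset + post)]
            if blank > 0:
                w = w[(w < onset) | (w >= onset + blank)]
            if w.size:
                # epsilon guards against float drift at bin edges
                idx = np.floor((w - (onset - pre)) / bin_size
                               + 1e-9).astype(np.int64)
                np.add.at(counts[k, row], np.minimum(idx, n_bins - 1), 1)
    return TrialTensor(counts=counts, bin_size=bin_size, pre=pre, post=post,
                       alignment=onsets.copy())
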