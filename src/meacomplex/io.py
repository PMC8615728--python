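"""Serialization of recordings: CSV for spikes/stimulation, HDF5 for signals.

Formats
-------
Spike trains
    CSV with header ``electrode_id,time_s``, rows sorted by electrode then
    time.  Recording bounds and layout size travel in ``#``-prefixed header
    comments so the round trip is lossless.  An HDF5 mirror of the same
    schema is provided for large sessions.
Stimulation
    CSV with header ``site,onset_s``.
Analog signals
    HDF5 with dataset ``samples`` (channel x time, microvolts) and
    attributes ``sampling_rate_hz``, ``t_start_s``, ``kind``.

Spike times are written with microsecond precision.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import h5py
import numpy as np

from .core import AnalogSignalSet, ElectrodeLayout, SpikeTrainSet, StimulationRecord

__all__ = [
    "write_spike_csv", "read_spike_csv",
    "write_spike_hdf5", "read_spike_hdf5",
    "write_stimulation_csv", "read_stimulation_csv",
    "write_analog_hdf5", "read_analog_hdf5",
]

PathLike = Union[str, Path]

_TIME_FMT = "{:.6f}"  # microsecond precision


class FormatError(ValueError):
    """Malformed serialized session file."""


def write_spike_csv(spikes: SpikeTrainSet, path: PathLike) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# t_start_s={_TIME_FMT.format(spikes.t_start)}"
                 f" t_stop_s={_TIME_FMT.format(spikes.t_stop)}"
                 f" n_electrodes={spikes.layout.n_electrodes}\n")
        writer = csv.writer(fh)
        writer.writerow(["electrode_id", "time_s"])
        for eid in sorted(spikes.trains):
            for t in spikes.trains[eid]:
                writer.writerow([eid, _TIME_FMT.format(t)])


def read_spike_csv(path: PathLike) -> SpikeTrainSet:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}:1: missing metadata header")
        meta = dict(item.split("=") for item in header[1:].split())
        try:
            t_start = float(meta["t_start_s"])
            t_stop = float(meta["t_stop_s"])
            n_elec = int(meta["n_electrodes"])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}:1: bad metadata: {exc}") from exc
        reader = csv.reader(fh)
        cols = next(reader, None)
        if cols != ["electrode_id", "time_s"]:
            raise FormatError(f"{path}:2: expected header electrode_id,time_s")
        trains: dict[int, list[float]] = {}
        for lineno, row in enumerate(reader, start=3):
            if not row:
                continue
            try:
                eid, t = int(row[0]), float(row[1])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad row {row!r}") from exc
            if not 0 <= eid < n_elec:
                raise FormatError(
                    f"{path}:{lineno}: electrode id {eid} out of range")
            bucket = trains.setdefault(eid, [])
            if bucket and t <= bucket[-1]:
                raise FormatError(
                    f"{path}:{lineno}: field time_s not strictly increasing")
            bucket.append(t)
    layout = ElectrodeLayout(n_electrodes=n_elec)
    try:
        return SpikeTrainSet({e: np.array(v) for e, v in trains.items()},
                             t_start, t_stop, layout)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spike_hdf5(spikes: SpikeTrainSet, path: PathLike) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["t_start_s"] = spikes.t_start
        h5.attrs["t_stop_s"] = spikes.t_stop
        h5.attrs["n_electrodes"] = spikes.layout.n_electrodes
        eids = np.concatenate([np.full(t.size, eid, dtype=np.int64)
                               for eid, t in sorted(spikes.trains.items())]
                              or [np.empty(0, dtype=np.int64)])
        times = np.concatenate([t for _, t in sorted(spikes.trains.items())]
                               or [np.empty(0)])
        h5.create_dataset("electrode_id", data=eids)
        h5.create_dataset("time_s", data=np.round(times, 6))


def read_spike_hdf5(path: PathLike) -> SpikeTrainSet:
    with h5py.File(path, "r") as h5:
        t_start = float(h5.attrs["t_start_s"])
        t_stop = float(h5.attrs["t_stop_s"])
        n_elec = int(h5.attrs["n_electrodes"])
        eids = h5["electrode_id"][:]
        times = h5["time_s"][:]
    trains = {int(e): times[eids == e] for e in np.unique(eids)}
    try:
        return SpikeTrainSet(trains, t_start, t_stop,
                             ElectrodeLayout(n_electrodes=n_elec))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_stimulation_csv(stim: StimulationRecord, path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["site", "onset_s"])
        for onset in stim.onsets:
            writer.writerow([stim.site, _TIME_FMT.format(onset)])


def read_stimulation_csv(path: PathLike) -> StimulationRecord:
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh)
        cols = next(reader, None)
        if cols != ["site", "onset_s"]:
            raise FormatError(f"{path}:1: expected header site,onset_s")
        sites, onsets = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                sites.append(int(row[0]))
                onsets.append(float(row[1]))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad row {row!r}") from exc
    if not onsets:
        raise FormatError(f"{path}: no stimulation onsets")
    if len(set(sites)) != 1:
        raise FormatError(f"{path}: multiple stimulation sites in one record")
    try:
        return StimulationRecord(site=sites[0], onsets=np.array(onsets))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_analog_hdf5(signal: AnalogSignalSet, path: PathLike) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("samples", data=signal.samples)
        h5.attrs["sampling_rate_hz"] = signal.sampling_rate
        h5.attrs["t_start_s"] = signal.t_start
        h5.attrs["kind"] = signal.kind


def read_analog_hdf5(path: PathLike) -> AnalogSignalSet:
    with h5py.File(path, "r") as h5:
        samples = h5["samples"][:]
        rate = float(h5.attrs["sampling_rate_hz"])
        t_start = float(h5.attrs["t_start_s"])
        kind = str(h5.attrs["kind"])
    return AnalogSignalSet(samples=samples, sampling_rate=rate,
                           t_start=t_start, kind=kind)
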