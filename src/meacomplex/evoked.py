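"""PSTH construction, PSTH-area statistics, and channel classification.

The post-stimulus time histogram (PSTH) of a channel is the trial-mean
firing profile over the 400 ms following each stimulus, in 4 ms bins:

    psth[b] = count[b] / (n_trials * bin_size)        [spikes/s]

Its *area* (sum of bin values times the bin width) is the mean number of
evoked spikes per trial; channels with area below one spike/trial are
dropped before any group statistics.  The drug effect per channel is the
percentage change of the PSTH area,

    dPA[%] = 100 * (PA_drug - PA_basal) / PA_basal,

classified against a stability threshold TH: the mean +- SD of the
area variation between the two 5-minute halves of a drug-free stimulation
session.  When no stability data are supplied the study's empirical value
of +-20% is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import SpikeTrainSet, StimulationRecord, TrialTensor, align_trials

__all__ = [
    "PSTH", "ChannelChange", "DEFAULT_STABILITY_THRESHOLD",
    "compute_psth", "psth_from_spikes", "filter_active_channels",
    "delta_pa", "stability_threshold", "classify_channels",
    "summarize_changes",
]

#: Fallback classification band (percent) when no stability session exists.
DEFAULT_STABILITY_THRESHOLD = 20.0


@dataclass
class PSTH:
    """Trial-averaged evoked firing profiles.

    rates : (n_channels, n_bins) array, spikes/s
    bin_size : bin width in seconds (default 4 ms)
    n_trials : number of stimuli averaged
    """

    rates: np.ndarray
    bin_size: float
    n_trials: int

    @property
    def area(self) -> np.ndarray:
        """Mean evoked spikes per trial, per channel."""
        return self.rates.sum(axis=1) * self.bin_size


@dataclass(frozen=True)
class ChannelChange:
    channel: int
    pa_bas: float
    pa_drug: float
    delta_pa_percent: float
    label: str  # 'increased' | 'decreased' | 'unchanged'


def compute_psth(trials: TrialTensor) -> PSTH:
    """PSTH from an aligned trial tensor (post-stimulus bins only)."""
    if trials.n_trials == 0:
        raise ValueError("no trials")
    counts = trials.post_counts().sum(axis=0)  # channel x bin
    rates = counts / (trials.n_trials * trials.bin_size)
    return PSTH(rates=rates, bin_size=trials.bin_size,
                n_trials=trials.n_trials)


def psth_from_spikes(spikes: SpikeTrainSet, stim: StimulationRecord,
                     window: float = 0.400, bin_size: float = 0.004,
                     blank: float = 0.010) -> PSTH:
    """Align trials over [onset, onset + window) and compute the PSTH."""
    tensor = align_trials(spikes, stim, pre=0.0, post=window,
                          bin_size=bin_size, blank=blank)
    return compute_psth(tensor)


def filter_active_channels(psth: PSTH, min_area: float = 1.0) -> np.ndarray:
    """Ids of channels with PSTH area >= ``min_area`` spikes/trial.

    The boundary is inclusive: a channel at exactly one spike per trial is
    retained.  Warns when nothing survives.
    """
    keep = np.where(psth.area >= min_area)[0]
    if keep.size == 0:
        warnings.warn("no channels reach the PSTH-area threshold",
                      stacklevel=2)
    return keep


def delta_pa(pa_bas: float, pa_drug: float) -> float:
    """Percentage change of the PSTH area; NaN when the baseline is zero."""
    if pa_bas <= 0:
        return float("nan")
    return 100.0 * (pa_drug - pa_bas) / pa_bas


def stability_threshold(spikes: SpikeTrainSet, stim: StimulationRecord,
                        active: Optional[Sequence[int]] = None,
                        window: float = 0.400, bin_size: float = 0.004,
                        blank: float = 0.010
                        ) -> Tuple[float, float, np.ndarray]:
    """Natural PSTH-area fluctuation from a drug-free stimulation session.

    The session is split into two equal halves (first and second 5 minutes
    of a standard 10-minute session); per channel the area change of the
    second half relative to the first is expressed in percent.  Returns
    ``(mean, sd, per_channel_percent)`` of that distribution; ``mean + sd``
    magnitudes are the classification band.

    Raises ``ValueError`` when either half has no trials.
    """
    n = stim.n_trials
    if n < 2:
        raise ValueError("need at least one trial per half")
    half = n // 2
    first = StimulationRecord(site=stim.site, onsets=stim.onsets[:half],
                              inter_stimulus_interval=stim.inter_stimulus_interval)
    second = StimulationRecord(site=stim.site, onsets=stim.onsets[half:],
                               inter_stimulus_interval=stim.inter_stimulus_interval)
    p1 = psth_from_spikes(spikes, first, window, bin_size, blank)
    p2 = psth_from_spikes(spikes, second, window, bin_size, blank)
    if active is None:
        active = filter_active_channels(p1)
    a1, a2 = p1.area[list(active)], p2.area[list(active)]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (a2 - a1) / a1
    pct = pct[np.isfinite(pct)]
    if pct.size == 0:
        raise ValueError("no active channels with nonzero baseline area")
    return float(pct.mean()), float(pct.std(ddof=1) if pct.size > 1 else 0.0), pct


def classify_channels(deltas: Dict[int, float],
                      threshold: Optional[float] = None
                      ) -> List[ChannelChange]:
    """Three-way classification of per-channel PSTH-area changes.

    ``threshold`` is the half-width of the 'unchanged' band in percent;
    when None, the fallback +-20% stability band is applied.  Channels with
    NaN deltas are excluded.
    """
    th = DEFAULT_STABILITY_THRESHOLD if threshold is None else abs(threshold)
    out: List[ChannelChange] = []
    for ch, d in sorted(deltas.items()):
        if not np.isfinite(d):
            continue
        if d < -th:
            label = "decreased"
        elif d > th:
            label = "increased"
        else:
            label = "unchanged"
        out.append(ChannelChange(channel=ch, pa_bas=float("nan"),
                                 pa_drug=float("nan"),
                                 delta_pa_percent=float(d), label=label))
    return out


def summarize_changes(changes: Sequence[ChannelChange]) -> Dict[str, float]:
    """Fractions per class and the median percentage change."""
    n = len(changes)
    if n == 0:
        return {"n": 0, "pct_decreased": float("nan"),
                "pct_increased": float("nan"), "pct_unchanged": float("nan"),
                "median_delta_pa": float("nan")}
    deltas = np.array([c.delta_pa_percent for c in changes])
    counts = {lab: sum(c.label == lab for c in changes)
              for lab in ("decreased", "increased", "unchanged")}
    return {
        "n": n,
        "pct_decreased": 100.0 * counts["decreased"] / n,
        "pct_increased": 100.0 * counts["increased"] / n,
        "pct_unchanged": 100.0 * counts["unchanged"] / n,
        "median_delta_pa": float(np.median(deltas)),
    }
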