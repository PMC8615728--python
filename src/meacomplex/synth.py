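"""Synthetic cortical-culture recordings for the two pharmacological regimes.

The generator emulates the two activity regimes the analysis pipeline is
built to contrast:

* **basal** — sleep-like, synchronized activity: sparse network bursts
  (a mother Poisson process of burst events; each electrode joins a burst
  with a recruitment probability, with jittered onset) riding on low,
  homogeneous tonic firing.  The population rate is dominated by large,
  slow burst deflections, so the LFP proxy concentrates power in the delta
  band.
* **cch** — carbachol-like, desynchronized activity: network bursts are
  rare, tonic firing is strong and heterogeneous across electrodes
  (log-normal rates), and all electrodes share a slow multiplicative
  rate modulation.  The shared modulation keeps the population weakly
  integrated — a realistic feature of desynchronized cultures without
  which electrodes would be mutually independent and any
  partition-to-partition mutual information would vanish.

Both presets are constructed to the same expected per-electrode mean firing
rate: the carbachol-like tonic rate is rescaled so that the regime contrast
is never a firing-rate confound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, signal

from .core import (AnalogSignalSet, ElectrodeLayout, SpikeTrainSet,
                   StimulationRecord, LFP_RATE_HZ, RAW_RATE_HZ)

__all__ = [
    "RegimeConfig", "EvokedConfig",
    "basal_config", "cch_config", "expected_mfr",
    "generate_spontaneous", "generate_lfp_proxy",
    "generate_evoked", "generate_raw_trace",
]


@dataclass(frozen=True)
class RegimeConfig:
    """Parameters of one spontaneous-activity regime.

    Attributes
    ----------
    regime : {"basal", "cch"}
    duration : float
        Recording length in seconds.
    burst_rate : float
        Rate of network-burst events (events/s).
    recruitment_prob : float
        Probability that an electrode joins a given network burst.
    intra_burst_rate : float
        Firing rate (spikes/s) of a recruited electrode during a burst.
    burst_duration : float
        Mean burst length in seconds; per-burst lengths carry a log-normal
        jitter of ``burst_duration_jitter`` (log-SD).
    onset_jitter_sd : float
        SD (s) of the per-electrode burst-onset jitter.
    tonic_rate_mean : float
        Target mean of the per-electrode tonic rates (spikes/s).
    tonic_rate_sigma : float
        Log-SD of the log-normal tonic-rate distribution; 0 gives
        homogeneous rates.
    common_mod_sd, common_mod_tau : float
        Log-SD and correlation time (s) of the shared slow multiplicative
        rate modulation applied to tonic firing (0 disables it).
    n_electrodes : int
    seed : int
    """

    regime: str = "basal"
    duration: float = 600.0
    burst_rate: float = 0.2
    recruitment_prob: float = 0.9
    intra_burst_rate: float = 80.0
    burst_duration: float = 0.3
    burst_duration_jitter: float = 0.15
    onset_jitter_sd: float = 0.01
    tonic_rate_mean: float = 0.5
    tonic_rate_sigma: float = 0.25
    common_mod_sd: float = 0.0
    common_mod_tau: float = 0.15
    n_electrodes: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("basal", "cch"):
            raise ValueError("regime must be 'basal' or 'cch'")
        for name in ("burst_rate", "intra_burst_rate", "tonic_rate_mean",
                     "duration", "burst_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.recruitment_prob <= 1.0:
            raise ValueError("recruitment_prob must lie in [0, 1]")


@dataclass(frozen=True)
class EvokedConfig:
    """Parameters of a synthetic electrical-stimulation session.

    Early responses are stimulus-locked spikes at a per-channel latency in
    the 5-50 ms range; the late component is a shared reverberant burst in
    the 100-400 ms window.  In the carbachol-like regime all response
    probabilities are multiplied by ``response_scale_cch`` (< 1), shrinking
    response amplitude without changing its spatio-temporal layout.
    """

    n_channels: int = 60
    n_responsive: int = 40
    n_trials: int = 120
    isi: float = 5.0
    early_prob: float = 0.8
    early_n_spikes: int = 3
    early_latency_range: Tuple[float, float] = (0.005, 0.050)
    early_latency_jitter: float = 0.002
    late_prob: float = 0.3
    late_window: Tuple[float, float] = (0.100, 0.400)
    late_rate: float = 30.0
    late_duration: float = 0.120
    late_participation: float = 0.5
    background_rate: float = 2.0
    response_scale_cch: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("early_prob", "late_prob", "late_participation"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.response_scale_cch <= 1.0:
            raise ValueError("response_scale_cch must lie in (0, 1]")


def expected_mfr(config: RegimeConfig) -> float:
    """Expected per-electrode mean firing rate (spikes/s) of a regime."""
    burst = (config.burst_rate * config.recruitment_prob
             * config.intra_burst_rate * config.burst_duration)
    return burst + config.tonic_rate_mean


def basal_config(duration: float = 600.0, seed: int = 0) -> RegimeConfig:
    """Preset for the synchronized, burst-dominated baseline regime."""
    return RegimeConfig(regime="basal", duration=duration, seed=seed)


def cch_config(duration: float = 600.0, seed: int = 0,
               match_mfr_to: Optional[RegimeConfig] = None) -> RegimeConfig:
    """Preset for the desynchronized carbachol-like regime.

    The tonic rate is set so the expected MFR matches ``match_mfr_to``
    (default: the basal preset), making the regime contrast rate-matched.
    """
    ref = match_mfr_to if match_mfr_to is not None else basal_config(duration)
    cfg = RegimeConfig(regime="cch", duration=duration, seed=seed,
                       burst_rate=0.02, recruitment_prob=0.3,
                       tonic_rate_mean=0.0, tonic_rate_sigma=0.8,
                       common_mod_sd=1.0, common_mod_tau=0.15)
    burst = (cfg.burst_rate * cfg.recruitment_prob
             * cfg.intra_burst_rate * cfg.burst_duration)
    tonic = expected_mfr(ref) - burst
    if tonic <= 0:
        raise ValueError("reference MFR too low to rate-match the cch preset")
    return replace(cfg, tonic_rate_mean=tonic)


def _sorted_strict(times: np.ndarray, t_start: float, t_stop: float) -> np.ndarray:
    """Clip to [t_start, t_stop), sort, drop spikes closer than 1 us.

    The separation floor matches the serialization precision (microsecond)
    and is far below any physical refractory period.
    """
    t = np.sort(times[(times >= t_start) & (times < t_stop)])
    if t.size > 1:
        keep = np.concatenate(([True], np.diff(t) >= 1e-6))
        t = t[keep]
    return t


def _common_modulation(rng: np.random.Generator, n_cells: int, dt: float,
                       sd: float, tau: float) -> np.ndarray:
    """Mean-one log-normal modulation with correlation time ``tau``."""
    if sd <= 0:
        return np.ones(n_cells)
    g = rng.standard_normal(n_cells + 1)
    width = max(tau / dt, 1e-6)
    g = ndimage.gaussian_filter1d(g, sigma=width, mode="wrap")[:n_cells]
    s = g.std()
    g = g / s * sd if s > 0 else np.zeros(n_cells)
    return np.exp(g - 0.5 * sd ** 2)


def generate_spontaneous(config: RegimeConfig) -> SpikeTrainSet:
    """Simulate one spontaneous-activity recording.

    Network bursts follow a doubly stochastic construction: a mother
    Poisson process of burst events, thinned per electrode by the
    recruitment probability, with Gaussian onset jitter and log-normal
    duration jitter.  Tonic firing is an (optionally modulated)
    inhomogeneous Poisson process with per-electrode log-normal rates
    rescaled so their empirical mean equals ``tonic_rate_mean`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    n, dur = config.n_electrodes, config.duration
    if (config.burst_rate > 0 and config.burst_rate * dur < 1.0):
        warnings.warn("duration too short for one expected network burst",
                      stacklevel=2)

    n_bursts = rng.poisson(config.burst_rate * dur)
    burst_times = np.sort(rng.uniform(0.0, dur, size=n_bursts))

    # per-electrode tonic rates, rescaled to the exact target mean
    if config.tonic_rate_mean > 0:
        if config.tonic_rate_sigma > 0:
            raw = rng.lognormal(mean=0.0, sigma=config.tonic_rate_sigma, size=n)
            rates = raw / raw.mean() * config.tonic_rate_mean
        else:
            rates = np.full(n, config.tonic_rate_mean)
    else:
        rates = np.zeros(n)

    # shared slow modulation sampled on a 50 ms grid
    grid_dt = 0.05
    n_cells = int(np.ceil(dur / grid_dt))
    mod = _common_modulation(rng, n_cells, grid_dt,
                             config.common_mod_sd, config.common_mod_tau)

    trains = {}
    for eid in range(n):
        pieces = []
        # tonic component: piecewise-constant-rate Poisson on the grid
        if rates[eid] > 0:
            lam = rates[eid] * mod * grid_dt
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total:
                cell_idx = np.repeat(np.arange(n_cells), counts)
                pieces.append((cell_idx + rng.uniform(size=total)) * grid_dt)
        # burst component
        for bt in burst_times:
            if rng.uniform() >= config.recruitment_prob:
                continue
            onset = bt + rng.normal(0.0, config.onset_jitter_sd)
            length = config.burst_duration * np.exp(
                rng.normal(0.0, config.burst_duration_jitter))
            k = rng.poisson(config.intra_burst_rate * length)
            if k:
                pieces.append(onset + rng.uniform(0.0, length, size=k))
        if pieces:
            t = _sorted_strict(np.concatenate(pieces), 0.0, dur)
            if t.size:
                trains[eid] = t
    layout = ElectrodeLayout(n_electrodes=n)
    return SpikeTrainSet(trains, 0.0, dur, layout)


# 3-pole IIR approximation to a 1/f amplitude spectrum (audio-dsp classic)
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sd: float) -> np.ndarray:
    """Gaussian 1/f ("pink") noise, independent per channel, SD = ``sd``."""
    if sd <= 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples), dtype=np.float32)
    out = signal.lfilter(_PINK_B, _PINK_A, white, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out * sd


def generate_lfp_proxy(spikes: SpikeTrainSet, kernel_width: float = 0.3,
                       gain_uv: float = 10.0, noise_sd_uv: float = 2.0,
                       seed: int = 0) -> AnalogSignalSet:
    """Build a 1 kHz LFP-like signal from spiking activity.

    Each channel carries the negative of the population firing rate
    convolved with a Gaussian kernel of total width ``kernel_width``
    seconds (SD = width/4; population deflections in cultures are
    negative-going), plus independent 1/f noise.  Burst-dominated input
    therefore yields a delta-dominated power spectrum, with burst edges
    contributing theta-band power.
    """
    if spikes.n_spikes() == 0 and noise_sd_uv == 0:
        n_samples = int(round(spikes.duration * LFP_RATE_HZ))
        return AnalogSignalSet(np.zeros((spikes.n_electrodes, n_samples)),
                               LFP_RATE_HZ, spikes.t_start, kind="lfp")
    rng = np.random.default_rng(seed)
    fs = LFP_RATE_HZ
    n_samples = int(round(spikes.duration * fs))
    all_times = np.concatenate([t for t in spikes.trains.values()]
                               or [np.empty(0)])
    rate = np.zeros(n_samples)
    if all_times.size:
        idx = np.minimum(((all_times - spikes.t_start) * fs).astype(np.int64),
                         n_samples - 1)
        np.add.at(rate, idx, 1.0)
        rate *= fs / max(spikes.n_electrodes, 1)  # spikes/s per electrode
        rate = ndimage.gaussian_filter1d(rate, sigma=kernel_width / 4 * fs)
    base = -gain_uv * rate
    noise = _pink_noise(rng, spikes.n_electrodes, n_samples, noise_sd_uv)
    return AnalogSignalSet(base[None, :] + noise, fs, spikes.t_start,
                           kind="lfp")


def generate_evoked(config: EvokedConfig, regime: str = "basal"
                    ) -> Tuple[SpikeTrainSet, StimulationRecord]:
    """Simulate one stimulation session (spikes plus stimulus record).

    Responsive channels emit, with probability ``early_prob`` per trial,
    a burst of ``early_n_spikes`` spikes at a channel-specific latency;
    a shared reverberant late burst follows in ``late_window`` with
    probability ``late_prob``.  In the ``"cch"`` regime both probabilities
    are multiplied by ``response_scale_cch``.  Background firing is
    homogeneous Poisson on every channel.
    """
    if regime not in ("basal", "cch"):
        raise ValueError("regime must be 'basal' or 'cch'")
    rng = np.random.default_rng(config.seed)
    scale = config.response_scale_cch if regime == "cch" else 1.0
    lead_in = 2.0
    onsets = lead_in + config.isi * np.arange(config.n_trials)
    duration = lead_in + config.isi * config.n_trials
    n = config.n_channels

    responsive = rng.choice(n, size=min(config.n_responsive, n), replace=False)
    lat_lo, lat_hi = config.early_latency_range
    latencies = rng.uniform(lat_lo, lat_hi, size=responsive.size)

    trains: dict[int, list] = {eid: [] for eid in range(n)}
    # background
    for eid in range(n):
        k = rng.poisson(config.background_rate * duration)
        trains[eid].append(rng.uniform(0.0, duration, size=k))
    # evoked components, trial by trial (trial loop keeps late events shared)
    for onset in onsets:
        for ch, lat in zip(responsive, latencies):
            if rng.uniform() < config.early_prob * scale:
                t = onset + lat + rng.normal(
                    0.0, config.early_latency_jitter, size=config.early_n_spikes)
                trains[int(ch)].append(t)
        if rng.uniform() < config.late_prob * scale:
            w_lo, w_hi = config.late_window
            start = onset + rng.uniform(w_lo, max(w_lo, w_hi - config.late_duration))
            for ch in responsive:
                if rng.uniform() < config.late_participation:
                    k = rng.poisson(config.late_rate * config.late_duration)
                    trains[int(ch)].append(
                        start + rng.uniform(0.0, config.late_duration, size=k))

    layout = ElectrodeLayout(n_electrodes=n)
    out = {}
    for eid, pieces in trains.items():
        t = _sorted_strict(np.concatenate(pieces), 0.0, duration)
        if t.size:
            out[eid] = t
    spikes = SpikeTrainSet(out, 0.0, duration, layout)
    stim = StimulationRecord(site=0, onsets=onsets,
                             inter_stimulus_interval=config.isi)
    return spikes, stim


def default_spike_waveform(fs: float = RAW_RATE_HZ,
                           amplitude_uv: float = 80.0) -> np.ndarray:
    """Biphasic extracellular spike template (~1.2 ms, negative-leading)."""
    t = np.arange(int(round(1.2e-3 * fs))) / fs
    # negative lobe peaks 0.15 ms after the nominal spike time
    wf = (-np.exp(-((t - 1.5e-4) / 1.0e-4) ** 2)
          + 0.35 * np.exp(-((t - 6e-4) / 2.5e-4) ** 2))
    return amplitude_uv * wf / np.max(np.abs(wf))


def generate_raw_trace(spikes: SpikeTrainSet, noise_sd_uv: float = 10.0,
                       waveform: Optional[np.ndarray] = None,
                       seed: int = 0) -> AnalogSignalSet:
    """Render spike trains as a noisy 10 kHz extracellular voltage trace.

    A biphasic waveform is added at each spike time over Gaussian noise;
    the input spike times are the detection ground truth.
    """
    fs = RAW_RATE_HZ
    if waveform is None:
        waveform = default_spike_waveform(fs)
    waveform = np.asarray(waveform, dtype=float)
    rng = np.random.default_rng(seed)
    n_samples = int(round(spikes.duration * fs))
    traces = rng.standard_normal((spikes.n_electrodes, n_samples)) * noise_sd_uv
    L = waveform.size
    for eid, t in spikes.trains.items():
        starts = ((t - spikes.t_start) * fs).astype(np.int64)
        for s in starts:
            stop = min(s + L, n_samples)
            traces[eid, s:stop] += waveform[:stop - s]
    return AnalogSignalSet(traces, fs, spikes.t_start, kind="raw")
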