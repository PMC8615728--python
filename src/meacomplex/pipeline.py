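"""Study orchestration: phase splitting, regime contrasts, reporting.

``run_study`` executes the full analysis chain on a synthetic culture
session — spontaneous LFP band powers, MUA network metrics, neural
complexity, evoked PSTH statistics, and PCI — for the basal and
carbachol-like regimes, normalizing every spontaneous metric to the basal
mean as done for per-experiment group statistics.

``compare_conditions`` is a thin wrapper over standard statistical
routines: a Kolmogorov-Smirnov normality check decides between the t-test
and the Mann-Whitney U test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import synth
from .complexity import NCConfig, neural_complexity, pci_spiking
from .core import SessionPhases, SpikeTrainSet
from .evoked import (classify_channels, delta_pa, filter_active_channels,
                     psth_from_spikes, stability_threshold, summarize_changes,
                     DEFAULT_STABILITY_THRESHOLD)
from .lfp import band_powers
from .mua import NetworkMetrics, compute_network_metrics

__all__ = ["StudyConfig", "StudyReport", "run_study", "compare_conditions",
           "split_phases"]


def split_phases(spikes: SpikeTrainSet, phases: SessionPhases
                 ) -> Dict[str, SpikeTrainSet]:
    """Slice one continuous recording into its experimental phases."""
    out = {}
    for name in ("basal", "cch1", "cch2"):
        lo, hi = getattr(phases, name)
        out[name] = spikes.slice(lo, hi)
    return out


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a synthetic regime-contrast study."""

    duration: float = 600.0
    n_trials: int = 120
    seed: int = 0
    sttc_dt: float = 0.010
    nc: NCConfig = field(default_factory=NCConfig)
    n_boot: int = 500
    alpha: float = 0.05
    response_scale_cch: float = 0.5
    include_lfp: bool = True
    include_evoked: bool = True


@dataclass
class StudyReport:
    """All stage outputs of one study run, with serialization helpers."""

    config: StudyConfig
    metrics: Dict[str, NetworkMetrics]
    normalized_metrics: pd.DataFrame
    band_power: Optional[pd.DataFrame]
    nc_segments: Dict[str, np.ndarray]
    evoked_summary: Optional[Dict[str, float]]
    channel_changes: Optional[pd.DataFrame]
    pci: Optional[Dict[str, dict]]
    statistics: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.normalized_metrics.to_csv(outdir / "metrics.csv", index=False)
        if self.band_power is not None:
            self.band_power.to_csv(outdir / "band_power.csv", index=False)
        nc = pd.DataFrame([
            {"regime": reg, "segment": i, "nc_bits": float(v)}
            for reg, vals in self.nc_segments.items()
            for i, v in enumerate(vals)])
        nc.to_csv(outdir / "neural_complexity.csv", index=False)
        if self.channel_changes is not None:
            self.channel_changes.to_csv(outdir / "channel_changes.csv",
                                        index=False)
        self.statistics.to_csv(outdir / "statistics.csv", index=False)
        payload = {
            "seed": self.config.seed,
            "evoked_summary": self.evoked_summary,
            "pci": self.pci,
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=2))


def compare_conditions(groups: Dict[str, np.ndarray],
                       normality_alpha: float = 0.05) -> pd.DataFrame:
    """Two-group comparison with data-driven test selection.

    Both groups are checked for normality with a Kolmogorov-Smirnov test
    on the z-scored values; if both pass, an independent t-test is used,
    otherwise Mann-Whitney U.  With fewer than 3 values per group only
    descriptive statistics are returned.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (name_a, a), (name_b, b) = [(k, np.asarray(v, float)) for k, v in
                                groups.items()]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    row = {"group_a": name_a, "group_b": name_b,
           "mean_a": a.mean() if a.size else np.nan,
           "mean_b": b.mean() if b.size else np.nan}
    if a.size < 3 or b.size < 3:
        row.update(test="descriptive", statistic=np.nan, p=np.nan)
        return pd.DataFrame([row])

    def is_normal(x):
        if np.std(x, ddof=1) == 0:
            return False
        z = (x - x.mean()) / x.std(ddof=1)
        return stats.kstest(z, "norm").pvalue > normality_alpha

    if is_normal(a) and is_normal(b):
        res = stats.ttest_ind(a, b)
        row.update(test="t-test", statistic=res.statistic, p=res.pvalue)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        row.update(test="mann-whitney", statistic=res.statistic, p=res.pvalue)
    return pd.DataFrame([row])


def _derive_seed(seed: int, offset: int) -> int:
    return int((seed * 1000 + offset) % (2 ** 31 - 1))


def run_study(config: StudyConfig = StudyConfig()) -> StudyReport:
    """Run the full basal-vs-carbachol contrast on synthetic data."""
    seed = config.seed
    bas_cfg = synth.basal_config(config.duration, seed=_derive_seed(seed, 1))
    cch_cfg = synth.cch_config(config.duration, seed=_derive_seed(seed, 2))
    spikes = {"basal": synth.generate_spontaneous(bas_cfg),
              "cch": synth.generate_spontaneous(cch_cfg)}

    metrics = {reg: compute_network_metrics(sp, sttc_dt=config.sttc_dt)
               for reg, sp in spikes.items()}
    basal = metrics["basal"]
    rows = []
    for reg, m in metrics.items():
        rows.append({
            "regime": reg, "mfr": m.mfr, "ibr": m.ibr, "bi": m.bi,
            "cv_mfr": m.cv_mfr, "sttc_mean": m.sttc_mean,
            "spike_sync": m.spike_sync,
            "mfr_norm": m.mfr / basal.mfr if basal.mfr else np.nan,
            "ibr_norm": m.ibr / basal.ibr if basal.ibr else np.nan,
            "bi_norm": m.bi / basal.bi if basal.bi else np.nan,
        })
    normalized_metrics = pd.DataFrame(rows)

    band_df = None
    if config.include_lfp:
        lfps = {reg: synth.generate_lfp_proxy(sp, seed=_derive_seed(seed, 3))
                for reg, sp in spikes.items()}
        ref = band_powers(lfps["basal"])
        band_rows = []
        for reg, sig in lfps.items():
            bp = band_powers(sig, reference_mean=ref.mean)
            for band, power in bp.mean.items():
                band_rows.append({
                    "regime": reg, "band": band, "power_uv2": power,
                    "normalized_power": bp.normalized[band]})
        band_df = pd.DataFrame(band_rows)

    nc_segments = {reg: neural_complexity(sp, config.nc,
                                          seed=_derive_seed(seed, 4))
                   for reg, sp in spikes.items()}

    evoked_summary = None
    changes_df = None
    pci_out = None
    if config.include_evoked:
        ev_cfg = synth.EvokedConfig(n_trials=config.n_trials,
                                    response_scale_cch=config.response_scale_cch,
                                    seed=_derive_seed(seed, 5))
        ev_spikes, ev_stim = {}, {}
        for reg in ("basal", "cch"):
            ev_spikes[reg], ev_stim[reg] = synth.generate_evoked(ev_cfg, reg)
        psths = {reg: psth_from_spikes(ev_spikes[reg], ev_stim[reg])
                 for reg in ev_spikes}
        active = filter_active_channels(psths["basal"])
        deltas = {int(ch): delta_pa(psths["basal"].area[ch],
                                    psths["cch"].area[ch])
                  for ch in active}
        try:
            th_mean, th_sd, _ = stability_threshold(
                ev_spikes["basal"], ev_stim["basal"], active=active)
            threshold = max(abs(th_mean) + th_sd, 1e-9)
        except ValueError:
            threshold = DEFAULT_STABILITY_THRESHOLD
        changes = classify_channels(deltas, threshold)
        evoked_summary = summarize_changes(changes)
        evoked_summary["threshold_percent"] = threshold
        changes_df = pd.DataFrame([
            {"channel": c.channel, "pa_bas": psths["basal"].area[c.channel],
             "pa_cch": psths["cch"].area[c.channel],
             "delta_pa_percent": c.delta_pa_percent, "class": c.label}
            for c in changes])
        pci_out = {}
        for reg in ("basal", "cch"):
            res, ss = pci_spiking(ev_spikes[reg], ev_stim[reg],
                                  n_boot=config.n_boot, alpha=config.alpha,
                                  seed=_derive_seed(seed, 6))
            pci_out[reg] = {"pci": res.pci, "complexity": res.complexity,
                            "hsrc": res.hsrc, "p1": res.p1, "L": res.L}

    stats_df = compare_conditions({
        "nc_basal": nc_segments["basal"], "nc_cch": nc_segments["cch"]})
    return StudyReport(config=config, metrics=metrics,
                       normalized_metrics=normalized_metrics,
                       band_power=band_df, nc_segments=nc_segments,
                       evoked_summary=evoked_summary,
                       channel_changes=changes_df, pci=pci_out,
                       statistics=stats_df)
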