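"""Spike/burst detection, firing statistics, STTC, SPIKE-synchronization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meacomplex import (AnalogSignalSet, ElectrodeLayout, SpikeTrainSet,
                        burstiness_index, detect_bursts, detect_spikes,
                        firing_stats, generate_raw_trace, mean_sttc,
                        spike_synchronization, sttc)
from conftest import poisson_train


def sttc_oracle(a, b, dt, t0, t1):
    """Brute-force STTC: explicit merged tiling intervals, direct counts."""

    def tiled(t):
        ivals = [(max(x - dt, t0), min(x + dt, t1)) for x in t]
        merged = []
        for lo, hi in sorted(ivals):
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
            else:
                merged.append((lo, hi))
        return sum(hi - lo for lo, hi in merged) / (t1 - t0), merged

    def prop(t, intervals):
        return np.mean([any(lo <= x <= hi for lo, hi in intervals)
                        for x in t])

    ta, ia = tiled(a)
    tb, ib = tiled(b)
    pa, pb = prop(a, ib), prop(b, ia)
    if pa * tb == 1.0:
        return 1.0 if pb * ta == 1.0 else 0.5 + 0.5 * (pb - ta) / (1 - pb * ta)
    if pb * ta == 1.0:
        return 0.5 + 0.5 * (pa - tb) / (1 - pa * tb)
    return 0.5 * ((pa - tb) / (1 - pa * tb) + (pb - ta) / (1 - pb * ta))


class TestSpikeDetection:
    def test_snr8_recall_and_precision(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(1.0, 59.0, 40))
        sts = SpikeTrainSet({0: times}, 0.0, 60.0, ElectrodeLayout(1))
        raw = generate_raw_trace(sts, noise_sd_uv=10.0, seed=1)  # amp 80 uV
        det = detect_spikes(raw).train(0)
        recall = np.mean([np.abs(det - t).min() < 1e-3 for t in times])
        precision = np.mean([np.abs(times - t).min() < 1e-3 for t in det])
        assert recall >= 0.95 and precision >= 0.95

    def test_pure_noise_low_false_positive_rate(self):
        rng = np.random.default_rng(2)
        raw = AnalogSignalSet(rng.standard_normal((1, 600_000)) * 10.0,
                              10_000.0, kind="raw")
        det = detect_spikes(raw, k=7.0)
        assert det.train(0).size / 60.0 < 0.1

    def test_flat_channel_empty(self):
        raw = AnalogSignalSet(np.zeros((1, 50_000)), 10_000.0, kind="raw")
        assert detect_spikes(raw).train(0).size == 0


class TestBurstDetection:
    def test_single_burst_detected(self):
        t = 1.0 + 0.005 * np.arange(10)
        sts = SpikeTrainSet({0: np.concatenate([t, [3.0]])}, 0.0, 5.0,
                            ElectrodeLayout(1))
        bs = detect_bursts(sts)
        assert len(bs.bursts[0]) == 1
        assert bs.bursts[0][0].n_spikes == 10

    def test_sparse_poisson_yields_no_bursts(self):
        rng = np.random.default_rng(3)
        t = poisson_train(rng, 0.5, 600.0)
        sts = SpikeTrainSet({0: t}, 0.0, 600.0, ElectrodeLayout(1))
        assert detect_bursts(sts).n_bursts() == 0

    def test_bursts_separated_by_gap_not_merged(self):
        t1 = 1.0 + 0.005 * np.arange(6)
        t2 = t1[-1] + 0.150 + 0.005 * np.arange(6)
        sts = SpikeTrainSet({0: np.concatenate([t1, t2])}, 0.0, 5.0,
                            ElectrodeLayout(1))
        assert len(detect_bursts(sts).bursts[0]) == 2


class TestFiringStats:
    def test_ibr_extremes(self):
        burst = 1.0 + 0.005 * np.arange(10)
        sts = SpikeTrainSet({0: burst}, 0.0, 5.0, ElectrodeLayout(1))
        _, _, ibr, _ = firing_stats(sts)
        assert ibr == 0.0
        lone = SpikeTrainSet({0: [0.5, 1.5, 2.5]}, 0.0, 5.0, ElectrodeLayout(1))
        _, _, ibr2, _ = firing_stats(lone)
        assert ibr2 == 100.0

    def test_identical_rates_zero_cv(self):
        sts = SpikeTrainSet({e: np.arange(1, 10, 1.0) + e * 1e-4
                             for e in range(4)},
                            0.0, 10.0, ElectrodeLayout(4))
        _, _, _, cv = firing_stats(sts)
        assert cv == pytest.approx(0.0, abs=1e-12)


class TestBurstinessIndex:
    def test_uniform_counts_give_zero(self):
        # one spike per 1 s bin: perfectly uniform
        sts = SpikeTrainSet({0: np.arange(0.5, 100.0, 1.0)}, 0.0, 100.0,
                            ElectrodeLayout(1))
        assert burstiness_index(sts) == pytest.approx(0.0, abs=1e-9)

    def test_concentrated_counts_give_one(self):
        # all spikes inside 15 of 100 bins
        t = np.sort(np.concatenate(
            [b + np.linspace(0.01, 0.99, 20) for b in range(15)]))
        sts = SpikeTrainSet({0: t}, 0.0, 100.0, ElectrodeLayout(1))
        assert burstiness_index(sts) == pytest.approx(1.0)

    def test_no_spikes_missing(self):
        sts = SpikeTrainSet({}, 0.0, 100.0, ElectrodeLayout(1))
        assert np.isnan(burstiness_index(sts))


class TestSttc:
    def test_identical_trains_give_one(self):
        t = np.array([1.0, 2.0, 5.5])
        assert sttc(t, t, 0.01, 0.0, 10.0) == 1.0

    def test_worked_formula_example(self):
        # A={1.0}, B={5.0}: P terms 0, tiling 0.002 each
        v = sttc([1.0], [5.0], 0.01, 0.0, 10.0)
        assert v == pytest.approx(-0.002, abs=1e-12)

    def test_empty_train_missing(self):
        assert np.isnan(sttc([], [1.0], 0.01, 0.0, 10.0))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a = np.sort(rng.uniform(0, 10, rng.integers(1, 15)))
        b = np.sort(rng.uniform(0, 10, rng.integers(1, 15)))
        a = a[np.concatenate(([True], np.diff(a) > 0))]
        b = b[np.concatenate(([True], np.diff(b) > 0))]
        v1 = sttc(a, b, 0.05, 0.0, 10.0)
        v2 = sttc(b, a, 0.05, 0.0, 10.0)
        assert v1 == pytest.approx(v2, abs=1e-12)
        assert -1.0 <= v1 <= 1.0

    def test_joint_time_shift_invariance(self):
        rng = np.random.default_rng(11)
        a = np.sort(rng.uniform(1, 9, 10))
        b = np.sort(rng.uniform(1, 9, 12))
        v1 = sttc(a, b, 0.05, 0.0, 10.0)
        v2 = sttc(a + 5.0, b + 5.0, 0.05, 5.0, 15.0)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            na, nb = rng.integers(1, 21, size=2)
            a = np.sort(rng.uniform(0, 10, na))
            b = np.sort(rng.uniform(0, 10, nb))
            a = a[np.concatenate(([True], np.diff(a) > 0))]
            b = b[np.concatenate(([True], np.diff(b) > 0))]
            dt = rng.uniform(0.005, 0.5)
            assert sttc(a, b, dt, 0.0, 10.0) == pytest.approx(
                sttc_oracle(a, b, dt, 0.0, 10.0), abs=1e-12)

    def test_independent_poisson_null_mean_near_zero(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(50):
            a = poisson_train(rng, 2.0, 600.0)
            b = poisson_train(rng, 2.0, 600.0)
            vals.append(sttc(a, b, 0.01, 0.0, 600.0))
        assert abs(np.mean(vals)) < 0.02


class TestSpikeSynchronization:
    def test_identical_trains_fully_synchronous(self):
        t = np.array([1.0, 2.0, 3.0, 5.0])
        sts = SpikeTrainSet({0: t, 1: t.copy()}, 0.0, 10.0, ElectrodeLayout(2))
        assert spike_synchronization(sts) == pytest.approx(1.0)

    def test_distant_spikes_zero(self):
        sts = SpikeTrainSet({0: [1.0, 1.2, 1.4], 1: [8.0, 8.2, 8.4]},
                            0.0, 10.0, ElectrodeLayout(2))
        assert spike_synchronization(sts) == pytest.approx(0.0)

    def test_hand_worked_three_train_case(self):
        # A={1.0, 2.0}, B={1.05, 3.0}, C={1.02}: adaptive windows give
        # coincidences only among the three spikes near t=1; SYNC = 3/5.
        sts = SpikeTrainSet({0: [1.0, 2.0], 1: [1.05, 3.0], 2: [1.02]},
                            0.0, 10.0, ElectrodeLayout(3))
        assert spike_synchronization(sts) == pytest.approx(0.6)

    def test_fewer_than_two_trains_missing(self):
        sts = SpikeTrainSet({0: [1.0]}, 0.0, 10.0, ElectrodeLayout(2))
        assert np.isnan(spike_synchronization(sts))


class TestMeanSttc:
    def test_empty_pairs_excluded_not_zero_filled(self):
        t = np.array([1.0, 2.0, 3.0])
        sts = SpikeTrainSet({0: t, 1: t + 0.001}, 0.0, 10.0,
                            ElectrodeLayout(4))  # electrodes 2, 3 silent
        v = mean_sttc(sts)
        assert v > 0.9  # only the correlated pair contributes
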