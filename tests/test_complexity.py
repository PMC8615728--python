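"""Lempel-Ziv complexity, mutual information, NC, bootstrap, PCI."""

import itertools

import numpy as np
import pytest

from meacomplex import (ElectrodeLayout, SpikeTrainSet, StimulationRecord,
                        TrialTensor, NCConfig, bootstrap_activation_threshold,
                        lz76, mutual_information_pt, neural_complexity, pci,
                        pci_lfp, significant_sources, source_entropy)
from meacomplex.complexity import SignificantSourceMatrix, discretize


def lz76_oracle(s: str) -> int:
    """Exhaustive-history parse by brute-force substring search."""
    words, i, n = 0, 0, len(s)
    while i < n:
        k = 1
        while i + k <= n and s[i:i + k] in s[:i + k - 1]:
            k += 1
        k = min(k, n - i)
        words += 1
        i += k
    return words


class TestLz76:
    def test_single_symbol(self):
        assert lz76("0") == 1

    def test_constant_string(self):
        assert lz76("0" * 100) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lz76("")

    def test_accepts_binary_arrays(self):
        assert lz76(np.array([0, 0, 0, 0])) == lz76("0000")

    def test_matches_exhaustive_oracle_up_to_length_12(self):
        for length in range(1, 13):
            for bits in itertools.product("01", repeat=length):
                s = "".join(bits)
                assert lz76(s) == lz76_oracle(s), s


class TestSourceEntropy:
    @pytest.mark.parametrize("p,expected", [
        (0.5, 1.0), (0.0, 0.0), (1.0, 0.0), (0.1, 0.4689955935892812)])
    def test_closed_forms(self, p, expected):
        assert source_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        for p in (0.1, 0.25, 0.4):
            assert source_entropy(p) == pytest.approx(source_entropy(1 - p))

    def test_maximal_at_half(self):
        grid = np.linspace(0.01, 0.99, 99)
        vals = [source_entropy(p) for p in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.5, abs=0.01)


class TestMutualInformation:
    def test_identical_uniform_four_levels(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, size=50_000)
        assert mutual_information_pt(x, x) == pytest.approx(2.0, abs=0.01)

    def test_independent_null_is_small_after_correction(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 6, size=10_000)
        y = rng.integers(0, 6, size=10_000)
        assert abs(mutual_information_pt(x, y)) < 0.01

    def test_constant_series_zero(self):
        x = np.zeros(1000, dtype=int)
        y = np.arange(1000) % 4
        assert mutual_information_pt(x, y) == 0.0

    def test_bias_correction_reduces_overestimate(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 6, size=500)
        y = rng.integers(0, 6, size=500)
        plugin = mutual_information_pt(x, y, bias_correction=False)
        corrected = mutual_information_pt(x, y, bias_correction=True)
        assert corrected < plugin

    def test_quantile_discretization_levels(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(6000)
        levels = discretize(x, 6)
        counts = np.bincount(levels)
        assert counts.size == 6
        assert counts.min() > 900  # roughly equipopulated


class TestNeuralComplexity:
    def _synchronized_set(self, n_electrodes=31, duration=300.0, p=0.5,
                          seed=1):
        rng = np.random.default_rng(seed)
        bins = int(duration / 0.02)
        active = rng.uniform(size=bins) < p
        times = np.where(active)[0] * 0.02 + 0.01
        trains = {e: times + e * 1e-6 for e in range(n_electrodes)}
        return SpikeTrainSet(trains, 0.0, duration,
                             ElectrodeLayout(n_electrodes))

    def test_constant_activity_zero_complexity(self):
        # every electrode fires once in every 20 ms bin: constant IFR
        sts = self._synchronized_set(p=1.01, seed=0)  # p>1 -> all bins active
        nc = neural_complexity(sts, seed=0)
        assert np.allclose(nc, 0.0)

    def test_synchronized_two_level_network_sums_to_six_bits(self):
        sts = self._synchronized_set(p=0.5)
        nc = neural_complexity(sts, seed=0)
        assert nc.shape == (1,)
        assert nc[0] == pytest.approx(6.0, abs=0.3)

    def test_seed_reproducible(self):
        sts = self._synchronized_set(p=0.3, seed=5)
        a = neural_complexity(sts, seed=3)
        b = neural_complexity(sts, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_partition_size_must_fit(self):
        sts = self._synchronized_set(n_electrodes=10)
        with pytest.raises(ValueError):
            neural_complexity(sts, NCConfig(partition_sizes=(5, 10, 15)))

    def test_short_segment_rejected(self):
        sts = self._synchronized_set(duration=300.0)
        with pytest.raises(ValueError):
            neural_complexity(sts, NCConfig(segment_length=1.0))


def stationary_tensor(rng, rate=4.0, n_trials=120, n_channels=6):
    counts = rng.poisson(rate * 0.005, size=(n_trials, n_channels, 300))
    return TrialTensor(counts=counts, bin_size=0.005, pre=1.0, post=0.5,
                       alignment=5.0 * np.arange(n_trials))


class TestBootstrapThreshold:
    def test_strong_response_bin_always_flagged(self):
        rng = np.random.default_rng(0)
        tt = stationary_tensor(rng)
        counts = tt.counts.copy()
        counts[:, 2, 210] += rng.poisson(10 * 0.005 * 10, size=120) + 1
        tt2 = TrialTensor(counts=counts, bin_size=0.005, pre=1.0, post=0.5,
                          alignment=tt.alignment)
        for seed in range(5):
            thr, _ = bootstrap_activation_threshold(tt2, seed=seed)
            ss = significant_sources(tt2, thr)
            row = np.where(ss.channel_order == 2)[0][0]
            assert ss.matrix[row, 10] == 1  # post bin 210 - 200

    def test_all_zero_tensor_no_significant_bins(self):
        tt = TrialTensor(counts=np.zeros((30, 4, 300), dtype=np.int64),
                         bin_size=0.005, pre=1.0, post=0.5,
                         alignment=5.0 * np.arange(30))
        thr, silent = bootstrap_activation_threshold(tt, seed=0)
        assert silent.all()
        ss = significant_sources(tt, thr)
        assert ss.matrix.sum() == 0

    def test_silent_channel_uses_pooled_null(self):
        rng = np.random.default_rng(1)
        tt = stationary_tensor(rng)
        counts = tt.counts.copy()
        counts[:, 0, :200] = 0  # silent pre-stimulus channel
        tt2 = TrialTensor(counts=counts, bin_size=0.005, pre=1.0, post=0.5,
                          alignment=tt.alignment)
        thr, silent = bootstrap_activation_threshold(tt2, seed=0)
        assert silent[0] and not silent[1:].any()
        assert thr[0] > 0


class TestSignificantSources:
    def test_rows_sorted_by_total_activity(self):
        m = np.array([[1, 1, 1], [0, 0, 0], [1, 0, 0]], dtype=np.int8)
        ss = SignificantSourceMatrix(matrix=m[np.argsort(m.sum(axis=1))],
                                     channel_order=np.array([1, 2, 0]),
                                     thresholds=np.zeros(3))
        assert list(ss.matrix.sum(axis=1)) == [0, 1, 3]

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(4)
        tt = stationary_tensor(rng, rate=8.0)
        thr, _ = bootstrap_activation_threshold(tt, seed=0)
        ss = significant_sources(tt, thr)
        perm = rng.permutation(tt.n_channels)
        tt_p = TrialTensor(counts=tt.counts[:, perm, :], bin_size=0.005,
                           pre=1.0, post=0.5, alignment=tt.alignment)
        ss_p = significant_sources(tt_p, thr[perm])
        np.testing.assert_array_equal(ss.matrix, ss_p.matrix)


class TestPci:
    @staticmethod
    def _ss(matrix):
        m = np.asarray(matrix, dtype=np.int8)
        order = sorted(range(m.shape[0]),
                       key=lambda i: (int(m[i].sum()), tuple(m[i])))
        return SignificantSourceMatrix(matrix=m[order],
                                       channel_order=np.array(order),
                                       thresholds=np.zeros(m.shape[0]))

    def test_zero_matrix_pci_zero_by_convention(self):
        res = pci(self._ss(np.zeros((60, 100))))
        assert res.pci == 0.0 and res.hsrc == 0.0

    def test_random_matrix_calibrated_near_one(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = (rng.uniform(size=(60, 100)) < 0.5).astype(np.int8)
            vals.append(pci(self._ss(m)).pci)
        assert 0.85 <= np.mean(vals) <= 1.10

    def test_compressibility_ordering(self):
        rng = np.random.default_rng(0)
        random_m = (rng.uniform(size=(60, 100)) < 0.5).astype(np.int8)
        single = np.zeros((60, 100), dtype=np.int8)
        single[0, :] = 1
        v_rand = pci(self._ss(random_m)).pci
        v_single = pci(self._ss(single)).pci
        assert v_rand > v_single > 0.0

    def test_flatten_orders_differ_but_both_valid(self):
        rng = np.random.default_rng(1)
        m = (rng.uniform(size=(20, 30)) < 0.3).astype(np.int8)
        ss = self._ss(m)
        res_t = pci(ss, flatten="time-major")
        res_r = pci(ss, flatten="row-major")
        assert res_t.L == res_r.L == 600
        assert res_t.p1 == res_r.p1

    def test_relabeling_invariance_through_sorting(self):
        rng = np.random.default_rng(2)
        m = (rng.uniform(size=(30, 50)) < 0.2).astype(np.int8)
        perm = rng.permutation(30)
        assert pci(self._ss(m)).pci == pci(self._ss(m[perm])).pci


class TestPciLfp:
    def test_zero_signal_gives_zero_pci(self):
        from meacomplex import AnalogSignalSet
        onsets = 2.0 + 5.0 * np.arange(10)
        sig = AnalogSignalSet(np.zeros((4, int(60 * 1000))), 1000.0,
                              kind="lfp")
        stim = StimulationRecord(site=0, onsets=onsets)
        res, ss = pci_lfp(sig, stim, seed=0)
        assert res.pci == 0.0

    def test_deterministic_wave_less_complex_than_shuffled(self):
        from meacomplex import AnalogSignalSet
        rng = np.random.default_rng(3)
        onsets = 2.0 + 5.0 * np.arange(30)
        n = int((onsets[-1] + 2.0) * 1000)
        x = rng.standard_normal((8, n)) * 0.5
        wave = 40.0 * np.hanning(300)
        for o in onsets:
            i = int(o * 1000)
            x[0, i + 20:i + 320] += wave  # single strongly driven channel
        sig = AnalogSignalSet(x, 1000.0, kind="lfp")
        stim = StimulationRecord(site=0, onsets=onsets)
        res, ss = pci_lfp(sig, stim, seed=0)
        # surrogate: shuffle the significant activations in space and time
        m = ss.matrix
        flat = m.ravel().copy()
        rng.shuffle(flat)
        shuffled = flat.reshape(m.shape)
        order = sorted(range(m.shape[0]),
                       key=lambda i: (int(shuffled[i].sum()),
                                      tuple(shuffled[i])))
        ss_shuf = SignificantSourceMatrix(matrix=shuffled[order],
                                          channel_order=np.array(order),
                                          thresholds=ss.thresholds)
        assert pci(ss_shuf).pci > res.pci
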