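"""Stimulus-specific information: exact anchors, brute-force oracle,
bias correction, sparsity index, coupling."""

import numpy as np
import pytest

import callcode as cc
from callcode.information import (InfoConfig, SSIResult, bias_corrected_issi,
                                  bin_starts, binned_psth,
                                  mi_sparsity_and_coupling,
                                  mutual_information,
                                  stimulus_specific_information, symbolize)
from conftest import poisson_raster


def brute_force_issi(counts, prior):
    """Independent enumeration of the information decomposition for one bin.

    counts: (n_stim, n_trials) integer table.
    """
    n_stim, n_trials = counts.shape
    responses = sorted(set(counts.ravel().tolist()))
    p_stim = np.asarray(prior, dtype=float)
    h_total = -sum(p * np.log2(p) for p in p_stim if p > 0)
    issi = np.zeros(n_stim)
    for s in range(n_stim):
        for resp in responses:
            p_r_given_s = np.mean(counts[s] == resp)
            if p_r_given_s == 0:
                continue
            p_r = sum(p_stim[s2] * np.mean(counts[s2] == resp)
                      for s2 in range(n_stim))
            h_cond = 0.0
            for s2 in range(n_stim):
                p_s2_given_r = (p_stim[s2] * np.mean(counts[s2] == resp)) / p_r
                if p_s2_given_r > 0:
                    h_cond -= p_s2_given_r * np.log2(p_s2_given_r)
            issi[s] += p_r_given_s * (h_total - h_cond)
    return issi


class TestRawSSI:
    def test_sixteen_unique_symbols_give_four_bits(self):
        """A neuron whose response uniquely identifies each of 16
        equiprobable stimuli carries exactly 4 bits."""
        symbols = np.tile(np.arange(16)[:, None, None], (1, 10, 2))
        issi = stimulus_specific_information(symbols)
        assert np.allclose(issi, 4.0)
        assert np.allclose(mutual_information(issi), 4.0)

    def test_identical_distributions_give_zero(self):
        symbols = np.ones((16, 10, 3), dtype=int)
        issi = stimulus_specific_information(symbols)
        assert np.allclose(issi, 0.0)

    def test_two_stimulus_brute_force_oracle(self):
        counts = np.array([[0, 0, 1], [1, 1, 1]])
        symbols = counts[:, :, None]
        prior = np.array([0.5, 0.5])
        issi = stimulus_specific_information(symbols, prior)[:, 0]
        expected = brute_force_issi(counts, prior)
        assert np.allclose(issi, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 3, size=(3, 4))
        symbols = counts[:, :, None]
        prior = np.full(3, 1 / 3)
        issi = stimulus_specific_information(symbols, prior)[:, 0]
        assert np.allclose(issi, brute_force_issi(counts, prior), atol=1e-12)

    def test_mi_identity_and_bounds(self):
        rng = np.random.default_rng(5)
        symbols = rng.integers(0, 4, size=(8, 10, 6))
        issi = stimulus_specific_information(symbols)
        mi = mutual_information(issi)
        assert np.allclose(mi, issi.mean(axis=0))  # uniform prior identity
        assert np.all(mi >= -1e-12)
        assert np.all(mi <= 3.0 + 1e-12)  # log2(8)

    def test_merging_symbols_never_increases_mi(self):
        """Data-processing sanity: collapsing response symbols can only
        lose information."""
        rng = np.random.default_rng(11)
        symbols = rng.integers(0, 6, size=(4, 8, 5))
        merged = symbols // 2
        mi_full = mutual_information(stimulus_specific_information(symbols))
        mi_merged = mutual_information(stimulus_specific_information(merged))
        assert np.all(mi_merged <= mi_full + 1e-12)

    def test_single_stimulus_rejected(self):
        with pytest.raises(ValueError):
            stimulus_specific_information(np.zeros((1, 10, 3), dtype=int))


class TestSymbolize:
    def test_bin_count_follows_slide_rule(self):
        cfg = InfoConfig(window_ms=100.0)
        # span 1507 ms, window 100, slide 50 -> floor((1507-100)/50) + 1 = 29
        assert len(bin_starts(cfg)) == 29
        cfg14 = InfoConfig(window_ms=14.0)
        assert len(bin_starts(cfg14)) == int((1507 - 14) // 7) + 1

    def test_single_spike_lands_in_covering_bins(self):
        durations = {"s-0": 1.0, "s-1": 1.0}
        spikes = {}
        for sid in durations:
            for k in range(10):
                spikes[(sid, k)] = (np.array([0.130]) if sid == "s-0"
                                    else np.empty(0))
        raster = cc.TrialRaster("n", spikes, durations)
        cfg = InfoConfig(window_ms=100.0)
        counts = symbolize(raster, cfg)
        starts = bin_starts(cfg)
        covering = (starts <= 0.130) & (0.130 < starts + 0.1)
        assert np.all(counts[0, :, covering] == 1)
        assert np.all(counts[0, :, ~covering] == 0)
        assert counts[1].sum() == 0

    def test_empty_raster_all_zero(self):
        durations = {"s-0": 1.0, "s-1": 1.0}
        spikes = {(sid, k): np.empty(0) for sid in durations
                  for k in range(10)}
        raster = cc.TrialRaster("n", spikes, durations)
        assert symbolize(raster).sum() == 0

    def test_missing_trial_rejected(self):
        durations = {"s-0": 1.0}
        spikes = {("s-0", k): np.empty(0) for k in range(9)}
        raster = cc.TrialRaster("n", spikes, durations, n_trials=10)
        with pytest.raises(ValueError):
            symbolize(raster)


class TestBiasCorrection:
    def test_null_calibration(self):
        """Stimulus-independent responses: bias-corrected MI ~ 0."""
        durations = {f"s-{i}": 1.0 for i in range(16)}
        raster = poisson_raster(lambda sid: [(0.0, 2.0, 5.0)], durations,
                                seed=3)
        symbols = symbolize(raster)
        res = bias_corrected_issi(symbols, n_shuffles=100, seed=1)
        assert abs(res.mi.mean()) < 0.05

    def test_correction_reduces_deterministic_mi(self):
        symbols = np.tile(np.arange(16)[:, None, None], (1, 10, 2))
        res = bias_corrected_issi(symbols, n_shuffles=50, seed=0)
        assert np.all(res.mi < res.mi_raw)
        assert np.allclose(res.mi_raw, 4.0)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        symbols = rng.integers(0, 3, size=(4, 10, 5))
        a = bias_corrected_issi(symbols, n_shuffles=20, seed=7)
        b = bias_corrected_issi(symbols, n_shuffles=20, seed=7)
        assert np.array_equal(a.issi, b.issi)

    def test_shuffle_count_validated(self):
        with pytest.raises(ValueError):
            bias_corrected_issi(np.zeros((2, 5, 2), dtype=int), n_shuffles=0)


class TestSparsityAndCoupling:
    @staticmethod
    def make_result(issi, mi=None):
        issi = np.asarray(issi, dtype=float)
        return SSIResult(issi=issi, mi=issi.mean(axis=0) if mi is None
                         else np.asarray(mi), issi_raw=issi,
                         mi_raw=issi.mean(axis=0), bias=np.zeros_like(issi),
                         bin_starts=np.arange(issi.shape[1]))

    def test_concentrated_issi_high_kurtosis(self):
        rng = np.random.default_rng(0)
        n_bins = 20
        conc = 0.01 * rng.uniform(size=(16, n_bins))
        conc[0, :5] = 3.0  # one informative stimulus in the high-MI bins
        res = self.make_result(conc)
        psth = np.abs(conc) + 0.1
        mi_sparsity_and_coupling(res, psth)
        assert res.si_mi > 5.0
        spread = rng.normal(1.0, 0.2, size=(16, n_bins))
        spread[:, :5] += 3.0
        res2 = self.make_result(spread)
        mi_sparsity_and_coupling(res2, np.abs(spread) + 0.1)
        assert abs(res2.si_mi) < 2.0
        assert res.si_mi > res2.si_mi

    def test_proportional_issi_psth(self):
        rng = np.random.default_rng(4)
        psth = rng.uniform(0, 5, size=(8, 15))
        res = self.make_result(0.37 * psth)
        mi_sparsity_and_coupling(res, psth)
        assert res.issi_psth_corr == pytest.approx(1.0)
        assert res.issi_psth_slope == pytest.approx(0.37)

    def test_no_high_mi_bins_flagged(self):
        res = self.make_result(np.ones((4, 6)))
        mi_sparsity_and_coupling(res, np.ones((4, 6)))
        assert np.isnan(res.si_mi)

    def test_zero_psth_variance_flagged(self):
        rng = np.random.default_rng(1)
        res = self.make_result(rng.uniform(size=(4, 8)))
        mi_sparsity_and_coupling(res, np.ones((4, 8)))
        assert np.isnan(res.issi_psth_corr)


def test_stage_slope_ordering(call_library, cochleagrams):
    """Superficial-layer-like neurons convey more information per spike:
    median I_SSI-PSTH slope above the granular-layer median."""
    pop = cc.generate_population(8, seed=17, calls=call_library)
    slopes = {"L4-like": [], "L2/3-like": []}
    rng = np.random.default_rng(17)
    for n in pop:
        if n.stage not in slopes:
            continue
        raster = cc.simulate_raster(n, cochleagrams, 10,
                                    int(rng.integers(2**31)))
        si = cc.StimulusInformation(n_shuffles=50, random_state=1).fit(raster)
        if np.isfinite(si.psth_slope_):
            slopes[n.stage].append(si.psth_slope_)
    assert np.median(slopes["L2/3-like"]) > np.median(slopes["L4-like"])


def test_estimator_interface(cochleagrams, population):
    raster = cc.simulate_raster(population[6], cochleagrams, 10, seed=1)
    est = cc.StimulusInformation(window_ms=200.0, n_shuffles=20,
                                 random_state=5)
    assert est.get_params()["window_ms"] == 200.0
    est.fit(raster)
    assert est.issi_.shape[0] == 16
    assert est.mi_.shape == (est.issi_.shape[1],)
    assert est.high_mi_bins_.dtype == bool
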