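"""Spectral metrics: epoch spectra, reference, binning, TPF, TDW."""

import numpy as np
import pytest

from somnokit.records import EpochSpectra, NREM, ProtocolMeta, REM, WAKE
from somnokit.spectral import (
    band_power,
    classify_tdw,
    delta_timecourse,
    epoch_spectra,
    normalize_spectra,
    spectral_reference,
    theta_peak_frequency,
    wake_theta_ratio,
)

from conftest import make_hypnogram


class TestEpochSpectra:
    def test_pure_sine_peaks_at_its_frequency(self):
        fs, f0 = 200.0, 8.0
        t = np.arange(int(fs * 40)) / fs  # 10 epochs
        sp = epoch_spectra(np.sin(2 * np.pi * f0 * t), fs)
        assert sp.power.shape == (10, 401)
        assert (sp.freqs[np.argmax(sp.power, axis=1)] == f0).all()

    def test_grid_is_401_bins_at_quarter_hz(self):
        sp = epoch_spectra(np.random.default_rng(0).normal(size=1600), 200.0)
        assert len(sp.freqs) == 401
        assert sp.freqs[1] - sp.freqs[0] == 0.25
        assert sp.freqs[-1] == 100.0

    def test_white_noise_flat_spectrum(self):
        """Mean white-noise spectrum is flat within 5% (Monte Carlo against
        the analytic flat expectation; window-leakage edge bins excluded)."""
        rng = np.random.default_rng(1)
        sp = epoch_spectra(rng.normal(size=800 * 1000), 200.0)
        mean = sp.power.mean(axis=0)[3:-3]
        dev = np.abs(mean / mean.mean() - 1.0)
        assert dev.mean() < 0.05
        assert np.percentile(dev, 95) < 0.08

    def test_non_integer_epoch_sampling_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            epoch_spectra(np.zeros(100), fs=33.3, epoch_s=4.0)


def _flat_spectra(n_epochs, level=1.0, freqs=None):
    if freqs is None:
        freqs = np.arange(401) * 0.25
    power = np.full((n_epochs, len(freqs)), float(level))
    return EpochSpectra(freqs=freqs, power=power)


class TestReference:
    def test_uniform_power_reference(self):
        hyp = make_hypnogram(
            list("WNR") * 14400, protocol=ProtocolMeta(n_days=2, sd_day=None)
        )
        sp = _flat_spectra(hyp.n_epochs)
        ref = spectral_reference(sp, hyp)
        n_band = ((sp.freqs >= 0.75) & (sp.freqs <= 45.0)).sum()
        assert ref == pytest.approx(n_band)

    def test_equal_weighting_ignores_prevalence(self):
        """State totals 1, 2, 3 with unequal prevalences -> reference 2."""
        states = ["W"] * 600 + ["N"] * 200 + ["R"] * 100
        hyp = make_hypnogram(states)
        sp = _flat_spectra(hyp.n_epochs)
        scale = {"W": 1.0, "N": 2.0, "R": 3.0}
        for s, f in scale.items():
            sp.power[np.asarray(states) == s] *= f
        n_band = ((sp.freqs >= 0.75) & (sp.freqs <= 45.0)).sum()
        ref = spectral_reference(sp, hyp, baseline=(0.0, 1.0))
        assert ref == pytest.approx(2.0 * n_band)

    def test_normalized_grand_mean_is_100(self):
        states = ["W"] * 600 + ["N"] * 200 + ["R"] * 100
        hyp = make_hypnogram(states)
        sp = _flat_spectra(hyp.n_epochs)
        ref = spectral_reference(sp, hyp, baseline=(0.0, 1.0))
        norm = normalize_spectra(sp, ref)
        band = (norm.freqs >= 0.75) & (norm.freqs <= 45.0)
        totals = norm.power[:, band].sum(axis=1)
        state_means = [totals[np.asarray(states) == s].mean() for s in "WNR"]
        assert np.mean(state_means) == pytest.approx(100.0)

    def test_absent_state_rejected(self):
        hyp = make_hypnogram(["W", "N"] * 450)
        with pytest.raises(ValueError, match="absent"):
            spectral_reference(_flat_spectra(900), hyp, baseline=(0.0, 1.0))


class TestDeltaTimecourse:
    def test_block_bin_counts(self, default_bundle):
        """12 bins per baseline/REC2 light, 8 for REC1 ZT6-12, 6 per dark."""
        tc = delta_timecourse(
            default_bundle.hypnogram, default_bundle.records.traces["delta"].values
        )
        counts = {}
        for b in tc.bins:
            counts[b["interval"]] = counts.get(b["interval"], 0) + 1
        assert counts[(0.0, 12.0)] == 12
        assert counts[(24.0, 36.0)] == 12
        assert counts[(72.0, 84.0)] == 12
        assert counts[(54.0, 60.0)] == 8
        for lo in (12.0, 36.0, 60.0, 84.0):
            assert counts[(lo, lo + 12.0)] == 6
        assert len(tc.bins) == 68

    def test_bin_epoch_counts_within_one(self, default_bundle):
        """Cumulative-count oracle: per-block bin sizes differ by <= 1."""
        tc = delta_timecourse(
            default_bundle.hypnogram, default_bundle.records.traces["delta"].values
        )
        by_block = {}
        for b in tc.bins:
            by_block.setdefault(b["interval"], []).append(b["n_epochs"])
        for ns in by_block.values():
            assert max(ns) - min(ns) <= 1

    def test_conservation_of_nrem_epochs(self, default_bundle):
        hyp = default_bundle.hypnogram
        tc = delta_timecourse(hyp, default_bundle.records.traces["delta"].values)
        binned = sum(b["n_epochs"] for b in tc.bins)
        eligible = hyp.state_mask(NREM, artefact_free=True)
        sd_sl = hyp.window_epochs(48.0, 54.0)
        in_sd = np.zeros(hyp.n_epochs, bool)
        in_sd[sd_sl] = True
        assert binned == (eligible & ~in_sd).sum()

    def test_uniform_nrem_gives_equal_duration_bins(self):
        hyp = make_hypnogram(
            ["N"] * 43200, protocol=ProtocolMeta(n_days=2, sd_day=None)
        )
        delta = np.full(43200, 100.0)
        tc = delta_timecourse(hyp, delta)
        widths = np.diff([b["zt_mid"] for b in tc.bins if b["interval"] == (0.0, 12.0)])
        assert np.allclose(widths, widths[0], atol=1e-6)

    def test_too_few_nrem_epochs_rejected(self):
        states = ["W"] * 10795 + ["N"] * 5 + ["W"] * 10800
        hyp = make_hypnogram(states, protocol=ProtocolMeta(n_days=1, sd_day=None))
        with pytest.raises(ValueError, match="fewer than"):
            delta_timecourse(hyp, np.full(len(states), 100.0),
                             reference_windows=((8.0, 12.0),))


class TestThetaMetrics:
    def _peaked_spectra(self, hyp, peaks):
        freqs = np.arange(401) * 0.25
        power = np.full((hyp.n_epochs, 401), 0.1)
        for i, p in enumerate(peaks):
            if p is not None:
                power[i, int(p / 0.25)] = 10.0
        return EpochSpectra(freqs=freqs, power=power)

    def test_constant_peak(self):
        hyp = make_hypnogram(["R"] * 900)
        sp = self._peaked_spectra(hyp, [7.5] * 900)
        _, mean = theta_peak_frequency(sp, hyp, "REM")
        assert mean == 7.5

    def test_mean_of_two_peaks(self):
        hyp = make_hypnogram(["R"] * 900)
        sp = self._peaked_spectra(hyp, [7.0] * 450 + [9.0] * 450)
        _, mean = theta_peak_frequency(sp, hyp, "REM")
        assert mean == pytest.approx(8.0)

    def test_generator_rem_peak_recovered(self, spectra_bundle):
        """Synthetic REM template peaked at 7.5 Hz: mean TPF within 0.25 Hz."""
        _, mean = theta_peak_frequency(
            spectra_bundle.records.spectra, spectra_bundle.hypnogram, "REM"
        )
        assert abs(mean - 7.5) <= 0.25

    def test_no_qualifying_epochs(self):
        hyp = make_hypnogram(["W"] * 900)
        sp = self._peaked_spectra(hyp, [None] * 900)
        with pytest.raises(ValueError):
            theta_peak_frequency(sp, hyp, "REM")


class TestTdw:
    def test_zero_theta_means_no_tdw(self):
        hyp = make_hypnogram(["W"] * 900)
        freqs = np.arange(401) * 0.25
        power = np.zeros((900, 401))
        power[:, freqs < 4.0] = 1.0  # all power in delta
        sp = EpochSpectra(freqs=freqs, power=power)
        flags, _ = classify_tdw(sp, hyp, threshold=0.5)
        assert not flags.any()

    def test_generator_flags_recovered(self, spectra_bundle):
        """Template-based classification agrees >= 95% with generator truth."""
        hyp = spectra_bundle.hypnogram
        flags, thr = classify_tdw(spectra_bundle.records.spectra, hyp)
        wake = hyp.state_mask(WAKE, artefact_free=True)
        agreement = (flags[wake] == hyp.tdw[wake]).mean()
        assert agreement >= 0.95
        assert 0.0 < thr < 1.0

    def test_threshold_monotonicity(self, spectra_bundle):
        hyp = spectra_bundle.hypnogram
        sp = spectra_bundle.records.spectra
        counts = [
            classify_tdw(sp, hyp, threshold=t)[0].sum()
            for t in (0.1, 0.3, 0.5, 0.7)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_dark_tdw_fraction_in_study_band(self, default_bundle):
        """Dark-phase TDW fraction of waking near 179/512 (as in Table-like
        baseline accounting of the emulated study)."""
        hyp = default_bundle.hypnogram
        zt = hyp.zt_hours() % 24.0
        dark = (zt >= 12.0) & (hyp.zt_hours() < 48.0)
        wake = hyp.states == WAKE
        frac = hyp.tdw[wake & dark].mean()
        assert abs(frac - 179 / 512) < 0.07


class TestBandPower:
    def test_flat_spectrum_returns_level(self):
        sp = _flat_spectra(10, level=3.0)
        assert np.allclose(band_power(sp, (0.75, 4.0)), 3.0)

    def test_single_bin_band(self):
        sp = _flat_spectra(5)
        sp.power[:, 8] = 7.0  # 2.0 Hz bin
        assert np.allclose(band_power(sp, (2.0, 2.0)), 7.0)

    def test_matches_sum_count_oracle(self):
        rng = np.random.default_rng(3)
        sp = EpochSpectra(freqs=np.arange(401) * 0.25, power=rng.uniform(0, 1, (20, 401)))
        band = (0.75, 4.0)
        got = band_power(sp, band)
        m = (sp.freqs >= 0.75) & (sp.freqs <= 4.0)
        oracle = sp.power[:, m].sum(axis=1) / m.sum()
        assert np.allclose(got, oracle)
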