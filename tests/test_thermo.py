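"""Thermometry: calibration identities, QC, transition profiles, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from somnokit.records import ProtocolMeta, SampledTrace
from somnokit.thermo import (
    ThermistorCalibration,
    calibrate,
    mixed_model_compare,
    partial_correlation,
    residual_sine_fit,
    resistance_to_temperature,
    temperature_from_voltage,
    temperature_qc,
    transition_profiles,
    wake_temperature_association,
)

from conftest import make_hypnogram


class TestCalibration:
    def test_beta_direct_evaluation(self):
        # oracle: direct formula, T25*T37/(T25-T37)*ln(R37/R25)
        beta = calibrate(1000.0, 657.2)
        oracle = 298.15 * 310.15 / (298.15 - 310.15) * np.log(657.2 / 1000.0)
        assert beta == pytest.approx(oracle)
        assert beta == pytest.approx(3234.0, abs=1.0)

    def test_equal_resistances_rejected(self):
        with pytest.raises(ValueError):
            calibrate(1000.0, 1000.0)

    def test_beta_scale_invariant(self):
        assert calibrate(1000.0, 600.0) == pytest.approx(calibrate(5000.0, 3000.0))

    @given(
        st.floats(100.0, 1e6),
        st.floats(0.05, 0.95),
    )
    def test_calibration_point_identities(self, r25, ratio):
        """Conversion returns exactly 25/37 degC at the calibration points."""
        cal = ThermistorCalibration(R25=r25, R37=r25 * ratio)
        assert resistance_to_temperature(r25, cal) == pytest.approx(25.0, abs=1e-9)
        assert resistance_to_temperature(cal.R37, cal) == pytest.approx(37.0, abs=1e-9)

    def test_monotone_decreasing_in_resistance(self):
        cal = ThermistorCalibration(R25=1000.0, R37=624.0)
        r = np.geomspace(200.0, 2000.0, 50)
        t = resistance_to_temperature(r, cal)
        assert (np.diff(t) < 0).all()
        mid = resistance_to_temperature(np.sqrt(1000.0 * 624.0), cal)
        assert 25.0 < mid < 37.0

    def test_voltage_path_with_epoch_median(self):
        cal = ThermistorCalibration(R25=1000.0, R37=624.0)
        v = np.full((3, 40), 1000.0 * cal.I_const)  # 3 epochs of 10 Hz samples
        v[:, 0] = 2000.0 * cal.I_const  # outlier sample; median immune
        t = temperature_from_voltage(v, cal, sample_axis=1)
        assert np.allclose(t, 25.0, atol=1e-9)

    def test_nonpositive_voltage_rejected(self):
        cal = ThermistorCalibration(R25=1000.0, R37=624.0)
        with pytest.raises(ValueError):
            temperature_from_voltage(0.0, cal)


class TestTemperatureQc:
    def test_constant_trace_zero_amplitude(self):
        tr = {
            "a": SampledTrace(np.full(54 * 900, 36.0), dt_s=4.0),
            "b": SampledTrace(np.full(54 * 900, 36.5), dt_s=4.0),
        }
        report, _ = temperature_qc(tr)
        assert report.loc["a", "amplitude"] == 0.0

    def test_known_offsets_recovered(self):
        rng = np.random.default_rng(0)
        base = 36.0 + 0.5 * np.sin(np.arange(54 * 900) / 5000.0)
        traces = {
            "ok1": SampledTrace(base.copy(), dt_s=4.0),
            "ok2": SampledTrace(base.copy(), dt_s=4.0),
            "low": SampledTrace(base - 1.0, dt_s=4.0),
        }
        report, corrected = temperature_qc(traces, correct=["low"])
        assert report.loc["low", "offset_applied"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(corrected["low"].values, base, atol=1e-9)

    def test_needs_two_animals(self):
        with pytest.raises(ValueError):
            temperature_qc({"a": SampledTrace(np.full(54 * 900, 36.0), dt_s=4.0)})


class TestTransitionProfiles:
    def test_step_profile_antisymmetric_through_zero(self):
        """Alternating 8-epoch W/N blocks with +-1 degC temperature."""
        states = (["W"] * 8 + ["N"] * 8) * 225  # 4 h
        hyp = make_hypnogram(states)
        temp = np.where(np.asarray(states) == "W", 1.0, -1.0)
        profs = transition_profiles(
            hyp, SampledTrace(temp, dt_s=4.0), min_traces=5
        )
        p = profs["W->N"]
        # anchor = mean(last W, first N) = 0; profile is the step itself
        pre = p.mean_dT[p.times_s < 0]
        post = p.mean_dT[p.times_s >= 0]
        assert np.allclose(pre, 1.0) and np.allclose(post, -1.0)

    def test_seven_epoch_bouts_do_not_qualify(self):
        states = (["W"] * 7 + ["N"] * 7) * 450  # 7 h
        hyp = make_hypnogram(states, protocol=ProtocolMeta(n_days=1, sd_day=None))
        profs = transition_profiles(hyp, SampledTrace(np.zeros(len(states)), dt_s=4.0))
        assert "W->N" not in profs

    def test_truncation_at_min_traces(self, baseline_bundle):
        """Profile points exist exactly where >= 10 traces contribute."""
        profs = transition_profiles(
            baseline_bundle.hypnogram, baseline_bundle.records.traces["temperature"]
        )
        for p in profs.values():
            assert (p.n_traces >= 10).all()
            assert np.abs(p.times_s).max() <= 90.0

    def test_census_in_study_band(self, baseline_bundle):
        """W->N census over 2 baseline days within 50% of the observed 38."""
        profs = transition_profiles(
            baseline_bundle.hypnogram, baseline_bundle.records.traces["temperature"]
        )
        assert abs(profs["W->N"].n_transitions - 38) <= 19

    def test_sign_pattern(self, baseline_bundle):
        """Rise entering REM and wake from NREM; fall entering NREM."""
        profs = transition_profiles(
            baseline_bundle.hypnogram, baseline_bundle.records.traces["temperature"]
        )
        for kind, sign in (("N->R", 1), ("N->W", 1), ("W->N", -1)):
            p = profs[kind]
            late = p.mean_dT[p.times_s >= 60.0]
            assert sign * late.mean() > 0, kind


class TestAssociation:
    def _triplets(self, seed=0, n=96):
        rng = np.random.default_rng(seed)
        wake = rng.uniform(0, 60, n)
        lma = rng.uniform(0, 8, n)
        T = 35 + 0.02 * wake + 0.05 * lma + rng.normal(0, 0.1, n)
        return wake, lma, T

    def test_near_exact_linear_dependence(self):
        """T a linear function of wake (tiny noise): pcor(T,wake|LMA) ~ 1,
        pcor(T,LMA|wake) ~ 0."""
        rng = np.random.default_rng(1)
        wake = rng.uniform(0, 60, 96)
        lma = rng.normal(0, 1, 96)
        T = 30.0 + 0.05 * wake + rng.normal(0, 1e-5, 96)
        out = wake_temperature_association(wake, lma, T)
        assert out["pcor_wake_given_lma"] == pytest.approx(1.0, abs=1e-6)
        assert abs(out["pcor_lma_given_wake"]) < 0.2
        assert out["r2_wake"] == pytest.approx(1.0, abs=1e-6)

    def test_duplicated_predictor_rejected(self):
        wake, _, T = self._triplets()
        with pytest.raises(ValueError, match="collinear|undefined"):
            wake_temperature_association(wake, wake, T)

    def test_matches_residual_regression_oracle(self):
        """Partial correlation equals the two-stage residual oracle."""
        for seed in range(5):
            wake, lma, T = self._triplets(seed)
            got = partial_correlation(T, wake, lma)
            # oracle: correlate OLS residuals of T|lma and wake|lma
            def resid(y, x):
                A = np.column_stack([x, np.ones_like(x)])
                return y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            oracle = np.corrcoef(resid(T, lma), resid(wake, lma))[0, 1]
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        wake, lma, T = self._triplets(7)
        df = pd.DataFrame({"T": T, "wake": wake, "lma": lma})
        ref = pingouin.partial_corr(df, x="T", y="wake", covar="lma")["r"].iloc[0]
        assert partial_correlation(T, wake, lma) == pytest.approx(ref, abs=1e-9)

    def test_translation_invariance(self):
        wake, lma, T = self._triplets(3)
        a = wake_temperature_association(wake, lma, T)
        b = wake_temperature_association(wake, lma, T + 5.0)
        for k in ("r2_wake", "r2_lma", "pcor_wake_given_lma", "pcor_lma_given_wake"):
            assert a[k] == pytest.approx(b[k], abs=1e-9)


class TestResidualSine:
    def test_zero_residuals_zero_amplitude(self):
        out = residual_sine_fit(np.zeros(48))
        assert out["amplitude"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_sine_recovered(self):
        t = np.arange(48.0)
        r = 0.1 + 0.3 * np.sin(2 * np.pi * (t + 7.0) / 24.0)
        out = residual_sine_fit(r, t)
        assert out["amplitude"] == pytest.approx(0.3, abs=1e-9)
        assert out["phase_h"] == pytest.approx(7.0, abs=1e-9)
        assert out["baseline"] == pytest.approx(0.1, abs=1e-9)

    def test_noisy_amplitude_recovery(self):
        """A = 0.3 recovered within 0.05 under sigma = 0.1 noise, 20 seeds."""
        t = np.arange(48.0)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r = 0.3 * np.sin(2 * np.pi * (t + 5.0) / 24.0) + rng.normal(0, 0.1, 48)
            errs.append(abs(residual_sine_fit(r, t)["amplitude"] - 0.3))
        assert np.mean(np.array(errs) <= 0.05) >= 0.8

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            residual_sine_fit(np.zeros(2))


def _mixed_data(seed, interaction=0.0, n_animals=6, n_hours=48):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        intercept = rng.normal(0, 0.3)
        wake = rng.uniform(0, 60, n_hours)
        lpw = rng.uniform(0, 3, n_hours)
        T = (
            36.0
            + intercept
            + 0.02 * wake
            + interaction * wake * lpw
            + rng.normal(0, 0.1, n_hours)
        )
        for w, l, t in zip(wake, lpw, T):
            rows.append({"animal": f"m{a}", "T": t, "wake": w, "lma_per_wake": l})
    return pd.DataFrame(rows)


class TestMixedModels:
    def test_conditional_at_least_marginal(self):
        table = mixed_model_compare(_mixed_data(0))
        assert (table["r2_conditional"] >= table["r2_marginal"] - 1e-12).all()

    def test_wake_only_truth_keeps_model1(self):
        """Under a wake-only truth, Model2 rarely beats Model1 (alpha 0.05)."""
        rejections = 0
        for seed in range(10):
            table = mixed_model_compare(_mixed_data(seed))
            rejections += table.loc["Model2", "p_vs_previous"] < 0.05
        assert rejections <= 2

    def test_interaction_truth_prefers_model3(self):
        hits = 0
        for seed in range(10):
            table = mixed_model_compare(_mixed_data(seed, interaction=0.002))
            hits += table.loc["Model3", "p_vs_previous"] < 0.05
        assert hits >= 9

    def test_needs_two_animals(self):
        df = _mixed_data(0, n_animals=1)
        with pytest.raises(ValueError):
            mixed_model_compare(df)
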