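"""Cortical thermometry: NTC thermistor calibration, temperature QC,
transition-aligned temperature profiles, and the waking/LMA -> temperature
statistical stack (regression, partial correlation, residual sine fit,
nested mixed models).

An NTC thermistor supplied with a constant measuring current I_const
(100 uA) yields the resistance R_t = V / I_const.  The material constant
beta is derived from the manufacturer's calibration resistances at 25 and
37 degC,

    beta = T25 * T37 / (T25 - T37) * ln(R37 / R25)    [Kelvin]

and temperature follows from

    t = [ ln(R_t / R25) / beta + 1 / T25 ]^-1 - 273.15   [degC]

with natural logarithms throughout (required for the conversion to return
exactly 25 and 37 degC at the calibration points).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .records import Hypnogram, NREM, REM, SampledTrace, WAKE

T25_K = 298.15
T37_K = 310.15

#: transition kinds as (state before, state after)
TRANSITION_KINDS = {
    "W->N": (WAKE, NREM),
    "N->R": (NREM, REM),
    "R->W": (REM, WAKE),
    "N->W": (NREM, WAKE),
}


def calibrate(R25: float, R37: float) -> float:
    """Material constant beta (K) from the two calibration resistances."""
    if R25 <= 0 or R37 <= 0:
        raise ValueError("resistances must be positive")
    if R37 >= R25:
        raise ValueError("NTC requires R37 < R25")
    return T25_K * T37_K / (T25_K - T37_K) * np.log(R37 / R25)


@dataclass(frozen=True)
class ThermistorCalibration:
    R25: float
    R37: float
    I_const: float = 1e-4

    def __post_init__(self):
        if self.I_const <= 0:
            raise ValueError("I_const must be positive")
        calibrate(self.R25, self.R37)  # validates resistances

    @property
    def beta(self) -> float:
        return calibrate(self.R25, self.R37)


def resistance_to_temperature(Rt, cal: ThermistorCalibration):
    """Temperature (degC) from thermistor resistance (ohm)."""
    Rt = np.asarray(Rt, float)
    if np.any(Rt <= 0):
        raise ValueError("resistance must be positive")
    inv_t = np.log(Rt / cal.R25) / cal.beta + 1.0 / T25_K
    out = 1.0 / inv_t - 273.15
    return float(out) if out.ndim == 0 else out


def temperature_from_voltage(V, cal: ThermistorCalibration, sample_axis=None):
    """Temperature (degC) from measured voltage (V).

    When ``sample_axis`` is given, ``V`` holds the 10 Hz samples of each
    4-s epoch along that axis and the median resistance per epoch is used.
    """
    V = np.asarray(V, float)
    if np.any(V <= 0):
        raise ValueError("voltage must be positive")
    Rt = V / cal.I_const
    if sample_axis is not None:
        Rt = np.median(Rt, axis=sample_axis)
    return resistance_to_temperature(Rt, cal)


# ---------------------------------------------------------------------------
# temperature QC


def hourly_means(trace: SampledTrace) -> np.ndarray:
    per_h = int(round(3600.0 / trace.dt_s))
    n_h = trace.n // per_h
    return trace.values[: n_h * per_h].reshape(n_h, per_h).mean(axis=1)


def temperature_qc(
    traces: dict[str, SampledTrace],
    baseline_days: Sequence[tuple[float, float]] = ((0.0, 24.0), (24.0, 48.0)),
    sd_window: tuple[float, float] = (48.0, 54.0),
    correct: Optional[Sequence[str]] = None,
    amplitude_outlier_sd: float = 3.0,
) -> tuple[pd.DataFrame, dict[str, SampledTrace]]:
    """Cohort temperature quality control and offset correction.

    Per animal: daily amplitude (mean over baseline days of the difference
    between the highest and lowest hourly mean) and the mean over the SD
    window.  Animals named in ``correct`` are shifted by (cohort SD-window
    mean of the remaining animals - own SD-window mean).  Amplitude
    outliers (beyond ``amplitude_outlier_sd`` cohort SDs) are flagged in
    the report but never dropped automatically.
    """
    if len(traces) < 2:
        raise ValueError("QC needs at least two animals")
    rows = {}
    for name, tr in traces.items():
        hm = hourly_means(tr)
        amps = []
        for lo, hi in baseline_days:
            a, b = int(lo), int(hi)
            if b > len(hm):
                raise ValueError(f"animal {name}: missing hourly coverage")
            day = hm[a:b]
            amps.append(day.max() - day.min())
        per_h = int(round(3600.0 / tr.dt_s))
        sd_mean = tr.values[
            int(sd_window[0] * 3600 / tr.dt_s): int(sd_window[1] * 3600 / tr.dt_s)
        ].mean()
        rows[name] = {"amplitude": float(np.mean(amps)), "sd_window_mean": float(sd_mean)}
    report = pd.DataFrame(rows).T

    amp = report["amplitude"]
    if amp.std(ddof=1) > 0:
        z = (amp - amp.mean()) / amp.std(ddof=1)
    else:
        z = amp * 0.0
    report["amplitude_outlier"] = z.abs() > amplitude_outlier_sd

    corrected = dict(traces)
    correct = list(correct or [])
    if correct:
        others = [n for n in traces if n not in correct]
        if not others:
            raise ValueError("cannot correct every animal at once")
        cohort = report.loc[others, "sd_window_mean"].mean()
        for name in correct:
            offset = cohort - report.loc[name, "sd_window_mean"]
            tr = traces[name]
            corrected[name] = SampledTrace(
                values=tr.values + offset, dt_s=tr.dt_s,
                zt0_index=tr.zt0_index, unit=tr.unit,
            )
            report.loc[name, "offset_applied"] = offset
    if "offset_applied" in report:
        report["offset_applied"] = report["offset_applied"].fillna(0.0)
    else:
        report["offset_applied"] = 0.0
    return report, corrected


# ---------------------------------------------------------------------------
# transition-aligned profiles


@dataclass
class TransitionProfile:
    kind: str
    times_s: np.ndarray  # seconds relative to the transition
    mean_dT: np.ndarray  # degC relative to the transition anchor
    n_traces: np.ndarray
    n_transitions: int


def _find_transitions(
    hyp: Hypnogram, before: str, after: str, min_bout_epochs: int
) -> list[tuple[int, int, int]]:
    """(transition epoch index, pre-bout length, post-bout length) triples.

    The transition index is the first epoch of the post state.  Both
    flanking bouts must last at least ``min_bout_epochs``.
    """
    s = hyp.states
    change = np.flatnonzero(s[1:] != s[:-1]) + 1
    starts = np.concatenate(([0], change))
    lens = np.diff(np.concatenate((starts, [len(s)])))
    out = []
    for k in range(1, len(starts)):
        if s[starts[k - 1]] == before and s[starts[k]] == after:
            if lens[k - 1] >= min_bout_epochs and lens[k] >= min_bout_epochs:
                out.append((int(starts[k]), int(lens[k - 1]), int(lens[k])))
    return out


def transition_profiles(
    hyp: Hypnogram,
    temperature: SampledTrace,
    window: Optional[tuple[float, float]] = None,
    min_bout_epochs: int = 8,
    window_s: float = 90.0,
    min_traces: int = 10,
    kinds: Sequence[str] = tuple(TRANSITION_KINDS),
) -> dict[str, TransitionProfile]:
    """Temperature profiles aligned on consolidated state transitions.

    A transition qualifies when the states immediately before and after it
    each last at least ``min_bout_epochs`` (>32 s).  Each transition's
    trace is temperature relative to the anchor (mean of the last pre- and
    first post-transition epoch), extends at most ``window_s`` each way and
    is truncated at the flanking bouts' ends; profile time points where
    fewer than ``min_traces`` traces contribute are dropped, so sparse
    kinds naturally shorten.  Kinds with no qualifying transitions are
    omitted.
    """
    if abs(temperature.dt_s - hyp.epoch_s) > 1e-9:
        raise ValueError("temperature must be at epoch resolution")
    sl = hyp.window_epochs(*window) if window else slice(0, hyp.n_epochs)
    half = int(window_s / hyp.epoch_s)
    temp = temperature.values
    profiles = {}
    offsets = np.arange(-half, half + 1)
    for kind in kinds:
        before, after = TRANSITION_KINDS[kind]
        trans = [
            t for t in _find_transitions(hyp, before, after, min_bout_epochs)
            if sl.start <= t[0] < sl.stop
        ]
        if not trans:
            continue
        acc = np.zeros(len(offsets))
        cnt = np.zeros(len(offsets), dtype=int)
        for t0, pre_len, post_len in trans:
            anchor = 0.5 * (temp[t0 - 1] + temp[t0])
            lo = max(-min(pre_len, half), -t0)
            hi = min(post_len - 1, half, hyp.n_epochs - 1 - t0)
            ks = np.arange(lo, hi + 1)
            acc[ks + half] += temp[t0 + ks] - anchor
            cnt[ks + half] += 1
        ok = cnt >= min_traces
        if not ok.any():
            continue
        profiles[kind] = TransitionProfile(
            kind=kind,
            times_s=offsets[ok] * hyp.epoch_s,
            mean_dT=acc[ok] / cnt[ok],
            n_traces=cnt[ok],
            n_transitions=len(trans),
        )
    return profiles


# ---------------------------------------------------------------------------
# waking / LMA -> temperature statistics


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial correlation of x and y controlling for z.

    Computed from the pairwise correlations
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); equals the
    correlation of the residuals of x|z and y|z.
    """
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if min(1 - r_xz**2, 1 - r_yz**2) < 1e-12:
        raise ValueError("partial correlation undefined (collinear predictors)")
    den = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if not np.isfinite(den):
        raise ValueError("partial correlation undefined (collinear predictors)")
    return float((r_xy - r_xz * r_yz) / den)


def wake_temperature_association(
    hourly_wake: np.ndarray,
    hourly_lma: np.ndarray,
    hourly_T: np.ndarray,
) -> dict:
    """OLS and partial-correlation decomposition of hourly temperature.

    Inputs are per-hour triplets: waking (min/h), log2-transformed LMA and
    cortical temperature (degC).  Returns R^2 of each single-predictor
    regression, the partial correlations of temperature with each predictor
    controlling the other, per-hour residuals of the wake-only regression,
    and Fisher-Z transforms for cross-animal comparison.
    """
    w = np.asarray(hourly_wake, float)
    l = np.asarray(hourly_lma, float)
    T = np.asarray(hourly_T, float)
    if not (len(w) == len(l) == len(T)) or len(w) < 3:
        raise ValueError("need >= 3 complete hourly triplets")
    for name, v in (("wake", w), ("lma", l)):
        if np.std(v) == 0:
            raise ValueError(f"zero-variance predictor {name}")

    fit_w = scipy.stats.linregress(w, T)
    fit_l = scipy.stats.linregress(l, T)
    residuals = T - (fit_w.intercept + fit_w.slope * w)
    pcor_w = partial_correlation(T, w, l)
    pcor_l = partial_correlation(T, l, w)
    return {
        "r2_wake": float(fit_w.rvalue**2),
        "r2_lma": float(fit_l.rvalue**2),
        "pcor_wake_given_lma": pcor_w,
        "pcor_lma_given_wake": pcor_l,
        "residuals": residuals,
        "fisher_z_wake": float(np.arctanh(np.clip(fit_w.rvalue**2, 0, 1 - 1e-15))),
        "fisher_z_lma": float(np.arctanh(np.clip(fit_l.rvalue**2, 0, 1 - 1e-15))),
    }


def residual_sine_fit(
    residuals: np.ndarray,
    t_hours: Optional[np.ndarray] = None,
    period_h: float = 24.0,
) -> dict:
    """Least-squares sine with non-zero baseline at a fixed 24-h period.

    Fits b + A sin(2 pi (t + phi) / period); A >= 0 and phi normalised to
    [0, period).  Linear in (sin, cos, 1), so solved by ordinary least
    squares.
    """
    r = np.asarray(residuals, float)
    if t_hours is None:
        t_hours = np.arange(len(r), dtype=float)
    t = np.asarray(t_hours, float)
    if len(r) < 3:
        raise ValueError("need at least 3 points for a 3-parameter fit")
    w = 2 * np.pi / period_h
    X = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    (a, b, c), *_ = np.linalg.lstsq(X, r, rcond=None)
    amplitude = float(np.hypot(a, b))
    # a sin + b cos = A sin(w t + delta), delta = atan2(b, a); phi = delta / w
    phase = float((np.arctan2(b, a) / w) % period_h)
    return {"amplitude": amplitude, "phase_h": phase, "baseline": float(c)}


def mixed_model_compare(data: pd.DataFrame) -> pd.DataFrame:
    """Nested mixed-model comparison of hourly cortical temperature.

    ``data`` columns: animal, T, wake, lma_per_wake.  Three linear mixed
    models with a per-animal random intercept are fitted by maximum
    likelihood: Model1 T ~ wake; Model2 adds lma_per_wake; Model3 adds the
    interaction.  Successive models are compared by likelihood-ratio
    chi-squared tests; marginal R^2 (fixed effects only) and conditional
    R^2 (fixed plus random) follow the variance-decomposition convention.
    Singular fits are reported via the 'converged' column, never dropped.
    """
    import statsmodels.formula.api as smf

    required = {"animal", "T", "wake", "lma_per_wake"}
    if not required <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    if data["animal"].nunique() < 2:
        raise ValueError("need >= 2 animals")

    formulas = {
        "Model1": "T ~ wake",
        "Model2": "T ~ wake + lma_per_wake",
        "Model3": "T ~ wake * lma_per_wake",
    }
    rows = []
    prev = None
    for name, f in formulas.items():
        md = smf.mixedlm(f, data, groups=data["animal"])
        fit = md.fit(reml=False)
        var_re = float(fit.cov_re.iloc[0, 0])
        var_resid = float(fit.scale)
        # marginal fitted values: fixed-effect design only
        exog = fit.model.exog
        fixed_pred = exog @ fit.fe_params.to_numpy()
        var_f = float(np.var(fixed_pred, ddof=0))
        denom = var_f + var_re + var_resid
        row = {
            "model": name,
            "formula": f,
            "llf": float(fit.llf),
            "n_params": int(fit.model.exog.shape[1]) + 2,
            "r2_marginal": var_f / denom,
            "r2_conditional": (var_f + var_re) / denom,
            "converged": bool(fit.converged),
        }
        if prev is not None:
            lr = 2.0 * (row["llf"] - prev["llf"])
            df = row["n_params"] - prev["n_params"]
            row["chi2"] = max(lr, 0.0)
            row["df"] = df
            row["p_vs_previous"] = float(scipy.stats.chi2.sf(max(lr, 0.0), df))
        rows.append(row)
        prev = row
    return pd.DataFrame(rows).set_index("model")
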