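"""Synthetic study-bundle generator with known ground truth.

Emulates a 96-h LD 12:12 mouse EEG/temperature/activity recording with a
6-h forced-wake (sleep-deprivation, SD) block at ZT0-6 of day 3:

* a semi-Markov hypnogram (wake <-> NREM with NREM -> REM branching) whose
  per-phase dwell-time mixtures and stationary state fractions reproduce
  typical baseline time-in-state (NREM ~389/189 min, REM ~70/19 min, wake
  ~260/512 min per light/dark 12 h) and whose mostly-brief wake bouts keep
  the count of consolidated (>=8 epochs both sides) wake->NREM transitions
  near the few tens per two baseline days seen in real recordings;
* NREM delta power generated from a known Process S plus multiplicative
  lognormal noise (delta power is positive and heteroscedastic);
* state-templated spectra (delta peak in NREM, theta peaks in REM and
  theta-dominated waking, 1/f background) with lognormal jitter;
* cortical temperature relaxing first-order toward state-specific
  asymptotes plus a locomotor-activity (LMA) coupling, and wake-gated
  per-minute LMA counts;
* a qPCR Ct/efficiency table with known fold changes and reference genes.

Sleep rebound after SD is modelled phenomenologically (a transient shift
of the state-fraction targets toward sleep), keeping the generator
independent of the Process S model under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .records import (
    EpochSpectra,
    Hypnogram,
    NREM,
    ProtocolMeta,
    RecordBundle,
    REM,
    SampledTrace,
    WAKE,
    default_freq_grid,
)
from .process_s import ProcessSParams


@dataclass(frozen=True)
class PhaseBoutParams:
    """Semi-Markov parameters for one lighting phase.

    ``fractions`` are the target stationary time fractions (W, N, R).
    Dwell times are mixtures of geometric distributions, ``(weight,
    mean_epochs)`` pairs; brief-bout components dominate so that the
    >=8-epoch consolidation criterion prunes most transitions, as in real
    sleep.  The N->R branching probability p and the R->W probability q are
    derived from the fractions and mean dwells.
    """

    fractions: tuple[float, float, float]
    wake_dwell: tuple[tuple[float, float], ...]
    nrem_dwell: tuple[tuple[float, float], ...]
    rem_dwell: tuple[tuple[float, float], ...]

    def mean_dwell(self, state: str) -> float:
        mix = {WAKE: self.wake_dwell, NREM: self.nrem_dwell, REM: self.rem_dwell}[state]
        return sum(w * m for w, m in mix)

    def branching(self) -> tuple[float, float]:
        """(p = P(N->R), q = P(R->W)) matching the target fractions."""
        f_w, f_n, f_r = self.fractions
        v_w = f_w / self.mean_dwell(WAKE)
        v_n = f_n / self.mean_dwell(NREM)
        v_r = f_r / self.mean_dwell(REM)
        p = v_r / v_n
        q = (v_w - (1 - p) * v_n) / v_r if v_r > 0 else 1.0
        if not (0 <= p <= 1 and 0 <= q <= 1):
            raise ValueError(
                f"bout parameters imply invalid branching p={p:.3f} q={q:.3f}"
            )
        return p, q


#: light phase: sleep-dominant, many brief awakenings
LIGHT_BOUTS = PhaseBoutParams(
    fractions=(260 / 720, 389 / 720, 70 / 720),
    wake_dwell=((0.88, 2.0), (0.12, 165.0)),
    nrem_dwell=((0.45, 4.0), (0.55, 55.0)),
    rem_dwell=((1.0, 15.0),),
)

#: dark phase: wake-dominant with long active bouts
DARK_BOUTS = PhaseBoutParams(
    fractions=(512 / 720, 189 / 720, 19 / 720),
    wake_dwell=((0.75, 3.0), (0.25, 320.0)),
    nrem_dwell=((0.55, 4.0), (0.45, 50.0)),
    rem_dwell=((1.0, 12.0),),
)

#: first hours after SD: sleep propensity transiently increased
REBOUND_BOUTS = PhaseBoutParams(
    fractions=(0.24, 0.64, 0.12),
    wake_dwell=((0.85, 2.0), (0.15, 95.0)),
    nrem_dwell=((0.35, 4.0), (0.65, 60.0)),
    rem_dwell=((1.0, 17.0),),
)


@dataclass(frozen=True)
class TempParams:
    """First-order relaxation targets (degC) and time constants (s)."""

    asymptote: dict = field(
        default_factory=lambda: {WAKE: 36.7, NREM: 35.8, REM: 36.3}
    )
    tau_s: dict = field(
        default_factory=lambda: {WAKE: 120.0, NREM: 150.0, REM: 60.0}
    )
    lma_coupling: float = 0.09  # degC per count per epoch
    noise_sd: float = 0.01  # degC per 4-s step
    t_init: float = 36.0


@dataclass(frozen=True)
class LmaParams:
    """Per-wake-minute Poisson movement rates (counts/min)."""

    rate_light: float = 0.46
    rate_dark: float = 1.6


@dataclass(frozen=True)
class SpectralTemplates:
    """Per-state mean-spectrum shape parameters on the 0-100 Hz grid."""

    nrem_delta_peak_hz: float = 2.0
    rem_theta_peak_hz: float = 7.5
    tdw_theta_peak_hz: float = 8.1
    peak_width_hz: float = 1.0
    jitter_cv: float = 0.2

    def template(self, kind: str, freqs: np.ndarray) -> np.ndarray:
        background = 1.0 / (1.0 + freqs) ** 1.5
        bump = np.zeros_like(freqs)
        if kind == NREM:
            bump = 8.0 * np.exp(
                -0.5 * ((freqs - self.nrem_delta_peak_hz) / self.peak_width_hz) ** 2
            )
        elif kind == REM:
            bump = 5.0 * np.exp(
                -0.5 * ((freqs - self.rem_theta_peak_hz) / (self.peak_width_hz * 0.5)) ** 2
            )
        elif kind == "TDW":
            bump = 5.0 * np.exp(
                -0.5 * ((freqs - self.tdw_theta_peak_hz) / (self.peak_width_hz * 0.5)) ** 2
            )
        elif kind != WAKE:  # quiet waking: background only
            raise ValueError(f"unknown template kind {kind!r}")
        return background + bump


@dataclass(frozen=True)
class SyntheticStudyConfig:
    seed: int = 0
    protocol: ProtocolMeta = field(default_factory=ProtocolMeta)
    epoch_s: float = 4.0
    light_bouts: PhaseBoutParams = LIGHT_BOUTS
    dark_bouts: PhaseBoutParams = DARK_BOUTS
    rebound_bouts: PhaseBoutParams = REBOUND_BOUTS
    rebound_hours: float = 6.0
    sd_wake_fraction: float = 0.985
    sd_intrusion_mean_epochs: float = 3.0
    tdw_fraction: dict = field(default_factory=lambda: {"light": 45 / 260, "dark": 179 / 512})
    tdw_mean_run_epochs: float = 8.0
    artefact_rate: dict = field(
        default_factory=lambda: {WAKE: 0.07, NREM: 0.021, REM: 0.025}
    )
    true_process_s: ProcessSParams = ProcessSParams(
        tau_i=13.0, tau_d=3.0, UA=290.0, LA=45.0
    )
    delta_noise_cv: float = 0.4
    rem_delta_cv: float = 0.3
    temp_params: TempParams = field(default_factory=TempParams)
    lma_params: LmaParams = field(default_factory=LmaParams)
    spectral_templates: SpectralTemplates = field(default_factory=SpectralTemplates)


# ---------------------------------------------------------------------------
# hypnogram


def _draw_dwell(rng: np.random.Generator, mixture) -> int:
    weights = np.array([w for w, _ in mixture])
    means = [m for _, m in mixture]
    k = rng.choice(len(means), p=weights / weights.sum())
    return int(rng.geometric(1.0 / means[k]))


def generate_hypnogram(cfg: SyntheticStudyConfig) -> Hypnogram:
    """Semi-Markov hypnogram with forced wake during the SD window.

    Bout parameters are those of the phase in force at bout onset; during
    the SD window long wake stretches alternate with brief NREM intrusions
    so that ~98.5% of the window is scored wake; the first
    ``rebound_hours`` after SD use sleep-biased rebound parameters.
    Fully deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    proto = cfg.protocol
    eph = int(round(3600.0 / cfg.epoch_s))
    n_epochs = proto.n_days * 24 * eph

    sd = proto.sd_hours
    sd_a = int(sd[0] * eph) if sd else None
    sd_b = int(sd[1] * eph) if sd else None
    reb_b = int((sd[1] + cfg.rebound_hours) * eph) if sd else None

    def phase_at(epoch: int) -> PhaseBoutParams:
        if sd and sd_b <= epoch < reb_b:
            return cfg.rebound_bouts
        zt = (epoch / eph) % 24.0
        if proto.lights_on_zt <= zt < proto.lights_off_zt:
            return cfg.light_bouts
        return cfg.dark_bouts

    states = np.empty(n_epochs, dtype="U1")
    pos = 0
    current = WAKE
    while pos < n_epochs:
        if sd and sd_a <= pos < sd_b:
            # forced wakefulness with brief sleep intrusions
            wake_mean = cfg.sd_intrusion_mean_epochs * cfg.sd_wake_fraction / (
                1.0 - cfg.sd_wake_fraction
            )
            while pos < sd_b:
                n = min(int(rng.geometric(1.0 / wake_mean)), sd_b - pos)
                states[pos: pos + n] = WAKE
                pos += n
                if pos >= sd_b:
                    break
                n = min(
                    int(rng.geometric(1.0 / cfg.sd_intrusion_mean_epochs)),
                    sd_b - pos,
                )
                states[pos: pos + n] = NREM
                pos += n
            current = WAKE
            continue

        params = phase_at(pos)
        p, q = params.branching()
        mix = {
            WAKE: params.wake_dwell,
            NREM: params.nrem_dwell,
            REM: params.rem_dwell,
        }[current]
        n = _draw_dwell(rng, mix)
        end = min(pos + n, n_epochs)
        if sd and pos < sd_a < end:
            end = sd_a  # truncate at SD onset
        states[pos:end] = current
        pos = end
        if sd and pos == sd_a:
            current = WAKE
            continue
        if current == WAKE:
            current = NREM
        elif current == NREM:
            current = REM if rng.random() < p else WAKE
        else:
            current = WAKE if rng.random() < q else NREM

    # TDW: two-state Markov chain over wake epochs, per-phase stationary target
    tdw = np.zeros(n_epochs, dtype=bool)
    a = 1.0 / cfg.tdw_mean_run_epochs
    zt = (np.arange(n_epochs) / eph) % 24.0
    is_light = (zt >= proto.lights_on_zt) & (zt < proto.lights_off_zt)
    in_tdw = False
    prev_wake = False
    for i in np.flatnonzero(states == WAKE):
        pi = cfg.tdw_fraction["light" if is_light[i] else "dark"]
        b = a * pi / (1.0 - pi)
        if not prev_wake:
            in_tdw = rng.random() < pi
        elif in_tdw:
            in_tdw = rng.random() >= a
        else:
            in_tdw = rng.random() < b
        tdw[i] = in_tdw
        prev_wake = True
        # reset chain when wake is interrupted
        if i + 1 < n_epochs and states[i + 1] != WAKE:
            prev_wake = False

    artefact = np.zeros(n_epochs, dtype=bool)
    for s, rate in cfg.artefact_rate.items():
        m = states == s
        artefact[m] = rng.random(m.sum()) < rate

    return Hypnogram(
        states=states,
        artefact=artefact,
        tdw=tdw,
        epoch_s=cfg.epoch_s,
        protocol=proto,
    )


# ---------------------------------------------------------------------------
# delta power


def _simulate_s_truth(hyp: Hypnogram, p: ProcessSParams) -> np.ndarray:
    """Forward Process S recursion used as generator ground truth.

    Repeated passes over the opening 24 h (starting at ``p.S0``) bring S to
    its baseline steady state, mimicking an animal whose sleep pressure is
    already entrained when the recording starts; the reported trace then
    restarts from that level.  Kept as a simple per-epoch loop, independent
    of the fitting code path.
    """
    r_i = np.exp(-hyp.epoch_s / (p.tau_i * 3600.0))
    r_d = np.exp(-hyp.epoch_s / (p.tau_d * 3600.0))
    n_warm = min(int(round(24 * 3600.0 / hyp.epoch_s)), hyp.n_epochs)

    def run(states, val, out=None):
        for k, st in enumerate(states):
            if st == NREM:
                val = p.LA + (val - p.LA) * r_d
            else:
                val = p.UA - (p.UA - val) * r_i
            if out is not None:
                out[k] = val
        return val

    val = p.S0
    for _ in range(50):
        end = run(hyp.states[:n_warm], val)
        if abs(end - val) < 1e-9:
            val = end
            break
        val = end
    s = np.empty(hyp.n_epochs)
    run(hyp.states, val, out=s)
    return s


def generate_delta_power(
    hyp: Hypnogram,
    true_process_s: ProcessSParams,
    delta_noise_cv: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch NREM delta power from a known Process S.

    ``delta[k] = S[k] * eps`` on non-artefact NREM epochs (NaN elsewhere),
    with eps lognormal, mean 1, coefficient of variation ``delta_noise_cv``.
    Returns (delta values, ground-truth S trace).
    """
    rng = np.random.default_rng(seed)
    s = _simulate_s_truth(hyp, true_process_s)
    delta = np.full(hyp.n_epochs, np.nan)
    m = hyp.state_mask(NREM, artefact_free=True)
    if delta_noise_cv > 0:
        sigma = np.sqrt(np.log1p(delta_noise_cv**2))
        eps = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=m.sum())
    else:
        eps = 1.0
    delta[m] = s[m] * eps
    return delta, s


def generate_rem_delta(
    hyp: Hypnogram,
    la: float,
    cv: float,
    seed: int,
) -> np.ndarray:
    """Delta power on artefact-free REM epochs, centred below LA.

    Emulates the low, narrow REM delta distribution whose intersection
    with the NREM distribution estimates the lower asymptote.
    """
    rng = np.random.default_rng(seed)
    out = np.full(hyp.n_epochs, np.nan)
    m = hyp.state_mask(REM, artefact_free=True)
    sigma = np.sqrt(np.log1p(cv**2))
    out[m] = 0.8 * la * rng.lognormal(-0.5 * sigma**2, sigma, m.sum())
    return out


# ---------------------------------------------------------------------------
# spectra


def generate_spectra(
    hyp: Hypnogram,
    templates: SpectralTemplates,
    seed: int,
    freqs: Optional[np.ndarray] = None,
) -> EpochSpectra:
    """State-templated spectra with per-epoch lognormal jitter.

    Wake epochs flagged TDW receive the theta-peaked waking template.
    """
    rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = default_freq_grid()
    base = {
        NREM: templates.template(NREM, freqs),
        REM: templates.template(REM, freqs),
        WAKE: templates.template(WAKE, freqs),
        "TDW": templates.template("TDW", freqs),
    }
    sigma = np.sqrt(np.log1p(templates.jitter_cv**2))
    power = np.empty((hyp.n_epochs, len(freqs)), dtype=np.float32)
    kinds = hyp.states.copy()
    if hyp.tdw is not None:
        kinds = np.where(hyp.tdw, "T", kinds)
    for code, key in (("W", WAKE), ("N", NREM), ("R", REM), ("T", "TDW")):
        m = kinds == code
        if not m.any():
            continue
        scalar = rng.lognormal(-0.5 * sigma**2, sigma, m.sum())[:, None]
        per_bin = rng.lognormal(
            -0.5 * sigma**2 * 0.25, sigma * 0.5, (m.sum(), len(freqs))
        )
        power[m] = (base[key][None, :] * scalar * per_bin).astype(np.float32)
    return EpochSpectra(freqs=freqs, power=power, normalized=False)


# ---------------------------------------------------------------------------
# temperature and locomotor activity


def generate_temperature_lma(
    hyp: Hypnogram,
    temp_params: TempParams,
    lma_params: LmaParams,
    seed: int,
) -> tuple[SampledTrace, SampledTrace]:
    """Cortical temperature (epoch resolution) and per-minute LMA counts.

    Temperature relaxes first-order toward the current state's asymptote
    plus a term proportional to concurrent LMA; LMA counts are Poisson
    draws gated on the wake fraction of each minute.
    """
    rng = np.random.default_rng(seed)
    eph = hyp.epochs_per_hour
    per_min = int(round(60.0 / hyp.epoch_s))
    n_min = hyp.n_epochs // per_min

    zt = hyp.zt_hours()[::per_min][:n_min] % 24.0
    proto = hyp.protocol
    is_light = (zt >= proto.lights_on_zt) & (zt < proto.lights_off_zt)
    wake_frac = (
        (hyp.states[: n_min * per_min] == WAKE)
        .reshape(n_min, per_min)
        .mean(axis=1)
    )
    rates = np.where(is_light, lma_params.rate_light, lma_params.rate_dark)
    lma = rng.poisson(rates * wake_frac).astype(float)

    lma_per_epoch = np.repeat(lma / per_min, per_min)
    if len(lma_per_epoch) < hyp.n_epochs:
        lma_per_epoch = np.pad(
            lma_per_epoch, (0, hyp.n_epochs - len(lma_per_epoch))
        )

    tp = temp_params
    alpha = {s: 1.0 - np.exp(-hyp.epoch_s / tp.tau_s[s]) for s in tp.tau_s}
    noise = rng.normal(0.0, tp.noise_sd, hyp.n_epochs) if tp.noise_sd > 0 else np.zeros(hyp.n_epochs)
    temp = np.empty(hyp.n_epochs)
    val = tp.t_init
    for k, st in enumerate(hyp.states):
        val = val + alpha[st] * (tp.asymptote[st] - val)
        val += tp.lma_coupling * lma_per_epoch[k] + noise[k]
        temp[k] = val

    return (
        SampledTrace(values=temp, dt_s=hyp.epoch_s, unit="degC"),
        SampledTrace(values=lma, dt_s=60.0, unit="counts"),
    )


# ---------------------------------------------------------------------------
# qPCR


def generate_qpcr_table(
    n_samples: int = 10,
    fold_changes: Optional[dict[str, float]] = None,
    reference_genes: tuple[str, ...] = ("Eef1a2", "Gapdh"),
    efficiency: float = 2.0,
    ct_noise_sd: float = 0.0,
    ext_com_ratio_true: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format Ct/efficiency table with known truth.

    Half the samples are 'treated' and express each target gene at
    ``fold_changes[gene]`` times the control level; reference genes are
    flat.  An ext/com primer pair for gene 'Sfpq' is included with a known
    isoform ratio.  Columns: gene, sample, Ct, E, is_reference.
    """
    rng = np.random.default_rng(seed)
    if fold_changes is None:
        fold_changes = {"Cirbp": 0.5, "Per2": 2.0, "Nr1d1": 1.0}
    if len(reference_genes) < 2:
        raise ValueError("need at least two reference genes")
    rows = []
    samples = [f"s{i:02d}" for i in range(n_samples)]
    treated = {s: i >= n_samples // 2 for i, s in enumerate(samples)}
    base_ct = 24.0
    logE = np.log(efficiency)
    for g in reference_genes:
        for s in samples:
            rows.append((g, s, base_ct + rng.normal(0, ct_noise_sd), efficiency, True))
    for g, fc in fold_changes.items():
        for s in samples:
            # fold change fc in expression => Ct lower by log_E(fc)
            ct = base_ct - (np.log(fc) / logE if treated[s] else 0.0)
            rows.append((g, s, ct + rng.normal(0, ct_noise_sd), efficiency, False))
    # ext/com pair: ratio = E^(Ct_comm - Ct_ext)
    d_ct = np.log(ext_com_ratio_true) / logE
    for s in samples:
        ct_comm = base_ct + rng.normal(0, ct_noise_sd)
        rows.append(("Sfpq_comm", s, ct_comm, efficiency, False))
        rows.append(("Sfpq_ext", s, ct_comm - d_ct + rng.normal(0, ct_noise_sd), efficiency, False))
    return pd.DataFrame(
        rows, columns=["gene", "sample", "Ct", "E", "is_reference"]
    )


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class SyntheticBundle:
    records: RecordBundle
    s_true: np.ndarray
    config: SyntheticStudyConfig

    @property
    def hypnogram(self) -> Hypnogram:
        return self.records.hypnogram


def generate_bundle(
    cfg: SyntheticStudyConfig,
    with_spectra: bool = False,
) -> SyntheticBundle:
    """Full study bundle (hypnogram, delta, temperature, LMA; spectra on
    request) from one seed.  Delta values cover artefact-free NREM epochs
    (Process S plus noise) and REM epochs (near-LA values for asymptote
    estimation)."""
    hyp = generate_hypnogram(cfg)
    seed = cfg.seed
    delta, s_true = generate_delta_power(
        hyp, cfg.true_process_s, cfg.delta_noise_cv, seed=seed + 1
    )
    rem_delta = generate_rem_delta(
        hyp, cfg.true_process_s.LA, cfg.rem_delta_cv, seed=seed + 2
    )
    delta = np.where(np.isfinite(rem_delta), rem_delta, delta)
    temp, lma = generate_temperature_lma(
        hyp, cfg.temp_params, cfg.lma_params, seed=seed + 3
    )
    spectra = None
    if with_spectra:
        spectra = generate_spectra(hyp, cfg.spectral_templates, seed=seed + 4)
    records = RecordBundle(
        hypnogram=hyp,
        traces={
            "delta": SampledTrace(values=delta, dt_s=hyp.epoch_s, unit="uV2"),
            "temperature": temp,
            "lma": lma,
        },
        spectra=spectra,
    )
    return SyntheticBundle(records=records, s_true=s_true, config=cfg)
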