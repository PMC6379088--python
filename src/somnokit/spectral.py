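"""EEG spectral state metrics.

Covers the spectral stages of the pipeline: per-epoch power spectra
(Hamming-windowed DFT, 0-100 Hz at 0.25 Hz), the equal-state-weighted
baseline reference normalization, the NREM delta-power percentile time
course, theta-peak frequency, theta-dominated-waking (TDW) classification
and band power extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import scipy.signal

from .records import (
    EpochSpectra,
    Hypnogram,
    NREM,
    REM,
    SampledTrace,
    STATES,
    WAKE,
)


@dataclass(frozen=True)
class BandSpec:
    """Frequency bands (Hz).  Membership is by bin-center inclusion on the
    closed interval, so 4.0 Hz belongs to delta exactly once."""

    delta: tuple[float, float] = (0.75, 4.0)
    theta_tdw: tuple[float, float] = (6.5, 12.0)
    theta_rem: tuple[float, float] = (5.5, 12.0)
    slow_gamma: tuple[float, float] = (32.0, 45.0)
    fast_gamma: tuple[float, float] = (55.0, 80.0)
    reference_total: tuple[float, float] = (0.75, 45.0)


DEFAULT_BANDS = BandSpec()


@dataclass
class DeltaTimecourse:
    """NREM delta power averaged within equal-NREM-time percentile bins.

    ``bins`` is a list of dicts with keys ``zt_mid`` (epoch-weighted
    midpoint, hours), ``mean_delta`` (% of reference), ``n_epochs`` and
    ``interval`` (ZT span of the parent block).  ``epoch_bin_ids`` maps
    every hypnogram epoch to its bin (-1 = not binned) so that a fit can
    average simulated S over exactly the epochs behind each observation.
    """

    bins: list[dict]
    reference_value: float
    epoch_bin_ids: Optional[np.ndarray] = None

    @property
    def values(self) -> np.ndarray:
        return np.array([b["mean_delta"] for b in self.bins])

    @property
    def times(self) -> np.ndarray:
        return np.array([b["zt_mid"] for b in self.bins])


# ---------------------------------------------------------------------------
# spectra from raw signal


def epoch_spectra(signal: np.ndarray, fs: float, epoch_s: float = 4.0) -> EpochSpectra:
    """Per-epoch power spectra of a raw EEG signal.

    Each consecutive ``epoch_s`` block is Hamming-windowed and Fourier
    transformed; with 800 samples at 200 Hz this yields 401 bins on the
    0-100 Hz grid at 0.25 Hz resolution.
    """
    n_per = fs * epoch_s
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("fs * epoch_s must be an integer sample count")
    n_per = int(round(n_per))
    signal = np.asarray(signal, float)
    n_epochs = len(signal) // n_per
    blocks = signal[: n_epochs * n_per].reshape(n_epochs, n_per)
    freqs, power = scipy.signal.periodogram(
        blocks, fs=fs, window="hamming", axis=1, detrend=False
    )
    return EpochSpectra(freqs=freqs, power=power, normalized=False)


# ---------------------------------------------------------------------------
# reference normalization


def _total_power(spectra: EpochSpectra, band: tuple[float, float]) -> np.ndarray:
    mask = spectra.band_slice(*band)
    return spectra.power[:, mask].sum(axis=1)


def spectral_reference(
    spectra: EpochSpectra,
    hyp: Hypnogram,
    baseline: tuple[float, float] = (0.0, 48.0),
    band: tuple[float, float] = DEFAULT_BANDS.reference_total,
) -> float:
    """Equal-state-weighted baseline reference for EEG normalization.

    Total power (0.75-45 Hz) is averaged over the artefact-free epochs of
    each vigilance state within the 48-h baseline, and the reference is the
    unweighted mean of the three state means, so every state contributes
    equally regardless of its prevalence.
    """
    sl = hyp.window_epochs(*baseline)
    totals = _total_power(spectra, band)[sl]
    art = hyp.artefact[sl]
    states = hyp.states[sl]
    state_means = []
    for s in STATES:
        m = (states == s) & ~art
        if not m.any():
            raise ValueError(f"state {s!r} absent from baseline window")
        state_means.append(totals[m].mean())
    return float(np.mean(state_means))


def normalize_spectra(spectra: EpochSpectra, reference: float) -> EpochSpectra:
    """Express spectra in % of the reference value."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return EpochSpectra(
        freqs=spectra.freqs,
        power=spectra.power / reference * 100.0,
        normalized=True,
    )


def band_power(
    spectra: EpochSpectra, band: tuple[float, float]
) -> np.ndarray:
    """Mean power density per epoch over the closed band [lo, hi]."""
    mask = spectra.band_slice(*band)
    return spectra.power[:, mask].mean(axis=1)


# ---------------------------------------------------------------------------
# delta-power percentile time course


def _delta_blocks(hyp: Hypnogram) -> list[dict]:
    """Recording blocks and their percentile-bin counts.

    Light periods get 12 bins, dark periods 6; on the SD day the light
    period is the post-SD remainder (ZT6-12) with 8 bins, and NREM epochs
    inside the SD window are not binned.
    """
    proto = hyp.protocol
    blocks = []
    for d in range(proto.n_days):
        day = d + 1
        base = 24.0 * d
        lo_l, hi_l = base + proto.lights_on_zt, base + proto.lights_off_zt
        if proto.sd_day == day:
            sd_lo, sd_hi = proto.sd_hours
            lo_eff = max(lo_l, sd_hi)
            blocks.append({"interval": (lo_eff, hi_l), "n_bins": 8})
        else:
            blocks.append({"interval": (lo_l, hi_l), "n_bins": 12})
        blocks.append({"interval": (hi_l, base + 24.0), "n_bins": 6})
    return blocks


def assign_delta_bins(
    hyp: Hypnogram,
    blocks: Optional[list[dict]] = None,
) -> tuple[np.ndarray, list[dict]]:
    """Assign artefact-free NREM epochs to equal-count percentile bins.

    Within each block, bin boundaries are placed so that each bin holds an
    equal number (+/-1) of artefact-free NREM epochs; bin timing therefore
    follows the prevalence of NREM sleep.  Returns the per-epoch bin id
    (-1 = unbinned) and per-bin metadata.
    """
    if blocks is None:
        blocks = _delta_blocks(hyp)
    bin_ids = np.full(hyp.n_epochs, -1, dtype=int)
    meta = []
    mids = hyp.zt_hours(mid=True)
    eligible = hyp.state_mask(NREM, artefact_free=True)
    next_id = 0
    for blk in blocks:
        sl = hyp.window_epochs(*blk["interval"])
        idx = np.flatnonzero(eligible[sl]) + sl.start
        n_bins = blk["n_bins"]
        if len(idx) < n_bins:
            raise ValueError(
                f"block {blk['interval']} has {len(idx)} NREM epochs, "
                f"fewer than {n_bins} bins"
            )
        for part in np.array_split(idx, n_bins):
            bin_ids[part] = next_id
            meta.append(
                {
                    "zt_mid": float(mids[part].mean()),
                    "n_epochs": int(len(part)),
                    "interval": blk["interval"],
                }
            )
            next_id += 1
    return bin_ids, meta


def delta_timecourse(
    hyp: Hypnogram,
    delta: Union[np.ndarray, SampledTrace],
    blocks: Optional[list[dict]] = None,
    reference_windows: Sequence[tuple[float, float]] = ((8.0, 12.0), (32.0, 36.0)),
) -> DeltaTimecourse:
    """Build the NREM delta-power percentile time course.

    ``delta`` holds per-epoch delta power (NaN outside NREM).  Bin values
    are expressed in % of the reference: the mean delta power over the
    artefact-free NREM epochs in the last 4 h of the two main baseline rest
    periods (ZT8-12), where delta power is lowest and least influenced by
    prior sleep-wake history.
    """
    if isinstance(delta, SampledTrace):
        if abs(delta.dt_s - hyp.epoch_s) > 1e-9:
            raise ValueError("delta trace must be at epoch resolution")
        delta = delta.values
    delta = np.asarray(delta, float)
    if len(delta) != hyp.n_epochs:
        raise ValueError("delta length must equal hypnogram epoch count")

    eligible = hyp.state_mask(NREM, artefact_free=True) & np.isfinite(delta)
    ref_vals = []
    for lo, hi in reference_windows:
        sl = hyp.window_epochs(lo, hi)
        m = eligible[sl]
        if not m.any():
            raise ValueError(f"no NREM delta values in reference window [{lo},{hi})")
        ref_vals.append(delta[sl][m])
    reference = float(np.concatenate(ref_vals).mean())

    bin_ids, meta = assign_delta_bins(hyp, blocks=blocks)
    # a binned epoch lacking a finite delta value is dropped from the mean
    bins = []
    for i, b in enumerate(meta):
        m = (bin_ids == i) & np.isfinite(delta)
        if not m.any():
            raise ValueError(f"bin {i} has no finite delta values")
        bins.append(dict(b, mean_delta=float(delta[m].mean() / reference * 100.0)))
    return DeltaTimecourse(
        bins=bins, reference_value=reference, epoch_bin_ids=bin_ids
    )


# ---------------------------------------------------------------------------
# theta metrics


def theta_peak_frequency(
    spectra: EpochSpectra,
    hyp: Hypnogram,
    state: str = "REM",
    bands: BandSpec = DEFAULT_BANDS,
) -> tuple[np.ndarray, float]:
    """Per-epoch theta-peak frequency and its mean over the recording.

    The peak is the argmax of power density within the state's theta band:
    6.5-12 Hz for theta-dominated waking ('TDW'), 5.5-12 Hz for REM sleep.
    Only artefact-free epochs of the state qualify.
    """
    if state == "TDW":
        if hyp.tdw is None:
            raise ValueError("hypnogram carries no TDW flags")
        m = hyp.tdw & ~hyp.artefact
        band = bands.theta_tdw
    elif state == REM or state == "REM":
        m = hyp.state_mask(REM, artefact_free=True)
        band = bands.theta_rem
    else:
        raise ValueError("state must be 'TDW' or 'REM'")
    if not m.any():
        raise ValueError(f"no artefact-free {state} epochs")
    mask = spectra.band_slice(*band)
    sub = spectra.power[np.ix_(m, mask)]
    peak_f = spectra.freqs[mask][np.argmax(sub, axis=1)]
    return peak_f, float(peak_f.mean())


def wake_theta_ratio(
    spectra: EpochSpectra,
    hyp: Hypnogram,
    bands: BandSpec = DEFAULT_BANDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Theta (6.5-12 Hz) to overall (0.75-45 Hz) power ratio of artefact-free
    wake epochs.  Returns (wake epoch indices, ratios)."""
    m = hyp.state_mask(WAKE, artefact_free=True)
    if not m.any():
        raise ValueError("no artefact-free wake epochs")
    theta = spectra.power[:, spectra.band_slice(*bands.theta_tdw)].sum(axis=1)
    total = spectra.power[:, spectra.band_slice(*bands.reference_total)].sum(axis=1)
    idx = np.flatnonzero(m)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = theta[idx] / total[idx]
    return idx, ratios


def tdw_threshold_from_ratios(ratios: np.ndarray, random_state: int = 0) -> float:
    """Bimodal split of the wake theta-ratio distribution.

    A two-component Gaussian mixture is fitted to the ratios; the threshold
    is the equal-posterior point between the component means (the valley of
    the bimodal histogram).
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(ratios, float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=random_state).fit(x)
    lo, hi = np.sort(gm.means_.ravel())
    grid = np.linspace(lo, hi, 2001).reshape(-1, 1)
    post = gm.predict_proba(grid)
    low_comp = int(np.argmin(gm.means_.ravel()))
    crossing = np.flatnonzero(post[:, low_comp] < 0.5)
    if len(crossing) == 0:
        return float(0.5 * (lo + hi))
    return float(grid[crossing[0], 0])


def classify_tdw(
    spectra: EpochSpectra,
    hyp: Hypnogram,
    threshold: Optional[float] = None,
    bands: BandSpec = DEFAULT_BANDS,
) -> tuple[np.ndarray, float]:
    """Flag theta-dominated waking epochs.

    A wake epoch is TDW when its theta-band (6.5-12 Hz) power exceeds
    ``threshold`` times its overall (0.75-45 Hz) power.  When no threshold
    is given it is derived from the bimodal wake ratio distribution.
    Returns a full-length boolean array (False off wake) and the threshold.
    """
    idx, ratios = wake_theta_ratio(spectra, hyp, bands)
    if threshold is None:
        threshold = tdw_threshold_from_ratios(ratios)
    flags = np.zeros(hyp.n_epochs, dtype=bool)
    flags[idx] = ratios > threshold
    return flags, float(threshold)
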