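"""Recovery-versus-baseline sleep accounting, LMA-per-waking time courses
and robust (MAD-based) outlier screening."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .records import Hypnogram, SampledTrace, STATES, WAKE, minutes_in_state

#: consistency constant making 1.4826*MAD estimate sigma for normal data
MAD_SCALE = 1.4826


@dataclass
class AccumulationCurve:
    """Cumulative recovery - baseline difference in state time.

    ``times_h`` are hours since the end of sleep deprivation; ``cum_diff``
    is in minutes, zero at t = 0.
    """

    state: str
    times_h: np.ndarray
    cum_diff: np.ndarray


def accumulated_difference(
    hyp: Hypnogram,
    state: str,
    baseline: Union[str, int] = "matched",
    recovery_span: Optional[tuple[float, float]] = None,
) -> AccumulationCurve:
    """Accumulated recovery-baseline difference in time spent in a state.

    Per 1-h interval from the end of SD, minutes in ``state`` during
    recovery minus minutes in the clock-matched baseline hour, cumulatively
    summed.  ``baseline='matched'`` pairs each recovery hour with the same
    clock hour two days earlier (REC1 vs BL1, REC2 vs BL2);
    ``baseline='mean'`` uses the mean of both baseline days; an integer
    selects one baseline day (1-based) for all recovery hours.
    """
    proto = hyp.protocol
    if proto.sd_day is None:
        raise ValueError("protocol has no sleep-deprivation day")
    sd_lo, sd_hi = proto.sd_hours
    if recovery_span is None:
        recovery_span = (sd_hi, hyp.duration_h)
    lo, hi = recovery_span
    if lo < sd_hi - 1e-9 or hi > hyp.duration_h + 1e-9:
        raise ValueError("recovery span misaligned with the protocol")
    n_h = int(round(hi - lo))

    def baseline_hour(rec_h: float) -> list[float]:
        clock = rec_h % 24.0
        day_offset = int(rec_h // 24.0) - (proto.sd_day - 1)
        if baseline == "matched":
            bl_day = min(day_offset + 1, proto.sd_day - 1)  # 1-based
            return [24.0 * (bl_day - 1) + clock]
        if baseline == "mean":
            return [24.0 * d + clock for d in range(proto.sd_day - 1)]
        return [24.0 * (int(baseline) - 1) + clock]

    diffs = np.empty(n_h)
    for k in range(n_h):
        rec_lo = lo + k
        rec_min = minutes_in_state(hyp, state, (rec_lo, rec_lo + 1.0))
        bl = baseline_hour(rec_lo)
        bl_min = np.mean(
            [minutes_in_state(hyp, state, (b, b + 1.0)) for b in bl]
        )
        diffs[k] = rec_min - bl_min
    return AccumulationCurve(
        state=state,
        times_h=np.arange(n_h + 1, dtype=float),
        cum_diff=np.concatenate(([0.0], np.cumsum(diffs))),
    )


def _lma_blocks(hyp: Hypnogram) -> list[dict]:
    """Blocks and bin counts for the LMA-per-unit-waking time course:
    light 6, dark 12, SD window 6, post-SD remainder of that light phase 3.
    """
    proto = hyp.protocol
    blocks = []
    for d in range(proto.n_days):
        day = d + 1
        base = 24.0 * d
        lo_l, hi_l = base + proto.lights_on_zt, base + proto.lights_off_zt
        if proto.sd_day == day:
            sd_lo, sd_hi = proto.sd_hours
            blocks.append({"interval": (sd_lo, sd_hi), "n_bins": 6})
            if sd_hi < hi_l:
                blocks.append({"interval": (sd_hi, hi_l), "n_bins": 3})
        else:
            blocks.append({"interval": (lo_l, hi_l), "n_bins": 6})
        blocks.append({"interval": (hi_l, base + 24.0), "n_bins": 12})
    return blocks


def lma_per_waking_timecourse(
    hyp: Hypnogram,
    lma: SampledTrace,
    blocks: Optional[list[dict]] = None,
) -> list[dict]:
    """Locomotor activity per unit of time awake, in equal-waking bins.

    Within each block, bin boundaries are placed on the cumulative-waking
    axis so that each bin receives an equal share of the block's waking
    time; a minute straddling a boundary is apportioned pro rata (waking
    time and movement counts alike), so bins are equal to float precision.
    The bin value is total movements divided by waking minutes.  LMA
    accrued during sleep minutes carries zero waking weight by
    construction.
    """
    if abs(lma.dt_s - 60.0) > 1e-9:
        raise ValueError("LMA trace must be per minute")
    per_min = int(round(60.0 / hyp.epoch_s))
    n_min = min(hyp.n_epochs // per_min, lma.n)
    wake_min = (
        (hyp.states[: n_min * per_min] == WAKE)
        .reshape(n_min, per_min)
        .mean(axis=1)
    )  # waking minutes contributed by each clock minute
    counts = lma.values[:n_min]
    minute_h = (np.arange(n_min) + 0.5) / 60.0

    if blocks is None:
        blocks = _lma_blocks(hyp)
    out = []
    for blk in blocks:
        lo, hi = blk["interval"]
        sel = np.flatnonzero((minute_h >= lo) & (minute_h < hi))
        w = wake_min[sel]
        if w.sum() <= 0:
            raise ValueError(f"block {blk['interval']} contains no waking")
        n_bins = blk["n_bins"]
        cum = np.concatenate(([0.0], np.cumsum(w)))
        bounds = cum[-1] * np.arange(n_bins + 1) / n_bins
        t = minute_h[sel]
        c = counts[:][sel]
        for j in range(n_bins):
            lo_b, hi_b = bounds[j], bounds[j + 1]
            overlap = np.clip(
                np.minimum(cum[1:], hi_b) - np.maximum(cum[:-1], lo_b), 0.0, None
            )
            waking = overlap.sum()
            with np.errstate(invalid="ignore", divide="ignore"):
                share = np.where(w > 0, overlap / np.where(w > 0, w, 1.0), 0.0)
            out.append(
                {
                    "interval": blk["interval"],
                    "zt_mid": float((t * overlap).sum() / waking),
                    "waking_min": float(waking),
                    "lma_per_waking": float((c * share).sum() / waking),
                }
            )
    return out


def mad_outliers(values: np.ndarray, threshold_mads: float = 3.0) -> np.ndarray:
    """Median-absolute-deviation outlier flags.

    Flags x where |x - median| / (1.4826 * MAD) > threshold.  When the MAD
    is zero (a majority of identical values) any non-zero deviation from
    the median is flagged.
    """
    x = np.asarray(values, float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    dev = np.abs(x - med)
    if mad == 0:
        return dev > 0
    return dev / (MAD_SCALE * mad) > threshold_mads
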