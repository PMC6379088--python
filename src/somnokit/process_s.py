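"""Process S simulation and grid-search fitting to NREM delta power.

Process S is the homeostatic sleep-pressure variable of the two-process
model.  It rises toward an upper asymptote UA as an exponential saturating
function with time constant ``tau_i`` during waking and REM sleep, and
decays toward a lower asymptote LA with time constant ``tau_d`` during NREM
sleep, iterated at the epoch step ``dt`` (4 s):

    wake/REM:  S' = UA - (UA - S) * exp(-dt/tau_i)
    NREM:      S' = LA + (S - LA) * exp(-dt/tau_d)

S is expressed in % of the EEG delta-power reference (see
:mod:`somnokit.spectral`).  The asymptotes are estimated per animal from
the delta-power distributions: UA as the 99th percentile of the NREM
sample, LA as the intersection of the NREM and REM distributions.  The
time constants are fitted by exhaustive grid search (tau_i 1-25 h step
0.125, tau_d 0.1-5.0 h step 0.025; 193 x 197 = 38,021 combinations)
minimising the mean squared difference between simulated S and the
observed delta-power percentile time course.  A warm-up iteration over
the first 24 h starting at S0 = 150% determines the level of S at the
start of the reported trace; that level is independent of S0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .records import Hypnogram, NREM, REM, WAKE
from .spectral import DeltaTimecourse, assign_delta_bins

_CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class ProcessSParams:
    """Complete parameter set of the Process S recursion.

    tau_i/tau_d in hours; UA, LA, S0 in % of the spectral reference;
    dt in seconds.
    """

    tau_i: float
    tau_d: float
    UA: float
    LA: float
    S0: float = 150.0
    dt: float = 4.0

    def __post_init__(self):
        if not (0 < self.LA < self.UA):
            raise ValueError("require 0 < LA < UA")
        if min(self.tau_i, self.tau_d, self.dt) <= 0:
            raise ValueError("tau_i, tau_d and dt must be positive")


@dataclass(frozen=True)
class GridSpec:
    """Inclusive-endpoint search grid over (tau_i, tau_d) in hours."""

    tau_i_range: tuple[float, float] = (1.0, 25.0)
    tau_i_step: float = 0.125
    tau_d_range: tuple[float, float] = (0.1, 5.0)
    tau_d_step: float = 0.025

    def __post_init__(self):
        if self.tau_i_step <= 0 or self.tau_d_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.tau_i_range[0] > self.tau_i_range[1] or (
            self.tau_d_range[0] > self.tau_d_range[1]
        ):
            raise ValueError("grid ranges out of order")

    @staticmethod
    def _axis(lo: float, hi: float, step: float) -> np.ndarray:
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    @property
    def tau_i_values(self) -> np.ndarray:
        return self._axis(*self.tau_i_range, self.tau_i_step)

    @property
    def tau_d_values(self) -> np.ndarray:
        return self._axis(*self.tau_d_range, self.tau_d_step)

    @property
    def n_combinations(self) -> int:
        return len(self.tau_i_values) * len(self.tau_d_values)

    def coarsened(self, factor: int = 4) -> "GridSpec":
        """Grid with both steps multiplied by ``factor`` (fast CI variant)."""
        return replace(
            self,
            tau_i_step=self.tau_i_step * factor,
            tau_d_step=self.tau_d_step * factor,
        )


@dataclass
class FitResult:
    best: ProcessSParams
    mse: float
    s_trace: np.ndarray
    s0_at_t0: float
    surface: Optional[np.ndarray] = None  # (n_tau_i, n_tau_d) MSE
    grid: Optional[GridSpec] = None


# ---------------------------------------------------------------------------
# simulation


def step_s(S: float, state: str, p: ProcessSParams) -> float:
    """One epoch step of the Process S recursion.

    The underlying state is used even for artefact epochs.  S is clamped
    to [LA, UA] to guard against floating-point overshoot.
    """
    S = min(max(S, p.LA), p.UA)
    if state == NREM:
        out = p.LA + (S - p.LA) * np.exp(-p.dt / (p.tau_d * 3600.0))
    elif state in (WAKE, REM):
        out = p.UA - (p.UA - S) * np.exp(-p.dt / (p.tau_i * 3600.0))
    else:
        raise ValueError(f"unknown state {state!r}")
    return min(max(out, p.LA - _CLAMP_TOL), p.UA + _CLAMP_TOL)


def _run_lengths(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a state sequence -> (run states, run lengths)."""
    if len(states) == 0:
        return states, np.array([], dtype=int)
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [len(states)])))
    return states[starts], lengths


def simulate(
    hyp: Hypnogram,
    p: ProcessSParams,
    warmup_h: float = 24.0,
    warmup_tol: float = 1e-9,
    max_warmup_passes: int = 50,
) -> np.ndarray:
    """Simulate S per epoch, after warm-up passes over the first 24 h.

    The warm-up iterates the recursion over the first ``warmup_h`` hours of
    the hypnogram starting at ``p.S0``, repeating the pass until the level
    reached at the end of the day changes by less than ``warmup_tol`` —
    the baseline steady-state assumption made exact, which renders the
    seeded level independent of S0.  ``s[k]`` is the value of S after
    applying epoch ``k``'s transition.
    """
    n_warm = int(round(warmup_h * 3600.0 / hyp.epoch_s))
    if hyp.n_epochs < n_warm:
        raise ValueError("recording shorter than the warm-up window")

    is_nrem = hyp.states == NREM
    r_i = np.exp(-hyp.epoch_s / (p.tau_i * 3600.0))
    r_d = np.exp(-hyp.epoch_s / (p.tau_d * 3600.0))

    def pass_over(mask_nrem: np.ndarray, s0: float) -> np.ndarray:
        out = np.empty(len(mask_nrem))
        s = min(max(s0, p.LA), p.UA)
        # run-wise closed form: within a run, S_k = asym + (S-asym)*r^k
        run_states, run_lens = _run_lengths(mask_nrem)
        pos = 0
        for nrem_run, n in zip(run_states, run_lens):
            if nrem_run:
                asym, r = p.LA, r_d
            else:
                asym, r = p.UA, r_i
            ks = np.arange(1, n + 1)
            out[pos: pos + n] = asym + (s - asym) * r ** ks
            s = out[pos + n - 1]
            pos += n
        return np.clip(out, p.LA, p.UA)

    s_init = p.S0
    for _ in range(max_warmup_passes):
        end = pass_over(is_nrem[:n_warm], s_init)[-1]
        if abs(end - s_init) < warmup_tol:
            s_init = end
            break
        s_init = end
    return pass_over(is_nrem, s_init)


# ---------------------------------------------------------------------------
# asymptote estimation


def estimate_asymptotes(
    delta_nrem: np.ndarray,
    delta_rem: np.ndarray,
    hist_bin_width: float = 2.0,
) -> tuple[float, float]:
    """Estimate (LA, UA) from the NREM and REM delta-power samples.

    UA is the 99th percentile of the NREM sample.  LA is the delta value at
    which the two normalised relative-frequency distributions cross between
    their modes: histograms are taken on a common grid (default bin width
    2% of reference), the crossing is the first bin between the REM and
    NREM modes where the NREM frequency reaches the REM frequency, refined
    by linear interpolation.
    """
    delta_nrem = np.asarray(delta_nrem, float)
    delta_rem = np.asarray(delta_rem, float)
    delta_nrem = delta_nrem[np.isfinite(delta_nrem)]
    delta_rem = delta_rem[np.isfinite(delta_rem)]
    if len(delta_nrem) == 0 or len(delta_rem) == 0:
        raise ValueError("both NREM and REM delta samples must be non-empty")

    ua = float(np.percentile(delta_nrem, 99))

    lo = min(delta_nrem.min(), delta_rem.min())
    hi = max(delta_nrem.max(), delta_rem.max())
    edges = np.arange(lo, hi + 2 * hist_bin_width, hist_bin_width)
    f_n, _ = np.histogram(delta_nrem, bins=edges)
    f_r, _ = np.histogram(delta_rem, bins=edges)
    f_n = f_n / f_n.sum()
    f_r = f_r / f_r.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    mode_r = int(np.argmax(f_r))
    if mode_r >= len(f_n) - 1:
        raise ValueError(
            "REM mode does not lie below the NREM mode; supply LA manually"
        )
    # NREM mode searched above the REM mode (flat NREM histograms tie-break
    # toward the lowest bin otherwise)
    mode_n = mode_r + 1 + int(np.argmax(f_n[mode_r + 1:]))
    diff = f_n - f_r
    cross = None
    for i in range(mode_r, mode_n + 1):
        if diff[i] >= 0:
            cross = i
            break
    if cross is None:
        raise ValueError(
            "NREM and REM delta distributions never cross between their "
            "modes; supply LA manually"
        )
    if cross == mode_r or diff[cross] == diff[cross - 1]:
        la = float(centers[cross])
    else:
        # linear interpolation of the sign change of f_n - f_r
        x0, x1 = centers[cross - 1], centers[cross]
        d0, d1 = diff[cross - 1], diff[cross]
        la = float(x0 + (0.0 - d0) * (x1 - x0) / (d1 - d0))
    if not la < ua:
        raise ValueError("estimated LA not below UA; supply LA manually")
    return la, ua


# ---------------------------------------------------------------------------
# detrending


def detrend_delta(
    tc: DeltaTimecourse,
    reference_windows: Sequence[tuple[float, float]] = (
        (8.0, 12.0),
        (32.0, 36.0),
        (80.0, 84.0),
    ),
) -> DeltaTimecourse:
    """Remove a linear across-days drift from a delta-power time course.

    A straight line is least-squares fitted through the mean bin values of
    the three reference windows (ZT8-12 of baseline days 1 and 2 and of
    recovery day 2) against recording time, all bin values are divided by
    it, and the series is re-anchored so that the grand mean over the
    reference windows is 100%.  Division (rather than subtraction) is used
    because delta power is a positive relative quantity.
    """
    t_ref, m_ref = [], []
    for lo, hi in reference_windows:
        in_win = [(b["zt_mid"], b["mean_delta"]) for b in tc.bins
                  if lo <= b["zt_mid"] < hi]
        if not in_win:
            raise ValueError(f"no bins inside reference window [{lo}, {hi})")
        ts, ms = zip(*in_win)
        t_ref.append(float(np.mean(ts)))
        m_ref.append(float(np.mean(ms)))
    slope, intercept = np.polyfit(t_ref, m_ref, 1)

    t = np.array([b["zt_mid"] for b in tc.bins])
    vals = np.array([b["mean_delta"] for b in tc.bins])
    line = intercept + slope * t
    corrected = vals / line

    ref_means = []
    for lo, hi in reference_windows:
        sel = (t >= lo) & (t < hi)
        ref_means.append(corrected[sel].mean())
    scale = 100.0 / float(np.mean(ref_means))
    corrected *= scale

    new_bins = [dict(b, mean_delta=float(v)) for b, v in zip(tc.bins, corrected)]
    return DeltaTimecourse(
        bins=new_bins,
        reference_value=tc.reference_value,
        epoch_bin_ids=tc.epoch_bin_ids,
    )


# ---------------------------------------------------------------------------
# grid search


def _grid_pass(
    run_is_nrem: np.ndarray,
    run_lens: np.ndarray,
    r_i: np.ndarray,
    r_d: np.ndarray,
    la: float,
    ua: float,
    s0,
    bin_of_epoch: Optional[np.ndarray] = None,
    n_bins: int = 0,
):
    """Vectorised run-wise simulation for all grid points simultaneously.

    ``r_i`` has shape (n_tau_i, 1) and ``r_d`` (1, n_tau_d); S is carried
    as an (n_tau_i, n_tau_d) array.  When ``bin_of_epoch`` is given, the
    sum of S over the binned NREM epochs of each bin is accumulated via
    the geometric-series partial sum

        sum_{k=a+1}^{a+m} S_k = LA*m + (S_run - LA) * (r^(a+1) - r^(a+m+1)) / (1 - r)

    which is exact for the run-wise recursion.
    """
    shape = np.broadcast_shapes(r_i.shape, r_d.shape)
    S = np.full(shape, float(s0)) if np.isscalar(s0) else s0.copy()
    np.clip(S, la, ua, out=S)
    sums = np.zeros((n_bins,) + shape) if bin_of_epoch is not None else None

    log_ri = np.log(r_i)
    log_rd = np.log(r_d)
    pos = 0
    for nrem_run, n in zip(run_is_nrem, run_lens):
        n = int(n)
        if nrem_run:
            if sums is not None:
                # split run at bin-id changes (incl. unbinned stretches)
                ids = bin_of_epoch[pos: pos + n]
                change = np.flatnonzero(ids[1:] != ids[:-1]) + 1
                starts = np.concatenate(([0], change, [n]))
                dS = S - la
                one_minus_rd = -np.expm1(log_rd)
                for a, b in zip(starts[:-1], starts[1:]):
                    bid = ids[a]
                    if bid >= 0:
                        m = b - a
                        part = (
                            np.exp((a + 1) * log_rd) - np.exp((b + 1) * log_rd)
                        ) / one_minus_rd
                        sums[bid] += la * m + dS * part
            S = la + (S - la) * np.exp(n * log_rd)
        else:
            S = ua + (S - ua) * np.exp(n * log_ri)
        pos += n
    return S, sums


def fit_grid(
    hyp: Hypnogram,
    tc: DeltaTimecourse,
    asymptotes: tuple[float, float],
    grid: GridSpec = GridSpec(),
    s0_warmup: float = 150.0,
    warmup_h: float = 24.0,
    keep_surface: bool = False,
) -> FitResult:
    """Exhaustive grid search of (tau_i, tau_d) minimising the MSE between
    simulated S and the observed delta-power percentile time course.

    For every grid point S is simulated over the full recording (after the
    24-h warm-up at ``s0_warmup``) and averaged over the artefact-free NREM
    epochs inside each percentile bin; the MSE is taken against the bin
    values.  Ties are broken toward smaller (tau_i, tau_d) lexicographically.
    """
    la, ua = asymptotes
    if not la < ua:
        raise ValueError("require LA < UA")
    tau_i = grid.tau_i_values
    tau_d = grid.tau_d_values
    if len(tau_i) == 0 or len(tau_d) == 0:
        raise ValueError("empty grid")

    if tc.epoch_bin_ids is not None:
        bin_of_epoch = np.asarray(tc.epoch_bin_ids)
    else:
        bin_of_epoch, _ = assign_delta_bins(hyp)
    n_bins = len(tc.bins)
    observed = np.array([b["mean_delta"] for b in tc.bins])
    n_per_bin = np.bincount(
        bin_of_epoch[bin_of_epoch >= 0], minlength=n_bins
    ).astype(float)
    if np.any(n_per_bin == 0):
        raise ValueError("a percentile bin contains no NREM epochs")

    dt = hyp.epoch_s
    r_i = np.exp(-dt / (tau_i * 3600.0))[:, None]
    r_d = np.exp(-dt / (tau_d * 3600.0))[None, :]

    is_nrem = hyp.states == NREM
    n_warm = int(round(warmup_h * 3600.0 / dt))
    if hyp.n_epochs < n_warm:
        raise ValueError("recording shorter than the warm-up window")

    warm_states, warm_lens = _run_lengths(is_nrem[:n_warm])
    s_init = np.full(np.broadcast_shapes(r_i.shape, r_d.shape), float(s0_warmup))
    for _ in range(50):
        end, _ = _grid_pass(warm_states, warm_lens, r_i, r_d, la, ua, s_init)
        if np.max(np.abs(end - s_init)) < 1e-9:
            s_init = end
            break
        s_init = end

    run_states, run_lens = _run_lengths(is_nrem)
    _, sums = _grid_pass(
        run_states, run_lens, r_i, r_d, la, ua, s_init,
        bin_of_epoch=bin_of_epoch, n_bins=n_bins,
    )
    means = sums / n_per_bin[:, None, None]
    mse = ((means - observed[:, None, None]) ** 2).mean(axis=0)

    flat = int(np.argmin(mse))  # first minimum = smaller tau_i, then tau_d
    i, j = divmod(flat, mse.shape[1])
    best = ProcessSParams(
        tau_i=float(tau_i[i]), tau_d=float(tau_d[j]),
        UA=ua, LA=la, S0=s0_warmup, dt=dt,
    )
    s_trace = simulate(hyp, best, warmup_h=warmup_h)
    return FitResult(
        best=best,
        mse=float(mse[i, j]),
        s_trace=s_trace,
        s0_at_t0=float(s_init[i, j]),
        surface=mse if keep_surface else None,
        grid=grid,
    )
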