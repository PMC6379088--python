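"""Data model and tabular I/O for hypnograms, physiological traces and spectra.

The central object is the :class:`Hypnogram`: a Zeitgeber-time-anchored
sequence of 4-s epoch vigilance-state labels (wake ``W``, NREM sleep ``N``,
REM sleep ``R``) with per-epoch artefact flags and, optionally, a
theta-dominated-waking (TDW) sub-state flag on wake epochs.  Artefact epochs
keep their state label: they are excluded from spectral computations but
included in all state-time accounting.

Conventions used throughout the package:

* epoch indexing is 0-based; windows are half-open ``[start, end)``;
* Zeitgeber time (ZT) is expressed in decimal hours since lights-on of
  day 1, so a 4-day recording spans ZT hours ``[0, 96)``;
* files are tab-separated with one row per epoch/sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

WAKE = "W"
NREM = "N"
REM = "R"
STATES = (WAKE, NREM, REM)

#: fixed tie-break priority for per-minute state assignment
STATE_PRIORITY = (WAKE, NREM, REM)

SPECTRAL_STEP_HZ = 0.25
SPECTRAL_MAX_HZ = 100.0


@dataclass(frozen=True)
class ProtocolMeta:
    """Lighting and sleep-deprivation (SD) protocol of a recording.

    Defaults describe the standard design: LD 12:12, 4 recording days,
    6-h SD by gentle handling at ZT0-6 of day 3 (days are 1-based).
    ``sd_day=None`` means an undisturbed recording.
    """

    lights_on_zt: float = 0.0
    lights_off_zt: float = 12.0
    n_days: int = 4
    sd_day: Optional[int] = 3
    sd_window_zt: tuple[float, float] = (0.0, 6.0)

    def __post_init__(self):
        if not (0 <= self.lights_on_zt < self.lights_off_zt <= 24):
            raise ValueError("require 0 <= lights_on < lights_off <= 24")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.sd_day is not None:
            lo, hi = self.sd_window_zt
            if not (0 <= lo < hi <= 24):
                raise ValueError("SD window must lie within one day")
            if not (1 <= self.sd_day <= self.n_days):
                raise ValueError("sd_day outside recording")

    @property
    def sd_hours(self) -> Optional[tuple[float, float]]:
        """SD window as absolute recording hours, or None."""
        if self.sd_day is None:
            return None
        base = 24.0 * (self.sd_day - 1)
        return (base + self.sd_window_zt[0], base + self.sd_window_zt[1])

    def light_dark_blocks(self) -> list[tuple[str, float, float]]:
        """(phase, start_h, end_h) blocks over the whole recording."""
        blocks = []
        for d in range(self.n_days):
            base = 24.0 * d
            blocks.append(("light", base + self.lights_on_zt, base + self.lights_off_zt))
            blocks.append(("dark", base + self.lights_off_zt, base + 24.0))
        return blocks

    def to_dict(self) -> dict:
        return {
            "lights_on_zt": self.lights_on_zt,
            "lights_off_zt": self.lights_off_zt,
            "n_days": self.n_days,
            "sd_day": self.sd_day,
            "sd_window_zt": list(self.sd_window_zt),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolMeta":
        d = dict(d)
        if "sd_window_zt" in d:
            d["sd_window_zt"] = tuple(d["sd_window_zt"])
        return cls(**d)


@dataclass
class Hypnogram:
    """Epoch-scored vigilance states with artefact and TDW flags."""

    states: np.ndarray
    artefact: np.ndarray
    epoch_s: float = 4.0
    tdw: Optional[np.ndarray] = None
    zt0_index: int = 0
    protocol: ProtocolMeta = field(default_factory=ProtocolMeta)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype="U1")
        self.artefact = np.asarray(self.artefact, dtype=bool)
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if self.states.shape != self.artefact.shape:
            raise ValueError("states and artefact must have equal length")
        bad = ~np.isin(self.states, STATES)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"unknown state label {self.states[i]!r} at epoch {i}"
            )
        if self.tdw is not None:
            self.tdw = np.asarray(self.tdw, dtype=bool)
            if self.tdw.shape != self.states.shape:
                raise ValueError("tdw flag length mismatch")
            if (self.tdw & (self.states != WAKE)).any():
                raise ValueError("tdw flagged on a non-wake epoch")
        total_s = self.n_epochs * self.epoch_s
        if abs(total_s / 3600.0 - round(total_s / 3600.0)) > 1e-9:
            raise ValueError("recording must cover an integer number of hours")

    @property
    def n_epochs(self) -> int:
        return len(self.states)

    @property
    def duration_h(self) -> float:
        return self.n_epochs * self.epoch_s / 3600.0

    @property
    def epochs_per_hour(self) -> int:
        return int(round(3600.0 / self.epoch_s))

    def zt_hours(self, mid: bool = False) -> np.ndarray:
        """ZT of each epoch's start (or midpoint) in decimal hours."""
        t = (np.arange(self.n_epochs) - self.zt0_index) * self.epoch_s
        if mid:
            t = t + 0.5 * self.epoch_s
        return t / 3600.0

    def window_epochs(self, start_h: float, end_h: float) -> slice:
        """Epoch slice for the half-open ZT window [start_h, end_h)."""
        a = int(round(start_h * 3600.0 / self.epoch_s)) + self.zt0_index
        b = int(round(end_h * 3600.0 / self.epoch_s)) + self.zt0_index
        if a < 0 or b > self.n_epochs or a > b:
            raise ValueError(
                f"window [{start_h}, {end_h}) h outside recording of "
                f"{self.duration_h} h"
            )
        return slice(a, b)

    def state_mask(self, state: str, artefact_free: bool = False) -> np.ndarray:
        m = self.states == state
        if artefact_free:
            m &= ~self.artefact
        return m


@dataclass
class SampledTrace:
    """A regularly sampled scalar series (temperature, LMA counts, delta power)."""

    values: np.ndarray
    dt_s: float
    zt0_index: int = 0
    unit: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")

    @property
    def n(self) -> int:
        return len(self.values)

    def t_seconds(self) -> np.ndarray:
        return (np.arange(self.n) - self.zt0_index) * self.dt_s


@dataclass
class EpochSpectra:
    """Per-epoch EEG power densities on the fixed 0-100 Hz, 0.25 Hz grid."""

    freqs: np.ndarray
    power: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power)
        steps = np.diff(self.freqs)
        if len(self.freqs) < 2 or np.any(steps <= 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("freqs must be uniformly spaced")
        if self.power.ndim != 2 or self.power.shape[1] != len(self.freqs):
            raise ValueError("power must be (n_epochs, n_freqs)")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    def band_slice(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of bins whose centers fall in the closed band [lo, hi]."""
        if hi < lo:
            raise ValueError("band limits out of order")
        m = (self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9)
        if not m.any():
            raise ValueError("band contains no frequency bins")
        return m


def default_freq_grid() -> np.ndarray:
    n = int(round(SPECTRAL_MAX_HZ / SPECTRAL_STEP_HZ)) + 1
    return np.arange(n) * SPECTRAL_STEP_HZ


@dataclass
class RecordBundle:
    """A validated, ZT-aligned set of records for one animal."""

    hypnogram: Hypnogram
    traces: dict[str, SampledTrace] = field(default_factory=dict)
    spectra: Optional[EpochSpectra] = None

    def __post_init__(self):
        if self.spectra is not None and (
            self.spectra.n_epochs != self.hypnogram.n_epochs
        ):
            raise ValueError("spectra epoch count does not match hypnogram")


# ---------------------------------------------------------------------------
# state-time accounting


def minutes_in_state(
    hyp: Hypnogram,
    state: str,
    window: Optional[tuple[float, float]] = None,
    count_artefacts: bool = True,
) -> float:
    """Minutes spent in ``state`` within a ZT-hour window.

    Artefact epochs are counted by default, matching the convention that
    artefacts are excluded from spectral but not state-time analyses.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    sl = hyp.window_epochs(*window) if window else slice(None)
    m = hyp.states[sl] == state
    if not count_artefacts:
        m &= ~hyp.artefact[sl]
    return float(m.sum()) * hyp.epoch_s / 60.0


def per_minute_states(hyp: Hypnogram) -> np.ndarray:
    """Modal state of each minute; ties broken by priority W > N > R.

    Because REM occurs in short bouts it is slightly under-represented
    relative to its epoch fraction under any modal rule.
    """
    per_min = int(round(60.0 / hyp.epoch_s))
    if abs(per_min * hyp.epoch_s - 60.0) > 1e-9:
        raise ValueError("epoch_s must divide 60 s")
    n_min = hyp.n_epochs // per_min
    states = hyp.states[: n_min * per_min].reshape(n_min, per_min)
    counts = np.stack(
        [(states == s).sum(axis=1) for s in STATE_PRIORITY], axis=1
    )
    # argmax returns the first maximum, i.e. the highest-priority state
    return np.asarray(STATE_PRIORITY)[np.argmax(counts, axis=1)]


# ---------------------------------------------------------------------------
# tabular I/O

_HYP_FILE = "hypnogram.tsv"
_PROTOCOL_FILE = "protocol.yaml"
_SPECTRA_FILE = "spectra.tsv"


def write_records(bundle: RecordBundle, outdir: str | Path) -> list[Path]:
    """Write a bundle as TSV/YAML files; inverse of :func:`read_records`.

    Output is deterministic: fixed column order, fixed headers, full float
    precision (two writes of the same bundle are byte-identical).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    hyp = bundle.hypnogram
    df = pd.DataFrame(
        {
            "epoch": np.arange(hyp.n_epochs),
            "state": hyp.states,
            "artefact": hyp.artefact.astype(int),
        }
    )
    if hyp.tdw is not None:
        df["tdw"] = hyp.tdw.astype(int)
    p = outdir / _HYP_FILE
    df.to_csv(p, sep="\t", index=False)
    written.append(p)

    meta = hyp.protocol.to_dict()
    meta.update({"epoch_s": hyp.epoch_s, "zt0_index": hyp.zt0_index})
    p = outdir / _PROTOCOL_FILE
    with open(p, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    written.append(p)

    for name, tr in sorted(bundle.traces.items()):
        tdf = pd.DataFrame({"t_s": tr.t_seconds(), "value": tr.values})
        p = outdir / f"trace_{name}.tsv"
        header = f"# dt_s={tr.dt_s!r} zt0_index={tr.zt0_index} unit={tr.unit}\n"
        with open(p, "w") as fh:
            fh.write(header)
            tdf.to_csv(fh, sep="\t", index=False)
        written.append(p)

    if bundle.spectra is not None:
        sp = bundle.spectra
        cols = [f"f{f:.2f}" for f in sp.freqs]
        sdf = pd.DataFrame(sp.power, columns=cols)
        sdf.insert(0, "epoch", np.arange(sp.n_epochs))
        p = outdir / _SPECTRA_FILE
        with open(p, "w") as fh:
            fh.write(f"# normalized={int(sp.normalized)}\n")
            sdf.to_csv(fh, sep="\t", index=False)
        written.append(p)
    return written


def read_records(indir: str | Path) -> RecordBundle:
    """Read a bundle directory written by :func:`write_records`."""
    indir = Path(indir)
    hp = indir / _HYP_FILE
    if not hp.exists():
        raise FileNotFoundError(f"missing {hp}")
    df = pd.read_csv(hp, sep="\t", dtype={"state": str})
    bad = ~df["state"].isin(STATES)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(
            f"unknown state label {df['state'][row]!r} in {hp} row {row}"
        )

    with open(indir / _PROTOCOL_FILE) as fh:
        meta = yaml.safe_load(fh)
    epoch_s = float(meta.pop("epoch_s", 4.0))
    zt0_index = int(meta.pop("zt0_index", 0))
    protocol = ProtocolMeta.from_dict(meta)

    hyp = Hypnogram(
        states=df["state"].to_numpy(),
        artefact=df["artefact"].to_numpy().astype(bool),
        tdw=df["tdw"].to_numpy().astype(bool) if "tdw" in df else None,
        epoch_s=epoch_s,
        zt0_index=zt0_index,
        protocol=protocol,
    )

    traces = {}
    for p in sorted(indir.glob("trace_*.tsv")):
        with open(p) as fh:
            header = fh.readline()
            tdf = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        attrs = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").strip().split(" ")
        )
        name = p.stem[len("trace_"):]
        traces[name] = SampledTrace(
            values=tdf["value"].to_numpy(),
            dt_s=float(attrs["dt_s"]),
            zt0_index=int(attrs["zt0_index"]),
            unit=attrs.get("unit", ""),
        )

    spectra = None
    sp = indir / _SPECTRA_FILE
    if sp.exists():
        with open(sp) as fh:
            header = fh.readline()
            sdf = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        normalized = bool(int(header.lstrip("# ").strip().split("=")[1]))
        freq_cols = [c for c in sdf.columns if c.startswith("f")]
        freqs = np.array([float(c[1:]) for c in freq_cols])
        spectra = EpochSpectra(
            freqs=freqs, power=sdf[freq_cols].to_numpy(), normalized=normalized
        )

    n = hyp.n_epochs
    for name, tr in traces.items():
        expected = n * hyp.epoch_s / tr.dt_s
        if abs(tr.n - expected) > 1:
            raise ValueError(
                f"trace {name!r} length {tr.n} inconsistent with "
                f"{n} epochs of {hyp.epoch_s} s"
            )
    return RecordBundle(hypnogram=hyp, traces=traces, spectra=spectra)


def bundles_equal(a: RecordBundle, b: RecordBundle) -> bool:
    """Exact equality of two bundles (used to verify I/O round trips)."""
    ha, hb = a.hypnogram, b.hypnogram
    if ha.epoch_s != hb.epoch_s or ha.zt0_index != hb.zt0_index:
        return False
    if ha.protocol != hb.protocol:
        return False
    if not (np.array_equal(ha.states, hb.states)
            and np.array_equal(ha.artefact, hb.artefact)):
        return False
    if (ha.tdw is None) != (hb.tdw is None):
        return False
    if ha.tdw is not None and not np.array_equal(ha.tdw, hb.tdw):
        return False
    if set(a.traces) != set(b.traces):
        return False
    for k in a.traces:
        ta, tb = a.traces[k], b.traces[k]
        if ta.dt_s != tb.dt_s or not np.array_equal(
            ta.values, tb.values, equal_nan=True
        ):
            return False
    if (a.spectra is None) != (b.spectra is None):
        return False
    if a.spectra is not None:
        if not np.array_equal(a.spectra.freqs, b.spectra.freqs):
            return False
        if not np.allclose(a.spectra.power, b.spectra.power, rtol=0, atol=0, equal_nan=True):
            return False
    return True
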