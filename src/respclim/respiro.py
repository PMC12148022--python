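"""Flow-through respirometry: CO2 trace -> metabolic rate and gas-exchange frequency.

A recording for one animal is a ~1 Hz series of excurrent CO2 concentration
(ppm) from a chamber flushed at a known mass-flow-controlled rate, bracketed
by short empty-chamber segments that sample the incurrent air.  Processing
follows the standard pipeline for discontinuously breathing insects:

1. fit a straight line through the pre/post baseline segments to model
   analyser drift and give the incurrent fraction Fi(t);
2. discard settling-in/out periods at the ends of the measurement;
3. detect CO2 bursts (spiracle-open phases); consecutive burst starts
   delimit one discontinuous gas-exchange (DGC) cycle;
4. average the instantaneous CO2 production
   ``v(t) = FR * (Fe - Fi) / (1 - Fe)``
   over a whole number of cycles (default the first seven) to obtain V'CO2
   in ml min^-1, and report the frequency of gas exchange (FGE, cycles
   min^-1) over the same span.

Averaging over whole cycles makes the estimate independent of where within
a cycle the window starts, and the drift model cancels any linear analyser
ramp.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RespTrace",
    "BaselinePair",
    "DriftModel",
    "CycleSet",
    "TraitRecord",
    "DetectOpts",
    "MeasureOpts",
    "load_trace",
    "load_multichannel",
    "flow_to_stp",
    "fit_baseline_drift",
    "trim_settling",
    "detect_cycles",
    "compute_vco2",
    "compute_fge",
    "measure_bee",
]

PPM = 1e-6  # ppm -> fractional concentration
STP_KPA = 101.3
ZERO_C_K = 273.15


@dataclass
class RespTrace:
    """One chamber's CO2 recording: time (s, strictly increasing) and ppm."""

    time: np.ndarray
    co2_ppm: np.ndarray
    flow_rate_stp: float  # ml min^-1 at 0 degC, 101.3 kPa
    chamber_id: str = ""
    block_id: str = ""
    channel_id: str = ""
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.co2_ppm = np.asarray(self.co2_ppm, dtype=float)
        if self.time.shape != self.co2_ppm.shape:
            raise ValueError("time and co2_ppm must have equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(f"time not strictly increasing at row {i + 1}")
        if not np.all(np.isfinite(self.co2_ppm)):
            raise ValueError("co2_ppm contains non-finite values")
        if not self.flow_rate_stp > 0:
            raise ValueError("flow_rate_stp must be positive")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def window(self, start_s: float, end_s: float) -> "RespTrace":
        """Sub-trace with time in [start_s, end_s] (timestamps preserved)."""
        m = (self.time >= start_s) & (self.time <= end_s)
        if not m.any():
            raise ValueError(f"window [{start_s}, {end_s}] selects no samples")
        return dataclasses.replace(
            self, time=self.time[m], co2_ppm=self.co2_ppm[m],
            qc_flags=list(self.qc_flags),
        )


@dataclass
class BaselinePair:
    """Empty-chamber segments recorded before and after the measurement."""

    pre_time: np.ndarray
    pre_ppm: np.ndarray
    post_time: np.ndarray
    post_ppm: np.ndarray

    def __post_init__(self) -> None:
        for name in ("pre", "post"):
            t = np.asarray(getattr(self, f"{name}_time"), dtype=float)
            p = np.asarray(getattr(self, f"{name}_ppm"), dtype=float)
            if t.size == 0:
                raise ValueError(f"{name} baseline segment is empty")
            setattr(self, f"{name}_time", t)
            setattr(self, f"{name}_ppm", p)
        if self.post_time[0] <= self.pre_time[-1]:
            raise ValueError("post baseline must start after pre baseline ends")


@dataclass(frozen=True)
class DriftModel:
    """Linear analyser-drift model of the incurrent CO2 concentration."""

    intercept_ppm: float
    slope_ppm_per_s: float

    def fi_ppm(self, t):
        """Incurrent concentration (ppm) at time t."""
        return self.intercept_ppm + self.slope_ppm_per_s * np.asarray(t, dtype=float)

    def fi_of(self, t):
        """Fractional incurrent concentration Fi(t) (unitless)."""
        return self.fi_ppm(t) * PPM


@dataclass
class CycleSet:
    """Detected bursts and the DGC cycles they delimit (absolute seconds)."""

    bursts: list[tuple[float, float]]
    cycles: list[tuple[float, float]]
    n_complete: int
    flags: list[str] = field(default_factory=list)


@dataclass
class TraitRecord:
    """Derived physiological traits for one animal."""

    vco2_ml_min: float
    fge_min: float
    span_used_s: float
    n_cycles_used: int
    mass_mg: float | None = None
    species: str = ""
    sex: str = ""
    site_id: str = ""
    block_id: str = ""
    channel_id: str = ""
    qc_flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class DetectOpts:
    """Burst-detection constants (all in seconds / multiples; see methods note)."""

    smooth_s: float = 5.0        # centred moving-mean width
    mad_mult: float = 3.0        # noise multiple for the entry threshold
    p95_frac: float = 0.1        # floor: fraction of the 95th-percentile excess
    min_burst_s: float = 5.0
    min_interburst_s: float = 10.0
    hysteresis: float = 0.5      # exit threshold as fraction of entry
    min_threshold_ppm: float = 1.0  # absolute floor; below this is analyser dust


@dataclass(frozen=True)
class MeasureOpts:
    """End-to-end options for :func:`measure_bee`."""

    k_cycles: int = 7
    settle_in_s: float = 600.0
    settle_out_s: float = 600.0
    require_k: bool = True       # exclude records with < k_cycles complete cycles
    min_accept_cycles: int = 3   # used only when require_k is False
    fge_mode: str = "start_to_start"  # or "first_to_last_burst_end"
    detect: DetectOpts = DetectOpts()


# ---------------------------------------------------------------------------
# I/O

def load_trace(path, metadata) -> tuple[RespTrace, BaselinePair]:
    """Read a two-column CSV trace (time_s, co2_ppm) plus its metadata.

    ``metadata`` is a mapping (or a path to a YAML file) with keys
    ``flow_rate_stp`` (ml min^-1), ``baseline_pre`` and ``baseline_post``
    (``[start_s, end_s]`` windows), ``measurement`` (``[start_s, end_s]``)
    and optional ``chamber_id`` / ``block_id`` / ``channel_id``.

    Returns the measurement-window trace and the baseline pair.  Sampling
    gaps longer than 5 s add a ``"gap"`` qc flag; non-monotone timestamps
    raise ``ValueError`` naming the first offending row.
    """
    if isinstance(metadata, (str, Path)):
        with open(metadata) as fh:
            metadata = yaml.safe_load(fh)
    try:
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(dtype=float)
        ppm = df.iloc[:, 1].to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"could not parse trace file {path}: {exc}") from None

    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise ValueError(f"time not strictly increasing at row {i + 1} of {path}")

    flags = []
    if np.any(dt > 5.0):
        flags.append("gap")

    def _seg(key):
        try:
            lo, hi = metadata[key]
        except KeyError:
            raise KeyError(f"metadata missing {key!r} window") from None
        m = (t >= lo) & (t <= hi)
        if not m.any():
            raise ValueError(f"{key} window [{lo}, {hi}] selects no samples")
        return t[m], ppm[m]

    pre_t, pre_p = _seg("baseline_pre")
    post_t, post_p = _seg("baseline_post")
    meas_t, meas_p = _seg("measurement")

    trace = RespTrace(
        time=meas_t,
        co2_ppm=meas_p,
        flow_rate_stp=float(metadata["flow_rate_stp"]),
        chamber_id=str(metadata.get("chamber_id", "")),
        block_id=str(metadata.get("block_id", "")),
        channel_id=str(metadata.get("channel_id", "")),
        qc_flags=flags,
    )
    return trace, BaselinePair(pre_t, pre_p, post_t, post_p)


def load_multichannel(path, *, time_col: str = "time_s") -> dict[str, pd.DataFrame]:
    """Import a wide tab-delimited multi-channel acquisition export.

    Expects one time column and one CO2 (ppm) column per channel; returns
    ``{channel_name: DataFrame(time_s, co2_ppm)}`` ready for per-channel
    processing.
    """
    wide = pd.read_csv(path, sep="\t")
    if time_col not in wide.columns:
        raise KeyError(f"multichannel export lacks time column {time_col!r}")
    out = {}
    for col in wide.columns:
        if col == time_col:
            continue
        out[col] = pd.DataFrame({"time_s": wide[time_col], "co2_ppm": wide[col]})
    return out


# ---------------------------------------------------------------------------
# Trace processing

def flow_to_stp(flow_measured: float, temp_amb: float, pressure_amb: float,
                f_h2o: float = 0.0) -> float:
    """Correct a volumetric flow (ml min^-1) to STP (0 degC, 101.3 kPa), dry.

    ``FR_stp = FR * 273.15/(273.15+T) * P/101.3 * (1 - f_h2o)`` where
    ``f_h2o`` is the fractional water-vapour content of the measured stream.
    """
    if pressure_amb <= 0:
        raise ValueError("pressure_amb must be positive")
    if temp_amb <= -ZERO_C_K:
        raise ValueError("temperature below absolute zero")
    if not 0 <= f_h2o < 1:
        raise ValueError("f_h2o must lie in [0, 1)")
    return flow_measured * (ZERO_C_K / (ZERO_C_K + temp_amb)) * (pressure_amb / STP_KPA) * (1 - f_h2o)


def fit_baseline_drift(baselines: BaselinePair) -> DriftModel:
    """OLS line through all pre+post baseline samples (time vs ppm).

    The line interpolates (and extrapolates) the incurrent CO2 concentration
    across the whole recording, absorbing linear analyser drift.
    """
    t = np.concatenate([baselines.pre_time, baselines.post_time])
    p = np.concatenate([baselines.pre_ppm, baselines.post_ppm])
    if np.ptp(t) == 0:
        raise ValueError("baseline samples share a single timestamp; cannot fit drift")
    slope, intercept = np.polyfit(t, p, 1)
    return DriftModel(intercept_ppm=float(intercept), slope_ppm_per_s=float(slope))


def trim_settling(trace: RespTrace, settle_in: float = 600.0,
                  settle_out: float = 600.0) -> RespTrace:
    """Drop the settling-in/out periods at either end of the measurement."""
    if settle_in < 0 or settle_out < 0:
        raise ValueError("settling periods must be non-negative")
    if trace.duration <= settle_in + settle_out:
        raise ValueError(
            f"trace of {trace.duration:.0f} s cannot absorb "
            f"{settle_in:.0f}+{settle_out:.0f} s settling"
        )
    return trace.window(trace.time[0] + settle_in, trace.time[-1] - settle_out)


def _moving_mean(x: np.ndarray, width: int) -> np.ndarray:
    # centred moving mean with edge shrinkage (same-length output)
    if width <= 1:
        return x.copy()
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_cycles(trace: RespTrace, drift: DriftModel,
                  opts: DetectOpts = DetectOpts()) -> CycleSet:
    """Detect CO2 bursts and the DGC cycles between consecutive burst starts.

    The baseline-subtracted signal is smoothed with a centred moving mean;
    a burst is a maximal run above an entry threshold (robust noise scale of
    the quiet samples, with a floor at a fraction of the 95th-percentile
    excess) with hysteresis on exit.  Runs shorter than ``min_burst_s`` are
    discarded and runs separated by less than ``min_interburst_s`` merged.
    A trace with no bursts returns an empty set flagged ``"no_dgc"`` rather
    than raising, so batch callers can exclude the record.
    """
    t = trace.time
    dt = float(np.median(np.diff(t)))
    excess = trace.co2_ppm - drift.fi_ppm(t)
    width = max(1, int(round(opts.smooth_s / dt)))
    sm = _moving_mean(excess, width)

    # quiet (interburst) samples approximated by the lowest 30% of the signal
    quiet = np.sort(sm)[: max(1, int(0.3 * sm.size))]
    mad = np.median(np.abs(quiet - np.median(quiet)))
    noise = 1.4826 * mad
    p95 = np.percentile(sm, 95)
    thr_hi = max(opts.mad_mult * noise, opts.p95_frac * max(p95, 0.0),
                 opts.min_threshold_ppm)
    if p95 < thr_hi:
        return CycleSet(bursts=[], cycles=[], n_complete=0, flags=["no_dgc"])
    thr_lo = opts.hysteresis * thr_hi

    # hysteresis state machine
    runs: list[tuple[int, int]] = []
    inside = False
    start = 0
    for i, v in enumerate(sm):
        if not inside and v >= thr_hi:
            inside, start = True, i
        elif inside and v < thr_lo:
            runs.append((start, i - 1))
            inside = False
    if inside:
        runs.append((start, len(sm) - 1))

    # a run already above threshold at the first sample is the tail of a
    # burst that began before the window; its true start is unobservable
    if runs and runs[0][0] == 0:
        runs = runs[1:]

    # merge runs separated by short gaps, then drop short runs
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and (t[s] - t[merged[-1][1]]) < opts.min_interburst_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    bursts = [(float(t[s]), float(t[e])) for s, e in merged
              if t[e] - t[s] >= opts.min_burst_s]

    if not bursts:
        return CycleSet(bursts=[], cycles=[], n_complete=0, flags=["no_dgc"])

    cycles = [(bursts[i][0], bursts[i + 1][0]) for i in range(len(bursts) - 1)]
    return CycleSet(bursts=bursts, cycles=cycles, n_complete=len(cycles))


def compute_vco2(trace: RespTrace, drift: DriftModel,
                 window: tuple[float, float]) -> float:
    """Time-averaged CO2 production (ml min^-1) over ``window``.

    Instantaneous rate ``v(t) = FR * (Fe(t) - Fi(t)) / (1 - Fe(t))`` with Fe
    the recorded excurrent fraction and Fi from the drift model; the window
    average uses trapezoidal integration.  Negative instantaneous values are
    retained (clipping would bias the mean upward); only a negative window
    mean is a qc condition, signalled by the returned value itself.
    """
    sub = trace.window(*window)
    fe = sub.co2_ppm * PPM
    if np.any(fe >= 1):
        raise ValueError("excurrent fraction Fe >= 1; not a gas fraction")
    fi = drift.fi_of(sub.time)
    v = trace.flow_rate_stp * (fe - fi) / (1.0 - fe)
    if sub.time.size == 1:
        return float(v[0])
    return float(np.trapezoid(v, sub.time) / (sub.time[-1] - sub.time[0]))


def compute_fge(cycles: CycleSet, k: int = 7,
                mode: str = "start_to_start") -> tuple[float, float]:
    """Frequency of gas exchange over the first ``k`` cycles.

    Returns ``(fge_per_min, span_s)``.  The default span runs from the start
    of burst 1 to the start of burst k+1 (k whole periods) when a (k+1)-th
    burst exists, falling back to start of burst 1 -> end of burst k — the
    span the original field protocol describes — otherwise.  Passing
    ``mode="first_to_last_burst_end"`` forces the fallback definition.
    """
    if mode not in ("start_to_start", "first_to_last_burst_end"):
        raise ValueError(f"unknown fge mode {mode!r}")
    if cycles.n_complete < k:
        raise ValueError(
            f"only {cycles.n_complete} complete cycles detected; {k} required"
        )
    b = cycles.bursts
    if mode == "start_to_start" and len(b) >= k + 1:
        span = b[k][0] - b[0][0]
    else:
        span = b[k - 1][1] - b[0][0]
    if span <= 0:
        raise ValueError("non-positive cycle span")
    return k / (span / 60.0), float(span)


def measure_bee(trace: RespTrace, baselines: BaselinePair,
                opts: MeasureOpts = MeasureOpts(), *,
                mass_mg: float | None = None, species: str = "",
                sex: str = "", site_id: str = "") -> TraitRecord:
    """Full per-animal pipeline: drift fit -> trim -> detect -> V'CO2 + FGE.

    Metabolic rate is averaged over the same whole-cycle span used for FGE,
    so both traits describe the identical stretch of the recording.  Records
    failing the cycle-count rule return a qc-flagged record with NaN traits
    (mirroring a field protocol that retains the animal but excludes the
    measurement) rather than raising.
    """
    drift = fit_baseline_drift(baselines)
    trimmed = trim_settling(trace, opts.settle_in_s, opts.settle_out_s)
    cyc = detect_cycles(trimmed, drift, opts.detect)
    flags = list(trace.qc_flags) + list(cyc.flags)

    k = opts.k_cycles
    if cyc.n_complete < k:
        if opts.require_k or cyc.n_complete < opts.min_accept_cycles:
            flags.append("insufficient_cycles")
            return TraitRecord(
                vco2_ml_min=float("nan"), fge_min=float("nan"),
                span_used_s=0.0, n_cycles_used=cyc.n_complete,
                mass_mg=mass_mg, species=species, sex=sex, site_id=site_id,
                block_id=trace.block_id, channel_id=trace.channel_id,
                qc_flags=flags,
            )
        flags.append("fewer_cycles_accepted")
        k = cyc.n_complete

    fge, span = compute_fge(cyc, k=k, mode=opts.fge_mode)
    start = cyc.bursts[0][0]
    vco2 = compute_vco2(trimmed, drift, (start, start + span))
    if vco2 < 0:
        flags.append("negative_mr")
    return TraitRecord(
        vco2_ml_min=vco2, fge_min=fge, span_used_s=span, n_cycles_used=k,
        mass_mg=mass_mg, species=species, sex=sex, site_id=site_id,
        block_id=trace.block_id, channel_id=trace.channel_id, qc_flags=flags,
    )


def measure_batch(records: Sequence[tuple[RespTrace, BaselinePair, dict]],
                  opts: MeasureOpts = MeasureOpts()) -> pd.DataFrame:
    """Process many chambers; one trait-table row per recording."""
    rows = []
    for trace, baselines, meta in records:
        rec = measure_bee(trace, baselines, opts, **meta)
        rows.append(dataclasses.asdict(rec))
    df = pd.DataFrame(rows)
    df["qc_flags"] = df["qc_flags"].map(";".join)
    return df
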