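"""Synthetic respirometry traces and trait/climate tables with known truth.

Every downstream stage of the pipeline — burst detection, drift correction,
metabolic-rate integration, mixed-model inference, slope-vs-climate
regression — is validated against data generated here, where the true
quantities are known exactly.

Trace model
-----------
A discontinuously breathing insect is modelled as a square-wave CO2 emitter:
during the spiracle-open (burst) fraction of each cycle it releases CO2 at a
constant rate chosen so the cycle-mean equals ``true_vco2``; between bursts
it releases none.  The chamber acts as a first-order mixing volume with time
constant ``washout_tau`` (volume / flow), which rounds the square wave into
the burst shapes seen in real traces but, crucially, only *redistributes*
CO2 in time: the flow-weighted integral of the excess concentration over the
whole record equals the emitted volume.  The analyser adds a linear drift
ramp and white Gaussian noise.  Empty-chamber baseline segments bracket the
measurement, separated from it by a washout gap so the post-baseline samples
incurrent air once the chamber has cleared.

Trait-table model
-----------------
Sites sit on a linear altitudinal climate gradient with a wet/dry rain-shadow
split.  Per bee,

``log10 MR = b0 + b_mass*log10(mass) + b_T*Tmin + b_P*Pdry + u_block + u_channel + e``

and FGE is linear in log10 MR with a species-specific slope, plus a mass
term and its own block/channel/residual noise — the same structure the
inference module fits, so parameter recovery can be checked directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as _climate
from .respiro import BaselinePair, RespTrace

__all__ = [
    "TraceSimParams",
    "TraitSimParams",
    "TraceTruth",
    "simulate_trace",
    "split_record",
    "write_trace",
    "simulate_climate_gradient",
    "simulate_trait_table",
]


# ---------------------------------------------------------------------------
# Respirometry trace simulation

@dataclass(frozen=True)
class TraceSimParams:
    """Ground-truth parameters for one simulated recording.

    Defaults describe a typical small bee in a 100 ml min^-1 flow-through
    system sampled at 1 Hz: V'CO2 of 0.002 ml min^-1, one gas-exchange cycle
    every two minutes with bursts occupying 30% of the cycle, 2 min baselines
    and 10 min settling at each end of a 60 min measurement.
    """

    true_vco2: float = 0.002        # ml CO2 min^-1
    cycle_period: float = 120.0     # s
    burst_fraction: float = 0.3     # open-phase fraction of the cycle
    flow_rate: float = 100.0        # ml min^-1 at STP
    baseline_start_ppm: float = 10.0
    drift_slope: float = 0.0        # ppm min^-1
    noise_sd: float = 0.0           # ppm
    washout_tau: float = 12.0       # s, (chamber + analyser cell volume) / flow
    duration: float = 3600.0        # s of animal measurement
    settle_in: float = 600.0        # s discarded at the start
    settle_out: float = 600.0       # s discarded at the end
    sample_rate: float = 1.0        # Hz
    baseline_len: float = 120.0     # s of empty-chamber recording each side
    washout_gap: float = 150.0      # s between animal removal and post baseline
    cycle_jitter_sd: float = 0.0    # s, sd of per-cycle period (unknown in the field)
    seed: int = 0

    def validate(self) -> None:
        checks = [
            ("true_vco2", self.true_vco2 >= 0),
            ("burst_fraction", 0 < self.burst_fraction < 1),
            ("flow_rate", self.flow_rate > 0),
            ("duration", self.duration > self.settle_in + self.settle_out),
            ("sample_rate", self.sample_rate > 0),
            ("noise_sd", self.noise_sd >= 0),
            ("washout_tau", self.washout_tau >= 0),
            ("cycle_period", self.cycle_period > 0),
            ("baseline_len", self.baseline_len >= 30),
            ("cycle_jitter_sd", self.cycle_jitter_sd >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid trace parameter: {name}")


@dataclass
class TraceTruth:
    """What is actually true in a simulated recording."""

    true_vco2: float
    cycle_period: float
    true_fge: float                       # cycles min^-1 = 60 / period
    burst_bounds: list[tuple[float, float]]  # absolute (start_s, end_s)
    baseline_pre: tuple[float, float]
    baseline_post: tuple[float, float]
    measurement: tuple[float, float]
    params: TraceSimParams

    def __post_init__(self) -> None:
        starts = [b[0] for b in self.burst_bounds]
        if any(b - a <= 0 for a, b in zip(starts, starts[1:])):
            raise ValueError("burst boundaries must be strictly increasing")


def _burst_schedule(p: TraceSimParams, rng: np.random.Generator,
                    t0: float) -> list[tuple[float, float]]:
    bounds = []
    t = t0
    end = t0 + p.duration
    while t < end:
        period = p.cycle_period
        if p.cycle_jitter_sd > 0:
            period = max(p.cycle_period * 0.2,
                         rng.normal(p.cycle_period, p.cycle_jitter_sd))
        bounds.append((t, min(t + p.burst_fraction * period, end)))
        t += period
    return bounds


def _cumulative_burst_time(bounds, times):
    """Total burst seconds elapsed by each time point (piecewise linear)."""
    knots, vals = [0.0], [0.0]
    acc = 0.0
    for s, e in bounds:
        knots += [s, e]
        vals += [acc, acc + (e - s)]
        acc += e - s
    return np.interp(times, knots, vals)


def simulate_trace(params: TraceSimParams) -> tuple[RespTrace, TraceTruth]:
    """Simulate one full recording (pre baseline + measurement + post baseline).

    Returns the full-record trace and its truth.  The excess concentration is
    propagated through the first-order washout exactly (per-sample-interval
    exponential update with the exactly-integrated emission of each
    interval), so for a noiseless trace the flow-weighted integral of the
    excess over the record equals ``true_vco2 x duration`` up to the residual
    CO2 left in the chamber at the end of the record.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / params.sample_rate

    t_meas0 = params.baseline_len
    t_meas1 = t_meas0 + params.duration
    t_post0 = t_meas1 + params.washout_gap
    t_end = t_post0 + params.baseline_len

    n = int(round(t_end / dt)) + 1
    time = np.arange(n) * dt

    bounds = _burst_schedule(params, rng, t_meas0)
    # emission rate (ml min^-1) while the spiracles are open
    open_rate = params.true_vco2 / params.burst_fraction

    # emitted volume within each sample interval, computed exactly
    cum = _cumulative_burst_time(bounds, time)
    burst_s_per_step = np.diff(cum)                     # s of open phase per step
    m_step = open_rate * burst_s_per_step / dt          # mean ml min^-1 per step

    # exact piecewise-constant-input update of dx/dt = (m/F - x)/tau
    x = np.zeros(n)
    if params.washout_tau > 0:
        decay = np.exp(-dt / params.washout_tau)
        for i in range(n - 1):
            x_ss = m_step[i] / params.flow_rate
            x[i + 1] = x_ss + (x[i] - x_ss) * decay
    else:
        x[1:] = m_step / params.flow_rate

    base = params.baseline_start_ppm + params.drift_slope * time / 60.0
    co2 = base + x * 1e6
    if params.noise_sd > 0:
        co2 = co2 + rng.normal(0.0, params.noise_sd, size=n)

    trace = RespTrace(time=time, co2_ppm=co2, flow_rate_stp=params.flow_rate)
    truth = TraceTruth(
        true_vco2=params.true_vco2,
        cycle_period=params.cycle_period,
        true_fge=60.0 / params.cycle_period,
        burst_bounds=bounds,
        baseline_pre=(0.0, t_meas0),
        baseline_post=(t_post0, t_end),
        measurement=(t_meas0, t_meas1),
        params=params,
    )
    return trace, truth


def split_record(trace: RespTrace, truth: TraceTruth) -> tuple[RespTrace, BaselinePair]:
    """Split a full simulated record into its measurement trace and baselines."""
    meas = trace.window(*truth.measurement)
    pre = trace.window(*truth.baseline_pre)
    post = trace.window(*truth.baseline_post)
    return meas, BaselinePair(pre.time, pre.co2_ppm, post.time, post.co2_ppm)


def write_trace(trace: RespTrace, truth: TraceTruth, csv_path, meta_path=None) -> Path:
    """Write a record as two-column CSV plus a YAML metadata sidecar.

    The sidecar carries everything :func:`respclim.respiro.load_trace` needs
    (flow rate, baseline/measurement windows, ids) plus the simulation truth
    under a ``truth`` key.
    """
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.time, "co2_ppm": trace.co2_ppm}).to_csv(
        csv_path, index=False
    )
    meta = {
        "flow_rate_stp": float(trace.flow_rate_stp),
        "baseline_pre": [float(v) for v in truth.baseline_pre],
        "baseline_post": [float(v) for v in truth.baseline_post],
        "measurement": [float(v) for v in truth.measurement],
        "chamber_id": trace.chamber_id,
        "block_id": trace.block_id,
        "channel_id": trace.channel_id,
        "truth": {
            "true_vco2": truth.true_vco2,
            "cycle_period": truth.cycle_period,
            "true_fge": truth.true_fge,
            "burst_bounds": [[float(a), float(b)] for a, b in truth.burst_bounds],
            "seed": truth.params.seed,
        },
    }
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".yaml")
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return meta_path


# ---------------------------------------------------------------------------
# Climate gradient and trait tables

@dataclass(frozen=True)
class TraitSimParams:
    """Design and effect sizes for the synthetic trait/climate tables.

    Defaults emulate the tropical-island study system this pipeline targets:
    16 collection sites along a ~1070 m altitudinal gradient (10 on the dry
    rain-shadow side, 6 on the wet side), ~5 degC cooling and ~100 mm extra
    dry-month precipitation per 1000 m, four species with altitude-limited
    ranges, and ~13 bees per site measured in blocks of 7 channels.  Effect
    sizes default to the regime reported for Fijian bees (mass exponent
    0.76, Tmin effect -0.041, Pdry effect -0.002 on log10 MR); variance
    components default to values giving a marginal R^2 near 0.55 for the
    generating model.
    """

    n_sites: int = 16
    n_dry_sites: int | None = None          # default: ~60% of sites
    altitude_range: float = 1072.0          # m
    temp_lapse: float = -0.005              # degC per m
    precip_gain: float = 0.1                # mm per m
    rain_shadow_offset: float = 100.0       # mm extra on the wet side
    t0_c: float = 23.0                      # sea-level coldest-month mean, degC
    p0_mm: float = 80.0                     # sea-level dry-side driest-month precip
    rh_dry: float = 0.75                    # relative humidity -> VP, dry side
    rh_wet: float = 0.88

    beta0: float = -1.75                    # log10 MR intercept
    beta_mass: float = 0.76                 # allometric exponent (log-log)
    beta_T: float = -0.041                  # per degC
    beta_P: float = -0.002                  # per mm
    sd_block: float = 0.04
    sd_channel: float = 0.025
    sd_resid: float = 0.11

    # FGE ~ a + slope_s * log10 MR + b * log10 mass (+ block/channel/resid)
    species_slopes: dict[str, float] = field(default_factory=lambda: {
        "sp_lowhigh": 0.67, "sp_lowland": 0.80,
        "sp_highland1": 0.38, "sp_highland2": 0.30,
    })
    fge_intercept: float = 3.0
    fge_beta_mass: float = -0.45
    fge_sd_block: float = 0.05
    fge_sd_channel: float = 0.03
    fge_sd_resid: float = 0.12

    # species ranges: name -> (alt_min, alt_max, sampling weight, mean log10 mass mg)
    species_ranges: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "sp_lowhigh": (0.0, 1100.0, 2.0, 0.255),
            "sp_lowland": (0.0, 450.0, 1.0, 0.447),
            "sp_highland1": (550.0, 1100.0, 1.0, 0.176),
            "sp_highland2": (550.0, 1100.0, 1.0, 0.204),
        }
    )
    sd_log10_mass: float = 0.12
    n_per_site: int = 13
    channels_per_block: int = 7
    seed: int = 0

    def validate(self) -> None:
        checks = [
            ("n_sites", self.n_sites >= 2),
            ("n_per_site", self.n_per_site >= 1),
            ("altitude_range", self.altitude_range > 0),
            ("sd_block", self.sd_block >= 0),
            ("sd_channel", self.sd_channel >= 0),
            ("sd_resid", self.sd_resid >= 0),
            ("fge_sd_block", self.fge_sd_block >= 0),
            ("fge_sd_channel", self.fge_sd_channel >= 0),
            ("fge_sd_resid", self.fge_sd_resid >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid trait-sim parameter: {name}")
        missing = set(self.species_ranges) - set(self.species_slopes)
        if missing:
            raise ValueError(
                f"species_slopes missing entries for: {sorted(missing)}"
            )


def simulate_climate_gradient(params: TraitSimParams) -> pd.DataFrame:
    """Site-climate table on a linear altitudinal gradient with a rain shadow.

    Tmin decreases with altitude at ``temp_lapse``; Pdry increases with
    altitude at ``precip_gain`` and gains ``rain_shadow_offset`` on the wet
    side; VP is a side-specific relative humidity times SVP(Tmin), so VPD is
    positive everywhere.  Returns the schema of
    :data:`respclim.climate.SITE_SCHEMA` with ``svp_kpa``/``vpd_kpa`` added.
    """
    params.validate()
    n = params.n_sites
    n_dry = params.n_dry_sites
    if n_dry is None:
        n_dry = int(round(0.6 * n))
    n_dry = min(max(n_dry, 1), n - 1)

    altitudes = np.linspace(0.0, params.altitude_range, n)
    # spread the wet sites evenly through the altitude ordering so both
    # sides span the gradient (breaks Tmin/Pdry collinearity)
    wet_pos = np.linspace(0, n - 1, n - n_dry).round().astype(int)
    side_col = np.array(["dry"] * n, dtype=object)
    side_col[wet_pos] = "wet"

    tmin = params.t0_c + params.temp_lapse * altitudes
    pdry = params.p0_mm + params.precip_gain * altitudes
    pdry = pdry + np.where(side_col == "wet", params.rain_shadow_offset, 0.0)
    rh = np.where(side_col == "wet", params.rh_wet, params.rh_dry)
    vp = rh * _climate.svp(tmin)

    sites = pd.DataFrame({
        "site_id": [f"S{i + 1:02d}" for i in range(n)],
        "altitude_m": altitudes,
        "tmin_c": tmin,
        "pdry_mm": pdry,
        "vp_kpa": vp,
        "side": side_col,
    })
    return _climate.annotate_sites(sites)


def simulate_trait_table(
    params: TraitSimParams, sites: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate a per-bee trait table joined to site climate.

    Species occupy altitude-limited ranges; each bee's species is drawn among
    those whose range covers its site, weighted by the species' sampling
    weight.  Bees are shuffled into measurement blocks of
    ``channels_per_block`` chambers, so blocks cut across sites and the
    block/channel random intercepts are identifiable.  Returns the table and
    a truth dict with every coefficient and variance component used.
    """
    params.validate()
    if sites is None:
        sites = simulate_climate_gradient(params)
    if len(sites) == 0:
        raise ValueError("sites table is empty")
    rng = np.random.default_rng(params.seed)

    rows = []
    for _, site in sites.iterrows():
        alt = site["altitude_m"]
        names, weights = [], []
        for name, (lo, hi, w, _mass) in params.species_ranges.items():
            if lo <= alt <= hi:
                names.append(name)
                weights.append(w)
        if not names:  # no species covers this altitude; nearest range wins
            names = [min(
                params.species_ranges,
                key=lambda s: min(abs(alt - params.species_ranges[s][0]),
                                  abs(alt - params.species_ranges[s][1])),
            )]
            weights = [1.0]
        pw = np.asarray(weights) / np.sum(weights)
        for _ in range(params.n_per_site):
            sp = rng.choice(names, p=pw)
            rows.append({"site_id": site["site_id"], "species": str(sp)})
    bees = pd.DataFrame(rows)

    # measurement design: shuffle bees, fill blocks of `channels_per_block`
    perm = rng.permutation(len(bees))
    bees = bees.iloc[perm].reset_index(drop=True)
    idx = np.arange(len(bees))
    bees["block_id"] = [f"B{i // params.channels_per_block + 1:02d}" for i in idx]
    bees["channel_id"] = [f"ch{i % params.channels_per_block + 1}" for i in idx]
    bees["sex"] = rng.choice(["F", "M"], size=len(bees))
    bees["bee_id"] = [f"bee{i + 1:03d}" for i in idx]

    mass_mu = bees["species"].map(
        {k: v[3] for k, v in params.species_ranges.items()}
    ).to_numpy(dtype=float)
    log10_mass = rng.normal(mass_mu, params.sd_log10_mass)
    bees["mass_mg"] = 10.0 ** log10_mass

    joined = bees.merge(sites, on="site_id", how="left", validate="many_to_one")

    blocks = joined["block_id"].unique()
    channels = joined["channel_id"].unique()
    u_block = dict(zip(blocks, rng.normal(0.0, params.sd_block, len(blocks))))
    u_chan = dict(zip(channels, rng.normal(0.0, params.sd_channel, len(channels))))
    v_block = dict(zip(blocks, rng.normal(0.0, params.fge_sd_block, len(blocks))))
    v_chan = dict(zip(channels, rng.normal(0.0, params.fge_sd_channel, len(channels))))

    lin = (
        params.beta0
        + params.beta_mass * log10_mass
        + params.beta_T * joined["tmin_c"].to_numpy()
        + params.beta_P * joined["pdry_mm"].to_numpy()
    )
    log10_mr = (
        lin
        + joined["block_id"].map(u_block).to_numpy()
        + joined["channel_id"].map(u_chan).to_numpy()
        + rng.normal(0.0, params.sd_resid, len(joined))
    )
    slopes = joined["species"].map(params.species_slopes).to_numpy(dtype=float)
    fge = (
        params.fge_intercept
        + slopes * log10_mr
        + params.fge_beta_mass * log10_mass
        + joined["block_id"].map(v_block).to_numpy()
        + joined["channel_id"].map(v_chan).to_numpy()
        + rng.normal(0.0, params.fge_sd_resid, len(joined))
    )

    joined["vco2_ml_min"] = 10.0 ** log10_mr
    joined["fge_min"] = fge

    truth = {
        "beta0": params.beta0,
        "beta_mass": params.beta_mass,
        "beta_T": params.beta_T,
        "beta_P": params.beta_P,
        "sd_block": params.sd_block,
        "sd_channel": params.sd_channel,
        "sd_resid": params.sd_resid,
        "species_slopes": dict(params.species_slopes),
        "fge_intercept": params.fge_intercept,
        "fge_beta_mass": params.fge_beta_mass,
        "fixed_linear_predictor": np.asarray(lin),
        "seed": params.seed,
    }
    cols = [
        "bee_id", "species", "sex", "site_id", "block_id", "channel_id",
        "mass_mg", "vco2_ml_min", "fge_min",
        "altitude_m", "tmin_c", "pdry_mm", "vp_kpa", "svp_kpa", "vpd_kpa", "side",
    ]
    return joined[cols], truth
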