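"""Raw instrument time series to per-bottle, per-cycle production records.

The measurement setup multiplexes up to 16 incubation bottles through a
valve manifold onto two analyzers: a cavity ring-down spectrometer (CRDS)
reporting 12CH4/13CH4/12CO2/13CO2 in ppm, and a PTR-MS reporting the
H2S and CH3SH isotopologue channels m/z 35/36/49/50 in ppb.  Each port is
open for one dwell period (default 15 min) per multiplex cycle.

Processing steps:

1. :func:`demultiplex` — split the port-tagged series into per-bottle
   open-valve windows, discarding a configurable transient after each
   valve switch.
2. :func:`integrate_production` — trapezoidal integration of the
   background-subtracted concentration curve times the carrier flow,
   converted to moles with the ideal gas law.
3. :func:`window_delta` / :func:`compound_excess_ratio` /
   :func:`methanethiol_isotopologue_correct` — isotope quantities per
   window, including the 13C shoulder subtraction on the CH3SH m/z 50
   channel.
4. :func:`build_production_records` — the orchestrator producing the
   tidy record table (one row per bottle, cycle and gas).

Two operating modes are supported.  In ``accumulate_release`` mode the gas
accumulates while a bottle's port is closed and the released pulse during
the open window represents production over the whole multiplex cycle; a
residual-carryover correction (see :func:`build_production_records`)
restores exact mass closure.  In ``continuous_flow`` mode the carrier
flows permanently through every bottle and the window integral represents
the window only; per-cycle amounts are the mean window emission rate times
the multiplex period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .isotopes import excess_ratio
from .references import S33_REFERENCE, VPDB

__all__ = [
    "FlowConfig",
    "CRDS_CHANNELS",
    "PTRMS_CHANNELS",
    "R13C_NATURAL",
    "GAS_CONSTANT_L_ATM",
    "read_gas_timeseries",
    "write_gas_timeseries",
    "demultiplex",
    "integrate_production",
    "window_delta",
    "methanethiol_isotopologue_correct",
    "compound_excess_ratio",
    "build_production_records",
    "cumulative_by_bottle",
    "emission_reduction",
]

#: CRDS isotopologue channels (ppm).
CRDS_CHANNELS = ("12CH4", "13CH4", "12CO2", "13CO2")
#: PTR-MS isotopologue channels (ppb).
PTRMS_CHANNELS = ("mz35", "mz36", "mz49", "mz50")

#: Natural 13C/12C ratio (delta13C = -28.5 permil) used for the m/z 50
#: 13C-shoulder subtraction on methanethiol.
R13C_NATURAL = 0.01086

#: Ideal gas constant, L atm mol^-1 K^-1.
GAS_CONSTANT_L_ATM = 0.0820573661

_PPM = 1e-6
_PPB = 1e-9
#: Unit scale (mole fraction per reported unit) per channel.
CHANNEL_SCALE = {c: _PPM for c in CRDS_CHANNELS} | {c: _PPB for c in PTRMS_CHANNELS}


@dataclass(frozen=True)
class FlowConfig:
    """Carrier-gas and headspace geometry of the multiplexed setup.

    ``mode`` is ``"accumulate_release"`` (carrier flows only through the
    open port) or ``"continuous_flow"`` (carrier always on, nothing
    accumulates).  ``cycle_length_s`` is the valve dwell per port.
    """

    flow_rate_L_min: float
    headspace_volume_L: float
    cycle_length_s: float = 900.0
    mode: str = "accumulate_release"
    temperature_C: float = 23.0
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if self.flow_rate_L_min <= 0:
            raise ValueError("flow_rate_L_min must be > 0")
        if self.headspace_volume_L <= 0:
            raise ValueError("headspace_volume_L must be > 0")
        if self.cycle_length_s <= 0:
            raise ValueError("cycle_length_s must be > 0")
        if self.mode not in ("accumulate_release", "continuous_flow"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def molar_volume_L(self) -> float:
        """Molar volume of an ideal gas at the configured T and P, L/mol."""
        return GAS_CONSTANT_L_ATM * (self.temperature_C + 273.15) / self.pressure_atm


def read_gas_timeseries(path) -> pd.DataFrame:
    """Read a long-format instrument CSV with columns time_s, port, channel, value."""
    df = pd.read_csv(path)
    required = {"time_s", "port", "channel", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    bad = set(df["channel"]) - set(CHANNEL_SCALE)
    if bad:
        raise ValueError(f"unknown channels: {sorted(bad)}")
    if not df["port"].between(1, 16).all():
        raise ValueError("port numbers must lie in 1..16")
    for ch, grp in df.groupby("channel"):
        t = grp["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"timestamps not strictly increasing within channel {ch}")
    return df


def write_gas_timeseries(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=["time_s", "port", "channel", "value"])


def demultiplex(
    series: pd.DataFrame,
    port_map: Mapping[str, int] | Mapping[int, int],
    transient_discard_s: float = 120.0,
) -> pd.DataFrame:
    """Assign each sample to a (bottle, cycle) open-valve window.

    Windows are the maximal contiguous runs of a constant port in the
    time-ordered series.  The first ``transient_discard_s`` seconds of
    each window are dropped (valve-switch transient).  Every port present
    in the series must appear in ``port_map`` (bottle -> port); samples
    are assigned exactly once.

    Returns the series with ``bottle``, ``cycle`` (0-based per bottle),
    ``window_start_s`` and ``window_end_s`` columns added, transient
    samples removed.
    """
    inverse: dict[int, object] = {}
    for bottle, port in port_map.items():
        if port in inverse:
            raise ValueError(f"port {port} mapped to both {inverse[port]!r} and {bottle!r}")
        inverse[int(port)] = bottle
    present = set(int(p) for p in series["port"].unique())
    unmapped = sorted(present - set(inverse))
    if unmapped:
        raise ValueError(f"ports present in series but missing from port map: {unmapped}")

    df = series.sort_values("time_s", kind="stable").reset_index(drop=True)
    run_id = (df["port"] != df["port"].shift()).cumsum()
    df["_run"] = run_id
    starts = df.groupby("_run")["time_s"].transform("min")
    ends = df.groupby("_run")["time_s"].transform("max")
    df["window_start_s"] = starts
    df["window_end_s"] = ends
    df["bottle"] = df["port"].map(lambda p: inverse[int(p)])
    # cycle index: enumeration of runs per bottle
    run_per_bottle = df.drop_duplicates("_run")[["_run", "bottle"]]
    run_per_bottle = run_per_bottle.assign(
        cycle=run_per_bottle.groupby("bottle").cumcount()
    )
    df = df.merge(run_per_bottle[["_run", "cycle"]], on="_run")
    keep = df["time_s"] >= df["window_start_s"] + transient_discard_s
    return df.loc[keep].drop(columns="_run").reset_index(drop=True)


def integrate_production(
    times_s: np.ndarray,
    conc: np.ndarray,
    flow: FlowConfig,
    background: float = 0.0,
    unit_scale: float = _PPM,
) -> float:
    """Moles of gas vented during a window, by trapezoidal integration.

    ``conc`` is in the channel's reporting unit (``unit_scale`` mole
    fraction per unit, ppm by default); ``background`` in the same unit.
    Negative integrals are clipped to zero; a warning is raised only when
    the deficit is large relative to the window's absolute signal (i.e.
    not plain zero-mean noise around the background).
    """
    times_s = np.asarray(times_s, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times_s.size < 2:
        raise ValueError("window must contain at least 2 samples")
    if background < 0:
        raise ValueError("background must be >= 0")
    excess = (conc - background) * unit_scale
    liters = np.trapezoid(excess, times_s) * flow.flow_rate_L_min / 60.0
    mol = liters / flow.molar_volume_L
    if mol < 0:
        abs_mol = (
            np.trapezoid(np.abs(excess), times_s)
            * flow.flow_rate_L_min / 60.0 / flow.molar_volume_L
        )
        # a zero-signal channel integrates to +/- noise; only a deficit
        # comparable to the window's absolute signal indicates a
        # misconfigured background
        if -mol > 0.5 * abs_mol and -mol > 1e-12:
            warnings.warn(
                f"negative window integral ({mol:.3e} mol) clipped to 0", stacklevel=2
            )
        mol = 0.0
    return mol


def window_delta(light_mol: float, heavy_mol: float) -> tuple[float, str]:
    """Flux-weighted delta13C (permil vs VPDB) of a window from isotopologue integrals.

    Returns ``(delta_permil, qc_flag)``.  A zero light integral yields
    ``(nan, "undefined")``; a zero heavy integral yields the invalid
    sentinel ``(-1000.0, "invalid_zero_heavy")``.
    """
    if light_mol <= 0:
        return float("nan"), "undefined"
    if heavy_mol <= 0:
        return -1000.0, "invalid_zero_heavy"
    return 1000.0 * (heavy_mol / light_mol / VPDB.ratio - 1.0), ""


def methanethiol_isotopologue_correct(s49: float, s50: float) -> float:
    """33S/32S signal ratio of CH3SH after subtracting the 13C shoulder.

    The m/z 50 channel carries both CH3-33SH and the 13C isotopologue of
    CH3-32SH; the latter is removed assuming the natural 13C/12C ratio
    1.086 %.  The result may be negative (retained for diagnostics).
    """
    if s49 <= 0:
        raise ValueError("m/z 49 signal must be > 0")
    return (s50 - R13C_NATURAL * s49) / s49


def compound_excess_ratio(
    light_integral: float, heavy_integral: float, carbon_corrected: bool = False
) -> tuple[float, str]:
    """Excess 33S/32S ratio (percent) of a window from isotopologue integrals.

    For H2S pass the raw m/z 35 and 36 integrals; for CH3SH pass m/z 49
    and 50 with ``carbon_corrected=True`` to subtract the 13C shoulder
    first.  Returns ``(rex_percent, qc_flag)``; a negative corrected ratio
    is retained and flagged.
    """
    if light_integral <= 0:
        return float("nan"), "undefined"
    ratio = heavy_integral / light_integral
    if carbon_corrected:
        ratio -= R13C_NATURAL
    rex = 100.0 * (ratio - S33_REFERENCE.ratio)
    flag = "negative_ratio" if ratio < 0 else ""
    return rex, flag


#: gas -> (light channel, heavy channel, isotope kind)
_GAS_CHANNELS = {
    "CH4": ("12CH4", "13CH4", "carbon"),
    "CO2": ("12CO2", "13CO2", "carbon"),
    "H2S": ("mz35", "mz36", "sulfur"),
    "CH3SH": ("mz49", "mz50", "sulfur_carbon_corrected"),
}


def _window_channel_integrals(
    grp: pd.DataFrame,
    flow: FlowConfig,
    backgrounds: Mapping[str, float],
    gains: Mapping[str, float],
) -> dict[str, tuple[float, float]]:
    """Per-channel (vented mol, last excess concentration in mole fraction)."""
    out: dict[str, tuple[float, float]] = {}
    for ch, sub in grp.groupby("channel"):
        t = sub["time_s"].to_numpy()
        v = sub["value"].to_numpy() * gains.get(ch, 1.0)
        bg = backgrounds.get(ch, 0.0)
        scale = CHANNEL_SCALE[ch]
        if t.size < 2:
            continue
        mol = integrate_production(t, v, flow, bg, unit_scale=scale)
        out[ch] = (mol, (v[-1] - bg) * scale)
    return out


def build_production_records(
    series: pd.DataFrame,
    port_map: Mapping,
    flow: FlowConfig,
    backgrounds: Optional[Mapping[str, float]] = None,
    gains: Optional[Mapping[str, float]] = None,
    transient_discard_s: float = 120.0,
    tail_correction: bool = True,
) -> pd.DataFrame:
    """Tidy production-record table from a raw multiplexed series.

    One row per (bottle, cycle, gas) with columns ``bottle, cycle,
    t_mid_s, gas, amount_mol, delta_permil, rex_percent, qc_flags``.

    In ``accumulate_release`` mode with ``tail_correction`` the washout
    tail truncated at each window end is added analytically as
    V*(C_end - background) and the residual inherited from the bottle's
    previous window is subtracted, which telescopes to exact mass closure
    over the experiment.  With ``tail_correction=False`` the pure
    truncated integral is reported.  In ``continuous_flow`` mode window
    integrals are scaled to the multiplex period inferred from
    consecutive window starts.
    """
    backgrounds = dict(backgrounds or {})
    gains = dict(gains or {})
    demuxed = demultiplex(series, port_map, transient_discard_s)
    rows = []
    for bottle, bdf in demuxed.groupby("bottle", sort=False):
        cycles = sorted(bdf["cycle"].unique())
        starts = bdf.groupby("cycle")["window_start_s"].min()
        if len(starts) > 1:
            periods = np.diff(starts.sort_index().to_numpy())
            period_s = float(np.median(periods))
        else:
            period_s = flow.cycle_length_s
        prev_residual: dict[str, float] = {}
        for cyc in cycles:
            grp = bdf[bdf["cycle"] == cyc]
            t0 = grp["window_start_s"].iloc[0]
            t1 = grp["window_end_s"].iloc[0]
            integrals = _window_channel_integrals(grp, flow, backgrounds, gains)
            adjusted: dict[str, float] = {}
            for ch, (mol, c_end) in integrals.items():
                amount = mol
                if flow.mode == "accumulate_release" and tail_correction:
                    residual_mol = c_end * flow.headspace_volume_L / flow.molar_volume_L
                    amount = mol + residual_mol - prev_residual.get(ch, 0.0)
                    prev_residual[ch] = residual_mol
                elif flow.mode == "continuous_flow":
                    duration = t1 - t0
                    if duration > 0:
                        amount = mol * period_s / duration
                adjusted[ch] = max(amount, 0.0)
            for gas, (light_ch, heavy_ch, kind) in _GAS_CHANNELS.items():
                if light_ch not in adjusted and heavy_ch not in adjusted:
                    continue
                light = adjusted.get(light_ch, 0.0)
                heavy = adjusted.get(heavy_ch, 0.0)
                amount = light + heavy
                delta = np.nan
                rex = np.nan
                if kind == "carbon":
                    delta, flag = window_delta(light, heavy)
                elif kind == "sulfur":
                    rex, flag = compound_excess_ratio(light, heavy)
                else:
                    rex, flag = compound_excess_ratio(light, heavy, carbon_corrected=True)
                    if light > 0:
                        # remove the 13C shoulder from the amount as well
                        amount = light + max(heavy - R13C_NATURAL * light, 0.0)
                rows.append(
                    {
                        "bottle": bottle,
                        "cycle": cyc,
                        "t_mid_s": 0.5 * (t0 + t1),
                        "gas": gas,
                        "amount_mol": amount,
                        "delta_permil": delta,
                        "rex_percent": rex,
                        "qc_flags": flag,
                    }
                )
    return pd.DataFrame(rows)


def cumulative_by_bottle(records: pd.DataFrame, gas: str) -> pd.Series:
    """Cumulative emission (mol) per bottle for one gas."""
    sub = records[records["gas"] == gas]
    if sub.empty:
        raise ValueError(f"no records for gas {gas!r}")
    return sub.groupby("bottle")["amount_mol"].sum()


def emission_reduction(
    treated: pd.DataFrame | Iterable[float],
    control: pd.DataFrame | Iterable[float],
    gas: Optional[str] = None,
) -> tuple[float, float]:
    """Percent emission reduction of treated vs control bottles, with SD.

    Accepts production-record tables (then ``gas`` selects the compound and
    records are restricted to the common time range before summing per
    bottle) or iterables of per-replicate cumulative totals.  Returns
    ``(reduction_percent, sd_percent)`` where the SD is first-order
    propagated from the replicate scatter of both group means; positive
    values mean the treatment reduced emission.
    """
    if isinstance(treated, pd.DataFrame) or isinstance(control, pd.DataFrame):
        if gas is None:
            raise ValueError("gas must be given when passing record tables")
        t0 = max(treated["t_mid_s"].min(), control["t_mid_s"].min())
        t1 = min(treated["t_mid_s"].max(), control["t_mid_s"].max())
        treated = cumulative_by_bottle(
            treated[(treated["t_mid_s"] >= t0) & (treated["t_mid_s"] <= t1)], gas
        ).to_numpy()
        control = cumulative_by_bottle(
            control[(control["t_mid_s"] >= t0) & (control["t_mid_s"] <= t1)], gas
        ).to_numpy()
    t = np.asarray(list(treated), dtype=float)
    c = np.asarray(list(control), dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("need >= 2 replicates per group")
    cbar = c.mean()
    if cbar <= 0:
        raise ValueError("control emission is zero; reduction undefined")
    tbar = t.mean()
    reduction = 100.0 * (1.0 - tbar / cbar)
    se_t2 = t.var(ddof=1) / t.size
    se_c2 = c.var(ddof=1) / c.size
    sd = 100.0 * np.sqrt(se_t2 / cbar**2 + (tbar**2 / cbar**4) * se_c2)
    return reduction, sd
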