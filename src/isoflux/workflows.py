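"""Composed pipeline steps: simulation output to fitted quantities.

These helpers wire the stages together the way an analysis script would:
process a simulated (or real) series into production records, pair the
CH4/CO2 windows, and run the pathway fits and sulfur apportionment.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .headspace import FlowConfig, build_production_records
from .isotopes import DeltaValue
from .pathways import FitResult, SulfurApportionment, apportion_sulfur, fit_pathway_fractions
from .simulate import SimulationResult

__all__ = [
    "records_from_simulation",
    "emission_weighted_rex",
    "paired_carbon_observations",
    "fit_carbon_from_records",
    "apportion_sulfur_from_records",
]


def records_from_simulation(
    result: SimulationResult,
    flow: FlowConfig,
    transient_discard_s: float = 0.0,
    tail_correction: bool = True,
) -> pd.DataFrame:
    """Production records from a simulation (no port-switch transient is
    modeled, so no discard by default)."""
    return build_production_records(
        result.series,
        result.ledger["port_map"],
        flow,
        transient_discard_s=transient_discard_s,
        tail_correction=tail_correction,
    )


def emission_weighted_rex(records: pd.DataFrame, gas: str) -> float:
    """Emission-weighted mean excess ratio (percent) over all valid windows."""
    sub = records[(records["gas"] == gas) & records["rex_percent"].notna()]
    if sub.empty or sub["amount_mol"].sum() <= 0:
        raise ValueError(f"no valid {gas} windows with positive emission")
    return float(np.average(sub["rex_percent"], weights=sub["amount_mol"]))


def paired_carbon_observations(records: pd.DataFrame) -> pd.DataFrame:
    """CH4/CO2 windows paired by (bottle, cycle), valid deltas only."""
    ch4 = records[(records["gas"] == "CH4") & records["delta_permil"].notna()]
    co2 = records[(records["gas"] == "CO2") & records["delta_permil"].notna()]
    paired = ch4.merge(co2, on=["bottle", "cycle"], suffixes=("_ch4", "_co2"))
    return paired[
        (paired["amount_mol_ch4"] > 0)
        & (paired["amount_mol_co2"] > 0)
        & (paired["qc_flags_ch4"].fillna("") == "")
        & (paired["qc_flags_co2"].fillna("") == "")
    ]


def fit_carbon_from_records(
    records: pd.DataFrame,
    delta_methyl: DeltaValue,
    delta_carboxyl: DeltaValue = DeltaValue(-28.5),
    delta_bg_co2: DeltaValue = DeltaValue(10.0),
    weight_permil: float = 5.0,
    **kwargs,
) -> FitResult:
    """Pathway-fraction fit over all paired windows of a record table."""
    obs = paired_carbon_observations(records)
    if obs.empty:
        raise ValueError("no paired CH4/CO2 observations")
    return fit_pathway_fractions(
        obs["delta_permil_ch4"].to_numpy(),
        obs["delta_permil_co2"].to_numpy(),
        obs["amount_mol_ch4"].to_numpy(),
        obs["amount_mol_co2"].to_numpy(),
        delta_methyl=delta_methyl,
        delta_carboxyl=delta_carboxyl,
        delta_bg_co2=delta_bg_co2,
        weight_ch4=weight_permil,
        weight_co2=weight_permil,
        **kwargs,
    )


def apportion_sulfur_from_records(
    records: pd.DataFrame,
    rex_so4_percent: float,
    with_ch3sh: bool = True,
) -> SulfurApportionment:
    """Source apportionment from emission-weighted record excess ratios."""
    rex_h2s = emission_weighted_rex(records, "H2S")
    rex_ch3sh = emission_weighted_rex(records, "CH3SH") if with_ch3sh else None
    return apportion_sulfur(rex_so4_percent, rex_h2s, rex_ch3sh)
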