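"""Exact conversions among delta values, isotope ratios and atom fractions.

Deltas are reported in per mil (permil) against a named reference; excess
ratios in percent.  All pool mixing is done in atom-fraction space, where
amount-weighted averaging is exact; delta-space averaging is a linear
approximation that breaks down at the enrichment levels reached by
methyl-labeled acetate (delta13C up to ~28 000 permil).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .references import IsotopeReference, S33_REFERENCE, VPDB

__all__ = [
    "DeltaValue",
    "ExcessRatio",
    "IsotopePool",
    "delta_from_ratio",
    "ratio_from_delta",
    "excess_ratio",
    "ratio_from_excess",
    "atom_fraction_from_ratio",
    "ratio_from_atom_fraction",
    "atom_fraction_from_delta",
    "delta_from_atom_fraction",
    "mix_pools",
]


@dataclass(frozen=True)
class DeltaValue:
    """Per-mil deviation of a heavy/light ratio from a reference ratio."""

    value: float  # permil
    reference: IsotopeReference = VPDB

    def __post_init__(self) -> None:
        if not self.value > -1000.0:
            raise ValueError(
                f"delta must exceed -1000 permil (ratio must stay positive), got {self.value}"
            )

    @property
    def ratio(self) -> float:
        return ratio_from_delta(self)

    @property
    def atom_fraction(self) -> float:
        return atom_fraction_from_ratio(self.ratio)


@dataclass(frozen=True)
class ExcessRatio:
    """Percentage-point excess of a heavy/light ratio over the reference ratio."""

    value: float  # percent
    reference: IsotopeReference = S33_REFERENCE

    def __post_init__(self) -> None:
        if self.value < -100.0 * self.reference.ratio:
            raise ValueError(
                f"excess {self.value} % implies a negative isotope ratio"
            )

    @property
    def ratio(self) -> float:
        return ratio_from_excess(self)


@dataclass(frozen=True)
class IsotopePool:
    """An element pool: amount of the element (mol) and heavy-isotope atom fraction."""

    amount: float
    heavy_fraction: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"pool amount must be >= 0, got {self.amount}")
        if not 0.0 <= self.heavy_fraction <= 1.0:
            raise ValueError(
                f"heavy_fraction must lie in [0, 1], got {self.heavy_fraction}"
            )

    @property
    def heavy_amount(self) -> float:
        return self.amount * self.heavy_fraction


def delta_from_ratio(sample_ratio: float, reference: IsotopeReference = VPDB) -> DeltaValue:
    """Delta value (permil) of ``sample_ratio`` against ``reference``."""
    if not sample_ratio > 0:
        raise ValueError(f"sample ratio must be > 0, got {sample_ratio}")
    return DeltaValue(1000.0 * (sample_ratio / reference.ratio - 1.0), reference)


def ratio_from_delta(delta: DeltaValue) -> float:
    """Heavy/light ratio corresponding to a delta value."""
    return delta.reference.ratio * (1.0 + delta.value / 1000.0)


def excess_ratio(
    heavy_count: float,
    light_count: float,
    reference: IsotopeReference = S33_REFERENCE,
) -> ExcessRatio:
    """Excess of heavy/light over the reference ratio, in percent.

    ``heavy_count``/``light_count`` may be mole amounts or (calibrated)
    signal integrals of the two isotopologue channels.
    """
    if light_count == 0:
        raise ValueError("light-isotopologue count is zero; excess ratio undefined")
    if light_count < 0:
        raise ValueError(f"light-isotopologue count must be > 0, got {light_count}")
    return ExcessRatio(100.0 * (heavy_count / light_count - reference.ratio), reference)


def ratio_from_excess(excess: ExcessRatio) -> float:
    return excess.reference.ratio + excess.value / 100.0


def atom_fraction_from_ratio(ratio: float) -> float:
    """Heavy atom fraction x = R/(1+R) of a heavy/light ratio R."""
    if ratio < 0:
        raise ValueError(f"isotope ratio must be >= 0, got {ratio}")
    return ratio / (1.0 + ratio)


def ratio_from_atom_fraction(fraction: float) -> float:
    """Heavy/light ratio R = x/(1-x) of a heavy atom fraction x."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"atom fraction must lie in [0, 1), got {fraction}")
    return fraction / (1.0 - fraction)


def atom_fraction_from_delta(delta: DeltaValue) -> float:
    return atom_fraction_from_ratio(ratio_from_delta(delta))


def delta_from_atom_fraction(
    fraction: float, reference: IsotopeReference = VPDB
) -> DeltaValue:
    return delta_from_ratio(ratio_from_atom_fraction(fraction), reference)


def mix_pools(pools: Iterable[IsotopePool] | Sequence[IsotopePool]) -> IsotopePool:
    """Amount-weighted mixture of element pools in atom-fraction space.

    Exact for any enrichment level; associative and order-independent up to
    floating-point rounding, and amount-conserving.
    """
    pools = list(pools)
    if not pools:
        raise ValueError("mix_pools requires at least one pool")
    total = math.fsum(p.amount for p in pools)
    if total == 0:
        raise ValueError("all pool amounts are zero; mixture undefined")
    heavy = math.fsum(p.heavy_amount for p in pools)
    return IsotopePool(amount=total, heavy_fraction=heavy / total)
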