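"""Label-design arithmetic: from amendment recipes to pool isotope compositions.

The tracer experiments spike an inoculum (swine manure or similar slurry)
with a mixture of unlabeled and isotopically labeled substrate:

* acetate labeled with 13C at the methyl (2-C) position, which anchors the
  carbon mass-balance inversion via the methyl-carbon delta13C of the total
  acetate pool; and
* sulfate labeled with 33S, which anchors the sulfur source apportionment
  via the excess 33S/32S ratio of the total sulfate pool.

Both computations are three-pool mixtures (inoculum pool + unlabeled spike
+ labeled spike) carried out in atom-fraction space with
:func:`isoflux.isotopes.mix_pools`.

Unit conversions from the printed recipes (mL of a molar stock, mg of a
salt) are exposed as tested helpers so the provenance of every mole amount
is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .isotopes import (
    DeltaValue,
    ExcessRatio,
    IsotopePool,
    atom_fraction_from_delta,
    delta_from_atom_fraction,
    excess_ratio,
    mix_pools,
)
from .references import NATURAL_SULFUR, S33_REFERENCE, SulfurAbundance, VPDB

__all__ = [
    "SpikePlan",
    "acetate_methyl_delta",
    "sulfate_excess_ratio",
    "sulfate_excess_with_uncertainty",
    "acetate_methyl_delta_with_uncertainty",
    "mol_from_volume",
    "mol_from_mass",
    "MOLAR_MASS_NA2SO4",
    "DELTA_UNLABELED_ACETATE",
    "swine_acetate_plan",
    "swine_sulfate_plan",
]

#: Molar mass of anhydrous sodium sulfate, g/mol.
MOLAR_MASS_NA2SO4 = 142.04

#: delta13C assigned to unlabeled acetate (slurry organic matter), permil vs VPDB.
DELTA_UNLABELED_ACETATE = DeltaValue(-28.5, VPDB)


def mol_from_volume(volume_mL: float, molarity_M: float) -> float:
    """Moles delivered by ``volume_mL`` of a stock of ``molarity_M`` mol/L."""
    if volume_mL < 0 or molarity_M < 0:
        raise ValueError("volume and molarity must be >= 0")
    return volume_mL * 1e-3 * molarity_M


def mol_from_mass(mass_g: float, molar_mass_g_mol: float) -> float:
    """Moles in ``mass_g`` grams of a compound of the given molar mass."""
    if mass_g < 0:
        raise ValueError("mass must be >= 0")
    if molar_mass_g_mol <= 0:
        raise ValueError("molar mass must be > 0")
    return mass_g / molar_mass_g_mol


@dataclass(frozen=True)
class SpikePlan:
    """One bottle's amendment recipe plus its inoculum pool.

    Parameters
    ----------
    inoculum_mass_g
        Mass of slurry per bottle, g.
    inoculum_pool_conc_mol_per_kg
        Concentration of the target compound (acetate or sulfate) in the
        slurry, mol per kg slurry.
    inoculum_delta
        Isotopic composition of the inoculum pool.  For carbon this is a
        :class:`DeltaValue`; ``None`` means reference (natural) composition,
        which is the convention for sulfate.
    unlabeled_spike_mol
        Moles of unlabeled compound added.
    labeled_spike_mol
        Moles of labeled compound added.
    label_purity
        Atom fraction of the labeled isotope at the labeled position
        (0 < purity <= 1).
    inoculum_pool_conc_sd
        Standard deviation of the inoculum concentration measurement,
        mol per kg; used only by the uncertainty-propagation helpers.
    """

    inoculum_mass_g: float
    inoculum_pool_conc_mol_per_kg: float
    unlabeled_spike_mol: float
    labeled_spike_mol: float
    label_purity: float
    inoculum_delta: Optional[DeltaValue] = None
    inoculum_pool_conc_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "inoculum_mass_g",
            "inoculum_pool_conc_mol_per_kg",
            "unlabeled_spike_mol",
            "labeled_spike_mol",
            "inoculum_pool_conc_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.label_purity <= 1.0:
            raise ValueError(f"label_purity must lie in (0, 1], got {self.label_purity}")

    @property
    def inoculum_pool_mol(self) -> float:
        return self.inoculum_mass_g * 1e-3 * self.inoculum_pool_conc_mol_per_kg


def acetate_methyl_delta(plan: SpikePlan) -> DeltaValue:
    """delta13C of the methyl (2-C) carbon of the pooled acetate after spiking.

    The inoculum acetate and the unlabeled spike are assigned the slurry
    organic-matter composition (-28.5 permil by default, overridable through
    ``plan.inoculum_delta``); the labeled spike carries ``label_purity`` 13C
    at the methyl position only (its carboxyl carbon is natural and does not
    enter the methyl pool).
    """
    natural = plan.inoculum_delta or DELTA_UNLABELED_ACETATE
    x_nat = atom_fraction_from_delta(natural)
    pools = [
        IsotopePool(plan.inoculum_pool_mol, x_nat),
        IsotopePool(plan.unlabeled_spike_mol, x_nat),
        IsotopePool(plan.labeled_spike_mol, plan.label_purity),
    ]
    mixture = mix_pools(pools)
    return delta_from_atom_fraction(mixture.heavy_fraction, natural.reference)


def sulfate_excess_ratio(
    plan: SpikePlan, abundance: SulfurAbundance = NATURAL_SULFUR
) -> ExcessRatio:
    """Excess 33S/32S ratio (percent) of the pooled sulfate after spiking.

    The inoculum sulfate and the unlabeled Na2SO4 spike are at natural
    composition (33S/32S equal to the reference ratio; 32S share taken from
    ``abundance``).  The labeled spike is ``label_purity`` 33S with its
    remainder spread over 32/34/36S in natural relative proportions.
    """
    natural_mol = plan.inoculum_pool_mol + plan.unlabeled_spike_mol
    if natural_mol + plan.labeled_spike_mol <= 0:
        raise ValueError("total sulfate pool is empty")
    s32 = natural_mol * abundance.x32 + plan.labeled_spike_mol * abundance.labeled_remainder_x32(
        plan.label_purity
    )
    s33 = natural_mol * abundance.x33 + plan.labeled_spike_mol * plan.label_purity
    return excess_ratio(s33, s32, S33_REFERENCE)


def _first_order_sd(f, plan: SpikePlan) -> float:
    """First-order propagated SD of f(plan) w.r.t. the inoculum concentration."""
    sd = plan.inoculum_pool_conc_sd
    if sd == 0:
        return 0.0
    c = plan.inoculum_pool_conc_mol_per_kg
    h = max(1e-6, 1e-4 * max(c, 1.0))
    up = f(replace(plan, inoculum_pool_conc_mol_per_kg=c + h)).value
    down = f(replace(plan, inoculum_pool_conc_mol_per_kg=max(0.0, c - h))).value
    return abs(up - down) / (2 * h) * sd


def acetate_methyl_delta_with_uncertainty(plan: SpikePlan) -> tuple[DeltaValue, float]:
    """Methyl delta13C plus first-order SD from the acetate-concentration SD."""
    return acetate_methyl_delta(plan), _first_order_sd(acetate_methyl_delta, plan)


def sulfate_excess_with_uncertainty(
    plan: SpikePlan, abundance: SulfurAbundance = NATURAL_SULFUR
) -> tuple[ExcessRatio, float]:
    """Sulfate excess ratio plus first-order SD from the sulfate-concentration SD."""
    f = lambda p: sulfate_excess_ratio(p, abundance)
    return f(plan), _first_order_sd(f, plan)


def swine_acetate_plan(
    inoculum_conc_mol_per_kg: float = 12.3e-3,
    inoculum_conc_sd: float = 0.7e-3,
) -> SpikePlan:
    """Methyl-13C acetate labeling recipe for a 100 g swine-manure bottle.

    Amendments: 2.15 mL of 1.67 M unlabeled sodium acetate plus 0.25 mL of
    1.67 M sodium acetate-2-13C at 99 atom% 13C.  The default inoculum
    acetate concentration (12.3 mmol/kg slurry) is a synthetic,
    back-calculated value consistent with the shipped label-design numbers;
    pass a measured concentration for real inocula.
    """
    return SpikePlan(
        inoculum_mass_g=100.0,
        inoculum_pool_conc_mol_per_kg=inoculum_conc_mol_per_kg,
        unlabeled_spike_mol=mol_from_volume(2.15, 1.67),
        labeled_spike_mol=mol_from_volume(0.25, 1.67),
        label_purity=0.99,
        inoculum_pool_conc_sd=inoculum_conc_sd,
    )


def swine_sulfate_plan(
    inoculum_conc_mol_per_kg: float = 2.86e-3,
    inoculum_conc_sd: float = 0.29e-3,
) -> SpikePlan:
    """33S-sulfate labeling recipe for a 40 g swine-manure bottle.

    Amendments: 17 mg anhydrous Na2SO4 (119.7 umol) plus 0.6 mL of a 20 mM
    sodium 33S-sulfate stock (12 umol) at 98 atom% 33S.  The default
    inoculum sulfate concentration (2.86 mmol/kg slurry) is a synthetic,
    back-calculated value consistent with the shipped label-design numbers;
    pass a measured concentration for real inocula.
    """
    return SpikePlan(
        inoculum_mass_g=40.0,
        inoculum_pool_conc_mol_per_kg=inoculum_conc_mol_per_kg,
        unlabeled_spike_mol=mol_from_mass(17e-3, MOLAR_MASS_NA2SO4),
        labeled_spike_mol=mol_from_volume(0.6, 20e-3),
        label_purity=0.98,
        inoculum_pool_conc_sd=inoculum_conc_sd,
    )
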