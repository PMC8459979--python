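"""Isotope reference ratios and natural-abundance bookkeeping.

A reference is an immutable heavy/light isotope ratio with a provenance
string.  Two references ship with the package:

* ``VPDB`` — the Vienna Peedee Belemnite carbon scale, 13C/12C = 0.01118.
* ``S33_REFERENCE`` — the 33S/32S ratio of the IAEA-S-1 sulfur reference
  material, 0.0078791, used as the zero point of excess-ratio reporting
  because no consensus delta-33S scale exists for V-CDT.

Additional references can be registered at run time with
:func:`register_reference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "IsotopeReference",
    "SulfurAbundance",
    "VPDB",
    "S33_REFERENCE",
    "NATURAL_SULFUR",
    "register_reference",
    "get_reference",
    "reference_table",
]


@dataclass(frozen=True)
class IsotopeReference:
    """An immutable heavy/light isotope ratio used as a reporting anchor."""

    name: str
    ratio: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError(f"reference ratio must be > 0, got {self.ratio}")


VPDB = IsotopeReference(
    name="VPDB",
    ratio=0.01118,
    provenance="Vienna Peedee Belemnite 13C/12C, anchored to NBS-19 (+1.95 permil) "
    "and L-SVEC (-46.6 permil)",
)

S33_REFERENCE = IsotopeReference(
    name="33S-reference",
    ratio=0.0078791,
    provenance="33S/32S of the IAEA-S-1 reference material",
)

_REGISTRY: dict[str, IsotopeReference] = {
    VPDB.name: VPDB,
    S33_REFERENCE.name: S33_REFERENCE,
}


def register_reference(ref: IsotopeReference) -> IsotopeReference:
    """Register a user-supplied reference; shipped references cannot be replaced."""
    if ref.name in (VPDB.name, S33_REFERENCE.name):
        raise ValueError(f"cannot replace shipped reference {ref.name!r}")
    _REGISTRY[ref.name] = ref
    return ref


def get_reference(name: str) -> IsotopeReference:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown isotope reference {name!r}; known: {sorted(_REGISTRY)}"
        ) from None


def reference_table():
    """All registered references as a :class:`pandas.DataFrame` (name, ratio, provenance)."""
    import pandas as pd

    return pd.DataFrame(
        [(r.name, r.ratio, r.provenance) for r in _REGISTRY.values()],
        columns=["name", "ratio", "provenance"],
    )


@dataclass(frozen=True)
class SulfurAbundance:
    """Sulfur isotope abundance vector for the two-plus-other model.

    Only the 32S/33S pair is observable at the measured m/z channels
    (35/36 for H2S, 49/50 for CH3SH); 34S and 36S are lumped into an
    invisible "other" share.  The 33S fraction is tied to the reference
    ratio so that a natural pool has zero excess by construction.
    """

    x32: float = 0.9499
    x34: float = 0.0425
    x36: float = 0.0001

    @property
    def x33(self) -> float:
        return self.x32 * S33_REFERENCE.ratio

    @property
    def other(self) -> float:
        return self.x34 + self.x36

    def labeled_remainder_x32(self, purity: float) -> float:
        """32S atom fraction of a labeled spike of given 33S ``purity``.

        The non-33S remainder is distributed across 32/34/36S in natural
        relative proportions (vendor certificates do not specify it).
        """
        non33 = self.x32 + self.x34 + self.x36
        return (1.0 - purity) * self.x32 / non33


NATURAL_SULFUR = SulfurAbundance()
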