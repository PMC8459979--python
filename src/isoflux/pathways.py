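"""Pathway partitioning from isotope signatures.

Carbon
------
Methane in the slurry forms along three routes: acetoclastic
methanogenesis (the acetate methyl carbon becomes CH4, the carboxyl
carbon becomes CO2), syntrophic acetate oxidation coupled to
hydrogenotrophic methanogenesis (SAO-HM: both acetate carbons are
oxidized to CO2, then CH4 is formed by CO2 reduction), and background
hydrogenotrophic methanogenesis from non-acetate CO2.  With the methyl
position 13C-labeled, the two routes leave distinct fingerprints on
delta13C_CH4 and delta13C_CO2, and a static two-parameter mass balance
can be inverted for

* ``f_ac`` — the fraction of CH4 carbon derived from acetate, and
* ``f_am`` — the fraction of acetate-derived CH4 formed acetoclastically
  (1 - f_am is the SAO-HM share).

:func:`forward_deltas` evaluates the model; :func:`fit_pathway_fractions`
inverts it by weighted least squares on a coarse grid followed by bounded
local refinement, returning the full objective grid so flat valleys
(ill-identified fits) are visible.

All mixing is in atom-fraction space.  Fractionation offsets ``eps_ac``
and ``eps_hm`` (permil, additive on the product delta) default to zero;
at methyl enrichments of several thousand permil the fitted fractions are
insensitive to them.

Sulfur
------
With the sulfate pool 33S-labeled at excess ratio Rex(SO4) and the
s-amino-acid pools unlabeled, two-endmember mixing gives the source
fractions directly: the sulfate-derived share of H2S is
Rex(H2S)/Rex(SO4) and the methylation-derived share of CH3SH is
Rex(CH3SH)/Rex(H2S) (the methylation donor is contemporaneous H2S; the
remainder is methionine degradation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

from .isotopes import DeltaValue, ExcessRatio
from .references import VPDB

__all__ = [
    "CarbonPathwayParams",
    "FitResult",
    "Fraction",
    "SulfurApportionment",
    "forward_deltas",
    "fit_pathway_fractions",
    "sulfate_fraction_h2s",
    "methylation_fraction_ch3sh",
    "apportion_sulfur",
]

_RV = VPDB.ratio


def _x_of_delta(delta_permil):
    """Atom fraction from delta13C (permil vs VPDB); vectorized."""
    r = _RV * (1.0 + np.asarray(delta_permil, dtype=float) / 1000.0)
    return r / (1.0 + r)


def _delta_of_x(x):
    """delta13C (permil vs VPDB) from atom fraction; vectorized."""
    x = np.asarray(x, dtype=float)
    r = x / (1.0 - x)
    return 1000.0 * (r / _RV - 1.0)


def _shift(x_source, eps_permil):
    """Apply an additive permil fractionation to the delta of ``x_source``."""
    if eps_permil == 0:
        return x_source
    return _x_of_delta(_delta_of_x(x_source) + eps_permil)


@dataclass(frozen=True)
class CarbonPathwayParams:
    """Parameters of the static carbon mass-balance model.

    ``sao_source`` selects the composition of the CO2 reduced by the
    SAO-coupled methanogens: ``"acetate_pool"`` (default) draws from the
    well-mixed acetate-derived CO2 sub-pool (atom-fraction mean of methyl
    and carboxyl), ``"bulk_co2"`` draws from the whole CO2 pool
    (sensitivity variant).
    """

    f_ac: float
    f_am: float
    delta_methyl: DeltaValue
    delta_carboxyl: DeltaValue = DeltaValue(-28.5)
    delta_bg_co2: DeltaValue = DeltaValue(10.0)
    eps_ac: float = 0.0
    eps_hm: float = 0.0
    sao_source: str = "acetate_pool"

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_ac <= 1.0:
            raise ValueError(f"f_ac must lie in [0, 1], got {self.f_ac}")
        if not 0.0 <= self.f_am <= 1.0:
            raise ValueError(f"f_am must lie in [0, 1], got {self.f_am}")
        if self.sao_source not in ("acetate_pool", "bulk_co2"):
            raise ValueError(f"unknown sao_source {self.sao_source!r}")


def _forward_x(
    f_ac,
    f_am,
    x_me: float,
    x_cx: float,
    x_bg: float,
    eps_ac: float,
    eps_hm: float,
    m_ch4,
    m_co2,
    sao_source: str = "acetate_pool",
):
    """Atom fractions (x_CH4, x_CO2) of the product gases; broadcasts over f_ac/f_am."""
    f_ac = np.asarray(f_ac, dtype=float)
    f_am = np.asarray(f_am, dtype=float)
    x_mean = 0.5 * (x_me + x_cx)

    # CO2 pool: carboxyl from the acetoclastic route, net acetate-mean
    # carbon from the SAO route, background for the remainder
    w_aceto = f_ac * f_am * m_ch4
    w_sao = f_ac * (1.0 - f_am) * m_ch4
    w_bg_co2 = m_co2 - f_ac * m_ch4
    x_co2 = (w_aceto * x_cx + w_sao * x_mean + w_bg_co2 * x_bg) / m_co2

    x_sao_src = x_co2 if sao_source == "bulk_co2" else x_mean
    x_ch4 = (
        f_ac * f_am * _shift(x_me, eps_ac)
        + f_ac * (1.0 - f_am) * _shift(x_sao_src, eps_hm)
        + (1.0 - f_ac) * _shift(x_bg, eps_hm)
    )
    return x_ch4, x_co2


def forward_deltas(
    params: CarbonPathwayParams, m_ch4: float, m_co2: float
) -> tuple[float, float]:
    """Modeled (delta13C_CH4, delta13C_CO2) in permil for one interval.

    ``m_ch4`` and ``m_co2`` are the moles of carbon emitted as CH4 and CO2
    over the interval; the CO2 pool must accommodate the acetate-derived
    CO2, i.e. ``m_co2 >= f_ac * m_ch4``.
    """
    if not m_ch4 > 0:
        raise ValueError(f"m_ch4 must be > 0, got {m_ch4}")
    if not m_co2 > 0:
        raise ValueError(f"m_co2 must be > 0, got {m_co2}")
    if m_co2 < params.f_ac * m_ch4 - 1e-12 * m_ch4:
        raise ValueError(
            f"CO2 pool too small: m_co2 ({m_co2}) < f_ac*m_ch4 "
            f"({params.f_ac * m_ch4}); the acetate-derived CO2 does not fit"
        )
    x_ch4, x_co2 = _forward_x(
        params.f_ac,
        params.f_am,
        params.delta_methyl.atom_fraction,
        params.delta_carboxyl.atom_fraction,
        params.delta_bg_co2.atom_fraction,
        params.eps_ac,
        params.eps_hm,
        m_ch4,
        m_co2,
        params.sao_source,
    )
    return float(_delta_of_x(x_ch4)), float(_delta_of_x(x_co2))


@dataclass
class FitResult:
    """Outcome of the two-parameter inversion."""

    f_ac: float
    f_am: float
    objective: float
    residuals_ch4: np.ndarray
    residuals_co2: np.ndarray
    converged: bool
    on_boundary: bool
    grid_f_ac: np.ndarray
    grid_f_am: np.ndarray
    grid_objective: np.ndarray

    def summary(self) -> str:
        edge = " (boundary solution)" if self.on_boundary else ""
        return (
            f"f_ac = {self.f_ac:.3f}, f_am = {self.f_am:.3f}, "
            f"objective = {self.objective:.4g}{edge}"
        )


def fit_pathway_fractions(
    delta_ch4_obs: Sequence[float],
    delta_co2_obs: Sequence[float],
    m_ch4: Sequence[float] | float,
    m_co2: Sequence[float] | float,
    delta_methyl: DeltaValue,
    delta_carboxyl: DeltaValue = DeltaValue(-28.5),
    delta_bg_co2: DeltaValue = DeltaValue(10.0),
    eps_ac: float = 0.0,
    eps_hm: float = 0.0,
    sao_source: str = "acetate_pool",
    weight_ch4: float = 1.0,
    weight_co2: float = 1.0,
    grid_step: float = 0.005,
) -> FitResult:
    """Weighted least-squares fit of (f_ac, f_am) to observed deltas.

    Minimizes sum_t [((dCH4_obs - dCH4_mod)/w_CH4)^2 +
    ((dCO2_obs - dCO2_mod)/w_CO2)^2] over the unit square, by exhaustive
    evaluation on a ``grid_step``-spaced grid followed by bounded local
    refinement (L-BFGS-B).  The grid is returned in the result so flat or
    multi-modal objectives are visible to the caller; a solution on the
    boundary of the square is flagged, not treated as an error.
    """
    d4 = np.atleast_1d(np.asarray(delta_ch4_obs, dtype=float))
    d2 = np.atleast_1d(np.asarray(delta_co2_obs, dtype=float))
    n = d4.size
    if d2.size != n:
        raise ValueError("delta13C_CH4 and delta13C_CO2 series differ in length")
    if n == 0:
        raise ValueError("at least one observation is required")
    if not (np.isfinite(d4).all() and np.isfinite(d2).all()):
        raise ValueError("non-finite observations")
    if weight_ch4 <= 0 or weight_co2 <= 0:
        raise ValueError("weights must be > 0")
    m4 = np.broadcast_to(np.asarray(m_ch4, dtype=float), (n,)).copy()
    m2 = np.broadcast_to(np.asarray(m_co2, dtype=float), (n,)).copy()
    if (m4 <= 0).any() or (m2 <= 0).any():
        raise ValueError("gas amounts must be > 0")

    x_me = delta_methyl.atom_fraction
    x_cx = delta_carboxyl.atom_fraction
    x_bg = delta_bg_co2.atom_fraction
    # feasibility: the acetate-derived CO2 must fit into the CO2 pool
    f_ac_max = float(min(1.0, np.min(m2 / m4)))

    def objective_vec(f_ac, f_am):
        """Objective for broadcastable f_ac, f_am arrays; shape preserved."""
        fa = np.asarray(f_ac, dtype=float)[..., None]
        fm = np.asarray(f_am, dtype=float)[..., None]
        x_ch4, x_co2 = _forward_x(
            fa, fm, x_me, x_cx, x_bg, eps_ac, eps_hm, m4, m2, sao_source
        )
        r4 = (_delta_of_x(x_ch4) - d4) / weight_ch4
        r2 = (_delta_of_x(x_co2) - d2) / weight_co2
        return np.sum(r4**2 + r2**2, axis=-1)

    g_ac = np.arange(0.0, f_ac_max + grid_step / 2, grid_step)
    g_am = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    fa_mesh, fm_mesh = np.meshgrid(g_ac, g_am, indexing="ij")
    grid_obj = objective_vec(fa_mesh.ravel(), fm_mesh.ravel()).reshape(fa_mesh.shape)
    i, j = np.unravel_index(np.argmin(grid_obj), grid_obj.shape)
    start = np.array([g_ac[i], g_am[j]])

    res = optimize.minimize(
        lambda p: float(objective_vec(np.array([p[0]]), np.array([p[1]]))[0]),
        start,
        method="L-BFGS-B",
        bounds=[(0.0, f_ac_max), (0.0, 1.0)],
    )
    best = res.x if res.fun <= grid_obj[i, j] else start
    best_obj = float(min(res.fun, grid_obj[i, j]))

    x_ch4, x_co2 = _forward_x(
        best[0], best[1], x_me, x_cx, x_bg, eps_ac, eps_hm, m4, m2, sao_source
    )
    tol = 1e-9
    on_boundary = bool(
        best[0] < tol or best[0] > f_ac_max - tol or best[1] < tol or best[1] > 1 - tol
    )
    return FitResult(
        f_ac=float(best[0]),
        f_am=float(best[1]),
        objective=best_obj,
        residuals_ch4=_delta_of_x(x_ch4) - d4,
        residuals_co2=_delta_of_x(x_co2) - d2,
        converged=bool(res.success),
        on_boundary=on_boundary,
        grid_f_ac=g_ac,
        grid_f_am=g_am,
        grid_objective=grid_obj,
    )


@dataclass(frozen=True)
class Fraction:
    """A mixing fraction clipped to [0, 1] with the raw value retained."""

    value: float
    raw: float

    @property
    def clipped(self) -> bool:
        return self.value != self.raw


def _as_percent(rex: Union[ExcessRatio, float]) -> float:
    return rex.value if isinstance(rex, ExcessRatio) else float(rex)


def sulfate_fraction_h2s(
    rex_h2s: Union[ExcessRatio, float], rex_so4: Union[ExcessRatio, float]
) -> Fraction:
    """Fraction of H2S derived from sulfate reduction.

    Two-endmember mixing between the labeled sulfate pool (excess
    Rex(SO4)) and unlabeled s-amino-acid sulfur (zero excess):
    f = Rex(H2S)/Rex(SO4).  Scale-invariant in the common Rex scale.
    """
    so4 = _as_percent(rex_so4)
    if so4 <= 0:
        raise ValueError(f"Rex(SO4) must be > 0 for apportionment, got {so4}")
    raw = _as_percent(rex_h2s) / so4
    return Fraction(value=float(np.clip(raw, 0.0, 1.0)), raw=raw)


def methylation_fraction_ch3sh(
    rex_ch3sh: Union[ExcessRatio, float], rex_h2s: Union[ExcessRatio, float]
) -> Fraction:
    """Fraction of CH3SH formed by H2S methylation (remainder: methionine).

    The methylation donor pool is contemporaneous H2S, so the labeled
    endmember is Rex(H2S): f = Rex(CH3SH)/Rex(H2S).
    """
    h2s = _as_percent(rex_h2s)
    if h2s <= 0:
        raise ValueError(f"Rex(H2S) must be > 0 for apportionment, got {h2s}")
    raw = _as_percent(rex_ch3sh) / h2s
    return Fraction(value=float(np.clip(raw, 0.0, 1.0)), raw=raw)


@dataclass(frozen=True)
class SulfurApportionment:
    """Excess ratios of the three sulfur pools and the derived source fractions."""

    rex_so4: float
    rex_h2s: float
    rex_ch3sh: float
    f_sulfate_reduction: Fraction
    f_methylation: Optional[Fraction] = None


def apportion_sulfur(
    rex_so4: Union[ExcessRatio, float],
    rex_h2s: Union[ExcessRatio, float],
    rex_ch3sh: Union[ExcessRatio, float, None] = None,
) -> SulfurApportionment:
    """Full two-stage sulfur apportionment from the three excess ratios."""
    f_sr = sulfate_fraction_h2s(rex_h2s, rex_so4)
    f_me = None
    if rex_ch3sh is not None:
        f_me = methylation_fraction_ch3sh(rex_ch3sh, rex_h2s)
    return SulfurApportionment(
        rex_so4=_as_percent(rex_so4),
        rex_h2s=_as_percent(rex_h2s),
        rex_ch3sh=_as_percent(rex_ch3sh) if rex_ch3sh is not None else float("nan"),
        f_sulfate_reduction=f_sr,
        f_methylation=f_me,
    )
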