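"""Carbon mass-balance model, its inversion, and sulfur source apportionment."""

from fractions import Fraction as Frac

import numpy as np
import pytest

from isoflux.isotopes import DeltaValue
from isoflux.pathways import (
    CarbonPathwayParams,
    Fraction,
    apportion_sulfur,
    fit_pathway_fractions,
    forward_deltas,
    methylation_fraction_ch3sh,
    sulfate_fraction_h2s,
)

D_METHYL = DeltaValue(7719.0)
D_CARBOXYL = DeltaValue(-28.5)
D_BG = DeltaValue(10.0)


def oracle_forward(f_ac, f_am, d_me, d_cx, d_bg, m_ch4, m_co2):
    """Independent atom-fraction bookkeeping in exact rational arithmetic."""
    rv = Frac(1118, 100000)

    def x(d):
        r = rv * (1 + Frac(d) / 1000)
        return r / (1 + r)

    def delta(xx):
        return float(1000 * ((xx / (1 - xx)) / rv - 1))

    f_ac, f_am = Frac(f_ac), Frac(f_am)
    m_ch4, m_co2 = Frac(m_ch4), Frac(m_co2)
    x_me, x_cx, x_bg = x(d_me), x(d_cx), x(d_bg)
    x_mean = (x_me + x_cx) / 2
    x_ch4 = f_ac * f_am * x_me + f_ac * (1 - f_am) * x_mean + (1 - f_ac) * x_bg
    x_co2 = (
        f_ac * f_am * m_ch4 * x_cx
        + f_ac * (1 - f_am) * m_ch4 * x_mean
        + (m_co2 - f_ac * m_ch4) * x_bg
    ) / m_co2
    return delta(x_ch4), delta(x_co2)


class TestForwardDeltas:
    def test_pure_acetoclastic_limit(self):
        p = CarbonPathwayParams(1.0, 1.0, D_METHYL, D_CARBOXYL, D_BG)
        d_ch4, d_co2 = forward_deltas(p, 1.0, 2.0)
        assert d_ch4 == pytest.approx(D_METHYL.value, abs=1e-9)
        # CO2 is a carboxyl/background mixture, between the two endmembers
        assert min(D_CARBOXYL.value, D_BG.value) < d_co2 < max(
            D_CARBOXYL.value, D_BG.value
        )

    def test_no_acetate_route_ignores_methyl_label(self):
        p1 = CarbonPathwayParams(0.0, 0.5, D_METHYL, D_CARBOXYL, D_BG, eps_hm=-30.0)
        p2 = CarbonPathwayParams(
            0.0, 0.5, DeltaValue(20000.0), D_CARBOXYL, D_BG, eps_hm=-30.0
        )
        d1, _ = forward_deltas(p1, 1.0, 2.0)
        d2, _ = forward_deltas(p2, 1.0, 2.0)
        assert d1 == pytest.approx(D_BG.value - 30.0, abs=1e-6)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_against_rational_oracle(self):
        """Frozen values from the exact-rational bookkeeping oracle."""
        p = CarbonPathwayParams(0.21, 0.0, D_METHYL, D_CARBOXYL, D_BG)
        d_ch4, d_co2 = forward_deltas(p, 1.0, 2.0)
        exp_ch4, exp_co2 = oracle_forward(
            Frac(21, 100), 0, 7719, Frac(-57, 2), 10, 1, 2
        )
        assert d_ch4 == pytest.approx(exp_ch4, abs=1e-9)
        assert d_co2 == pytest.approx(exp_co2, abs=1e-9)
        # magnitudes frozen from the oracle
        assert d_ch4 == pytest.approx(757.968, abs=1e-3)
        assert d_co2 == pytest.approx(382.444, abs=1e-3)

    @pytest.mark.parametrize("f_ac", [0.1, 0.21, 0.5, 0.9])
    @pytest.mark.parametrize("f_am", [0.0, 0.3, 0.7, 1.0])
    def test_matches_oracle_on_grid(self, f_ac, f_am):
        p = CarbonPathwayParams(f_ac, f_am, D_METHYL, D_CARBOXYL, D_BG)
        got = forward_deltas(p, 1.0, 2.0)
        exp = oracle_forward(
            Frac(str(f_ac)), Frac(str(f_am)), 7719, Frac(-57, 2), 10, 1, 2
        )
        assert got[0] == pytest.approx(exp[0], abs=1e-8)
        assert got[1] == pytest.approx(exp[1], abs=1e-8)

    def test_monotone_in_acetoclastic_share(self):
        """delta13C_CH4 rises with f_am when the methyl pool is enriched."""
        deltas = [
            forward_deltas(
                CarbonPathwayParams(0.3, f_am, D_METHYL, D_CARBOXYL, D_BG), 1.0, 2.0
            )[0]
            for f_am in np.linspace(0, 1, 11)
        ]
        assert np.all(np.diff(deltas) > 0)

    def test_carbon13_conservation(self):
        """13C leaving as CH4 + CO2 equals 13C supplied by the source pools."""
        f_ac, f_am, m4, m2 = 0.37, 0.42, 1.3, 2.9
        p = CarbonPathwayParams(f_ac, f_am, D_METHYL, D_CARBOXYL, D_BG)
        d_ch4, d_co2 = forward_deltas(p, m4, m2)
        x = lambda d: DeltaValue(d).atom_fraction
        out = m4 * x(d_ch4) + m2 * x(d_co2)
        supplied = (
            f_ac * m4 * (x(7719.0) + x(-28.5))
            + ((1 - f_ac) * m4 + m2 - f_ac * m4) * x(10.0)
        )
        assert out == pytest.approx(supplied, rel=1e-9)

    def test_co2_pool_too_small_rejected(self):
        p = CarbonPathwayParams(0.9, 0.5, D_METHYL)
        with pytest.raises(ValueError, match="m_co2"):
            forward_deltas(p, 1.0, 0.5)

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            CarbonPathwayParams(1.2, 0.5, D_METHYL)

    @pytest.mark.parametrize("eps", [-80.0, -20.0, 20.0, 80.0])
    def test_epsilon_insensitivity_at_high_enrichment(self, eps):
        """At methyl enrichment ~7700 permil the fitted acetate share moves
        by < 0.02, and the acetoclastic split by < 0.05, when fractionation
        offsets of up to 80 permil are ignored in the fit."""
        truth = CarbonPathwayParams(
            0.21, 0.01, D_METHYL, D_CARBOXYL, D_BG, eps_ac=eps, eps_hm=eps
        )
        d_ch4, d_co2 = forward_deltas(truth, 1.0, 2.0)
        fit = fit_pathway_fractions(
            [d_ch4], [d_co2], 1.0, 2.0,
            D_METHYL, D_CARBOXYL, D_BG,  # eps = 0 in the fit
        )
        assert abs(fit.f_ac - 0.21) < 0.02
        assert abs(fit.f_am - 0.01) < 0.05


class TestFitPathwayFractions:
    def test_noise_free_self_consistency(self):
        truth = CarbonPathwayParams(0.30, 0.50, D_METHYL, D_CARBOXYL, D_BG)
        d_ch4, d_co2 = forward_deltas(truth, 1.0, 2.0)
        fit = fit_pathway_fractions(
            [d_ch4] * 3, [d_co2] * 3, 1.0, 2.0, D_METHYL, D_CARBOXYL, D_BG
        )
        assert fit.f_ac == pytest.approx(0.30, abs=0.005)
        assert fit.f_am == pytest.approx(0.50, abs=0.005)
        assert not fit.on_boundary

    def test_boundary_solution_flagged(self):
        truth = CarbonPathwayParams(0.21, 0.0, D_METHYL, D_CARBOXYL, D_BG)
        d_ch4, d_co2 = forward_deltas(truth, 1.0, 2.0)
        fit = fit_pathway_fractions(
            [d_ch4], [d_co2], 1.0, 2.0, D_METHYL, D_CARBOXYL, D_BG
        )
        assert fit.f_am == pytest.approx(0.0, abs=0.005)
        assert fit.on_boundary

    def test_single_observation_returns_grid_with_valley(self):
        truth = CarbonPathwayParams(0.4, 0.6, D_METHYL, D_CARBOXYL, D_BG)
        d_ch4, d_co2 = forward_deltas(truth, 1.0, 2.0)
        fit = fit_pathway_fractions(
            [d_ch4], [d_co2], 1.0, 2.0, D_METHYL, D_CARBOXYL, D_BG
        )
        assert fit.objective < 1e-6
        # the returned objective grid exposes identifiability structure
        assert fit.grid_objective.shape == (len(fit.grid_f_ac), len(fit.grid_f_am))
        assert fit.grid_objective.min() >= 0

    def test_nonfinite_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_pathway_fractions([np.nan], [0.0], 1.0, 2.0, D_METHYL)

    def test_weights_must_be_positive(self):
        with pytest.raises(ValueError):
            fit_pathway_fractions([0.0], [0.0], 1.0, 2.0, D_METHYL, weight_ch4=0.0)

    def test_recovery_under_noise_small(self):
        """Short Monte-Carlo check of noisy recovery near the SAO-dominated
        regime (the full calibration lives in the acceptance suite)."""
        rng = np.random.default_rng(42)
        truth = CarbonPathwayParams(0.21, 0.01, D_METHYL, D_CARBOXYL, D_BG)
        d_ch4, d_co2 = forward_deltas(truth, 1.0, 2.0)
        errs = []
        for _ in range(20):
            obs4 = d_ch4 + rng.normal(0, 5.0, 20)
            obs2 = d_co2 + rng.normal(0, 5.0, 20)
            fit = fit_pathway_fractions(
                obs4, obs2, 1.0, 2.0, D_METHYL, D_CARBOXYL, D_BG,
                weight_ch4=5.0, weight_co2=5.0,
            )
            errs.append((fit.f_ac - 0.21, fit.f_am - 0.01))
        errs = np.array(errs)
        assert np.abs(errs.mean(axis=0)).max() < 0.02
        assert np.sqrt((errs**2).mean(axis=0)).max() < 0.05


class TestSulfurApportionment:
    def test_endmember_identity(self):
        f = sulfate_fraction_h2s(5.28, 5.28)
        assert f.value == pytest.approx(1.0)
        assert not f.clipped

    def test_zero_excess_gives_zero_fraction(self):
        assert sulfate_fraction_h2s(0.0, 5.28).value == 0.0

    def test_two_source_mixing(self):
        f = sulfate_fraction_h2s(4.224, 5.28)
        assert f.value == pytest.approx(0.80, abs=1e-12)

    def test_methylation_examples(self):
        assert methylation_fraction_ch3sh(4.0, 4.0).value == pytest.approx(1.0)
        assert methylation_fraction_ch3sh(0.0, 4.0).value == 0.0
        assert methylation_fraction_ch3sh(2.0, 4.0).value == pytest.approx(0.5)

    def test_scale_invariance(self):
        """Multiplying all excess ratios by a common factor changes nothing."""
        for k in (0.1, 1.0, 7.3):
            assert sulfate_fraction_h2s(4.224 * k, 5.28 * k).value == pytest.approx(
                0.80, rel=1e-12
            )
            assert methylation_fraction_ch3sh(2.0 * k, 4.0 * k).value == pytest.approx(
                0.5, rel=1e-12
            )

    def test_clipping_retains_raw(self):
        f = sulfate_fraction_h2s(6.0, 5.28)
        assert f.value == 1.0
        assert f.raw == pytest.approx(6.0 / 5.28)
        assert f.clipped

    def test_nonpositive_endmember_rejected(self):
        with pytest.raises(ValueError):
            sulfate_fraction_h2s(1.0, 0.0)
        with pytest.raises(ValueError):
            methylation_fraction_ch3sh(1.0, -0.5)

    def test_full_apportionment(self):
        app = apportion_sulfur(5.28, 4.224, 2.112)
        assert app.f_sulfate_reduction.value == pytest.approx(0.80)
        assert app.f_methylation.value == pytest.approx(0.50)
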