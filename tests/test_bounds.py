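"""Bound-allocation formulas: worked examples, normalization, reductions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcfba import (
    RegulationSpec,
    bounds_growth_tendency,
    bounds_three_cell_asocial,
    bounds_three_cell_mutual,
    bounds_three_cell_oneway,
    bounds_two_cell,
    bounds_two_cell_regulated,
    regulation_factor,
)

BIOMASS = st.floats(min_value=1e-6, max_value=1.5)
MU = st.floats(min_value=0.01, max_value=0.5)
ELASTICITY = st.floats(min_value=0.0, max_value=1.5)


def spec(**kw):
    return RegulationSpec(**kw)


class TestRegulationFactor:
    def test_identity_is_biomass(self):
        assert regulation_factor(0.37, spec()) == 0.37

    @pytest.mark.parametrize(
        "kd,B,expected", [(1.0, 1.0, 0.5), (0.7, 0.0, 0.0), (0.2, 0.6, 0.75)]
    )
    def test_hyperbolic_receptor_occupancy(self, kd, B, expected):
        s = spec(factor_form="hyperbolic", kd_over_alpha=kd)
        assert regulation_factor(B, s) == pytest.approx(expected)

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            regulation_factor(-0.1, spec())


class TestGrowthTendency:
    def test_symmetry(self):
        bs = bounds_growth_tendency((0.25, 0.25), 1.0, 1.0)
        assert bs.b_ub == pytest.approx([0.25, 0.25])

    def test_weighted_by_mu(self):
        bs = bounds_growth_tendency((0.2, 0.3), 1.0, 1.0)
        assert bs.b_ub == pytest.approx([0.2, 0.3])

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bounds_growth_tendency((0.2, 0.3), 0.0, 0.0)

    @given(f1=st.floats(0.01, 10), f2=st.floats(0.01, 10), m1=MU, m2=MU)
    @settings(max_examples=50, deadline=None)
    def test_normalization(self, f1, f2, m1, m2):
        assert bounds_growth_tendency((m1, m2), f1, f2).total == pytest.approx(0.5)


class TestTwoCell:
    def test_worked_example(self):
        bs = bounds_two_cell((0.4, 0.6), (0.2, 0.3))
        assert bs.b_ub == pytest.approx([0.04 / 0.26, 0.09 / 0.26], abs=1e-12)
        # glucose-to-intermediate fluxes carry the common-goods demand
        assert bs.v_g == pytest.approx(0.25 + bs.b_ub)

    def test_omega_scales_linearly(self):
        full = bounds_two_cell((0.4, 0.6), (0.2, 0.3), omega=0.0)
        half = bounds_two_cell((0.4, 0.6), (0.2, 0.3), omega=0.5)
        assert half.b_ub == pytest.approx(full.b_ub / 2)

    def test_extinct_community_flagged(self):
        bs = bounds_two_cell((0.0, 0.0), (0.2, 0.3))
        assert bs.extinct and bs.b_ub == pytest.approx([0.0, 0.0])

    @given(B1=BIOMASS, B2=BIOMASS, m1=MU, m2=MU, omega=st.floats(0.0, 0.9))
    @settings(max_examples=100, deadline=None)
    def test_normalization_with_omega(self, B1, B2, m1, m2, omega):
        bs = bounds_two_cell((B1, B2), (m1, m2), omega=omega)
        assert bs.total == pytest.approx((1 - omega) / 2, abs=1e-12)

    @given(B1=BIOMASS, B2=BIOMASS, m1=MU, m2=MU)
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_own_biomass_and_mu(self, B1, B2, m1, m2):
        base = bounds_two_cell((B1, B2), (m1, m2)).b_ub[0]
        assert bounds_two_cell((B1 * 1.1, B2), (m1, m2)).b_ub[0] > base
        assert bounds_two_cell((B1, B2), (m1 * 1.1, m2)).b_ub[0] > base


class TestTwoCellRegulated:
    def test_epsilon_zero_reduces_to_unregulated(self):
        r = bounds_two_cell_regulated((0.4, 0.6), (0.2, 0.3), spec(mode="two_cell_regulated"))
        u = bounds_two_cell((0.4, 0.6), (0.2, 0.3))
        assert r.b_ub == pytest.approx(u.b_ub)

    @given(B1=BIOMASS, B2=BIOMASS)
    @settings(max_examples=50, deadline=None)
    def test_full_regulation_is_state_independent(self, B1, B2):
        """At elasticity 1 the bounds collapse to 0.5*mu_i/(mu1+mu2)."""
        s = spec(mode="two_cell_regulated", epsilon=1.0)
        bs = bounds_two_cell_regulated((B1, B2), (0.2, 0.3), s)
        assert bs.b_ub == pytest.approx([0.2, 0.3], abs=1e-12)

    @given(B1=BIOMASS, B2=BIOMASS, m1=MU, m2=MU, e=ELASTICITY)
    @settings(max_examples=100, deadline=None)
    def test_normalization(self, B1, B2, m1, m2, e):
        s = spec(mode="two_cell_regulated", epsilon=e)
        assert bounds_two_cell_regulated((B1, B2), (m1, m2), s).total == pytest.approx(0.5)

    def test_zero_biomass_with_zero_epsilon(self):
        s = spec(mode="two_cell_regulated", epsilon=0.0)
        bs = bounds_two_cell_regulated((0.0, 0.6), (0.2, 0.3), s)
        assert bs.b_ub == pytest.approx([0.0, 0.5])


MU3 = (0.2, 0.3, 0.2)


class TestThreeCellAsocial:
    def test_worked_example_case1(self):
        s = spec(mode="three_cell_asocial", epsilon=1.0)
        bs = bounds_three_cell_asocial((0.39, 0.59, 0.02), MU3, s)
        n = np.array([0.2 * 0.39 * 0.59, 0.3 * 0.59 * 0.39, 0.2 * 0.02])
        assert bs.b_ub == pytest.approx(0.5 * n / n.sum(), abs=1e-12)
        # the asocial type's specific growth tendency exceeds the others'
        tendency = bs.b_ub / np.array([0.39, 0.59, 0.02])
        assert tendency[2] > tendency[0] and tendency[2] > tendency[1]

    def test_social_control_reduces_to_pair_at_B3_zero(self):
        s = spec(mode="three_cell_asocial", epsilon=1.0, epsilon1=1.0, partial=1)
        bs = bounds_three_cell_asocial((0.4, 0.6, 0.0), MU3, s)
        pair = bounds_two_cell_regulated((0.4, 0.6), MU3[:2], spec(mode="two_cell_regulated", epsilon=1.0))
        assert bs.b_ub[:2] == pytest.approx(pair.b_ub)
        assert bs.b_ub[2] == 0.0

    @given(B=st.tuples(BIOMASS, BIOMASS, BIOMASS), e=ELASTICITY, e1=ELASTICITY,
           part=st.integers(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_normalization(self, B, e, e1, part):
        s = spec(mode="three_cell_asocial", epsilon=e, epsilon1=e1, partial=part)
        assert bounds_three_cell_asocial(B, MU3, s).total == pytest.approx(0.5)


class TestThreeCellMutual:
    def test_equal_biomass_full_regulation(self):
        s = spec(mode="three_cell_mutual", epsilon=1.0, gamma=1.0)
        bs = bounds_three_cell_mutual((0.3, 0.3, 0.3), MU3, s)
        assert bs.b_ub == pytest.approx(0.5 * np.array(MU3) / sum(MU3), abs=1e-12)

    @given(B=st.tuples(BIOMASS, BIOMASS, BIOMASS), e=ELASTICITY)
    @settings(max_examples=50, deadline=None)
    def test_gamma_zero_reduces_to_asocial_mutant(self, B, e):
        s = spec(mode="three_cell_mutual", epsilon=e, gamma=0.0)
        a = spec(mode="three_cell_asocial", epsilon=e, epsilon1=0.0, partial=0)
        assert bounds_three_cell_mutual(B, MU3, s).b_ub == pytest.approx(
            bounds_three_cell_asocial(B, MU3, a).b_ub
        )

    @given(B=st.tuples(BIOMASS, BIOMASS, BIOMASS), e=ELASTICITY, g=ELASTICITY)
    @settings(max_examples=100, deadline=None)
    def test_normalization(self, B, e, g):
        s = spec(mode="three_cell_mutual", epsilon=e, gamma=g)
        assert bounds_three_cell_mutual(B, MU3, s).total == pytest.approx(0.5)


class TestThreeCellOneway:
    def test_gamma_zero_leaves_type3_unregulated(self):
        s = spec(mode="three_cell_oneway", epsilon=1.0, gamma=0.0)
        bs = bounds_three_cell_oneway((0.39, 0.59, 0.02), MU3, s)
        n = np.array([0.2 * 0.39 * 0.59, 0.3 * 0.39 * 0.59, 0.2 * 0.02])
        assert bs.b_ub == pytest.approx(0.5 * n / n.sum())

    def test_B3_zero_reduces_to_regulated_pair(self):
        s = spec(mode="three_cell_oneway", epsilon=1.0, gamma=0.7)
        bs = bounds_three_cell_oneway((0.4, 0.6, 0.0), MU3, s)
        pair = bounds_two_cell_regulated((0.4, 0.6), MU3[:2], spec(mode="two_cell_regulated", epsilon=1.0))
        assert bs.b_ub[:2] == pytest.approx(pair.b_ub)

    def test_worked_example(self):
        s = spec(mode="three_cell_oneway", epsilon=1.0, gamma=1.0)
        bs = bounds_three_cell_oneway((0.39, 0.59, 0.02), MU3, s)
        n = np.array(
            [0.2 * 0.39 * 0.59, 0.3 * 0.39 * 0.59, 0.2 * 0.39 * 0.59 * 0.02]
        )
        assert bs.b_ub == pytest.approx(0.5 * n / n.sum(), abs=1e-12)
        assert bs.total == pytest.approx(0.5)

    @given(B=st.tuples(BIOMASS, BIOMASS, BIOMASS), e=ELASTICITY, g=ELASTICITY)
    @settings(max_examples=100, deadline=None)
    def test_normalization(self, B, e, g):
        s = spec(mode="three_cell_oneway", epsilon=e, gamma=g)
        assert bounds_three_cell_oneway(B, MU3, s).total == pytest.approx(0.5)


class TestSpecValidation:
    def test_gamma_needs_three_cell_mode(self):
        with pytest.raises(ValueError):
            RegulationSpec(mode="none", gamma=0.3)

    def test_negative_elasticity_rejected(self):
        with pytest.raises(ValueError):
            RegulationSpec(mode="two_cell_regulated", epsilon=-0.1)

    def test_partial_is_binary(self):
        with pytest.raises(ValueError):
            RegulationSpec(mode="three_cell_asocial", partial=2)
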