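"""Force-length fitting, Hill constants, and force potentials."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtulab import (
    FitError,
    LeverArm,
    MuscleParameters,
    ValidationError,
    a_rel_from_ft,
    b_rel_from,
    derive_vmax,
    fit_force_length,
    fl_potential,
    flv_potential,
    fv_potential,
    tendon_force,
)
from mtulab.contractile import (
    SOLEUS_A_REL,
    SOLEUS_B_REL,
    SOLEUS_VMAX_NORM,
    VL_A_REL,
    VL_B_REL,
    VL_VMAX_NORM,
)


def quad_samples(L0=41.3, Fmax=2887.0, c2=-3.0, n=8):
    L = np.linspace(0.75 * L0, 1.2 * L0, n)
    return L, Fmax + c2 * (L - L0) ** 2


class TestFitForceLength:
    def test_exact_vertex_recovery(self):
        L, F = quad_samples()
        curve = fit_force_length(L, F)
        assert curve.L0_mm == pytest.approx(41.3, rel=1e-9)
        assert curve.Fmax_N == pytest.approx(2887.0, rel=1e-9)
        assert np.max(np.abs(curve.force(L) - F)) / 2887.0 < 1e-9

    def test_collinear_points_rejected(self):
        with pytest.raises(FitError):
            fit_force_length([30.0, 40.0, 50.0], [100.0, 200.0, 300.0])

    def test_extrapolated_vertex_flagged(self):
        # samples far on one flank: vertex outside the +/-20% extended range
        L = np.linspace(10.0, 20.0, 6)
        F = 2000.0 - 1.0 * (L - 41.3) ** 2
        curve = fit_force_length(L, F)
        assert curve.extrapolated_vertex

    def test_too_few_distinct_lengths(self):
        with pytest.raises(ValidationError):
            fit_force_length([40.0, 40.0, 40.0, 41.0], [1.0, 1.0, 1.0, 2.0])


class TestTendonForce:
    def test_closed_form(self):
        assert tendon_force(150.0, LeverArm.constant(50.0)) == pytest.approx(3000.0)

    def test_zero_moment(self):
        assert tendon_force(0.0, LeverArm.constant(40.0)) == 0.0

    def test_angle_dependent_lever_matches_interp_oracle(self):
        lever = LeverArm.from_table([0, 10, 30], [40.0, 44.0, 56.0])
        r = np.interp(20.0, [0, 10, 30], [40.0, 44.0, 56.0])
        assert tendon_force(100.0, lever, 20.0) == pytest.approx(100.0 / (r / 1000.0))


class TestHillConstants:
    @pytest.mark.parametrize("ft,expected", [(0.0, 0.1), (0.63, 0.352), (1.0, 0.5)])
    def test_a_rel_formula(self, ft, expected):
        assert a_rel_from_ft(ft) == pytest.approx(expected, abs=1e-12)

    def test_a_rel_domain(self):
        with pytest.raises(ValidationError):
            a_rel_from_ft(1.2)

    @pytest.mark.parametrize(
        "a,v,expected", [(0.351, 11.51, 4.040), (0.175, 6.77, 1.185), (0.0, 5.0, 0.0)]
    )
    def test_b_rel_product(self, a, v, expected):
        assert b_rel_from(a, v) == pytest.approx(a * v) == pytest.approx(expected, abs=5e-3)

    def test_derive_vmax_identity_and_weighting(self):
        assert derive_vmax(4.0, 12.0, 1.0) == 4.0
        assert derive_vmax(4.0, 12.0, 0.5, temp_factor=2.0) == pytest.approx(16.0)

    def test_published_constants_self_consistent(self):
        # printed rounded constants agree with the formula path to < 1%
        assert SOLEUS_B_REL == pytest.approx(SOLEUS_A_REL * SOLEUS_VMAX_NORM, rel=0.01)
        assert VL_B_REL == pytest.approx(VL_A_REL * VL_VMAX_NORM, rel=0.01)


class TestMuscleParameters:
    def test_absolute_vmax_consistency(self):
        vl = MuscleParameters.vastus_lateralis()
        assert vl.vmax_abs_mm_s == pytest.approx(vl.vmax_norm * vl.L0_mm)
        assert round(vl.vmax_abs_mm_s) == 1082

    def test_vmax_factor_rescales_b_rel_only(self):
        sol = MuscleParameters.soleus()
        scaled = sol.with_vmax_factor(1.3)
        assert scaled.a_rel == sol.a_rel
        assert scaled.vmax_norm == pytest.approx(1.3 * sol.vmax_norm)
        assert scaled.b_rel == pytest.approx(1.3 * sol.b_rel)

    def test_default_constants_derive_from_fiber_fractions(self):
        p = MuscleParameters("generic", 40.0, 3000.0, ft=0.4, vmax_norm=8.0)
        assert p.a_rel == pytest.approx(0.26)
        assert p.b_rel == pytest.approx(0.26 * 8.0)


class TestPotentials:
    def test_fl_vertex_is_one_and_negative_clipped(self):
        L, F = quad_samples()
        curve = fit_force_length(L, F)
        assert fl_potential(41.3, curve) == pytest.approx(1.0)
        assert fl_potential(200.0, curve) == 0.0

    def test_fl_closed_form(self):
        curve = fit_force_length(*quad_samples())
        assert fl_potential(31.3, curve) == pytest.approx((2887 - 300) / 2887, rel=1e-6)

    def test_fv_endpoints(self):
        sol = MuscleParameters.soleus()
        assert fv_potential(0.0, sol) == 1.0
        assert fv_potential(sol.vmax_norm, sol) == pytest.approx(0.0, abs=1e-12)
        assert fv_potential(2 * sol.vmax_norm, sol) == 0.0

    def test_fv_vl_closed_form(self):
        vl = MuscleParameters.vastus_lateralis()
        expected = (4.042 - 0.351 * 0.084) / (4.042 + 0.084)
        assert fv_potential(0.084, vl) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9724, abs=5e-4)

    def test_fv_eccentric_policies(self):
        sol = MuscleParameters.soleus()
        assert fv_potential(-0.5, sol, eccentric="clamp") == 1.0
        hyper = fv_potential(-0.5, sol, eccentric="hyperbola")
        assert 1.0 < hyper <= 1.3 + 0.3 * sol.a_rel
        assert fv_potential(0.0, sol, eccentric="hyperbola") == pytest.approx(1.0)

    def test_flv_product_and_domain(self):
        assert flv_potential(0.92, 0.63) == pytest.approx(0.5796)
        assert flv_potential(1.0, 1.0) == 1.0
        assert flv_potential(0.5, 0.0) == 0.0
        with pytest.raises(ValidationError):
            flv_potential(1.2, 0.5)


@given(st.floats(0.0, 1.0), st.floats(1.0, 15.0), st.data())
def test_fv_strictly_decreasing_on_concentric_branch(ft, vmax, data):
    p = MuscleParameters("m", 40.0, 1000.0, ft=ft, vmax_norm=vmax)
    ticks = sorted(data.draw(st.lists(st.integers(0, 1000), min_size=2, max_size=8, unique=True)))
    vals = [fv_potential(i / 1000.0 * vmax, p) for i in ticks]
    assert all(a > b for a, b in zip(vals, vals[1:]))


@given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
def test_flv_monotone_in_each_argument(fl, fv, other):
    lo, hi = sorted([fv, other])
    assert flv_potential(fl, lo) <= flv_potential(fl, hi)
    lo, hi = sorted([fl, other])
    assert flv_potential(lo, fv) <= flv_potential(hi, fv)
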