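"""Steady-state H2 diffusion: closed form, finite differences, comparison."""

import numpy as np
import pytest

from radh2.nuclear import ValidationError
from radh2.transport import (
    H2Profile,
    Layer,
    LayeredColumn,
    TransportParameters,
    compare_profiles,
    diffusion_coefficient_h2,
    numeric_profile,
    steady_state_profile,
    two_layer_profile,
)

PARAMS = TransportParameters(D_cm2_yr=800.0, phi=0.8, Z_m=50.0)
P_PW = 2e-11  # mol cm^-3 porewater yr^-1


def peak_nM(p_pw, params):
    z_cm = params.Z_m * 100
    q = p_pw * params.phi * params.formation_factor / params.D_cm2_yr
    return q * z_cm**2 / 8.0 * 1e12


def test_boundary_and_vertex_identities():
    x = np.array([0.0, 25.0, 50.0])
    conc = steady_state_profile(P_PW, PARAMS, x)
    assert conc[0] == 0.0 and conc[-1] == 0.0
    assert conc[1] == pytest.approx(peak_nM(P_PW, PARAMS), rel=1e-12)
    # profile maximum is at mid-column
    xs = np.linspace(0, 50, 501)
    cs = steady_state_profile(P_PW, PARAMS, xs)
    assert xs[np.argmax(cs)] == pytest.approx(25.0, abs=0.1)


def test_closed_form_point_evaluation():
    # q = P phi F / D = 8 per (unit length)^2 with Z = 1: H2(0.5) = 0.5*8*(0.5-0.25)
    params = TransportParameters(D_cm2_yr=1.0, phi=0.5, F=1.0, Z_m=0.01)  # Z = 1 cm
    p_pw = 16.0  # q = 16*0.5*1/1 = 8 cm^-2 (concentration units mol/cm3)
    conc = steady_state_profile(p_pw, params, np.array([0.005]))  # x = 0.5 cm
    assert conc[0] / 1e12 == pytest.approx(0.5 * 8 * (0.5 - 0.25), rel=1e-12)


def test_scaling_in_production_and_diffusivity():
    x = np.linspace(0, 50, 11)
    base = steady_state_profile(P_PW, PARAMS, x)
    double_p = steady_state_profile(2 * P_PW, PARAMS, x)
    np.testing.assert_allclose(double_p, 2 * base, rtol=1e-12)
    half_d = steady_state_profile(
        P_PW,
        TransportParameters(D_cm2_yr=1600.0, phi=0.8, Z_m=50.0),
        x,
    )
    np.testing.assert_allclose(half_d, base / 2, rtol=1e-12)


def test_integral_balance_production_equals_boundary_fluxes():
    """Total production over the column equals the diffusive loss through
    the two boundaries (closed form, exact)."""
    z_cm = PARAMS.Z_m * 100
    q = P_PW * PARAMS.phi * PARAMS.formation_factor / PARAMS.D_cm2_yr
    # C(x) = q/2 (xZ - x^2);  |C'(0)| = |C'(Z)| = q Z / 2
    flux_per_bulk_area = (
        PARAMS.phi * (PARAMS.D_cm2_yr / (PARAMS.phi * PARAMS.formation_factor)) * q * z_cm / 2
    )
    production_per_bulk_area = P_PW * PARAMS.phi * z_cm
    assert 2 * flux_per_bulk_area == pytest.approx(production_per_bulk_area, rel=1e-12)


def test_out_of_domain_error():
    with pytest.raises(ValidationError):
        steady_state_profile(P_PW, PARAMS, np.array([60.0]))


UNIFORM = LayeredColumn([Layer(50.0, P_PW, 0.8, 800.0)])


def test_numeric_matches_analytic_on_uniform_column():
    num = numeric_profile(UNIFORM, n_nodes=10_001)
    ana = steady_state_profile(P_PW, PARAMS, num.x_m)
    assert np.max(np.abs(num.conc_nM - ana)) / ana.max() < 1e-6


def test_numeric_zero_source():
    col = LayeredColumn([Layer(50.0, 0.0, 0.8, 800.0)])
    num = numeric_profile(col, n_nodes=101)
    assert np.all(num.conc_nM == 0.0)


def test_numeric_exact_on_uniform_and_converges_on_layered():
    """The finite-volume scheme reproduces the quadratic single-layer
    solution to round-off at any resolution; on a layered column with the
    interface between nodes, refinement does not degrade the solution and
    the error stays far below the closed form's scale."""
    for n in (51, 501):
        num = numeric_profile(UNIFORM, n_nodes=n)
        ana = steady_state_profile(P_PW, PARAMS, num.x_m)
        assert np.max(np.abs(num.conc_nM - ana)) / ana.max() < 1e-9
    exact = two_layer_profile(TWO_LAYER, n_points=60_001)
    errs = []
    for n in (101, 401):
        num = numeric_profile(TWO_LAYER, n_nodes=n)
        ref = np.interp(num.x_m, exact.x_m, exact.conc_nM)
        errs.append(np.max(np.abs(num.conc_nM - ref)) / exact.conc_nM.max())
    assert errs[1] <= errs[0]
    assert errs[1] < 1e-5


TWO_LAYER = LayeredColumn(
    [Layer(20.0, 4e-11, 0.85, 900.0), Layer(40.0, 8e-12, 0.6, 700.0)]
)


def test_two_layer_degenerates_to_single_layer():
    col = LayeredColumn([Layer(25.0, P_PW, 0.8, 800.0), Layer(25.0, P_PW, 0.8, 800.0)])
    two = two_layer_profile(col, n_points=41)
    ana = steady_state_profile(P_PW, PARAMS, two.x_m)
    np.testing.assert_allclose(two.conc_nM, ana, rtol=1e-10, atol=1e-6)


def test_two_layer_interface_continuity():
    l1, l2 = TWO_LAYER.layers
    h = l1.thickness_m
    eps = 1e-7
    prof = two_layer_profile(TWO_LAYER, n_points=100_001)
    left = np.interp(h - eps, prof.x_m, prof.conc_nM)
    right = np.interp(h + eps, prof.x_m, prof.conc_nM)
    assert abs(left - right) / max(prof.conc_nM) < 1e-8
    # flux continuity, via one-sided gradients scaled by D/(phi F)
    x = prof.x_m * 100
    c = prof.conc_nM
    i = np.searchsorted(prof.x_m, h)
    g_left = (c[i - 1] - c[i - 2]) / (x[i - 1] - x[i - 2])
    g_right = (c[i + 2] - c[i + 1]) / (x[i + 2] - x[i + 1])
    assert l1.conductance * g_left == pytest.approx(
        l2.conductance * g_right, rel=1e-2
    )


def test_two_layer_matches_numeric():
    two = two_layer_profile(TWO_LAYER, n_points=2001)
    num = numeric_profile(TWO_LAYER, n_nodes=120_001)
    interp = np.interp(two.x_m, num.x_m, num.conc_nM)
    assert np.max(np.abs(two.conc_nM - interp)) / two.conc_nM.max() < 1e-5


def test_two_layer_requires_two_layers():
    with pytest.raises(ValidationError):
        two_layer_profile(UNIFORM)


def test_diffusion_coefficient_monotone_in_temperature():
    assert diffusion_coefficient_h2(25.0) > diffusion_coefficient_h2(2.0) > 0


class TestCompareProfiles:
    def test_identical_profiles(self):
        x = np.linspace(1, 40, 10)
        c = np.linspace(5, 50, 10)
        out = compare_profiles(
            H2Profile(x, c, "measured", detection_limit_nM=0.5), H2Profile(x, c)
        )
        np.testing.assert_allclose(out["table"]["ratio"], 1.0, rtol=1e-12)
        assert not out["consumption_flag"]

    def test_censoring_below_detection(self):
        x = np.linspace(1, 40, 10)
        measured = H2Profile(x, np.zeros(10), "measured", detection_limit_nM=2.0)
        expected = H2Profile(x, np.full(10, 2000.0))
        out = compare_profiles(measured, expected)
        assert out["table"]["ratio_is_lower_bound"].all()
        np.testing.assert_allclose(out["table"]["ratio"], 1000.0)
        assert out["orders_of_magnitude"] == pytest.approx(3.0)
        assert out["consumption_flag"]

    def test_empty_overlap_raises(self):
        a = H2Profile(np.array([1.0, 2.0]), np.array([1.0, 1.0]), "measured")
        b = H2Profile(np.array([10.0, 20.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValidationError):
            compare_profiles(a, b)
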