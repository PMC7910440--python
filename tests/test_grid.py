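"""Global rollup: cell areas, reclassification rules, grid integration."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from radh2.column import (
    SedimentColumn,
    integrate_column,
    lithology_table,
)
from radh2.gridmap import (
    LITHOLOGY_CODES,
    SeafloorGrid,
    _solid_column_integral_cm,
    apply_reclassification,
    assign_parameters,
    cell_area_km2,
    global_production,
)
from radh2.nuclear import ElementalComposition, ValidationError
from radh2.column import PHI_MIN, compaction_coefficient, porosity_at


def make_tiny_grid(lith, thickness, phi0, depth, lat=None, lon=None, basin=None):
    lith = np.atleast_2d(np.asarray(lith, dtype=np.int8))
    n_lat, n_lon = lith.shape
    lat = np.linspace(-10, 10, n_lat) if lat is None else np.asarray(lat, float)
    lon = np.linspace(100, 120, n_lon) if lon is None else np.asarray(lon, float)
    data = {
        "lithology": (("lat", "lon"), lith),
        "thickness_m": (("lat", "lon"), np.broadcast_to(np.asarray(thickness, float), lith.shape).copy()),
        "phi0": (("lat", "lon"), np.broadcast_to(np.asarray(phi0, float), lith.shape).copy()),
        "water_depth_m": (("lat", "lon"), np.broadcast_to(np.asarray(depth, float), lith.shape).copy()),
    }
    if basin is not None:
        data["basin"] = (("lat", "lon"), np.broadcast_to(np.asarray(basin, np.int8), lith.shape).copy())
    return SeafloorGrid(xr.Dataset(data, coords={"lat": lat, "lon": lon}))


class TestCellArea:
    def test_hemispheric_symmetry(self):
        np.testing.assert_allclose(
            cell_area_km2(np.array([30.0]), 1.0), cell_area_km2(np.array([-30.0]), 1.0)
        )

    def test_five_arc_minute_equatorial_cell(self):
        # R^2 * dlambda * (sin(phi2) - sin(phi1)) with R = 6371 km
        area = cell_area_km2(np.array([0.0]), 5.0 / 60.0)[0]
        assert area == pytest.approx(85.9, rel=0.005)

    def test_globe_closure_4_pi_r_squared(self):
        res = 0.5
        lats = np.arange(-90 + res / 2, 90, res)
        total = cell_area_km2(lats, res).sum() * int(360 / res)
        assert total == pytest.approx(4 * np.pi * 6371.0**2, rel=1e-3)


class TestReclassification:
    def test_atlantic_abyssal_clay_becomes_marl(self):
        g = make_tiny_grid(
            [[LITHOLOGY_CODES["abyssal_clay"]]], 100.0, 0.8, 4000.0,
            lat=[10.0], lon=[-30.0], basin=[[1]],
        )
        out = apply_reclassification(g)
        assert out.ds["lithology"].values[0, 0] == LITHOLOGY_CODES["calcareous_marl"]

    def test_pacific_abyssal_clay_untouched(self):
        g = make_tiny_grid(
            [[LITHOLOGY_CODES["abyssal_clay"]]], 100.0, 0.8, 4000.0,
            lat=[10.0], lon=[-150.0], basin=[[0]],
        )
        out = apply_reclassification(g)
        assert out.ds["lithology"].values[0, 0] == LITHOLOGY_CODES["abyssal_clay"]

    def test_southern_ocean_opal_belt(self):
        g = make_tiny_grid(
            [[LITHOLOGY_CODES["abyssal_clay"]]], 100.0, 0.8, 4000.0,
            lat=[-60.0], lon=[-150.0], basin=[[0]],
        )
        out = apply_reclassification(g)
        assert out.ds["lithology"].values[0, 0] == LITHOLOGY_CODES["siliceous_ooze"]

    def test_high_latitude_unclassified_becomes_lithogenous(self):
        for lat in (-53.0, -75.0, 80.0):
            g = make_tiny_grid(
                [[LITHOLOGY_CODES["unclassified"]]], 100.0, 0.8, 2000.0,
                lat=[lat], lon=[-150.0], basin=[[0]],
            )
            out = apply_reclassification(g)
            assert out.ds["lithology"].values[0, 0] == LITHOLOGY_CODES["lithogenous"]


def test_solid_integral_closed_form_matches_explicit_midpoint_sum():
    rng = np.random.default_rng(5)
    for _ in range(50):
        phi0 = rng.uniform(0.4, 0.9)
        depth = rng.uniform(0, 6000)
        c0 = compaction_coefficient(depth)
        z = rng.uniform(0, 11000)
        closed = _solid_column_integral_cm(phi0, c0, z)
        mids = (np.arange(int(z)) + 0.5)
        phi = porosity_at(phi0, c0, mids)
        mids = mids[phi > PHI_MIN]
        explicit = np.sum(1.0 - porosity_at(phi0, c0, mids)) * 100.0
        assert closed == pytest.approx(explicit, rel=1e-10, abs=1e-8)


def test_single_cell_total_equals_column_integral():
    """One grid cell must reproduce integrate_column on the equivalent
    sediment column exactly (same parameters, same 1-m sum)."""
    phi0, depth, thick = 0.78, 4200.0, 850.0
    g = make_tiny_grid([[LITHOLOGY_CODES["calcareous_marl"]]], thick, phi0, depth)
    res = global_production(g, reclassify=False)
    tab = lithology_table()
    row = tab.loc["calcareous_marl"]
    col = SedimentColumn(
        water_depth_m=depth, thickness_m=thick, lithology="calcareous_marl",
        phi0=phi0, rho=float(row.grain_density_g_cm3),
        composition=ElementalComposition(
            U_ppm=float(row.U_ppm), Th_ppm=float(row.Th_ppm),
            K2O_wt_pct=float(row.K2O_wt_pct),
        ),
    )
    areal, _ = integrate_column(col)
    assert res.areal.values[0, 0] == pytest.approx(areal, rel=1e-9)
    area_cm2 = res.cell_area_km2.values[0, 0] * 1e10
    assert res.total_h2_eeq_mol_yr == pytest.approx(areal * area_cm2, rel=1e-12)


def test_additivity_and_permutation_invariance():
    code = LITHOLOGY_CODES["abyssal_clay"]
    thick = np.array([[100.0, 100.0]])
    g2 = make_tiny_grid([[code, code]], thick, 0.8, 4500.0, lat=[0.0], lon=[10.0, 11.0])
    g1 = make_tiny_grid([[code]], 100.0, 0.8, 4500.0, lat=[0.0], lon=[10.0])
    t2 = global_production(g2, reclassify=False).total_h2_eeq_mol_yr
    t1 = global_production(g1, reclassify=False).total_h2_eeq_mol_yr
    assert t2 == pytest.approx(2 * t1, rel=1e-9)
    # permuting cells leaves the sum unchanged
    mixed = [[LITHOLOGY_CODES["abyssal_clay"], LITHOLOGY_CODES["lithogenous"]]]
    swapped = [[LITHOLOGY_CODES["lithogenous"], LITHOLOGY_CODES["abyssal_clay"]]]
    ta = global_production(
        make_tiny_grid(mixed, thick, 0.8, 4500.0, lat=[0.0], lon=[10.0, 11.0]),
        reclassify=False,
    ).total_h2_eeq_mol_yr
    tb = global_production(
        make_tiny_grid(swapped, thick, 0.8, 4500.0, lat=[0.0], lon=[10.0, 11.0]),
        reclassify=False,
    ).total_h2_eeq_mol_yr
    assert ta == pytest.approx(tb, rel=1e-12)


def test_mosaic_brute_force_summation(rng):
    """A random 6x6 mosaic equals the cell-by-cell hand sum."""
    codes = rng.integers(1, 6, size=(6, 6)).astype(np.int8)
    thick = rng.uniform(5, 3000, size=(6, 6))
    phi0 = rng.uniform(0.5, 0.9, size=(6, 6))
    depth = rng.uniform(500, 5500, size=(6, 6))
    g = make_tiny_grid(codes, thick, phi0, depth,
                       lat=np.linspace(-30, 30, 6), lon=np.linspace(0, 50, 6))
    res = global_production(g, reclassify=False)
    hand = float(np.sum(res.areal.values * res.cell_area_km2.values * 1e10))
    assert res.total_h2_eeq_mol_yr == pytest.approx(hand, rel=1e-12)
    assert res.total_oxidant_eeq_mol_yr == res.total_h2_eeq_mol_yr
    assert res.total_combined_eeq_mol_yr == pytest.approx(2 * hand, rel=1e-12)


def test_unclassified_cells_excluded_and_counted():
    lith = [[0, LITHOLOGY_CODES["abyssal_clay"]]]
    g = make_tiny_grid(lith, [[100.0, 100.0]], 0.8, 4500.0, lat=[0.0], lon=[10.0, 11.0])
    res = global_production(g, reclassify=False)
    assert res.areal.values[0, 0] == 0.0
    assert res.coverage_fraction == pytest.approx(0.5, rel=1e-6)


def test_zero_thickness_cells_contribute_zero_but_are_not_unclassified():
    lith = [[LITHOLOGY_CODES["abyssal_clay"], LITHOLOGY_CODES["abyssal_clay"]]]
    g = make_tiny_grid(lith, [[0.0, 100.0]], 0.8, 4500.0, lat=[0.0], lon=[10.0, 11.0])
    res = global_production(g, reclassify=False)
    assert res.areal.values[0, 0] == 0.0
    assert res.coverage_fraction == 1.0


def test_all_unclassified_raises():
    g = make_tiny_grid([[0]], 100.0, 0.8, 4500.0)
    with pytest.raises(ValidationError):
        global_production(g, reclassify=False)


def test_assign_parameters_has_all_lithologies():
    params = assign_parameters(make_tiny_grid([[1]], 10.0, 0.8, 4000.0))
    assert set(params["lithology"]) == {
        "abyssal_clay", "calcareous_ooze", "siliceous_ooze",
        "calcareous_marl", "lithogenous",
    }
    assert (params[["spec_alpha", "spec_beta", "spec_gamma"]] > 0).all().all()
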