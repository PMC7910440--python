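"""Global rollup: lithology-parameterized lat/lon grid -> global production.

Each ocean cell carries a seafloor lithology category, sediment thickness,
seafloor porosity and water depth.  Reclassification rules mirror the
global-map construction: Atlantic cells mapped as abyssal clay are treated
as calcareous marl (Atlantic abyssal clay overlies carbonate-rich sections),
a Southern Ocean opal belt (57-66 degS) is set to siliceous ooze, and the
50-57 degS, 66-90 degS and Arctic bands default to lithogenous sediment
where unclassified.  Every cell is then depth-integrated with its
lithology-specific parameter set in one-metre steps (closed form of the
midpoint sum, exact to round-off) and the area-weighted total gives the
global radiolytic production in mol electron equivalents per year.

Grids are xarray Datasets (cell-centered lat ascending, lon in [-180, 180));
NetCDF3 I/O via the scipy engine keeps files plain and dependency-light.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .column import (
    PHI_MIN,
    compaction_coefficient,
    lithology_table,
)
from .constants import AVOGADRO, EARTH_RADIUS_KM, EV_PER_MEV
from .nuclear import (
    RADIATIONS,
    ElementalComposition,
    ValidationError,
    activities_from_composition,
    energy_partition,
)
from .radiolysis import ELECTRON_EQUIVALENTS, YieldTable, default_yield_table

LITHOLOGY_CODES = {
    "unclassified": 0,
    "abyssal_clay": 1,
    "calcareous_ooze": 2,
    "siliceous_ooze": 3,
    "calcareous_marl": 4,
    "lithogenous": 5,
}
CODE_TO_LITHOLOGY = {v: k for k, v in LITHOLOGY_CODES.items()}

BASIN_CODES = {"other": 0, "atlantic": 1, "arctic": 2}


@dataclass
class SeafloorGrid:
    """Lat/lon grid of seafloor properties.

    ``ds`` holds integer ``lithology`` and ``basin`` codes plus
    ``thickness_m``, ``phi0`` and ``water_depth_m`` on (lat, lon).
    """

    ds: xr.Dataset

    def __post_init__(self) -> None:
        needed = {"lithology", "thickness_m", "phi0", "water_depth_m"}
        missing = needed - set(self.ds.data_vars)
        if missing:
            raise ValidationError(f"grid missing variables: {sorted(missing)}")
        lat = self.ds["lat"].values
        if np.any(np.abs(lat) > 90):
            raise ValidationError("latitudes outside [-90, 90]")
        if np.nanmin(self.ds["thickness_m"].values) < 0:
            raise ValidationError("negative sediment thickness")

    @property
    def resolution_deg(self) -> float:
        lat = self.ds["lat"].values
        return float(abs(lat[1] - lat[0])) if len(lat) > 1 else 360.0

    def to_netcdf(self, path) -> None:
        self.ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "SeafloorGrid":
        return cls(xr.load_dataset(path, engine="scipy"))


def default_basin_codes(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Coarse ocean-basin mask: Atlantic box and the Arctic cap.

    Deliberately simple (rectangle in lon/lat); supply your own basin field
    for anything resembling real geography.
    """
    lat2, lon2 = np.meshgrid(lat, lon, indexing="ij")
    basin = np.zeros(lat2.shape, dtype=np.int8)
    basin[(lon2 >= -70) & (lon2 <= 20) & (lat2 >= -60) & (lat2 <= 70)] = BASIN_CODES[
        "atlantic"
    ]
    basin[lat2 > 70] = BASIN_CODES["arctic"]
    return basin


def apply_reclassification(grid: SeafloorGrid) -> SeafloorGrid:
    """Apply the map-construction rules; returns a new grid.

    Only ocean cells (water_depth > 0) are touched.
    """
    ds = grid.ds.copy(deep=True)
    lith = ds["lithology"].values.copy()
    lat2 = np.broadcast_to(ds["lat"].values[:, None], lith.shape)
    ocean = ds["water_depth_m"].values > 0
    if "basin" in ds:
        basin = ds["basin"].values
    else:
        basin = default_basin_codes(ds["lat"].values, ds["lon"].values)
        ds["basin"] = (("lat", "lon"), basin)

    # Atlantic abyssal clay -> calcareous marl
    atl = ocean & (basin == BASIN_CODES["atlantic"])
    lith[atl & (lith == LITHOLOGY_CODES["abyssal_clay"])] = LITHOLOGY_CODES[
        "calcareous_marl"
    ]
    # Southern Ocean opal belt
    belt = ocean & (lat2 >= -66) & (lat2 <= -57)
    lith[belt] = LITHOLOGY_CODES["siliceous_ooze"]
    # high-latitude lithogenous fills where unclassified
    unclass = lith == LITHOLOGY_CODES["unclassified"]
    south_band = ocean & (lat2 > -57) & (lat2 <= -50)
    antarctic = ocean & (lat2 < -66)
    arctic = ocean & (lat2 > 70)
    lith[unclass & (south_band | antarctic | arctic)] = LITHOLOGY_CODES["lithogenous"]

    ds["lithology"] = (("lat", "lon"), lith)
    return SeafloorGrid(ds)


def assign_parameters(
    grid: SeafloorGrid,
    litho_table: pd.DataFrame | None = None,
    yields: YieldTable | None = None,
    iso_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-lithology parameter sets used by the rollup.

    Returns a table indexed by lithology code with grain density and the
    specific production (molecules H2 per g solid per yr, split by radiation
    type) implied by the lithology's U/Th/K content and G(H2) values.
    """
    tab = lithology_table() if litho_table is None else litho_table
    yt = default_yield_table() if yields is None else yields
    energies = energy_partition(iso_table)
    rows = []
    for name, row in tab.iterrows():
        comp = ElementalComposition(
            U_ppm=float(row.U_ppm),
            Th_ppm=float(row.Th_ppm),
            K2O_wt_pct=float(row.K2O_wt_pct),
        )
        acts = activities_from_composition(comp, iso_table)
        spec = {r: 0.0 for r in RADIATIONS}
        for iso, a_m in acts.activity.items():
            for rad in RADIATIONS:
                spec[rad] += (
                    a_m * energies[iso][rad] * EV_PER_MEV * yt.lookup(name, rad) / 100.0
                )
        rows.append(
            {
                "code": LITHOLOGY_CODES[name],
                "lithology": name,
                "rho": float(row.grain_density_g_cm3),
                **{f"spec_{r}": spec[r] for r in RADIATIONS},
            }
        )
    return pd.DataFrame(rows).set_index("code")


def cell_area_km2(lat_deg, resolution_deg: float) -> np.ndarray:
    """Area of a cell centered at *lat_deg* on the authalic sphere (km^2)."""
    lat = np.asarray(lat_deg, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValidationError("latitude outside [-90, 90]")
    half = np.radians(resolution_deg) / 2.0
    phi = np.radians(lat)
    s_hi = np.sin(np.minimum(phi + half, np.pi / 2))
    s_lo = np.sin(np.maximum(phi - half, -np.pi / 2))
    return EARTH_RADIUS_KM**2 * np.radians(resolution_deg) * (s_hi - s_lo)


def _solid_column_integral_cm(phi0, c0, thickness_m, dz_m=1.0):
    """Closed form of the 1-m midpoint sum of (1 - phi(z)) dz, in cm.

    Identical (to round-off) to summing (1 - phi0 e^{-c0 z_mid}) over 1-m
    midpoints with the 0.1%-porosity halt; vectorized over cells.
    """
    phi0 = np.asarray(phi0, float)
    c0 = np.asarray(c0, float)
    z = np.asarray(thickness_m, float)
    n_total = np.floor(z / dz_m + 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_halt = np.where(phi0 > PHI_MIN, np.log(phi0 / PHI_MIN) / c0, 0.0)
    n_halt = np.maximum(np.ceil(z_halt / dz_m - 0.5), 0.0)
    n = np.minimum(n_total, n_halt)
    r = np.exp(-c0 * dz_m)
    geo = np.where(
        n > 0, np.exp(-c0 * dz_m / 2.0) * (1.0 - r**n) / (1.0 - r), 0.0
    )
    return (n * dz_m - phi0 * geo * dz_m) * 100.0


@dataclass
class GlobalResult:
    """Area-resolved and globally summed radiolytic production."""

    areal: xr.DataArray  # mol e-eq cm^-2 yr^-1 per cell
    cell_area_km2: xr.DataArray
    total_h2_eeq_mol_yr: float
    total_oxidant_eeq_mol_yr: float
    coverage_fraction: float  # classified fraction of sediment-bearing ocean area

    @property
    def total_combined_eeq_mol_yr(self) -> float:
        """H2 plus oxidant electron equivalents (twice the H2 figure)."""
        return self.total_h2_eeq_mol_yr + self.total_oxidant_eeq_mol_yr

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {"areal_eeq_mol_cm2_yr": self.areal, "cell_area_km2": self.cell_area_km2}
        )
        ds.attrs.update(
            total_h2_eeq_mol_yr=self.total_h2_eeq_mol_yr,
            total_oxidant_eeq_mol_yr=self.total_oxidant_eeq_mol_yr,
            coverage_fraction=self.coverage_fraction,
        )
        return ds


def global_production(
    grid: SeafloorGrid,
    litho_table: pd.DataFrame | None = None,
    yields: YieldTable | None = None,
    iso_table: pd.DataFrame | None = None,
    reclassify: bool = True,
) -> GlobalResult:
    """Depth-integrate every cell and sum to the global production rate."""
    if reclassify:
        grid = apply_reclassification(grid)
    ds = grid.ds
    lith = ds["lithology"].values
    ocean = (ds["water_depth_m"].values > 0) & (ds["thickness_m"].values > 0)
    classified = lith != LITHOLOGY_CODES["unclassified"]
    if not np.any(ocean & classified):
        raise ValidationError("grid has no classified sediment-bearing cells")

    params = assign_parameters(grid, litho_table, yields, iso_table)
    spec_total = {
        code: row[[f"spec_{r}" for r in RADIATIONS]].sum() * row["rho"]
        for code, row in params.iterrows()
    }  # molecules cm^-3 yr^-1 per (1 - phi)

    c0 = np.vectorize(compaction_coefficient)(
        np.maximum(ds["water_depth_m"].values, 0.0)
    )
    solid_cm = _solid_column_integral_cm(
        ds["phi0"].values, c0, ds["thickness_m"].values
    )
    k_cell = np.zeros_like(solid_cm)
    for code, val in spec_total.items():
        k_cell[lith == code] = val
    eeq = ELECTRON_EQUIVALENTS["H2"] / AVOGADRO
    areal = np.where(ocean & classified, k_cell * solid_cm * eeq, 0.0)

    res = grid.resolution_deg
    area_km2 = np.broadcast_to(
        cell_area_km2(ds["lat"].values, res)[:, None], areal.shape
    )
    total = float(np.sum(areal * area_km2 * 1e10))  # km^2 -> cm^2

    sediment_area = float(np.sum(area_km2[ocean]))
    classified_area = float(np.sum(area_km2[ocean & classified]))
    coverage = classified_area / sediment_area if sediment_area else 0.0

    coords = {"lat": ds["lat"], "lon": ds["lon"]}
    return GlobalResult(
        areal=xr.DataArray(areal, coords=coords, dims=("lat", "lon")),
        cell_area_km2=xr.DataArray(
            np.array(area_km2), coords=coords, dims=("lat", "lon")
        ),
        total_h2_eeq_mol_yr=total,
        total_oxidant_eeq_mol_yr=total,
        coverage_fraction=coverage,
    )
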