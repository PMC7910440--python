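"""Discretized sediment columns: compaction, depth integration, depth-to-age.

A column is integrated in one-metre intervals with porosity evaluated at the
interval midpoint from an Athy-type exponential compaction law
phi(z) = phi0 * exp(-c0 * z), with the compaction length-scale coefficient
c0 chosen by water-depth class.  Integration halts at the base of the column
or where porosity falls to 0.1%, whichever comes first.

Sediment age is linear in depth (mean accumulation rate = thickness /
basement age); site-specific age models can be substituted upstream.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import pandas as pd

from .constants import AVOGADRO, EV_PER_MEV
from .nuclear import (
    RADIATIONS,
    ElementalComposition,
    ValidationError,
    activities_from_composition,
    energy_partition,
)
from .radiolysis import ELECTRON_EQUIVALENTS, YieldTable, default_yield_table

#: porosity e-folding coefficients per water-depth class, m^-1
COMPACTION_COEFFICIENTS = {
    "continental_shelf": 0.5e-3,  # 0-200 m water depth
    "continental_margin": 1.7e-3,  # 200-2500 m
    "abyssal": 0.85e-3,  # > 3500 m (also assigned to the 2500-3500 m gap)
}

#: integration is halted where porosity reaches 0.1%
PHI_MIN = 0.001


@functools.lru_cache(maxsize=None)
def lithology_table() -> pd.DataFrame:
    """Packaged lithology-typical parameters (U/Th/K2O, grain density, phi0)."""
    with resources.files("radh2.data").joinpath("lithologies.csv").open() as fh:
        return pd.read_csv(fh, index_col="lithology")


@dataclass(frozen=True)
class SedimentColumn:
    water_depth_m: float
    thickness_m: float
    lithology: str
    phi0: float
    rho: float  # grain density, g cm^-3
    composition: ElementalComposition
    basement_age_ma: float | None = None

    def __post_init__(self) -> None:
        if self.thickness_m < 0:
            raise ValidationError("thickness must be >= 0")
        if not 0.0 < self.phi0 < 1.0:
            raise ValidationError("seafloor porosity must be in (0, 1)")
        if self.water_depth_m < 0:
            raise ValidationError("water depth must be >= 0")


@dataclass(frozen=True)
class DepthProfile:
    """Values on the 1-m interval midpoints of a column."""

    z_m: np.ndarray
    values: np.ndarray
    units: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.z_m)


def compaction_coefficient(water_depth_m: float) -> float:
    """Water-depth-class compaction coefficient c0 (m^-1).

    The 2500-3500 m band, which falls between the published margin and
    abyssal classes, is assigned the abyssal coefficient.
    """
    if water_depth_m < 0:
        raise ValidationError("water depth must be >= 0")
    if water_depth_m <= 200.0:
        return COMPACTION_COEFFICIENTS["continental_shelf"]
    if water_depth_m <= 2500.0:
        return COMPACTION_COEFFICIENTS["continental_margin"]
    return COMPACTION_COEFFICIENTS["abyssal"]


def porosity_at(phi0: float, c0: float, z_m) -> np.ndarray | float:
    """Athy-type porosity phi(z) = phi0 * exp(-c0 z); non-increasing in z."""
    return phi0 * np.exp(-c0 * np.asarray(z_m, dtype=float))


def _specific_production(col, iso_table, yields: YieldTable):
    """Molecules H2 per gram solid per year, split by radiation type."""
    acts = activities_from_composition(col.composition, iso_table)
    energies = energy_partition(iso_table)
    spec = {r: 0.0 for r in RADIATIONS}
    for iso, a_m in acts.activity.items():
        for rad in RADIATIONS:
            g = yields.lookup(col.lithology, rad)
            spec[rad] += a_m * energies[iso][rad] * EV_PER_MEV * g / 100.0
    return spec


def integrate_column(
    col: SedimentColumn,
    iso_table: pd.DataFrame | None = None,
    yields: YieldTable | None = None,
    dz_m: float = 1.0,
) -> tuple[float, DepthProfile]:
    """Depth-integrate radiolytic production to an areal rate.

    Returns ``(areal_rate, profile)`` where the areal rate is in
    mol e-eq cm^-2 yr^-1 and the profile carries the volumetric production
    (molecules H2 cm^-3 yr^-1) on interval midpoints.  The profile ``meta``
    records the halt depth and the areal breakdown by radiation type.
    """
    yields = default_yield_table() if yields is None else yields
    c0 = compaction_coefficient(col.water_depth_m)
    n = int(np.floor(col.thickness_m / dz_m + 1e-9))
    if n == 0:
        z = np.empty(0)
        profile = DepthProfile(
            z, np.empty(0), "molecules H2 cm^-3 yr^-1",
            meta={"halted_at_m": 0.0, "by_radiation_areal": dict.fromkeys(RADIATIONS, 0.0)},
        )
        return 0.0, profile

    z_mid = (np.arange(n) + 0.5) * dz_m
    phi = porosity_at(col.phi0, c0, z_mid)
    keep = phi > PHI_MIN
    if not keep.all():
        first_bad = int(np.argmin(keep))
        z_mid, phi = z_mid[:first_bad], phi[:first_bad]

    spec = _specific_production(col, iso_table, yields)
    solid = col.rho * (1.0 - phi)  # g solid per cm^3 sediment
    dz_cm = dz_m * 100.0
    eeq = ELECTRON_EQUIVALENTS["H2"] / AVOGADRO
    by_rad_areal = {r: float(np.sum(s * solid) * dz_cm * eeq) for r, s in spec.items()}
    p_vol = sum(spec.values()) * solid  # molecules cm^-3 yr^-1
    areal = float(np.sum(p_vol) * dz_cm * eeq)
    profile = DepthProfile(
        z_mid,
        p_vol,
        "molecules H2 cm^-3 yr^-1",
        meta={
            "halted_at_m": float(z_mid[-1] + dz_m / 2) if len(z_mid) else 0.0,
            "by_radiation_areal": by_rad_areal,
            "c0_per_m": c0,
        },
    )
    return areal, profile


def depth_to_age(z_m, col: SedimentColumn) -> np.ndarray | float:
    """Sediment age (Ma) at depth z from the mean accumulation rate."""
    z = np.asarray(z_m, dtype=float)
    if col.basement_age_ma is None or col.basement_age_ma <= 0:
        raise ValidationError("basement_age_ma must be > 0 for age conversion")
    if col.thickness_m == 0:
        if np.any(z > 0):
            raise ValidationError("cannot assign ages in a zero-thickness column")
        return np.zeros_like(z) if z.ndim else 0.0
    if np.any(z < 0) or np.any(z > col.thickness_m):
        raise ValidationError("depth outside [0, thickness]")
    age = z / (col.thickness_m / col.basement_age_ma)
    return age if age.ndim else float(age)


def column_from_lithology(
    lithology: str,
    water_depth_m: float,
    thickness_m: float,
    basement_age_ma: float | None = None,
    table: pd.DataFrame | None = None,
) -> SedimentColumn:
    """Build a column from the packaged lithology-typical parameter table."""
    tab = lithology_table() if table is None else table
    if lithology not in tab.index:
        raise ValidationError(f"unknown lithology {lithology!r}")
    row = tab.loc[lithology]
    return SedimentColumn(
        water_depth_m=water_depth_m,
        thickness_m=thickness_m,
        lithology=lithology,
        phi0=float(row.phi0),
        rho=float(row.grain_density_g_cm3),
        composition=ElementalComposition(
            U_ppm=float(row.U_ppm),
            Th_ppm=float(row.Th_ppm),
            K2O_wt_pct=float(row.K2O_wt_pct),
        ),
        basement_age_ma=basement_age_ma,
    )
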