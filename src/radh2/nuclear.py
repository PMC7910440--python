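"""Radionuclide inventories: U/Th/K concentrations -> per-isotope activities.

The sediment's bulk U (ppm), Th (ppm) and K2O (wt%) content is converted to
per-isotope mass concentrations using packaged natural-abundance constants,
then to activities A = lambda * N (decays yr^-1 g^-1 solid).  Both U decay
series and the Th series are assumed to be in secular equilibrium, so the
energy released per parent decay is the chain sum tabulated per radiation
type (alpha, beta, gamma).  All constants ship as a machine-readable CSV and
can be overridden by passing a modified table.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .constants import AVOGADRO, K2O_TO_K, SECONDS_PER_YEAR

import numpy as np

ISOTOPES = ("U238", "U235", "Th232", "K40")
RADIATIONS = ("alpha", "beta", "gamma")

#: decays yr^-1 g^-1  ->  Bq kg^-1
_PER_YR_G_TO_BQ_KG = 1000.0 / SECONDS_PER_YEAR


class ValidationError(ValueError):
    """Raised when a physical precondition on the inputs is violated."""


@functools.lru_cache(maxsize=None)
def isotope_table() -> pd.DataFrame:
    """Packaged isotope constants (abundances, half-lives, chain energies)."""
    with resources.files("radh2.data").joinpath("isotopes.csv").open() as fh:
        return pd.read_csv(fh, index_col="isotope")


@dataclass(frozen=True)
class ElementalComposition:
    """Bulk radioelement content of the solid phase.

    Potassium may be given either as K2O weight percent (the form usually
    reported by ICP analyses) or directly as elemental K weight percent;
    the K2O -> K molar-mass conversion is applied exactly once, here.
    """

    U_ppm: float = 0.0
    Th_ppm: float = 0.0
    K2O_wt_pct: float | None = None
    K_wt_pct: float | None = None

    def __post_init__(self) -> None:
        if self.K2O_wt_pct is not None and self.K_wt_pct is not None:
            raise ValidationError("give K2O_wt_pct or K_wt_pct, not both")
        vals = [self.U_ppm, self.Th_ppm, self.K2O_wt_pct, self.K_wt_pct]
        if any(v is not None and v < 0 for v in vals):
            raise ValidationError("element concentrations must be >= 0")

    @property
    def K_elemental_wt_pct(self) -> float:
        if self.K_wt_pct is not None:
            return self.K_wt_pct
        if self.K2O_wt_pct is not None:
            return self.K2O_wt_pct * K2O_TO_K
        return 0.0


@dataclass(frozen=True)
class IsotopeActivitySet:
    """Per-isotope activity in decays yr^-1 g^-1 solid."""

    activity: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iso, a in self.activity.items():
            if iso not in ISOTOPES:
                raise ValidationError(f"unknown isotope {iso!r}")
            if a < 0:
                raise ValidationError(f"negative activity for {iso}")

    def __getitem__(self, isotope: str) -> float:
        return self.activity.get(isotope, 0.0)

    def to_bq_per_kg(self) -> dict[str, float]:
        return {k: v * _PER_YR_G_TO_BQ_KG for k, v in self.activity.items()}

    @classmethod
    def from_bq_per_kg(cls, bq_kg: Mapping[str, float]) -> "IsotopeActivitySet":
        return cls({k: v / _PER_YR_G_TO_BQ_KG for k, v in bq_kg.items()})

    def scaled(self, k: float) -> "IsotopeActivitySet":
        return IsotopeActivitySet({i: a * k for i, a in self.activity.items()})


@dataclass(frozen=True)
class DecayEnergyPartition:
    """MeV emitted per parent decay, per chain and radiation type.

    Chain sums at secular equilibrium; the K40 alpha entry is zero (K40 has
    no alpha branch).
    """

    energy_mev: Mapping[str, Mapping[str, float]]

    def __getitem__(self, isotope: str) -> Mapping[str, float]:
        return self.energy_mev[isotope]


def isotope_abundances(
    comp: ElementalComposition, table: pd.DataFrame | None = None
) -> dict[str, float]:
    """Per-isotope mass concentration in ug/g solid (ppm).

    Each isotope concentration is the elemental concentration times the
    packaged natural isotopic mass fraction (Th232 fraction is 1).
    """
    tab = isotope_table() if table is None else table
    k_ppm = comp.K_elemental_wt_pct * 1e4  # wt% -> ug/g
    elemental = {"U": comp.U_ppm, "Th": comp.Th_ppm, "K": k_ppm}
    return {
        iso: elemental[row.parent_element] * row.abundance_mass_fraction
        for iso, row in tab.iterrows()
    }


def activities(
    isotope_conc_ppm: Mapping[str, float], table: pd.DataFrame | None = None
) -> IsotopeActivitySet:
    """Activities A = lambda*N from isotope concentrations (ug/g solid)."""
    tab = isotope_table() if table is None else table
    out: dict[str, float] = {}
    for iso, c in isotope_conc_ppm.items():
        if iso not in tab.index:
            raise ValidationError(f"unknown isotope {iso!r}")
        if c < 0:
            raise ValidationError(f"negative concentration for {iso}")
        row = tab.loc[iso]
        n_atoms = c * 1e-6 / row.atomic_mass_g_mol * AVOGADRO  # atoms / g solid
        lam = np.log(2.0) / row.half_life_yr  # yr^-1
        out[iso] = lam * n_atoms
    return IsotopeActivitySet(out)


def activities_from_composition(
    comp: ElementalComposition, table: pd.DataFrame | None = None
) -> IsotopeActivitySet:
    return activities(isotope_abundances(comp, table), table)


def energy_partition(table: pd.DataFrame | None = None) -> DecayEnergyPartition:
    """Chain-summed alpha/beta/gamma energies (MeV per parent decay)."""
    tab = isotope_table() if table is None else table
    return DecayEnergyPartition(
        {
            iso: {
                "alpha": float(row.E_alpha_MeV),
                "beta": float(row.E_beta_MeV),
                "gamma": float(row.E_gamma_MeV),
            }
            for iso, row in tab.iterrows()
        }
    )


def read_composition_csv(path) -> pd.DataFrame:
    """Read a site composition table (site, depth_m, U_ppm, Th_ppm, K2O_wt_pct)."""
    df = pd.read_csv(path)
    required = {"site", "depth_m", "U_ppm", "Th_ppm", "K2O_wt_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"composition CSV missing columns: {sorted(missing)}")
    return df
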