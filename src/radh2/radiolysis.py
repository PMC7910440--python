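"""Volumetric radiolytic H2 production and the lithology-specific yield table.

The production rate per unit bulk sediment volume is

    P_H2 = sum_i  A_m,i * rho * (1 - phi) * E_i * G(H2)_i

summed over radiation types i (alpha, beta, gamma) and decay series, where
A_m is activity per mass solid, rho the grain density, phi porosity, E_i the
chain decay energy and G(H2)_i the radiolytic yield (molecules per 100 eV
absorbed).  The eV -> "per 100 eV" scaling is applied at exactly one site in
:func:`production_rate` to avoid double scaling.

Water radiolysis produces oxidants in stoichiometric balance with H2
(net 2H2O -> H2 + H2O2), so the oxidant production rate in electron
equivalents equals the H2 rate in electron equivalents by construction.

Because the radiolytic yield of beta radiation has not been measured for
water-saturated sediment, the packaged table resolves beta queries to the
gamma value of the same medium; :func:`beta_assumption_sensitivity`
quantifies how much the total changes under alternative beta assumptions.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .constants import AVOGADRO, EV_PER_MEV
from .nuclear import (
    RADIATIONS,
    DecayEnergyPartition,
    IsotopeActivitySet,
    ValidationError,
    energy_partition,
)

#: mol of transferable electrons per mol of species oxidized/reduced
ELECTRON_EQUIVALENTS = {"H2": 2, "O2": 4, "organic_C": 4}

MEDIA = (
    "pure_water",
    "seawater",
    "abyssal_clay",
    "calcareous_marl",
    "siliceous_ooze",
    "calcareous_ooze",
    "lithogenous",
)


class YieldTable:
    """G(H2) values (molecules per 100 eV) indexed by (medium, radiation).

    Beta queries return the gamma entry of the same medium (measured beta
    yields for wet sediment do not exist); this substitution is the single
    place the rule is applied.
    """

    def __init__(self, frame: pd.DataFrame):
        if (frame["G_mean"] < 0).any():
            raise ValidationError("G values must be >= 0")
        self._frame = frame.set_index(["medium", "radiation"], drop=False)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.reset_index(drop=True)

    @property
    def media(self) -> list[str]:
        return sorted(self._frame.index.get_level_values("medium").unique())

    def lookup(self, medium: str, radiation: str) -> float:
        if radiation == "beta":
            radiation = "gamma"
        if radiation not in ("alpha", "gamma"):
            raise ValidationError(f"unknown radiation type {radiation!r}")
        try:
            return float(self._frame.loc[(medium, radiation), "G_mean"])
        except KeyError:
            raise ValidationError(
                f"no G(H2) entry for medium={medium!r}, radiation={radiation!r}"
            ) from None

    def amplification(self, medium: str, radiation: str) -> float:
        """Yield of *medium* relative to pure water, same radiation type."""
        return self.lookup(medium, radiation) / self.lookup("pure_water", radiation)


@functools.lru_cache(maxsize=None)
def default_yield_table() -> YieldTable:
    with resources.files("radh2.data").joinpath("yields.csv").open() as fh:
        return YieldTable(pd.read_csv(fh))


@dataclass(frozen=True)
class ProductionRate:
    """Radiolytic H2 production per bulk sediment volume.

    ``by_radiation`` carries the decomposition of the sum over radiation
    types, used for the beta-share diagnostics.
    """

    molecules_cm3_yr: float
    by_radiation: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.molecules_cm3_yr < 0:
            raise ValidationError("production rate must be >= 0")

    @property
    def mol_cm3_yr(self) -> float:
        return self.molecules_cm3_yr / AVOGADRO

    @property
    def eeq_mol_cm3_yr(self) -> float:
        return ELECTRON_EQUIVALENTS["H2"] * self.mol_cm3_yr


def production_rate(
    activities: IsotopeActivitySet,
    rho: float,
    phi: float,
    energies: DecayEnergyPartition | None = None,
    yields: YieldTable | None = None,
    medium: str = "abyssal_clay",
) -> ProductionRate:
    """Evaluate the volumetric H2 production sum for one sediment parcel.

    Parameters are activity per mass solid (decays yr^-1 g^-1), grain density
    (g cm^-3) and porosity (fraction); the result is molecules H2 cm^-3
    bulk sediment yr^-1.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValidationError(f"porosity {phi} outside [0, 1]")
    if rho <= 0:
        raise ValidationError("grain density must be > 0")
    energies = energy_partition() if energies is None else energies
    yields = default_yield_table() if yields is None else yields

    solid_mass = rho * (1.0 - phi)  # g solid per cm^3 sediment
    by_rad = {r: 0.0 for r in RADIATIONS}
    for iso, a_m in activities.activity.items():
        chain = energies[iso]
        for rad in RADIATIONS:
            e_ev = chain[rad] * EV_PER_MEV
            g = yields.lookup(medium, rad)
            # G is per 100 eV: the only place the 1/100 scaling appears
            by_rad[rad] += a_m * solid_mass * e_ev * g / 100.0
    total = sum(by_rad.values())
    return ProductionRate(total, by_radiation=by_rad)


def oxidant_production(p: ProductionRate) -> float:
    """Radiolytic oxidant production in mol e-eq cm^-3 yr^-1.

    Exactly equal to the H2 electron-equivalent rate (2H2O -> H2 + H2O2).
    """
    return p.eeq_mol_cm3_yr


def to_electron_equivalents(rate, species: str):
    """Convert a molar rate of *species* to electron equivalents."""
    try:
        factor = ELECTRON_EQUIVALENTS[species]
    except KeyError:
        raise ValidationError(
            f"unknown species {species!r}; known: {sorted(ELECTRON_EQUIVALENTS)}"
        ) from None
    return factor * np.asarray(rate) if np.ndim(rate) else factor * rate


def beta_fraction(p: ProductionRate) -> float:
    """Fraction of total H2 production contributed by beta radiation."""
    if p.by_radiation is None or p.molecules_cm3_yr == 0:
        return 0.0
    return p.by_radiation["beta"] / p.molecules_cm3_yr


def beta_assumption_sensitivity(
    column,
    alternatives: tuple[str, ...] = ("pure_water", "alpha"),
    iso_table: pd.DataFrame | None = None,
    yields: YieldTable | None = None,
) -> dict:
    """Sensitivity of a column's total H2 production to the beta-yield rule.

    For each alternative, the beta term of the production sum is rescaled by
    G_alt / G_beta and the relative difference |P - P_alt| / P of the
    depth-integrated total is returned.  Because production is additive over
    radiation types, rescaling only the beta term is algebraically identical
    to re-summing with the alternative table.  ``alternatives`` entries are
    either ``"pure_water"`` (use the pure-water gamma yield for beta) or
    ``"alpha"`` (use the sediment's own alpha yield).

    Returns a dict with the beta fraction of total production and one
    relative-difference entry per alternative.
    """
    from .column import integrate_column  # local import to avoid a cycle

    yields = default_yield_table() if yields is None else yields
    _, profile = integrate_column(column, iso_table=iso_table, yields=yields)
    by_rad = profile.meta["by_radiation_areal"]
    total = sum(by_rad.values())
    beta = by_rad["beta"]
    g_beta = yields.lookup(column.lithology, "beta")
    out = {"beta_fraction": beta / total if total else 0.0}
    for alt in alternatives:
        if alt == "pure_water":
            g_alt = yields.lookup("pure_water", "gamma")
        elif alt == "alpha":
            g_alt = yields.lookup(column.lithology, "alpha")
        else:
            raise ValidationError(f"unknown beta alternative {alt!r}")
        p_alt = total - beta + beta * (g_alt / g_beta)
        out[alt] = abs(total - p_alt) / total if total else 0.0
    return out
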