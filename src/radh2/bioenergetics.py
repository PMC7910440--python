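"""Catabolic energetics of the Knallgas reaction and the radiolytic/organic
electron-equivalent ratio analysis versus sediment age.

In situ Gibbs energy of H2 + 1/2 O2 -> H2O:

    dG_r = dG0_r(T, P) + 2.3 * R * T * log10(Q),      Q = a_H2O / (a_H2 * a_O2^1/2)

with R = 8.314e-3 kJ mol^-1 K^-1 and dG_r in kJ per mol H2.  The package
accepts dG0_r as input and ships a rough linear temperature default for the
aqueous Knallgas reaction; users with site thermodynamics should override.

The ratio analysis divides radiolytic electron-equivalent production by the
magnitude of the net organic-fuelled rate (O2 reduction in oxic columns,
DIC production in anoxic columns), per depth interval, and locates the
crossover age where radiolytic supply first matches organic-fuelled
respiration.  In electron equivalents the H2-based and oxidant-based ratios
are identical by stoichiometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import R_GAS_KJ
from .inversion import NetRateProfile
from .nuclear import ValidationError
from .radiolysis import to_electron_equivalents


def dG0_knallgas(T_K: float) -> float:
    """Default standard-state Gibbs energy of H2(aq) + 1/2 O2(aq) -> H2O(l).

    kJ per mol H2.  Linearization around 25 degC (-263 kJ/mol, slope from
    the reaction entropy); a coarse default meant to be overridden with
    site-specific dG0_r(T, P) values.
    """
    return -263.0 + 0.08 * (T_K - 298.15)


@dataclass(frozen=True)
class ThermoState:
    T_K: float
    P_MPa: float = 0.1
    dG0_kj_mol: float | None = None  # default: dG0_knallgas(T)
    Q: float = 1.0

    def __post_init__(self) -> None:
        if self.T_K <= 0:
            raise ValidationError("temperature must be > 0 K")
        if self.Q <= 0:
            raise ValidationError("activity quotient must be > 0")


def knallgas_quotient(a_H2: float, a_O2: float, a_H2O: float = 1.0) -> float:
    """Activity quotient Q = a_H2O / (a_H2 * a_O2^1/2)."""
    if a_H2 <= 0 or a_O2 <= 0 or a_H2O <= 0:
        raise ValidationError("activities must be > 0")
    return a_H2O / (a_H2 * np.sqrt(a_O2))


def gibbs_energy(state: ThermoState) -> float:
    """In situ dG_r (kJ per mol H2) for the state's T and activity quotient."""
    dg0 = state.dG0_kj_mol if state.dG0_kj_mol is not None else dG0_knallgas(state.T_K)
    return dg0 + 2.3 * R_GAS_KJ * state.T_K * np.log10(state.Q)


@dataclass(frozen=True)
class RatioSeries:
    """Radiolytic / organic electron-equivalent ratio against sediment age."""

    age_ma: np.ndarray
    ratio: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.age_ma) < 0):
            raise ValidationError("ages must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_ma": self.age_ma, "ratio": self.ratio, "sd": self.sigma}
        )


def ratio_series(
    radiolytic_eeq_mol_cm3_yr,
    organic: NetRateProfile,
    ages_ma,
) -> RatioSeries:
    """Per-interval ratio of radiolytic e-eq production to net organic rate.

    ``radiolytic_eeq_mol_cm3_yr`` is the radiolytic production (already in
    electron equivalents) per interval of the organic rate profile, scalar
    or array; ``ages_ma`` are the interval ages.  Organic rates are
    converted to electron equivalents via the stoichiometric ledger (4 e-
    per O2 or per organic C) and entered as magnitudes.  Intervals with zero
    organic rate yield an infinite ratio, flagged by sigma = nan and ignored
    by downstream statistics.
    """
    ages = np.asarray(ages_ma, dtype=float)
    rad = np.broadcast_to(
        np.asarray(radiolytic_eeq_mol_cm3_yr, dtype=float), ages.shape
    ).astype(float)
    organic_eeq = np.abs(to_electron_equivalents(organic.rate_mol_cm3_yr, organic.species))
    sigma_eeq = np.abs(to_electron_equivalents(organic.sigma_mol_cm3_yr, organic.species))
    if ages.shape != organic_eeq.shape:
        raise ValidationError("ages and organic rate profile lengths differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(organic_eeq > 0, rad / organic_eeq, np.inf)
        # first-order propagation: sd(ratio)/ratio = sd(rate)/rate
        sigma = np.where(
            organic_eeq > 0, ratio * sigma_eeq / np.where(organic_eeq > 0, organic_eeq, 1.0), np.nan
        )
    order = np.argsort(ages)
    return RatioSeries(ages[order], ratio[order], sigma[order])


def crossover_age(series: RatioSeries) -> float | None:
    """Smallest age at which the ratio first reaches 1 (linear interpolation).

    Returns None when the (finite part of the) series never reaches 1.
    """
    finite = np.isfinite(series.ratio)
    ages = series.age_ma[finite]
    ratio = series.ratio[finite]
    if len(ages) == 0:
        return None
    if ratio[0] >= 1.0:
        return float(ages[0])
    above = np.nonzero(ratio >= 1.0)[0]
    if len(above) == 0:
        return None
    j = above[0]
    a0, a1 = ages[j - 1], ages[j]
    r0, r1 = ratio[j - 1], ratio[j]
    return float(a0 + (1.0 - r0) / (r1 - r0) * (a1 - a0))
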