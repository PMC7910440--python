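"""Steady-state dissolved-H2 transport: expected profiles without consumption.

At steady state, diffusion balancing a depth-constant radiolytic source P
(per porewater volume) gives

    d^2 H2 / dx^2 = -P * phi * F / D,

with H2 = 0 at the sediment-water interface (diffusive loss to the ocean)
and at the sediment-basement interface (loss to permeable basement).  The
closed form is the parabola

    H2(x) = 1/2 * (P phi F / D) * (x Z - x^2).

A conservative finite-difference solver handles layered columns (flux
continuity -(D/(phi F)) dC/dx at internal interfaces), and a closed-form
two-layer solution covers the common case of a lithologic break.

Production computed per bulk sediment volume upstream is converted to the
per-porewater-volume rate used here by dividing by porosity — that
conversion happens in :func:`porewater_production` and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .constants import MOL_CM3_TO_NM, SECONDS_PER_YEAR
from .nuclear import ValidationError


def diffusion_coefficient_h2(temperature_c: float) -> float:
    """Free-solution diffusion coefficient of H2(aq), cm^2 yr^-1.

    Linearization of published H2 diffusivities in water
    (~2.45e-5 cm^2 s^-1 at 0 degC, ~4.5e-5 at 25 degC); adequate over the
    0-30 degC porewater range.  Pass a measured value to the transport
    parameters to override.
    """
    d_cm2_s = (2.45 + 0.082 * temperature_c) * 1e-5
    return d_cm2_s * SECONDS_PER_YEAR


def formation_factor(phi: float, n: float = 2.0) -> float:
    """Archie-type formation factor F = phi^-n (default n = 2)."""
    if not 0 < phi < 1:
        raise ValidationError("porosity must be in (0, 1)")
    return phi**-n


def porewater_production(p_sediment_mol_cm3_yr, phi):
    """Convert a per-bulk-sediment-volume rate to per-porewater-volume."""
    return np.asarray(p_sediment_mol_cm3_yr) / phi


@dataclass(frozen=True)
class TransportParameters:
    D_cm2_yr: float
    phi: float
    Z_m: float
    F: float | None = None  # defaults to Archie phi^-2

    def __post_init__(self) -> None:
        if self.D_cm2_yr <= 0 or self.Z_m <= 0:
            raise ValidationError("D and Z must be > 0")
        if not 0 < self.phi < 1:
            raise ValidationError("porosity must be in (0, 1)")
        if self.F is not None and self.F < 1:
            raise ValidationError("formation factor must be >= 1")

    @property
    def formation_factor(self) -> float:
        return self.F if self.F is not None else formation_factor(self.phi)


@dataclass(frozen=True)
class H2Profile:
    """Dissolved H2 vs depth; depths in m, concentrations in nM."""

    x_m: np.ndarray
    conc_nM: np.ndarray
    kind: str = "expected"  # "measured" | "expected"
    detection_limit_nM: float | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x_m, float)
        if np.any(np.asarray(self.conc_nM) < -1e-9):
            raise ValidationError("concentrations must be >= 0")
        if len(x) > 1 and np.any(np.diff(x) <= 0):
            raise ValidationError("depths must be strictly increasing")


@dataclass(frozen=True)
class Layer:
    thickness_m: float
    P_pw_mol_cm3_yr: float  # production per porewater volume
    phi: float
    D_cm2_yr: float
    F: float | None = None

    @property
    def formation_factor(self) -> float:
        return self.F if self.F is not None else formation_factor(self.phi)

    @property
    def source(self) -> float:
        """P phi F / D in mol cm^-3 cm^-2 (curvature of the profile)."""
        return self.P_pw_mol_cm3_yr * self.phi * self.formation_factor / self.D_cm2_yr

    @property
    def conductance(self) -> float:
        """D / (phi F): the coefficient in the diffusive flux."""
        return self.D_cm2_yr / (self.phi * self.formation_factor)


@dataclass(frozen=True)
class LayeredColumn:
    layers: Sequence[Layer] = field(default_factory=list)

    @property
    def Z_m(self) -> float:
        return sum(l.thickness_m for l in self.layers)


def steady_state_profile(
    P_pw_mol_cm3_yr: float, params: TransportParameters, x_m
) -> np.ndarray:
    """Closed-form expected H2(x) in nM for a uniform column.

    ``P_pw_mol_cm3_yr`` is the radiolytic source per porewater volume.
    Zero at both boundaries; maximum P phi F Z^2 / (8 D) at mid-column.
    """
    x_cm = np.asarray(x_m, dtype=float) * 100.0
    z_cm = params.Z_m * 100.0
    if np.any(x_cm < -1e-9) or np.any(x_cm > z_cm * (1 + 1e-12)):
        raise ValidationError("depth outside [0, Z]")
    q = P_pw_mol_cm3_yr * params.phi * params.formation_factor / params.D_cm2_yr
    conc_mol_cm3 = 0.5 * q * (x_cm * z_cm - x_cm**2)
    return conc_mol_cm3 * MOL_CM3_TO_NM


def numeric_profile(column: LayeredColumn, n_nodes: int = 2001) -> H2Profile:
    """Finite-difference steady-state solution on a layered column.

    Conservative second-order scheme for d/dx(k dC/dx) = -P_pw phi F ... in
    the equivalent form d/dx(k dC/dx) = -P_bulk with k = D/(phi F); interface
    conductances use harmonic means so diffusive flux is continuous across
    layer boundaries.  Dirichlet zero concentration at both ends.
    """
    if n_nodes < 3:
        raise ValidationError("n_nodes must be >= 3")
    z_cm = column.Z_m * 100.0
    x = np.linspace(0.0, z_cm, n_nodes)
    h = x[1] - x[0]

    bounds = np.cumsum([0.0] + [l.thickness_m * 100.0 for l in column.layers])
    k_layer = np.array([l.conductance for l in column.layers])
    # source per bulk-equivalent form: k * (P phi F / D) = P_pw
    s_layer = np.array([l.conductance * l.source for l in column.layers])

    # exact piecewise-linear cumulative integrals of 1/k and of the source,
    # so transmissibilities and cell averages are exact for any alignment of
    # layer interfaces with the grid
    seg = np.diff(bounds)
    cum_invk = np.concatenate([[0.0], np.cumsum(seg / k_layer)])
    cum_src = np.concatenate([[0.0], np.cumsum(seg * s_layer)])
    invk_at = lambda q: np.interp(q, bounds, cum_invk)
    src_at = lambda q: np.interp(q, bounds, cum_src)

    k_face = h / np.diff(invk_at(x))  # transmissibility between nodes i, i+1
    cell_lo = np.clip(x - h / 2.0, 0.0, z_cm)
    cell_hi = np.clip(x + h / 2.0, 0.0, z_cm)
    s_cell = (src_at(cell_hi) - src_at(cell_lo)) / (cell_hi - cell_lo)

    n = n_nodes - 2
    ab = np.zeros((3, n))
    ab[0, 1:] = k_face[1:-1] / h**2
    ab[1, :] = -(k_face[:-1] + k_face[1:]) / h**2
    ab[2, :-1] = k_face[1:-1] / h**2
    rhs = -s_cell[1:-1]
    try:
        interior = solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValidationError("singular transport system") from exc
    conc = np.zeros(n_nodes)
    conc[1:-1] = interior
    return H2Profile(x / 100.0, np.maximum(conc, 0.0) * MOL_CM3_TO_NM)


def two_layer_profile(column: LayeredColumn, n_points: int = 201) -> H2Profile:
    """Closed-form piecewise-parabolic solution for exactly two layers.

    Zero concentration at top and bottom; continuity of concentration and of
    diffusive flux -(D/(phi F)) dC/dx at the internal interface.
    """
    if len(column.layers) != 2:
        raise ValidationError("two_layer_profile requires exactly 2 layers")
    l1, l2 = column.layers
    h = l1.thickness_m * 100.0
    z = column.Z_m * 100.0
    q1, q2 = l1.source, l2.source
    k1, k2 = l1.conductance, l2.conductance
    # C1 = -q1/2 x^2 + a1 x ; C2 = -q2/2 x^2 + a2 x + b2
    # unknowns (a1, a2, b2): continuity at h, flux continuity, C2(Z) = 0
    mat = np.array(
        [
            [h, -h, -1.0],
            [k1, -k2, 0.0],
            [0.0, z, 1.0],
        ]
    )
    rhs = np.array(
        [
            (q1 - q2) * h**2 / 2.0,
            (k1 * q1 - k2 * q2) * h,
            q2 * z**2 / 2.0,
        ]
    )
    a1, a2, b2 = np.linalg.solve(mat, rhs)
    x = np.linspace(0.0, z, n_points)
    conc = np.where(
        x <= h,
        -q1 / 2.0 * x**2 + a1 * x,
        -q2 / 2.0 * x**2 + a2 * x + b2,
    )
    return H2Profile(x / 100.0, np.maximum(conc, 0.0) * MOL_CM3_TO_NM)


def compare_profiles(measured: H2Profile, expected: H2Profile) -> dict:
    """Per-depth expected/measured ratios and an order-of-magnitude summary.

    Measured values below the detection limit are replaced by the detection
    limit and flagged: their ratios are lower bounds.  A consumption flag is
    raised when the median ratio exceeds 10 (expected concentrations cannot
    be sustained without in situ consumption).
    """
    lo = max(measured.x_m.min(), expected.x_m.min())
    hi = min(measured.x_m.max(), expected.x_m.max())
    sel = (measured.x_m >= lo) & (measured.x_m <= hi)
    if not np.any(sel):
        raise ValidationError("no overlapping depth support")
    x = np.asarray(measured.x_m)[sel]
    meas = np.asarray(measured.conc_nM, float)[sel]
    exp = np.interp(x, expected.x_m, expected.conc_nM)
    dl = measured.detection_limit_nM
    censored = np.zeros_like(meas, dtype=bool)
    if dl is not None:
        censored = meas < dl
        meas = np.where(censored, dl, meas)
    with np.errstate(divide="ignore"):
        ratio = np.where(meas > 0, exp / meas, np.inf)
    finite = ratio[np.isfinite(ratio) & (ratio > 0)]
    median = float(np.median(finite)) if len(finite) else np.inf
    table = pd.DataFrame(
        {
            "depth_m": x,
            "measured_nM": meas,
            "expected_nM": exp,
            "ratio": ratio,
            "ratio_is_lower_bound": censored,
        }
    )
    return {
        "table": table,
        "median_ratio": median,
        "orders_of_magnitude": float(np.log10(median)) if median > 0 else -np.inf,
        "consumption_flag": bool(median > 10.0),
    }


def read_h2_csv(path) -> H2Profile:
    """Read a measured H2 profile (site, depth_m, H2_nM, detection_limit_nM)."""
    df = pd.read_csv(path)
    missing = {"depth_m", "H2_nM"} - set(df.columns)
    if missing:
        raise ValidationError(f"H2 CSV missing columns: {sorted(missing)}")
    dl = float(df["detection_limit_nM"].iloc[0]) if "detection_limit_nM" in df else None
    df = df.sort_values("depth_m")
    return H2Profile(
        df["depth_m"].to_numpy(float),
        df["H2_nM"].to_numpy(float),
        kind="measured",
        detection_limit_nM=dl,
    )
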