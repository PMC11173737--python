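"""Closed-form hydration thermodynamics of shape-dependent hydrophobicity.

The model partitions the hydration free energy of a spherical solute of
radius R into a bulk-water term and an interfacial term.  The interfacial
term scales with the number ratio of interfacial water to volume, which for a
sphere is 4·r_H2O/R, and with the free-energy cost ΔG_DDAA of breaking a
tetrahedral hydrogen-bonding environment per lost bond:

    ΔG_hydration(R) = ΔG_water_water + ΔG_DDAA · (4 r_H2O / R) · n_HB

With n_HB = 2 bonds lost per interfacial molecule the interfacial term is
8·ΔG_DDAA·r_H2O/R.  The two terms balance at the critical radius

    Rc = 8 |ΔG_DDAA| r_H2O / |ΔG_water_water|

below which the solute mostly perturbs interfacial water and above which the
bulk term dominates (hydrophobic solvation; solutes aggregate to minimise
surface-area-to-volume ratio).  Aggregation bookkeeping is carried by the
geometric factor γ (ratio of aggregated to separated SA/V) and by the count
of water molecules expelled from the interface into the bulk, each worth
ΔG_DDAA.  The long-range water-induced interaction between two solutes is
well described by a hyperbolic decay a + γ·b/(r − r0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import ThermoConstants
from .errors import DegenerateDataError, DomainError, InsufficientDataError

__all__ = [
    "spherical_radius_from_volume",
    "interfacial_volume_ratio_sphere",
    "solute_water_free_energy",
    "hydration_free_energy",
    "critical_radius",
    "GeometricFactorInput",
    "geometric_factor",
    "hydrophobic_interaction_energy",
    "WaterInducedModel",
    "WaterInducedFit",
    "evaluate_water_induced_model",
    "fit_water_induced_model",
    "PackingParameterInput",
    "packing_parameter_shape",
]

_M_TO_ANGSTROM = 1e10


def spherical_radius_from_volume(volume_m3: float) -> float:
    """Radius (Å) of a sphere with the given molecular volume (m³).

    For the ambient molecular volume of water, ~3e-29 m³, this gives the
    effective water radius r_H2O ≈ 1.9 Å.
    """
    if volume_m3 <= 0:
        raise DomainError(f"volume must be > 0, got {volume_m3}")
    return (3.0 * volume_m3 / (4.0 * math.pi)) ** (1.0 / 3.0) * _M_TO_ANGSTROM


def interfacial_volume_ratio_sphere(radius: float, constants: ThermoConstants) -> float:
    """Number ratio of interfacial-layer water to volume for a sphere: 4·r_H2O/R."""
    if radius <= 0:
        raise DomainError(f"radius must be > 0, got {radius}")
    return 4.0 * constants.r_h2o / radius


def solute_water_free_energy(
    radius: float, constants: ThermoConstants, n_hb: float = 2.0
) -> float:
    """Interfacial (solute–water) free-energy term, kJ/mol.

    ΔG_solute_water = ΔG_DDAA · (4 r_H2O / R) · n_HB, where ``n_hb`` is the
    number of hydrogen bonds lost per interfacial molecule.  The default
    n_HB = 2 reproduces the 8·ΔG_DDAA·r_H2O/R interfacial term of the
    hydration free energy.
    """
    if n_hb < 0:
        raise DomainError(f"n_hb must be >= 0, got {n_hb}")
    return constants.dg_ddaa * interfacial_volume_ratio_sphere(radius, constants) * n_hb


def hydration_free_energy(
    radius: float, constants: ThermoConstants, n_hb: float = 2.0
) -> float:
    """Hydration free energy of a spherical solute, kJ/mol.

    Sum of the bulk-water term and the interfacial term; converges to
    ΔG_water_water as R → ∞.
    """
    return constants.dg_water_water + solute_water_free_energy(radius, constants, n_hb)


def critical_radius(constants: ThermoConstants) -> float:
    """Critical solute radius Rc (Å) at which the two hydration terms balance.

    Evaluated as a ratio of magnitudes, 8·|ΔG_DDAA|·r_H2O/|ΔG_water_water|;
    both constants are negative under the standard convention, so the raw
    ratio and the magnitude ratio coincide.
    """
    if constants.dg_water_water == 0:
        raise DomainError("dg_water_water must be nonzero for the critical radius")
    return 8.0 * abs(constants.dg_ddaa) * constants.r_h2o / abs(constants.dg_water_water)


@dataclass(frozen=True)
class GeometricFactorInput:
    """Inputs of the geometric factor γ.

    Attributes
    ----------
    sa_over_v_aggregate : float
        Surface-area-to-volume ratio of the aggregated state, 1/Å.
    sa_over_v_separate : float
        Surface-area-to-volume ratio of the non-aggregated state, 1/Å.
    r_separation : float
        Solute–solute separation, Å.
    r_hydrophobic : float
        Hydrophobic radius R_H: the separation at which solute surfaces first
        touch; beyond it no surface is shared and γ = 1.
    """

    sa_over_v_aggregate: float
    sa_over_v_separate: float
    r_separation: float
    r_hydrophobic: float

    def __post_init__(self) -> None:
        if self.sa_over_v_aggregate <= 0 or self.sa_over_v_separate <= 0:
            raise DomainError("surface-area-to-volume ratios must be > 0")
        if self.r_separation < 0:
            raise DomainError("r_separation must be >= 0")


def geometric_factor(inp: GeometricFactorInput) -> float:
    """γ = (SA/V)_aggregate / (SA/V)_separate; exactly 1 when surfaces are apart.

    When the separation exceeds the hydrophobic radius R_H the solutes share
    no surface and γ is exactly 1 regardless of the supplied ratios.
    """
    if inp.r_separation > inp.r_hydrophobic:
        return 1.0
    return inp.sa_over_v_aggregate / inp.sa_over_v_separate


def hydrophobic_interaction_energy(n_transferred: int, constants: ThermoConstants) -> float:
    """Free-energy gain from ``n_transferred`` interfacial→bulk molecules, kJ/mol.

    Each molecule moving from the interface to the bulk regains a tetrahedral
    hydrogen-bonding environment worth ΔG_DDAA; the interaction energy is
    strictly proportional to the count.
    """
    if n_transferred < 0:
        raise DomainError(f"n_transferred must be >= 0, got {n_transferred}")
    if n_transferred != int(n_transferred):
        raise DomainError(f"n_transferred must be an integer, got {n_transferred}")
    return float(n_transferred) * constants.dg_ddaa


@dataclass(frozen=True)
class WaterInducedModel:
    """Hyperbolic model of the water-induced interaction: ΔG(r) = a + γ·b/(r − r0).

    ``a`` is the asymptotic offset (kJ/mol), ``b`` the amplitude (kJ/mol·Å),
    ``r0`` the vacuum contact-minimum distance (Å), and ``gamma`` the
    geometric factor in (0, 1].
    """

    a: float
    b: float
    r0: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise DomainError(f"gamma must be in (0, 1], got {self.gamma}")


def evaluate_water_induced_model(r, coeffs: WaterInducedModel):
    """Evaluate the hyperbolic water-induced model at separation(s) ``r`` (Å)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= coeffs.r0):
        raise DomainError(f"model defined only for r > r0 = {coeffs.r0}")
    out = coeffs.a + coeffs.gamma * coeffs.b / (r_arr - coeffs.r0)
    return float(out) if np.isscalar(r) else out


@dataclass(frozen=True)
class WaterInducedFit:
    """Least-squares fit of the hyperbolic water-induced model."""

    model: WaterInducedModel
    a_stderr: float
    b_stderr: float
    rss: float
    rmse: float
    n_points: int

    def predict(self, r):
        return evaluate_water_induced_model(r, self.model)


def fit_water_induced_model(
    points: Sequence[tuple[float, float]] | np.ndarray,
    r0: float,
    gamma: float = 1.0,
) -> WaterInducedFit:
    """Fit a and b of ΔG(r) = a + γ·b/(r − r0) with r0 and γ held fixed.

    Linear least squares in the transformed variable x = γ/(r − r0); standard
    errors come from the unbiased residual variance and (XᵀX)⁻¹.  Points with
    r ≤ r0 are outside the model domain and rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError("points must be a sequence of (r, dG) pairs")
    r, y = pts[:, 0], pts[:, 1]
    valid = r > r0
    r, y = r[valid], y[valid]
    n = r.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 points with r > r0, got {n}")
    if np.ptp(r) == 0:
        raise DegenerateDataError("all r values are equal; fit is degenerate")
    x = gamma / (r - r0)
    X = np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    a_hat, b_hat = float(coef[0]), float(coef[1])
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = max(n - 2, 1)
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    model = WaterInducedModel(a=a_hat, b=b_hat, r0=r0, gamma=gamma)
    return WaterInducedFit(
        model=model,
        a_stderr=float(np.sqrt(cov[0, 0])),
        b_stderr=float(np.sqrt(cov[1, 1])),
        rss=rss,
        rmse=float(np.sqrt(rss / n)),
        n_points=n,
    )


@dataclass(frozen=True)
class PackingParameterInput:
    """Inputs of the surfactant packing parameter p = v0/(a·l0).

    ``v0``: tail volume (Å³); ``a_head``: surface area per molecule of the
    aggregate's hydrophobic core (Å²); ``l0``: tail length (Å).
    """

    v0: float
    a_head: float
    l0: float

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.a_head <= 0 or self.l0 <= 0:
            raise DomainError("all packing-parameter fields must be > 0")

    @property
    def value(self) -> float:
        return self.v0 / (self.a_head * self.l0)


def packing_parameter_shape(inp: PackingParameterInput) -> str:
    """Aggregate shape class predicted by the packing parameter.

    p ≤ 1/3 → sphere; 1/3 < p ≤ 1/2 → cylinder; 1/2 < p ≤ 1 → bilayer;
    p > 1 → out-of-range.  The printed interval boundaries overlap, so exact
    boundary values are deterministically assigned to the smaller class.
    """
    p = inp.value
    if p <= 1.0 / 3.0:
        return "sphere"
    if p <= 0.5:
        return "cylinder"
    if p <= 1.0:
        return "bilayer"
    return "out-of-range"
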