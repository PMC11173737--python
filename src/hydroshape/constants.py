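"""Physical constants and the thermodynamic parameter set of the hydration model.

The hydration model accounts for the free-energy cost of converting bulk water
(tetrahedrally hydrogen-bonded, DDAA) into interfacial water at a solute
surface.  Two literature constants drive everything: the free energy of a
tetrahedral (DDAA) hydrogen-bonding environment and the free energy of bulk
water, both at ambient conditions.  All internal arithmetic is in kJ/mol;
calorie-based inputs are converted on entry (1 cal = 4.184 J), so ratios such
as the critical radius are never formed across mixed units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

from scipy.constants import R as _R_J_MOL_K
from scipy.constants import calorie as CAL_TO_J

from .errors import DomainError

#: Molar gas constant in kJ/(mol K).
GAS_CONSTANT_KJ_MOL_K: float = _R_J_MOL_K / 1000.0


def cal_to_kj(value_cal: float) -> float:
    """Convert cal/mol to kJ/mol (thermochemical calorie, 4.184 J)."""
    return value_cal * CAL_TO_J / 1000.0


@dataclass(frozen=True)
class ThermoConstants:
    """Constants of the hydration free-energy model, in canonical units.

    Parameters
    ----------
    dg_ddaa : float
        Free energy of tetrahedral (DDAA) hydrogen bonding, kJ/mol.
        Negative under the convention used here.
    dg_water_water : float
        Free energy of bulk water, kJ/mol (converted from cal/mol where the
        source quotes calories).
    r_h2o : float
        Effective water-molecule radius, Å.
    temperature : float
        Temperature, K.
    pressure : float
        Pressure, MPa.
    """

    dg_ddaa: float = -2.66
    dg_water_water: float = cal_to_kj(-1500.0)
    r_h2o: float = 1.9
    temperature: float = 293.0
    pressure: float = 0.1

    def __post_init__(self) -> None:
        if self.r_h2o <= 0:
            raise DomainError(f"r_h2o must be > 0, got {self.r_h2o}")
        if self.temperature <= 0:
            raise DomainError(f"temperature must be > 0, got {self.temperature}")
        # Both free energies must share a sign convention; a mixed-sign pair
        # silently flips the sign of every derived quantity.
        if self.dg_ddaa * self.dg_water_water < 0:
            raise DomainError(
                "dg_ddaa and dg_water_water must share a sign convention "
                f"(got {self.dg_ddaa} and {self.dg_water_water})"
            )

    @property
    def kt(self) -> float:
        """Thermal energy k_B·T (as R·T per mole), kJ/mol."""
        return GAS_CONSTANT_KJ_MOL_K * self.temperature

    @classmethod
    def ambient(cls) -> "ThermoConstants":
        """The literature constants at 293 K and 0.1 MPa."""
        return cls()

    @classmethod
    def from_config(cls, mapping: Mapping[str, Any]) -> "ThermoConstants":
        """Build from a config mapping.

        Recognised keys: ``dG_DDAA_kJ_mol``, ``dG_water_water_cal_mol`` (or
        ``dG_water_water_kJ_mol``), ``r_H2O_A``, ``T_K``, ``P_MPa``.  Missing
        keys fall back to the ambient defaults.
        """
        defaults = cls()
        if "dG_water_water_kJ_mol" in mapping:
            dgww = float(mapping["dG_water_water_kJ_mol"])
        elif "dG_water_water_cal_mol" in mapping:
            dgww = cal_to_kj(float(mapping["dG_water_water_cal_mol"]))
        else:
            dgww = defaults.dg_water_water
        return cls(
            dg_ddaa=float(mapping.get("dG_DDAA_kJ_mol", defaults.dg_ddaa)),
            dg_water_water=dgww,
            r_h2o=float(mapping.get("r_H2O_A", defaults.r_h2o)),
            temperature=float(mapping.get("T_K", defaults.temperature)),
            pressure=float(mapping.get("P_MPa", defaults.pressure)),
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "dG_DDAA_kJ_mol": self.dg_ddaa,
            "dG_water_water_kJ_mol": self.dg_water_water,
            "r_H2O_A": self.r_h2o,
            "T_K": self.temperature,
            "P_MPa": self.pressure,
        }
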