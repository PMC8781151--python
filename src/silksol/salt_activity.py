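"""Water-activity tables for aqueous NaCl and KCl at 25 degC.

Compiled by the package authors from the standard osmotic-coefficient
compilation of Hamer & Wu (J. Phys. Chem. Ref. Data 1, 1047 (1972)),
rounded to four figures. The water activity follows from the osmotic
coefficient phi via

    ln a_w = -nu * m * phi * M_w / 1000

with nu = 2 ions per formula unit, molality m in mol/kg and M_w = 18.015
g/mol. The activity of a saturated NaCl solution (~6.1 mol/kg) evaluates
to ~0.755, matching the familiar 75 % relative humidity of the saturated
salt. Entries are interpolated piecewise-linearly; requests outside the
tabulated range are rejected rather than extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import WATER_MOLAR_MASS

__all__ = ["SaltActivityTable", "NACL_TABLE", "KCL_TABLE", "activity_from_salt"]


@dataclass(frozen=True)
class SaltActivityTable:
    """Water activity vs molality for one salt, with a provenance note."""

    salt: str
    molality: tuple[float, ...]  # mol kg^-1, increasing, starting at 0
    water_activity: tuple[float, ...]  # (0, 1], decreasing
    source: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.molality)
        a = np.asarray(self.water_activity)
        if m.shape != a.shape:
            raise ValueError("molality and activity grids must match")
        if np.any(np.diff(m) <= 0):
            raise ValueError("molality grid must be increasing")
        if np.any(np.diff(a) >= 0):
            raise ValueError("water activity must decrease with concentration")
        if np.any(a <= 0) or np.any(a > 1):
            raise ValueError("activities must lie in (0, 1]")

    def molality_from_mass_fraction(self, w_percent: float, molar_mass: float) -> float:
        """Convert % w/w salt to molality, mol per kg of water."""
        w = w_percent / 100.0
        if not 0 <= w < 1:
            raise ValueError("mass fraction out of range")
        return 1000.0 * w / (molar_mass * (1.0 - w))


def _from_phi(entries: dict[float, float]) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """(molality, activity) grids from {molality: osmotic coefficient}."""
    ms = [0.0]
    acts = [1.0]
    for m, phi in sorted(entries.items()):
        ms.append(m)
        acts.append(math.exp(-2.0 * m * phi * WATER_MOLAR_MASS / 1000.0))
    return tuple(ms), tuple(acts)


_NACL_PHI = {
    0.1: 0.9324, 0.2: 0.9245, 0.3: 0.9215, 0.5: 0.9209, 0.7: 0.9257,
    1.0: 0.9355, 1.5: 0.9589, 2.0: 0.9833, 2.5: 1.0130, 3.0: 1.0453,
    3.5: 1.0793, 4.0: 1.1158, 4.5: 1.1539, 5.0: 1.1916, 5.5: 1.2310,
    6.0: 1.2706,
}

_KCL_PHI = {
    0.1: 0.9266, 0.2: 0.9130, 0.3: 0.9063, 0.5: 0.9000, 0.7: 0.8980,
    1.0: 0.8984, 1.5: 0.9024, 2.0: 0.9114, 2.5: 0.9227, 3.0: 0.9356,
    3.5: 0.9493, 4.0: 0.9635, 4.5: 0.9779,
}

_SOURCE = "osmotic coefficients after Hamer & Wu (1972), 25 degC"

_nacl_m, _nacl_a = _from_phi(_NACL_PHI)
NACL_TABLE = SaltActivityTable("NaCl", _nacl_m, _nacl_a, _SOURCE)

_kcl_m, _kcl_a = _from_phi(_KCL_PHI)
KCL_TABLE = SaltActivityTable("KCl", _kcl_m, _kcl_a, _SOURCE)

_TABLES = {"NaCl": NACL_TABLE, "KCl": KCL_TABLE}


def activity_from_salt(
    salt: str,
    concentration: float,
    table: SaltActivityTable | None = None,
) -> float:
    """Water activity at ``concentration`` (mol/kg) by linear interpolation.

    ``table`` overrides the packaged NaCl/KCl tables. Concentrations
    outside the tabulated range raise rather than extrapolate.
    """
    if table is None:
        try:
            table = _TABLES[salt]
        except KeyError:
            raise ValueError(f"no packaged activity table for salt {salt!r}") from None
    m = np.asarray(table.molality)
    if not m[0] <= concentration <= m[-1]:
        raise ValueError(
            f"concentration {concentration} mol/kg outside table range "
            f"[{m[0]}, {m[-1]}] for {table.salt}"
        )
    return float(np.interp(concentration, m, np.asarray(table.water_activity)))
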