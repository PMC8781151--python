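"""Closed-form coil-size, density and hydration-stoichiometry calculations.

A polypeptide in solution under theta conditions is characterised here only
by its residue count ``N``, monomer (virtual-bond) length ``b`` and masses.
For *B. mori* fibroin the conjoined heavy + light chain has N = 5525
residues, an average residue mass of 75.9 g/mol and a chain mass of about
419.6 kDa; with b = 0.4 nm the freely jointed chain predicts a radius of
gyration of ~12.1 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import AVOGADRO, WATER_MOLAR_MASS

__all__ = [
    "ChainSpec",
    "SolutionComposition",
    "FIBROIN",
    "rg_random_coil",
    "rg_power_law",
    "coil_mass_density",
    "water_to_residue_ratio",
]


@dataclass(frozen=True)
class ChainSpec:
    """Minimal description of a polypeptide chain.

    Parameters
    ----------
    n_residues : int
        Number of amino-acid residues (monomers), >= 1.
    monomer_length : float
        Virtual bond length b between consecutive residues, nm.
    avg_residue_mass : float
        Mean residue formula weight, g/mol.
    chain_molar_mass : float, optional
        Total chain mass, g/mol. If given it must agree with
        ``n_residues * avg_residue_mass`` to within 2 %.
    """

    n_residues: int
    monomer_length: float
    avg_residue_mass: float
    chain_molar_mass: float | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.monomer_length <= 0:
            raise ValueError("monomer_length must be > 0")
        if self.avg_residue_mass <= 0:
            raise ValueError("avg_residue_mass must be > 0")
        if self.chain_molar_mass is not None:
            implied = self.n_residues * self.avg_residue_mass
            if abs(self.chain_molar_mass - implied) / self.chain_molar_mass > 0.02:
                raise ValueError(
                    "chain_molar_mass inconsistent with n_residues * avg_residue_mass"
                )

    @property
    def molar_mass(self) -> float:
        """Chain molar mass, g/mol (explicit value or N * residue mass)."""
        if self.chain_molar_mass is not None:
            return self.chain_molar_mass
        return self.n_residues * self.avg_residue_mass

    @classmethod
    def from_dict(cls, d: dict) -> "ChainSpec":
        """Build from config keys n_residues, monomer_length_nm, avg_residue_mass[, chain_molar_mass]."""
        return cls(
            n_residues=int(d["n_residues"]),
            monomer_length=float(d.get("monomer_length_nm", d.get("monomer_length"))),
            avg_residue_mass=float(d["avg_residue_mass"]),
            chain_molar_mass=(
                float(d["chain_molar_mass"]) if "chain_molar_mass" in d else None
            ),
        )


#: The conjoined Fib-H + Fib-L chain of *B. mori* fibroin.
FIBROIN = ChainSpec(
    n_residues=5525,
    monomer_length=0.4,
    avg_residue_mass=75.9,
    chain_molar_mass=419_600.0,
)


@dataclass(frozen=True)
class SolutionComposition:
    """Composition of an aqueous solution of a peptide-bearing solute.

    Either ``solute_mass_fraction`` (w/w) or ``solute_concentration``
    (g/cm^3, overrides the mass fraction when given) fixes the solute
    content; the water content is whatever mass remains per cm^3 of
    solution at ``total_density``.
    """

    solute_mass_fraction: float
    solute_residue_mass: float
    water_molar_mass: float = WATER_MOLAR_MASS
    total_density: float = 1.0  # g cm^-3
    solute_concentration: float | None = None  # g cm^-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.solute_mass_fraction <= 1.0:
            raise ValueError("solute_mass_fraction must be in [0, 1]")
        if self.total_density <= 0:
            raise ValueError("total_density must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SolutionComposition":
        return cls(
            solute_mass_fraction=float(d.get("mass_fraction", 0.0)),
            solute_residue_mass=float(d["solute_residue_mass"]),
            water_molar_mass=float(d.get("water_molar_mass", WATER_MOLAR_MASS)),
            total_density=float(d.get("density", 1.0)),
            solute_concentration=(
                float(d["solute_concentration"]) if "solute_concentration" in d else None
            ),
        )


def rg_random_coil(chain: ChainSpec) -> float:
    """Radius of gyration of a freely jointed chain under theta conditions.

    R_G = sqrt(N b^2 / 6) = b sqrt(N / 6), in nm.
    """
    return chain.monomer_length * math.sqrt(chain.n_residues / 6.0)


def rg_power_law(n_residues: float, prefactor: float, exponent: float) -> float:
    """Empirical scaling R_G = prefactor * N**exponent (nm).

    Several such relations exist in the literature for globular, denatured
    and intrinsically disordered proteins; the coefficients are
    caller-supplied so any of them can be evaluated.
    """
    if prefactor <= 0:
        raise ValueError("prefactor must be > 0")
    return prefactor * n_residues**exponent


def coil_mass_density(chain_molar_mass: float, rg: float) -> float:
    """Mean mass density of one chain smeared over its coil volume, g/cm^3.

    The coil is represented by the uniform sphere with the same radius of
    gyration, i.e. sphere radius R = sqrt(5/3) * R_G. One chain of mass
    M / N_A is divided by that sphere's volume.
    """
    if chain_molar_mass <= 0 or rg <= 0:
        raise ValueError("chain_molar_mass and rg must be > 0")
    radius_cm = math.sqrt(5.0 / 3.0) * rg * 1e-7  # nm -> cm
    volume = 4.0 / 3.0 * math.pi * radius_cm**3
    return chain_molar_mass / AVOGADRO / volume


def water_to_residue_ratio(comp: SolutionComposition) -> float:
    """Molar ratio of water molecules to peptide (residue) groups.

    For a mass-fraction specification, per gram of solution:
    (water mass / M_w) / (solute mass / residue mass). When
    ``solute_concentration`` (g/cm^3) is given it overrides the mass
    fraction and the water mass per cm^3 is total_density − concentration.
    """
    if comp.solute_concentration is not None:
        if comp.solute_concentration >= comp.total_density:
            raise ValueError("solute_concentration must be below total_density")
        water_mass = comp.total_density - comp.solute_concentration
        solute_mass = comp.solute_concentration
    else:
        if comp.solute_mass_fraction >= 1.0:
            raise ValueError("solute mass fraction must be < 1")
        solute_mass = comp.solute_mass_fraction
        water_mass = 1.0 - comp.solute_mass_fraction
    water_moles = water_mass / comp.water_molar_mass
    solute_moles = solute_mass / comp.solute_residue_mass
    return water_moles / solute_moles
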