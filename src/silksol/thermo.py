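"""Hydration-shell thermodynamics: the package's core model.

The stability of the water shell H-bonded to the peptide backbone is
framed as a competition of chemical potentials. Relative to liquid water
at the triple point, published vapour-pressure data give quadratic
mu(T) curves for ice and water (T in deg C, mu in J/mol):

    mu_ice(T)   = 10.286 + 22.186 T - 0.0717 T^2
    mu_water(T) =  8.038 - 0.7842 T - 0.1167 T^2

Dissolved salts lower the water chemical potential by R T ln(a_w), with
the activity a_w = p/p# taken from vapour-pressure (osmotic-coefficient)
data. The hydration shell itself is modelled with three parameters — the
enthalpy and entropy offsets from free water at T0 = 273.15 K and a
constant shell heat capacity C_p:

    mu_hyd(T) = [dH0 + C_p (T - T0)] - T [dS0 + C_p ln(T / T0)]

(T absolute inside the increment and log ratio). Fitting this to cloud
and aggregation points gives dH0 = -69.7 J/mol, dS0 = 0.2 J/(mol K),
C_p = 57.9 J/(mol K). Relative to bulk water (C_p 75.7 J/(mol K)) the
shell is short of Delta C_p = 17.8 J/(mol K) of heat capacity; the
resulting Delta G crosses zero near 68 degC (gelation on heating) and the
shell curve crosses the ice curve near -6 degC (gelation on freezing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares

from .constants import (
    CP_WATER,
    GAS_CONSTANT,
    T_ZERO_C,
    TRIPLE_POINT_P,
    TRIPLE_POINT_T,
)
from .salt_activity import (  # re-exported: part of this module's surface
    KCL_TABLE,
    NACL_TABLE,
    SaltActivityTable,
    activity_from_salt,
)

__all__ = [
    "QuadraticMuCurve",
    "HydrationShellParams",
    "CloudPointDatum",
    "SaltActivityTable",
    "NACL_TABLE",
    "KCL_TABLE",
    "ICE_CURVE",
    "WATER_CURVE",
    "FITTED_SHELL",
    "mu_ice",
    "mu_water",
    "mu_solution",
    "mu_hydration",
    "fit_quadratic_mu",
    "reference_mu_table",
    "delta_thermo",
    "gelation_temperature_heating",
    "gelation_temperature_freezing",
    "enthalpy_penalty_at_gelation",
    "fit_hydration_model",
    "HydrationFitReport",
    "activity_from_salt",
    "hbond_displacement_enthalpy",
]


@dataclass(frozen=True)
class QuadraticMuCurve:
    """mu(T) = c0 + c1 T + c2 T^2 with T in deg C, mu in J/mol."""

    c0: float
    c1: float
    c2: float
    phase: str = ""

    def __call__(self, temperature_c) -> float | np.ndarray:
        t = np.asarray(temperature_c, dtype=float)
        out = self.c0 + self.c1 * t + self.c2 * t**2
        return float(out) if out.ndim == 0 else out


#: Fitted quadratics for the chemical potential of ice and liquid water,
#: relative to liquid water at the triple point.
ICE_CURVE = QuadraticMuCurve(10.286, 22.186, -0.0717, phase="ice")
WATER_CURVE = QuadraticMuCurve(8.038, -0.7842, -0.1167, phase="water")

_VALID_RANGE_C = (-30.0, 100.0)


@dataclass(frozen=True)
class HydrationShellParams:
    """Three-parameter hydration-shell model state.

    dH0, dS0: enthalpy (J/mol) and entropy (J/(mol K)) offsets of shell
    water from free water at the reference temperature T0 (K).
    cp_shell: constant molar heat capacity of shell water, J/(mol K).
    cp_water_ref: bulk-water heat capacity used for the relative
    (Delta H, Delta S, Delta G) quantities.
    """

    dH0: float
    dS0: float
    cp_shell: float
    T0: float = T_ZERO_C
    cp_water_ref: float = CP_WATER

    def __post_init__(self) -> None:
        if self.cp_shell <= 0:
            raise ValueError("cp_shell must be > 0")
        if self.T0 <= 0:
            raise ValueError("T0 must be > 0 (Kelvin)")

    @property
    def delta_cp(self) -> float:
        """Heat-capacity deficit of shell water, J/(mol K)."""
        return self.cp_water_ref - self.cp_shell


#: Parameters from the fit to cloud/aggregation-point data.
FITTED_SHELL = HydrationShellParams(dH0=-69.7, dS0=0.2, cp_shell=57.9)


@dataclass(frozen=True)
class CloudPointDatum:
    """One observation for the hydration fit: (temperature, water activity)."""

    temperature: float  # deg C
    water_activity: float  # p/p#, in (0, 1]
    salt: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.water_activity <= 1.0:
            raise ValueError("water_activity must be in (0, 1]")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


def _warn_range(t_c: float) -> None:
    import warnings

    if not _VALID_RANGE_C[0] <= t_c <= _VALID_RANGE_C[1]:
        warnings.warn(
            f"temperature {t_c} degC outside the fitted validity range "
            f"{_VALID_RANGE_C}", stacklevel=3,
        )


def mu_ice(temperature_c: float, curve: QuadraticMuCurve = ICE_CURVE) -> float:
    """Chemical potential of ice, J/mol, relative to water at the triple point."""
    _warn_range(float(np.min(temperature_c)))
    return curve(temperature_c)


def mu_water(temperature_c: float, curve: QuadraticMuCurve = WATER_CURVE) -> float:
    """Chemical potential of pure liquid water, J/mol (same reference)."""
    _warn_range(float(np.min(temperature_c)))
    return curve(temperature_c)


def mu_solution(temperature_c, water_activity: float,
                water_curve: QuadraticMuCurve = WATER_CURVE):
    """Water chemical potential in a solution: mu_water + R T ln(a_w)."""
    if np.any(np.asarray(water_activity) <= 0):
        raise ValueError("water activity must be > 0")
    t = np.asarray(temperature_c, dtype=float)
    out = water_curve(t) + GAS_CONSTANT * (t + T_ZERO_C) * np.log(water_activity)
    return float(out) if np.ndim(out) == 0 else out


def mu_hydration(temperature_c, p: HydrationShellParams):
    """Chemical potential of shell water, mu = dH(T) - T dS(T), J/mol.

    The enthalpy increment and the log ratio use absolute temperature.
    """
    t_k = np.asarray(temperature_c, dtype=float) + T_ZERO_C
    dh = p.dH0 + p.cp_shell * (t_k - p.T0)
    ds = p.dS0 + p.cp_shell * np.log(t_k / p.T0)
    out = dh - t_k * ds
    return float(out) if np.ndim(out) == 0 else out


def fit_quadratic_mu(data: list[tuple[float, float]],
                     phase: str = "") -> QuadraticMuCurve:
    """Least-squares quadratic through (T degC, mu J/mol) points."""
    if len(data) < 4:
        raise ValueError("need >= 4 (T, mu) points")
    t = np.array([x for x, _ in data], dtype=float)
    mu = np.array([y for _, y in data], dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("rank-deficient temperature grid")
    c2, c1, c0 = np.polyfit(t, mu, 2)
    return QuadraticMuCurve(float(c0), float(c1), float(c2), phase=phase)


# --- reference mu(T) tables from standard vapour-pressure correlations ----

def _p_sat_water(t_k: float) -> float:
    """Saturation vapour pressure of liquid water, Pa (Wagner-Pruss)."""
    tc, pc = 647.096, 22.064e6
    theta = 1.0 - t_k / tc
    a = (-7.85951783, 1.84408259, -11.7866497, 22.6807411, -15.9618719, 1.80122502)
    powers = (1.0, 1.5, 3.0, 3.5, 4.0, 7.5)
    s = sum(ai * theta**pi for ai, pi in zip(a, powers))
    return pc * math.exp(tc / t_k * s)


def _p_sub_ice(t_k: float) -> float:
    """Sublimation vapour pressure of ice, Pa (Murphy & Koop 2005)."""
    return math.exp(
        9.550426 - 5723.265 / t_k + 3.53068 * math.log(t_k) - 0.00728332 * t_k
    )


_DH_VAP_TRIPLE = 45051.0  # J/mol, vaporisation enthalpy of water at the triple point
_CP_VAPOUR = 33.6  # J/(mol K), water vapour


def _mu_from_vapour(t_k: float, p_pa: float) -> float:
    """mu of the condensed phase in equilibrium with vapour at p_pa.

    Referenced to the enthalpy and entropy of liquid water at the triple
    point; the vapour is treated as ideal with constant heat capacity.
    """
    tt = TRIPLE_POINT_T
    return (
        _DH_VAP_TRIPLE * (1.0 - t_k / tt)
        + _CP_VAPOUR * (t_k - tt - t_k * math.log(t_k / tt))
        + GAS_CONSTANT * t_k * math.log(p_pa / TRIPLE_POINT_P)
    )


def reference_mu_table(phase: str, t_min_c: float | None = None,
                       t_max_c: float | None = None,
                       step_c: float = 5.0) -> list[tuple[float, float]]:
    """Generate a (T degC, mu J/mol) reference table for 'water' or 'ice'.

    Built at run time from the Wagner-Pruss saturation (liquid) or
    Murphy-Koop sublimation (ice) vapour-pressure correlations through the
    ideal-vapour route, relative to liquid water at the triple point.
    These tables stand in for the published compilations the quadratic
    curves were originally fitted to.
    """
    if phase == "water":
        lo, hi, p_of_t = t_min_c if t_min_c is not None else 0.0, \
            t_max_c if t_max_c is not None else 100.0, _p_sat_water
    elif phase == "ice":
        lo, hi, p_of_t = t_min_c if t_min_c is not None else -30.0, \
            t_max_c if t_max_c is not None else 0.0, _p_sub_ice
    else:
        raise ValueError("phase must be 'water' or 'ice'")
    temps = np.arange(lo, hi + 0.5 * step_c, step_c)
    return [(float(t), _mu_from_vapour(t + T_ZERO_C, p_of_t(t + T_ZERO_C)))
            for t in temps]


# --- relative (Delta H, Delta S, Delta G) and gelation predictions --------

@dataclass(frozen=True)
class DeltaThermo:
    dH: float  # J/mol
    dS: float  # J/(mol K)
    TdS: float  # J/mol
    dG: float  # J/mol


def delta_thermo(temperature_c: float, p: HydrationShellParams) -> DeltaThermo:
    """Shell-minus-free-water Delta H, Delta S, T Delta S and Delta G.

    Uses the constant bulk-water heat capacity ``p.cp_water_ref`` so that
    Delta Cp = cp_water_ref - cp_shell is the only temperature coupling:

        dH(T) = dH0 - DeltaCp (T_K - T0)
        dS(T) = dS0 - DeltaCp ln(T_K / T0)
        dG(T) = dH(T) - T_K dS(T)
    """
    t_k = temperature_c + T_ZERO_C
    dcp = p.delta_cp
    dh = p.dH0 - dcp * (t_k - p.T0)
    ds = p.dS0 - dcp * math.log(t_k / p.T0)
    return DeltaThermo(dH=dh, dS=ds, TdS=t_k * ds, dG=dh - t_k * ds)


def _bracketed_root(fn, lo: float, hi: float, scan_step: float = 0.5,
                    xtol: float = 1e-4) -> float | None:
    """Unique root of fn on (lo, hi) via coarse sign scan + brentq.

    Returns None when no sign change exists; raises when several do.
    """
    grid = np.arange(lo, hi + 0.5 * scan_step, scan_step)
    vals = np.array([fn(t) for t in grid])
    signs = np.sign(vals)
    changes = np.nonzero(np.diff(signs) != 0)[0]
    changes = [i for i in changes if signs[i] != 0 or signs[i + 1] != 0]
    if len(changes) == 0:
        return None
    if len(changes) > 1:
        raise RuntimeError("multiple sign changes in the bracket")
    i = changes[0]
    return float(brentq(fn, grid[i], grid[i + 1], xtol=xtol))


def gelation_temperature_heating(
    p: HydrationShellParams, bracket: tuple[float, float] = (0.0, 100.0)
) -> float | None:
    """Temperature (degC) where the relative Delta G changes sign, or None."""
    return _bracketed_root(lambda t: delta_thermo(t, p).dG, *bracket)


def gelation_temperature_freezing(
    p: HydrationShellParams,
    ice: QuadraticMuCurve = ICE_CURVE,
    bracket: tuple[float, float] = (-25.0, 0.0),
) -> float | None:
    """Temperature (degC) where the shell and ice chemical potentials cross."""
    return _bracketed_root(lambda t: mu_hydration(t, p) - ice(t), *bracket)


def enthalpy_penalty_at_gelation(p: HydrationShellParams) -> float:
    """|Delta H| of shell water at the heating-gelation temperature, kJ/mol."""
    t_star = gelation_temperature_heating(p)
    if t_star is None:
        raise ValueError("no heating-gelation root for these parameters")
    return abs(delta_thermo(t_star, p).dH) / 1000.0


# --- fitting the shell model to cloud/aggregation points ------------------

@dataclass
class HydrationFitReport:
    params: HydrationShellParams
    residuals: np.ndarray  # J/mol, per point (weighted)
    cost: float
    converged: bool


def fit_hydration_model(
    data: list[CloudPointDatum],
    init: HydrationShellParams = FITTED_SHELL,
    fit_cp: bool = True,
    water_curve: QuadraticMuCurve = WATER_CURVE,
) -> HydrationFitReport:
    """Fit (dH0, dS0[, cp_shell]) to cloud/aggregation observations.

    Minimises the squared mismatch of chemical potentials at the observed
    temperatures, sum_i w_i [mu_hyd(T_i) - mu_solution(T_i, a_i)]^2
    (vertical residuals, unit weights by default). Deterministic for a
    given ``init``.
    """
    if len(data) < 4:
        raise ValueError("need >= 4 cloud-point observations")
    temps = np.array([d.temperature for d in data])
    if temps.max() - temps.min() < 15.0:
        raise ValueError("observations must span >= 15 degC")
    acts = np.array([d.water_activity for d in data])
    weights = np.sqrt(np.array([d.weight for d in data]))
    target = mu_solution(temps, acts, water_curve=water_curve)

    def unpack(x):
        cp = float(x[2]) if fit_cp else init.cp_shell
        return replace(init, dH0=float(x[0]), dS0=float(x[1]), cp_shell=cp)

    def residual(x):
        p = unpack(x)
        return weights * (mu_hydration(temps, p) - target)

    x0 = [init.dH0, init.dS0] + ([init.cp_shell] if fit_cp else [])
    lower = [-np.inf, -np.inf] + ([1e-6] if fit_cp else [])
    upper = [np.inf] * len(x0)
    sol = least_squares(residual, x0, bounds=(lower, upper))
    params = unpack(sol.x)
    return HydrationFitReport(
        params=params,
        residuals=residual(sol.x),
        cost=float(sol.cost),
        converged=bool(sol.success),
    )


# --- model-compound H-bond arithmetic -------------------------------------

def hbond_displacement_enthalpy(
    solution_enthalpy: float = -9.45,
    acceptor_to_donor: float = 1.75,
) -> float:
    """Enthalpy to displace the donor-site plus one acceptor-site water, kJ/mol.

    A secondary amide (N-methylacetamide, or a peptide group) holds three
    water H-bonds: two at the carbonyl oxygen (acceptor sites, each a
    factor ``acceptor_to_donor`` stronger than the N-H donor site, with
    the modelled range 1.6-1.9) and one at N-H. beta-sheet formation needs
    only two inter-peptide H-bonds, so it displaces the donor water and
    one acceptor water; their share of the total solution enthalpy
    ``solution_enthalpy`` (kJ/mol, negative for exothermic dissolution) is

        |dH_sol| * (1 + r) / (1 + 2 r),  r = acceptor_to_donor.
    """
    if acceptor_to_donor <= 0:
        raise ValueError("acceptor_to_donor must be > 0")
    r = acceptor_to_donor
    return abs(solution_enthalpy) * (1.0 + r) / (1.0 + 2.0 * r)
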