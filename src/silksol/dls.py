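"""Dynamic light scattering: g2 simulation and cumulant sizing.

The measured intensity autocorrelation of a dilute suspension obeys the
Siegert relation g2(tau) = 1 + beta |g1(tau)|^2 with the field correlation
g1(tau) = sum_i w_i exp(-D_i q^2 tau) for an intensity-weighted mixture of
diffusers. The second-order cumulant expansion

    ln(g2 - 1) = ln beta - 2 Gamma tau + mu2 tau^2

yields the mean decay rate Gamma, hence the Z-average hydrodynamic radius
through Stokes-Einstein R_H = k_B T / (6 pi eta D) with D = Gamma / q^2,
and the polydispersity index PDI = mu2 / Gamma^2.

Defaults mirror a backscattering instrument: 173 deg, 633 nm, n = 1.33.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import BOLTZMANN, T_ZERO_C
from .scattering import size_jump_onset

__all__ = [
    "Autocorrelation",
    "SizeResult",
    "water_viscosity",
    "dls_q",
    "simulate_g2",
    "cumulant_fit",
    "rh_onset",
]

# Dynamic viscosity of water, mPa s, at 5 degC intervals (standard
# handbook correlation values anchored at 1.002 mPa s / 20 degC);
# linearly interpolated between nodes.
_VISCOSITY_T = np.arange(0.0, 101.0, 5.0)
_VISCOSITY_MPAS = np.array([
    1.792, 1.519, 1.307, 1.138, 1.002, 0.890, 0.798, 0.719, 0.653,
    0.596, 0.547, 0.504, 0.467, 0.433, 0.404, 0.378, 0.354, 0.333,
    0.315, 0.298, 0.282,
])


def water_viscosity(temperature: float) -> float:
    """Viscosity of water at ``temperature`` (deg C), in mPa s."""
    if not _VISCOSITY_T[0] <= temperature <= _VISCOSITY_T[-1]:
        raise ValueError("water viscosity table covers 0-100 degC")
    return float(np.interp(temperature, _VISCOSITY_T, _VISCOSITY_MPAS))


@dataclass
class Autocorrelation:
    """An intensity autocorrelation record with its instrument geometry."""

    lag: np.ndarray  # s, strictly increasing, > 0
    g2: np.ndarray
    angle: float = 173.0  # degrees
    wavelength: float = 633.0  # nm
    temperature: float = 25.0  # deg C
    refractive_index: float = 1.33
    viscosity: float | None = None  # mPa s; from temperature when absent

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.lag.shape != self.g2.shape or self.lag.ndim != 1:
            raise ValueError("lag and g2 must be 1-D arrays of equal length")
        if np.any(self.lag <= 0) or np.any(np.diff(self.lag) <= 0):
            raise ValueError("lag times must be positive and strictly increasing")
        if not 0 < self.angle < 180:
            raise ValueError("angle must be in (0, 180)")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")

    @property
    def eta(self) -> float:
        """Viscosity in mPa s (explicit value or water at the record temperature)."""
        if self.viscosity is not None:
            return self.viscosity
        return water_viscosity(self.temperature)

    @property
    def q(self) -> float:
        """Scattering vector, nm^-1."""
        return dls_q(self.angle, self.wavelength, self.refractive_index)


@dataclass
class SizeResult:
    z_average_rh: float  # nm
    pdi: float
    decay_rate: float  # s^-1
    intercept_beta: float


def dls_q(angle: float, wavelength: float, refractive_index: float) -> float:
    """In-medium scattering vector q = 4 pi n sin(angle/2) / lambda, nm^-1."""
    return (
        4.0 * math.pi * refractive_index
        * math.sin(math.radians(angle) / 2.0) / wavelength
    )


def _decay_rate(rh_nm: float, record: Autocorrelation) -> float:
    """Gamma = D q^2 for a sphere of hydrodynamic radius rh_nm, s^-1."""
    t_kelvin = record.temperature + T_ZERO_C
    eta_pas = record.eta * 1e-3
    diffusion = BOLTZMANN * t_kelvin / (6.0 * math.pi * eta_pas * rh_nm * 1e-9)  # m^2/s
    q_m = record.q * 1e9  # nm^-1 -> m^-1
    return diffusion * q_m**2


def simulate_g2(
    sizes: list[tuple[float, float]],
    instrument: Autocorrelation,
    beta: float = 0.9,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Autocorrelation:
    """Forward-simulate g2 for a mixture of (rh_nm, intensity_weight) modes.

    Weights must be nonnegative and sum to 1. Additive Gaussian noise of
    standard deviation ``noise_sd`` is applied with the given seed.
    """
    weights = np.array([w for _, w in sizes], dtype=float)
    radii = np.array([r for r, _ in sizes], dtype=float)
    if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("weights must be >= 0 and sum to 1")
    if np.any(radii <= 0):
        raise ValueError("hydrodynamic radii must be > 0")
    gammas = np.array([_decay_rate(r, instrument) for r in radii])
    g1 = (weights[None, :] * np.exp(-np.outer(instrument.lag, gammas))).sum(axis=1)
    g2 = 1.0 + beta * g1**2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g2 = g2 + rng.normal(0.0, noise_sd, size=g2.shape)
    return Autocorrelation(
        lag=instrument.lag.copy(),
        g2=g2,
        angle=instrument.angle,
        wavelength=instrument.wavelength,
        temperature=instrument.temperature,
        refractive_index=instrument.refractive_index,
        viscosity=instrument.viscosity,
    )


def cumulant_fit(acorr: Autocorrelation, tail_fraction: float = 0.1) -> SizeResult:
    """Second-order cumulant analysis of one autocorrelation record.

    The fit window keeps lags where g2 - 1 exceeds ``tail_fraction`` of the
    estimated intercept (common practice; the deep tail is noise-dominated).
    Raises if g2 - 1 is nonpositive anywhere in that window.
    """
    y = acorr.g2 - 1.0
    beta_est = float(np.mean(y[: max(3, y.size // 50)]))
    if beta_est <= 0:
        raise ValueError("no decaying signal: g2 - 1 nonpositive at short lags")
    mask = y > tail_fraction * beta_est
    # keep the contiguous head of the record only
    if not mask[0]:
        raise ValueError("g2 - 1 nonpositive at the first lag")
    head = int(np.argmin(mask)) if not mask.all() else y.size
    tau = acorr.lag[:head]
    yh = y[:head]
    if tau.size < 4:
        raise ValueError("too few points above the cumulant fit threshold")
    if np.any(yh <= 0):
        raise ValueError("g2 - 1 nonpositive inside the fit window")
    c2, c1, c0 = np.polyfit(tau, np.log(yh), 2)
    gamma = -c1 / 2.0
    if gamma <= 0:
        raise ValueError("non-decaying record: fitted decay rate <= 0")
    mu2 = c2
    pdi = max(float(mu2 / gamma**2), 0.0)
    beta = math.exp(c0)
    # invert Stokes-Einstein at the record's temperature/viscosity
    t_kelvin = acorr.temperature + T_ZERO_C
    eta_pas = acorr.eta * 1e-3
    q_m = acorr.q * 1e9
    diffusion = gamma / q_m**2
    rh_nm = BOLTZMANN * t_kelvin / (6.0 * math.pi * eta_pas * diffusion) * 1e9
    return SizeResult(
        z_average_rh=float(rh_nm),
        pdi=pdi,
        decay_rate=float(gamma),
        intercept_beta=float(beta),
    )


def rh_onset(
    series: list[tuple[float, SizeResult]],
    jump_factor: float = 1.5,
    min_baseline: int = 3,
) -> float | None:
    """Aggregation onset over a temperature series of Z-average radii.

    Same rule as :func:`silksol.scattering.aggregation_onset`: first
    temperature where R_H exceeds the prior median by 50 %.
    """
    return size_jump_onset(
        [(t, res.z_average_rh, True) for t, res in series],
        jump_factor=jump_factor,
        min_baseline=min_baseline,
    )
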