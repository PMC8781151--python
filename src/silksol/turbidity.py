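"""Turbidity forward model and cloud-point detection.

For small scatterers the turbidity of a dilute solution follows

    tau(lambda) = Q(lambda) * (32 pi^3 / 3) * n0^2 * c * M * (dn/dc)^2
                  / (N_A * lambda^4)

so an increase in turbidity at constant composition signals growth in the
scatterer mass M, i.e. protein aggregation. The cloud point of a
turbidity-versus-temperature trace is detected as the first persistent
excursion above the initial baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO

__all__ = [
    "TurbidityModelParams",
    "TurbidityTrace",
    "turbidity_forward",
    "turbidity_from_transmittance",
    "detect_cloud_point",
]


@dataclass(frozen=True)
class TurbidityModelParams:
    """Inputs to the Rayleigh-Debye turbidity expression.

    Q is the transmittance dissipation factor, within (0, 1]; it is close
    to 1 for scatterers small relative to the wavelength (the case for
    ~12 nm protein coils in visible light), hence the default.
    """

    n0: float  # solvent refractive index
    dn_dc: float  # refractive-index increment, cm^3 g^-1
    c: float  # protein concentration, g cm^-3
    M: float  # scatterer molar mass, g mol^-1
    wavelength: float  # nm
    Q: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.Q <= 1:
            raise ValueError("Q must be in (0, 1]")
        for name in ("n0", "dn_dc", "M", "wavelength"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.c < 0:
            raise ValueError("c must be >= 0")


@dataclass
class TurbidityTrace:
    """Turbidity vs temperature for one salt/protein composition."""

    temperature: np.ndarray  # deg C, increasing
    turbidity: np.ndarray  # cm^-1 or a.u.
    wavelength: float = 600.0  # nm
    salt: str = ""
    salt_concentration: float = 0.0  # mol kg^-1 (or % w/w, caller's choice)
    protein_mass_fraction: float = 0.001

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.turbidity = np.asarray(self.turbidity, dtype=float)
        if self.temperature.shape != self.turbidity.shape or self.temperature.ndim != 1:
            raise ValueError("temperature and turbidity must be 1-D, equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")


def turbidity_forward(params: TurbidityModelParams) -> float:
    """Evaluate the turbidity expression; result in cm^-1.

    The wavelength is converted from nm to cm so all lengths are in cm.
    """
    lam_cm = params.wavelength * 1e-7
    return (
        params.Q
        * (32.0 * math.pi**3 / 3.0)
        * params.n0**2
        * params.c
        * params.M
        * params.dn_dc**2
        / (AVOGADRO * lam_cm**4)
    )


def turbidity_from_transmittance(
    transmittance: np.ndarray,
    reference_transmittance: float = 1.0,
    path_length_cm: float = 1.0,
) -> np.ndarray:
    """Convert raw transmittance to turbidity, -ln(T/T0) / pathlength (cm^-1)."""
    t = np.asarray(transmittance, dtype=float)
    if np.any(t <= 0) or reference_transmittance <= 0 or path_length_cm <= 0:
        raise ValueError("transmittances and path length must be positive")
    return -np.log(t / reference_transmittance) / path_length_cm


def detect_cloud_point(
    trace: TurbidityTrace,
    baseline_fraction: float = 0.25,
    k_sigma: float = 5.0,
    persistence: int = 3,
) -> float | None:
    """Cloud point: first persistent rise above the initial baseline.

    The baseline mean and SD are taken from the first ``baseline_fraction``
    of points; the cloud point is the first temperature at which turbidity
    exceeds mean + ``k_sigma`` * SD for ``persistence`` consecutive points.
    Returns None when never triggered. The rule is invariant to affine
    rescaling of the turbidity axis. A trace rising within the baseline
    window itself (baseline contaminated by signal) is rejected.
    """
    tau = trace.turbidity
    if tau.size < 8:
        raise ValueError("need >= 8 points to detect a cloud point")
    n_base = max(int(round(baseline_fraction * tau.size)), 3)
    base = tau[:n_base]
    t_base = trace.temperature[:n_base]
    # a baseline that trends upward from the very first points is signal,
    # not background: reject rather than report a meaningless onset
    slope, intercept = np.polyfit(t_base, base, 1)
    resid_sd = float(np.std(base - (slope * t_base + intercept)))
    drift = abs(slope) * (t_base[-1] - t_base[0])
    if drift > 3.0 * max(resid_sd, 1e-30):
        raise ValueError("trace rises from the very first points: no baseline")
    threshold = float(np.mean(base)) + k_sigma * float(np.std(base, ddof=1))
    above = tau > threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= persistence:
            start = i - persistence + 1
            if start < n_base // 2:
                raise ValueError("turbidity rise overlaps the baseline window")
            return float(trace.temperature[start])
    return None
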