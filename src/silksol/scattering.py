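"""Debye/Guinier modelling of small-angle scattering curves.

The scattered intensity of a Gaussian chain (3-D random walk) is described
by the Debye function

    I(q) = 2 I0 (exp(-x) + x - 1) / x^2,   x = q^2 R_G^2,

which reduces to the Guinier law I0 exp(-q^2 R_G^2 / 3) at small q and to a
q^-2 power law at q R_G >> 1. Fitting it to a (q, I) curve yields the coil
radius of gyration. A temperature series of such fits is scanned for the
onset of aggregation: the point where the fit fails or R_G jumps well above
its prior level.

Units: q in nm^-1 throughout (readers can convert from Å^-1), R_G in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "ScatteringCurve",
    "DebyeFitResult",
    "q_from_angle",
    "debye_intensity",
    "guinier_fit",
    "fit_debye",
    "power_law_exponent",
    "background_subtract",
    "size_jump_onset",
    "aggregation_onset",
]


@dataclass
class ScatteringCurve:
    """One reduced scattering curve: q (nm^-1), intensity, optional sigma."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    temperature: float | None = None  # deg C
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")

    def window(self, q_min: float | None = None, q_max: float | None = None) -> "ScatteringCurve":
        """Restrict to q_min <= q <= q_max."""
        mask = np.ones_like(self.q, dtype=bool)
        if q_min is not None:
            mask &= self.q >= q_min
        if q_max is not None:
            mask &= self.q <= q_max
        if not mask.any():
            raise ValueError("empty q window")
        return ScatteringCurve(
            self.q[mask],
            self.intensity[mask],
            None if self.sigma is None else self.sigma[mask],
            self.temperature,
            self.label,
        )


@dataclass
class DebyeFitResult:
    """Outcome of a Debye-model fit."""

    I0: float
    rg: float  # nm
    residual_norm: float
    parameter_uncertainties: tuple[float, float] = (math.nan, math.nan)
    converged: bool = True
    q_window: tuple[float, float] = field(default=(math.nan, math.nan))


def q_from_angle(two_theta: float, wavelength: float) -> float:
    """Scattering vector q = 4 pi sin(theta) / lambda, nm^-1.

    ``two_theta`` is the full scattering angle in degrees, ``wavelength``
    in nm.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    if not 0 <= two_theta < 180:
        raise ValueError("two_theta must be in [0, 180)")
    return 4.0 * math.pi * math.sin(math.radians(two_theta) / 2.0) / wavelength


def debye_intensity(q, I0: float, rg: float):
    """Debye form factor intensity; scalar or array q (nm^-1).

    The q -> 0 limit I(0) = I0 is taken via the series expansion for small
    x = q^2 rg^2 to avoid cancellation.
    """
    if rg <= 0:
        raise ValueError("rg must be > 0")
    q = np.asarray(q, dtype=float)
    x = q**2 * rg**2
    out = np.empty_like(x)
    small = x < 1e-4
    xs = x[small]
    # 2 (e^-x + x - 1)/x^2 = 1 - x/3 + x^2/12 - x^3/60 + ...
    out[small] = 1.0 - xs / 3.0 + xs**2 / 12.0 - xs**3 / 60.0
    xl = x[~small]
    out[~small] = 2.0 * (np.exp(-xl) + xl - 1.0) / xl**2
    result = I0 * out
    return float(result) if result.ndim == 0 else result


def guinier_fit(curve: ScatteringCurve, q_rg_max: float = 1.3) -> tuple[float, float]:
    """Guinier analysis: straight-line fit of ln I vs q^2.

    The admissible window q * rg <= ``q_rg_max`` is found iteratively:
    an initial fit on q <= q_max / 3 gives a first rg estimate, and the
    window is re-restricted with the running estimate until it
    stabilises. Returns (I0, rg).
    """

    def _line_fit(sub: ScatteringCurve) -> tuple[float, float]:
        if sub.q.size < 4:
            raise ValueError("need >= 4 points in the Guinier window")
        if np.any(sub.intensity <= 0):
            raise ValueError("nonpositive intensities in Guinier window")
        # quadratic in q^2: the linear coefficient is -rg^2/3 at q -> 0,
        # which removes most of the window bias a straight line suffers
        # on coil (Debye) curves; exact when ln I is truly linear in q^2
        x = sub.q**2
        c2, slope, intercept = np.polyfit(x, np.log(sub.intensity), 2)
        if slope >= 0:
            raise ValueError("no Guinier regime (nonnegative slope of ln I vs q^2)")
        return math.exp(intercept), math.sqrt(-3.0 * slope)

    sub = curve.window(q_max=curve.q[-1] / 3.0)
    if sub.q.size < 4:
        sub = curve
    I0, rg = _line_fit(sub)
    prev_lim = None
    for _ in range(15):
        q_lim = q_rg_max / rg
        if prev_lim is not None and abs(q_lim - prev_lim) < 1e-3 * prev_lim:
            break
        prev_lim = q_lim
        try:
            sub = curve.window(q_max=q_lim)
        except ValueError:
            break
        if sub.q.size < 4:
            break
        I0, rg = _line_fit(sub)
    return I0, rg


def fit_debye(
    curve: ScatteringCurve,
    q_window: tuple[float, float] | None = None,
) -> DebyeFitResult:
    """Weighted nonlinear least-squares fit of the Debye model.

    Weights are 1/sigma^2 when uncertainties are present, otherwise
    uniform; the fit is in intensity space (not log space). The initial
    guess comes from Guinier analysis, falling back to rg = 2 pi / q_max.
    Non-convergence is flagged on the result rather than raised.
    """
    sub = curve if q_window is None else curve.window(*q_window)
    if sub.q.size < 6:
        raise ValueError("need >= 6 points for a Debye fit")

    try:
        I0_init, rg_init = guinier_fit(sub)
    except ValueError:
        rg_init = 2.0 * math.pi / sub.q[-1]
        I0_init = float(np.max(sub.intensity))

    model = lmfit.Model(lambda q, I0, rg: debye_intensity(q, I0, rg))
    params = model.make_params(I0=dict(value=I0_init, min=0.0),
                               rg=dict(value=rg_init, min=1e-3))
    weights = None if sub.sigma is None else 1.0 / sub.sigma
    fit = model.fit(sub.intensity, params, q=sub.q, weights=weights)

    i0 = float(fit.params["I0"].value)
    rg = float(fit.params["rg"].value)
    stderr = (
        float(fit.params["I0"].stderr or math.nan),
        float(fit.params["rg"].stderr or math.nan),
    )
    scale = float(np.linalg.norm(sub.intensity))
    residual_norm = float(np.linalg.norm(sub.intensity - fit.best_fit)) / (scale or 1.0)
    converged = bool(fit.success) and rg > 0 and np.isfinite(rg)
    return DebyeFitResult(
        I0=i0,
        rg=rg,
        residual_norm=residual_norm,
        parameter_uncertainties=stderr,
        converged=converged,
        q_window=(float(sub.q[0]), float(sub.q[-1])),
    )


def power_law_exponent(curve: ScatteringCurve, q_window: tuple[float, float]) -> float:
    """Slope of log I vs log q in the given window (e.g. -2 for a Gaussian chain)."""
    sub = curve.window(*q_window)
    if sub.q.size < 4:
        raise ValueError("need >= 4 points in the power-law window")
    if np.any(sub.intensity <= 0):
        raise ValueError("nonpositive intensities in power-law window")
    slope, _ = np.polyfit(np.log(sub.q), np.log(sub.intensity), 1)
    return float(slope)


def background_subtract(
    sample: ScatteringCurve,
    background: ScatteringCurve,
    scale: float = 1.0,
) -> ScatteringCurve:
    """Subtract ``scale`` x background from sample on the sample's q grid.

    The background is linearly interpolated onto the sample grid; the q
    ranges must overlap the full sample grid. Uncertainties combine in
    quadrature when both curves carry them.
    """
    if background.q[0] > sample.q[0] or background.q[-1] < sample.q[-1]:
        if background.q[0] > sample.q[-1] or background.q[-1] < sample.q[0]:
            raise ValueError("disjoint q ranges")
        raise ValueError("background q range must cover the sample q range")
    bg = np.interp(sample.q, background.q, background.intensity)
    intensity = sample.intensity - scale * bg
    sigma = None
    if sample.sigma is not None and background.sigma is not None:
        bg_sig = np.interp(sample.q, background.q, background.sigma)
        sigma = np.sqrt(sample.sigma**2 + (scale * bg_sig) ** 2)
    elif sample.sigma is not None:
        sigma = sample.sigma.copy()
    return ScatteringCurve(sample.q.copy(), intensity, sigma,
                           sample.temperature, sample.label)


def size_jump_onset(
    series: list[tuple[float, float, bool]],
    jump_factor: float = 1.5,
    min_baseline: int = 3,
) -> float | None:
    """Generic onset rule over a (temperature, size, ok) series.

    Returns the first temperature where ``ok`` is False or the size exceeds
    ``jump_factor`` times the median of all prior sizes; None if never
    triggered. At least ``min_baseline`` points must precede the candidate
    onset; an earlier trigger is rejected as having no baseline.
    """
    if len(series) < 4:
        raise ValueError("need >= 4 (temperature, size) points")
    temps = [t for t, _, _ in series]
    if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
        raise ValueError("series must be sorted by increasing temperature")
    prior: list[float] = []
    for i, (temp, value, ok) in enumerate(series):
        triggered = (not ok) or (
            len(prior) > 0 and value >= jump_factor * float(np.median(prior))
        )
        if triggered:
            if i < min_baseline:
                raise ValueError(
                    f"onset trigger at index {i} with fewer than {min_baseline} baseline points"
                )
            return temp
        prior.append(value)
    return None


def aggregation_onset(
    series: list[tuple[float, DebyeFitResult]],
    jump_factor: float = 1.5,
    min_baseline: int = 3,
) -> float | None:
    """First temperature where single-chain Debye fitting breaks down.

    The trigger is either a failed fit (``converged`` False) or a fitted
    R_G exceeding the median of all prior R_G values by at least 50 %
    (``jump_factor`` 1.5). At least ``min_baseline`` points must precede
    the candidate onset; a trigger earlier than that is rejected.
    """
    return size_jump_onset(
        [(t, res.rg, res.converged) for t, res in series],
        jump_factor=jump_factor,
        min_baseline=min_baseline,
    )
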