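"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates one experimental stream under the study
conditions: Debye-shaped scattering of a ~12.5 nm coil that grows a
large-aggregate component above an onset temperature; mono- or bimodal
DLS decays (12.5 nm chains, 90 nm aggregates); amide I/II spectra whose
amide II centre drifts from ~1545 to ~1540 cm^-1 between 27 and 81 degC;
sigmoidal turbidity onsets; and cloud points produced by the
hydration-shell model itself against a salt water-activity table.

Noise models: multiplicative Gaussian for scattering (counting-like),
additive Gaussian for spectra, g2 traces and turbidity; default SDs give
a signal-to-noise ratio of roughly 20. All generators are deterministic
for a fixed config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dls import Autocorrelation, simulate_g2
from .scattering import ScatteringCurve, debye_intensity
from .spectroscopy import PeakModel, Spectrum, evaluate_peak_model
from .thermo import (
    FITTED_SHELL,
    NACL_TABLE,
    CloudPointDatum,
    HydrationShellParams,
    SaltActivityTable,
    _bracketed_root,
    mu_hydration,
    mu_solution,
)
from .turbidity import TurbidityTrace

__all__ = [
    "GeneratorConfig",
    "gen_scattering_series",
    "gen_dls_series",
    "gen_ir_series",
    "gen_turbidity_trace",
    "gen_cloud_points",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truths, grids and noise levels for the synthetic streams."""

    seed: int = 0

    # scattering
    rg_chain: float = 12.5  # nm
    rg_aggregate: float = 90.0  # nm
    saxs_onset_c: float = 65.0  # aggregate component appears above this
    q_grid: tuple[float, float, int] = (0.03, 2.0, 120)  # nm^-1: lo, hi, n
    saxs_noise: float = 0.05  # multiplicative SD
    saxs_temperatures: tuple[float, ...] = tuple(float(t) for t in range(25, 81, 5))

    # DLS
    rh_chain: float = 12.5  # nm
    rh_aggregate: float = 90.0  # nm
    dls_onset_c: float = 65.0
    aggregate_weight: float = 0.5  # intensity weight above onset
    lag_grid: tuple[float, float, int] = (1e-7, 1e-2, 160)  # s, log-spaced
    dls_noise: float = 0.002
    dls_beta: float = 0.9
    dls_temperatures: tuple[float, ...] = tuple(float(t) for t in range(25, 81, 5))

    # IR
    amide_ii_start: float = 1545.0  # cm^-1 at ir_t_start
    amide_ii_end: float = 1540.0  # cm^-1 at ir_t_end
    ir_t_start: float = 27.0
    ir_t_end: float = 81.0
    amide_i_center: float = 1640.0
    ir_noise: float = 0.002
    ir_grid: tuple[float, float, float] = (1400.0, 1800.0, 2.0)  # cm^-1: lo, hi, step
    ir_temperatures: tuple[float, ...] = tuple(float(t) for t in range(27, 82, 6))

    # turbidity
    turbidity_onset_c: float = 40.0
    turbidity_steepness: float = 1.0  # degC^-1 logistic rate
    turbidity_amplitude: float = 1.0
    turbidity_baseline: float = 0.02
    turbidity_noise: float = 0.005
    turbidity_grid: tuple[float, float, float] = (20.0, 60.0, 0.5)


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def gen_scattering_series(cfg: GeneratorConfig) -> list[tuple[float, ScatteringCurve]]:
    """Debye curves over temperature with a growing aggregate component.

    Below the onset the curve is a single-chain Debye form with
    multiplicative Gaussian noise; above it a large-particle Debye
    component is added with weight growing with the excess temperature.
    """
    rng = _rng(cfg, 1)
    lo, hi, n = cfg.q_grid
    q = np.linspace(lo, hi, n)
    series = []
    for temp in cfg.saxs_temperatures:
        intensity = debye_intensity(q, 1.0, cfg.rg_chain)
        if temp > cfg.saxs_onset_c:
            # aggregates outscatter chains as M^2: let their weight grow
            # tenfold per 2.5 degC so low-q intensity rises sharply, as
            # seen when fits rapidly stop being possible above the onset
            w = 10.0 ** ((temp - cfg.saxs_onset_c) / 2.5)
            intensity = intensity + w * debye_intensity(q, 1.0, cfg.rg_aggregate)
        noisy = intensity * (1.0 + rng.normal(0.0, cfg.saxs_noise, size=q.shape))
        sigma = np.maximum(cfg.saxs_noise * intensity, 1e-12)
        series.append(
            (temp, ScatteringCurve(q, noisy, sigma, temperature=temp,
                                   label=f"synthetic {temp:.0f}C"))
        )
    return series


def gen_dls_series(cfg: GeneratorConfig) -> list[tuple[float, Autocorrelation]]:
    """g2 records: monomodal chains below the onset, bimodal above."""
    lo, hi, n = cfg.lag_grid
    lag = np.geomspace(lo, hi, n)
    series = []
    for i, temp in enumerate(cfg.dls_temperatures):
        header = Autocorrelation(lag=lag, g2=np.ones_like(lag), temperature=temp)
        if temp > cfg.dls_onset_c:
            w = cfg.aggregate_weight
            sizes = [(cfg.rh_chain, 1.0 - w), (cfg.rh_aggregate, w)]
        else:
            sizes = [(cfg.rh_chain, 1.0)]
        seed = int(np.random.SeedSequence([cfg.seed, 2, i]).generate_state(1)[0] % (2**31))
        series.append(
            (temp, simulate_g2(sizes, header, beta=cfg.dls_beta,
                               noise_sd=cfg.dls_noise, seed=seed))
        )
    return series


def _amide_model(cfg: GeneratorConfig, amide_ii_center: float) -> PeakModel:
    return PeakModel(
        baseline_intercept=0.05,
        baseline_slope=0.0,
        components=[
            (0.30, amide_ii_center, 18.0),
            (0.45, cfg.amide_i_center, 16.0),
        ],
    )


def gen_ir_series(cfg: GeneratorConfig) -> list[Spectrum]:
    """Two-Gaussian amide spectra with a linear amide II drift in T."""
    rng = _rng(cfg, 3)
    lo, hi, step = cfg.ir_grid
    nu = np.arange(lo, hi + 0.5 * step, step)
    span = cfg.ir_t_end - cfg.ir_t_start
    spectra = []
    for temp in cfg.ir_temperatures:
        frac = 0.0 if span == 0 else (temp - cfg.ir_t_start) / span
        center = cfg.amide_ii_start + frac * (cfg.amide_ii_end - cfg.amide_ii_start)
        clean = evaluate_peak_model(_amide_model(cfg, center), nu)
        noisy = clean.absorbance + rng.normal(0.0, cfg.ir_noise, size=nu.shape)
        spectra.append(Spectrum(nu, noisy, temperature=temp,
                                label=f"synthetic {temp:.0f}C"))
    return spectra


def gen_turbidity_trace(cfg: GeneratorConfig) -> TurbidityTrace:
    """Flat baseline plus a logistic turbidity rise at the configured onset."""
    rng = _rng(cfg, 4)
    lo, hi, step = cfg.turbidity_grid
    temp = np.arange(lo, hi + 0.5 * step, step)
    rise = cfg.turbidity_amplitude / (
        1.0 + np.exp(-cfg.turbidity_steepness * (temp - cfg.turbidity_onset_c))
    )
    # the logistic is centred on the onset; zero it below so the baseline is flat
    rise = np.where(temp < cfg.turbidity_onset_c, 0.0, rise - cfg.turbidity_amplitude / 2.0)
    tau = cfg.turbidity_baseline + rise + rng.normal(0.0, cfg.turbidity_noise, temp.shape)
    return TurbidityTrace(temperature=temp, turbidity=tau, salt="NaCl")


def gen_cloud_points(
    truth: HydrationShellParams = FITTED_SHELL,
    table: SaltActivityTable = NACL_TABLE,
    concentrations: tuple[float, ...] | None = None,
    temp_noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[list[CloudPointDatum], list[float]]:
    """Cloud points generated from a ground-truth hydration-shell model.

    For each salt concentration (mol/kg; defaults to an even spread over
    the table) the crossing mu_hyd(T) = mu_solution(T, a_w) is solved on
    (-10, 100) degC and Gaussian temperature noise added. Returns the
    observations plus the list of concentrations that produced no
    crossing (reported, never silently dropped).
    """
    from .salt_activity import activity_from_salt

    if concentrations is None:
        # 0-2 mol/kg spans cloud points from ~70 degC down to a few degC,
        # the range accessible to a turbidity experiment; 20 observations
        # mirror a realistic campaign over two salts
        hi = min(2.0, float(table.molality[-1]))
        concentrations = tuple(np.linspace(0.0, hi, 20))
    rng = np.random.default_rng(seed)
    out: list[CloudPointDatum] = []
    missing: list[float] = []
    for conc in concentrations:
        a = activity_from_salt(table.salt, conc, table=table)
        root = _bracketed_root(
            lambda t: mu_hydration(t, truth) - mu_solution(t, a), -10.0, 100.0
        )
        if root is None:
            missing.append(float(conc))
            continue
        temp = root + (rng.normal(0.0, temp_noise_sd) if temp_noise_sd > 0 else 0.0)
        out.append(CloudPointDatum(temperature=float(temp), water_activity=float(a),
                                   salt=table.salt))
    return out, missing
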