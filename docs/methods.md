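# Methods

This note documents the models implemented in `silksol`, their
assumptions, the numerical choices behind the fits, and what the
synthetic-data generators do and do not emulate.

## Chain geometry

The fibroin chain is reduced to a residue count N, a virtual bond length
b and masses; no sequence information is used. `rg_random_coil` is the
freely jointed chain under theta conditions, `R_G = b sqrt(N/6)`. The
defaults (N = 5525, b = 0.4 nm, 75.9 g/mol per residue, 419.6 kDa per
chain) describe the conjoined heavy + light *B. mori* fibroin.

`coil_mass_density` needs a convention for turning an R_G into a volume;
we use the uniform sphere with the same radius of gyration, i.e. sphere
radius `R = sqrt(5/3) R_G`. This is the standard equal-R_G sphere and
reproduces the familiar ~0.045 g/cm³ figure for a 419.6 kDa chain at
R_G = 12 nm to within 0.5 %. Other conventions (e.g. the pervaded-volume
sphere of radius R_G) differ by a constant factor; the choice is
documented here because the literature value does not state one.

Water:peptide ratios at concentrations given in g/cm³ assume a total
solution density of 1.0 g/cm³ (overridable); Avogadro's number and the
18.015 g/mol water molar mass are package constants.

## Scattering

Intensities are modelled by the Debye function of a Gaussian chain; the
q → 0 limit is evaluated by series expansion below x = 10⁻⁴ to avoid
cancellation. q is in nm⁻¹ throughout; the reader converts Å⁻¹ on
request (×10).

Guinier analysis fits ln I against q², iteratively restricting the
window to q·R_G ≤ 1.3 with the running estimate until the window
stabilises. Within that window we fit a *quadratic* in q² and take R_G
from the linear coefficient: for data that are truly linear in q² this
is exact, while on coil (Debye) curves it removes the systematic few-
percent underestimate a straight line suffers over a finite window. A
nonnegative slope is reported as "no Guinier regime".

The Debye fit is weighted least squares in intensity space (weights 1/σ²
when uncertainties are present, uniform otherwise; no log transform),
initialised from the Guinier result with fallback `R_G = 2π/q_max`.
Non-convergence is flagged on the result, not raised.

The aggregation-onset rule over a temperature series is: first
temperature at which the fit fails or the fitted size exceeds 1.5× the
median of all prior sizes, requiring at least three baseline points. The
factor and the median baseline are package choices — the experimental
observation being emulated is only that single-chain fits "stop being
possible" above an onset. The same rule serves the DLS R_H series.

## Dynamic light scattering

Records carry their instrument geometry (defaults: 173°, 633 nm,
n = 1.33 — a standard backscattering protein-sizing configuration).
Water viscosity vs temperature is a 5 °C-spaced handbook table (1.002
mPa·s at 20 °C) with linear interpolation, overridable per record.

`cumulant_fit` is the second-order cumulant expansion
`ln(g2−1) = ln β − 2Γτ + μ₂τ²`, fitted on the contiguous head of the
record where g2−1 exceeds 10 % of the estimated intercept (the deep tail
is noise-dominated). R_H follows from Γ via Stokes–Einstein at the
record's temperature and viscosity; PDI = μ₂/Γ². Inverse-Laplace
(CONTIN-style) size distributions are out of scope; bimodal samples are
characterised only by their Z-average and PDI.

## IR spectroscopy

The band model is a linear baseline plus Gaussians,
`S(ν) = a + mν + Σ A_i exp(−((ν−ν_i)/(2Δ_i))²)`. Note the width
convention: 2Δ sits inside the square, so Δ relates to the usual
Gaussian σ by σ = √2·Δ. The convention is kept end to end (fits,
synthetic generators, tests) so no silent re-parameterisation occurs;
anyone comparing Δ values to FWHM-based software should convert.

The default window is 1450–1750 cm⁻¹ with two components — one near
1640 cm⁻¹ (amide I overlapped by the water bending band) and the amide
II near 1545 cm⁻¹; two components are the most that remain reliable in
this window. Fits restart five times from centres jittered ±5 cm⁻¹
(seeded); the best residual wins and the restart-to-restart centre
spread is reported — ≤ 0.1 cm⁻¹ on well-conditioned data, matching the
reproducibility quoted for this kind of analysis. Temperature series are
warm-started from the previous solution, and per-spectrum failures
become gaps rather than aborting the series.

Grid alignment for spectral subtraction is linear interpolation on the
overlap; no smoothing or ATR penetration-depth correction is applied.

## Turbidity

The forward model is the Rayleigh–Debye turbidity expression
`τ = Q (32π³/3) n0² c M (dn/dc)² / (N_A λ⁴)` with λ converted to cm; the
transmittance dissipation factor Q defaults to 1.0, valid for scatterers
(~12 nm) far below the wavelength of visible light. Raw transmittance
converts to turbidity as −ln(T/T₀)/path with a 10 mm default path.

Cloud-point detection: baseline mean and SD from the first quartile of
points, onset at the first temperature exceeding mean + 5σ for three
consecutive points. The 5σ/3-point/first-quartile rule is a package
choice implementing the verbal criterion "the temperature above which
turbidity rises from the initial background". The rule is invariant to
affine rescaling of the turbidity axis. A baseline whose linear trend
over the window exceeds three residual SDs is rejected as contaminated
(no flat background to measure against).

## Hydration-shell thermodynamics

Chemical potentials are expressed relative to liquid water at the triple
point (273.16 K, 611.657 Pa), in J/mol, with the quadratic curves for
ice and water taking temperature in °C as printed:
`mu_ice = 10.286 + 22.186 T − 0.0717 T²`,
`mu_water = 8.038 − 0.7842 T − 0.1167 T²`, valid over roughly −30 to
100 °C (a warning is issued outside). Salt solutions add `R T_K ln a_w`
with a_w interpolated from packaged osmotic-coefficient tables (NaCl to
6 mol/kg, KCl to 4.5 mol/kg, compiled from the Hamer & Wu 1972
compilation at 25 °C; extrapolation is refused).

The shell model `mu_hyd(T) = [dH0 + Cp(T_K−T0)] − T_K[dS0 + Cp ln(T_K/T0)]`
uses absolute temperature inside the enthalpy increment and the log
ratio — a Celsius log ratio would be undefined at 0 °C, and enthalpy
differences are unit-invariant. T0 = 273.15 K. Shell Cp is constant by
assumption; bulk-water Cp actually varies by <1 % over 0–62 °C, which
bounds the error of that simplification.

Relative quantities (Fig.-style ΔH, ΔS, ΔG against free water) use a
constant bulk-water Cp of 75.7 J/(mol K), so ΔCp = 75.7 − Cp_shell is
the only temperature coupling. Using the water quadratic itself as the
baseline instead moves the ΔG = 0 crossing from 67.6 to ≈70 °C; the
constant-Cp convention is adopted because it reproduces the published
crossing (≈68 °C) and enthalpy penalty (1.27 kJ/mol) and keeps ΔCp the
single interpretable driver. With the printed rounded parameters the
shell stability at 0 °C evaluates to 124.3 J/mol; quoting it as "up to
~128" requires unrounded fit parameters, which we do not force.

Root-finding for the gelation temperatures is a 0.5 °C sign scan
followed by Brent's method (xtol 10⁻⁴ °C); multiple sign changes raise.
The test-suite oracle is an independent 0.01 °C grid scan.

The hydration fit minimises vertical residuals in chemical potential,
`Σ w_i [mu_hyd(T_i) − mu_solution(T_i, a_i)]²`, over (dH0, dS0, Cp) with
unit weights by default, via trust-region least squares; it is
deterministic for a given start. At least four observations spanning
15 °C are required — with fewer, the three parameters are not
identifiable.

Reference (T, mu) tables for regenerating the ice/water quadratics are
built at run time from the Wagner–Pruß saturation and Murphy–Koop
sublimation vapour-pressure correlations through the ideal-vapour route
(vaporisation enthalpy 45.051 kJ/mol and vapour Cp 33.6 J/(mol K) at the
triple point). Refitting quadratics to these tables reproduces the
curvature and slope of the printed curves and agrees with them to
≲25 J/mol across the data range; the small constant terms (≈8–10 J/mol)
are below the accuracy of this reconstruction.

The model-compound calculation `hbond_displacement_enthalpy` apportions
the −9.45 kJ/mol solution enthalpy of N-methylacetamide at 68 °C over
its three water H-bonds (two acceptor sites, each 1.6–1.9× the donor
strength; midpoint 1.75) and returns the share of the donor plus one
acceptor — the two bonds that must vacate for β-sheet formation —
≈5.8 kJ/mol per peptide, robust across the whole strength-ratio range.

## Synthetic data

Generators are deterministic for a fixed config + seed and default to
study-scale truths: coil R_G and R_H 12.5 nm, aggregate mode 90 nm,
onsets at 65 °C, amide II drifting 1545 → 1540 cm⁻¹ over 27 → 81 °C,
turbidity onset 40 °C on a 0.5 °C grid, and shell parameters
(−69.7, 0.2, 57.9). Noise is multiplicative Gaussian for scattering
(counting-like statistics) and additive for spectra, g2 and turbidity,
with defaults giving SNR ≈ 20. Above the scattering onset the aggregate
weight grows tenfold per 2.5 °C, so low-q intensity rises sharply and
single-chain fits break within one temperature step — mimicking how
fitting "rapidly ceases to be possible" in practice. Cloud points are
roots of the ground-truth model against the salt activity tables
(concentrations 0–2 mol/kg, 20 per salt; concentrations whose crossing
falls outside −10 to 100 °C are reported, not dropped) with 0.3 °C
temperature noise.

What the generators do *not* emulate: instrument artefacts (detector
nonlinearity, ATR penetration depth), inter-specimen biological
variability, multiple scattering, hysteresis in heating/cooling, or any
flow- or pH-driven gelation pathway. Passing round-trip tests therefore
demonstrates the correctness and statistical power of the analysis
chain under the assumed noise models, not robustness to real-instrument
systematics.

## Problem sizes

The shipped defaults are chosen so the whole synthetic pipeline runs in
seconds on one core: 120–300-point scattering curves at 12 temperatures,
160-lag g2 records, 200-point spectra at 10 temperatures, 81-point
turbidity traces, and 20 cloud points per salt with 20-replicate
recovery studies in the test suite.

## Known limitations

- Only Debye/Guinier/power-law scattering models; no structure factors,
  2-D reduction or absolute calibration.
- Cumulant DLS only; no regularised size distributions.
- The shell model treats all shell water as a single species with
  temperature-independent Cp and ignores protein-side contributions.
- Salt activities are 25 °C tables applied across the full temperature
  range; the temperature dependence of osmotic coefficients (a few
  percent over 0–70 °C for these salts) is neglected, as it was in the
  original analysis.
- The onset and cloud-point thresholds are conventions; alternative
  reasonable choices shift detected onsets by about one temperature
  step.
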