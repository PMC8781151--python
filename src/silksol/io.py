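"""Plain-text readers and writers for the pipeline's data streams.

All formats are delimited text with ``#`` comment lines; metadata rides in
``# key: value`` header lines. Spectra can additionally be read from a
minimal JCAMP-DX subset (fixed-point ``XYDATA=(X++(Y..Y))`` blocks).
Cloud-point tables are CSV with columns temperature_C, salt, conc and
optionally activity (computed from the packaged salt tables when absent).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dls import Autocorrelation
from .scattering import ScatteringCurve
from .spectroscopy import Spectrum
from .thermo import CloudPointDatum, HydrationShellParams
from .turbidity import TurbidityTrace

__all__ = [
    "read_scattering",
    "write_scattering",
    "read_spectrum",
    "write_spectrum",
    "read_jcamp",
    "read_autocorrelation",
    "write_autocorrelation",
    "read_turbidity_trace",
    "write_turbidity_trace",
    "read_cloud_points",
    "write_cloud_points",
    "load_shell_params",
    "save_shell_params",
]


def _read_table(path) -> tuple[np.ndarray, dict[str, str]]:
    """Numeric columns + '# key: value' metadata from a delimited text file."""
    meta: dict[str, str] = {}
    rows: list[str] = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip().lower()] = value.strip()
            continue
        rows.append(stripped.replace(",", " "))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    # tolerate a single non-numeric header row
    try:
        float(rows[0].split()[0])
    except ValueError:
        rows = rows[1:]
    data = np.loadtxt(_io.StringIO("\n".join(rows)), ndmin=2)
    return data, meta


def _meta_float(meta: dict[str, str], key: str) -> float | None:
    return float(meta[key]) if key in meta else None


def read_scattering(path, q_unit: str = "nm") -> ScatteringCurve:
    """Read (q, I[, sigma]) columns; ``q_unit`` 'nm' or 'angstrom' (x10)."""
    data, meta = _read_table(path)
    if data.shape[1] < 2:
        raise ValueError("scattering file needs at least q and intensity columns")
    q = data[:, 0]
    if q_unit == "angstrom":
        q = q * 10.0
    elif q_unit != "nm":
        raise ValueError("q_unit must be 'nm' or 'angstrom'")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringCurve(
        q, data[:, 1], sigma,
        temperature=_meta_float(meta, "temperature"),
        label=meta.get("label", str(path)),
    )


def write_scattering(path, curve: ScatteringCurve) -> None:
    cols = [curve.q, curve.intensity]
    header = ["q_nm^-1 intensity" + (" sigma" if curve.sigma is not None else "")]
    if curve.temperature is not None:
        header.insert(0, f"temperature: {curve.temperature}")
    if curve.label:
        header.insert(0, f"label: {curve.label}")
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(path, np.column_stack(cols), header="\n".join(header))


def read_spectrum(path) -> Spectrum:
    """Read a 2-column (wavenumber, absorbance) delimited text spectrum."""
    data, meta = _read_table(path)
    if data.shape[1] < 2:
        raise ValueError("spectrum file needs wavenumber and absorbance columns")
    nu, ab = data[:, 0], data[:, 1]
    if nu[0] > nu[-1]:  # descending instruments are common; normalise
        nu, ab = nu[::-1], ab[::-1]
    return Spectrum(nu, ab, temperature=_meta_float(meta, "temperature"),
                    label=meta.get("label", str(path)))


def write_spectrum(path, spectrum: Spectrum) -> None:
    header = ["wavenumber_cm^-1 absorbance"]
    if spectrum.temperature is not None:
        header.insert(0, f"temperature: {spectrum.temperature}")
    if spectrum.label:
        header.insert(0, f"label: {spectrum.label}")
    np.savetxt(path, np.column_stack([spectrum.wavenumber, spectrum.absorbance]),
               header="\n".join(header))


def read_jcamp(path) -> Spectrum:
    """Minimal JCAMP-DX reader: fixed-point ``XYDATA=(X++(Y..Y))`` only.

    Applies FIRSTX/LASTX/NPOINTS/XFACTOR/YFACTOR; no compression schemes
    (ASDF/DIF/DUP) are supported.
    """
    xfactor = yfactor = 1.0
    firstx = lastx = npoints = None
    temperature = None
    in_data = False
    ys: list[float] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "FIRSTX":
                firstx = float(value)
            elif key == "LASTX":
                lastx = float(value)
            elif key == "NPOINTS":
                npoints = int(float(value))
            elif key == "TEMPERATURE":
                temperature = float(value)
            elif key == "XYDATA":
                if "X++(Y..Y)" not in value:
                    raise ValueError("only XYDATA=(X++(Y..Y)) is supported")
                in_data = True
            elif key == "END":
                in_data = False
            continue
        if in_data and line:
            parts = line.replace(",", " ").split()
            ys.extend(float(p) * yfactor for p in parts[1:])  # first token is X
    if firstx is None or lastx is None or npoints is None:
        raise ValueError("JCAMP file missing FIRSTX/LASTX/NPOINTS")
    if len(ys) != npoints:
        raise ValueError(f"expected {npoints} points, found {len(ys)}")
    nu = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    ab = np.asarray(ys)
    if nu[0] > nu[-1]:
        nu, ab = nu[::-1], ab[::-1]
    return Spectrum(nu, ab, temperature=temperature, label=str(path))


def read_autocorrelation(path) -> Autocorrelation:
    """Read (lag_s, g2) columns with an instrument-geometry header block."""
    data, meta = _read_table(path)
    if data.shape[1] < 2:
        raise ValueError("autocorrelation file needs lag and g2 columns")
    kwargs = {}
    for key in ("angle", "wavelength", "temperature", "refractive_index", "viscosity"):
        value = _meta_float(meta, key)
        if value is not None:
            kwargs[key] = value
    return Autocorrelation(lag=data[:, 0], g2=data[:, 1], **kwargs)


def write_autocorrelation(path, acorr: Autocorrelation) -> None:
    header = [
        f"angle: {acorr.angle}",
        f"wavelength: {acorr.wavelength}",
        f"temperature: {acorr.temperature}",
        f"refractive_index: {acorr.refractive_index}",
    ]
    if acorr.viscosity is not None:
        header.append(f"viscosity: {acorr.viscosity}")
    header.append("lag_s g2")
    np.savetxt(path, np.column_stack([acorr.lag, acorr.g2]), header="\n".join(header))


def read_turbidity_trace(path) -> TurbidityTrace:
    data, meta = _read_table(path)
    if data.shape[1] < 2:
        raise ValueError("turbidity file needs temperature and turbidity columns")
    return TurbidityTrace(
        temperature=data[:, 0],
        turbidity=data[:, 1],
        wavelength=_meta_float(meta, "wavelength") or 600.0,
        salt=meta.get("salt", ""),
        salt_concentration=_meta_float(meta, "salt_concentration") or 0.0,
        protein_mass_fraction=_meta_float(meta, "protein_mass_fraction") or 0.001,
    )


def write_turbidity_trace(path, trace: TurbidityTrace) -> None:
    header = [
        f"wavelength: {trace.wavelength}",
        f"salt: {trace.salt}",
        f"salt_concentration: {trace.salt_concentration}",
        f"protein_mass_fraction: {trace.protein_mass_fraction}",
        "temperature_C turbidity",
    ]
    np.savetxt(path, np.column_stack([trace.temperature, trace.turbidity]),
               header="\n".join(header))


def read_cloud_points(path) -> list[CloudPointDatum]:
    """CSV with columns temperature_C, salt, conc[, activity[, weight]].

    Activity, when absent, is interpolated from the packaged table for the
    named salt at ``conc`` mol/kg.
    """
    from .salt_activity import activity_from_salt

    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    out = []
    for _, row in df.iterrows():
        salt = str(row.get("salt", "")).strip()
        if "activity" in df.columns and not pd.isna(row["activity"]):
            activity = float(row["activity"])
        else:
            activity = activity_from_salt(salt, float(row["conc"]))
        out.append(CloudPointDatum(
            temperature=float(row["temperature_c"]),
            water_activity=activity,
            salt=salt,
            weight=float(row["weight"]) if "weight" in df.columns
            and not pd.isna(row.get("weight")) else 1.0,
        ))
    return out


def write_cloud_points(path, data: list[CloudPointDatum]) -> None:
    pd.DataFrame(
        {
            "temperature_C": [d.temperature for d in data],
            "salt": [d.salt for d in data],
            "conc": [float("nan")] * len(data),
            "activity": [d.water_activity for d in data],
            "weight": [d.weight for d in data],
        }
    ).to_csv(path, index=False)


def load_shell_params(path) -> HydrationShellParams:
    """Hydration-shell parameters from a YAML or JSON mapping."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return HydrationShellParams(
        dH0=float(data["dH0"]),
        dS0=float(data["dS0"]),
        cp_shell=float(data["cp_shell"]),
        T0=float(data.get("T0", 273.15)),
        cp_water_ref=float(data.get("cp_water_ref", 75.7)),
    )


def save_shell_params(path, params: HydrationShellParams) -> None:
    payload = {
        "dH0": float(params.dH0),
        "dS0": float(params.dS0),
        "cp_shell": float(params.cp_shell),
        "T0": float(params.T0),
        "cp_water_ref": float(params.cp_water_ref),
    }
    text = (json.dumps(payload, indent=2) if str(path).endswith(".json")
            else yaml.safe_dump(payload))
    Path(path).write_text(text)
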