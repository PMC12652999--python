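"""Plain-text readers and writers for spectra, decay traces, and manifests.

CSV dialect: UTF-8, ``.`` decimal, a one-line column header, and optional
``# key=value`` comment lines carrying metadata.  Numeric values are written
with :func:`repr`, i.e. the shortest decimal text that round-trips the float
bit-for-bit.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .spectra import AbsorbanceSpectrum, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_absorbance",
    "write_absorbance",
    "read_trace",
    "write_trace",
    "read_irf",
    "write_irf",
    "parse_concentration",
    "read_titration_manifest",
    "read_exposure_manifest",
]

_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


def parse_concentration(text: str, default_unit: str = "M") -> float:
    """Parse a concentration with an optional unit suffix into molar.

    Accepts ``M``, ``mM``, ``uM``/``µM``, ``nM``; a bare number is read in
    ``default_unit``.
    """
    s = str(text).strip()
    m = re.fullmatch(r"([-+0-9.eE]+)\s*([munµ]?M)?", s)
    if m is None:
        raise ValidationError(f"cannot parse concentration {text!r}")
    unit = m.group(2) or default_unit
    if unit not in _UNIT_FACTORS:
        raise ValidationError(f"unknown concentration unit {unit!r} in {text!r}")
    return float(m.group(1)) * _UNIT_FACTORS[unit]


def _fmt(x: float) -> str:
    return repr(float(x))


def _write_table(path, header: str, columns, meta: dict | None) -> None:
    lines = []
    for key, value in (meta or {}).items():
        if isinstance(value, (str, int, float, bool)):
            lines.append(f"# {key}={value}")
    lines.append(header)
    for row in zip(*columns):
        lines.append(",".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_table(path, expected_header: str):
    meta: dict = {}
    rows: list[list[float]] = []
    header = None
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = _coerce(value.strip())
                continue
            if header is None:
                header = line
                if header.replace(" ", "") != expected_header:
                    raise DataError(
                        f"{path}: expected header {expected_header!r}, got {header!r}"
                    )
                continue
            rows.append([float(tok) for tok in line.split(",")])
    if header is None or not rows:
        raise DataError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    return arr, meta


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value in ("True", "False"):
        return value == "True"
    return value


def write_spectrum(spec: Spectrum, path) -> None:
    _write_table(path, "wavelength_nm,intensity", (spec.wavelength, spec.intensity), spec.meta)


def read_spectrum(path) -> Spectrum:
    arr, meta = _read_table(path, "wavelength_nm,intensity")
    return Spectrum(arr[:, 0], arr[:, 1], meta)


def write_absorbance(spec: AbsorbanceSpectrum, path) -> None:
    _write_table(path, "wavelength_nm,od", (spec.wavelength, spec.od), spec.meta)


def read_absorbance(path) -> AbsorbanceSpectrum:
    arr, meta = _read_table(path, "wavelength_nm,od")
    return AbsorbanceSpectrum(arr[:, 0], arr[:, 1], meta)


def write_trace(trace, path) -> None:
    meta = {**trace.meta, "kind": trace.kind, "averages": trace.averages}
    _write_table(path, "time_ns,signal", (trace.time, trace.signal), meta)


def read_trace(path):
    from .time_resolved import DecayTrace

    arr, meta = _read_table(path, "time_ns,signal")
    kind = meta.pop("kind", "trpl")
    averages = int(meta.pop("averages", 1))
    return DecayTrace(arr[:, 0], arr[:, 1], kind=kind, averages=averages, meta=meta)


def write_irf(irf, path) -> None:
    meta = {**irf.meta, "kind": "irf"}
    _write_table(path, "time_ns,signal", (irf.time, irf.response), meta)


def read_irf(path):
    from .time_resolved import IRF

    arr, meta = _read_table(path, "time_ns,signal")
    meta.pop("kind", None)
    return IRF(arr[:, 0], arr[:, 1], meta)


def read_titration_manifest(path, unit: str = "M"):
    """Load a titration manifest CSV into a :class:`TitrationSeries`.

    Columns: ``conc_M, spectrum_path, absorbance_path, blank_path`` (the last
    two optional).  Relative paths resolve against the manifest directory.
    Blank spectra, when present, are subtracted before the series is built.
    ``unit`` rescales the concentration column when it is expressed in mM etc.
    """
    from .spectra import subtract_blank
    from .stern_volmer import TitrationSeries

    base = Path(path).parent
    df = pd.read_csv(path, comment="#", skipinitialspace=True, dtype=str)
    if "conc_M" not in df.columns or "spectrum_path" not in df.columns:
        raise ValidationError(f"{path}: manifest needs conc_M and spectrum_path columns")

    conc, spectra, absorbances = [], [], []
    any_abs = False
    for _, row in df.iterrows():
        conc.append(parse_concentration(row["conc_M"], default_unit=unit))
        spec = read_spectrum(base / row["spectrum_path"])
        blank_path = row.get("blank_path")
        if isinstance(blank_path, str) and blank_path.strip():
            spec = subtract_blank(spec, read_spectrum(base / blank_path.strip()))
        spectra.append(spec)
        abs_path = row.get("absorbance_path")
        if isinstance(abs_path, str) and abs_path.strip():
            absorbances.append(read_absorbance(base / abs_path.strip()))
            any_abs = True
        else:
            absorbances.append(None)
    if any_abs and any(a is None for a in absorbances):
        raise ValidationError(f"{path}: absorbance_path present for some rows but not all")
    order = np.argsort(conc)
    return TitrationSeries(
        conc=np.asarray(conc)[order],
        spectra=[spectra[i] for i in order],
        absorbances=[absorbances[i] for i in order] if any_abs else None,
    )


def read_exposure_manifest(path, unit: str = "M"):
    """Load an exposure manifest CSV into per-cell :class:`ExposureSeries`.

    Columns: ``cell_id, cum_exposure_s, conc_M_or_PRE, spectrum_path,
    preparation``.  Rows tagged ``PRE`` are agonist-free pre-exposures used
    for the photobleach fit.
    """
    from .binding import Exposure, ExposureSeries

    base = Path(path).parent
    df = pd.read_csv(path, comment="#", skipinitialspace=True, dtype=str)
    needed = {"cell_id", "cum_exposure_s", "conc_M_or_PRE", "spectrum_path"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: manifest needs columns {sorted(needed)}")

    series = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        exposures = []
        preparation = "cell"
        for _, row in group.iterrows():
            tag = str(row["conc_M_or_PRE"]).strip()
            conc = None if tag.upper() == "PRE" else parse_concentration(tag, default_unit=unit)
            exposures.append(
                Exposure(
                    time_s=float(row["cum_exposure_s"]),
                    conc=conc,
                    spectrum=read_spectrum(base / row["spectrum_path"]),
                )
            )
            if "preparation" in row and isinstance(row["preparation"], str):
                preparation = row["preparation"].strip() or preparation
        exposures.sort(key=lambda e: e.time_s)
        series.append(ExposureSeries(exposures=exposures, cell_id=str(cell_id), preparation=preparation))
    return series
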