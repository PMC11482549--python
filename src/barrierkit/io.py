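"""CSV and config I/O for spectra, assays and calibration standards.

Spectrum dialect: header ``freq_hz,z_mod_ohm,z_phase_deg``, one row per
frequency, '.' decimal separator; leading ``# key: value`` comment lines
carry metadata (stage, electrode pair, amplitude_mV).  A ``semicolon``
dialect (';' separators, ',' decimals) is accepted for instrument exports
from locales that use decimal commas.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuit_core import FrequencyGrid, ImpedanceSpectrum, bode_table

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_assays_csv",
    "read_calibration_csv",
    "load_config",
]

logger = logging.getLogger(__name__)

SPECTRUM_COLUMNS = ["freq_hz", "z_mod_ohm", "z_phase_deg"]
ASSAY_COLUMNS = ["sample_id", "v_rec_ml", "signal", "a_cm2", "dt_s",
                 "c_t0_mg_ml", "role"]


class ParseError(ValueError):
    """Malformed input file."""


def _read_metadata_lines(path: Path) -> dict:
    meta: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_spectrum_csv(path, dialect: str = "standard") -> ImpedanceSpectrum:
    """Read a spectrum table; rows are sorted ascending by frequency.

    Duplicate frequencies and non-positive magnitudes are validation errors
    naming the offending file row.
    """
    path = Path(path)
    sep, decimal = (";", ",") if dialect == "semicolon" else (",", ".")
    meta = _read_metadata_lines(path)
    try:
        df = pd.read_csv(path, comment="#", sep=sep, decimal=decimal)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    if list(df.columns) != SPECTRUM_COLUMNS:
        raise ParseError(
            f"{path}: expected header {','.join(SPECTRUM_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    for col in SPECTRUM_COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric {col} at data row "
                             f"{int(bad[0]) + 1}")
        df[col] = pd.to_numeric(df[col])

    neg = df.index[df["z_mod_ohm"] <= 0]
    if len(neg):
        raise ParseError(f"{path}: non-positive magnitude at data row "
                         f"{int(neg[0]) + 1}")
    if df["freq_hz"].duplicated().any():
        dup = float(df["freq_hz"][df["freq_hz"].duplicated()].iloc[0])
        raise ParseError(f"{path}: duplicate frequency {dup} Hz")
    if not df["freq_hz"].is_monotonic_increasing:
        logger.info("%s: rows were not frequency-sorted; sorting", path)
        df = df.sort_values("freq_hz").reset_index(drop=True)

    grid = FrequencyGrid(df["freq_hz"].to_numpy())
    return ImpedanceSpectrum(grid, df["z_mod_ohm"].to_numpy(),
                             df["z_phase_deg"].to_numpy(), meta)


def write_spectrum_csv(spectrum: ImpedanceSpectrum, path) -> None:
    """Write the standard spectrum dialect (metadata as '#' comments)."""
    path = Path(path)
    lines = []
    for key, value in spectrum.metadata.items():
        if isinstance(value, (str, int, float)):
            lines.append(f"# {key}: {value}")
    table = bode_table(spectrum)
    body = table.to_csv(index=False, float_format="%.10g")
    path.write_text("\n".join(lines + [body]) if lines else body,
                    encoding="utf-8")


def read_assays_csv(path) -> pd.DataFrame:
    """Read tracer-assay records (per-sample volumes, signals, roles)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing assay columns {missing}")
    bad_roles = set(df["role"]) - {"barrier", "control"}
    if bad_roles:
        raise ParseError(f"{path}: unknown roles {sorted(bad_roles)}")
    return df


def read_calibration_csv(path) -> list:
    """Read calibration standards as (conc_mg_ml, signal) pairs."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("conc_mg_ml", "signal"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing calibration column {col!r}")
    return list(zip(df["conc_mg_ml"].astype(float),
                    df["signal"].astype(float)))


def load_config(path) -> dict:
    """Load a YAML/JSON config mapping."""
    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data
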