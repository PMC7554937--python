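"""CSV and JSON input/output.

Spectral time series travel as plain CSV: an optional sidecar header block
of ``# key: value`` lines (temperature_C, reactants, dead_time_s, ...),
then a ``time_s`` column followed by numeric wavelength columns in nm.
Comma, semicolon and tab delimiters are auto-detected; wavelength columns
are canonicalized to ascending order on read.  JSON reports are written
with 9 significant digits so round-trips are stable, and validate against
the schema shipped in ``flavokin/schemas``.
"""

from __future__ import annotations

import hashlib
import json
import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, ParseError
from .globalfit import SpectralTimeSeries

_META_NUMERIC = {"temperature_C", "dead_time_s", "total_conc_uM", "noise_sd_AU", "seed"}


def _sniff_delimiter(line: str) -> str:
    for cand in ("\t", ";", ","):
        if cand in line:
            return cand
    return ","


def _parse_sidecar(path: Path) -> tuple[dict, str]:
    meta: dict = {}
    first_data_line = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key, value = key.strip(), value.strip()
                    if key in _META_NUMERIC:
                        try:
                            meta[key] = float(value) if "." in value or "e" in value.lower() else int(value)
                        except ValueError:
                            meta[key] = value
                    else:
                        meta[key] = value
            elif line.strip():
                first_data_line = line
                break
    return meta, first_data_line


def read_spectral_csv(path) -> SpectralTimeSeries:
    """Parse a spectral time-series CSV into a validated SpectralTimeSeries."""
    path = Path(path)
    meta, header = _parse_sidecar(path)
    if not header:
        raise ParseError(f"{path}: no data rows found")
    sep = _sniff_delimiter(header)
    try:
        df = pd.read_csv(path, comment="#", sep=sep)
    except Exception as exc:
        raise ParseError(f"{path}: could not parse CSV ({exc})") from exc
    if df.columns[0] != "time_s":
        raise ParseError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: need at least 2 wavelength columns")
    try:
        wl = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ParseError(
            f"{path}: wavelength headers must be numeric nm values ({exc})"
        ) from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    values = numeric.to_numpy(dtype=float, na_value=np.nan)
    if np.any(~np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(
            f"{path}: non-numeric or missing cell at row {bad[0] + 1}, "
            f"column {df.columns[bad[1]]!r}"
        )
    times = values[:, 0]
    absorbance = values[:, 1:]
    if np.any(np.diff(times) <= 0):
        row = int(np.nonzero(np.diff(times) <= 0)[0][0]) + 2
        raise ParseError(f"{path}: time column not strictly increasing at row {row}")
    order = np.argsort(wl)
    try:
        return SpectralTimeSeries(
            times=times, wavelengths=wl[order], absorbance=absorbance[:, order],
            meta=meta,
        )
    except InvalidInputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_spectral_csv(ts: SpectralTimeSeries, path) -> None:
    # data CSVs are written at full precision so round-trips are lossless;
    # the 9-significant-digit policy applies to JSON reports only
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in ts.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("time_s," + ",".join(f"{w:.17g}" for w in ts.wavelengths) + "\n")
        for t, row in zip(ts.times, ts.absorbance):
            fh.write(f"{t:.17g}," + ",".join(f"{v:.17g}" for v in row) + "\n")


def read_rate_table(path, value_col: str = "k_obs_per_s") -> pd.DataFrame:
    """Read a scalar rate table (concentration or temperature vs rate)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: could not parse CSV ({exc})") from exc
    if df.empty or value_col not in df.columns:
        raise ParseError(f"{path}: expected a non-empty table with a {value_col!r} column")
    return df


def write_rate_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


def _sig9(x: float) -> str:
    return f"{float(x):.9g}"


def _round_floats(obj):
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return float(_sig9(obj))
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json_report(report: dict, path) -> None:
    """Serialize a report with 9-significant-digit floats."""
    with open(path, "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_schema(name: str = "report.schema.json") -> dict:
    with resources.files("flavokin.schemas").joinpath(name).open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: dict | None = None, _path: str = "$") -> None:
    """Check a report against the shipped schema subset.

    Supports the schema constructs this package uses: ``type``,
    ``properties``, ``required``, ``items`` and ``enum``.  Raises
    InvalidInputError on the first violation.
    """
    if schema is None:
        schema = load_schema()
    _validate_node(report, schema, _path)


_TYPE_MAP = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
    "null": type(None),
}


def _validate_node(obj, schema: dict, path: str) -> None:
    stype = schema.get("type")
    if stype is not None:
        expected = _TYPE_MAP[stype]
        ok = isinstance(obj, expected)
        if stype == "number":
            ok = isinstance(obj, (int, float)) and not isinstance(obj, bool)
        if stype == "integer":
            ok = isinstance(obj, int) and not isinstance(obj, bool)
        if not ok:
            raise InvalidInputError(f"{path}: expected {stype}, got {type(obj).__name__}")
    if "enum" in schema and obj not in schema["enum"]:
        raise InvalidInputError(f"{path}: {obj!r} not in {schema['enum']}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                raise InvalidInputError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _validate_node(obj[key], sub, f"{path}.{key}")
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            _validate_node(item, schema["items"], f"{path}[{i}]")


def validate_config(config: dict, allowed: dict) -> dict:
    """Validate a flat run configuration against allowed keys.

    ``allowed`` maps key -> type (or tuple of types).  Unknown keys are
    rejected; values are type-checked.  Returns the config unchanged.
    """
    for key, value in config.items():
        if key not in allowed:
            raise InvalidInputError(f"unknown configuration key {key!r}")
        if not isinstance(value, allowed[key]):
            raise InvalidInputError(
                f"configuration key {key!r} has type {type(value).__name__}"
            )
    return config


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path, inputs: list, seed: int | None, params: dict) -> None:
    """Reproducibility manifest written next to each CLI output."""
    from . import __version__

    manifest = {
        "flavokin_version": __version__,
        "seed": seed,
        "parameters": _round_floats(params),
        "inputs": {str(p): file_sha256(p) for p in inputs},
    }
    path = Path(str(out_path) + ".manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
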