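"""Readers and writers for the package's plain-text interchange formats.

All scan-type files share one CSV dialect: ``# key=value`` metadata lines,
a header row naming the columns, then numeric rows with ``.`` as the
decimal separator and positions in cm. Calibrations travel as JSON.
Parsers validate strictly and raise rather than coerce malformed input.
"""

from __future__ import annotations

import json
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_calibration import QualityConversionTable
from .pion_core import PionCalibration, TwoVoltageReading
from .scan_correction import ScanCurve

__all__ = [
    "ScanFormatError",
    "read_scan_csv",
    "write_scan_csv",
    "read_rdf_csv",
    "write_rdf_csv",
    "read_two_voltage_csv",
    "write_two_voltage_csv",
    "read_mu_rate_csv",
    "write_mu_rate_csv",
    "read_calibration_json",
    "write_calibration_json",
    "load_builtin_calibration",
    "read_kq_table_csv",
    "write_kq_table_csv",
]

_DATA_DIR = Path(__file__).parent / "data"

#: Built-in calibrations shipped with the package: published linear
#: Pion(signal) fits for a TrueBeam 10 FFF, 6 FFF, and pooled 6/10 MV
#: flattened beam group (IC10/A19 chambers, 300/150 V).
_BUILTIN_FILES = {
    "10FFF": "calibration_10fff.json",
    "6FFF": "calibration_6fff.json",
    "6/10MV": "calibration_6_10mv.json",
}


class ScanFormatError(ValueError):
    """File does not conform to the interchange dialect."""


def _split_file(path) -> tuple[dict[str, str], str]:
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#"):
            stripped = raw.lstrip("#").strip()
            if "=" not in stripped:
                raise ScanFormatError(f"malformed metadata line: {raw!r}")
            key, _, value = stripped.partition("=")
            meta[key.strip()] = value.strip()
        elif raw.strip():
            body_lines.append(raw)
    if not body_lines:
        raise ScanFormatError(f"{path}: no data rows")
    return meta, "\n".join(body_lines) + "\n"


def _read_body(path, body: str, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(StringIO(body), dtype=float)
    except ValueError as exc:
        raise ScanFormatError(f"{path}: non-numeric data ({exc})") from exc
    got = tuple(df.columns)
    if got[: len(columns)] != columns:
        raise ScanFormatError(f"{path}: expected columns {columns}, got {got}")
    if df.isna().any().any():
        raise ScanFormatError(f"{path}: missing values in data rows")
    return df


def _require(meta: dict[str, str], key: str, path) -> str:
    if key not in meta:
        raise ScanFormatError(f"{path}: missing required metadata key '# {key}='")
    return meta[key]


def _fnum(x: float) -> str:
    # repr round-trips exactly through float(), keeping writes byte-stable
    return repr(float(x))


def read_scan_csv(path) -> ScanCurve:
    """Read a depth or crossplane scan from the CSV dialect.

    Required metadata: ``axis``, ``energy``, ``field_cm``, ``geometry``;
    ``distance_cm`` defaults to 100 and ``depth_cm`` is required for
    crossplane profiles. Extra numeric columns (e.g. ``signal_corrected``
    written by the correction commands) are ignored on read.
    """
    meta, body = _split_file(path)
    df = _read_body(path, body, ("position_cm", "signal"))
    axis = _require(meta, "axis", path)
    depth = None
    if axis == "crossplane":
        depth = float(_require(meta, "depth_cm", path))
    try:
        return ScanCurve(
            axis=axis,
            positions=df["position_cm"].to_numpy(),
            signals=df["signal"].to_numpy(),
            energy_label=_require(meta, "energy", path),
            field_size_cm=float(_require(meta, "field_cm", path)),
            geometry=_require(meta, "geometry", path),
            nominal_distance_cm=float(meta.get("distance_cm", "100")),
            depth_cm=depth,
        )
    except ValueError as exc:
        raise ScanFormatError(f"{path}: {exc}") from exc


def write_scan_csv(path, curve: ScanCurve, corrected_signals=None) -> None:
    """Write a scan in canonical formatting; optionally append a
    ``signal_corrected`` column."""
    lines = [
        f"# axis={curve.axis}",
        f"# energy={curve.energy_label}",
        f"# field_cm={_fnum(curve.field_size_cm)}",
        f"# geometry={curve.geometry}",
        f"# distance_cm={_fnum(curve.nominal_distance_cm)}",
    ]
    if curve.axis == "crossplane":
        lines.append(f"# depth_cm={_fnum(curve.depth_cm)}")
    if corrected_signals is None:
        lines.append("position_cm,signal")
        for p, s in zip(curve.positions, curve.signals):
            lines.append(f"{_fnum(p)},{_fnum(s)}")
    else:
        corrected_signals = np.asarray(corrected_signals, dtype=float)
        lines.append("position_cm,signal,signal_corrected")
        for p, s, c in zip(curve.positions, curve.signals, corrected_signals):
            lines.append(f"{_fnum(p)},{_fnum(s)},{_fnum(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rdf_csv(path) -> tuple[list[tuple[float, float]], dict[str, str]]:
    """Read output-factor point readings: ``field_cm,signal`` rows."""
    meta, body = _split_file(path)
    df = _read_body(path, body, ("field_cm", "signal"))
    return list(zip(df["field_cm"], df["signal"])), meta


def write_rdf_csv(path, readings, energy_label: str) -> None:
    lines = [f"# energy={energy_label}", "field_cm,signal"]
    for fs, s in readings:
        lines.append(f"{_fnum(fs)},{_fnum(s)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_two_voltage_csv(path) -> tuple[list[tuple[float, TwoVoltageReading]], dict[str, str]]:
    """Read two-voltage measurement rows.

    Each row carries the renormalized high-voltage signal the pair was
    taken at (``s_star_context``) plus voltages and raw readings; returns
    ``(s_star, reading)`` pairs ready for Pion estimation and fitting.
    """
    meta, body = _split_file(path)
    df = _read_body(
        path, body, ("s_star_context", "v_high", "v_low", "m_high", "m_low")
    )
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            (
                float(row.s_star_context),
                TwoVoltageReading(
                    v_high=row.v_high,
                    v_low=row.v_low,
                    m_high=row.m_high,
                    m_low=row.m_low,
                ),
            )
        )
    return pairs, meta


def write_two_voltage_csv(path, pairs, energy_label: str) -> None:
    lines = [f"# energy={energy_label}", "s_star_context,v_high,v_low,m_high,m_low"]
    for s_star, r in pairs:
        lines.append(
            ",".join(_fnum(v) for v in (s_star, r.v_high, r.v_low, r.m_high, r.m_low))
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_mu_rate_csv(path) -> list[tuple[float, float]]:
    """Read ``mu_rate,pion`` rows for the MU-rate independence check."""
    meta, body = _split_file(path)
    df = _read_body(path, body, ("mu_rate", "pion"))
    return list(zip(df["mu_rate"], df["pion"]))


def write_mu_rate_csv(path, points, energy_label: str = "") -> None:
    lines = []
    if energy_label:
        lines.append(f"# energy={energy_label}")
    lines.append("mu_rate,pion")
    for mu, p in points:
        lines.append(f"{_fnum(mu)},{_fnum(p)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _cal_to_dict(cal: PionCalibration) -> dict:
    out = {
        "energy_label": cal.energy_label,
        "slope_m": cal.slope_m,
        "intercept_b": cal.intercept_b,
        "slope_interval": list(cal.slope_interval),
        "intercept_interval": list(cal.intercept_interval),
        "r_squared": cal.r_squared,
        "fitted_support": list(cal.fitted_support),
        "v_high": cal.v_high,
        "v_low": cal.v_low,
        "n_points": cal.n_points,
        "seed": cal.seed,
    }
    if cal.slope_se is not None:
        out["slope_se"] = cal.slope_se
    if cal.intercept_se is not None:
        out["intercept_se"] = cal.intercept_se
    return out


def _cal_from_dict(d: dict) -> PionCalibration:
    return PionCalibration(
        energy_label=d["energy_label"],
        slope_m=float(d["slope_m"]),
        intercept_b=float(d["intercept_b"]),
        slope_interval=tuple(d["slope_interval"]),
        intercept_interval=tuple(d["intercept_interval"]),
        r_squared=float(d["r_squared"]),
        fitted_support=tuple(d["fitted_support"]),
        slope_se=d.get("slope_se"),
        intercept_se=d.get("intercept_se"),
        v_high=float(d.get("v_high", 300.0)),
        v_low=float(d.get("v_low", 150.0)),
        n_points=d.get("n_points"),
        seed=d.get("seed"),
    )


def read_calibration_json(path) -> PionCalibration:
    return _cal_from_dict(json.loads(Path(path).read_text()))


def write_calibration_json(path, cal: PionCalibration) -> None:
    Path(path).write_text(json.dumps(_cal_to_dict(cal), indent=2) + "\n")


def load_builtin_calibration(energy_label: str) -> PionCalibration:
    """Load one of the shipped published calibrations.

    ``energy_label`` is ``"10FFF"``, ``"6FFF"`` or ``"6/10MV"`` (the two
    flattened energies were pooled because their Pion behaviour is
    statistically indistinguishable).
    """
    try:
        fname = _BUILTIN_FILES[energy_label]
    except KeyError:
        raise KeyError(
            f"no built-in calibration {energy_label!r}; "
            f"available: {sorted(_BUILTIN_FILES)}"
        ) from None
    return read_calibration_json(_DATA_DIR / fname)


def read_kq_table_csv(path) -> QualityConversionTable:
    """Read a chamber kQ table: ``# chamber=<model>`` then ``pdd10,kq`` rows."""
    meta, body = _split_file(path)
    df = _read_body(path, body, ("pdd10", "kq"))
    return QualityConversionTable(
        chamber_model=_require(meta, "chamber", path),
        pdd10=df["pdd10"].to_numpy(),
        kq=df["kq"].to_numpy(),
    )


def write_kq_table_csv(path, table: QualityConversionTable) -> None:
    lines = [f"# chamber={table.chamber_model}", "pdd10,kq"]
    for p, k in zip(table.pdd10, table.kq):
        lines.append(f"{_fnum(p)},{_fnum(k)}")
    Path(path).write_text("\n".join(lines) + "\n")
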