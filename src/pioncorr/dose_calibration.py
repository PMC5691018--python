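"""Beam-quality conversion (kQ) and absolute dose, and how Pion moves them.

Absolute dose calibration follows the megavoltage-photon protocol chain
``Dw = M * kQ * N_D,w``: the fully corrected reading M, the quality
conversion factor kQ — interpolated against the beam-quality specifier
%dd(10) from a chamber-specific lookup table — and the absorbed-dose-to-
water coefficient N_D,w. Correcting the depth-dose curve for ion
recombination changes %dd(10), hence kQ, hence the absolute dose; the
relative change in kQ equals the relative change in the output. The
chamber's kQ table is protocol content and is supplied by the user, not
shipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pion_core import PionCalibration
from .scan_correction import DoseFunctionCurve, ScanCurve, correct_pdd

__all__ = [
    "KqRangeError",
    "QualityConversionTable",
    "AbsoluteDoseInputs",
    "interpolate_kq",
    "relative_kq_change",
    "absolute_dose",
    "kq_change_for_curve",
]


class KqRangeError(ValueError):
    """%dd(10) outside the chamber table's grid; extrapolation is refused."""


@dataclass(frozen=True)
class QualityConversionTable:
    """kQ vs %dd(10) grid for one chamber model."""

    chamber_model: str
    pdd10: np.ndarray
    kq: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pdd10", np.asarray(self.pdd10, dtype=float))
        object.__setattr__(self, "kq", np.asarray(self.kq, dtype=float))
        if self.pdd10.ndim != 1 or self.pdd10.shape != self.kq.shape:
            raise ValueError("pdd10 and kq must be 1-D and equal length")
        if self.pdd10.size < 2:
            raise ValueError("a kQ table needs at least two grid points")
        if np.any(np.diff(self.pdd10) <= 0):
            raise ValueError("%dd(10) grid must be strictly increasing")
        if np.any((self.kq <= 0.9) | (self.kq >= 1.05)):
            raise ValueError("kQ values must lie in (0.9, 1.05)")


@dataclass(frozen=True)
class AbsoluteDoseInputs:
    """Operands of the absolute-dose product ``Dw = M * kQ * N_D,w``.

    ``m_corrected`` is the fully corrected reading (all protocol factors
    applied); ``nd_w`` is in Gy per charge unit.
    """

    m_corrected: float
    kq: float
    nd_w: float

    def __post_init__(self) -> None:
        if not (self.m_corrected > 0 and self.kq > 0 and self.nd_w > 0):
            raise ValueError("all absolute-dose factors must be > 0")


def interpolate_kq(pdd10: float, table: QualityConversionTable) -> float:
    """Piecewise-linear kQ at the given %dd(10); exact at grid points.

    Raises :class:`KqRangeError` outside the table's range — the tabulated
    protocol values must not be extrapolated.
    """
    if not (table.pdd10[0] <= pdd10 <= table.pdd10[-1]):
        raise KqRangeError(
            f"%dd(10) = {pdd10:g} outside table range "
            f"[{table.pdd10[0]:g}, {table.pdd10[-1]:g}] for {table.chamber_model}"
        )
    return float(np.interp(pdd10, table.pdd10, table.kq))


def relative_kq_change(kq_uncorrected: float, kq_corrected: float) -> float:
    """Percent change ``100 (kQ - kQ*) / kQ*`` caused by the Pion correction.

    This is also the relative change in the absolute dose rate, since
    ``Dw`` is linear in kQ.
    """
    if not (kq_uncorrected > 0 and kq_corrected > 0):
        raise ValueError("kQ values must be > 0")
    return 100.0 * (kq_corrected - kq_uncorrected) / kq_uncorrected


def absolute_dose(inputs: AbsoluteDoseInputs) -> float:
    """Absolute dose to water ``Dw = M * kQ * N_D,w`` (Gy)."""
    return inputs.m_corrected * inputs.kq * inputs.nd_w


def _value_at(curve: DoseFunctionCurve, position: float) -> float:
    if not (curve.positions[0] <= position <= curve.positions[-1]):
        raise ValueError(f"position {position} outside the scanned range")
    return float(np.interp(position, curve.positions, curve.values))


def kq_change_for_curve(
    curve: ScanCurve,
    cal: PionCalibration,
    table: QualityConversionTable,
    depth: float = 10.0,
) -> dict:
    """End-to-end kQ chain for a depth scan: %dd(10) with and without
    Pion, the interpolated kQ pair, and the relative change.

    %dd at the specifier depth (default 10.0 cm) is linearly interpolated
    from each curve. Returns a dict with keys ``pdd10_uncorrected``,
    ``pdd10_corrected``, ``kq_uncorrected``, ``kq_corrected`` and
    ``delta_rel_percent``.
    """
    cor, unc = correct_pdd(curve, cal)
    pdd10_unc = _value_at(unc, depth)
    pdd10_cor = _value_at(cor, depth)
    kq_unc = interpolate_kq(pdd10_unc, table)
    kq_cor = interpolate_kq(pdd10_cor, table)
    return {
        "pdd10_uncorrected": pdd10_unc,
        "pdd10_corrected": pdd10_cor,
        "kq_uncorrected": kq_unc,
        "kq_corrected": kq_cor,
        "delta_rel_percent": relative_kq_change(kq_unc, kq_cor),
    }
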