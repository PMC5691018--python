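"""Derive tissue-maximum ratios from percent-depth-dose curves, with the
Pion correction applied at the *calculated* signal magnitudes.

Measuring TMR directly (chamber fixed at the isocenter, water added above
it) is rarely done; commissioning software derives TMR(d) from the %dd
curve by evaluating the dose at a point (SAD + d) cm from the source.
That geometric move changes the signal magnitude at which the chamber
would actually have operated — e.g. a measured TMR at 20 cm depth
involves signals of roughly 57 and 100 reference units (at depth and at
dmax), whereas the derived calculation places both points at 120 cm from
the source, where the inverse-square law shrinks the magnitudes to
roughly 40 and 69. Because Pion depends on signal magnitude, the
correction attached to a derived TMR differs from the one attached to a
measured TMR; this module makes the calculated magnitudes explicit so the
two can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pion_core import PionCalibration, pion_at_signal
from .scan_correction import DoseFunctionCurve, ScanCurve

__all__ = ["TmrDerivationConfig", "TmrDerivationResult", "derive_tmr_from_pdd"]


@dataclass(frozen=True)
class TmrDerivationConfig:
    """Geometry and options for the %dd -> TMR derivation.

    ``scatter_factor`` is a user-supplied multiplicative hook on the
    calculated signals, standing in for phantom/head-scatter effects
    beyond the inverse-square law (default 1: pure inverse square). It
    cancels in the TMR ratio itself and only shifts the signal magnitudes
    at which Pion is evaluated.
    """

    sad: float = 100.0
    scatter_factor: float = 1.0
    apply_pion: bool = True

    def __post_init__(self) -> None:
        if not self.sad > 0:
            raise ValueError("sad must be > 0")
        if not self.scatter_factor > 0:
            raise ValueError("scatter_factor must be > 0")


@dataclass(frozen=True)
class TmrDerivationResult:
    """Derived TMR curves plus the calculated signal magnitudes used.

    ``s_calc_depth[i]`` / ``s_calc_dmax[i]`` are the reference-scale
    signals at the (SAD + d_i) evaluation point for the depth-d_i sample
    and for the dmax sample respectively; both enter the Pion ratio of the
    corrected TMR.
    """

    corrected: DoseFunctionCurve
    uncorrected: DoseFunctionCurve
    s_calc_depth: np.ndarray
    s_calc_dmax: np.ndarray
    depths: np.ndarray
    config: TmrDerivationConfig = field(default_factory=TmrDerivationConfig)


def derive_tmr_from_pdd(
    pdd_curve: ScanCurve,
    cal: PionCalibration,
    config: TmrDerivationConfig | None = None,
) -> TmrDerivationResult:
    """Convert a %dd depth scan into TMR, correcting Pion at the
    calculated-geometry signal magnitudes.

    The uncorrected TMR* applies the standard inverse-square mapping of
    the fixed-SSD %dd to the isocentric geometry,

        TMR*(d) = [S*(d)/S*(dmax)] * ((SSD + d)/(SSD + dmax))^2 .

    For the correction, both the depth-d point and the dmax point are
    evaluated at source distance (SAD + d): on the reference scale the SAD
    dmax signal is 100, so the calculated magnitudes are

        S*calc(d)      = 100 * TMR*(d) * (SAD/(SAD + d))^2 * scatter_factor
        S*calc,dmax(d) = 100 *           (SAD/(SAD + d))^2 * scatter_factor

    and TMR(d) = S*calc Pion(S*calc) / (S*calc,dmax Pion(S*calc,dmax)).
    With ``apply_pion`` off (or a zero-slope calibration) the common
    factors cancel and the derived TMR reduces to TMR*.
    """
    if config is None:
        config = TmrDerivationConfig()
    if pdd_curve.axis != "depth":
        raise ValueError("TMR derivation requires a depth-axis %dd scan")
    if pdd_curve.geometry != "SSD":
        raise ValueError("the source %dd curve must be an SSD scan")
    s = pdd_curve.signals
    d = pdd_curve.positions
    ssd = pdd_curve.nominal_distance_cm
    # normalize at the maximum of the ISL-mapped dose: the TMR's depth of
    # maximum sits slightly deeper than the %dd's, because the fixed-SSD
    # scan folds the inverse-square falloff into its signals
    mapped = s * (ssd + d) ** 2
    i_max = int(np.argmax(mapped))
    if s[i_max] <= 0:
        raise ValueError("all-zero signal curve")
    dmax = d[i_max]

    tmr_unc = (s / s[i_max]) * ((ssd + d) / (ssd + dmax)) ** 2
    isl = (config.sad / (config.sad + d)) ** 2
    s_calc_depth = 100.0 * tmr_unc * isl * config.scatter_factor
    s_calc_dmax = 100.0 * isl * config.scatter_factor

    if config.apply_pion:
        num = s_calc_depth * pion_at_signal(s_calc_depth, cal)
        den = s_calc_dmax * pion_at_signal(s_calc_dmax, cal)
        tmr_cor = num / den
    else:
        tmr_cor = tmr_unc.copy()

    mk = lambda v, flag: DoseFunctionCurve(d, v, "tmr", flag, pdd_curve.energy_label)
    return TmrDerivationResult(
        corrected=mk(tmr_cor, True),
        uncorrected=mk(tmr_unc, False),
        s_calc_depth=s_calc_depth,
        s_calc_dmax=s_calc_dmax,
        depths=d,
        config=config,
    )
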