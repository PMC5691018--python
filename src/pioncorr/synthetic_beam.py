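"""Synthetic FFF beam scans and two-voltage readings with known ground truth.

Every correction stage in this package is exercised against data whose
true (recombination-free) dose values are known by construction. The
generators here build:

* central-axis depth-dose curves from a buildup-times-attenuation shape
  under inverse-square SSD geometry,
  ``S(d) ∝ (1 - exp(-beta d)) exp(-mu d) / (SSD + d)^2``;
* cone-shaped FFF crossplane profiles — a linear off-axis falloff inside
  the field rolled off through an error-function penumbra centred on the
  divergence-projected field edge;
* two-voltage reading pairs that are *algebraically* self-consistent with
  a prescribed linear Pion(signal) calibration: the low-voltage reading is
  obtained by exact inversion of the Boag two-voltage formula rather than
  from a recombination-physics model, so estimator and generator form an
  exact round trip on noiseless data;
* constant-Pion monitor-unit-rate datasets for the independence test.

Corrected (true) signals are converted to the uncorrected signals a real
chamber would report via the inverse quadratic signal relation; optional
multiplicative Gaussian noise is applied last. All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import erfc

from .pion_core import PionCalibration, TwoVoltageReading, uncorrect_signal
from .scan_correction import ScanCurve

__all__ = [
    "BeamModel",
    "TruthRecord",
    "BEAM_10FFF",
    "BEAM_6FFF",
    "generate_pdd",
    "generate_profile",
    "generate_two_voltage_set",
    "generate_mu_rate_set",
]


@dataclass(frozen=True)
class BeamModel:
    """Parametric FFF beam shape.

    ``mu_eff`` (1/cm) is the effective attenuation of the exponential
    falloff, ``beta_buildup`` (1/cm) the buildup rate (must exceed
    ``mu_eff`` so a dose maximum exists at positive depth), ``cone_slope``
    (1/cm) the fractional linear off-axis falloff of the unflattened cone
    inside the field, and ``penumbra_sigma`` (cm) the width parameter of
    the error-function penumbra.
    """

    mu_eff: float
    beta_buildup: float
    cone_slope: float = 0.02
    penumbra_sigma: float = 0.25
    ssd: float = 100.0
    sad: float = 100.0

    def __post_init__(self) -> None:
        if not self.mu_eff > 0:
            raise ValueError("mu_eff must be > 0")
        if not self.beta_buildup > self.mu_eff:
            raise ValueError("beta_buildup must exceed mu_eff")
        if not self.penumbra_sigma > 0:
            raise ValueError("penumbra_sigma must be > 0")
        if self.cone_slope < 0:
            raise ValueError("cone_slope must be >= 0")
        if not (self.ssd > 0 and self.sad > 0):
            raise ValueError("ssd and sad must be > 0")

    def depth_shape(self, d):
        """Unnormalized central-axis dose vs depth (buildup x attenuation
        x inverse square)."""
        d = np.asarray(d, dtype=float)
        return (
            (1.0 - np.exp(-self.beta_buildup * d))
            * np.exp(-self.mu_eff * d)
            / (self.ssd + d) ** 2
        )

    @property
    def dmax(self) -> float:
        """Depth of dose maximum: numerical maximizer of the depth shape."""
        res = minimize_scalar(
            lambda d: -self.depth_shape(d), bounds=(1e-3, 10.0), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)


#: 10 FFF-like and 6 FFF-like fixture beams. The attenuation/buildup
#: constants put the synthetic signals in the regime of clinical FFF
#: commissioning data; they are fixture parameters, not measurements.
BEAM_10FFF = BeamModel(mu_eff=0.044, beta_buildup=2.2, cone_slope=0.02)
BEAM_6FFF = BeamModel(mu_eff=0.056, beta_buildup=3.0, cone_slope=0.012)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth accompanying a generated dataset.

    ``corrected_signals`` are the noiseless recombination-free signals,
    ``pion_values`` the true Pion at each (noiseless) uncorrected signal,
    ``uncorrected_noiseless`` the pre-noise chamber signals. Regenerating
    with the same parameters and seed reproduces the dataset exactly.
    """

    corrected_signals: np.ndarray
    pion_values: np.ndarray
    uncorrected_noiseless: np.ndarray
    calibration: PionCalibration
    seed: int


def _true_to_uncorrected(s_true: np.ndarray, cal: PionCalibration):
    s_star = uncorrect_signal(s_true, cal)
    pion = np.divide(
        s_true, s_star, out=np.full_like(s_star, cal.intercept_b), where=s_star > 0
    )
    return s_star, pion


def _apply_noise(values, noise_sd, rng):
    if noise_sd == 0:
        return values.copy()
    return np.maximum(values * (1.0 + rng.normal(0.0, noise_sd, size=values.shape)), 0.0)


def _corrected_cax_scale(cal: PionCalibration) -> float:
    # the uncorrected reference reading is 100 by convention, so the true
    # corrected signal at dmax is 100 * Pion(100) = m*100^2 + b*100
    return cal.slope_m * 1e4 + cal.intercept_b * 100.0


def generate_pdd(
    model: BeamModel,
    cal: PionCalibration,
    depths,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ScanCurve, TruthRecord]:
    """Generate a fixed-SSD central-axis depth scan.

    The true corrected signal follows ``model.depth_shape`` scaled so that
    its value at dmax equals the corrected image of the 100-unit reference
    reading; chamber (uncorrected) signals are the inverse-quadratic image
    of the truth, with multiplicative Gaussian noise of fractional
    standard deviation ``noise_sd``.
    """
    depths = np.asarray(depths, dtype=float)
    if np.any(depths < 0) or np.any(depths > 40):
        raise ValueError("depth grid must lie within [0, 40] cm")
    scale = _corrected_cax_scale(cal) / model.depth_shape(model.dmax)
    s_true = scale * model.depth_shape(depths)
    s_star, pion = _true_to_uncorrected(s_true, cal)
    rng = np.random.default_rng(seed)
    noisy = _apply_noise(s_star, noise_sd, rng)
    curve = ScanCurve(
        axis="depth",
        positions=depths,
        signals=noisy,
        energy_label=cal.energy_label,
        field_size_cm=10.0,
        geometry="SSD",
        nominal_distance_cm=model.ssd,
    )
    return curve, TruthRecord(s_true, pion, s_star, cal, seed)


def generate_profile(
    model: BeamModel,
    cal: PionCalibration,
    field_size: float,
    depth: float,
    positions,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ScanCurve, TruthRecord]:
    """Generate a crossplane profile at the given depth.

    The true corrected profile is the CAX depth-dose value shaped by the
    FFF cone ``(1 - cone_slope |x|)`` and an erfc penumbra centred on the
    divergence-projected field edge at ``(field_size/2)(SSD + d)/SSD``.
    The grid must extend beyond the projected edges on both sides.
    """
    positions = np.asarray(positions, dtype=float)
    if not field_size > 0:
        raise ValueError("field_size must be > 0")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    edge = 0.5 * field_size * (model.ssd + depth) / model.ssd
    if positions.min() > -edge or positions.max() < edge:
        raise ValueError("profile grid must span beyond the projected field edge")

    def shape(x):
        x = np.abs(np.asarray(x, dtype=float))
        cone = np.maximum(1.0 - model.cone_slope * x, 0.0)
        roll = 0.5 * erfc((x - edge) / (np.sqrt(2.0) * model.penumbra_sigma))
        return cone * roll

    scale = _corrected_cax_scale(cal) / model.depth_shape(model.dmax)
    s_cax = scale * float(model.depth_shape(depth))
    s_true = s_cax * shape(positions) / float(shape(0.0))
    s_star, pion = _true_to_uncorrected(s_true, cal)
    rng = np.random.default_rng(seed)
    noisy = _apply_noise(s_star, noise_sd, rng)
    curve = ScanCurve(
        axis="crossplane",
        positions=positions,
        signals=noisy,
        energy_label=cal.energy_label,
        field_size_cm=field_size,
        geometry="SSD",
        nominal_distance_cm=model.ssd,
        depth_cm=depth,
    )
    return curve, TruthRecord(s_true, pion, s_star, cal, seed)


def generate_two_voltage_set(
    s_star_values,
    cal: PionCalibration,
    v_high: float = 300.0,
    v_low: float = 150.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[TwoVoltageReading], TruthRecord]:
    """Generate two-voltage reading pairs consistent with the calibration.

    For each uncorrected signal S*, the true Pion is ``m S* + b``; the
    high-voltage reading is S* itself (reference units) and the
    low-voltage reading is the exact Boag inverse

        M*low = M*high / ( Vr + (1 - Vr)/Pion ),   Vr = v_high/v_low,

    so the two-voltage estimator recovers the true Pion to machine
    precision on noiseless data. Noise is multiplicative Gaussian,
    independent between the two readings.
    """
    s_star = np.asarray(s_star_values, dtype=float)
    if np.any(s_star <= 0):
        raise ValueError("s_star values must be > 0 to form reading pairs")
    if not v_high > v_low > 0:
        raise ValueError("require v_high > v_low > 0")
    vr = v_high / v_low
    pion = cal.slope_m * s_star + cal.intercept_b
    if np.any(pion <= (vr - 1.0) / vr):
        raise ValueError(
            f"Pion at or below the two-voltage limit (Vr-1)/Vr = {(vr - 1) / vr:g}"
        )
    m_high = s_star.copy()
    m_low = m_high / (vr + (1.0 - vr) / pion)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        m_high = m_high * (1.0 + rng.normal(0.0, noise_sd, m_high.shape))
        m_low = m_low * (1.0 + rng.normal(0.0, noise_sd, m_low.shape))
    readings = [
        TwoVoltageReading(v_high=v_high, v_low=v_low, m_high=float(h), m_low=float(l))
        for h, l in zip(m_high, m_low)
    ]
    truth = TruthRecord(pion * s_star, pion, s_star, cal, seed)
    return readings, truth


def generate_mu_rate_set(
    mu_rates=(400.0, 800.0, 1200.0, 1600.0, 2400.0),
    true_pion: float = 1.010,
    noise_sd: float = 5e-4,
    reps: int = 10,
    seed: int = 7,
    trend_per_mu: float = 0.0,
) -> list[tuple[float, float]]:
    """Pion-vs-MU-rate samples under the null of rate independence.

    Constant ``true_pion`` across the requested rates with additive
    Gaussian noise, ``reps`` repeats per rate. ``trend_per_mu`` injects a
    deliberate linear dependence for power checks; the physical null is
    zero.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rates = np.repeat(np.asarray(mu_rates, dtype=float), reps)
    rng = np.random.default_rng(seed)
    pion = true_pion + trend_per_mu * rates + rng.normal(0.0, noise_sd, rates.shape)
    return list(zip(rates.tolist(), pion.tolist()))
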