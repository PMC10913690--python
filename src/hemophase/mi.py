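"""Per-window metabolic-index arithmetic.

The metabolic index couples arterial oxygen saturation and the cardiac-band
phase delay between the oxy- and deoxyhemoglobin pulsations:

    MI = SaO2 * (1 - SaO2) * |dtheta|

with SaO2 estimated from the fundamental amplitudes A_HbO2/(A_HbO2 + A_Hb),
and an optional perfusion-amplitude correction

    alpha = ((A_HbO2 + A_Hb) / (A_HbO2,0 + A_Hb,0)) ** (1 - 1/n),   MI' = alpha * MI

where n in (0, 1] models how the pulsatile path-length amplitude scales with
the slowly varying path length (n = 1 disables the correction exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple, Union

import numpy as np

from .errors import DomainError

QUALITY_OK = "ok"
QUALITY_LOW_SNR = "low_snr"
QUALITY_REJECTED = "rejected"


@dataclass
class WindowEstimate:
    """One analysis window's estimates (amplitudes in mM*cm, dtheta in rad)."""

    time_center: float
    a_hbo2: float
    a_hb: float
    sao2: float
    dtheta: float
    mi: float
    alpha: float = math.nan
    mi_corrected: float = math.nan
    quality: str = QUALITY_OK
    snr: float = math.nan
    frequency_hz: float = math.nan


@dataclass
class AlphaBaseline:
    """Normalization constants of the alpha correction.

    ``a0_sum`` is A_HbO2,0 + A_Hb,0 (mM*cm), by default the median pulsatile
    amplitude sum over a resting/fasting interval; ``provenance`` records
    whether it came from the config or was estimated from the baseline
    interval.
    """

    a0_sum: float
    n: float
    provenance: str = "baseline-interval"

    def __post_init__(self) -> None:
        if not self.a0_sum > 0:
            raise DomainError(f"a0_sum must be positive, got {self.a0_sum}")
        if not 0.0 < self.n <= 1.0:
            raise DomainError(f"alpha exponent n must be in (0, 1], got {self.n}")


ArrayLike = Union[float, np.ndarray]


def compute_sao2(a_hbo2: ArrayLike, a_hb: ArrayLike) -> ArrayLike:
    """Arterial oxygen saturation from the two fundamental amplitudes."""
    a_hbo2 = np.asarray(a_hbo2, dtype=float)
    a_hb = np.asarray(a_hb, dtype=float)
    if np.any(a_hbo2 < 0) or np.any(a_hb < 0):
        raise DomainError("amplitudes must be nonnegative")
    total = a_hbo2 + a_hb
    if np.any(total <= 0):
        raise DomainError("amplitude sum must be positive")
    out = a_hbo2 / total
    return float(out) if out.ndim == 0 else out


def wrap_phase(angle: ArrayLike) -> ArrayLike:
    """Wrap an angle (rad) to the interval (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    wrapped = np.angle(np.exp(1j * a))
    # np.angle returns [-pi, pi); map the -pi edge to +pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return float(wrapped) if wrapped.ndim == 0 else wrapped


def compute_phase_delay(peak) -> float:
    """Phase delay dtheta = phase(HbO2) - phase(Hb) at the cardiac peak, wrapped.

    Positive when the deoxyhemoglobin pulsation lags the oxyhemoglobin one.
    ``peak`` is a :class:`~hemophase.pulse.SpectralPeak` or any object with
    complex ``amp_hbo2`` / ``amp_hb`` attributes.
    """
    return float(wrap_phase(np.angle(peak.amp_hbo2) - np.angle(peak.amp_hb)))


def metabolic_index(sao2: ArrayLike, dtheta: ArrayLike) -> ArrayLike:
    """MI = SaO2 (1 - SaO2) |dtheta|; zero at full (de)saturation or zero delay."""
    s = np.asarray(sao2, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise DomainError("sao2 must lie in [0, 1]")
    out = s * (1.0 - s) * np.abs(np.asarray(dtheta, dtype=float))
    return float(out) if out.ndim == 0 else out


def alpha(a_hbo2: ArrayLike, a_hb: ArrayLike, baseline: AlphaBaseline) -> ArrayLike:
    """Perfusion-amplitude correction factor; identically 1 when n = 1."""
    total = np.asarray(a_hbo2, dtype=float) + np.asarray(a_hb, dtype=float)
    if np.any(total <= 0):
        raise DomainError("amplitude sum must be positive for alpha")
    out = (total / baseline.a0_sum) ** (1.0 - 1.0 / baseline.n)
    return float(out) if out.ndim == 0 else out


def corrected_index(mi: ArrayLike, alpha_value: ArrayLike) -> ArrayLike:
    """MI' = alpha * MI."""
    mi = np.asarray(mi, dtype=float)
    if np.any(mi < 0):
        raise DomainError("MI must be nonnegative")
    out = np.asarray(alpha_value, dtype=float) * mi
    return float(out) if out.ndim == 0 else out


def chb_ac_amplitude(a_hbo2: float, a_hb: float, path_length: float, dtheta: float) -> float:
    """Small-angle amplitude of the deoxyhemoglobin concentration pulsation.

    C_Hb,AC = (A_HbO2 + A_Hb) / L * SaO2 (1 - SaO2) |dtheta|.  Used as an
    oracle to validate the simulator and the small-angle approximation (the
    exact two-sinusoid difference has amplitude 2 sin(|dtheta|/2) in place of
    |dtheta|).
    """
    if path_length <= 0:
        raise DomainError("path length must be positive")
    s = compute_sao2(a_hbo2, a_hb)
    return (a_hbo2 + a_hb) / path_length * s * (1.0 - s) * abs(dtheta)


def saturation_factor(sao2: ArrayLike) -> ArrayLike:
    """The concave factor SaO2 (1 - SaO2); maximum 0.25 at SaO2 = 0.5."""
    s = np.asarray(sao2, dtype=float)
    out = s * (1.0 - s)
    return float(out) if out.ndim == 0 else out


def saturation_factor_range(sao2_lo: float, sao2_hi: float) -> Tuple[float, float, float]:
    """(min, max, max/min) of SaO2 (1 - SaO2) over a saturation interval.

    Over the physiological [0.88, 0.92] band this is (0.0736, 0.1056, ~1.4):
    the factor varies little, so MI trends are dominated by the phase delay.
    """
    if not 0 <= sao2_lo <= sao2_hi <= 1:
        raise DomainError("need 0 <= sao2_lo <= sao2_hi <= 1")
    grid = np.array([sao2_lo, sao2_hi, 0.5 if sao2_lo <= 0.5 <= sao2_hi else sao2_lo])
    vals = saturation_factor(grid)
    lo, hi = float(np.min(vals[:2])), float(np.max(vals))
    if lo <= 0:
        raise DomainError("saturation factor vanishes on the interval")
    return lo, hi, hi / lo


def measurement_time_bounds(
    hr_bpm: Tuple[float, float] = (60.0, 100.0),
    beats_per_set: int = 4,
    sets: Tuple[int, int] = (3, 5),
) -> Tuple[float, float]:
    """Min/max seconds to acquire the window sets for one stable MI value.

    With 3 to 5 sets of ~4 heartbeats each at adult resting rates of
    60-100 bpm this is 3*4*0.6 = 7.2 s up to 5*4*1.0 = 20 s.
    """
    if hr_bpm[0] <= 0 or hr_bpm[1] < hr_bpm[0]:
        raise DomainError("invalid heart-rate range")
    t_min = sets[0] * beats_per_set * 60.0 / hr_bpm[1]
    t_max = sets[1] * beats_per_set * 60.0 / hr_bpm[0]
    return t_min, t_max
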