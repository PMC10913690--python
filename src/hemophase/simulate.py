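"""Forward hemodynamic simulator with known ground truth.

Generates two-channel PPG intensities from the same signal model the inverse
pipeline assumes: oxy/deoxy AC NIRS signals are common-frequency sinusoids

    N_HbO2,AC(t) = A_HbO2(t) sin(phi(t)),
    N_Hb,AC(t)  = A_Hb(t)  sin(phi(t) - dtheta(t)),

with a shared pulsatile path length L_AC(t) = (N_HbO2,AC + N_Hb,AC) / c0
(total hemoglobin is conserved, so the concentration pulsations cancel:
c_HbO2,AC + c_Hb,AC = 0 holds exactly by construction). The c*L products are
mapped through the extinction matrix to absorbances, exponentiated to
intensities, and degraded with multiplicative source drift, additive noise
and optional quantization. Every intermediate is returned as ground truth so
each inverse stage can be tested without any recorded data.

Noise convention: ``noise_rel`` is the additive white-noise standard
deviation relative to the per-channel *pulsatile* (AC) intensity amplitude —
the scale PPG signal quality is normally quoted on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import expit
from scipy.stats import pearsonr

from .config import PipelineConfig
from .errors import ConfigError, DomainError
from .io import GlucoseSeries, PPGRecord
from .mbll import ExtinctionMatrix, default_extinction

DthetaSpec = Union[float, Callable[[np.ndarray], np.ndarray]]


@dataclass
class SimulationParams:
    """Physical and degradation parameters of one synthetic acquisition.

    Defaults describe a resting fingertip at 75 bpm: SaO2 0.90 (shallow
    capillary-rich sites read lower than pulse-oximeter SpO2), total
    hemoglobin c0 = 2.3 mM, baseline path length 1 cm with a 2% pulsatile
    amplitude (perfusion-index scale), a 0.1 rad phase delay, ±5% slow
    heart-rate modulation, a 30% second harmonic, and noise at 5% of the
    pulsatile intensity amplitude.
    """

    seed: int
    duration_s: float = 30.0
    sample_rate: float = 100.0
    heart_rate_hz: float = 1.25
    hrv_frac: float = 0.05
    hrv_period_s: float = 30.0
    c0_mM: float = 2.3
    sao2: float = 0.90
    l_lf_cm: float = 1.0
    l_ac_amplitude_cm: float = 0.02
    dtheta_rad: DthetaSpec = 0.10
    harmonic_frac: float = 0.3
    drift_frac: float = 0.0
    drift_period_s: float = 60.0
    noise_rel: float = 0.05
    quant_bits: Optional[int] = None
    base_intensity: float = 10000.0
    perfusion_mod_frac: float = 0.0
    perfusion_exponent: float = 0.5
    perfusion_period_s: float = 1200.0
    wavelengths: tuple = (650.0, 930.0)
    extinction: Optional[ExtinctionMatrix] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory for reproducible simulation")
        if not 0.0 < self.sao2 < 1.0:
            raise ConfigError(f"sao2 must be in (0, 1), got {self.sao2}")
        if self.l_ac_amplitude_cm / self.l_lf_cm >= 0.05:
            raise ConfigError(
                "pulsatile path amplitude must stay well below the baseline "
                f"(l_ac/l_lf = {self.l_ac_amplitude_cm / self.l_lf_cm:.3f} >= 0.05)"
            )
        if isinstance(self.dtheta_rad, (int, float)) and abs(self.dtheta_rad) >= math.pi / 4:
            raise ConfigError(f"|dtheta| must be below pi/4, got {self.dtheta_rad}")
        if not 0.0 < self.perfusion_exponent <= 1.0:
            raise ConfigError("perfusion_exponent must be in (0, 1]")
        if self.duration_s <= 0 or self.sample_rate <= 0 or self.heart_rate_hz <= 0:
            raise ConfigError("duration, sample_rate and heart_rate must be positive")


@dataclass
class SimulationTruth:
    """Noiseless ground truth attached to a synthetic record."""

    times: np.ndarray
    sao2: np.ndarray
    dtheta: np.ndarray
    mi: np.ndarray
    a_hbo2: np.ndarray
    a_hb: np.ndarray
    n_hbo2_ac: np.ndarray
    n_hb_ac: np.ndarray
    l_ac: np.ndarray
    l_lf: np.ndarray
    c0: float
    beat_times: np.ndarray


def _phase(t: np.ndarray, p: SimulationParams) -> np.ndarray:
    """Integrated cardiac phase with slow sinusoidal heart-rate modulation."""
    f0, h, T = p.heart_rate_hz, p.hrv_frac, p.hrv_period_s
    if h == 0:
        return 2 * np.pi * f0 * t
    return 2 * np.pi * (f0 * t - f0 * h * T / (2 * np.pi) * (np.cos(2 * np.pi * t / T) - 1.0))


def _eval_dtheta(spec: DthetaSpec, t: np.ndarray) -> np.ndarray:
    if callable(spec):
        out = np.broadcast_to(np.asarray(spec(t), dtype=float), t.shape).copy()
    else:
        out = np.full_like(t, float(spec))
    if np.max(np.abs(out)) >= math.pi / 4:
        raise ConfigError("dtheta profile leaves the small-delay regime (|dtheta| >= pi/4)")
    return out


def simulate_window(params: SimulationParams) -> Tuple[PPGRecord, SimulationTruth]:
    """Forward-simulate one acquisition; returns the record and full truth.

    With ``perfusion_mod_frac > 0`` the baseline path length is slowly
    modulated and the pulsatile amplitude follows it with the configured
    power exponent, while the deoxyhemoglobin pulsation amplitude (the
    oxygen-consumption signal) is held at its coupled target — the raw phase
    delay then inherits the perfusion distortion that the alpha correction
    is designed to remove.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.sample_rate))
    t = np.arange(n) / p.sample_rate
    phase = _phase(t, p)
    dtheta = _eval_dtheta(p.dtheta_rad, t)

    l_lf = p.l_lf_cm * np.ones_like(t)
    l_ac_amp = p.l_ac_amplitude_cm * np.ones_like(t)
    if p.perfusion_mod_frac:
        mod = 1.0 + p.perfusion_mod_frac * np.sin(2 * np.pi * t / p.perfusion_period_s)
        l_lf = p.l_lf_cm * mod
        l_ac_amp = p.l_ac_amplitude_cm * mod**p.perfusion_exponent
        # hold C_Hb,AC at its coupled target: dtheta absorbs the perfusion change
        dtheta = dtheta * (p.l_ac_amplitude_cm / l_ac_amp) * (l_lf / p.l_lf_cm)

    a_sum = p.c0_mM * l_ac_amp
    a_hbo2 = p.sao2 * a_sum
    a_hb = (1.0 - p.sao2) * a_sum
    h = p.harmonic_frac
    n1 = a_hbo2 * (np.sin(phase) + h * np.sin(2 * phase))
    n2 = a_hb * (np.sin(phase - dtheta) + h * np.sin(2 * phase - 2 * dtheta))
    l_ac = (n1 + n2) / p.c0_mM  # pulsatile path length, conservation by construction

    # full concentration x path products (LF + AC), relative absorbance, intensities
    c1_lf = p.sao2 * p.c0_mM
    c2_lf = (1.0 - p.sao2) * p.c0_mM
    prod1 = c1_lf * l_lf + n1
    prod2 = c2_lf * l_lf + n2
    eps = p.extinction or default_extinction(p.wavelengths)
    da = eps.matrix @ np.vstack([prod1 - prod1[0], prod2 - prod2[0]])
    base = np.power(10.0, -da) if eps.log_base == "10" else np.exp(-da)
    intensities = p.base_intensity * base
    # LF-only intensity (pulsatile NIRS components removed): the pulsatile
    # amplitude anchoring the noise scale is measured against this, so slow
    # perfusion/path drifts do not inflate the noise.
    prod1_lf = c1_lf * l_lf
    prod2_lf = c2_lf * l_lf
    da_lf = eps.matrix @ np.vstack([prod1_lf - prod1[0], prod2_lf - prod2[0]])
    base_lf = np.power(10.0, -da_lf) if eps.log_base == "10" else np.exp(-da_lf)
    intensities_lf = p.base_intensity * base_lf

    channels = []
    drift_phases = (0.0, np.pi / 2)
    for ch, ch_lf, phi0 in zip(intensities, intensities_lf, drift_phases):
        ac_amp_i = math.sqrt(2.0) * float(np.std(ch - ch_lf))
        out = ch
        if p.drift_frac:
            out = out * (1.0 + p.drift_frac * np.sin(2 * np.pi * t / p.drift_period_s + phi0))
        if p.noise_rel:
            out = out + rng.normal(0.0, p.noise_rel * ac_amp_i, n)
        out = np.maximum(out, 1e-6 * p.base_intensity)
        if p.quant_bits is not None:
            step = 2.0 * p.base_intensity / 2**p.quant_bits
            out = np.round(out / step) * step
        channels.append(out)

    record = PPGRecord(
        sample_rate=p.sample_rate,
        times=t,
        channel_a=channels[0],
        channel_b=channels[1],
        labels=tuple(f"{w:g}nm" for w in p.wavelengths),
    )
    # true beat boundaries: trough instants of sin(phase), phase = 3pi/2 (mod 2pi)
    k0 = math.ceil((phase[0] - 1.5 * np.pi) / (2 * np.pi))
    k1 = math.floor((phase[-1] - 1.5 * np.pi) / (2 * np.pi))
    targets = 1.5 * np.pi + 2 * np.pi * np.arange(k0, k1 + 1)
    beat_times = np.interp(targets, phase, t)
    truth = SimulationTruth(
        times=t,
        sao2=np.full_like(t, p.sao2),
        dtheta=dtheta,
        mi=p.sao2 * (1.0 - p.sao2) * np.abs(dtheta),
        a_hbo2=a_hbo2,
        a_hb=a_hb,
        n_hbo2_ac=n1,
        n_hb_ac=n2,
        l_ac=l_ac,
        l_lf=l_lf,
        c0=p.c0_mM,
        beat_times=beat_times,
    )
    return record, truth


# ------------------------------------------------------------------- sessions


def oral_challenge_profile(
    t,
    baseline_mgdl: float = 90.0,
    rise_mgdl: float = 70.0,
    challenge_s: float = 1800.0,
    rise_tau_s: float = 300.0,
    fall_tau_s: float = 700.0,
    fall_after_s: float = 2700.0,
):
    """Double-sigmoid oral-challenge glucose profile (mg/dL).

    Fasting baseline, a rise beginning ~10 min after the challenge instant,
    and a slower decay — the canonical shape of a sugary-drink test.
    """
    t = np.asarray(t, dtype=float)
    up = expit((t - challenge_s - 600.0) / rise_tau_s)
    down = expit((t - challenge_s - fall_after_s) / fall_tau_s)
    out = baseline_mgdl + rise_mgdl * (up - down * up)
    return float(out) if out.ndim == 0 else out


def flat_profile(t, baseline_mgdl: float = 90.0):
    """Sugar-free control: constant glucose."""
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, baseline_mgdl)
    return float(out) if out.ndim == 0 else out


@dataclass
class LinearGlucoseCoupling:
    """Linear glucose -> phase-delay map at the observed scale.

    Default gain 0.1 rad per 40 mg/dL — the magnitude reported for the
    fingertip measurements — on top of a small positive resting delay. The
    physiological transfer function is unknown; this stand-in only has to
    produce delays of the observed size and sign.
    """

    gain_rad_per_mgdl: float = 0.1 / 40.0
    baseline_glucose_mgdl: float = 90.0
    baseline_dtheta_rad: float = 0.05

    def __post_init__(self) -> None:
        if self.gain_rad_per_mgdl <= 0:
            raise ConfigError("coupling must be monotone increasing (gain > 0)")

    def __call__(self, glucose_mgdl):
        g = np.asarray(glucose_mgdl, dtype=float)
        out = self.baseline_dtheta_rad + self.gain_rad_per_mgdl * (g - self.baseline_glucose_mgdl)
        return float(out) if out.ndim == 0 else out


def session_params(seed: int, duration_s: float = 5400.0, **overrides) -> SimulationParams:
    """Session-flavored defaults: 90 min, mild drift, moderate noise."""
    defaults = dict(drift_frac=0.02, drift_period_s=300.0, noise_rel=0.05)
    defaults.update(overrides)
    return SimulationParams(seed=seed, duration_s=duration_s, **defaults)


def simulate_session(
    params: SimulationParams,
    glucose_profile: Optional[Callable] = None,
    coupling: Optional[Callable] = None,
    sensor_delay_s: float = 0.0,
    cgm_period_s: float = 60.0,
) -> Tuple[PPGRecord, GlucoseSeries, SimulationTruth]:
    """Oral-challenge-style session: glucose drives the phase delay.

    The reference series mimics a CGM: readings every ``cgm_period_s``
    seconds, each reporting the glucose of ``sensor_delay_s`` seconds
    earlier, with the delay recorded in ``GlucoseSeries.delay_s``.
    """
    glucose_profile = glucose_profile or oral_challenge_profile
    coupling = coupling or LinearGlucoseCoupling(
        baseline_glucose_mgdl=float(glucose_profile(0.0))
    )
    dtheta_fn = lambda t: coupling(glucose_profile(t))  # noqa: E731
    record, truth = simulate_window(replace(params, dtheta_rad=dtheta_fn))
    cgm_times = np.arange(0.0, params.duration_s + 1e-9, cgm_period_s)[1:]
    glucose = GlucoseSeries(
        times=cgm_times,
        values=np.asarray(glucose_profile(cgm_times - sensor_delay_s), dtype=float),
        delay_s=float(sensor_delay_s),
    )
    return record, glucose, truth


# ---------------------------------------------------------- alpha exponent sweep


def sweep_alpha_exponent(
    estimates: Sequence,
    glucose: GlucoseSeries,
    n_grid: Sequence[float],
    config: Optional[PipelineConfig] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Correlation r(n) of the alpha-corrected trend against the reference.

    Re-evaluates MI' for each exponent on the same window estimates (baseline
    amplitude sum re-used across the grid), post-processes, interpolates onto
    the compensated reference grid and returns Pearson r per n. r at n = 1
    equals the uncorrected correlation exactly (alpha is identically 1).
    """
    from dataclasses import replace as dc_replace

    from .mi import QUALITY_OK, AlphaBaseline
    from .mi import alpha as alpha_factor
    from .pipeline import compute_a0_sum
    from .postprocess import chunk_and_average, compensate_delay, interpolate_to, smooth_series

    config = config or PipelineConfig()
    n_grid = np.asarray(list(n_grid), dtype=float)
    if np.any((n_grid <= 0) | (n_grid > 1)):
        raise DomainError("alpha exponents must lie in (0, 1]")
    a0 = compute_a0_sum(estimates, config)
    g = compensate_delay(glucose) if glucose.delay_s else glucose
    r_values = np.empty_like(n_grid)
    for i, n in enumerate(n_grid):
        baseline = AlphaBaseline(a0_sum=a0, n=float(n), provenance="sweep")
        corrected = [
            dc_replace(
                e,
                alpha=alpha_factor(e.a_hbo2, e.a_hb, baseline),
                mi_corrected=alpha_factor(e.a_hbo2, e.a_hb, baseline) * e.mi,
            )
            if e.quality == QUALITY_OK and np.isfinite(e.a_hbo2 + e.a_hb)
            else e
            for e in estimates
        ]
        series = smooth_series(
            chunk_and_average(
                corrected,
                chunk_s=config.chunk_s,
                value_field="mi_corrected",
                iqr_factor=config.outlier_iqr_factor,
                max_reject_frac=config.outlier_max_frac,
            ),
            config,
        )
        mi_at = interpolate_to(series.times, series.smoothed, g.times)
        mask = np.isfinite(mi_at)
        r_values[i] = pearsonr(mi_at[mask], g.values[mask]).statistic
    return n_grid, r_values
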