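"""End-to-end orchestration: PPG record -> per-window estimates.

The chain is: absorbance change -> MBLL inversion -> zero-phase band-pass ->
trough detection on the oxyhemoglobin channel -> non-overlapping windows of
a fixed beat count -> FFT fundamental -> SaO2, phase delay, MI -> alpha
correction against a resting-baseline amplitude sum. Low-SNR and
low-amplitude windows are flagged, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .errors import InsufficientDataError, InsufficientSignalError
from .io import PPGRecord
from .mbll import absorbance_change, invert_mbll, resolve_extinction
from .mi import (
    QUALITY_LOW_SNR,
    QUALITY_OK,
    QUALITY_REJECTED,
    AlphaBaseline,
    WindowEstimate,
    alpha,
    compute_phase_delay,
    compute_sao2,
    metabolic_index,
)
from .postprocess import MISeries, chunk_and_average, smooth_series
from .pulse import design_bandpass, detect_pulse_boundaries, main_peak, spectrum, trim_to_boundaries

logger = logging.getLogger(__name__)


@dataclass
class ProcessResult:
    """Window estimates plus run bookkeeping for the manifest."""

    estimates: List[WindowEstimate]
    baseline: Optional[AlphaBaseline]
    filter_order: int
    n_windows: int
    n_ok: int
    n_low_snr: int
    n_rejected: int

    def minute_series(self, config: Optional[PipelineConfig] = None, corrected: bool = False) -> MISeries:
        """Post-processed per-minute trend (raw robust means + smoothing)."""
        config = config or PipelineConfig()
        series = chunk_and_average(
            self.estimates,
            chunk_s=config.chunk_s,
            value_field="mi_corrected" if corrected else "mi",
            iqr_factor=config.outlier_iqr_factor,
            max_reject_frac=config.outlier_max_frac,
        )
        return smooth_series(series, config)


def extract_window_estimates(
    record: PPGRecord, config: Optional[PipelineConfig] = None
) -> Tuple[List[WindowEstimate], dict]:
    """Run the spectral front half over non-overlapping beat windows."""
    config = config or PipelineConfig()
    eps = resolve_extinction(config)
    reference = (float(record.channel_a.mean()), float(record.channel_b.mean()))
    da = absorbance_change(record, reference, log_base=eps.log_base)
    nirs = invert_mbll(da, eps, times=record.times, sample_rate=record.sample_rate)

    sos, order = design_bandpass(record.sample_rate, config)
    ac_hbo2 = sps.sosfiltfilt(sos, nirs.n_hbo2)
    ac_hb = sps.sosfiltfilt(sos, nirs.n_hb)

    boundaries = detect_pulse_boundaries(
        ac_hbo2, record.sample_rate, hr_band=config.hr_band_hz, min_beats=config.beats_per_window
    )
    # keep clear of filtfilt edge transients
    t0, t1 = record.times[0] + config.edge_margin_s, record.times[-1] - config.edge_margin_s
    in_span = (record.times[boundaries] >= t0) & (record.times[boundaries] <= t1)
    boundaries = boundaries[in_span]
    k = config.beats_per_window
    if boundaries.size < k + 1:
        raise InsufficientSignalError(
            f"only {max(boundaries.size - 1, 0)} usable beats; need >= {k}"
        )

    estimates: List[WindowEstimate] = []
    for start in range(0, boundaries.size - k, k):
        sub = boundaries[start : start + k + 1]
        window = trim_to_boundaries(record.times, ac_hbo2, ac_hb, sub)
        spec = spectrum(window)
        peak = main_peak(spec, hr_band=config.hr_band_hz, floor_band=config.bpf_passband_hz)
        t_center = 0.5 * (window.start_time + window.end_time)
        a_sum = peak.a_hbo2 + peak.a_hb
        if a_sum < config.amplitude_floor:
            quality = QUALITY_REJECTED  # hypoperfusion guard
        elif peak.snr < config.snr_min:
            quality = QUALITY_LOW_SNR
        else:
            quality = QUALITY_OK
        if a_sum > 0:
            sao2 = compute_sao2(peak.a_hbo2, peak.a_hb)
            dtheta = compute_phase_delay(peak)
            mi = metabolic_index(sao2, dtheta)
        else:
            sao2 = dtheta = mi = float("nan")
        estimates.append(
            WindowEstimate(
                time_center=t_center,
                a_hbo2=peak.a_hbo2,
                a_hb=peak.a_hb,
                sao2=sao2,
                dtheta=dtheta,
                mi=mi,
                quality=quality,
                snr=peak.snr,
                frequency_hz=peak.frequency,
            )
        )
    meta = {
        "filter_order": order,
        "extinction_source": eps.source,
        "extinction_condition_number": eps.condition_number,
        "n_boundaries": int(boundaries.size),
    }
    return estimates, meta


def compute_a0_sum(estimates: Sequence[WindowEstimate], config: PipelineConfig) -> float:
    """Baseline amplitude sum A_HbO2,0 + A_Hb,0.

    Explicit config value if given, else the median amplitude sum of
    quality-ok windows inside the resting/fasting interval at the session
    start (falling back to all ok windows when the interval is empty).
    """
    if config.a0_sum is not None:
        return float(config.a0_sum)
    ok = [e for e in estimates if e.quality == QUALITY_OK and np.isfinite(e.a_hbo2 + e.a_hb)]
    if not ok:
        raise InsufficientDataError("no quality-ok windows to estimate the alpha baseline from")
    t_start = min(e.time_center for e in ok)
    in_interval = [e for e in ok if e.time_center <= t_start + config.baseline_interval_s]
    pool = in_interval or ok
    return float(np.median([e.a_hbo2 + e.a_hb for e in pool]))


def attach_alpha(
    estimates: Sequence[WindowEstimate], config: Optional[PipelineConfig] = None
) -> AlphaBaseline:
    """Fill in alpha and MI' on each estimate; returns the baseline used."""
    config = config or PipelineConfig()
    baseline = AlphaBaseline(
        a0_sum=compute_a0_sum(estimates, config),
        n=config.alpha_n,
        provenance="config" if config.a0_sum is not None else "baseline-interval",
    )
    for e in estimates:
        total = e.a_hbo2 + e.a_hb
        if e.quality != QUALITY_REJECTED and np.isfinite(total) and total > 0:
            e.alpha = float(alpha(e.a_hbo2, e.a_hb, baseline))
            e.mi_corrected = e.alpha * e.mi
        else:
            e.alpha = float("nan")
            e.mi_corrected = float("nan")
    return baseline


def process_record(record: PPGRecord, config: Optional[PipelineConfig] = None) -> ProcessResult:
    """Full per-window processing of one record, with alpha correction."""
    config = config or PipelineConfig()
    estimates, meta = extract_window_estimates(record, config)
    baseline = None
    try:
        baseline = attach_alpha(estimates, config)
    except InsufficientDataError:
        logger.warning("no quality-ok windows; alpha correction skipped")
    n_ok = sum(e.quality == QUALITY_OK for e in estimates)
    n_low = sum(e.quality == QUALITY_LOW_SNR for e in estimates)
    n_rej = sum(e.quality == QUALITY_REJECTED for e in estimates)
    logger.info(
        "processed %d windows (%d ok, %d low-SNR, %d rejected), filter order %d",
        len(estimates), n_ok, n_low, n_rej, meta["filter_order"],
    )
    return ProcessResult(
        estimates=estimates,
        baseline=baseline,
        filter_order=meta["filter_order"],
        n_windows=len(estimates),
        n_ok=n_ok,
        n_low_snr=n_low,
        n_rejected=n_rej,
    )
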