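"""Back half of the chain: minute-level trend extraction.

Window estimates are pooled into fixed-length chunks (1 min by default),
robustly averaged (1.5 x IQR outlier rule within each chunk), smoothed with a
Savitzky-Golay filter (order 1, window 29 one-minute points by default) and
finally interpolated onto the reference timestamps after compensating the
reference sensor's constant delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .config import PipelineConfig
from .errors import DomainError, InsufficientDataError
from .mi import QUALITY_OK, WindowEstimate

logger = logging.getLogger(__name__)


@dataclass
class MISeries:
    """Per-chunk MI trend: raw robust means, smoothed values, bookkeeping."""

    times: np.ndarray  # chunk-center times, s
    raw: np.ndarray  # NaN where the chunk is missing
    smoothed: Optional[np.ndarray]
    counts: np.ndarray  # windows contributing per chunk
    rejected: np.ndarray  # outliers removed per chunk


def _iqr_mask(values: np.ndarray, factor: float) -> np.ndarray:
    """True for values inside [Q1 - f*IQR, Q3 + f*IQR] (linear percentiles)."""
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    return (values >= lo) & (values <= hi)


def chunk_and_average(
    estimates: Sequence[WindowEstimate],
    chunk_s: float = 60.0,
    value_field: str = "mi",
    iqr_factor: float = 1.5,
    max_reject_frac: float = 0.4,
) -> MISeries:
    """Robust per-chunk means of quality-ok window values.

    The IQR rule is applied within each chunk (chunks of fewer than 4 values
    are kept as-is — quartiles of 2-3 points reject nothing meaningful).
    A chunk whose rule would discard more than ``max_reject_frac`` of its
    values is marked missing rather than averaged from a minority.
    """
    if chunk_s <= 0:
        raise DomainError("chunk_s must be positive")
    ok = [e for e in estimates if e.quality == QUALITY_OK]
    times = np.array([e.time_center for e in ok])
    if times.size and np.any(np.diff(times) < 0):
        raise DomainError("estimates must be time-sorted")
    values = np.array([getattr(e, value_field) for e in ok], dtype=float)
    finite = np.isfinite(values)
    times, values = times[finite], values[finite]
    if times.size == 0:
        raise InsufficientDataError("no usable window estimates to average")

    first = int(np.floor(times.min() / chunk_s))
    last = int(np.floor(times.max() / chunk_s))
    centers, raw, counts, rejected = [], [], [], []
    for j in range(first, last + 1):
        lo, hi = j * chunk_s, (j + 1) * chunk_s
        centers.append(lo + chunk_s / 2.0)
        in_chunk = values[(times >= lo) & (times < hi)]
        if in_chunk.size == 0:
            raw.append(np.nan)
            counts.append(0)
            rejected.append(0)
            continue
        if in_chunk.size >= 4:
            keep = _iqr_mask(in_chunk, iqr_factor)
        else:
            keep = np.ones(in_chunk.size, dtype=bool)
        n_rej = int(in_chunk.size - keep.sum())
        if n_rej > max_reject_frac * in_chunk.size:
            raw.append(np.nan)  # too contaminated to trust a minority mean
            counts.append(int(in_chunk.size))
            rejected.append(n_rej)
            continue
        raw.append(float(in_chunk[keep].mean()))
        counts.append(int(in_chunk.size))
        rejected.append(n_rej)

    raw_arr = np.array(raw, dtype=float)
    if not np.any(np.isfinite(raw_arr)):
        raise InsufficientDataError("all chunks empty after quality/outlier screening")
    return MISeries(
        times=np.array(centers),
        raw=raw_arr,
        smoothed=None,
        counts=np.array(counts, dtype=int),
        rejected=np.array(rejected, dtype=int),
    )


def savgol_smooth(values: np.ndarray, order: int = 1, window: int = 29) -> np.ndarray:
    """Savitzky-Golay smoothing of a finite 1-D series.

    Series shorter than the window shrink it to the largest valid odd length
    (logged); edges are handled by evaluating the local polynomial fitted to
    the terminal window, so no data are invented by padding. An exactly
    linear input is reproduced exactly at order >= 1.
    """
    x = np.asarray(values, dtype=float)
    if window % 2 == 0 or window <= order:
        raise DomainError(f"window must be odd and > order (window={window}, order={order})")
    if not np.all(np.isfinite(x)):
        raise DomainError("savgol_smooth requires a finite series; bridge gaps first")
    if x.size <= order:
        return x.copy()
    if x.size < window:
        window = x.size if x.size % 2 == 1 else x.size - 1
        if window <= order:
            return x.copy()
        logger.info("Savitzky-Golay window shrunk to %d for a length-%d series", window, x.size)
    return savgol_filter(x, window_length=window, polyorder=order, mode="interp")


def smooth_series(series: MISeries, config: Optional[PipelineConfig] = None) -> MISeries:
    """Attach the smoothed trend, bridging only short gaps.

    Missing chunks are linearly interpolated before smoothing when the gap is
    at most ``max_gap_chunks`` long; longer gaps stay missing and split the
    series into independently smoothed runs (no trend fabrication across
    dropouts).
    """
    config = config or PipelineConfig()
    raw = series.raw.copy()
    finite = np.isfinite(raw)
    idx = np.arange(raw.size)
    bridged = raw.copy()
    # bridge interior gaps of <= max_gap_chunks missing chunks
    gap_start = None
    for i in range(raw.size):
        if not finite[i]:
            if gap_start is None:
                gap_start = i
        elif gap_start is not None:
            gap_len = i - gap_start
            if gap_start > 0 and gap_len <= config.max_gap_chunks:
                bridged[gap_start:i] = np.interp(
                    idx[gap_start:i], idx[finite], raw[finite]
                )
            gap_start = None
    smoothed = np.full_like(raw, np.nan)
    ok = np.isfinite(bridged)
    # smooth each contiguous finite run separately
    run_start = None
    for i in range(raw.size + 1):
        inside = i < raw.size and ok[i]
        if inside and run_start is None:
            run_start = i
        elif not inside and run_start is not None:
            smoothed[run_start:i] = savgol_smooth(
                bridged[run_start:i], order=config.savgol_order, window=config.savgol_window
            )
            run_start = None
    return replace(series, smoothed=smoothed)


def interpolate_to(
    times: np.ndarray, values: np.ndarray, target_times: np.ndarray
) -> np.ndarray:
    """Linear interpolation onto target timestamps; exact at knots.

    Targets outside the finite support return NaN — the series is never
    extrapolated.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.asarray(target_times, dtype=float)
    finite = np.isfinite(values)
    if not np.any(finite):
        return np.full(targets.shape, np.nan)
    t, v = times[finite], values[finite]
    out = np.interp(targets, t, v)
    out = np.where((targets < t[0]) | (targets > t[-1]), np.nan, out)
    return out


def compensate_delay(glucose, delay_s: Optional[float] = None):
    """Shift reference timestamps by -delay_s to undo a constant sensor lag.

    A CGM reading timestamped t reflects blood at t - delay, so the
    compensated series re-labels it accordingly. ``delay_s=None`` uses the
    series' own ``delay_s`` tag; the returned series carries ``delay_s=0``.
    """
    d = glucose.delay_s if delay_s is None else float(delay_s)
    if not np.isfinite(d):
        raise DomainError("delay_s must be finite")
    return type(glucose)(times=glucose.times - d, values=glucose.values.copy(), delay_s=0.0)
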