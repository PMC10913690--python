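"""CSV readers/writers and the core time-series containers.

The ingestion boundary is deliberately plain: a two-channel PPG intensity CSV
(``time_s,ch_a,ch_b``) and an optional reference glucose CSV
(``time_s,glucose_mgdl``). How the intensities were produced (smartwatch
photodiodes, camera channel means, ...) is upstream of this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import FormatError, SamplingError
from .mi import QUALITY_REJECTED, WindowEstimate

#: tolerated deviation of successive timestamps from the nominal grid, seconds
GRID_TOL_S = 1e-6


@dataclass
class PPGRecord:
    """Uniformly sampled two-channel light-intensity time series.

    ``channel_a``/``channel_b`` are nonnegative detector readings in arbitrary
    units, oriented as *intensities* (decreasing at systole). ``labels`` tag
    each channel with its wavelength or color (e.g. ``"650nm"``, ``"red"``).
    """

    sample_rate: float
    times: np.ndarray
    channel_a: np.ndarray
    channel_b: np.ndarray
    labels: tuple = ("650nm", "930nm")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        if self.sample_rate <= 0:
            raise FormatError(f"sample_rate must be positive, got {self.sample_rate}")
        n = self.times.size
        if self.channel_a.size != n or self.channel_b.size != n:
            raise FormatError(
                "channel lengths differ from time axis "
                f"({self.channel_a.size}, {self.channel_b.size} vs {n})"
            )
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise FormatError("times must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.sample_rate) >= GRID_TOL_S):
                worst = float(np.max(np.abs(dt - 1.0 / self.sample_rate)))
                raise SamplingError(
                    f"non-uniform sampling: worst grid deviation {worst:.3g} s "
                    f"exceeds {GRID_TOL_S:.0e} s at {self.sample_rate} Hz"
                )
        if np.any(self.channel_a < 0) or np.any(self.channel_b < 0):
            raise FormatError("intensities must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n_samples else 0.0


@dataclass
class GlucoseSeries:
    """Reference glucose readings in mg/dL with an optional constant sensor delay."""

    times: np.ndarray
    values: np.ndarray
    delay_s: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise FormatError("glucose times and values differ in length")
        if self.times.size == 0:
            raise FormatError("empty glucose series")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise FormatError("glucose times must be strictly increasing")
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise FormatError("glucose values must be finite and positive (mg/dL)")


# --------------------------------------------------------------------------- PPG


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_ppg_csv(path, config: Optional[PipelineConfig] = None) -> PPGRecord:
    """Read a ``time_s,ch_a,ch_b`` CSV into a validated :class:`PPGRecord`.

    The sample rate is inferred from the median timestamp spacing and the
    grid then validated against it. With ``config.polarity == "inverted"``
    each channel is reflected (``max + min - x``) back to intensity
    orientation; only the AC content matters downstream, so the reflection
    offset is immaterial.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"PPG file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: empty PPG file")
    _require_columns(df, ("time_s", "ch_a", "ch_b"), path)
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    sample_rate = 1.0 / float(np.median(np.diff(times)))
    a = df["ch_a"].to_numpy(dtype=float)
    b = df["ch_b"].to_numpy(dtype=float)
    config = config or PipelineConfig()
    if config.polarity == "inverted":
        a = a.max() + a.min() - a
        b = b.max() + b.min() - b
    labels = tuple(f"{w:g}nm" for w in config.wavelengths)
    return PPGRecord(sample_rate=sample_rate, times=times, channel_a=a, channel_b=b, labels=labels)


def write_ppg_csv(record: PPGRecord, path) -> None:
    df = pd.DataFrame(
        {"time_s": record.times, "ch_a": record.channel_a, "ch_b": record.channel_b}
    )
    df.to_csv(path, index=False, float_format="%.9g")


# ----------------------------------------------------------------------- glucose


def read_glucose_csv(path, delay_s: float = 0.0) -> GlucoseSeries:
    """Read a ``time_s,glucose_mgdl`` CSV; ``delay_s`` is the sensor delay tag."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"glucose file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty glucose file") from exc
    if df.empty:
        raise FormatError(f"{path}: empty glucose file")
    _require_columns(df, ("time_s", "glucose_mgdl"), path)
    return GlucoseSeries(
        times=df["time_s"].to_numpy(dtype=float),
        values=df["glucose_mgdl"].to_numpy(dtype=float),
        delay_s=float(delay_s),
    )


def write_glucose_csv(series: GlucoseSeries, path) -> None:
    pd.DataFrame({"time_s": series.times, "glucose_mgdl": series.values}).to_csv(
        path, index=False, float_format="%.9g"
    )


# ----------------------------------------------------------------------- results

RESULT_COLUMNS = (
    "time_s",
    "mi",
    "mi_corrected",
    "sao2",
    "dtheta_rad",
    "quality",
    "a_hbo2",
    "a_hb",
    "alpha",
    "snr",
)


def write_results_csv(estimates: Sequence[WindowEstimate], path) -> None:
    """Write per-window estimates; values round-trip to 1e-9 relative.

    Printed with 12 significant digits (comfortably beyond the 9 the
    round-trip contract needs). Rows containing a NaN in any numeric
    estimate column are emitted with the cell empty and quality forced to
    ``"rejected"``.
    """
    rows = []
    for e in estimates:
        core = (e.mi, e.mi_corrected, e.sao2, e.dtheta)
        quality = e.quality
        if any(isinstance(v, float) and math.isnan(v) for v in core):
            quality = QUALITY_REJECTED
        rows.append(
            {
                "time_s": e.time_center,
                "mi": e.mi,
                "mi_corrected": e.mi_corrected,
                "sao2": e.sao2,
                "dtheta_rad": e.dtheta,
                "quality": quality,
                "a_hbo2": e.a_hbo2,
                "a_hb": e.a_hb,
                "alpha": e.alpha,
                "snr": e.snr,
            }
        )
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g", na_rep="")


def read_results_csv(path) -> list:
    """Read a results CSV back into :class:`WindowEstimate` objects."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"results file not found: {path}")
    df = pd.read_csv(path)
    _require_columns(df, RESULT_COLUMNS[:6], path)
    estimates = []
    for _, row in df.iterrows():
        estimates.append(
            WindowEstimate(
                time_center=float(row["time_s"]),
                a_hbo2=float(row.get("a_hbo2", np.nan)),
                a_hb=float(row.get("a_hb", np.nan)),
                sao2=float(row["sao2"]),
                dtheta=float(row["dtheta_rad"]),
                mi=float(row["mi"]),
                alpha=float(row.get("alpha", np.nan)),
                mi_corrected=float(row["mi_corrected"]),
                quality=str(row["quality"]),
                snr=float(row.get("snr", np.nan)),
            )
        )
    return estimates
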