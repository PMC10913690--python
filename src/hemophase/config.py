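"""Pipeline configuration.

All tunables of the processing chain live in one flat dataclass that can be
round-tripped through a YAML key-value file, so every run is reproducible from
its config snapshot alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Parameters of the PPG -> metabolic-index pipeline.

    Frequencies in Hz, times in seconds, extinction coefficients in
    1/(mM*cm). ``extinction`` is an explicit 2x2 row-per-channel matrix
    (columns HbO2, Hb); when ``None`` the embedded literature table is used
    for the configured wavelength pair.
    """

    # channels / chromophore inversion
    wavelengths: tuple = (650.0, 930.0)
    extinction: Optional[Sequence[Sequence[float]]] = None
    log_base: str = "10"  # "10" or "e"
    polarity: str = "intensity"  # "intensity" or "inverted" (raw ADC counts)

    # band-pass filter design spec (order chosen from this spec, then logged)
    bpf_passband_hz: tuple = (0.8, 10.0)
    bpf_stopband_hz: tuple = (0.4, 15.0)
    bpf_passband_loss_db: float = 3.0
    bpf_stopband_atten_db: float = 10.0

    # cardiac-fundamental search and windowing
    hr_band_hz: tuple = (0.7, 3.0)
    beats_per_window: int = 4
    edge_margin_s: float = 1.0
    snr_min: float = 10.0
    amplitude_floor: float = 1e-4  # mM*cm; guards false-hyperglycemia at low perfusion

    # alpha (perfusion-amplitude) correction
    alpha_n: float = 0.5
    baseline_interval_s: float = 600.0
    a0_sum: Optional[float] = None  # explicit A_HbO2,0 + A_Hb,0 override

    # post-processing
    chunk_s: float = 60.0
    outlier_iqr_factor: float = 1.5
    outlier_max_frac: float = 0.4
    max_gap_chunks: int = 3
    savgol_order: int = 1
    savgol_window: int = 29

    # reference handling
    glucose_delay_s: float = 0.0

    def __post_init__(self) -> None:
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        self.bpf_passband_hz = tuple(float(v) for v in self.bpf_passband_hz)
        self.bpf_stopband_hz = tuple(float(v) for v in self.bpf_stopband_hz)
        self.hr_band_hz = tuple(float(v) for v in self.hr_band_hz)
        if self.log_base not in ("10", "e"):
            raise ConfigError(f"log_base must be '10' or 'e', got {self.log_base!r}")
        if self.polarity not in ("intensity", "inverted"):
            raise ConfigError(f"polarity must be 'intensity' or 'inverted', got {self.polarity!r}")
        if not 0.0 < self.alpha_n <= 1.0:
            raise ConfigError(f"alpha exponent n must be in (0, 1], got {self.alpha_n}")
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ConfigError(
                "savgol_window must be odd and greater than savgol_order "
                f"(got window={self.savgol_window}, order={self.savgol_order})"
            )
        lo, hi = self.bpf_passband_hz
        slo, shi = self.bpf_stopband_hz
        if not (0 < slo < lo < hi < shi):
            raise ConfigError(
                "band-pass spec must satisfy 0 < stop_lo < pass_lo < pass_hi < stop_hi, "
                f"got passband {self.bpf_passband_hz}, stopband {self.bpf_stopband_hz}"
            )
        if not (0 < self.hr_band_hz[0] < self.hr_band_hz[1]):
            raise ConfigError(f"invalid heart-rate band {self.hr_band_hz}")
        if self.beats_per_window < 2:
            raise ConfigError("beats_per_window must be >= 2")
        if self.chunk_s <= 0:
            raise ConfigError("chunk_s must be positive")
        if not 0.0 <= self.outlier_max_frac < 1.0:
            raise ConfigError("outlier_max_frac must be in [0, 1)")
        if self.extinction is not None:
            self.extinction = [[float(v) for v in row] for row in self.extinction]
            if len(self.extinction) != 2 or any(len(r) != 2 for r in self.extinction):
                raise ConfigError("extinction must be a 2x2 matrix (rows=channels, cols=HbO2,Hb)")

    # ------------------------------------------------------------------ I/O

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("wavelengths", "bpf_passband_hz", "bpf_stopband_hz", "hr_band_hz"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must be a flat key-value mapping")
        return cls.from_mapping(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
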