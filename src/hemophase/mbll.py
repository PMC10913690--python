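"""Modified Beer-Lambert law (MBLL) inversion.

Two-channel intensity records are converted to absorbance changes
dA(lambda, t) = -log(I(lambda, t) / I_ref(lambda)) and then, through the 2x2
hemoglobin extinction matrix, to the oxy/deoxy "NIRS signals"

    N_HbO2(t), N_Hb(t) = Delta[c(t) * L(t)]   (mM*cm),

changes in concentration x optical path length relative to a reference
instant. The pipeline consumes only the cardiac-band AC content of these
signals, so the choice of reference intensity (any positive constant) only
shifts/offsets dA and is immaterial downstream; the differential path-length
factor is deliberately not modeled (path length is carried explicitly by the
signal model instead).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ConfigError, DomainError, SingularMatrixError

_SINGULAR_DET = 1e-9


@dataclass
class ExtinctionMatrix:
    """2x2 extinction coefficients, rows = channels, columns = (HbO2, Hb).

    Units 1/(mM*cm); ``log_base`` tags the logarithm convention the
    coefficients belong to ("10" for decadic molar extinction, "e" for
    natural-log absorption tables) so that :func:`absorbance_change` and the
    inversion stay mutually consistent.
    """

    matrix: np.ndarray
    labels: tuple = ("650nm", "930nm")
    log_base: str = "10"
    source: str = "user"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 2):
            raise ConfigError(f"extinction matrix must be 2x2, got {self.matrix.shape}")
        if np.any(self.matrix < 0):
            raise ConfigError("extinction coefficients must be nonnegative")
        if abs(float(np.linalg.det(self.matrix))) < _SINGULAR_DET:
            raise SingularMatrixError(
                f"extinction matrix for channels {self.labels} is singular "
                "(wavelengths too similar or duplicated?)"
            )

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.matrix))

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


@dataclass
class NIRSSignals:
    """Oxy/deoxy NIRS signals Delta[c*L] in mM*cm on the record's time grid."""

    times: np.ndarray
    n_hbo2: np.ndarray
    n_hb: np.ndarray
    sample_rate: float


def _extinction_table() -> pd.DataFrame:
    resource = importlib.resources.files("hemophase.data") / "extinction_coefficients.csv"
    with importlib.resources.as_file(resource) as path:
        return pd.read_csv(path)


def default_extinction(wavelength_pair: Sequence[float]) -> ExtinctionMatrix:
    """Embedded literature extinction matrix for a supported wavelength pair.

    Only pairs present in the packaged table (650/930 nm) are supported; any
    other pair — notably the camera pseudo-visible mode, whose matrix is
    device-specific — must be supplied explicitly in the config.
    """
    wl = tuple(float(w) for w in wavelength_pair)
    if wl[0] == wl[1]:
        raise SingularMatrixError(f"duplicate wavelength pair {wl} is singular by construction")
    table = _extinction_table()
    rows = []
    for w in wl:
        match = table[np.isclose(table["wavelength_nm"], w, atol=1.0)]
        if match.empty:
            raise ConfigError(
                f"no embedded extinction coefficients for {w} nm; "
                "supply an explicit 2x2 matrix in the config"
            )
        rows.append(match.iloc[0])
    matrix = np.array([[r["eps_hbo2"], r["eps_hb"]] for r in rows], dtype=float)
    return ExtinctionMatrix(
        matrix=matrix,
        labels=tuple(f"{w:g}nm" for w in wl),
        log_base="10",
        source="embedded literature table",
    )


def resolve_extinction(config: PipelineConfig) -> ExtinctionMatrix:
    """Extinction matrix from explicit config values or the embedded table."""
    if config.extinction is not None:
        return ExtinctionMatrix(
            matrix=np.asarray(config.extinction, dtype=float),
            labels=tuple(f"{w:g}nm" for w in config.wavelengths),
            log_base=config.log_base,
            source="config",
        )
    return default_extinction(config.wavelengths)


def absorbance_change(
    record, reference: Sequence[float], log_base: str = "10"
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-channel absorbance change dA = -log(I / I_ref).

    ``reference`` is one positive scalar per channel (conventionally the mean
    intensity over the analysis span). dA is dimensionless and zero wherever
    I equals the reference.
    """
    ref_a, ref_b = (float(r) for r in reference)
    if ref_a <= 0 or ref_b <= 0:
        raise DomainError(f"reference intensities must be positive, got ({ref_a}, {ref_b})")
    for name, ch in (("channel_a", record.channel_a), ("channel_b", record.channel_b)):
        if np.any(ch <= 0):
            raise DomainError(f"{name} contains nonpositive intensities; cannot take log")
    if log_base == "10":
        log = np.log10
    elif log_base == "e":
        log = np.log
    else:
        raise ConfigError(f"log_base must be '10' or 'e', got {log_base!r}")
    da_a = -log(record.channel_a / ref_a)
    da_b = -log(record.channel_b / ref_b)
    return da_a, da_b


def invert_mbll(
    delta_a: Tuple[np.ndarray, np.ndarray],
    eps: ExtinctionMatrix,
    times: Optional[np.ndarray] = None,
    sample_rate: float = float("nan"),
) -> NIRSSignals:
    """Solve eps @ [N_HbO2, N_Hb]^T = dA per time point (2x2 analytic inverse)."""
    da = np.vstack([np.asarray(delta_a[0], dtype=float), np.asarray(delta_a[1], dtype=float)])
    m = eps.matrix
    det = eps.determinant
    if abs(det) < _SINGULAR_DET:  # pragma: no cover - guarded at construction
        raise SingularMatrixError(f"extinction matrix for {eps.labels} is singular")
    inv = np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det
    n = inv @ da
    if times is None:
        times = np.arange(da.shape[1], dtype=float)
    return NIRSSignals(
        times=np.asarray(times, dtype=float),
        n_hbo2=n[0],
        n_hb=n[1],
        sample_rate=float(sample_rate),
    )


def forward_mbll(
    n_hbo2: np.ndarray, n_hb: np.ndarray, eps: ExtinctionMatrix
) -> Tuple[np.ndarray, np.ndarray]:
    """Forward map dA = eps @ [N_HbO2, N_Hb]^T (inverse of :func:`invert_mbll`)."""
    n = np.vstack([np.asarray(n_hbo2, dtype=float), np.asarray(n_hb, dtype=float)])
    da = eps.matrix @ n
    return da[0], da[1]
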