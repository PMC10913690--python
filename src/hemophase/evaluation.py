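"""Glucose agreement: calibration, MARD, RMSE and Parkes error-grid zoning.

The index-to-glucose calibration is ordinary least squares of reference
glucose on MI (a per-subject, per-study fit — no cross-subject transfer),
exposed as a scikit-learn regressor. Clinical risk is zoned with the Parkes
(consensus) error grid for type 1 diabetes, whose boundary polylines are
embedded as a versioned CSV resource; a point exactly on a boundary is
assigned to the lower-risk zone.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError, InsufficientDataError
from .io import GlucoseSeries
from .postprocess import MISeries, compensate_delay, interpolate_to

ZONE_LABELS = ("A", "B", "C", "D", "E")
_RISK = {"B": 1, "C": 2, "D": 3, "E": 4}
GRID_MAX_MGDL = 600.0


# ------------------------------------------------------------------ calibration


@dataclass
class CalibrationFit:
    """Linear least-squares map glucose = slope * MI + intercept."""

    slope: float  # mg/dL per MI unit
    intercept: float  # mg/dL
    r: float  # Pearson correlation of the fitted pairs
    n_points: int

    def predict(self, mi: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(mi, dtype=float) + self.intercept


class GlucoseCalibrator(RegressorMixin, BaseEstimator):
    """scikit-learn regressor wrapping the MI -> glucose least-squares fit.

    Fitted attributes: ``slope_`` (mg/dL per MI unit), ``intercept_``
    (mg/dL), ``r_`` (Pearson correlation, 0 when the reference is constant)
    and ``n_points_``.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        mask = np.isfinite(x) & np.isfinite(y)
        x, y = x[mask], y[mask]
        if x.size < 3:
            raise InsufficientDataError(f"calibration needs >= 3 finite pairs, got {x.size}")
        if np.ptp(x) == 0:
            raise DomainError("degenerate fit: MI values have zero variance")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_ = 0.0 if not np.isfinite(res.rvalue) else float(res.rvalue)
        self.n_points_ = int(x.size)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_

    def to_fit(self) -> CalibrationFit:
        return CalibrationFit(
            slope=self.slope_, intercept=self.intercept_, r=self.r_, n_points=self.n_points_
        )


def fit_calibration(mi_values, glucose_values) -> CalibrationFit:
    """OLS of glucose on MI; returns slope, intercept, Pearson r, point count."""
    return GlucoseCalibrator().fit(mi_values, glucose_values).to_fit()


# ---------------------------------------------------------------------- metrics


def mard(reference, estimate) -> float:
    """Mean absolute relative difference, percent of the reference."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise DomainError("reference and estimate must have equal length")
    if ref.size == 0:
        raise DomainError("mard of an empty series is undefined")
    if np.any(ref <= 0):
        raise DomainError("reference glucose must be positive for MARD")
    return float(np.mean(np.abs(est - ref) / ref) * 100.0)


def rmse(reference, estimate) -> float:
    """Root-mean-square error in the units of the inputs (mg/dL)."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape or ref.size == 0:
        raise DomainError("need equal-length, nonempty series")
    return float(np.sqrt(np.mean((est - ref) ** 2)))


# ------------------------------------------------------------------ Parkes grid


def _load_boundaries() -> Dict[str, Dict[str, np.ndarray]]:
    resource = importlib.resources.files("hemophase.data") / "parkes_t1_boundaries.csv"
    with importlib.resources.as_file(resource) as path:
        table = pd.read_csv(path)
    out: Dict[str, Dict[str, np.ndarray]] = {"upper": {}, "lower": {}}
    for (zone, side), grp in table.groupby(["zone", "side"], sort=False):
        out[side][zone] = grp[["x", "y"]].to_numpy(dtype=float)
    return out


_BOUNDARIES = _load_boundaries()


def _polyline_y(vertices: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Piecewise-linear y(x); the final segment's slope extends beyond 550."""
    xs, ys = vertices[:, 0], vertices[:, 1]
    y = np.interp(x, xs, ys)
    slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    return np.where(x > xs[-1], ys[-1] + slope * (x - xs[-1]), y)


def parkes_zones(reference_mgdl, estimate_mgdl) -> np.ndarray:
    """Vectorized type-1 Parkes zone labels for (reference, estimate) pairs.

    Assignment is by which-side-of-boundary tests against the embedded
    polylines, so every point of [0, 600]^2 receives exactly one zone;
    boundary points fall to the lower-risk side by the strict inequalities.
    """
    ref = np.atleast_1d(np.asarray(reference_mgdl, dtype=float))
    est = np.atleast_1d(np.asarray(estimate_mgdl, dtype=float))
    if ref.shape != est.shape:
        raise DomainError("reference and estimate must have equal shape")
    bad = (
        ~np.isfinite(ref)
        | ~np.isfinite(est)
        | (ref < 0)
        | (ref > GRID_MAX_MGDL)
        | (est < 0)
        | (est > GRID_MAX_MGDL)
    )
    if np.any(bad):
        raise DomainError(f"values must lie in [0, {GRID_MAX_MGDL:g}] mg/dL")
    risk = np.zeros(ref.shape, dtype=int)
    for zone, vertices in _BOUNDARIES["upper"].items():
        beyond = est > _polyline_y(vertices, ref)
        risk = np.maximum(risk, np.where(beyond, _RISK[zone], 0))
    for zone, vertices in _BOUNDARIES["lower"].items():
        x0 = vertices[0, 0]
        g = _polyline_y(vertices[1:], ref)  # skip the vertical entry segment
        beyond = (ref > x0) & (est < g)
        risk = np.maximum(risk, np.where(beyond, _RISK[zone], 0))
    labels = np.array(ZONE_LABELS, dtype="<U1")[risk]
    return labels


def parkes_zone(reference_mgdl: float, estimate_mgdl: float) -> str:
    """Zone label for a single (reference, estimate) pair."""
    return str(parkes_zones([reference_mgdl], [estimate_mgdl])[0])


# ----------------------------------------------------------------- session eval


@dataclass
class ErrorGridResult:
    """Zone assignment plus agreement metrics for a set of paired points."""

    zones: np.ndarray
    zone_percent: Dict[str, float]
    mard_pct: float
    rmse_mgdl: float
    n_points: int


@dataclass
class EvaluationReport:
    fit: CalibrationFit
    grid: ErrorGridResult
    reference: np.ndarray
    estimate: np.ndarray
    times: np.ndarray

    def summary(self) -> str:
        zp = ", ".join(f"{z}: {p:.1f}%" for z, p in self.grid.zone_percent.items() if p > 0)
        return (
            f"n={self.grid.n_points} pairs | r={self.fit.r:.3f} | "
            f"slope={self.fit.slope:.4g} mg/dL per MI, intercept={self.fit.intercept:.4g} mg/dL | "
            f"MARD={self.grid.mard_pct:.1f}% | RMSE={self.grid.rmse_mgdl:.1f} mg/dL | "
            f"zones [{zp}]"
        )


def zone_percentages(zones: np.ndarray) -> Dict[str, float]:
    n = zones.size
    return {z: float(100.0 * np.sum(zones == z) / n) for z in ZONE_LABELS}


def error_grid_result(reference, estimate) -> ErrorGridResult:
    ref = np.asarray(reference, dtype=float)
    est = np.clip(np.asarray(estimate, dtype=float), 0.0, GRID_MAX_MGDL)
    zones = parkes_zones(ref, est)
    return ErrorGridResult(
        zones=zones,
        zone_percent=zone_percentages(zones),
        mard_pct=mard(ref, est),
        rmse_mgdl=rmse(ref, est),
        n_points=int(ref.size),
    )


def evaluate_session(
    mi_series: Union[MISeries, Tuple[np.ndarray, np.ndarray]],
    glucose: GlucoseSeries,
    fit: Optional[CalibrationFit] = None,
    use_smoothed: bool = True,
) -> EvaluationReport:
    """Interpolate the MI trend onto the (delay-compensated) reference grid,
    calibrate (or apply a given fit), and compute zones/MARD/RMSE.

    Raises :class:`InsufficientDataError` with fewer than 3 overlapping
    points. Note the metrics fold together errors of the index method and of
    the reference sensor itself.
    """
    if isinstance(mi_series, MISeries):
        times = mi_series.times
        values = mi_series.smoothed if (use_smoothed and mi_series.smoothed is not None) else mi_series.raw
    else:
        times, values = (np.asarray(v, dtype=float) for v in mi_series)
    g = compensate_delay(glucose) if glucose.delay_s else glucose
    mi_at_ref = interpolate_to(times, values, g.times)
    mask = np.isfinite(mi_at_ref) & np.isfinite(g.values)
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} overlapping MI/reference points (need >= 3)"
        )
    mi_pairs = mi_at_ref[mask]
    ref_pairs = g.values[mask]
    if fit is None:
        fit = fit_calibration(mi_pairs, ref_pairs)
    est = fit.predict(mi_pairs)
    grid = error_grid_result(ref_pairs, est)
    return EvaluationReport(
        fit=fit, grid=grid, reference=ref_pairs, estimate=est, times=g.times[mask]
    )


def plot_error_grid(reference, estimate, path=None, ax=None):
    """Scatter the pairs over the type-1 Parkes zone boundaries (optional)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    xs = np.linspace(0, GRID_MAX_MGDL, 601)
    for side in ("upper", "lower"):
        for zone, vertices in _BOUNDARIES[side].items():
            v = vertices if side == "upper" else vertices[1:]
            ys = _polyline_y(v, xs)
            if side == "lower":
                ys = np.where(xs <= vertices[0, 0], np.nan, ys)
            ys = np.clip(ys, 0, GRID_MAX_MGDL)
            ax.plot(xs, ys, lw=0.8, color="0.4")
    ax.plot([0, GRID_MAX_MGDL], [0, GRID_MAX_MGDL], lw=0.6, ls="--", color="0.7")
    ax.scatter(reference, estimate, s=10, alpha=0.6)
    ax.set_xlim(0, GRID_MAX_MGDL)
    ax.set_ylim(0, GRID_MAX_MGDL)
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("estimated glucose (mg/dL)")
    ax.set_title("Parkes consensus error grid (type 1)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
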