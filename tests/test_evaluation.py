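"""Calibration, agreement metrics and Parkes type-1 error-grid geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import hemophase as hp
from hemophase.errors import DomainError, InsufficientDataError


class TestCalibration:
    def test_exact_line(self):
        fit = hp.fit_calibration([0.01, 0.02, 0.03], [100.0, 150.0, 200.0])
        assert fit.slope == pytest.approx(5000.0)
        assert fit.intercept == pytest.approx(50.0)
        assert fit.r == pytest.approx(1.0)

    def test_constant_glucose_gives_zero_slope_and_r(self):
        fit = hp.fit_calibration([0.01, 0.02, 0.03], [120.0, 120.0, 120.0])
        assert fit.slope == 0.0
        assert fit.r == 0.0

    def test_anticorrelated_line(self):
        fit = hp.fit_calibration([0.01, 0.02, 0.03], [200.0, 150.0, 100.0])
        assert fit.r == pytest.approx(-1.0)

    def test_zero_mi_variance_is_degenerate(self):
        with pytest.raises(DomainError):
            hp.fit_calibration([0.01, 0.01, 0.01], [100.0, 150.0, 200.0])

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            hp.fit_calibration([0.01, 0.02], [100.0, 150.0])

    def test_sklearn_estimator_contract(self):
        est = hp.GlucoseCalibrator()
        assert est.get_params() == {}
        cloned = clone(est)
        cloned.fit(np.array([[0.01], [0.02], [0.03]]), [100.0, 150.0, 200.0])
        assert cloned.slope_ == pytest.approx(5000.0)
        assert cloned.predict([[0.02]])[0] == pytest.approx(150.0)
        assert cloned.score([[0.01], [0.02], [0.03]], [100.0, 150.0, 200.0]) == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 50.0), b=st.floats(-5.0, 5.0),
        seed=st.integers(0, 1000),
    )
    def test_r_invariant_under_positive_affine_mi_transform(self, a, b, seed):
        """Calibration cannot inflate correlation by rescaling the index."""
        rng = np.random.default_rng(seed)
        mi = rng.uniform(0.005, 0.02, 12)
        glucose = 90 + 4000 * mi + rng.normal(0, 5, 12)
        r1 = hp.fit_calibration(mi, glucose).r
        r2 = hp.fit_calibration(a * mi + b, glucose).r
        assert r2 == pytest.approx(r1, abs=1e-9)


class TestMetrics:
    def test_mard_examples(self):
        assert hp.mard([100.0], [100.0]) == 0.0
        assert hp.mard([100.0, 200.0], [110.0, 180.0]) == pytest.approx(10.0)
        assert hp.mard([100.0], [150.0]) == pytest.approx(50.0)

    def test_rmse_examples(self):
        assert hp.rmse([100.0, 200.0], [100.0, 200.0]) == 0.0
        assert hp.rmse([100.0, 200.0], [110.0, 180.0]) == pytest.approx(15.811, abs=1e-3)
        assert hp.rmse([100.0], [120.0]) == pytest.approx(20.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(DomainError):
            hp.mard([0.0, 100.0], [10.0, 100.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_reorder_invariance(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(70, 300, 15)
        est = ref * rng.uniform(0.8, 1.2, 15)
        perm = rng.permutation(15)
        assert hp.mard(ref[perm], est[perm]) == pytest.approx(hp.mard(ref, est))
        assert hp.rmse(ref[perm], est[perm]) == pytest.approx(hp.rmse(ref, est))


class TestParkesGrid:
    # expected zones derived by hand from the embedded boundary polylines
    FROZEN = [
        (100, 100, "A"), (400, 400, "A"), (600, 600, "A"), (0, 0, "A"),
        (200, 230, "A"), (100, 175, "B"), (100, 185, "C"), (100, 400, "D"),
        (20, 160, "E"), (300, 100, "C"), (300, 50, "D"), (50, 350, "D"),
    ]

    @pytest.mark.parametrize("ref,est,zone", FROZEN)
    def test_frozen_points(self, ref, est, zone):
        assert hp.parkes_zone(ref, est) == zone

    def test_boundary_points_take_lower_risk_zone(self):
        assert hp.parkes_zone(0, 50) == "A"  # exactly on the upper B line
        assert hp.parkes_zone(50, 10) == "A"  # on the vertical lower-B segment
        assert hp.parkes_zone(30, 60) == "B"  # on the upper C line -> B, not C

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            hp.parkes_zone(650, 100)
        with pytest.raises(DomainError):
            hp.parkes_zone(100, -1)

    def test_partition_is_total_and_deterministic(self):
        g = np.arange(0.0, 601.0, 4.0)
        rr, ee = np.meshgrid(g, g)
        z1 = hp.parkes_zones(rr.ravel(), ee.ravel())
        z2 = hp.parkes_zones(rr.ravel(), ee.ravel())
        assert set(np.unique(z1)) <= {"A", "B", "C", "D", "E"}
        assert np.array_equal(z1, z2)
        # the identity diagonal is always zone A
        d = np.arange(0.0, 601.0, 1.0)
        assert np.all(hp.parkes_zones(d, d) == "A")


class TestEvaluateSession:
    def _glucose(self, values, dt=300.0, delay=0.0):
        times = dt * (1 + np.arange(len(values)))
        return hp.GlucoseSeries(times=times, values=np.asarray(values, float), delay_s=delay)

    def test_perfect_agreement(self):
        g = self._glucose([100.0, 150.0, 200.0, 250.0])
        mi_times = np.array([0.0, 2000.0])
        mi_vals = hp.interpolate_to(g.times, g.values / 5000.0, mi_times)
        report = hp.evaluate_session((g.times, g.values / 5000.0), g)
        assert report.grid.zone_percent["A"] == 100.0
        assert report.grid.mard_pct == pytest.approx(0.0, abs=1e-9)
        assert report.grid.rmse_mgdl == pytest.approx(0.0, abs=1e-9)
        assert report.fit.r == pytest.approx(1.0)
        assert mi_vals.size == 2  # sanity on helper usage

    def test_ten_percent_overestimate_mard(self):
        g = self._glucose([100.0, 200.0, 300.0])
        mi = g.values / 1000.0
        fit = hp.CalibrationFit(slope=1100.0, intercept=0.0, r=1.0, n_points=3)
        report = hp.evaluate_session((g.times, mi), g, fit=fit)
        assert report.grid.mard_pct == pytest.approx(10.0)

    def test_insufficient_overlap(self):
        g = self._glucose([100.0, 150.0, 200.0])
        with pytest.raises(InsufficientDataError):
            hp.evaluate_session((np.array([0.0, 10.0]), np.array([0.01, 0.02])), g)
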