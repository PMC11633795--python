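"""Correspondence-based dose errors, DVH metrics, and the six-metric panel."""

import numpy as np
import pytest

from dirqa.core import ImageVolume, VectorField, zero_field_like
from dirqa.deform import ground_truth_field, invert_dvf, respiratory_field
from dirqa.dose_qa import (
    DoseErrorMap,
    correspondence_points,
    dose_at_corresponded,
    dose_error_map,
    dvh_metrics,
    error_panel,
    dose_qa_report,
)
from dirqa.phantom import PlanPrescription, build_dose_model


class LinearDoseModel:
    """Synthetic planar dose ramp dose(p) = d0 + g . p — test oracle only."""

    def __init__(self, gradient, offset=10000.0):
        self.g = np.asarray(gradient, dtype=float)
        self.d0 = float(offset)

    def evaluate(self, points):
        return self.d0 + np.asarray(points, dtype=float) @ self.g


class FlatDoseModel:
    def __init__(self, value=5000.0):
        self.value = value

    def evaluate(self, points):
        return np.full(len(np.atleast_2d(points)), self.value)


@pytest.fixture()
def geometry():
    return ImageVolume(np.zeros((10, 10, 10)), origin=(0, 0, 0), spacing=(2, 2, 2))


class TestCorrespondence:
    def test_zero_field_identity(self, geometry):
        f = zero_field_like(geometry)
        pts, outside = correspondence_points(geometry, f)
        np.testing.assert_array_equal(pts, geometry.voxel_centers())
        assert not outside.any()

    def test_uniform_shift(self, geometry):
        f = zero_field_like(geometry)
        f.u[:] = (5.0, 5.0, 0.0)
        pts, _ = correspondence_points(geometry, f)
        np.testing.assert_array_equal(pts, geometry.voxel_centers() + [5.0, 5.0, 0.0])

    def test_outside_points_flagged(self, geometry):
        f = zero_field_like(geometry)
        f.u[..., 0] = 100.0
        _, outside = correspondence_points(geometry, f)
        assert outside.all()

    def test_forward_then_inverse_returns_home(self, phantom96):
        ct, s = phantom96
        f = respiratory_field(ct, "high", s)
        inv = invert_dvf(f, tol_mm=0.01)
        pts, _ = correspondence_points(ct, f)
        back = pts + inv.sample(pts, mode="nearest")
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(s["body"], iterations=2).ravel()
        d = np.linalg.norm(back - ct.voxel_centers(), axis=1)
        assert d[interior].max() < 0.5


class TestDoseErrorMap:
    def test_perfect_candidate_zero_everywhere(self, geometry, rng):
        rx = PlanPrescription([6000.0])
        f = VectorField(rng.normal(size=(10, 10, 10, 3)), geometry.origin, geometry.spacing)
        region = np.ones((10, 10, 10), dtype=bool)
        e = dose_error_map(LinearDoseModel([10, 5, -3]), f, f.copy(), region, rx)
        assert np.all(e.error == 0.0)

    def test_linear_ramp_closed_form(self, geometry):
        """Uniform candidate offset t on a ramp with gradient g: error = -g.t."""
        rx = PlanPrescription([6000.0])
        g = np.array([12.0, -7.0, 3.0])
        t = np.array([2.0, 1.0, -4.0])
        truth = zero_field_like(geometry)
        cand = zero_field_like(geometry)
        cand.u[:] = t
        region = np.ones((10, 10, 10), dtype=bool)
        e = dose_error_map(LinearDoseModel(g), truth, cand, region, rx)
        np.testing.assert_allclose(e.error, -g @ t, rtol=1e-12)

    def test_flat_dose_nulls_geometric_error(self, phantom_small, rx_two_level):
        ct, s = phantom_small
        truth = zero_field_like(ct)
        cand = ground_truth_field(ct, s, preset="medium")
        e = dose_error_map(FlatDoseModel(), truth, cand, s["body"], rx_two_level)
        assert np.all(e.error == 0.0)

    def test_error_bounded_by_lipschitz_times_geometric_error(
        self, phantom_small, rx_two_level, dose_model_small
    ):
        ct, s = phantom_small
        truth = ground_truth_field(ct, s, preset="medium")
        cand = zero_field_like(ct)
        e = dose_error_map(dose_model_small, truth, cand, s["body"], rx_two_level)
        geom = np.linalg.norm(truth.u - cand.u, axis=-1)
        L = dose_model_small.lipschitz_bound_cgy_per_mm()
        assert np.all(np.abs(e.error[s["body"]]) <= L * geom[s["body"]] + 1e-9)

    def test_empty_region_rejected(self, geometry, rx_two_level):
        f = zero_field_like(geometry)
        with pytest.raises(ValueError):
            dose_error_map(FlatDoseModel(), f, f, np.zeros((10, 10, 10), dtype=bool), rx_two_level)


class TestDvhMetrics:
    def test_uniform_dose_at_prescription(self):
        rx = PlanPrescription([5000.0])
        m = dvh_metrics(np.full(200, 5000.0), None, rx)
        assert m.v100 == 100.0
        assert m.dmax == m.dmin == m.d95 == 5000.0

    def test_two_valued_dvh(self):
        rx = PlanPrescription([4000.0])
        vals = np.concatenate([np.zeros(100), np.full(100, 8000.0)])
        m = dvh_metrics(vals, None, rx)
        assert m.v100 == 50.0
        assert m.d95 == 0.0

    def test_order_statistics_on_random_dose(self, rng):
        rx = PlanPrescription([4000.0])
        for _ in range(5):
            m = dvh_metrics(rng.random(500) * 9000, None, rx)
            assert m.dmin <= m.d95 <= m.dmax
            assert m.dmin <= m.mean <= m.dmax
            assert 0 <= m.v100 <= 100

    def test_volume_masked_form(self, rng):
        rx = PlanPrescription([1000.0])
        dose = ImageVolume(rng.random((6, 6, 6)) * 2000)
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[:3] = True
        m = dvh_metrics(dose, mask, rx)
        assert m.mean == pytest.approx(dose.data[mask].mean())

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            dvh_metrics(np.array([]), None, PlanPrescription([100.0]))


class TestErrorPanel:
    def _map(self, error, region=None, spacing=(2, 2, 2), ref=7500.0):
        error = np.asarray(error, dtype=float)
        region = np.ones(error.shape, dtype=bool) if region is None else region
        return DoseErrorMap(error, region, np.zeros(3), np.asarray(spacing, dtype=float), ref)

    def test_all_zero(self):
        rx = PlanPrescription([7500.0])
        e = self._map(np.zeros((10, 10, 10)))
        m = dvh_metrics(np.full(100, 5000.0), None, rx)
        p = error_panel(e, m, m, np.ones((10, 10, 10), dtype=bool), rx)
        for k, v in p.as_dict().items():
            if k.endswith("_pct"):
                assert v == 0.0

    def test_constant_error_panel(self):
        rx = PlanPrescription([7500.0])
        c = 150.0
        e = self._map(np.full((12, 12, 12), c))
        m = dvh_metrics(np.full(100, 5000.0), None, rx)
        p = error_panel(e, m, m, np.ones((12, 12, 12), dtype=bool), rx)
        expect = 100.0 * c / 7500.0
        assert p.mean_error_pct == pytest.approx(expect)
        assert p.max_error_pct == pytest.approx(expect)
        assert p.p95_error_pct == pytest.approx(expect)
        assert p.top_1cc_error_pct == pytest.approx(expect)

    def test_scale_invariance(self, rng):
        err = rng.normal(0, 200, size=(12, 12, 12))
        mask = np.ones((12, 12, 12), dtype=bool)
        rx1, rx2 = PlanPrescription([7500.0]), PlanPrescription([15000.0])
        mt = dvh_metrics(rng.random(100) * 7000, None, rx1)
        mc = dvh_metrics(rng.random(100) * 7000, None, rx1)
        mt2 = dvh_metrics(np.array([mt.dmax * 2]), None, rx2)  # scaled metrics
        p1 = error_panel(self._map(err, ref=7500.0), mt, mc, mask, rx1)
        p2 = error_panel(self._map(err * 2, ref=15000.0), mt, mc, mask, rx2)
        assert p2.mean_error_pct == pytest.approx(p1.mean_error_pct)
        assert p2.p95_error_pct == pytest.approx(p1.p95_error_pct)
        assert p2.top_1cc_error_pct == pytest.approx(p1.top_1cc_error_pct)

    def test_signed_max_is_largest_absolute_value(self):
        rx = PlanPrescription([1000.0])
        err = np.zeros((10, 10, 10))
        err[0, 0, 0] = -500.0
        err[1, 1, 1] = 300.0
        e = self._map(err)
        m = dvh_metrics(np.full(10, 100.0), None, rx)
        p = error_panel(e, m, m, np.ones((10, 10, 10), dtype=bool), rx)
        assert p.max_error_pct == pytest.approx(-50.0)  # signed, largest |.|

    def test_small_roi_warns_for_top_1cc(self):
        rx = PlanPrescription([1000.0])
        e = self._map(np.full((10, 10, 10), 10.0), spacing=(1, 1, 1))
        roi = np.zeros((10, 10, 10), dtype=bool)
        roi[:2, :2, :2] = True  # 8 mm^3 << 1 cc
        m = dvh_metrics(np.full(8, 100.0), None, rx)
        with pytest.warns(UserWarning, match="1 cc"):
            error_panel(e, m, m, roi, rx, roi="tiny")

    def test_mean_bounded_by_max_abs(self, rng):
        rx = PlanPrescription([1000.0])
        e = self._map(rng.normal(size=(10, 10, 10)) * 100)
        m = dvh_metrics(np.full(10, 100.0), None, rx)
        p = error_panel(e, m, m, np.ones((10, 10, 10), dtype=bool), rx)
        assert abs(p.mean_error_pct) <= abs(p.max_error_pct) + 1e-12


class TestDoseQaReport:
    def test_perfect_candidate_null_report(self, phantom_small, rx_two_level, dose_model_small):
        ct, s = phantom_small
        truth = ground_truth_field(ct, s, preset="medium")
        rep = dose_qa_report(dose_model_small, truth, truth.copy(), s, rx_two_level)
        for roi, panel in rep["panels"].items():
            for k, v in panel.as_dict().items():
                if k.endswith("_pct"):
                    assert v == 0.0, (roi, k)

    def test_corresponded_dose_matches_pointwise_eval(self, phantom_small, dose_model_small):
        ct, s = phantom_small
        truth = ground_truth_field(ct, s, preset="medium")
        vals = dose_at_corresponded(dose_model_small, truth, s["gtv"])
        idx = np.argwhere(s["gtv"])
        pts = s.origin + idx * s.spacing + truth.u[s["gtv"]]
        np.testing.assert_allclose(vals, dose_model_small.evaluate(pts))
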