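"""Analysis-grid resampling, magnitude-error maps, and ROI statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dirqa.core import ImageVolume, VectorField, zero_field_like
from dirqa.deform import digestive_shift, ground_truth_field, respiratory_field
from dirqa.geometry_qa import (
    ErrorMap,
    magnitude_error_map,
    magnitude_map,
    resample_mask_to,
    resample_to_analysis_grid,
    roi_error_stats,
)
from dirqa.phantom import StructureSet


def _field(u, origin=(0, 0, 0), spacing=(1, 1, 1)):
    return VectorField(np.asarray(u, dtype=float), origin, spacing)


def _err_from(data):
    data = np.asarray(data, dtype=float)
    return ErrorMap(data, np.zeros(3), np.ones(3), np.ones(data.shape, dtype=bool))


class TestResample:
    def test_noop_on_1mm_grid_is_bitwise(self, rng):
        f = _field(rng.normal(size=(6, 6, 6, 3)))
        out = resample_to_analysis_grid(f, f)
        assert np.array_equal(out.u, f.u)
        assert out.valid.all()

    def test_constant_field_preserved_exactly(self):
        f = _field(np.full((5, 5, 5, 3), 2.5), spacing=(2, 2, 2))
        out = resample_to_analysis_grid(f, f)
        assert out.shape == (9, 9, 9)
        assert np.allclose(out.spacing, 1.0)
        np.testing.assert_array_equal(out.u, 2.5)

    def test_trilinear_reproduces_linear_field(self):
        # u_SI = 0.3 * z sampled on a 2 mm lattice, resampled to 1 mm
        z = np.arange(8) * 2.0
        u = np.zeros((8, 8, 8, 3))
        u[..., 2] = 0.3 * z[None, None, :]
        f = _field(u, spacing=(2, 2, 2))
        out = resample_to_analysis_grid(f, f)
        z_fine = np.arange(15) * 1.0
        np.testing.assert_allclose(out.u[..., 2], np.broadcast_to(0.3 * z_fine, out.shape))

    def test_disjoint_extents_rejected(self):
        f = _field(np.zeros((4, 4, 4, 3)))
        ref = ImageVolume(np.zeros((4, 4, 4)), origin=(100, 100, 100))
        with pytest.raises(ValueError, match="disjoint"):
            resample_to_analysis_grid(f, ref)


class TestMagnitudeErrorMap:
    def test_self_comparison_is_zero(self, rng):
        f = _field(rng.normal(size=(5, 5, 5, 3)))
        a = resample_to_analysis_grid(f, f)
        assert np.all(magnitude_error_map(a, a).data == 0.0)

    def test_constant_345_offset(self, rng):
        t = _field(rng.normal(size=(6, 6, 6, 3)))
        c = _field(t.u + np.array([3.0, 4.0, 0.0]))
        for f in (t, c):
            f.valid = np.ones(f.shape, dtype=bool)
        np.testing.assert_allclose(magnitude_error_map(c, t).data, 5.0)

    def test_zero_candidate_reduces_to_truth_magnitude(self, phantom96):
        ct, s = phantom96
        truth = resample_to_analysis_grid(respiratory_field(ct, "high", s), ct)
        zero = resample_to_analysis_grid(zero_field_like(ct), ct)
        err = magnitude_error_map(zero, truth)
        assert np.array_equal(err.data, magnitude_map(truth).data)

    def test_symmetry(self, rng):
        a = _field(rng.normal(size=(5, 5, 5, 3)))
        b = _field(rng.normal(size=(5, 5, 5, 3)))
        for f in (a, b):
            f.valid = np.ones(f.shape, dtype=bool)
        assert np.array_equal(magnitude_error_map(a, b).data, magnitude_error_map(b, a).data)

    def test_triangle_inequality_vs_third_field(self, rng):
        a, b, c = (_field(rng.normal(size=(5, 5, 5, 3))) for _ in range(3))
        for f in (a, b, c):
            f.valid = np.ones(f.shape, dtype=bool)
        ab = magnitude_error_map(a, b).data
        ac = magnitude_error_map(a, c).data
        cb = magnitude_error_map(c, b).data
        assert np.all(ab <= ac + cb + 1e-12)

    def test_brute_force_oracle_5x5x5(self, rng):
        """Independent per-voxel loop: error = sqrt(sum of squared comp diffs)."""
        a = _field(rng.normal(size=(5, 5, 5, 3)))
        b = _field(rng.normal(size=(5, 5, 5, 3)))
        for f in (a, b):
            f.valid = np.ones(f.shape, dtype=bool)
        err = magnitude_error_map(a, b).data
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    expect = (
                        (a.u[i, j, k, 0] - b.u[i, j, k, 0]) ** 2
                        + (a.u[i, j, k, 1] - b.u[i, j, k, 1]) ** 2
                        + (a.u[i, j, k, 2] - b.u[i, j, k, 2]) ** 2
                    ) ** 0.5
                    assert err[i, j, k] == pytest.approx(expect, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        u=hnp.arrays(np.float64, (4, 4, 4, 3), elements=st.floats(-50, 50)),
        v=hnp.arrays(np.float64, (4, 4, 4, 3), elements=st.floats(-50, 50)),
    )
    def test_error_map_nonnegative_and_symmetric(self, u, v):
        a, b = _field(u), _field(v)
        for f in (a, b):
            f.valid = np.ones(f.shape, dtype=bool)
        e1, e2 = magnitude_error_map(a, b).data, magnitude_error_map(b, a).data
        assert np.all(e1 >= 0)
        assert np.array_equal(e1, e2)

    def test_grid_mismatch_rejected(self, rng):
        a = _field(rng.normal(size=(5, 5, 5, 3)))
        b = _field(rng.normal(size=(6, 6, 6, 3)))
        with pytest.raises(ValueError):
            magnitude_error_map(a, b)


class TestRoiStats:
    def _structs(self, masks, spacing=(1, 1, 1)):
        return StructureSet(masks, np.zeros(3), np.asarray(spacing, dtype=float))

    def test_constant_error_in_roi(self):
        err = _err_from(np.full((6, 6, 6), 1.75))
        s = self._structs({"roi": np.ones((6, 6, 6), dtype=bool)})
        st_ = roi_error_stats(err, s, rois=("roi",))["roi"]
        assert st_.mean == st_.p90 == st_.max == 1.75

    def test_half_zero_half_two(self):
        data = np.zeros((4, 4, 4))
        data[2:] = 2.0
        err = _err_from(data)
        s = self._structs({"roi": np.ones((4, 4, 4), dtype=bool)})
        st_ = roi_error_stats(err, s, rois=("roi",))["roi"]
        assert st_.mean == 1.0
        assert st_.max == 2.0

    def test_histogram_counts_conserve_roi_voxels(self, rng):
        err = _err_from(np.abs(rng.normal(size=(8, 8, 8))) * 3)
        mask = rng.random((8, 8, 8)) > 0.4
        s = self._structs({"roi": mask})
        st_ = roi_error_stats(err, s, rois=("roi",))["roi"]
        assert st_.hist_counts.sum() == st_.count == mask.sum()
        assert st_.p90 >= np.median(err.data[mask])

    def test_empty_roi_rejected(self):
        err = _err_from(np.zeros((4, 4, 4)))
        s = self._structs({"roi": np.zeros((4, 4, 4), dtype=bool)})
        with pytest.raises(ValueError, match="empty"):
            roi_error_stats(err, s, rois=("roi",))

    def test_mask_resampled_from_coarser_grid(self, phantom_small):
        ct, s = phantom_small
        f = resample_to_analysis_grid(zero_field_like(ct), ct)
        err = magnitude_error_map(f, f)
        stats = roi_error_stats(err, s, rois=("gtv",))["gtv"]
        # 3 mm voxels carry 27 analysis voxels each, up to boundary effects
        assert stats.count == pytest.approx(27 * s["gtv"].sum(), rel=0.2)


class TestMagnitudeMap:
    def test_zero_field(self, phantom_small):
        ct, _ = phantom_small
        f = resample_to_analysis_grid(zero_field_like(ct), ct)
        assert np.all(magnitude_map(f).data == 0.0)

    def test_digestive_only_field(self, phantom_small):
        ct, s = phantom_small
        f = digestive_shift(ct, s["stomach_duodenum"], 5.0, 5.0)
        mag = magnitude_map(resample_to_analysis_grid(f, f))
        m = resample_mask_to(
            s["stomach_duodenum"], s.origin, s.spacing, mag.origin, mag.spacing, mag.shape
        )
        # strictly interior analysis voxels carry the full shift
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(m, iterations=3)
        np.testing.assert_allclose(mag.data[interior], np.sqrt(50.0))

    def test_combined_max_not_below_respiratory_max(self, phantom96):
        ct, s = phantom96
        resp = respiratory_field(ct, "high", s)
        gt = ground_truth_field(ct, s)
        assert gt.magnitude()[s["body"]].max() >= resp.magnitude()[s["body"]].max()
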