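"""Preprocessing chain: flooring, log2, quantile normalization, batch
adjustment, median centering and detection calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nksig.io import ExpressionMatrix, SampleMetadata
from nksig.preprocess import (batch_adjust, detection_call, floor_threshold,
                              log2_transform, median_center,
                              quantile_normalize)


def _mat(values, scale="linear", features=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features,
                                         columns=samples), scale)


def _meta(groups, batches=None, samples=None):
    samples = samples or [f"s{j}" for j in range(len(groups))]
    return SampleMetadata(pd.DataFrame({
        "group": groups,
        "batch": batches or ["b1"] * len(groups),
    }, index=pd.Index(samples, name="sample_id")))


class TestFloorAndLog:
    def test_floor_elementwise_rule(self):
        out = floor_threshold(_mat([[0.5, 2.0], [1.0, 0.9]]), 1.0)
        np.testing.assert_array_equal(out.values, [[1, 2], [1, 1]])

    def test_floor_identity_when_all_above(self):
        m = _mat([[1.5, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(floor_threshold(m).values, m.values)

    def test_floor_rejects_non_positive(self):
        with pytest.raises(ValueError, match="positive"):
            floor_threshold(_mat([[1.0]]), 0.0)

    def test_log2_values_and_inverse(self):
        out = log2_transform(_mat([[1.0, 8.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 3.0]])
        assert out.scale == "log2"
        np.testing.assert_allclose(2 ** out.values, [[1.0, 8.0]])

    def test_log2_requires_positive_values(self):
        with pytest.raises(ValueError, match="floor"):
            log2_transform(_mat([[0.0, 1.0]]))


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = _mat([[1, 1], [5, 5], [3, 3]])
        np.testing.assert_allclose(quantile_normalize(m).values, m.values)

    def test_two_column_hand_case(self):
        # sorted means: (1+2)/2, (2+4)/2, (3+6)/2 = 1.5, 3, 4.5
        m = _mat(np.array([[1, 2], [2, 4], [3, 6]]))
        expected = np.array([[1.5, 1.5], [3.0, 3.0], [4.5, 4.5]])
        np.testing.assert_allclose(quantile_normalize(m).values, expected)

    def test_ties_receive_mean_reference_over_span(self):
        # col a=(1,1,3), col b=(4,2,6): reference = (1.5, 2.5, 4.5)
        # a's tie at ranks 1-2 -> (1.5+2.5)/2 = 2.0 for both
        m = _mat(np.array([[1, 4], [1, 2], [3, 6]]))
        expected = np.array([[2.0, 2.5], [2.0, 1.5], [4.5, 4.5]])
        np.testing.assert_allclose(quantile_normalize(m).values, expected)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(2, 20))
    def test_columns_share_distribution_and_total_sum(self, seed, m, n):
        rng = np.random.default_rng(seed)
        mat = _mat(rng.uniform(0, 10, size=(n, m)))
        out = quantile_normalize(mat).values
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, m):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0],
                                       atol=1e-12)
        np.testing.assert_allclose(out.sum(), mat.values.sum(), rtol=1e-12)

    def test_single_sample_noop_with_warning(self):
        m = _mat([[1.0], [2.0]])
        with pytest.warns(UserWarning, match="single sample"):
            out = quantile_normalize(m)
        np.testing.assert_array_equal(out.values, m.values)


class TestBatchAdjust:
    def test_single_batch_is_identity(self):
        m = _mat(np.arange(8.0).reshape(2, 4), scale="log2")
        md = _meta(["bright", "bright", "dim", "dim"])
        np.testing.assert_allclose(batch_adjust(m, md).values, m.values)

    def test_constant_offset_removed_contrasts_intact(self):
        rng = np.random.default_rng(5)
        base = rng.normal(5, 1, size=(6, 4))
        shifted = np.concatenate([base, base + 1.0], axis=1)
        m = _mat(shifted, scale="log2",
                 samples=[f"s{j}" for j in range(8)])
        md = _meta(["bright", "bright", "dim", "dim"] * 2,
                   batches=["b1"] * 4 + ["b2"] * 4)
        out = batch_adjust(m, md).values
        # batch means now equal per feature
        np.testing.assert_allclose(out[:, :4].mean(axis=1),
                                   out[:, 4:].mean(axis=1), atol=1e-12)
        # within-batch group contrast preserved exactly
        orig = shifted[:, :2].mean(1) - shifted[:, 2:4].mean(1)
        np.testing.assert_allclose(out[:, :2].mean(1) - out[:, 2:4].mean(1),
                                   orig, atol=1e-12)
        # grand mean per feature preserved
        np.testing.assert_allclose(out.mean(1), shifted.mean(1), atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        m = _mat(rng.normal(size=(3, 6)), scale="log2")
        md = _meta(["bright", "dim"] * 3, batches=["b1", "b1", "b2", "b2",
                                                   "b1", "b2"])
        once = batch_adjust(m, md)
        twice = batch_adjust(once, md)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_confounded_batch_raises(self):
        m = _mat(np.ones((2, 4)), scale="log2")
        md = _meta(["bright", "bright", "dim", "dim"],
                   batches=["b1", "b1", "b2", "b2"])
        with pytest.raises(ValueError, match="confounded"):
            batch_adjust(m, md)


class TestMedianCenter:
    def test_examples_and_idempotence(self):
        m = _mat([[0, 1, 5], [2, 2, 2]], scale="log2")
        out = median_center(m)
        np.testing.assert_array_equal(out.values, [[-1, 0, 4], [0, 0, 0]])
        np.testing.assert_array_equal(median_center(out).values, out.values)

    def test_requires_log2_scale(self):
        with pytest.raises(ValueError, match="log2"):
            median_center(_mat([[1.0, 2.0]]))


class TestDetectionCall:
    def _setup(self, values):
        m = _mat(values, scale="log2",
                 samples=[f"s{j}" for j in range(values.shape[1])])
        n = values.shape[1] // 2
        md = _meta(["bright"] * n + ["dim"] * n,
                   samples=m.sample_ids)
        return m, md

    def test_half_counting_rule(self):
        # feature over threshold in exactly 5 of 10 bright samples
        row = np.array([[2.0] * 5 + [0.0] * 5 + [0.0] * 10])
        m, md = self._setup(row)
        det = detection_call(m, md, threshold=1.0)
        assert "f0" in det.detected_half["bright"]
        assert "f0" not in det.detected_all["bright"]
        assert "f0" not in det.detected_half["dim"]
        assert det.exclusive["bright"] == {"f0"}

    def test_all_above_threshold(self):
        m, md = self._setup(np.full((3, 6), 5.0))
        det = detection_call(m, md)
        for g in ("bright", "dim"):
            assert det.detected_all[g] == {"f0", "f1", "f2"}
        assert det.shared == {"f0", "f1", "f2"}
        assert det.exclusive["bright"] == set() == det.exclusive["dim"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        m, md = self._setup(rng.uniform(0, 4, size=(40, 8)))
        prev = None
        for theta in (0.5, 1.0, 2.0, 3.0):
            det = detection_call(m, md, threshold=theta)
            if prev is not None:
                for g in ("bright", "dim"):
                    assert det.detected_half[g] <= prev.detected_half[g]
                    assert det.detected_all[g] <= prev.detected_all[g]
            prev = det

    def test_subset_invariant_all_within_half(self, null_dataset):
        norm, md, _ = null_dataset
        det = detection_call(norm, md)
        for g in ("bright", "dim"):
            assert det.detected_all[g] <= det.detected_half[g]
        assert det.shared | det.exclusive["bright"] | det.exclusive["dim"] == (
            det.detected_half["bright"] | det.detected_half["dim"])

    def test_empty_group_errors(self):
        m = _mat(np.ones((2, 2)), scale="log2")
        md = _meta(["bright", "bright"])
        with pytest.raises(ValueError, match="dim"):
            detection_call(m, md)
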