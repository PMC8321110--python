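"""Detection and evaluation: thresholds, ROC/AUC, DMTD, errors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from mwi3d import (dmtd, intersect_masks, intersection_score,
                   reconstruction_error, roc_analysis, threshold_detect)
from mwi3d.detection import BinaryMask


class TestThresholdDetect:
    def test_fraction_of_maximum(self):
        v = np.array([[10.0, 9.0], [8.4, 1.0]])
        m = threshold_detect(v, 0.85)
        assert np.array_equal(m.values, [[True, True], [False, False]])

    def test_uniform_positive_selects_all(self):
        m = threshold_detect(np.ones((4, 4)), 0.85)
        assert m.count == 16

    def test_frac_one_selects_argmax_only(self):
        v = np.arange(9.0).reshape(3, 3)
        m = threshold_detect(v, 1.0)
        assert m.count == 1 and m.values[2, 2]

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        v = rng.random((6, 6))
        a = threshold_detect(v, 0.85).values
        b = threshold_detect(3.7 * v, 0.85).values
        assert np.array_equal(a, b)

    def test_nonpositive_volume_warns_empty(self):
        with pytest.warns(RuntimeWarning):
            m = threshold_detect(np.zeros((3, 3)), 0.85)
        assert m.count == 0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            threshold_detect(np.ones((2, 2)), 0.0)


class TestIntersection:
    def test_identical_masks_unchanged(self):
        m = BinaryMask(np.eye(4, dtype=bool))
        assert np.array_equal(intersect_masks([m, m, m]).values, m.values)

    def test_disjoint_masks_empty(self):
        a = BinaryMask(np.array([[True, False]]))
        b = BinaryMask(np.array([[False, True]]))
        assert intersect_masks([a, b]).count == 0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            intersect_masks([BinaryMask(np.ones((2, 2), dtype=bool)),
                             BinaryMask(np.ones((3, 3), dtype=bool))])

    def test_score_level_sets_equal_mask_intersections(self):
        """score >= t  <=>  AND of per-frequency masks at fraction t."""
        rng = np.random.default_rng(1)
        vols = [rng.random((8, 8)) for _ in range(3)]
        score = intersection_score(vols)
        for t in (0.6, 0.85):
            masks = [threshold_detect(v, t) for v in vols]
            joint = intersect_masks(masks).values
            assert np.array_equal(score >= t, joint)


class TestRoc:
    def test_perfect_separation_auc_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([1, 1, 0, 0], dtype=bool)
        assert roc_analysis(scores, truth).auc == 1.0

    def test_uninformative_scores_auc_half(self):
        scores = np.full(10, 0.5)
        truth = np.array([1, 0] * 5, dtype=bool)
        assert roc_analysis(scores, truth).auc == pytest.approx(0.5)

    def test_six_voxel_toy_example(self):
        """Hand-enumerable case: AUC = 8/9 by pair counting."""
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        truth = np.array([1, 1, 0, 1, 0, 0], dtype=bool)
        assert roc_analysis(scores, truth).auc == pytest.approx(8 / 9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.ones(4), np.ones(4, dtype=bool))

    def test_monotone_with_endpoints(self):
        rng = np.random.default_rng(2)
        roc = roc_analysis(rng.random(50), rng.random(50) > 0.6)
        assert roc.fpr[0] == roc.tpr[0] == 0
        assert roc.fpr[-1] == roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_auc_equals_mann_whitney(self, seed):
        """Trapezoidal AUC == normalized Mann-Whitney U, ties included."""
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(1, 12))
        n_neg = int(rng.integers(1, 12))
        # quantized scores so ties occur
        scores = np.round(rng.random(n_pos + n_neg), 1)
        truth = np.zeros(n_pos + n_neg, dtype=bool)
        truth[:n_pos] = True
        auc = roc_analysis(scores, truth).auc
        u = mannwhitneyu(scores[truth], scores[~truth],
                         alternative="two-sided").statistic
        assert auc == pytest.approx(u / (n_pos * n_neg), abs=1e-12)


class TestDmtd:
    def test_perfect_roc_min_distance_zero(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([1, 1, 0, 0], dtype=bool)
        curve = dmtd(roc_analysis(scores, truth))
        assert curve.min_distance == pytest.approx(0.0)

    def test_chance_line_min_distance(self):
        """Chance diagonal: min sqrt(x^2 + (1-x)^2) = sqrt(2)/2 at x = 1/2."""
        fpr = tpr = np.linspace(0, 1, 101)
        from mwi3d.detection import RocCurve
        roc = RocCurve(fpr=fpr, tpr=tpr,
                       thresholds=np.linspace(1, 0, 101), auc=0.5)
        curve = dmtd(roc)
        assert curve.min_distance == pytest.approx(np.sqrt(2) / 2, abs=1e-4)
        assert curve.argmin_threshold == pytest.approx(0.5, abs=0.01)

    def test_distances_bounded_by_sqrt2(self):
        rng = np.random.default_rng(4)
        curve = dmtd(roc_analysis(rng.random(40), rng.random(40) > 0.5))
        assert np.all(curve.distances <= np.sqrt(2) + 1e-12)
        assert 0 <= curve.dip_width <= 1


def test_plot_report_writes_figure(tmp_path):
    from mwi3d.detection import DetectionReport, plot_report
    rng = np.random.default_rng(0)
    roc = roc_analysis(rng.random(30), rng.random(30) > 0.5)
    report = DetectionReport()
    report.add("demo", roc, dmtd(roc), {"mse": 1.0, "rms": 1.0})
    out = tmp_path / "r.svg"
    plot_report(report, out)
    assert out.exists() and out.stat().st_size > 0


class TestReconstructionError:
    def test_zero_for_identical(self):
        v = np.random.default_rng(0).random((4, 4))
        assert reconstruction_error(v, v) == {"mse": 0.0, "rms": 0.0}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(20), rng.random(20)
        perm = rng.permutation(20)
        assert reconstruction_error(a, b)["mse"] == \
            pytest.approx(reconstruction_error(a[perm], b[perm])["mse"])
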