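"""Detection matching, metric arithmetic, ROC construction, position errors."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patiploc.dataset import BoxAnnotation
from patiploc.evaluate import (Detection, RocCurve, categorize,
                               compute_metrics, f1_from_precision_recall, iou,
                               optimal_threshold, position_errors, roc_curve,
                               summarize_errors)
from patiploc.geometry import GridGeometry, TransducerSpec, processed_grid
from patiploc.simulate import ARTIFACT, SOURCE


def _det(cls=SOURCE, col=100.0, row=100.0, conf=0.9, fid=0):
    return Detection(object_class=cls, center_col=col, center_row=row,
                     confidence=conf, frame_id=fid)


def _truth(cls=SOURCE, col=100.0, row=100.0):
    return BoxAnnotation(cls, col, row)


THRESH = {SOURCE: 0.5, ARTIFACT: 0.5}


class TestIou:
    def test_identical_boxes(self):
        assert iou(_truth(), _truth()) == pytest.approx(1.0)

    def test_disjoint_boxes(self):
        assert iou(_truth(col=0), _truth(col=100)) == 0.0

    def test_lateral_offset_arithmetic(self):
        # two 32x16 boxes offset 16 px laterally: 256 / 768 = 1/3
        assert iou(_truth(col=100), _truth(col=116)) == pytest.approx(1 / 3)


class TestCategorize:
    def test_exact_match_is_tp(self):
        mf = categorize([_det()], [_truth()], THRESH)
        assert mf.detections[0][1] == "TP"
        assert mf.truth_status == ["detected"]

    def test_opposite_class_overlap_is_misclassification(self):
        mf = categorize([_det(cls=ARTIFACT)], [_truth(cls=SOURCE)], THRESH)
        det, status, mis, ti = mf.detections[0]
        assert status == "FP" and mis and ti == 0
        assert mf.truth_status == ["misclassified"]

    def test_below_threshold_discarded(self):
        mf = categorize([_det(conf=0.3)], [_truth()], THRESH)
        assert mf.detections == []
        assert mf.truth_status == ["missed"]

    def test_each_truth_matched_once(self):
        dets = [_det(conf=0.9), _det(conf=0.8)]
        mf = categorize(dets, [_truth()], THRESH)
        statuses = [s for _, s, _, _ in mf.detections]
        assert statuses == ["TP", "FP"]

    def _oracle(self, detections, truths, thresholds):
        """Exhaustive matcher: enumerate injective detection->truth maps and
        pick the lexicographically best outcome in confidence order
        (TP=2 > misclassified FP=1 > plain FP=0)."""
        retained = sorted(
            [d for d in detections
             if d.confidence > thresholds.get(d.object_class, 0.0)],
            key=lambda d: -d.confidence)
        n = len(retained)
        slots = list(range(len(truths))) + [None] * n
        best_key, best_assign = None, None
        for assign in itertools.permutations(slots, n):
            key = []
            ok = True
            for det, ti in zip(retained, assign):
                if ti is None:
                    key.append(0)
                    continue
                v = iou(det, truths[ti])
                if v <= 0.5:
                    ok = False
                    break
                key.append(2 if truths[ti].object_class == det.object_class
                           else 1)
            if ok and (best_key is None or key > best_key):
                best_key, best_assign = key, assign
        statuses = []
        for det, ti in zip(retained, best_assign or ()):
            if ti is not None and truths[ti].object_class == det.object_class:
                statuses.append("TP")
            else:
                statuses.append("FP")
        return statuses

    def test_agrees_with_exhaustive_matcher(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            truths = [_truth(cls=rng.choice([SOURCE, ARTIFACT]),
                             col=float(rng.integers(40, 220)),
                             row=float(rng.integers(40, 220)))
                      for _ in range(rng.integers(0, 4))]
            dets = [_det(cls=rng.choice([SOURCE, ARTIFACT]),
                         col=float(rng.integers(40, 220)),
                         row=float(rng.integers(40, 220)),
                         conf=float(np.round(rng.uniform(0.2, 1.0), 3)))
                    for _ in range(rng.integers(0, 4))]
            mf = categorize(dets, truths, THRESH)
            got = [s for _, s, _, _ in mf.detections]
            assert got == self._oracle(dets, truths, THRESH)


class TestComputeMetrics:
    def test_table_f1_from_precision_recall(self):
        assert f1_from_precision_recall(98.1, 98.5) == pytest.approx(98.3, abs=0.05)
        assert f1_from_precision_recall(96.9, 85.1) == pytest.approx(90.6, abs=0.05)

    def test_forty_frame_single_tp_fixture(self):
        matched = []
        for fid in range(40):
            truths = [_truth()]
            dets = [_det(fid=fid)] if fid == 0 else []
            matched.append(categorize(dets, truths, THRESH))
        m = compute_metrics(matched).per_class[SOURCE]
        assert m.recall_pct == pytest.approx(2.5)
        assert m.precision_pct == pytest.approx(100.0)
        assert round(m.f1_pct, 1) == 4.9
        assert m.missed_detection_rate_pct == pytest.approx(97.5)

    def test_perfect_detection(self):
        matched = [categorize([_det(fid=i)], [_truth()], THRESH)
                   for i in range(10)]
        m = compute_metrics(matched).per_class[SOURCE]
        assert m.recall_pct == m.precision_pct == 100.0
        assert m.f1_pct == pytest.approx(100.0)
        assert m.misclassification_rate_pct == m.missed_detection_rate_pct == 0.0

    def test_no_detections_precision_undefined(self):
        m = compute_metrics([categorize([], [_truth()], THRESH)]).per_class[SOURCE]
        assert not m.precision_defined
        assert math.isnan(m.precision_pct)

    @given(seed=st.integers(0, 1000))
    @settings(derandomize=True, max_examples=30)
    def test_partition_identity(self, seed):
        """recall + misclassification + missed = 100 % per class, always."""
        rng = np.random.default_rng(seed)
        matched = []
        for fid in range(8):
            truths = [_truth(cls=rng.choice([SOURCE, ARTIFACT]),
                             col=float(rng.integers(30, 230)),
                             row=float(rng.integers(30, 230)))
                      for _ in range(rng.integers(1, 4))]
            dets = []
            for t in truths:
                if rng.random() < 0.7:
                    dets.append(_det(cls=rng.choice([SOURCE, ARTIFACT]),
                                     col=t.center_col + rng.uniform(-6, 6),
                                     row=t.center_row + rng.uniform(-3, 3),
                                     conf=float(rng.uniform(0.1, 1.0)),
                                     fid=fid))
            matched.append(categorize(dets, truths, THRESH))
        report = compute_metrics(matched)
        for cls, m in report.per_class.items():
            if m.n_truths == 0:
                continue
            total = (m.recall_pct + m.misclassification_rate_pct
                     + m.missed_detection_rate_pct)
            assert total == pytest.approx(100.0)


class TestRoc:
    def test_perfect_separation_auc_one(self):
        truths = {i: [_truth()] for i in range(10)}
        dets = [_det(conf=1.0, fid=i) for i in range(10)]
        dets += [_det(conf=0.1, col=200.0, fid=i) for i in range(5)]
        curve = roc_curve(dets, truths, SOURCE)
        assert curve.auc == pytest.approx(1.0)

    def test_permuted_confidences_auc_near_half(self):
        # every frame holds one true and one false positive; confidences
        # are iid, so ranking carries no information and AUC averages 0.5
        rng = np.random.default_rng(31)
        aucs = []
        for trial in range(20):
            truths = {i: [_truth()] for i in range(30)}
            dets = []
            for i in range(30):
                dets.append(_det(conf=float(rng.uniform(0.01, 1.0)),
                                 col=100.0, fid=i))
                dets.append(_det(conf=float(rng.uniform(0.01, 1.0)),
                                 col=200.0, fid=i))
            curve = roc_curve(dets, truths, SOURCE)
            aucs.append(curve.auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_rates_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        truths = {i: [_truth()] for i in range(20)}
        dets = [_det(conf=float(rng.uniform(0, 1)),
                     col=float(rng.choice([100.0, 200.0])), fid=i)
                for i in range(20)]
        curve = roc_curve(dets, truths, SOURCE)
        # thresholds descend along the sweep, so TPR and FPR must ascend
        assert np.all(np.diff(curve.tpr) >= -1e-12)
        assert np.all(np.diff(curve.fpr) >= -1e-12)

    def test_auc_invariant_to_monotone_confidence_transform(self):
        rng = np.random.default_rng(6)
        truths = {i: [_truth()] for i in range(15)}
        dets = [_det(conf=float(rng.uniform(0.1, 0.9)),
                     col=float(rng.choice([100.0, 200.0])), fid=i)
                for i in range(15)]
        squashed = [Detection(d.object_class, d.center_col, d.center_row,
                              d.confidence ** 3, d.frame_id)
                    for d in dets]
        c1 = roc_curve(dets, truths, SOURCE)
        c2 = roc_curve(squashed, truths, SOURCE)
        assert c1.auc == pytest.approx(c2.auc)


class TestOptimalThreshold:
    def test_three_point_toy_curve(self):
        curve = RocCurve(thresholds=np.array([1.0, 0.6, 0.0]),
                         tpr=np.array([0.0, 0.9, 1.0]),
                         fpr=np.array([0.0, 0.2, 1.0]),
                         auc=0.85, fp0=10, tp0=10, object_class=SOURCE)
        # slope 1 line slid from (0, 1) first touches the (0.2, 0.9) vertex
        assert optimal_threshold(curve) == pytest.approx(0.6)

    def test_perfect_step_curve(self):
        truths = {i: [_truth()] for i in range(10)}
        dets = [_det(conf=1.0, fid=i) for i in range(10)]
        dets += [_det(conf=0.1, col=200.0, fid=i) for i in range(5)]
        curve = roc_curve(dets, truths, SOURCE)
        tau = optimal_threshold(curve)
        assert 0.1 <= tau < 1.0  # separates TPs from FPs

    def test_degenerate_single_point(self):
        curve = RocCurve(thresholds=np.array([0.7]), tpr=np.array([1.0]),
                         fpr=np.array([0.0]), auc=1.0, fp0=0, tp0=1,
                         object_class=SOURCE)
        assert optimal_threshold(curve) == pytest.approx(0.7)


class TestPositionErrors:
    def _grid(self):
        from patiploc.geometry import ImagingConfig
        return processed_grid(ImagingConfig(), TransducerSpec())

    def test_exact_detection_zero_error(self):
        mf = categorize([_det()], [_truth()], THRESH)
        df = position_errors([mf], self._grid(), TransducerSpec())
        assert df.euclidean_error_mm.iloc[0] == pytest.approx(0.0)

    def test_three_four_five(self):
        # coarse 2 mm pixels keep the offset detection above the IoU gate
        grid = GridGeometry(256, 256, 2.0, 2.0)
        tcol, trow = grid.world_to_pixel(0.0, 60.0)
        dcol, drow = grid.world_to_pixel(3.0, 64.0)
        mf = categorize([_det(col=float(dcol), row=float(drow))],
                        [_truth(col=float(tcol), row=float(trow))], THRESH)
        df = position_errors([mf], grid, TransducerSpec())
        assert df.lateral_error_mm.iloc[0] == pytest.approx(3.0, abs=1e-9)
        assert df.axial_error_mm.iloc[0] == pytest.approx(4.0, abs=1e-9)
        assert df.euclidean_error_mm.iloc[0] == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("axial,group", [(25.0, 1), (25.01, 2), (16.0, 1),
                                             (95.0, 8)])
    def test_depth_groups_left_open_right_closed(self, axial, group):
        grid = self._grid()
        col, row = grid.world_to_pixel(0.0, axial)
        mf = categorize([_det(col=float(col), row=float(row))],
                        [_truth(col=float(col), row=float(row))], THRESH)
        df = position_errors([mf], grid, TransducerSpec())
        assert df.depth_group.iloc[0] == group

    def test_aperture_strata(self):
        grid = self._grid()
        spec = TransducerSpec()
        rows = []
        for lat, stratum in [(0.0, "under"), (9.0, "under"), (30.0, "outside")]:
            col, row = grid.world_to_pixel(lat, 50.0)
            mf = categorize([_det(col=float(col), row=float(row))],
                            [_truth(col=float(col), row=float(row))], THRESH)
            df = position_errors([mf], grid, spec)
            assert df.aperture_stratum.iloc[0] == stratum

    def test_euclidean_dominates_components_and_summary(self):
        rng = np.random.default_rng(8)
        grid = self._grid()
        matched = []
        for fid in range(20):
            col = float(rng.uniform(60, 200))
            row = float(rng.uniform(60, 200))
            mf = categorize(
                [_det(col=col + rng.uniform(-4, 4), row=row + rng.uniform(-4, 4),
                      fid=fid)],
                [_truth(col=col, row=row)], THRESH)
            matched.append(mf)
        df = position_errors(matched, grid, TransducerSpec())
        assert (df.euclidean_error_mm + 1e-12
                >= df[["lateral_error_mm", "axial_error_mm"]].max(axis=1)).all()
        summary = summarize_errors(df, by="aperture_stratum")
        assert ("euclidean_error_mm", "mean") in summary.columns
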