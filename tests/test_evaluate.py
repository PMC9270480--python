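import math

import numpy as np
import pytest

from mammotile.errors import InputError
from mammotile.evaluate import (
    FROCCurve,
    FROCPoint,
    froc,
    is_hit,
    match_at_threshold,
    sensitivity_at_fpi,
)
from mammotile.geometry import Box, Detection

from _oracles import froc_reference
from conftest import random_detections


def det(x0, y0, x1, y1, score):
    return Detection(box=Box(x0, y0, x1, y1), score=score)


class TestIsHit:
    def test_center_inside(self):
        assert is_hit(Box(4, 4, 6, 6), Box(0, 0, 10, 10))

    def test_overlap_but_center_outside(self):
        # boxes overlap substantially, yet the center (14, 14) is outside
        assert not is_hit(Box(9, 9, 19, 19), Box(0, 0, 10, 10))

    def test_identical(self):
        b = Box(2, 3, 8, 9)
        assert is_hit(b, b)

    def test_half_open_boundary(self):
        # center exactly on gt.x_max is outside (half-open)
        assert not is_hit(Box(9, 4, 11, 6), Box(0, 0, 10, 10))
        # center exactly on gt.x_min is inside
        assert is_hit(Box(-1, 4, 1, 6), Box(0, 0, 10, 10))


class TestMatchAtThreshold:
    def test_single_hit(self):
        preds = {"a": [det(4, 4, 6, 6, 0.9)]}
        gts = {"a": [Box(0, 0, 10, 10)]}
        m = match_at_threshold(preds, gts, 0.5)
        assert m.sensitivity == 1.0 and m.fpi == 0.0

    def test_duplicates_count_once(self):
        preds = {"a": [det(4, 4, 6, 6, 0.9), det(3, 3, 7, 7, 0.8)]}
        gts = {"a": [Box(0, 0, 10, 10)]}
        m = match_at_threshold(preds, gts, 0.5)
        assert m.n_hit == 1 and len(m.false_positives) == 0

    def test_duplicates_as_fp_switch(self):
        preds = {"a": [det(4, 4, 6, 6, 0.9), det(3, 3, 7, 7, 0.8)]}
        gts = {"a": [Box(0, 0, 10, 10)]}
        m = match_at_threshold(preds, gts, 0.5, duplicates_are_fp=True)
        assert m.n_hit == 1 and len(m.false_positives) == 1

    def test_one_pred_credits_multiple_gt(self):
        preds = {"a": [det(8, 8, 12, 12, 0.9)]}  # center (10, 10)
        gts = {"a": [Box(0, 0, 11, 11), Box(9, 9, 20, 20)]}
        m = match_at_threshold(preds, gts, 0.5)
        assert m.n_hit == 2
        m2 = match_at_threshold(preds, gts, 0.5, credit_multiple_gt=False)
        assert m2.n_hit == 1

    def test_threshold_filters(self):
        preds = {"a": [det(4, 4, 6, 6, 0.3)]}
        gts = {"a": [Box(0, 0, 10, 10)]}
        m = match_at_threshold(preds, gts, 0.5)
        assert m.n_hit == 0 and m.fpi == 0.0

    def test_unknown_image_id_rejected(self):
        with pytest.raises(InputError):
            match_at_threshold({"b": [det(0, 0, 1, 1, 0.5)]}, {"a": []}, 0.1)

    def test_normal_images_in_denominator(self):
        preds = {"a": [det(50, 50, 60, 60, 0.9)]}
        gts = {"a": [Box(0, 0, 10, 10)], "b": []}
        m = match_at_threshold(preds, gts, 0.5)
        assert m.n_images == 2 and m.fpi == 0.5

    def test_conservation(self):
        """Kept predictions = credited-to-hits + false positives."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            preds = {"a": random_detections(rng, 8), "b": random_detections(rng, 5)}
            gts = {
                "a": [d.box for d in random_detections(rng, 2)],
                "b": [d.box for d in random_detections(rng, 1)],
            }
            thr = float(rng.uniform(0, 1))
            m = match_at_threshold(preds, gts, thr)
            kept = sum(
                1 for ds in preds.values() for d in ds if d.score >= thr
            )
            credited = {
                (img, p)
                for (img, _g), p_idxs in m.hits.items()
                for p in p_idxs
            }
            assert len(credited) + len(m.false_positives) == kept


class TestFroc:
    def test_perfect_detector(self):
        preds = {"a": [det(4, 4, 6, 6, 0.9)], "b": [det(4, 4, 6, 6, 0.8)]}
        gts = {"a": [Box(0, 0, 10, 10)], "b": [Box(0, 0, 10, 10)]}
        curve = froc(preds, gts)
        assert curve.points[-1].sensitivity == 1.0
        assert all(p.fpi == 0.0 for p in curve.points)

    def test_point_count(self):
        preds = {"a": [det(0, 0, 2, 2, s) for s in (0.2, 0.5, 0.9)]}
        gts = {"a": [Box(0, 0, 10, 10)]}
        curve = froc(preds, gts)
        assert len(curve.points) == 4  # 3 unique scores + inf
        assert curve.points[0].threshold == math.inf

    def test_zero_gt_rejected(self):
        with pytest.raises(InputError):
            froc({"a": []}, {"a": []})

    def test_monotonicity_invariants(self, rng):
        for _ in range(50):
            preds = {f"i{k}": random_detections(rng, 10) for k in range(3)}
            gts = {f"i{k}": [d.box for d in random_detections(rng, 2)] for k in range(3)}
            curve = froc(preds, gts)  # constructor validates monotonicity
            assert curve.points[0] == FROCPoint(math.inf, 0.0, 0.0)

    def test_oracle_equivalence_200_cases(self, rng):
        for _ in range(200):
            n_img = int(rng.integers(1, 5))
            preds = {
                f"i{k}": random_detections(rng, int(rng.integers(0, 8)))
                for k in range(n_img)
            }
            gts = {
                f"i{k}": [d.box for d in random_detections(rng, int(rng.integers(0, 3)))]
                for k in range(n_img)
            }
            if sum(len(v) for v in gts.values()) == 0:
                continue
            curve = froc(preds, gts)
            ref = froc_reference(preds, gts)
            assert len(curve.points) == len(ref)
            for p, (thr, fpi, sens) in zip(curve.points, ref):
                assert p.threshold == thr
                assert p.fpi == pytest.approx(fpi)
                assert p.sensitivity == pytest.approx(sens)

    def test_brute_force_match_agreement(self, rng):
        """4-image constructed instance: froc points equal fresh
        match_at_threshold runs at every threshold."""
        preds = {
            "a": [det(4, 4, 6, 6, 0.9), det(40, 40, 50, 50, 0.7)],
            "b": [det(4, 4, 6, 6, 0.6)],
            "c": [det(0, 0, 3, 3, 0.5), det(4, 4, 6, 6, 0.4), det(7, 7, 9, 9, 0.3)],
            "d": [],
        }
        gts = {
            "a": [Box(0, 0, 10, 10)],
            "b": [Box(20, 20, 30, 30)],
            "c": [Box(0, 0, 10, 10)],
            "d": [],
        }
        curve = froc(preds, gts)
        for p in curve.points:
            m = match_at_threshold(preds, gts, p.threshold)
            assert p.sensitivity == pytest.approx(m.sensitivity)
            assert p.fpi == pytest.approx(m.fpi)


class TestFROCCurveType:
    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(InputError):
            FROCCurve(points=(FROCPoint(0.5, 0, 0), FROCPoint(0.9, 1, 1)))

    def test_decreasing_sensitivity_rejected(self):
        with pytest.raises(InputError):
            FROCCurve(points=(FROCPoint(0.9, 0, 0.5), FROCPoint(0.5, 1, 0.2)))


class TestSensitivityAtFpi:
    def make_curve(self, pts):
        return FROCCurve(points=tuple(FROCPoint(*p) for p in pts))

    def test_readout(self):
        curve = self.make_curve([(0.9, 0.1, 0.6), (0.5, 0.3, 0.8)])
        assert sensitivity_at_fpi(curve, 0.3) == 0.8

    def test_below_first_point(self):
        curve = self.make_curve([(0.9, 0.1, 0.6)])
        assert sensitivity_at_fpi(curve, 0.05) == 0.0

    def test_step_convention_never_overcredits(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 10))
            fpis = np.sort(rng.uniform(0, 5, n))
            senss = np.sort(rng.uniform(0, 1, n))
            thrs = np.sort(rng.uniform(0, 1, n))[::-1]
            curve = self.make_curve(list(zip(thrs, fpis, senss)))
            target = float(rng.uniform(0, 6))
            val = sensitivity_at_fpi(curve, target)
            above = [p.sensitivity for p in curve.points if p.fpi > target]
            if above:
                assert val <= min(above) + 1e-12
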