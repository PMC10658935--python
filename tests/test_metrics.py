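"""Agreement metrics against brute-force set-arithmetic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dcebench.errors import IntegrityError
from dcebench.metrics import (
    center_slice_index,
    dice,
    effective_diameter,
    evaluate_lesion,
    hausdorff_slice,
    lesion_median_hd,
)
from dcebench.types import LesionVOI, SegmentationMask

from .conftest import random_mask


def brute_dice(a, b):
    sa = {tuple(p) for p in np.argwhere(a)}
    sb = {tuple(p) for p in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def brute_boundary(mask):
    pts = set()
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    pts.add((r, c))
                    break
    return pts


def brute_hausdorff(a, b, spacing):
    pa, pb = brute_boundary(a), brute_boundary(b)
    if not pa and not pb:
        return 0.0
    if not pa or not pb:
        return None

    def h(p, q):
        return max(
            min(
                np.hypot((x1 - x2) * spacing[0], (y1 - y2) * spacing[1])
                for x2, y2 in q
            )
            for x1, y1 in p
        )

    return max(h(pa, pb), h(pb, pa))


class TestDice:
    def test_identity_and_disjoint(self):
        a = np.zeros((4, 4), bool)
        a[1:3, 1:3] = True
        b = np.zeros((4, 4), bool)
        b[0, 0] = True
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_counted_example(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:4] = True
        b[1:7] = True
        assert dice(a, b) == pytest.approx(2 * 3 / (4 + 6))

    def test_shape_mismatch(self):
        with pytest.raises(IntegrityError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestHausdorff:
    def test_identity_is_zero(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        assert hausdorff_slice(m, m, (1.0, 1.0)) == 0.0

    def test_two_single_pixels(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[2, 0] = True
        b[2, 3] = True
        assert hausdorff_slice(a, b, (1.0, 1.0)) == pytest.approx(3.0)

    def test_anisotropic_spacing(self):
        a = np.zeros((1, 8), bool)
        b = np.zeros((1, 8), bool)
        a[0, 0] = a[0, 3] = True
        b[0, 0] = True
        # columns 3 apart at 0.5 mm column spacing
        assert hausdorff_slice(a, b, (1.0, 0.5)) == pytest.approx(1.5)

    def test_one_empty_is_undefined_both_empty_zero(self):
        e = np.zeros((3, 3), bool)
        m = e.copy()
        m[1, 1] = True
        assert hausdorff_slice(e, m, (1.0, 1.0)) is None
        assert hausdorff_slice(e, e, (1.0, 1.0)) == 0.0

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            a = random_mask(rng, (rng.integers(2, 13), rng.integers(2, 13)))
            b = random_mask(rng, a.shape)
            spacing = (float(rng.uniform(0.5, 2)), float(rng.uniform(0.5, 2)))
            expected = brute_hausdorff(a, b, spacing)
            got = hausdorff_slice(a, b, spacing)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)
            assert dice(a, b) == pytest.approx(brute_dice(a, b))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(bool, (7, 7), elements=st.booleans()),
        arrays(bool, (7, 7), elements=st.booleans()),
    )
    def test_symmetry_and_bounds_property(self, a, b):
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)
        h = hausdorff_slice(a, b, (1.0, 1.0))
        assert h == hausdorff_slice(b, a, (1.0, 1.0))
        if h is not None:
            assert h >= 0.0
            if h == 0.0:
                assert brute_boundary(a) == brute_boundary(b)

    def test_symmetry_and_scale_covariance(self):
        rng = np.random.default_rng(3)
        a = random_mask(rng, (10, 10))
        b = random_mask(rng, (10, 10))
        h1 = hausdorff_slice(a, b, (1.0, 1.0))
        assert h1 == hausdorff_slice(b, a, (1.0, 1.0))
        h2 = hausdorff_slice(a, b, (2.0, 2.0))
        if h1 is not None:
            assert h2 == pytest.approx(2 * h1)
        assert dice(a, b) == dice(b, a)


class TestMedianHD:
    def test_median_over_slices(self):
        # three slices with single-pixel offsets 1, 2, 9 columns
        pred = np.zeros((3, 1, 12), bool)
        ref = np.zeros((3, 1, 12), bool)
        for z, off in enumerate((1, 2, 9)):
            ref[z, 0, 0] = True
            pred[z, 0, off] = True
        assert lesion_median_hd(pred, ref, (1.0, 1.0, 1.0)) == pytest.approx(2.0)

    def test_even_count_mean_of_middle(self):
        pred = np.zeros((2, 1, 8), bool)
        ref = np.zeros((2, 1, 8), bool)
        for z, off in enumerate((1, 3)):
            ref[z, 0, 0] = True
            pred[z, 0, off] = True
        assert lesion_median_hd(pred, ref, (1.0, 1.0, 1.0)) == pytest.approx(2.0)

    def test_empty_prediction_undefined(self):
        ref = np.zeros((3, 4, 4), bool)
        ref[1, 1:3, 1:3] = True
        assert lesion_median_hd(np.zeros_like(ref), ref, (1.0, 1.0, 1.0)) is None


class TestCenterSliceAndDiameter:
    @pytest.mark.parametrize(
        "first,last,expected", [(2, 6, 4), (2, 5, 3), (7, 7, 7)]
    )
    def test_center_slice_index(self, first, last, expected):
        voi = LesionVOI((0, 4), (0, 4), first, last)
        assert center_slice_index(voi) == expected

    def test_effective_diameter_values(self):
        m = np.zeros((20, 20), bool)
        m.flat[:100] = True
        assert effective_diameter(m, (1.0, 1.0)) == pytest.approx(11.2838, abs=1e-4)
        single = np.zeros((3, 3), bool)
        single[1, 1] = True
        assert effective_diameter(single, (1.0, 1.0)) == pytest.approx(1.1284, abs=1e-4)
        with pytest.raises(ValueError):
            effective_diameter(np.zeros((3, 3), bool), (1.0, 1.0))

    def test_diameter_scale_covariance(self):
        m = np.zeros((10, 10), bool)
        m[2:7, 2:7] = True
        d1 = effective_diameter(m, (1.0, 1.0))
        assert effective_diameter(m, (2.0, 2.0)) == pytest.approx(2 * d1)


class TestEvaluateLesion:
    def _voi(self):
        return LesionVOI((0, 8), (0, 8), 0, 4)

    def test_identity(self):
        ref = np.zeros((5, 8, 8), bool)
        ref[1:4, 2:6, 2:6] = True
        sm = SegmentationMask.from_array(ref, (3.0, 1.0, 1.0))
        rec = evaluate_lesion(sm, sm, self._voi(), lesion_id="x")
        assert rec.dsc == 1.0
        assert rec.median_hd_mm == 0.0
        assert rec.center_dsc == 1.0
        assert not rec.failed

    def test_failed_policy(self):
        ref = np.zeros((5, 8, 8), bool)
        ref[1:4, 2:6, 2:6] = True
        pred = SegmentationMask.from_array(np.zeros_like(ref), (3.0, 1.0, 1.0))
        refm = SegmentationMask.from_array(ref, (3.0, 1.0, 1.0))
        rec = evaluate_lesion(pred, refm, self._voi())
        assert rec.failed
        assert rec.dsc == 0.0
        assert rec.median_hd_mm is None

    def test_one_voxel_shift(self):
        ref = np.zeros((3, 8, 8), bool)
        ref[1, 2:5, 2:5] = True
        pred = np.roll(ref, 1, axis=2)
        r = SegmentationMask.from_array(ref, (3.0, 1.0, 1.0))
        p = SegmentationMask.from_array(pred, (3.0, 1.0, 1.0))
        rec = evaluate_lesion(p, r, LesionVOI((0, 8), (0, 8), 0, 2))
        assert rec.median_hd_mm == pytest.approx(1.0)
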