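"""U-Net arm plumbing: sampling rules, resizing, thresholds, calibration."""

import numpy as np
import pytest

from dcebench.errors import ConfigurationError, IntegrityError
from dcebench.metrics import dice
from dcebench.nn import UNetConfig
from dcebench.pipeline import truth_on_voi
from dcebench.types import ProbabilityMap
from dcebench.unet_pipeline import (
    DEFAULT_THRESHOLD_GRID,
    assemble_quasi3d,
    binarize,
    calibrate_threshold,
    make_2d_training_set,
    make_3d_training_set,
    predict_slices,
    resize_prediction_to_voi,
    resize_preserve_range,
    train_unet,
)

from .conftest import make_case


@pytest.fixture(scope="module")
def labelled_cases(protocol):
    cases = [make_case(seed=500 + i, protocol=protocol, case_id=f"u{i}")
             for i in range(4)]
    labels = {c.case_id: truth_on_voi(c) for c in cases}
    return cases, labels


@pytest.fixture(scope="module")
def tiny_trained(labelled_cases):
    cases, labels = labelled_cases
    samples = make_2d_training_set(cases, labels, timepoint=2, size=32)
    return train_unet(
        samples, UNetConfig(ndim=2, base_filters=4, levels=2), epochs=3, seed=0
    )


class TestTrainingSets:
    def test_top_and_bottom_slices_excluded(self, labelled_cases):
        cases, labels = labelled_cases
        case = cases[0]
        samples = make_2d_training_set([case], labels, timepoint=2, size=32)
        n = case.voi.n_slices
        assert len(samples) == n - 2
        assert [s.slice_index for s in samples] == list(range(1, n - 1))

    def test_short_lesions_keep_all_slices(self, labelled_cases, caplog):
        import dataclasses

        cases, labels = labelled_cases
        case = cases[0]
        # shrink the VOI to two slices to simulate a thin lesion
        voi = dataclasses.replace(
            case.voi, first_slice=case.voi.first_slice,
            last_slice=case.voi.first_slice + 1,
        )
        thin = dataclasses.replace(case, voi=voi)
        ref = truth_on_voi(thin)
        with caplog.at_level("WARNING"):
            samples = make_2d_training_set(
                [thin], {thin.case_id: ref}, timepoint=2, size=32
            )
        assert len(samples) == 2
        assert "keeping all slices" in caplog.text

    def test_3d_samples_keep_slice_count(self, labelled_cases):
        cases, labels = labelled_cases
        samples = make_3d_training_set(cases[:2], labels, timepoint=2, size=32)
        for case, s in zip(cases[:2], samples):
            assert s.image.shape == (case.voi.n_slices, 32, 32)
            assert s.target.shape == s.image.shape


class TestResize:
    def test_range_preserved(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 812, size=(64, 48))
        img.flat[0], img.flat[1] = 0.0, 812.0
        out = resize_preserve_range(img, (256, 256))
        assert out.shape == (256, 256)
        assert out.min() == pytest.approx(0.0, abs=1e-5)
        assert out.max() == pytest.approx(812.0, abs=1e-5)

    def test_identity_resize(self):
        img = np.random.default_rng(1).uniform(size=(32, 32))
        assert np.allclose(resize_preserve_range(img, (32, 32)), img)

    def test_downsized_disk_stays_connected(self):
        from scipy import ndimage

        yy, xx = np.mgrid[:256, :256]
        disk = ((yy - 128) ** 2 + (xx - 128) ** 2 <= 80**2).astype(float)
        prob = np.stack([disk * 0.9])
        mask = resize_prediction_to_voi(prob, (1, 64, 64), (1, 1, 1), threshold=0.25)
        _, n = ndimage.label(mask.data[0])
        assert n == 1


class TestPredictionAndAssembly:
    def test_one_map_per_voi_slice(self, labelled_cases, tiny_trained):
        cases, _ = labelled_cases
        case = cases[1]
        maps = predict_slices(tiny_trained, case, timepoint=2, size=32)
        assert len(maps) == case.voi.n_slices
        for m in maps:
            assert m.data.shape == (32, 32)
            assert 0 <= m.data.min() and m.data.max() <= 1

    def test_inference_deterministic(self, labelled_cases, tiny_trained):
        cases, _ = labelled_cases
        a = predict_slices(tiny_trained, cases[2], timepoint=2, size=32)
        b = predict_slices(tiny_trained, cases[2], timepoint=2, size=32)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.data, mb.data)

    def test_quasi3d_threshold_exact(self):
        prob = np.full((3, 8, 8), 0.05)
        prob[:, 2:6, 2:6] = 0.9
        maps = [ProbabilityMap(p) for p in prob]
        mask = assemble_quasi3d(maps, threshold=0.25)
        expected = prob > 0.25
        assert np.array_equal(mask.data, expected)
        assert not mask.failed

    def test_uniform_low_probability_flags_failed(self):
        maps = [ProbabilityMap(np.full((8, 8), 0.1))] * 3
        mask = assemble_quasi3d(maps, threshold=0.25)
        assert mask.failed and not mask.data.any()

    def test_single_slice_identity(self):
        p = np.random.default_rng(2).uniform(size=(8, 8))
        mask = assemble_quasi3d([ProbabilityMap(p)], threshold=0.25)
        assert np.array_equal(mask.data[0], p > 0.25)

    def test_stacking_matches_independent_slices(self):
        rng = np.random.default_rng(6)
        prob = rng.uniform(size=(4, 8, 8))
        stacked = assemble_quasi3d([ProbabilityMap(p) for p in prob], 0.25)
        singles = [assemble_quasi3d([ProbabilityMap(p)], 0.25).data[0] for p in prob]
        assert np.array_equal(stacked.data, np.stack(singles))

    @pytest.mark.parametrize("thr", [0.0, 1.0, 1.5, -0.2])
    def test_threshold_out_of_range(self, thr):
        with pytest.raises(ValueError):
            assemble_quasi3d([ProbabilityMap(np.zeros((4, 4)))], threshold=thr)


class TestCalibration:
    def test_dilation_ring_selects_first_clean_threshold(self):
        from scipy import ndimage

        ref = np.zeros((16, 16), bool)
        ref[5:11, 5:11] = True
        ring = ndimage.binary_dilation(ref) & ~ref
        prob = np.full(ref.shape, 0.05)
        prob[ring] = 0.205  # strictly above the 0.20 grid point
        prob[ref] = 0.9
        cal = calibrate_threshold([prob], [ref], DEFAULT_THRESHOLD_GRID)
        assert cal.selected == pytest.approx(0.21)
        for t, d in zip(cal.grid, cal.mean_dsc):
            assert d == pytest.approx(1.0 if t >= 0.21 else dice(prob > t, ref))

    def test_perfect_map_ties_break_to_smallest(self):
        ref = np.zeros((8, 8), bool)
        ref[2:5, 2:5] = True
        cal = calibrate_threshold([ref.astype(float)], [ref], DEFAULT_THRESHOLD_GRID)
        assert cal.selected == pytest.approx(0.14)

    def test_singleton_grid(self):
        ref = np.zeros((4, 4), bool)
        ref[1, 1] = True
        cal = calibrate_threshold([ref.astype(float)], [ref], (0.25,))
        assert cal.selected == 0.25

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(9)
        probs = [rng.uniform(size=(10, 10)) for _ in range(6)]
        refs = [rng.uniform(size=(10, 10)) > 0.6 for _ in range(6)]
        cal = calibrate_threshold(probs, refs, DEFAULT_THRESHOLD_GRID)
        means = [
            np.mean([dice(binarize(p, t), r) for p, r in zip(probs, refs)])
            for t in cal.grid
        ]
        assert cal.selected == cal.grid[int(np.argmax(means))]
        assert max(cal.mean_dsc) == pytest.approx(max(means))

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            calibrate_threshold([], [], DEFAULT_THRESHOLD_GRID)


class TestBackResize:
    def test_identity_round_trip(self):
        rng = np.random.default_rng(3)
        prob = rng.uniform(size=(2, 16, 16))
        mask = resize_prediction_to_voi(prob, (2, 16, 16), (1, 1, 1), threshold=0.5)
        assert np.array_equal(mask.data, prob > 0.5)

    def test_slice_count_mismatch(self):
        with pytest.raises(IntegrityError):
            resize_prediction_to_voi(
                np.zeros((3, 8, 8)), (5, 8, 8), (1, 1, 1), threshold=0.5
            )


class TestTrainingErrors:
    def test_empty_training_set(self):
        with pytest.raises(ConfigurationError):
            train_unet([], UNetConfig(), epochs=1)

    def test_zero_epochs(self, labelled_cases):
        cases, labels = labelled_cases
        samples = make_2d_training_set(cases[:1], labels, timepoint=2, size=32)
        with pytest.raises(ConfigurationError):
            train_unet(samples, UNetConfig(ndim=2, base_filters=4, levels=2), epochs=0)

    def test_learning_sanity(self, tiny_trained):
        assert tiny_trained.loss_log[-1] < tiny_trained.loss_log[0]
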