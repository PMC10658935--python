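"""Phantom generator: kinetics, morphology, cohort composition, determinism."""

import numpy as np
import pytest
from scipy import ndimage

from dcebench.errors import GeometryError, InvalidProtocolError
from dcebench.metrics import effective_diameter
from dcebench.synthetic import (
    DEFAULT_KINETICS,
    ProtocolConfig,
    enhancement_curve,
    generate_lesion_shape,
    sample_specs,
    subtraction_image,
)
from dcebench.types import (
    EnhancementType,
    KineticClass,
    KineticClassName,
    LesionSpec,
    Pathology,
)

from .conftest import make_case

T = [0.0, 75.0, 150.0]


class TestEnhancementCurve:
    def test_persistent_monotone_from_zero(self):
        e = enhancement_curve(KineticClass(KineticClassName.PERSISTENT, 0.8), T)
        assert e[0] == 0.0
        assert np.all(np.diff(e) >= 0)

    def test_washout_declines_after_peak(self):
        k = KineticClass(KineticClassName.WASHOUT, 1.0, time_to_peak_s=75.0)
        e = enhancement_curve(k, T)
        assert e[1] > e[2]

    def test_plateau_holds_after_peak(self):
        k = KineticClass(KineticClassName.PLATEAU, 1.0, time_to_peak_s=75.0)
        e = enhancement_curve(k, T)
        assert e[1] == pytest.approx(e[2]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "times", [[0.0], [0.0, 75.0], [10.0, 75.0, 150.0], [0.0, 75.0, 75.0]]
    )
    def test_invalid_protocols_rejected(self, times):
        with pytest.raises(InvalidProtocolError):
            enhancement_curve(KineticClass(KineticClassName.PERSISTENT), times)


class TestLesionShape:
    def test_mass_diameter_calibration(self):
        spec = LesionSpec(
            EnhancementType.MASS, Pathology.MALIGNANT, 10.0,
            DEFAULT_KINETICS[Pathology.MALIGNANT], seed=4,
        )
        spacing = (2.0, 0.5, 0.5)
        mask = generate_lesion_shape(spec, spacing, (18, 64, 64))
        zs = np.nonzero(mask.any(axis=(1, 2)))[0]
        center = (zs[0] + zs[-1]) // 2
        d = effective_diameter(mask[center], spacing[1:])
        assert abs(d - 10.0) <= 0.5

    def test_mass_is_single_component(self):
        spec = LesionSpec(
            EnhancementType.MASS, Pathology.BENIGN, 12.0,
            DEFAULT_KINETICS[Pathology.BENIGN], seed=9,
        )
        mask = generate_lesion_shape(spec, (3.0, 0.8, 0.8), (18, 64, 64))
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_nonmass_scattered_in_center_slice(self):
        spec = LesionSpec(
            EnhancementType.NONMASS, Pathology.BENIGN, 10.0,
            DEFAULT_KINETICS[Pathology.BENIGN], seed=7,
        )
        mask = generate_lesion_shape(spec, (3.0, 0.8, 0.8), (18, 64, 64))
        center = mask.shape[0] // 2
        _, n = ndimage.label(mask[center])  # default structure = 4-connectivity
        assert n >= 2
        d = effective_diameter(mask[center], (0.8, 0.8))
        assert abs(d - 10.0) <= 0.8

    def test_oversized_lesion_rejected(self):
        spec = LesionSpec(
            EnhancementType.MASS, Pathology.BENIGN, 1000.0,
            DEFAULT_KINETICS[Pathology.BENIGN], seed=1,
        )
        with pytest.raises(GeometryError):
            generate_lesion_shape(spec, (3.0, 0.8, 0.8), (18, 64, 64))

    def test_size_calibration_mean_error_under_one_voxel(self):
        """Requested vs realized effective diameter over many masses."""
        rng = np.random.default_rng(5)
        spacing = (3.0, 0.8, 0.8)
        errors = []
        for i in range(100):
            d_req = float(rng.uniform(4.0, 24.0))
            spec = LesionSpec(
                EnhancementType.MASS, Pathology.MALIGNANT, d_req,
                DEFAULT_KINETICS[Pathology.MALIGNANT], seed=3000 + i,
            )
            mask = generate_lesion_shape(spec, spacing, (18, 64, 64))
            zs = np.nonzero(mask.any(axis=(1, 2)))[0]
            center = (zs[0] + zs[-1]) // 2
            errors.append(abs(effective_diameter(mask[center], spacing[1:]) - d_req))
        assert np.mean(errors) <= 0.8


class TestCaseGeneration:
    def test_zero_noise_closed_form(self, clean_protocol):
        case = make_case(protocol=clean_protocol, seed=5)
        curve = enhancement_curve(case.spec.kinetic, clean_protocol.timepoints_s)
        pre = case.series[0][case.truth_mask].mean()
        post1 = case.series[1][case.truth_mask].mean()
        assert post1 == pytest.approx((1.0 + curve[1]) * pre, rel=1e-5)

    def test_determinism(self, protocol):
        a = make_case(protocol=protocol, seed=42)
        b = make_case(protocol=protocol, seed=42)
        assert np.array_equal(a.series, b.series)
        assert np.array_equal(a.truth_mask, b.truth_mask)
        assert a.voi == b.voi

    def test_truth_mask_inside_voi(self, mass_case, nonmass_case):
        for case in (mass_case, nonmass_case):
            outside = case.truth_mask.copy()
            outside[case.voi.slicer()] = False
            assert not outside.any()

    def test_voi_slices_are_mask_support_plus_margin(self, protocol, mass_case):
        zs = np.nonzero(mass_case.truth_mask.any(axis=(1, 2)))[0]
        m = protocol.voi_margin_slices
        assert mass_case.voi.first_slice == max(zs[0] - m, 0)
        assert mass_case.voi.last_slice == min(
            zs[-1] + m, mass_case.truth_mask.shape[0] - 1
        )

    def test_second_postcontrast_has_more_lesion_contrast(self, clean_protocol):
        """Mass lesions enhance more at the second postcontrast timepoint."""
        for pathology in (Pathology.BENIGN, Pathology.MALIGNANT):
            case = make_case(pathology=pathology, protocol=clean_protocol, seed=8)
            s1 = subtraction_image(case, 1)[case.truth_mask].mean()
            s2 = subtraction_image(case, 2)[case.truth_mask].mean()
            assert s2 > s1


class TestSubtraction:
    def test_arithmetic(self, clean_mass_case):
        sub = subtraction_image(clean_mass_case, 1)
        expected = clean_mass_case.series[1] - clean_mass_case.series[0]
        assert np.array_equal(sub, expected)

    @pytest.mark.parametrize("idx", [0, 3, -1])
    def test_bad_index(self, clean_mass_case, idx):
        with pytest.raises(IndexError):
            subtraction_image(clean_mass_case, idx)

    def test_lesion_brighter_than_background(self, clean_mass_case):
        sub = subtraction_image(clean_mass_case, 1)
        lesion = sub[clean_mass_case.truth_mask]
        background = sub[~clean_mass_case.truth_mask]
        assert lesion.min() > background.max()


class TestCohortSampling:
    def test_largest_remainder_rounding(self):
        comp = {("mass", "malignant"): 0.7, ("nonmass", "malignant"): 0.3}
        specs = sample_specs(20, seed=1, composition=comp)
        kinds = [s.enhancement_type.value for s in specs]
        assert kinds.count("mass") == 14
        assert kinds.count("nonmass") == 6

    def test_clinical_composition_at_full_cohort_size(self):
        specs = sample_specs(994, seed=2)
        counts = {}
        for s in specs:
            key = (s.enhancement_type.value, s.pathology.value)
            counts[key] = counts.get(key, 0) + 1
        assert counts[("mass", "benign")] == 170
        assert counts[("mass", "malignant")] == 517
        assert counts[("nonmass", "benign")] == 49
        assert counts[("nonmass", "malignant")] == 175
        assert counts[("unknown", "benign")] == 51
        assert counts[("unknown", "malignant")] == 32

    def test_spec_sampling_deterministic(self):
        assert sample_specs(30, seed=9) == sample_specs(30, seed=9)

    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError):
            sample_specs(10, seed=0, composition={("mass", "benign"): 0.5})

    def test_cohort_written_manifest_roundtrip(self, tmp_path):
        from dcebench.synthetic import generate_cohort

        small = ProtocolConfig(volume_shape=(12, 48, 48))
        m1 = generate_cohort(4, tmp_path / "a", seed=3, protocol=small)
        m2 = generate_cohort(4, tmp_path / "b", seed=3, protocol=small)
        cols = ["case_id", "pathology", "enhancement_type",
                "effective_diameter_mm", "size_bin", "kinetic_class"]
        assert m1[cols].equals(m2[cols])
        assert m1.case_id.is_unique
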