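"""Sum-normalized permeation profiles, ROI mode, depth of detection."""

import numpy as np
import pytest

from skinmsi.io import IonImage
from skinmsi.layering import assign_layers, straighten
from skinmsi.profiles import (
    PermeationProfile,
    RoiLayerSet,
    compare_profiles,
    depth_of_detection,
    layer_profile,
    roi_profile,
)
from skinmsi.segmentation import TissueMask
from skinmsi.synthetic import SectionSpec, generate_section, true_profile


@pytest.fixture
def rect_layers():
    mask = TissueMask({(c, r) for c in range(10) for r in range(8)})
    st = straighten(mask)
    return st, assign_layers(st, 4, method="equal-width-bins")


def image_from(values: np.ndarray) -> IonImage:
    return IonImage(values, target_mz=292.207, tol=0.02)


class TestLayerProfile:
    def test_uniform_image_gives_equal_fractions(self, rect_layers):
        _, la = rect_layers
        prof = layer_profile(image_from(np.full((8, 10), 3.0)), la)
        assert np.allclose(prof.fraction, 0.25)

    def test_fractions_sum_to_one(self, rect_layers):
        _, la = rect_layers
        rng = np.random.default_rng(0)
        prof = layer_profile(image_from(rng.uniform(0, 10, (8, 10))), la)
        assert prof.fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, rect_layers):
        _, la = rect_layers
        rng = np.random.default_rng(1)
        img = image_from(rng.uniform(0, 10, (8, 10)))
        p1 = layer_profile(img, la)
        p2 = layer_profile(img.scaled(37.5), la)
        assert np.allclose(p1.fraction, p2.fraction)

    def test_blank_section_flagged_not_nan(self, rect_layers):
        _, la = rect_layers
        prof = layer_profile(image_from(np.zeros((8, 10))), la)
        assert not prof.valid
        assert np.all(prof.fraction == 0) and not np.any(np.isnan(prof.fraction))

    def test_mean_includes_zero_intensity_pixels(self, rect_layers):
        _, la = rect_layers
        values = np.zeros((8, 10))
        values[0, 0] = 10.0  # one hot pixel in layer 0 (20 pixels)
        prof = layer_profile(image_from(values), la)
        assert prof.mean_intensity[0] == pytest.approx(0.5)

    def test_recovers_exponential_decay_profile(self):
        """Pipeline-free check: layer means on a noisy synthetic section
        track the analytic slab expectation (Pearson r >= 0.95)."""
        spec = SectionSpec(n_cols=60, n_rows=40, band_center_row=20.0, seed=5)
        dataset, gt = generate_section(spec)
        from skinmsi.io import extract_ion_image

        mask = TissueMask(gt.tissue)
        st = straighten(mask)
        la = assign_layers(st, 10, pixel_size_um=spec.pixel_size_um)
        prof = layer_profile(extract_ion_image(dataset, spec.drug_mz, 0.02), la)
        expected = true_profile(gt, 10)
        r = np.corrcoef(prof.fraction, expected.fraction)[0, 1]
        assert r >= 0.95


class TestRoiProfile:
    def test_two_one_pixel_rois_span_100_um(self):
        rois = RoiLayerSet([{(c, 0) for c in range(5)}, {(c, 1) for c in range(5)}],
                           width_um=50.0)
        assert rois.cumulative_depth_um() == 100.0

    def test_single_roi_gets_fraction_one(self):
        rois = RoiLayerSet([{(c, r) for c in range(4) for r in range(4)}])
        prof = roi_profile(image_from(np.ones((4, 4))), rois)
        assert prof.fraction.tolist() == [1.0]

    def test_overlapping_rois_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RoiLayerSet([{(0, 0), (1, 0)}, {(1, 0)}])

    def test_matches_layer_profile_on_reprojected_layers(self, rect_layers):
        """Manual ROIs drawn as the automatic layers give the same profile."""
        _, la = rect_layers
        rng = np.random.default_rng(2)
        img = image_from(rng.uniform(0, 5, (8, 10)))
        auto = layer_profile(img, la)
        manual = roi_profile(img, RoiLayerSet.from_assignment(la))
        assert np.allclose(manual.mean_intensity, auto.mean_intensity)
        assert np.allclose(manual.fraction, auto.fraction)

    def test_permutation_safety(self, rect_layers):
        _, la = rect_layers
        rng = np.random.default_rng(4)
        img = image_from(rng.uniform(0, 5, (8, 10)))
        masks = [la.members(j) for j in range(la.n_layers)]
        p1 = roi_profile(img, RoiLayerSet(masks))
        p2 = roi_profile(img, RoiLayerSet([set(sorted(m)) for m in masks]))
        assert np.allclose(p1.fraction, p2.fraction)


class TestDepthOfDetection:
    def make_profile(self, fractions, width=50.0):
        n = len(fractions)
        f = np.asarray(fractions, dtype=float)
        widths = np.full(n, width)
        mids = width * (np.arange(n) + 0.5)
        return PermeationProfile(np.arange(n), mids, widths, f.copy(), f, valid=True)

    def test_half_half_profile_reaches_100_um(self):
        prof = self.make_profile([0.5, 0.5, 0.0, 0.0])
        assert depth_of_detection(prof, floor=0.01) == 100.0

    def test_floor_above_max_gives_zero(self):
        prof = self.make_profile([0.6, 0.4])
        assert depth_of_detection(prof, floor=0.7) == 0.0

    def test_floor_outside_unit_interval_rejected(self):
        prof = self.make_profile([0.6, 0.4])
        with pytest.raises(ValueError):
            depth_of_detection(prof, floor=1.5)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            raw = rng.uniform(0, 1, 6)
            f = raw / raw.sum()
            prof = self.make_profile(f)
            floor = float(rng.uniform(0.01, 0.5))
            expect = 0.0
            for j in range(6):
                if f[j] >= floor:
                    expect = 50.0 * (j + 1)
            assert depth_of_detection(prof, floor) == expect


class TestCompareProfiles:
    def test_duplicate_profile_gives_identical_rows(self):
        prof = TestDepthOfDetection().make_profile([0.7, 0.3])
        long, summary = compare_profiles([prof, prof], ids=["a", "b"])
        a = long[long.profile_id == "a"].drop(columns="profile_id").reset_index(drop=True)
        b = long[long.profile_id == "b"].drop(columns="profile_id").reset_index(drop=True)
        assert a.equals(b)
        assert set(summary.profile_id) == {"a", "b"}

    def test_detection_depth_increases_with_decay_scale(self):
        """Deeper-delivering formulations (larger decay scale) detect deeper."""
        from skinmsi.synthetic import SyntheticGroundTruth

        profs = []
        for scale in (100.0, 150.0, 300.0):
            spec = SectionSpec(drug_scale_um=scale)
            profs.append(true_profile(SyntheticGroundTruth(set(), {}, spec), 10))
        _, summary = compare_profiles(profs, ids=["e", "t", "m"])
        depths = summary.depth_of_detection_um.tolist()
        assert depths[0] < depths[1] < depths[2]

    def test_timepoint_series_table_shape(self):
        prof = TestDepthOfDetection().make_profile([0.5, 0.3, 0.2])
        long, _ = compare_profiles([prof] * 4, ids=[f"t{h}h" for h in (1, 3, 6, 24)])
        assert list(long.columns) == ["profile_id", "layer", "depth_um",
                                      "mean_intensity", "fraction"]
        assert len(long) == 12

    def test_fewer_than_two_rejected(self):
        prof = TestDepthOfDetection().make_profile([1.0])
        with pytest.raises(ValueError):
            compare_profiles([prof])
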