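"""Nuclear segmentation, intensity/area phenotypes, punctate quantification
and group statistics, scored against generator ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from arrayscreen.errors import InsufficientDataError, NoForegroundError
from arrayscreen.imaging import (
    ImageField,
    compare_groups,
    measure_nuclear_area,
    measure_nuclear_intensity,
    object_qc_filter,
    segment_golgi,
    segment_nuclei,
)
from arrayscreen.synth import ImageSimSpec, simulate_image

from conftest import match_centroids


def _field(**kw):
    return simulate_image(ImageSimSpec(**kw))


class TestSegmentNuclei:
    def test_recovers_separated_disks_with_accurate_centroids(self):
        fld, _, truth = _field(n_nuclei=12, gaussian_noise_sd=10,
                               background=50, seed=2)
        seg = segment_nuclei(fld)
        assert seg.n_objects == 12
        assert match_centroids(seg.objects, truth).max() <= 2.0

    def test_splits_canonical_touching_pair(self):
        """Two radius-15 disks, centers 24 px apart, split into two objects
        with areas near a single disk's."""
        nuclear = np.zeros((128, 128))
        rr, cc = np.ogrid[:128, :128]
        for r0, c0 in [(64, 52), (64, 76)]:
            nuclear += 500.0 * np.clip(
                15 - np.hypot(rr - r0, cc - c0) + 0.5, 0, 1
            )
        fld = ImageField(nuclear, np.zeros_like(nuclear))
        seg = segment_nuclei(fld)
        assert seg.n_objects == 2
        single = np.pi * 15**2
        for area in seg.objects["area_px"]:
            assert abs(area - single) / single < 0.15

    def test_generator_touching_pairs_split(self):
        fld, _, truth = _field(n_nuclei=6, touching_fraction=1.0,
                               gaussian_noise_sd=5, seed=0)
        seg = segment_nuclei(fld)
        assert seg.n_objects == len(truth)

    def test_constant_image_is_no_foreground(self):
        fld = ImageField(np.full((64, 64), 7.0), np.zeros((64, 64)))
        with pytest.raises(NoForegroundError):
            segment_nuclei(fld)

    def test_label_conservation_and_intensity_additivity(self):
        fld, _, _ = _field(n_nuclei=10, gaussian_noise_sd=8, seed=5)
        seg = segment_nuclei(fld)
        assert seg.objects["area_px"].sum() == np.count_nonzero(seg.label_map)
        np.testing.assert_allclose(
            seg.objects["total_signal"],
            seg.objects["mean_signal"] * seg.objects["area_px"],
            rtol=1e-9,
        )
        # labels contiguous 1..K
        labels = np.unique(seg.label_map)
        assert labels[0] == 0
        np.testing.assert_array_equal(
            labels[1:], np.arange(1, seg.n_objects + 1)
        )

    def test_invariant_to_affine_intensity_rescale(self):
        fld, _, _ = _field(n_nuclei=8, gaussian_noise_sd=5, seed=9)
        seg1 = segment_nuclei(fld)
        rescaled = ImageField(
            fld.nuclear_channel * 3.7 + 11.0, fld.signal_channel
        )
        seg2 = segment_nuclei(rescaled)
        np.testing.assert_array_equal(seg1.label_map, seg2.label_map)

    def test_matches_connected_components_oracle_on_separated_fields(self):
        """With no touching nuclei, the watershed must agree with plain
        connected-components labelling."""
        from skimage import filters, measure, morphology

        fld, _, truth = _field(n_nuclei=12, gaussian_noise_sd=10, seed=4)
        seg = segment_nuclei(fld)
        smoothed = filters.median(fld.nuclear_channel, morphology.disk(2))
        mask = smoothed > filters.threshold_otsu(smoothed)
        cc, _ = ndi.label(ndi.binary_fill_holes(mask))
        keep = [p for p in measure.regionprops(cc) if p.area >= 40]
        assert seg.n_objects == len(keep) == 12
        oracle_centroids = pd.DataFrame(
            [
                {"center_r": p.centroid[0], "center_c": p.centroid[1]}
                for p in keep
            ]
        )
        assert match_centroids(seg.objects, oracle_centroids).max() < 1.0


class TestMeasurements:
    def test_constant_intensity_objects_measured_exactly(self):
        nuclear = np.zeros((96, 96))
        signal = np.zeros((96, 96))
        rr, cc = np.ogrid[:96, :96]
        for (r0, c0), level in [((30, 30), 100.0), ((65, 65), 900.0)]:
            mask = np.hypot(rr - r0, cc - c0) < 10
            nuclear[mask] = 500.0
            signal[mask] = level
        fld = ImageField(nuclear, signal)
        seg = segment_nuclei(fld, smooth_radius=1)
        means = sorted(measure_nuclear_intensity(seg, "signal"))
        assert means == pytest.approx([100.0, 900.0], rel=0.02)
        nuc_means = measure_nuclear_intensity(seg, "nuclear")
        assert nuc_means.to_numpy() == pytest.approx([500.0, 500.0], rel=0.02)

    def test_disk_area_and_micron_conversion(self):
        nuclear = np.zeros((64, 64))
        rr, cc = np.ogrid[:64, :64]
        nuclear[np.hypot(rr - 32, cc - 32) < 10] = 400.0
        fld = ImageField(nuclear, np.zeros_like(nuclear), pixel_size=0.5)
        seg = segment_nuclei(fld, smooth_radius=1)
        areas = measure_nuclear_area(seg)
        assert len(areas) == 1
        area_px = areas["area_px"].iloc[0]
        assert abs(area_px - np.pi * 100) / (np.pi * 100) < 0.05
        assert areas["area_um2"].iloc[0] == pytest.approx(area_px * 0.25)

    def test_knockout_intensity_ratio_recovered(self):
        """A signal knockout rendered at 20% of control level reads out at
        a ~0.2 median intensity ratio."""
        ctrl_vals, ko_vals = [], []
        for seed in range(3):
            f_ctrl, _, _ = _field(n_nuclei=15, signal_level=400,
                                  gaussian_noise_sd=10, seed=seed)
            f_ko, _, _ = _field(n_nuclei=15, signal_level=80,
                                gaussian_noise_sd=10, seed=100 + seed)
            ctrl_vals += measure_nuclear_intensity(
                segment_nuclei(f_ctrl), "signal").tolist()
            ko_vals += measure_nuclear_intensity(
                segment_nuclei(f_ko), "signal").tolist()
        ratio = np.median(ko_vals) / np.median(ctrl_vals)
        assert 0.15 <= ratio <= 0.25

    def test_enlarged_nuclei_detected_by_ks(self):
        areas_ctrl, areas_big = [], []
        seed = 0
        while len(areas_ctrl) < 200:
            f, _, _ = _field(n_nuclei=14, gaussian_noise_sd=8, seed=seed)
            areas_ctrl += measure_nuclear_area(
                segment_nuclei(f))["area_px"].tolist()
            seed += 1
        while len(areas_big) < 200:
            f, _, _ = _field(n_nuclei=8, radius_scale=1.5,
                             gaussian_noise_sd=8, seed=1000 + seed)
            areas_big += measure_nuclear_area(
                segment_nuclei(f))["area_px"].tolist()
            seed += 1
        res = compare_groups(areas_big[:200], areas_ctrl[:200], test="ks")
        assert res["p_value"] < 1e-6
        assert res["normalized_effect"] > 1.5  # area scales ~ radius^2


class TestGolgi:
    def test_total_puncta_intensity_matches_ground_truth(self):
        fld, _, truth = _field(n_nuclei=5, signal_model="golgi_puncta",
                               signal_level=2000, seed=4)
        seg = segment_nuclei(fld)
        got = segment_golgi(fld, seg)
        d = match_centroids(seg.objects, truth)
        assert d.max() < 3
        from scipy.spatial import cKDTree

        _, idx = cKDTree(truth[["center_r", "center_c"]].to_numpy()).query(
            seg.objects[["centroid_r", "centroid_c"]].to_numpy()
        )
        expected = truth.iloc[idx]["signal_total"].to_numpy()
        np.testing.assert_allclose(got["total_golgi"], expected, rtol=0.10)

    def test_uniform_background_does_not_shift_totals(self):
        base, _, _ = _field(n_nuclei=5, signal_model="golgi_puncta",
                            signal_level=2000, seed=4)
        lifted, _, _ = _field(n_nuclei=5, signal_model="golgi_puncta",
                              signal_level=2000, background=100, seed=4)
        g0 = segment_golgi(base, segment_nuclei(base))
        g1 = segment_golgi(lifted, segment_nuclei(lifted))
        np.testing.assert_allclose(
            g1["total_golgi"], g0["total_golgi"], rtol=0.10
        )

    def test_knockout_puncta_collapse(self):
        ctrl, _, _ = _field(n_nuclei=5, signal_model="golgi_puncta",
                            signal_level=2000, seed=6)
        ko, _, _ = _field(n_nuclei=5, signal_model="golgi_puncta",
                          signal_level=0.0, seed=6)
        g_ctrl = segment_golgi(ctrl, segment_nuclei(ctrl))
        g_ko = segment_golgi(ko, segment_nuclei(ko))
        assert (
            g_ko["total_golgi"].median()
            <= 0.05 * g_ctrl["total_golgi"].median()
        )

    def test_requires_nuclei(self):
        fld, _, _ = _field(n_nuclei=3, signal_model="golgi_puncta", seed=1)
        empty_seg = segment_nuclei(fld)
        empty_seg.objects = empty_seg.objects.iloc[:0]
        empty_seg.label_map = np.zeros_like(empty_seg.label_map)
        with pytest.raises(NoForegroundError):
            segment_golgi(fld, empty_seg)


class TestCompareGroups:
    def test_identical_samples(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups(vals, list(vals), test="ks")
        assert res["p_value"] == pytest.approx(1.0)
        assert res["normalized_effect"] == pytest.approx(1.0)

    def test_disjoint_supports_are_extremely_significant(self):
        lo = np.linspace(0, 1, 50)
        hi = np.linspace(10, 11, 50)
        res = compare_groups(hi, lo, test="mann_whitney")
        assert res["p_value"] < 1e-10

    def test_minimum_group_size(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_type_i_error_near_nominal(self):
        """Shuffled null: the fraction of p < 0.05 stays near 5%."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            pooled = rng.normal(size=100)
            res = compare_groups(pooled[:50], pooled[50:],
                                 test="mann_whitney")
            rejections += res["p_value"] < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.02


class TestObjectQc:
    def test_no_rules_is_identity(self):
        fld, _, _ = _field(n_nuclei=8, seed=3)
        seg = segment_nuclei(fld)
        out = object_qc_filter(seg)
        np.testing.assert_array_equal(out.label_map, seg.label_map)
        pd.testing.assert_frame_equal(out.objects, seg.objects)

    def test_border_objects_excluded_with_reason(self):
        nuclear = np.zeros((64, 64))
        rr, cc = np.ogrid[:64, :64]
        nuclear[np.hypot(rr - 0, cc - 32) < 10] = 500.0  # touches top border
        nuclear[np.hypot(rr - 40, cc - 32) < 10] = 500.0
        fld = ImageField(nuclear, np.zeros_like(nuclear))
        seg = segment_nuclei(fld, smooth_radius=1, exclude_border=False)
        assert seg.n_objects == 2
        out = object_qc_filter(seg, border_exclusion=True)
        assert out.n_objects == 1
        assert list(out.excluded["reason"]) == ["border"]

    def test_bright_mitotic_like_blobs_excluded(self):
        fld, _, truth = _field(n_nuclei=12, nuclear_intensity=500,
                               gaussian_noise_sd=5, seed=8)
        # inject 3 over-bright blobs (mitotic/condensed-chromatin surrogate)
        bright = fld.nuclear_channel.copy()
        rr, cc = np.ogrid[: bright.shape[0], : bright.shape[1]]
        spots = [(60, 450), (450, 60), (250, 470)]
        for r0, c0 in spots:
            bright[np.hypot(rr - r0, cc - c0) < 8] = 5000.0
        fld2 = ImageField(bright, fld.signal_channel)
        seg = segment_nuclei(fld2)
        assert seg.n_objects == 15
        out = object_qc_filter(seg, max_intensity_percentile=80)
        assert len(out.excluded) == 3
        excluded_means = seg.objects.set_index("label").loc[
            out.excluded["label"], "mean_nuclear"
        ]
        assert (excluded_means > 2000).all()
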