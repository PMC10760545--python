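import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from punctaline import (
    PRESETS,
    DetectionParams,
    StraightenedImage,
    detect,
    find_puncta,
    gaussian_blur,
    phansalkar_threshold,
    preview_settings,
)
from punctaline.detect import disk_footprint, otsu_threshold

from .oracles import count_components_flood_fill, phansalkar_brute_force


def fimage(pixels, **kw):
    return StraightenedImage(np.asarray(pixels, dtype=float), bit_depth="float", **kw)


class TestDetectionParams:
    def test_presets_match_published_settings(self):
        p24 = PRESETS["nuIs24"]
        assert (p24.min_size, p24.sigma, p24.radius, p24.method) == (0.2, 1.0, 6, "phansalkar")
        p152 = PRESETS["nuIs152"]
        assert (p152.min_size, p152.sigma, p152.radius, p152.method) == (0.3, 0.75, 1, "phansalkar")

    @pytest.mark.parametrize(
        "kw",
        [
            {"min_size": -1},
            {"sigma": -0.5},
            {"radius": 0},
            {"method": "sauvola"},
            {"connectivity": 6},
        ],
    )
    def test_invalid_params(self, kw):
        with pytest.raises(ValueError):
            DetectionParams(**kw)


class TestGaussianBlur:
    def test_sigma_zero_identity(self, rng):
        img = fimage(rng.random((10, 30)))
        assert gaussian_blur(img, 0.0) is img

    def test_constant_preserved(self):
        img = fimage(np.full((8, 20), 4.5))
        assert np.allclose(gaussian_blur(img, 2.0).pixels, 4.5)

    def test_impulse_response_matches_kernel_summation(self):
        # explicit sampled-and-normalized separable kernel, radius 4*sigma
        sigma = 1.0
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-x.astype(float) ** 2 / (2 * sigma**2))
        k1 /= k1.sum()
        expected_center = k1[radius] ** 2
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        out = gaussian_blur(fimage(img), sigma).pixels
        assert out[10, 10] == pytest.approx(expected_center, rel=1e-12)
        # and close to the continuous-kernel value 1/(2*pi)
        assert out[10, 10] == pytest.approx(1 / (2 * np.pi), rel=0.02)

    def test_negative_sigma(self, rng):
        with pytest.raises(ValueError):
            gaussian_blur(fimage(rng.random((5, 5))), -1.0)


class TestPhansalkar:
    def test_constant_half_is_all_foreground(self):
        # threshold = 0.5*(1 + 2e^-5 + 0.25*(0/0.5 - 1)) ~ 0.3817 < 0.5
        img = fimage(np.full((10, 40), 0.5))
        assert phansalkar_threshold(img, radius=3).all()

    def test_all_zero_is_all_background(self):
        img = fimage(np.zeros((10, 40)))
        assert not phansalkar_threshold(img, radius=3).any()

    @pytest.mark.parametrize("radius", [1, 3, 6])
    def test_matches_brute_force_oracle(self, rng, radius):
        pixels = rng.random((12, 40))
        img = fimage(pixels)
        got = phansalkar_threshold(img, radius=radius)
        want = phansalkar_brute_force(pixels, radius=radius)
        assert np.array_equal(got, want)

    def test_oracle_equivalence_integer_image(self, rng):
        pixels = rng.integers(0, 256, (10, 30)).astype(float)
        img = StraightenedImage(pixels, bit_depth=8)
        got = phansalkar_threshold(img, radius=2)
        want = phansalkar_brute_force(pixels / 255.0, radius=2)
        assert np.array_equal(got, want)

    @settings(max_examples=20, deadline=None)
    @given(
        pixels=hnp.arrays(float, (6, 11), elements=st.floats(0, 1, width=32)),
        radius=st.sampled_from([1, 2, 3]),
    )
    def test_oracle_property(self, pixels, radius):
        got = phansalkar_threshold(fimage(pixels), radius=radius)
        assert np.array_equal(got, phansalkar_brute_force(pixels, radius=radius))

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            phansalkar_threshold(fimage(np.ones((4, 4))), radius=0)

    def test_disk_footprint_matches_euclidean_rule(self):
        fp = disk_footprint(2)
        rr, cc = np.mgrid[-2:3, -2:3]
        assert np.array_equal(fp, rr**2 + cc**2 <= 4)


class TestOtsu:
    def test_splits_bimodal(self):
        img = fimage(np.concatenate([np.zeros((4, 10)), np.ones((4, 10))], axis=0) * 10 + 1)
        mask = otsu_threshold(img)
        assert mask[4:].all() and not mask[:4].any()

    def test_flat_image_all_background(self):
        assert not otsu_threshold(fimage(np.full((4, 4), 3.0))).any()


class TestFindPuncta:
    def test_size_filter(self):
        mask = np.zeros((8, 30), dtype=bool)
        mask[2:4, 2:4] = True  # 4 px
        mask[2:4, 10:12] = True  # 4 px
        mask[6, 20] = True  # 1 px
        rois = find_puncta(mask, min_size=2)
        assert len(rois) == 2
        assert [r.roi_id for r in rois] == [1, 2]
        assert rois[0].bbox == (2, 2, 2, 2)

    def test_empty_mask(self):
        assert find_puncta(np.zeros((5, 5), dtype=bool), min_size=0) == []

    def test_component_count_matches_flood_fill(self, rng):
        for _ in range(20):
            mask = rng.random((16, 64)) < 0.25
            rois = find_puncta(mask, min_size=0)
            assert len(rois) == count_components_flood_fill(mask, connectivity=8)

    def test_four_connectivity(self, rng):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True  # diagonal touch
        assert len(find_puncta(mask, min_size=0, connectivity=8)) == 1
        assert len(find_puncta(mask, min_size=0, connectivity=4)) == 2

    def test_calibrated_area(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:3, 1:3] = True  # 4 px = 0.04 um^2 at 0.1 um/px
        rois = find_puncta(mask, min_size=0.03, pixel_size=0.1)
        assert len(rois) == 1
        assert rois[0].area == pytest.approx(0.04)
        assert rois[0].area_units == "um^2"
        assert find_puncta(mask, min_size=0.05, pixel_size=0.1) == []

    def test_left_to_right_ordering(self):
        mask = np.zeros((10, 40), dtype=bool)
        mask[7:9, 30:33] = True
        mask[1:3, 5:8] = True
        mask[5:7, 15:18] = True
        rois = find_puncta(mask, min_size=0)
        assert [r.bbox[1] for r in rois] == [5, 15, 30]
        assert [r.roi_id for r in rois] == [1, 2, 3]

    def test_rois_partition_foreground(self, rng):
        mask = rng.random((16, 64)) < 0.3
        rois = find_puncta(mask, min_size=0)
        all_pixels = [px for r in rois for px in r.pixel_set]
        assert len(all_pixels) == len(set(all_pixels)) == int(mask.sum())


class TestDetect:
    def test_recovers_synthetic_puncta(self, standard_fixture):
        from .conftest import FIXTURE_PARAMS

        img, truth = standard_fixture
        rois = detect(img, FIXTURE_PARAMS)
        assert len(rois) == truth.n_puncta
        for roi, center in zip(rois, truth.centers_px):
            bbox_center = roi.bbox[1] + roi.bbox[3] / 2
            assert abs(bbox_center - center) <= 1.0

    def test_min_size_monotone(self, standard_fixture):
        img, _ = standard_fixture
        counts = [
            len(detect(img, DetectionParams(min_size=s, sigma=1.0, radius=6)))
            for s in (0, 2, 5, 20, 50, 10_000)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_translation_equivariance(self):
        from punctaline import SynthSpec, generate

        def spec(shift):
            return SynthSpec(
                length_px=300, width_px=15, background_level=5140.0, cord_level=2570.0,
                n_puncta=3, punctum_amplitudes=(30000.0,) * 3,
                punctum_sigmas_px=(2.0,) * 3,
                punctum_positions_px=(60.0 + shift, 150.0 + shift, 240.0 + shift),
                bit_depth=16, seed=0,
            )

        params = DetectionParams(min_size=5, sigma=1.0, radius=6)
        base = detect(generate(spec(0))[0], params)
        shifted = detect(generate(spec(7))[0], params)
        assert len(base) == len(shifted) == 3
        for a, b in zip(base, shifted):
            assert b.bbox[1] == a.bbox[1] + 7
            assert b.bbox[0] == a.bbox[0]

    def test_nuIs24_preset_runs(self, standard_fixture):
        img, _ = standard_fixture
        rois = detect(img, PRESETS["nuIs24"])
        assert len(rois) >= 20  # min_size 0.2 px^2 on the uncalibrated fixture

    def test_areas_respect_min_size(self, standard_fixture):
        img, _ = standard_fixture
        rois = detect(img, DetectionParams(min_size=8, sigma=1.0, radius=6))
        assert all(r.area >= 8 for r in rois)


class TestPreviewSettings:
    def test_grid(self, standard_fixture):
        img, truth = standard_fixture
        grid = [
            DetectionParams(min_size=5, sigma=1.0, radius=6),
            DetectionParams(min_size=10_000, sigma=1.0, radius=6),
        ]
        results = preview_settings(img, grid)
        assert len(results) == 2
        assert results[0]["n_rois"] == truth.n_puncta
        assert results[1]["n_rois"] == 0
        assert results[0]["mask"].shape == img.pixels.shape

    def test_empty_grid(self, standard_fixture):
        with pytest.raises(ValueError):
            preview_settings(standard_fixture[0], [])
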