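"""Colour lightness scoring: channel means, ROI geometry, morph/sex/side
filtering, complex averaging, and cross-source validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melanomap.lightness import (EmptyROIError, ExclusionRecord,
                                 SpecimenImage, SpeciesTrait, build_roi_mask,
                                 complex_average, compute_lightness,
                                 cross_source_validation, species_lightness)
from melanomap.synth import SynthConfig, TrueSpecies, Wing, \
    render_specimen

EXTENT = (0.0, 0.0, 600_000.0, 400_000.0)


def make_image(pixels, mask=None, species_id="spX", side="dorsal",
               sex="monomorphic", morph_id="m0", family="Pieridae"):
    pixels = np.asarray(pixels, dtype=np.uint8)
    if mask is None:
        mask = np.ones(pixels.shape[:2], dtype=bool)
    return SpecimenImage(pixels=pixels, roi_mask=mask, species_id=species_id,
                         side=side, sex=sex, morph_id=morph_id, family=family)


class TestComputeLightness:
    @pytest.mark.parametrize("rgb,expected", [
        ((255, 255, 255), 255.0),     # pure white
        ((0, 0, 0), 0.0),             # pure black
        ((30, 60, 90), 60.0),         # channel mean of one pixel
    ])
    def test_uniform_roi(self, rgb, expected):
        img = make_image(np.full((4, 4, 3), rgb, dtype=np.uint8))
        assert compute_lightness(img) == expected

    def test_half_black_half_white(self):
        px = np.zeros((2, 2, 3), dtype=np.uint8)
        px[0, :, :] = 255
        assert compute_lightness(make_image(px)) == 127.5

    def test_matches_bruteforce_double_loop(self, rng):
        px = rng.integers(0, 256, size=(50, 50, 3), dtype=np.uint8)
        mask = rng.random((50, 50)) < 0.4
        mask[0, 0] = True
        total, count = 0.0, 0
        for i in range(50):
            for j in range(50):
                if mask[i, j]:
                    for c in range(3):
                        total += float(px[i, j, c])
                        count += 1
        assert compute_lightness(make_image(px, mask)) == pytest.approx(
            total / count, abs=1e-9)

    def test_empty_mask_is_an_error(self):
        img = make_image(np.zeros((4, 4, 3), dtype=np.uint8),
                         mask=np.zeros((4, 4), dtype=bool))
        with pytest.raises(EmptyROIError):
            compute_lightness(img)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance_and_bounds(self, seed):
        r = np.random.default_rng(seed)
        px = r.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        mask = r.random((8, 8)) < 0.5
        mask[0, 0] = True
        value = compute_lightness(make_image(px, mask))
        assert 0.0 <= value <= 255.0
        # permute the ROI pixels: the mean must not change
        idx = np.flatnonzero(mask.ravel())
        perm = r.permutation(idx)
        flat = px.reshape(-1, 3).copy()
        flat[idx] = flat[perm]
        assert compute_lightness(
            make_image(flat.reshape(8, 8, 3), mask)) == pytest.approx(value)


class TestBuildRoiMask:
    def test_axis_aligned_rectangle_wing_masks_one_third(self):
        # 90 x 30 wing, axis along x: proximal third = first 30 columns
        body = np.array([[0.2, 0.2], [5.2, 0.2], [5.2, 39.8], [0.2, 39.8]])
        wing = Wing(polygon=np.array([[10.2, 5.2], [100.2, 5.2],
                                      [100.2, 35.2], [10.2, 35.2]]),
                    base=(10.2, 20.0), tip=(100.2, 20.0))
        mask = build_roi_mask(body, [wing], (40, 110))
        wing_cols = mask[:, 11:]          # exclude the body region
        frac = wing_cols.sum() / (90 * 30)
        assert frac == pytest.approx(1 / 3, abs=0.02)

    def test_degenerate_wing_axis_raises(self):
        body = np.array([[0.2, 0.2], [5.2, 0.2], [5.2, 9.8], [0.2, 9.8]])
        wing = Wing(polygon=np.array([[10.2, 0.2], [20.2, 0.2], [20.2, 9.8]]),
                    base=(12.0, 5.0), tip=(12.0, 5.0))
        with pytest.raises(ValueError, match="degenerate"):
            build_roi_mask(body, [wing], (10, 30))

    def test_matches_generator_emitted_mask_exactly(self):
        cfg = SynthConfig(seed=1, extent=EXTENT)
        sp = TrueSpecies("sp0000", "Pieridae", 120.0, 150.0, 10.0)
        rend = render_specimen(sp, "dorsal", cfg)
        mask = build_roi_mask(rend.geometry.body, list(rend.geometry.wings),
                              rend.image.pixels.shape[:2])
        assert np.array_equal(mask, rend.image.roi_mask)

    def test_full_wing_lightness_differs_from_roi(self):
        # the proximal-third restriction matters on synthetic specimens
        cfg = SynthConfig(seed=1, extent=EXTENT, pixel_noise_sd=0.0)
        sp = TrueSpecies("sp0000", "Pieridae", 100.0, 130.0, 10.0)
        rend = render_specimen(sp, "dorsal", cfg)
        full = rend.image.roi_mask | rend.distal_mask
        img_full = make_image(rend.image.pixels, full)
        assert abs(compute_lightness(img_full)
                   - compute_lightness(rend.image)) > 5.0


class TestSpeciesLightness:
    def test_single_pair_of_sides(self):
        imgs = [make_image(np.full((2, 2, 3), 120, np.uint8), side="dorsal"),
                make_image(np.full((2, 2, 3), 150, np.uint8), side="ventral")]
        trait = species_lightness(imgs)
        assert (trait.lightness_dorsal, trait.lightness_ventral) == (120, 150)

    def test_morphs_averaged_per_side(self):
        imgs = [
            make_image(np.full((2, 2, 3), 100, np.uint8), side="dorsal",
                       morph_id="m0"),
            make_image(np.full((2, 2, 3), 140, np.uint8), side="dorsal",
                       morph_id="m1"),
            make_image(np.full((2, 2, 3), 150, np.uint8), side="ventral"),
        ]
        trait = species_lightness(imgs)
        assert trait.lightness_dorsal == 120.0
        assert trait.lightness_ventral == 150.0

    def test_missing_ventral_side_is_excluded(self):
        imgs = [make_image(np.full((2, 2, 3), 120, np.uint8), side="dorsal")]
        result = species_lightness(imgs)
        assert isinstance(result, ExclusionRecord)
        assert result.reason == "missing ventral"

    def test_male_images_dropped_by_default_policy(self):
        imgs = [make_image(np.full((2, 2, 3), 120, np.uint8), side="dorsal",
                           sex="female"),
                make_image(np.full((2, 2, 3), 90, np.uint8), side="dorsal",
                           sex="male"),
                make_image(np.full((2, 2, 3), 150, np.uint8), side="ventral",
                           sex="female")]
        trait = species_lightness(imgs)
        assert trait.lightness_dorsal == 120.0

    def test_conflicting_family_labels_raise(self):
        imgs = [make_image(np.full((2, 2, 3), 120, np.uint8), side="dorsal",
                           family="Pieridae"),
                make_image(np.full((2, 2, 3), 150, np.uint8), side="ventral",
                           family="Lycaenidae")]
        with pytest.raises(ValueError, match="family"):
            species_lightness(imgs)

    def test_noiseless_render_roundtrip_is_exact(self):
        cfg = SynthConfig(seed=4, extent=EXTENT, pixel_noise_sd=0.0)
        sp = TrueSpecies("sp0003", "Pieridae", 77.0, 107.0, 10.0)
        imgs = [render_specimen(sp, s, cfg).image
                for s in ("dorsal", "ventral")]
        trait = species_lightness(imgs)
        assert trait.lightness_dorsal == 77.0
        assert trait.lightness_ventral == 107.0


def trait(sid, dorsal, ventral, family="Pieridae"):
    return SpeciesTrait(species_id=sid, family=family,
                        lightness_dorsal=dorsal, lightness_ventral=ventral,
                        n_images_dorsal=1, n_images_ventral=1)


class TestComplexAverage:
    def test_two_members_average(self):
        out = complex_average([trait("a", 90, 120), trait("b", 110, 140)],
                              {"a": "cx1", "b": "cx1"})
        assert len(out) == 1
        assert out[0].lightness_dorsal == 100.0
        assert out[0].lightness_ventral == 130.0
        assert out[0].complex_id == "cx1"

    def test_singleton_complex_is_identity(self):
        out = complex_average([trait("a", 90, 120)], {"a": "cx1"})
        assert out[0].lightness_dorsal == 90.0
        assert out[0].lightness_ventral == 120.0

    def test_34_species_into_13_complexes_drops_21_rows(self):
        traits = [trait(f"s{i}", 100 + i, 130 + i) for i in range(40)]
        cmap = {}
        k = 0
        for c in range(13):           # 34 members over 13 complexes
            size = 3 if c < 8 else 2
            for _ in range(size):
                cmap[f"s{k}"] = f"cx{c}"
                k += 1
        assert k == 34
        out = complex_average(traits, cmap)
        assert len(out) == len(traits) - 21

    def test_cross_family_complex_raises(self):
        with pytest.raises(ValueError, match="famil"):
            complex_average([trait("a", 90, 120, "Pieridae"),
                             trait("b", 110, 140, "Lycaenidae")],
                            {"a": "cx1", "b": "cx1"})


class TestCrossSourceValidation:
    def test_identity_gives_unit_slope_and_r2(self):
        a = {f"s{i}": 80.0 + 7 * i for i in range(10)}
        res = cross_source_validation(a, dict(a))
        assert res.slope == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.n == 10

    def test_constant_shift_keeps_unit_slope(self):
        a = {f"s{i}": 80.0 + 7 * i for i in range(10)}
        b = {k: v + 12.5 for k, v in a.items()}
        res = cross_source_validation(a, b)
        assert res.slope == pytest.approx(1.0)

    def test_noisy_pair_matches_closed_form_ols(self, rng):
        a_vals = rng.uniform(60, 200, size=16)
        noise = rng.normal(0, 5, size=16)
        a = {f"s{i}": a_vals[i] for i in range(16)}
        b = {f"s{i}": a_vals[i] + noise[i] for i in range(16)}
        res = cross_source_validation(a, b)
        x = a_vals - a_vals.mean()
        y = (a_vals + noise) - (a_vals + noise).mean()
        slope = (x @ y) / (x @ x)
        r2 = (x @ y) ** 2 / ((x @ x) * (y @ y))
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.r2 == pytest.approx(r2, abs=1e-10)
        assert res.n == 16

    def test_too_few_shared_species_raises(self):
        with pytest.raises(ValueError, match="shared"):
            cross_source_validation({"a": 1.0, "b": 2.0},
                                    {"a": 1.0, "b": 2.0})
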