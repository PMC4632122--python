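"""Synthetic leaf-scene generator: absorbers, geometry, Beer-Lambert rendering."""

import numpy as np
import pytest

import swirindex as sx
from swirindex.synth_scene import (
    DEFAULT_WATER_BANDS,
    SceneSpec,
    default_baseline_absorption,
    default_light_spectrum,
    default_two_leaf_layout,
)


class TestWaterAbsorptionSpectrum:
    def test_single_band_peaks_at_center(self, default_axis):
        eps = sx.water_absorption_spectrum(
            default_axis, [sx.AbsorberBand(1470.0, 40.0, 1.0)]
        )
        peak = default_axis.wavelengths_nm[np.argmax(eps)]
        assert abs(peak - 1470.0) <= 0.78
        assert np.all(eps >= 0)

    def test_out_of_window_band_is_near_zero(self):
        axis = sx.SpectralAxis(np.arange(1300.0, 1600.0, 2.0))
        eps = sx.water_absorption_spectrum(axis, [sx.AbsorberBand(975.0, 30.0, 1.0)])
        assert eps.max() < 1e-8

    def test_default_profile_dominated_by_1470(self, default_axis):
        eps = sx.water_absorption_spectrum(default_axis, DEFAULT_WATER_BANDS)
        at = lambda nm: eps[np.argmin(np.abs(default_axis.wavelengths_nm - nm))]
        assert at(1470) > at(1050)
        assert at(1470) > at(975) > at(1050)
        # steep long-wave recovery: 1529 nm well below 1416 nm absorption
        assert at(1416) > 2 * at(1529)

    def test_empty_band_list_rejected(self, default_axis):
        with pytest.raises(ValueError):
            sx.water_absorption_spectrum(default_axis, [])


class TestLeafGeometry:
    def test_ellipse_area_matches_analytic(self):
        spec = sx.LeafSpec(center=(40.0, 40.0), semi_axes=(20.0, 10.0))
        mask = sx.leaf_mask(spec, 80, 80)
        assert mask.sum() == pytest.approx(np.pi * 20 * 10, rel=0.03)

    def test_outside_bounding_box_false(self):
        spec = sx.LeafSpec(center=(20.0, 20.0), semi_axes=(5.0, 3.0))
        mask = sx.leaf_mask(spec, 40, 40)
        assert not mask[0, 0] and not mask[30, 30]

    def test_rotation_by_180_is_symmetric(self):
        a = sx.LeafSpec(center=(20.0, 20.0), semi_axes=(8.0, 4.0), rotation_deg=30.0)
        b = sx.LeafSpec(center=(20.0, 20.0), semi_axes=(8.0, 4.0), rotation_deg=210.0)
        assert np.array_equal(sx.leaf_mask(a, 40, 40), sx.leaf_mask(b, 40, 40))

    def test_zero_area_rejected(self):
        spec = sx.LeafSpec(center=(500.0, 500.0), semi_axes=(2.0, 2.0))
        with pytest.raises(ValueError):
            sx.leaf_mask(spec, 10, 10)


class TestThicknessMap:
    def _spec(self, **kw):
        base = dict(center=(30.0, 30.0), semi_axes=(20.0, 10.0))
        base.update(kw)
        return sx.LeafSpec(**base)

    def test_flat_when_no_features(self):
        spec = self._spec(midrib_gain=0.0, edge_taper=0.0, base_thickness=1.5)
        mask = sx.leaf_mask(spec, 60, 60)
        t = sx.thickness_map(mask, spec)
        assert np.allclose(t.values[mask], 1.5)
        assert np.all(t.values[~mask] == 0.0)

    def test_midrib_thicker_than_lamina(self):
        spec = self._spec(midrib_gain=0.3, edge_taper=0.0)
        mask = sx.leaf_mask(spec, 60, 60)
        t = sx.thickness_map(mask, spec).values
        assert t[30, 30] > t[30, 36]

    def test_mean_thickness_decreases_with_taper(self):
        mask = sx.leaf_mask(self._spec(), 60, 60)
        t0 = sx.thickness_map(mask, self._spec(edge_taper=0.0)).values[mask].mean()
        t3 = sx.thickness_map(mask, self._spec(edge_taper=0.3)).values[mask].mean()
        assert t3 < t0


class TestRenderScene:
    def _clean_spec(self, leaves, **kw):
        base = dict(
            height=48, width=48, leaves=leaves, scatter_cv=0.0,
            thickness_roughness_cv=0.0, noise_multiplicative_cv=0.0,
            noise_additive_sd=0.0, seed=3,
        )
        base.update(kw)
        return SceneSpec(**base)

    def test_zero_optical_depth_transmits_source(self, default_axis):
        leaf = sx.LeafSpec(center=(24.0, 24.0), semi_axes=(12.0, 8.0),
                           water_level=0.0, midrib_gain=0.0, edge_taper=0.0)
        spec = self._clean_spec(
            [leaf], baseline_absorption=np.zeros(512),
        )
        cube = sx.render_scene(spec)
        mask = sx.leaf_mask(leaf, 48, 48)
        assert np.allclose(cube.intensities[mask], spec.light_spectrum, rtol=1e-12)

    def test_noise_free_matches_beer_lambert_closed_form(self):
        leaf = sx.LeafSpec(center=(24.0, 24.0), semi_axes=(12.0, 8.0),
                           water_level=0.7)
        spec = self._clean_spec([leaf])
        cube = sx.render_scene(spec)
        mask = sx.leaf_mask(leaf, 48, 48)
        thick = sx.thickness_map(mask, leaf).values
        eps = sx.water_absorption_spectrum(spec.axis, spec.water_bands)
        expect = spec.light_spectrum[None, :] * np.exp(
            -thick[mask][:, None] * (0.7 * eps + spec.baseline_absorption)[None, :]
        )
        assert np.allclose(cube.intensities[mask], expect, rtol=1e-12)

    def test_doubling_thickness_squares_transmittance(self):
        mk = lambda d: sx.LeafSpec(center=(24.0, 24.0), semi_axes=(12.0, 8.0),
                                   base_thickness=d, midrib_gain=0.0, edge_taper=0.0)
        c1 = sx.render_scene(self._clean_spec([mk(1.0)]))
        c2 = sx.render_scene(self._clean_spec([mk(2.0)]))
        mask = sx.leaf_mask(mk(1.0), 48, 48)
        t1 = c1.intensities[mask] / c1.light_reference
        t2 = c2.intensities[mask] / c2.light_reference
        assert np.allclose(t2, t1**2, rtol=1e-9)

    def test_drier_leaf_brighter_at_water_band(self):
        wet = sx.LeafSpec(center=(24.0, 12.0), semi_axes=(10.0, 6.0), water_level=1.0)
        dry = sx.LeafSpec(center=(24.0, 36.0), semi_axes=(10.0, 6.0), water_level=0.8)
        cube = sx.render_scene(self._clean_spec([wet, dry]))
        img = sx.band_image(cube, 1470.0)
        m_wet = sx.leaf_mask(wet, 48, 48)
        m_dry = sx.leaf_mask(dry, 48, 48)
        assert img.values[m_dry].mean() > img.values[m_wet].mean()

    def test_overlapping_leaves_rejected(self):
        a = sx.LeafSpec(center=(24.0, 20.0), semi_axes=(10.0, 8.0))
        b = sx.LeafSpec(center=(24.0, 28.0), semi_axes=(10.0, 8.0))
        with pytest.raises(ValueError, match="overlap"):
            sx.render_scene(self._clean_spec([a, b]))

    def test_seed_fixes_cube_bitwise(self):
        leaves = default_two_leaf_layout(48, 48)
        s1 = SceneSpec(height=48, width=48, leaves=leaves, seed=11)
        s2 = SceneSpec(height=48, width=48, leaves=leaves, seed=11)
        assert np.array_equal(
            sx.render_scene(s1).intensities, sx.render_scene(s2).intensities
        )

    def test_output_satisfies_cube_invariants(self):
        cube, _ = sx.two_leaf_scene(seed=5, height=48, width=48)
        assert np.all(np.isfinite(cube.intensities))
        assert np.all(cube.intensities >= 0)
        assert cube.n_bands == 512


class TestTwoLeafScene:
    def test_same_seed_identical(self):
        c1, _ = sx.two_leaf_scene(seed=9, height=32, width=32)
        c2, _ = sx.two_leaf_scene(seed=9, height=32, width=32)
        assert np.array_equal(c1.intensities, c2.intensities)

    def test_equal_water_levels_exchangeable_noise_free(self):
        cube, masks = sx.two_leaf_scene(0.9, 0.9, seed=0, height=48, width=48,
                                        noise_preset="clean")
        per_band_a = cube.intensities[masks[0]].mean(axis=0)
        per_band_b = cube.intensities[masks[1]].mean(axis=0)
        assert np.allclose(per_band_a, per_band_b, rtol=1e-9)

    def test_ratio_separates_leaves_better_than_water_band(self):
        """Monte-Carlo: the 1529/1416 ratio image shows larger between-leaf
        separation (in pooled-sd units) than the 1470 nm single band."""
        wins = 0
        for seed in range(10):
            cube, masks = sx.two_leaf_scene(1.0, 0.8, seed=seed)
            union = masks[0] | masks[1]

            def separation(img):
                a = img.values[img.mask & masks[0]]
                b = img.values[img.mask & masks[1]]
                pooled = np.sqrt((a.std() ** 2 + b.std() ** 2) / 2)
                return abs(a.mean() - b.mean()) / pooled

            ratio = sx.ratio_image(cube, 1529.0, 1416.0, union)
            band = sx.band_image(cube, 1470.0)
            band = sx.ScalarImage(band.values, union, band.label)
            if separation(ratio) > separation(band):
                wins += 1
        assert wins >= 9

    def test_serialization_round_trip(self):
        leaves = default_two_leaf_layout(32, 32)
        spec = SceneSpec(height=32, width=32, leaves=leaves, seed=4)
        back = SceneSpec.from_dict(spec.to_dict())
        assert np.array_equal(
            sx.render_scene(spec).intensities, sx.render_scene(back).intensities
        )


def test_default_spectra_shapes(default_axis):
    light = default_light_spectrum(default_axis)
    base = default_baseline_absorption(default_axis)
    assert light.shape == base.shape == (512,)
    assert np.all(light > 0)
    assert base[0] < base[-1]  # gentle rise with wavelength
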