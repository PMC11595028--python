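import numpy as np
import pytest
from scipy import stats as sps

import adipospec as a
from adipospec.core import BandWindow, Spectrum, integrate_band
from adipospec.library import (
    build_component_spectrum,
    fatty_acid,
    library_from_yaml,
    library_to_yaml,
    lipid_component,
    mean_chain_length,
    saturated_tag,
)
from adipospec.phantom import (
    COMPARTMENTS,
    CellLayout,
    CorruptionSpec,
    LayoutConfig,
    corrupt_cube,
    default_composition,
    default_ftir_axis,
    default_raman_axis,
    render_cube,
    sample_cell_layout,
)


def wide_area(spectrum, center, half=50.0):
    return integrate_band(spectrum, BandWindow("w", center - half, center + half))


class TestComponentSpectra:
    def test_trilaurin_ch2_ch3_area_ratio_is_ten(self):
        # trilaurin: three C12 chains -> 30 CH2 and 3 CH3 groups
        s = build_component_spectrum(saturated_tag(36), default_ftir_axis(),
                                     "ftir")
        ratio = wide_area(s, 2852.0, 40.0) / wide_area(s, 2954.0, 40.0)
        assert ratio == pytest.approx(10.0, rel=1e-4)

    def test_saturated_acid_has_no_cc_stretch(self):
        s = build_component_spectrum(fatty_acid(18, 0), default_raman_axis(),
                                     "raman")
        w = BandWindow("cc", 1650.0, 1670.0)
        assert integrate_band(s, w) == pytest.approx(0.0, abs=1e-9)

    def test_all_library_components_are_nonnegative(self, library):
        for comp in library.values():
            for modality, axis in (("raman", default_raman_axis()),
                                   ("ftir", default_ftir_axis())):
                s = build_component_spectrum(comp, axis, modality)
                assert np.all(s.intensities >= 0)

    def test_band_outside_axis_rejected(self):
        axis = a.WavenumberAxis.regular(1200.0, 3100.0, 3.0)
        with pytest.raises(a.ValidationError, match="outside axis"):
            build_component_spectrum(fatty_acid(18, 0), axis, "raman")

    def test_lipid_requires_ch_counts(self):
        with pytest.raises(a.ValidationError):
            a.ComponentSpectrum("broken", group_counts={"chain": 1.0})

    def test_saturated_tag_series_ratio_is_linear_in_carbons(self):
        # group counting: CH2/CH3 = (N - 6)/3 for a saturated TAG
        for n in (24, 36, 54, 66):
            s = build_component_spectrum(saturated_tag(n), default_ftir_axis(),
                                         "ftir")
            ratio = wide_area(s, 2852.0, 40.0) / wide_area(s, 2954.0, 40.0)
            assert ratio == pytest.approx(n / 3 - 2, rel=1e-4)

    def test_fatty_acid_series_cc_band_proportional_to_double_bonds(self):
        areas = {}
        for db in (1, 2, 3):
            s = build_component_spectrum(fatty_acid(18, db),
                                         default_raman_axis(), "raman")
            areas[db] = wide_area(s, 1660.0, 30.0) / wide_area(s, 1451.0, 30.0)
        assert areas[2] == pytest.approx(2 * areas[1], rel=1e-4)
        assert areas[3] == pytest.approx(3 * areas[1], rel=1e-4)

    def test_library_yaml_round_trip(self, library):
        back = library_from_yaml(library_to_yaml(library))
        assert set(back) == set(library)
        comp = back["MUFA_18_1"]
        assert comp.group_counts == library["MUFA_18_1"].group_counts
        assert comp.raman_bands == library["MUFA_18_1"].raman_bands


class TestLayout:
    def test_same_seed_same_layout(self):
        one = sample_cell_layout(seed=5)
        two = sample_cell_layout(seed=5)
        for name in one.masks:
            np.testing.assert_array_equal(one.masks[name], two.masks[name])
        assert one.ld_instances == two.ld_instances

    def test_masks_partition_the_field(self):
        layout = sample_cell_layout(seed=1)
        total = sum(m.astype(int) for m in layout.masks.values())
        assert total.max() == 1  # mutually exclusive
        assert set(layout.masks) == set(COMPARTMENTS)

    def test_default_ld_unsaturation_is_042(self, library):
        comp = default_composition()["lipid_droplet"]
        assert a.mean_unsaturation(comp, library) == pytest.approx(0.42,
                                                                   abs=1e-12)

    def test_default_ld_chain_length_near_c17(self, library):
        comp = default_composition()["lipid_droplet"]
        assert 14 < mean_chain_length(comp, library) < 20

    def test_compositions_sum_to_one(self):
        for fractions in default_composition().values():
            assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_too_small_field_rejected(self):
        with pytest.raises(a.ValidationError):
            sample_cell_layout(LayoutConfig(field_um=2.0, pixel_size=0.5))


class TestRender:
    def test_uniform_layout_without_psf_is_exact(self, library):
        n = 8
        masks = {name: np.zeros((n, n), dtype=bool) for name in COMPARTMENTS}
        masks["cytoplasm"] = np.ones((n, n), dtype=bool)
        composition = {"cytoplasm": default_composition()["cytoplasm"]}
        layout = CellLayout(masks, composition, 0.5, [])
        cube = render_cube(layout, library, "raman", psf_fwhm=0.0)
        expected = a.compartment_spectrum(
            composition["cytoplasm"], library, cube.axis, "raman"
        ).intensities
        assert np.allclose(cube.data, expected[None, None, :])

    def test_psf_conserves_per_channel_intensity(self, library):
        layout = sample_cell_layout(seed=3)
        sharp = render_cube(layout, library, "raman", psf_fwhm=0.0)
        blurred = render_cube(layout, library, "raman", psf_fwhm=0.3)
        s0 = sharp.data.sum(axis=(0, 1))
        s1 = blurred.data.sum(axis=(0, 1))
        assert np.all(np.abs(s1 - s0) <= 1e-3 * np.maximum(s0, s0.max() * 1e-9))

    def test_ld_pixels_have_stronger_ester_band_than_cytoplasm(self, ftir_sim):
        _, layout, registry = ftir_sim
        clean = registry["clean"]
        img = a.band_image(clean, BandWindow("tag", 1720.0, 1770.0))
        assert (img[layout.masks["lipid_droplet"]].mean()
                > img[layout.masks["cytoplasm"]].mean())


class TestCorruption:
    def test_zero_spec_is_identity(self, raman_sim):
        _, _, registry = raman_sim
        clean = registry["clean"]
        out, reg = corrupt_cube(clean, CorruptionSpec.none())
        np.testing.assert_array_equal(out.data, clean.data)
        assert reg["spikes"] == []

    def test_same_seed_reproduces_output(self, raman_sim):
        _, _, registry = raman_sim
        clean = registry["clean"]
        spec = CorruptionSpec.defaults("raman", seed=9)
        one, _ = corrupt_cube(clean, spec)
        two, _ = corrupt_cube(clean, spec)
        np.testing.assert_array_equal(one.data, two.data)

    def test_spike_count_within_binomial_interval(self):
        layout = sample_cell_layout(LayoutConfig(field_um=10.0), seed=2)
        clean = render_cube(layout, modality="raman", psf_fwhm=0.0)
        assert clean.n_pixels == 400
        spec = CorruptionSpec(gaussian_sigma=0.01, baseline_scale=0.0,
                              spike_rate=0.05, seed=4)
        corrupted, registry = corrupt_cube(clean, spec)
        # detect channels altered beyond 5 sigma of the injected noise
        delta = np.abs(corrupted.data - clean.data)
        detected = int((delta > 5 * registry["noise_sigma"]).sum())
        low, high = sps.binom.interval(0.99, 400, 0.05)
        assert low <= detected <= high
        assert detected == len(registry["spikes"])

    def test_registry_reports_injected_artifacts(self, raman_sim):
        _, _, registry = raman_sim
        assert registry["noise_sigma"] > 0
        assert registry["baseline"] is not None
        assert len(registry["spikes"]) > 0
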