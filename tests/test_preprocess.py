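import numpy as np
import pytest

import adipospec as a
from adipospec.core import BandWindow, HyperspectralCube, Spectrum, WavenumberAxis
from adipospec.library import PureBand
from adipospec.mie import extinction_curve
from adipospec.phantom import default_ftir_axis, default_raman_axis
from adipospec.preprocess import (
    correct_baseline,
    despike,
    despike_spectrum,
    pca_denoise,
    postprocess_mean_spectrum,
    quality_mask,
    rmies_correct,
    savgol,
    vector_normalize,
)


@pytest.fixture
def axis():
    return default_raman_axis()


class TestDespike:
    def test_smooth_spectrum_unchanged(self, axis):
        y = 2 + np.sin(axis.values / 150.0)
        out = despike_spectrum(Spectrum(axis, y))
        np.testing.assert_array_equal(out.intensities, y)

    def test_delta_on_constant_replaced_by_constant(self, axis):
        y = np.full(len(axis), 3.0)
        y[200] = 50.0
        out = despike_spectrum(Spectrum(axis, y))
        assert out.intensities[200] == pytest.approx(3.0)
        assert np.allclose(np.delete(out.intensities, 200),
                           np.delete(y, 200))

    def test_injected_spikes_removed_without_collateral(self, raman_sim):
        cube, _, registry = raman_sim
        spikes = {(r, c, ch) for r, c, ch in registry["spikes"]}
        assert len(spikes) >= 50
        _, flagged = despike(cube)
        flagged_set = {
            (i // cube.width, i % cube.width, int(ch))
            for i, ch in zip(*np.nonzero(flagged.reshape(cube.n_pixels, -1)))
        }
        removed = len(spikes & flagged_set)
        assert removed >= 0.98 * len(spikes)
        assert len(flagged_set - spikes) == 0  # no clean channel touched

    def test_despike_is_idempotent(self, raman_sim):
        cube, _, _ = raman_sim
        once, _ = despike(cube)
        twice, _ = despike(once)
        np.testing.assert_array_equal(once.data, twice.data)


class TestBaseline:
    def test_polynomial_input_removed_exactly(self, axis):
        x = axis.values
        y = 1.0 + 2e-3 * x + 1e-7 * x**2 - 3e-11 * x**3
        out = correct_baseline(Spectrum(axis, y), "poly")
        assert np.max(np.abs(out.intensities)) < 1e-6 * np.max(np.abs(y))

    def test_rubberband_recovers_peak_area_on_convex_baseline(self, axis):
        x = axis.values
        peak = np.exp(-0.5 * ((x - 1600.0) / 10.0) ** 2)
        baseline = 0.5 + 2e-4 * (x - 550.0) + 1e-7 * (x - 550.0) ** 2
        out = correct_baseline(Spectrum(axis, peak + baseline), "rubberband")
        w = BandWindow("peak", 1540.0, 1660.0)
        clean_area = a.integrate_band(Spectrum(axis, peak), w)
        recovered = a.integrate_band(out, w)
        assert recovered == pytest.approx(clean_area, rel=0.02)

    def test_rubberband_output_nonnegative_for_nonnegative_input(self, axis):
        rng = np.random.default_rng(3)
        y = np.abs(rng.normal(1.0, 0.3, len(axis)))
        out = correct_baseline(Spectrum(axis, y), "rubberband")
        assert out.intensities.min() >= -1e-9

    def test_unknown_method_rejected(self, axis):
        with pytest.raises(a.ValidationError):
            correct_baseline(Spectrum(axis, np.ones(len(axis))), "magic")


class TestSavgol:
    def test_low_order_polynomial_passes_through(self, axis):
        y = 1.0 + 0.01 * axis.values + 1e-6 * axis.values**2
        out = savgol(Spectrum(axis, y), 11, 2)
        interior = slice(5, -5)
        np.testing.assert_allclose(out.intensities[interior], y[interior],
                                   rtol=1e-10)

    def test_second_derivative_matches_analytic_sine(self, axis):
        omega = 2 * np.pi / 400.0
        y = np.sin(omega * axis.values)
        out = savgol(Spectrum(axis, y), 11, 3, deriv=2)
        expected = -(omega**2) * y
        interior = slice(20, -20)
        err = np.abs(out.intensities[interior] - expected[interior])
        assert err.max() < 0.01 * omega**2

    def test_constant_second_derivative_is_zero(self, axis):
        out = savgol(Spectrum(axis, np.full(len(axis), 7.0)), 13, 2, deriv=2)
        assert np.allclose(out.intensities, 0.0, atol=1e-12)


class TestVectorNormalize:
    def test_unit_norm_and_scale_invariance(self, axis):
        rng = np.random.default_rng(0)
        y = rng.uniform(0.1, 1.0, len(axis))
        one = vector_normalize(Spectrum(axis, y))
        assert np.linalg.norm(one.intensities) == pytest.approx(1.0, abs=1e-12)
        seven = vector_normalize(Spectrum(axis, 7 * y))
        np.testing.assert_allclose(seven.intensities, one.intensities)
        again = vector_normalize(one)
        np.testing.assert_allclose(again.intensities, one.intensities)

    def test_zero_spectrum_rejected(self, axis):
        with pytest.raises(a.ValidationError):
            vector_normalize(Spectrum(axis, np.zeros(len(axis))))


def _amide_cube(amplitudes):
    """10x10 FTIR cube with a single amide-I band of given peak height."""
    axis = default_ftir_axis()
    band = PureBand(1650.0, 20.0, 1.0, "gaussian")
    profile = band.profile(axis.values)
    profile /= profile.max()
    data = np.asarray(amplitudes).reshape(10, 10, 1) * profile
    return HyperspectralCube(axis, data, 5.5, "ftir")


class TestQualityMask:
    def test_pass_count_matches_construction(self):
        amps = np.concatenate([np.full(37, 0.35), np.full(63, 0.05)])
        rng = np.random.default_rng(1)
        rng.shuffle(amps)
        mask = quality_mask(_amide_cube(amps), threshold=0.2)
        assert int(mask.sum()) == 37
        np.testing.assert_array_equal(mask, amps.reshape(10, 10) >= 0.2)

    def test_zero_threshold_passes_nonnegative_pixels(self):
        amps = np.abs(np.random.default_rng(0).uniform(0, 1, 100))
        mask = quality_mask(_amide_cube(amps), threshold=0.0)
        assert mask.all()

    def test_subthreshold_cube_yields_empty_mask(self):
        mask = quality_mask(_amide_cube(np.full(100, 0.01)), threshold=0.2)
        assert not mask.any()

    def test_pass_count_monotone_in_threshold(self):
        amps = np.random.default_rng(2).uniform(0, 0.5, 100)
        cube = _amide_cube(amps)
        counts = [int(quality_mask(cube, threshold=t).sum())
                  for t in np.linspace(0.0, 0.5, 11)]
        assert all(x >= y for x, y in zip(counts, counts[1:]))


class TestPcaDenoise:
    def _rank3_cube(self, noise=0.0, seed=0):
        axis = default_ftir_axis()
        rng = np.random.default_rng(seed)
        basis = rng.normal(size=(3, len(axis)))
        weights = rng.uniform(0, 1, (12, 12, 3))
        data = weights @ basis
        if noise:
            data = data + rng.normal(0, noise, data.shape)
        return HyperspectralCube(axis, data, 5.5, "ftir")

    def test_noiseless_rank3_recovered_exactly(self):
        cube = self._rank3_cube()
        out = pca_denoise(cube, 3)
        err = np.abs(out.data - cube.data).max()
        assert err < 1e-8 * np.abs(cube.data).max()

    def test_denoising_reduces_rmse_to_clean_signal(self):
        clean = self._rank3_cube()
        noisy = self._rank3_cube(noise=0.1)  # same seed: same signal
        out = pca_denoise(noisy, 3)
        rmse_before = np.sqrt(((noisy.data - clean.data) ** 2).mean())
        rmse_after = np.sqrt(((out.data - clean.data) ** 2).mean())
        assert rmse_after < rmse_before

    def test_full_rank_reconstruction_is_identity(self):
        cube = self._rank3_cube(noise=0.05)
        out = pca_denoise(cube, cube.n_pixels - 1)
        np.testing.assert_allclose(out.data, cube.data, atol=1e-8)


class TestRmies:
    @pytest.fixture
    def clean_ftir(self, library):
        axis = default_ftir_axis()
        s = a.compartment_spectrum(a.default_composition()["cytoplasm"],
                                   library, axis, "ftir")
        return Spectrum(axis, 4.0 * s.intensities, "ftir")

    def test_reference_input_is_fixed_point(self, clean_ftir):
        out = rmies_correct([clean_ftir], clean_ftir)[0]
        np.testing.assert_allclose(out.intensities, clean_ftir.intensities,
                                   atol=1e-8)

    def test_mie_distortion_removed(self, clean_ftir):
        axis = clean_ftir.axis
        extinction = 0.12 * 0.5 * extinction_curve(axis.values, 5.1, 1.33)
        distorted = clean_ftir.with_intensities(
            clean_ftir.intensities + extinction
        )
        corrected = rmies_correct([distorted], clean_ftir)[0]
        rms = np.sqrt((clean_ftir.intensities**2).mean())
        before = np.sqrt(((distorted.intensities
                           - clean_ftir.intensities) ** 2).mean()) / rms
        after = np.sqrt(((corrected.intensities
                          - clean_ftir.intensities) ** 2).mean()) / rms
        assert after < 0.05
        assert before > 5 * after

    def test_constant_offset_removed(self, clean_ftir):
        shifted = clean_ftir.with_intensities(clean_ftir.intensities + 0.7)
        corrected = rmies_correct([shifted], clean_ftir)[0]
        np.testing.assert_allclose(corrected.intensities,
                                   clean_ftir.intensities, atol=1e-6)


class TestChains:
    def test_raman_chain_preserves_compartment_chemistry(
        self, raman_e2e, raman_sim, library
    ):
        """Class means after the full chain stay close (cosine >= 0.98) to
        the clean composition-weighted compartment spectra.

        The clean references are taken through the same deterministic
        smoothing so the comparison measures recovery of compartment
        chemistry from the corrupted cube, not the known transfer function
        of the Savitzky-Golay filter.
        """
        _, layout, _ = raman_sim
        _, result, _ = raman_e2e
        for lab, name in result.class_names.items():
            clean = postprocess_mean_spectrum(
                a.compartment_spectrum(
                    layout.composition[name], library,
                    result.class_mean_spectra[lab].axis, "raman",
                )
            ).intensities
            processed = postprocess_mean_spectrum(
                result.class_mean_spectra[lab]
            ).intensities
            cosine = processed @ clean / (
                np.linalg.norm(processed) * np.linalg.norm(clean)
            )
            assert cosine >= 0.98, name

    def test_ftir_chain_reports_kept_pixels(self, ftir_sim):
        cube, _, _ = ftir_sim
        _, mask, log = a.preprocess_ftir_cube(cube)
        assert log["pixels_kept"] == int(mask.sum())
        assert mask.any()
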