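import numpy as np
import pytest

import adipospec as a
from adipospec.core import Spectrum
from adipospec.library import SATURATED_TAG_STANDARDS
from adipospec.metrics import (
    CalibrationModel,
    build_chain_length_calibration,
    build_unsaturation_calibration,
    chain_length_from_spectrum,
    compute_ratio,
    default_metrics,
    fit_linear_calibration,
    ideal_fatty_acid_spectrum,
    ideal_tag_spectrum,
    metric_table,
    unsaturation_from_spectrum,
)


class TestComputeRatio:
    def test_ideal_trilaurin_chain_length_ratio_is_ten(self):
        ratio = compute_ratio(ideal_tag_spectrum(36),
                              default_metrics()["chain_length"])
        assert ratio == pytest.approx(10.0, rel=2e-3)

    def test_stearic_acid_has_zero_unsaturation_ratio(self):
        ratio = compute_ratio(ideal_fatty_acid_spectrum(0),
                              default_metrics()["ufas"])
        assert ratio == pytest.approx(0.0, abs=1e-9)

    def test_ratio_is_scale_invariant(self):
        s = ideal_tag_spectrum(48)
        metric = default_metrics()["tags"]
        one = compute_ratio(s, metric)
        seven = compute_ratio(s.with_intensities(7 * s.intensities), metric)
        assert seven == pytest.approx(one, rel=1e-12)

    def test_zero_denominator_yields_nan_flag(self):
        s = ideal_tag_spectrum(36)
        zeroed = s.with_intensities(np.zeros_like(s.intensities))
        assert np.isnan(compute_ratio(zeroed, default_metrics()["tags"]))


class TestCalibrations:
    def test_tag_series_fit_matches_group_counting_identity(self):
        # CH2/CH3 ratio of a saturated TAG is (N - 6)/3 = N/3 - 2
        model = build_chain_length_calibration()
        assert model.r_squared == pytest.approx(1.0, abs=1e-10)
        assert model.slope == pytest.approx(1 / 3, rel=1e-2)
        assert model.intercept == pytest.approx(-2.0, rel=1e-2)

    def test_fa_series_fit_is_exactly_linear(self):
        model = build_unsaturation_calibration()
        assert model.r_squared == pytest.approx(1.0, abs=1e-10)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)

    def test_two_points_interpolated_exactly(self):
        model = fit_linear_calibration([(24.0, 6.0), (66.0, 20.0)])
        assert model.predict_property(6.0)[0] == pytest.approx(24.0)
        assert model.predict_property(20.0)[0] == pytest.approx(66.0)

    def test_degenerate_fits_rejected(self):
        with pytest.raises(a.ValidationError):
            fit_linear_calibration([(5.0, 1.0), (5.0, 2.0)])
        with pytest.raises(a.ValidationError):
            fit_linear_calibration([(1.0, 2.0), (2.0, 2.0), (3.0, 2.0)])

    def test_model_json_round_trip(self):
        model = build_unsaturation_calibration()
        back = CalibrationModel.from_json(model.to_json())
        assert back.slope == model.slope
        assert back.training_points == model.training_points


class TestPredictions:
    def test_held_out_trilaurin_predicts_36_carbons(self):
        model = build_chain_length_calibration(exclude=["trilaurin"])
        pred = chain_length_from_spectrum(ideal_tag_spectrum(36), model)
        assert pred.value == pytest.approx(36.0, abs=1e-6)
        assert pred.nearest_standard == "trilaurin"
        assert not pred.extrapolated

    def test_training_point_round_trips_exactly(self):
        model = build_chain_length_calibration()
        for name, n in SATURATED_TAG_STANDARDS.items():
            pred = chain_length_from_spectrum(ideal_tag_spectrum(n), model)
            assert pred.value == pytest.approx(float(n), abs=1e-6)

    def test_ratio_below_series_flags_extrapolation(self):
        model = build_chain_length_calibration()
        pred = chain_length_from_spectrum(ideal_tag_spectrum(12), model)
        assert pred.extrapolated
        assert pred.value == pytest.approx(12.0, abs=1e-6)

    def test_held_out_alpha_linolenic_predicts_3_bonds(self):
        model = build_unsaturation_calibration(
            exclude=["alpha_linolenic_acid"]
        )
        pred = unsaturation_from_spectrum(ideal_fatty_acid_spectrum(3), model)
        assert pred.value == pytest.approx(3.0, abs=1e-6)

    def test_pure_stearic_predicts_zero_unsaturation(self):
        model = build_unsaturation_calibration()
        pred = unsaturation_from_spectrum(ideal_fatty_acid_spectrum(0), model)
        assert pred.value == pytest.approx(0.0, abs=1e-6)

    def test_wrong_model_kind_rejected(self):
        model = build_unsaturation_calibration()
        with pytest.raises(a.ValidationError):
            chain_length_from_spectrum(ideal_tag_spectrum(36), model)

    @pytest.mark.parametrize("seed", range(20))
    def test_recovery_under_noise(self, seed):
        """Default-level noise moves chain length by < 1 carbon and
        unsaturation by < 0.05 bonds."""
        rng = np.random.default_rng(seed)
        chain_model = build_chain_length_calibration()
        unsat_model = build_unsaturation_calibration()
        tag = ideal_tag_spectrum(48)
        noisy = tag.with_intensities(
            tag.intensities
            + rng.normal(0, 0.03 * tag.intensities.mean(),
                         tag.intensities.shape)
        )
        assert chain_length_from_spectrum(noisy, chain_model).value == \
            pytest.approx(48.0, abs=1.0)
        fa = ideal_fatty_acid_spectrum(1)
        noisy_fa = fa.with_intensities(
            fa.intensities
            + rng.normal(0, 0.03 * fa.intensities.mean(),
                         fa.intensities.shape)
        )
        assert unsaturation_from_spectrum(noisy_fa, unsat_model).value == \
            pytest.approx(1.0, abs=0.05)


class TestEndToEnd:
    def test_default_cube_ld_unsaturation_near_042(self, ld_unsaturation):
        """Full pipeline on the default Raman cube recovers the generator's
        lipid-droplet unsaturation of 0.42 C=C per chain."""
        assert ld_unsaturation == pytest.approx(0.42, abs=0.05)


class TestMetricTable:
    def _spectra_pair(self):
        return [ideal_fatty_acid_spectrum(1), ideal_tag_spectrum(36)]

    def test_full_grid_row_count(self):
        spectra = {
            s: {c: self._spectra_pair()
                for c in ("lipid_droplet", "perilipidic_area", "cytoplasm")}
            for s in ("s1", "s2")
        }
        table = metric_table(spectra)
        assert len(table) == 2 * 3 * 7

    def test_duplicated_sample_duplicates_values(self):
        spectra = {s: {"lipid_droplet": self._spectra_pair()}
                   for s in ("s1", "s2")}
        table = metric_table(spectra)
        v1 = table[table["sample"] == "s1"].set_index("metric")["value"]
        v2 = table[table["sample"] == "s2"].set_index("metric")["value"]
        assert (v1 == v2).all()

    def test_missing_modality_skipped_with_warning(self):
        spectra = {"s1": {"lipid_droplet": ideal_fatty_acid_spectrum(1)}}
        with pytest.warns(UserWarning, match="skipped"):
            table = metric_table(spectra)
        # only the three Raman metrics remain
        assert set(table["metric"]) == {"pls", "ufas", "cytochromes"}
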