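"""Calibration, determinism and instrument simulation of the synthetic landscape."""

import numpy as np
import pytest

from dnasensor import (
    Anchor,
    CalibrationError,
    KNOWN_SENSORS,
    Landscape,
    NoiseModel,
)
from dnasensor.landscape import READOUT_WAVELENGTH_NM
from dnasensor.response import intensity_at, spectrum_response
from dnasensor.sequences import FLANK, validate_sequence

ORIGINAL = KNOWN_SENSORS["original"]


class TestCalibration:
    def test_serotonin_anchor_is_exact(self, landscape, original):
        assert landscape.true_response(original, "5HT") == pytest.approx(0.949, abs=1e-9)

    def test_selectivity_anchor_is_exact(self, landscape, original):
        ratio = landscape.true_response(original, "5HT") / landscape.true_response(
            original, "DA"
        )
        assert ratio == pytest.approx(0.508, abs=1e-6)

    def test_anchored_kd_is_pinned(self, landscape, original):
        assert landscape.kd_um(original, "5HT") == 11.6

    def test_same_seed_gives_identical_model(self, original):
        a, b = Landscape(seed=7), Landscape(seed=7)
        for analyte in a.analytes:
            assert a.true_response(original, analyte) == b.true_response(
                original, analyte
            )

    def test_distinct_seeds_give_distinct_weights(self):
        a, b = Landscape(seed=1), Landscape(seed=2)
        assert not np.allclose(a._weights["5HT"], b._weights["5HT"])

    def test_recalibration_is_idempotent(self, original):
        model = Landscape(seed=3)
        before = model.true_response(original, "5HT")
        model._calibrate()
        assert model.true_response(original, "5HT") == before

    def test_contradictory_anchors_raise(self):
        anchors = (
            Anchor(ORIGINAL, "5HT", 1.0),
            Anchor(ORIGINAL, "5HT", 2.0),
        )
        with pytest.raises(CalibrationError):
            Landscape(seed=0, anchors=anchors)

    def test_anchor_below_response_floor_raises(self):
        with pytest.raises(CalibrationError):
            Landscape(seed=0, anchors=(Anchor(ORIGINAL, "5HT", -1.5),))

    def test_unknown_analyte_raises(self, landscape, original):
        with pytest.raises(KeyError):
            landscape.true_response(original, "histamine")


class TestGroundTruth:
    def test_response_floor_at_minus_one(self, landscape, full_library):
        values = landscape.true_response_batch(full_library.members[:2000], "GABA")
        assert np.all(values >= -1.0)

    def test_single_base_change_equals_weight_difference(self, landscape, original):
        """Finite-difference check against the weight table (additive model)."""
        var = list(original.variable_region)
        pos, new_base = 5, "G"
        old_base = var[pos]
        var[pos] = new_base
        mutant = validate_sequence(FLANK + "".join(var) + FLANK)
        base_idx = {b: i for i, b in enumerate("ACGT")}
        w = landscape._weights["5HT"]
        expected_delta = w[pos, base_idx[new_base]] - w[pos, base_idx[old_base]]
        observed = landscape.true_response(mutant, "5HT") - landscape.true_response(
            original, "5HT"
        )
        assert observed == pytest.approx(expected_delta, abs=1e-12)

    def test_batch_matches_scalar(self, landscape, full_library):
        sample = full_library.members[:50]
        batch = landscape.true_response_batch(sample, "DA")
        scalar = [landscape.true_response(s, "DA") for s in sample]
        assert np.allclose(batch, scalar)

    def test_epistatic_landscape_is_deterministic_and_differs(self, original):
        flat = Landscape(seed=5, epistasis_density=0.0)
        epi = Landscape(seed=5, epistasis_density=0.3)
        assert epi._epistasis["5HT"]  # interactions were drawn
        again = Landscape(seed=5, epistasis_density=0.3)
        assert epi.true_response(original, "5HT") == again.true_response(
            original, "5HT"
        )
        assert flat._epistasis["5HT"] == []


class TestSpectra:
    def test_zero_concentration_returns_baseline(self, landscape, original):
        base = landscape.baseline_spectrum()
        spec = landscape.simulate_spectrum(original, "5HT", 0.0)
        assert np.array_equal(spec.intensities, base.intensities)

    def test_saturating_concentration_scales_readout_peak(self, landscape, original):
        r = landscape.true_response(original, "5HT")
        kd = landscape.kd_um(original, "5HT")
        base = landscape.baseline_spectrum()
        spec = landscape.simulate_spectrum(original, "5HT", 1e6 * kd)
        f0 = intensity_at(base, READOUT_WAVELENGTH_NM)
        f = intensity_at(spec, READOUT_WAVELENGTH_NM)
        assert f / f0 == pytest.approx(1.0 + r, rel=1e-5)

    def test_readout_intensity_closed_form_at_protocol_concentration(
        self, landscape, original
    ):
        """At 100 µM with K_d = 11.6 µM the peak scales by 1 + 0.949*(100/111.6)."""
        base = landscape.baseline_spectrum()
        spec = landscape.simulate_spectrum(original, "5HT", 100.0)
        f0 = intensity_at(base, READOUT_WAVELENGTH_NM)
        f = intensity_at(spec, READOUT_WAVELENGTH_NM)
        assert f == pytest.approx(f0 * (1.0 + 0.949 * 100.0 / 111.6), rel=1e-9)

    def test_spectrum_stays_nonnegative_even_at_full_quench(self, original):
        model = Landscape(seed=0, anchors=(Anchor(ORIGINAL, "5HT", -1.0),))
        spec = model.simulate_spectrum(original, "5HT", 1e9)
        assert np.all(spec.intensities >= 0)

    def test_negative_concentration_raises(self, landscape, original):
        with pytest.raises(ValueError):
            landscape.simulate_spectrum(original, "5HT", -1.0)

    def test_spectrum_pipeline_matches_direct_response(self, landscape, original):
        via_spectra = spectrum_response(landscape, original, "5HT", 30.0)
        direct = landscape.response_at(original, "5HT", 30.0)
        assert via_spectra == pytest.approx(direct, abs=1e-9)


class TestMeasurements:
    def test_zero_noise_replicates_equal_noiseless_value(self, landscape, original, zero_noise):
        m = landscape.simulate_measurement(zero_noise, original, "5HT", 100.0)
        expected = landscape.response_at(original, "5HT", 100.0)
        assert m.replicates == [expected] * 3

    def test_triplicate_default(self, landscape, original):
        m = landscape.simulate_measurement(NoiseModel(seed=1), original, "5HT", 100.0)
        assert len(m.replicates) == 3

    def test_measurement_deterministic_per_identity(self, landscape, original):
        noise = NoiseModel(seed=9)
        a = landscape.simulate_measurement(noise, original, "DA", 100.0)
        b = landscape.simulate_measurement(noise, original, "DA", 100.0)
        assert a.replicates == b.replicates

    def test_replicate_means_are_unbiased(self, landscape, original):
        """Monte-Carlo: mean of replicate-means stays within 3 SE of truth."""
        truth = landscape.response_at(original, "5HT", 100.0)
        rng = np.random.default_rng(0)
        n_trials, sd = 5000, 0.05
        means = [
            landscape.simulate_measurement(
                NoiseModel(relative_sd=sd, seed=0), original, "5HT", 100.0, rng=rng
            ).mean
            for _ in range(n_trials)
        ]
        se = truth * sd / np.sqrt(3 * n_trials)
        assert abs(np.mean(means) - truth) < 3 * se

    def test_invalid_noise_parameters_raise(self):
        with pytest.raises(ValueError):
            NoiseModel(relative_sd=-0.1)
        with pytest.raises(ValueError):
            NoiseModel(replicate_count=0)
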