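import numpy as np
import pytest

from isofinger import (
    KineticSystem,
    LabelingScheme,
    NoiseModel,
    build_design_matrix,
    deconvolve,
    extract_vector,
    fit_dilution_series,
    label_count_distribution,
    predict_pattern,
    simulate_dilution,
    simulate_kinetics,
    simulate_plate,
    simulate_spectrum,
)
from isofinger.simulate import ZERO_NOISE


class TestSimulateSpectrum:
    def test_zero_noise_single_candidate_inverts_to_pattern(self, toy_candidates):
        cand = toy_candidates[0]
        spec = simulate_spectrum([cand], np.array([1.0]), noise=ZERO_NOISE, K=3)
        y = extract_vector(spec, cand.ion_mz(), 3)
        np.testing.assert_allclose(y.normalized(), predict_pattern(cand, 3).probs, atol=1e-9)

    def test_same_seed_is_deterministic(self, toy_candidates):
        noise = NoiseModel(0.05, 2.0, seed=77)
        f = np.array([0.5, 0.3, 0.2])
        s1 = simulate_spectrum(toy_candidates, f, noise=noise)
        s2 = simulate_spectrum(toy_candidates, f, noise=noise)
        np.testing.assert_array_equal(s1.intensity, s2.intensity)
        np.testing.assert_array_equal(s1.mz, s2.mz)

    def test_noise_is_unbiased_over_replicates(self, toy_candidates):
        # law of large numbers: mean of 1000 replicates near noiseless truth
        f = np.array([0.5, 0.3, 0.2])
        total = 1e5
        clean = simulate_spectrum(toy_candidates, f, noise=ZERO_NOISE, total_intensity=total, K=3)
        noise = NoiseModel(0.02, 1.0, seed=5)
        rng = noise.rng()
        acc = np.zeros(len(clean))
        n = 1000
        for _ in range(n):
            acc += simulate_spectrum(
                toy_candidates, f, noise=noise, rng=rng, total_intensity=total, K=3
            ).intensity
        mean = acc / n
        sigma = np.sqrt((0.02 * clean.intensity) ** 2 + 1.0**2)
        # clipping at zero biases empty bins; check bins clear of the noise floor
        hot = clean.intensity > 5 * sigma
        assert hot.any()
        np.testing.assert_array_less(
            np.abs(mean - clean.intensity)[hot], (3 * sigma / np.sqrt(n))[hot]
        )

    def test_invalid_fractions_rejected(self, toy_candidates):
        with pytest.raises(ValueError, match="fractions"):
            simulate_spectrum(toy_candidates, np.array([0.5, 0.5, 0.5]))
        with pytest.raises(ValueError, match="fractions"):
            simulate_spectrum(toy_candidates, np.array([-0.2, 0.6, 0.6]))


class TestSimulateKinetics:
    def test_unity_kies_mean_no_fractionation(self):
        scheme = LabelingScheme.from_dict({"a": 0.9, "b": 0.3})
        kh = (3.0, 1.0)
        initial = label_count_distribution(scheme.fractions)
        for conv in (1e-6, 0.3, 0.7, 0.99):
            res = simulate_kinetics(KineticSystem(scheme, kh, (1.0, 1.0), conv))
            fracs = np.array([res.site_fractions["a"], res.site_fractions["b"]])
            np.testing.assert_allclose(fracs, [0.75, 0.25], atol=1e-9)
            np.testing.assert_allclose(res.residual_pattern.probs, initial.probs, atol=1e-9)

    def test_low_conversion_matches_differential_model(self):
        scheme = LabelingScheme.from_dict({"a": 0.8, "b": 0.5, "c": 0.0})
        kh = np.array([2.0, 1.5, 1.0])
        kies = np.array([1.8, 3.0, 1.0])
        res = simulate_kinetics(KineticSystem(scheme, tuple(kh), tuple(kies), 1e-6))
        expected = kh * (1 - np.array(scheme.fractions) * (1 - 1 / kies))
        expected /= expected.sum()
        got = np.array([res.site_fractions[s] for s in scheme.site_ids])
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_mass_conservation_at_all_conversions(self):
        scheme = LabelingScheme.from_dict({"a": 0.9, "b": 0.5, "c": 0.2})
        sys_kh, sys_kie = (2.0, 1.0, 0.5), (2.5, 1.4, 1.0)
        for conv in (0.0, 1e-6, 0.1, 0.5, 0.9, 0.999):
            res = simulate_kinetics(KineticSystem(scheme, sys_kh, sys_kie, conv))
            converted = 1.0 - res.residual_mass
            assert converted == pytest.approx(conv, abs=1e-9)
            # all consumed material is accounted for across the product sites
            assert sum(res.site_fractions.values()) == pytest.approx(1.0, abs=1e-12)
            assert res.residual_pattern.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_full_conversion_limit(self):
        scheme = LabelingScheme.from_dict({"a": 0.9})
        res = simulate_kinetics(KineticSystem(scheme, (1.0,), (2.0,), 0.999999))
        assert res.residual_mass == pytest.approx(0.0, abs=1e-5)
        assert sum(res.site_fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_residual_enrichment_monotone_in_conversion(self):
        scheme = LabelingScheme.from_dict({"a": 0.9, "b": 0.0})
        shifts = []
        for conv in (0.1, 0.3, 0.5, 0.7, 0.9):
            res = simulate_kinetics(KineticSystem(scheme, (1.0, 1.0), (2.0, 1.0), conv))
            shifts.append(res.residual_pattern.mean_shift())
        assert all(a < b for a, b in zip(shifts, shifts[1:]))

    def test_invalid_systems_rejected(self):
        scheme = LabelingScheme.from_dict({"a": 0.5})
        with pytest.raises(ValueError, match="conversion"):
            KineticSystem(scheme, (1.0,), (1.5,), 1.0)
        with pytest.raises(ValueError, match="positive"):
            KineticSystem(scheme, (-1.0,), (1.5,), 0.5)
        with pytest.raises(ValueError, match="align"):
            KineticSystem(scheme, (1.0, 2.0), (1.5,), 0.5)
        big = LabelingScheme.from_dict({f"s{i}": 0.5 for i in range(17)})
        with pytest.raises(ValueError, match="16"):
            KineticSystem(big, (1.0,) * 17, (1.0,) * 17, 0.5)


class TestSimulateDilution:
    R0S = {"a": 2.16, "ref": 1.0}
    DS = {"a": 0.88, "ref": 0.0}
    KIES = {"a": 1.8, "ref": 1.0}

    def test_chi_zero_gives_exact_protio_ratio(self):
        series = simulate_dilution(self.R0S, self.DS, self.KIES, [0.0, 0.5])
        assert series.ratio[0] == pytest.approx(2.16, abs=1e-9)

    def test_zero_noise_round_trip_through_fit(self):
        chis = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        series = simulate_dilution(self.R0S, self.DS, self.KIES, chis)
        fit = fit_dilution_series(series, d=0.88)
        assert fit.r0 == pytest.approx(2.16, abs=1e-6)
        assert fit.kie == pytest.approx(1.80, abs=1e-6)

    def test_same_seed_reproducible(self):
        chis = [0.2, 0.6, 1.0]
        s1 = simulate_dilution(self.R0S, self.DS, self.KIES, chis, noise_sigma=0.02, seed=3)
        s2 = simulate_dilution(self.R0S, self.DS, self.KIES, chis, noise_sigma=0.02, seed=3)
        np.testing.assert_array_equal(s1.ratio, s2.ratio)

    def test_invalid_chi_rejected(self):
        with pytest.raises(ValueError, match="chi"):
            simulate_dilution(self.R0S, self.DS, self.KIES, [0.5, 1.5])


class TestSimulatePlate:
    def test_default_plate_counts(self):
        plate = simulate_plate(seed=1)
        assert plate.n_spectra == 72  # 24 wells x 3 replicates
        assert len(plate.truth) == 24

    def test_zero_noise_plate_deconvolves_to_truth(self):
        plate = simulate_plate(noise=ZERO_NOISE, replicates=1)
        for well, cands in plate.candidates.items():
            dm = build_design_matrix(cands)
            spec = plate.spectra[(well, 1)]
            y = extract_vector(spec, cands[0].ion_mz(), dm.window)
            res = deconvolve(y, dm)
            truth_row = plate.truth[plate.truth.well == well].iloc[0]
            truth = np.array([truth_row[f"f_{c.name}"] for c in cands])
            np.testing.assert_allclose(res.fractions, truth, atol=1e-8)

    def test_seeded_plate_regenerates_identically(self):
        p1 = simulate_plate(seed=9)
        p2 = simulate_plate(seed=9)
        assert p1.truth.equals(p2.truth)
        for key in p1.spectra:
            np.testing.assert_array_equal(p1.spectra[key].intensity, p2.spectra[key].intensity)

    def test_write_creates_csv_tree(self, tmp_path):
        plate = simulate_plate(seed=2, replicates=2)
        plate.write(tmp_path / "plate")
        assert (tmp_path / "plate" / "truth.csv").exists()
        assert (tmp_path / "plate" / "A1" / "rep1.csv").exists()
        assert len(list((tmp_path / "plate").glob("*/rep*.csv"))) == 48
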