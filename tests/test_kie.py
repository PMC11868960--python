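import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isofinger import (
    DilutionKIEModel,
    DilutionSeries,
    KIEFitError,
    KineticSystem,
    LabelingScheme,
    correct_fractions_for_kie,
    detect_kie,
    fit_dilution_series,
    fit_multisite_dilution,
    label_count_distribution,
    simulate_dilution,
    simulate_kinetics,
)

CHIS = np.array([0.2, 0.4, 0.6, 0.8, 1.0])


def model_series(r0, d, kie, chis=CHIS, sigma=None):
    ratios = r0 * (1 - d * chis * (1 - 1 / kie))
    return DilutionSeries(chis, ratios, sigma=sigma)


class TestDetectKIE:
    def test_identical_patterns_give_zero(self):
        initial = label_count_distribution([0.3, 0.64, 0.94])
        stat, flag = detect_kie(initial, initial)
        assert stat == 0.0 and not flag

    def test_unlabeled_substrate_never_flags(self):
        scheme = LabelingScheme.from_dict({"a": 0.0, "b": 0.0})
        initial = label_count_distribution(scheme.fractions)
        for conv in (0.2, 0.5, 0.9):
            sys_ = KineticSystem(scheme, (1.0, 2.0), (2.0, 1.5), conv)
            res = simulate_kinetics(sys_)
            stat, flag = detect_kie(res.residual_pattern, initial)
            assert stat == pytest.approx(0.0, abs=1e-12) and not flag

    def test_kie_two_enriches_residual_in_deuterium(self):
        scheme = LabelingScheme.from_dict({"a": 0.9, "b": 0.0})
        initial = label_count_distribution(scheme.fractions)
        res = simulate_kinetics(KineticSystem(scheme, (1.0, 1.0), (2.0, 1.0), 0.5))
        stat, _ = detect_kie(res.residual_pattern, initial)
        assert stat > 0
        # slow D material survives: residual mean shift above initial
        assert res.residual_pattern.mean_shift() > initial.mean_shift()
        # drift grows with conversion and crosses the default flag threshold
        deep = simulate_kinetics(KineticSystem(scheme, (1.0, 1.0), (2.0, 1.0), 0.8))
        stat80, flag80 = detect_kie(deep.residual_pattern, initial)
        assert stat80 > stat and flag80

    def test_window_mismatch_rejected(self):
        a = label_count_distribution([0.5])
        b = label_count_distribution([0.5, 0.5])
        with pytest.raises(KIEFitError, match="window"):
            detect_kie(a, b)


class TestFitDilutionSeries:
    def test_constant_ratio_means_no_isotope_effect(self):
        series = DilutionSeries(CHIS, np.full(5, 2.16))
        fit = fit_dilution_series(series, d=0.88)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.kie == pytest.approx(1.0, abs=1e-12)
        assert fit.r0 == pytest.approx(2.16, abs=1e-12)

    def test_recovers_reference_standards_exactly(self):
        # protio selectivity 2.16 and competitive KIE 1.80 at d = 0.88
        fit = fit_dilution_series(model_series(2.16, 0.88, 1.80), d=0.88)
        assert fit.r0 == pytest.approx(2.16, abs=1e-9)
        assert fit.kie == pytest.approx(1.80, abs=1e-9)
        assert fit.slope <= 0
        assert not fit.inverse

    @settings(max_examples=80, derandomize=True)
    @given(
        st.floats(0.11, 9.9), st.floats(1.01, 7.9), st.floats(0.1, 1.0)
    )
    def test_noiseless_inversion_over_parameter_space(self, r0, kie, d):
        fit = fit_dilution_series(model_series(r0, d, kie), d=d)
        assert fit.r0 == pytest.approx(r0, rel=1e-7)
        assert fit.kie == pytest.approx(kie, rel=1e-6)

    def test_inverse_kie_is_flagged(self):
        fit = fit_dilution_series(model_series(2.0, 0.9, 0.7), d=0.9)
        assert fit.inverse and fit.kie == pytest.approx(0.7, rel=1e-9)

    def test_noisy_median_within_tenth(self):
        # 2% multiplicative ratio noise, 200 seeded replicates
        rng = np.random.default_rng(7)
        truth = model_series(2.16, 0.88, 1.80).ratio
        kies = []
        for _ in range(200):
            noisy = truth * (1 + 0.02 * rng.standard_normal(truth.size))
            fit = fit_dilution_series(DilutionSeries(CHIS, noisy), d=0.88)
            kies.append(fit.kie)
        assert abs(np.median(kies) - 1.80) < 0.1

    def test_kie_near_one_is_noise_sensitive(self):
        # scatter relative to the effect size (KIE - 1) blows up as KIE -> 1:
        # small competitive isotope effects are hard to pin down from ratios
        rng = np.random.default_rng(8)

        def spread(kie_true):
            truth = model_series(2.16, 0.88, kie_true).ratio
            vals = []
            for _ in range(200):
                noisy = truth * (1 + 0.02 * rng.standard_normal(truth.size))
                try:
                    vals.append(fit_dilution_series(DilutionSeries(CHIS, noisy), d=0.88).kie)
                except KIEFitError:
                    continue
            return np.subtract(*np.percentile(vals, [75, 25]))

        assert spread(1.1) / 0.1 > spread(4.0) / 3.0

    def test_weighted_fit_uses_sigmas(self):
        series = model_series(2.16, 0.88, 1.80, sigma=np.full(5, 0.05))
        fit = fit_dilution_series(series, d=0.88)
        assert fit.kie == pytest.approx(1.80, abs=1e-9)
        assert np.isfinite(fit.se_kie)

    def test_degenerate_series_rejected(self):
        with pytest.raises(KIEFitError, match="distinct"):
            DilutionSeries(np.array([0.5, 0.5]), np.array([1.0, 1.1]))
        with pytest.raises(KIEFitError, match=">= 2"):
            DilutionKIEModel(DilutionSeries(np.array([0.5]), np.array([1.0])), d=0.8)
        with pytest.raises(KIEFitError, match="d must be"):
            DilutionKIEModel(model_series(2.0, 0.8, 1.5), d=0.0)

    def test_nonpositive_intercept_rejected(self):
        series = DilutionSeries(np.array([0.1, 0.9]), np.array([2.0, 0.1]))
        with pytest.raises(KIEFitError):
            fit_dilution_series(series, d=1.0)

    def test_csv_round_trip(self, tmp_path):
        series = model_series(2.16, 0.88, 1.80)
        pd.DataFrame({"chi": series.chi, "ratio": series.ratio}).to_csv(
            tmp_path / "s.csv", index=False
        )
        back = DilutionSeries.from_csv(tmp_path / "s.csv")
        fit = fit_dilution_series(back, d=0.88)
        assert fit.kie == pytest.approx(1.80, abs=1e-9)

    def test_summary_mentions_estimates(self):
        text = fit_dilution_series(model_series(2.16, 0.88, 1.80), d=0.88).summary()
        assert "2.16" in text and "1.8" in text


class TestMultisiteDilution:
    def test_two_labeled_positions_recovered_noiselessly(self):
        ds = {"a": 0.9, "b": 0.7, "ref": 0.0}
        kies = {"a": 1.8, "b": 2.5, "ref": 1.0}
        r0s = {"a": 2.0, "b": 1.2, "ref": 1.0}
        series = simulate_dilution(r0s, ds, kies, CHIS)
        fits = fit_multisite_dilution(CHIS, series.fractions, ds)
        assert set(fits) == {"a", "b"}
        assert fits["a"].kie == pytest.approx(1.8, abs=1e-6)
        assert fits["b"].kie == pytest.approx(2.5, abs=1e-6)
        assert fits["a"].r0 == pytest.approx(2.0, abs=1e-6)
        assert fits["b"].r0 == pytest.approx(1.2, abs=1e-6)

    def test_reference_site_required(self):
        with pytest.raises(KIEFitError, match="reference"):
            fit_multisite_dilution(
                CHIS, pd.DataFrame({"a": np.ones(5)}), {"a": 0.5}
            )


class TestCorrectFractions:
    def test_unity_kie_or_no_labels_is_identity(self):
        f = np.array([0.3, 0.7])
        np.testing.assert_allclose(
            correct_fractions_for_kie(f, [0.9, 0.5], [1.0, 1.0]), f, atol=1e-12
        )
        np.testing.assert_allclose(
            correct_fractions_for_kie(f, [0.0, 0.0], [1.8, 2.5]), f, atol=1e-12
        )

    def test_hand_worked_two_site_example(self):
        # factor at site 1: 1 - 0.9*(1 - 1/1.8) = 0.6 -> [0.625, 0.375]
        got = correct_fractions_for_kie([0.5, 0.5], [0.9, 0.0], [1.8, 1.0])
        np.testing.assert_allclose(got, [0.625, 0.375], atol=1e-12)

    def test_round_trip_against_kinetics_at_low_conversion(self):
        scheme = LabelingScheme.from_dict({"a": 0.8, "b": 0.4, "c": 0.0})
        kh = (3.0, 2.0, 1.0)
        kies = (1.8, 2.5, 1.0)
        res = simulate_kinetics(KineticSystem(scheme, kh, kies, 1e-7))
        observed = np.array([res.site_fractions[s] for s in scheme.site_ids])
        protio = correct_fractions_for_kie(observed, scheme.fractions, kies)
        expected = np.array(kh) / sum(kh)
        np.testing.assert_allclose(protio, expected, atol=1e-6)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(1.0, 2.99), st.floats(0.0, 1.0))
    def test_distortion_factor_bounded_for_moderate_kie(self, kie, d):
        # competitive KIE < 3 distorts a site's flux by at most 3x
        factor = 1 - d * (1 - 1 / kie)
        assert 0.33 <= factor <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(KIEFitError, match="sum to 1"):
            correct_fractions_for_kie([0.5, 0.6], [0.5, 0.5], [1.5, 1.5])
        with pytest.raises(KIEFitError, match="positive"):
            correct_fractions_for_kie([0.5, 0.5], [0.5, 0.5], [-1.0, 1.5])
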