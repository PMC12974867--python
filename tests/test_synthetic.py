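"""The synthetic study generator: determinism, structure, recovery hooks."""

import numpy as np
import pytest

from dendroiso import (
    generate_forcing_index,
    generate_rainfall,
    generate_world,
    rainfall_to_d13c,
    simulate_atm_records,
    simulate_radiocarbon_dates,
    simulate_tree,
    synth_calibration_curve,
)
from dendroiso.types import ValidationError, ce_to_bp


class TestGenerateRainfall:
    def test_structure_free_configuration_is_constant(self):
        rec = generate_rainfall(noise_sd_mm=0.0, centennial_amp_mm=0.0,
                                trend_mm_per_century=0.0, seed=1)
        assert np.allclose(rec.values, 450.0)

    def test_same_seed_bit_identical(self):
        a = generate_rainfall(seed=9)
        b = generate_rainfall(seed=9)
        assert np.array_equal(a.values, b.values)
        c = generate_rainfall(seed=10)
        assert not np.array_equal(a.values, c.values)

    def test_sample_mean_honours_configured_mean(self):
        """Monte Carlo over 100 seeds: the grand mean sits within 3
        standard errors of the configured 450 mm/yr."""
        means = [generate_rainfall(seed=s).values.mean() for s in range(100)]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 450.0) < 3 * se + 1.0

    def test_explosive_ar1_rejected(self):
        with pytest.raises(ValidationError, match="ar1"):
            generate_rainfall(ar1_phi=1.0)

    def test_short_span_rejected(self):
        with pytest.raises(ValidationError, match="100"):
            generate_rainfall(span=(1950, 2000))


class TestRainfallToD13c:
    def test_zero_noise_at_mean_rain_gives_baseline(self):
        rain = generate_rainfall(noise_sd_mm=0.0, centennial_amp_mm=0.0,
                                 trend_mm_per_century=0.0, seed=0)
        sig = rainfall_to_d13c(rain, noise_sd_permil=0.0)
        assert np.allclose(sig.values, -25.3)

    def test_zero_noise_is_perfectly_anticorrelated(self):
        rain = generate_rainfall(seed=3)
        sig = rainfall_to_d13c(rain, noise_sd_permil=0.0)
        r = np.corrcoef(rain.values, sig.values)[0, 1]
        assert r == pytest.approx(-1.0)

    def test_default_noise_keeps_strong_anticorrelation(self):
        rs = []
        for s in range(20):
            rain = generate_rainfall(seed=s)
            sig = rainfall_to_d13c(rain, seed=s + 1000)
            rs.append(np.corrcoef(rain.values, sig.values)[0, 1])
        assert all(-1.0 < r < -0.7 for r in rs)

    def test_positive_sensitivity_rejected(self):
        rain = generate_rainfall(seed=0)
        with pytest.raises(ValidationError, match="negative"):
            rainfall_to_d13c(rain, sensitivity_permil_per_100mm=0.1)


class TestSimulateTree:
    @staticmethod
    def signal(seed=0, span=(1300, 2015)):
        return rainfall_to_d13c(generate_rainfall(span=span, seed=seed),
                                seed=seed)

    def test_sample_count_matches_growth_budget(self):
        # ~0.63 samples/yr over 715 years: a 450-sample core
        series, ages = simulate_tree(self.signal(), growth_rate=0.63)
        assert 440 <= len(series) <= 460
        assert series.sample_numbers[0] == 1
        assert ages[0] == 2015.0  # bark side dated to the youngest year

    def test_hiatus_window_contains_no_samples(self):
        _, ages = simulate_tree(self.signal(), growth_rate=0.87,
                                hiatus=(1500.0, 1700.0))
        assert not np.any((ages > 1500.0) & (ages < 1700.0))
        # the gap shifts everything below it by its 200-yr duration
        assert ages.min() < 1400.0

    def test_zero_noise_reproduces_signal_exactly(self):
        sig = self.signal(seed=5)
        series, ages = simulate_tree(sig, growth_rate=0.8,
                                     measurement_noise_sd=0.0, seed=5)
        np.testing.assert_allclose(series.delta13c, sig.at(ages), atol=1e-12)

    def test_hiatus_covering_span_rejected(self):
        with pytest.raises(ValidationError):
            simulate_tree(self.signal(), growth_rate=0.8,
                          hiatus=(1301.0, 2014.0))


class TestSynthCalibrationCurve:
    def test_zero_wiggle_is_strictly_monotone(self):
        curve = synth_calibration_curve(wiggle_amp_14cyr=0.0)
        assert np.all(np.diff(curve.c14_value) > 0)

    def test_bomb_segment_is_non_monotone_with_multimodal_dates(self):
        curve = synth_calibration_curve(bomb=True, seed=2)
        bomb = curve.bomb_segment
        d = np.diff(bomb.c14_value)
        assert (d > 0).any() and (d < 0).any()
        # a mid-range F14C value maps to two disjoint year sets
        from dendroiso import calibrate_postbomb
        from dendroiso.types import RadiocarbonDate
        cal = calibrate_postbomb(
            RadiocarbonDate("T", 1, "F14C", 1.35, 0.01), bomb)
        hot = cal.year_ce[cal.density > 0.25 * cal.density.max()]
        assert np.ptp(hot) > 8 and np.any(np.diff(np.sort(hot)) > 3)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValidationError, match="slope"):
            synth_calibration_curve(slope=0.0)

    def test_calibrating_simulated_dates_recovers_truth_at_one_sigma(self):
        """Dates drawn from the curve put the true year inside the 68.3%
        HPD at roughly the nominal rate (small-n version of the larger
        acceptance simulation)."""
        from dendroiso import calibrate
        from dendroiso.types import RadiocarbonDate
        rng = np.random.default_rng(17)
        curve = synth_calibration_curve(seed=17)
        hits = 0
        n = 120
        for _ in range(n):
            true_ce = rng.uniform(1320, 1930)
            mu = float(curve.mu(ce_to_bp(true_ce)))
            sd = float(np.hypot(25.0, curve.sigma(ce_to_bp(true_ce))))
            meas = rng.normal(mu, sd)
            cal = calibrate(RadiocarbonDate("T", 1, "conventional_BP",
                                           float(meas), 25.0), curve)
            hits += cal.contains(true_ce)
        assert 0.58 <= hits / n <= 0.78


class TestSimulateRadiocarbonDates:
    def test_requested_count_and_endpoints_dated(self):
        sig = TestSimulateTree.signal()
        _, ages = simulate_tree(sig, growth_rate=0.7)
        curve = synth_calibration_curve(bomb=True)
        dates = simulate_radiocarbon_dates(ages, curve, n_dates=13)
        assert len(dates) == 13
        nums = sorted(d.sample_number for d in dates)
        assert nums[0] == 1 and nums[-1] == ages.size

    def test_noise_free_measurements_sit_on_the_curve(self):
        sig = TestSimulateTree.signal()
        _, ages = simulate_tree(sig, growth_rate=0.7)
        curve = synth_calibration_curve(wiggle_amp_14cyr=0.0, bomb=True)
        dates = simulate_radiocarbon_dates(ages, curve, lab_sigma=1e-12,
                                           lab_sigma_f14c=1e-12)
        for d in dates:
            true_age = ages[d.sample_number - 1]
            if d.measurement_type == "conventional_BP":
                assert d.value == pytest.approx(
                    float(curve.mu(ce_to_bp(true_age))), abs=1e-6)
            else:
                assert d.value == pytest.approx(
                    float(curve.bomb_segment.mu(ce_to_bp(true_age))),
                    abs=1e-6)

    def test_more_dates_than_samples_rejected(self):
        with pytest.raises(ValidationError):
            simulate_radiocarbon_dates(np.array([2000.0, 1990.0]),
                                       synth_calibration_curve(), n_dates=5)


class TestSimulateAtmRecords:
    def test_preindustrial_plateau_values(self):
        atm, co2 = simulate_atm_records()
        assert atm.at(1700) == -6.3
        assert co2.at(1700) == 280.0
        assert atm.at(1748) == -6.3
        assert co2.at(1748) == 280.0

    def test_modern_endpoints(self):
        atm, co2 = simulate_atm_records()
        assert atm.at(2015) == pytest.approx(-8.3)
        assert co2.at(2015) == pytest.approx(400.0)

    def test_flat_configuration_disables_corrections_downstream(self):
        from dendroiso import pin_correct, suess_correct
        from dendroiso.types import DatedSeries
        atm, co2 = simulate_atm_records(suess_decline_permil=0.0,
                                        co2_modern_ppm=280.0)
        s = DatedSeries("T", np.array([1500.0, 1980.0]),
                        np.array([-25.0, -24.8]))
        out = pin_correct(suess_correct(s, atm), atm, co2)
        assert np.array_equal(out.values, s.values)

    def test_span_must_include_reference_year(self):
        with pytest.raises(ValidationError, match="1748"):
            simulate_atm_records(span=(1800, 2015))


class TestGenerateWorld:
    def test_full_determinism_and_seed_sensitivity(self):
        a = generate_world(seed=3)
        b = generate_world(seed=3)
        c = generate_world(seed=4)
        for tid in a.trees:
            assert a.trees[tid] == b.trees[tid]
            assert not np.array_equal(a.trees[tid].delta13c,
                                      c.trees[tid].delta13c)
            assert np.array_equal(a.true_ages[tid], c.true_ages[tid])  # structure
        assert a.tie_points == b.tie_points

    def test_core_sizes_and_date_counts_match_study_design(self, world):
        sizes = {tid: len(s) for tid, s in world.trees.items()}
        assert 420 <= sizes["DFL"] <= 450
        assert 430 <= sizes["DFS"] <= 460
        assert 430 <= sizes["GTR"] <= 465
        assert 690 <= sizes["TSP"] <= 720
        assert {tid: len(d) for tid, d in world.dates.items()} == {
            "DFL": 12, "DFS": 12, "GTR": 13, "TSP": 15}

    def test_forcing_coupling_produces_expected_correlation(self, world):
        sst = world.forcings["SST"]
        r = np.corrcoef(sst.values, world.rainfall.values)[0, 1]
        assert 0.3 < r < 0.7  # coupled at 0.5

    def test_independent_index_determinism(self):
        a = generate_forcing_index(seed=5)
        b = generate_forcing_index(seed=5)
        assert np.array_equal(a.values, b.values)
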