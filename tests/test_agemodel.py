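"""Tie-point age models: fitting, age assignment, validation, inversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendroiso import (
    assign_ages,
    detect_inversions,
    fit_age_model,
    generate_world,
    validate_model,
)
from dendroiso.agemodel import TiePoint
from dendroiso.calibration import CalibratedDate
from dendroiso.synthetic import simulate_radiocarbon_dates, simulate_tree
from dendroiso.types import IsotopeSeries, ValidationError


def dfl_tie_points():
    """The three-anchor chronology of a slow-growing core: bark-side ring
    10 at 2005 CE, ring 265 at 1625 CE, ring 450 at 1280 CE."""
    return [TiePoint("DFL", 10, 2005.0), TiePoint("DFL", 265, 1625.0),
            TiePoint("DFL", 450, 1280.0)]


def gtr_tie_points():
    """Chronology with a growth hiatus: ring 380 carries 1750 and 1500 CE."""
    return [TiePoint("GTR", 18, 2015.0), TiePoint("GTR", 380, 1750.0),
            TiePoint("GTR", 380, 1500.0), TiePoint("GTR", 450, 1340.0)]


class TestFitAgeModel:
    def test_two_segment_model_from_three_anchors(self):
        model = fit_age_model(dfl_tie_points())
        assert len(model.knots) == 3
        assert model.hiatus is None
        assert model.domain == (10, 450)

    def test_midpoint_of_linear_segment(self):
        model = fit_age_model(dfl_tie_points())
        assert model.year_at(137.5) == pytest.approx(1815.0)

    def test_segment_growth_rate(self):
        model = fit_age_model(dfl_tie_points())
        rate = (model.year_at(10) - model.year_at(265)) / (265 - 10)
        assert rate == pytest.approx((2005 - 1625) / (265 - 10))
        assert rate == pytest.approx(1.490, abs=5e-4)

    def test_hiatus_pair_becomes_jump_of_250_years(self):
        model = fit_age_model(gtr_tie_points())
        assert model.hiatus is not None
        assert model.hiatus.sample_number == 380
        assert model.hiatus.duration == pytest.approx(250.0)
        # just outside ring 380 the model is on the young segment;
        # at the ring it drops to the old side
        assert model.year_at(379.99) == pytest.approx(1750.0, abs=0.1)
        assert model.year_at(380) == pytest.approx(1500.0)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            fit_age_model([TiePoint("X", 1, 2000.0)])

    def test_undeclared_inversion_rejected(self):
        pts = [TiePoint("X", 1, 1900.0), TiePoint("X", 100, 1950.0)]
        with pytest.raises(ValidationError, match="hiatus"):
            fit_age_model(pts)

    def test_queries_outside_domain_error(self):
        model = fit_age_model(dfl_tie_points())
        with pytest.raises(ValidationError, match="outside"):
            model.year_at(9)
        assert model.year_at(451, extrapolate="clamp") == model.year_at(450)

    def test_refit_from_extracted_knots_reproduces_model(self):
        model = fit_age_model(gtr_tie_points())
        refit = fit_age_model(list(model.knots))
        q = np.linspace(18, 450, 333)
        np.testing.assert_array_equal(refit.year_at(q), model.year_at(q))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=60), min_size=2,
                    max_size=6, unique=True))
    def test_year_strictly_decreases_with_ring_depth(self, depths):
        depths = sorted(depths)
        # years strictly decreasing with depth: 40 yr per knot step
        pts = [TiePoint("H", s, 2000.0 - 40.0 * i)
               for i, s in enumerate(depths)]
        model = fit_age_model(pts)
        lo, hi = model.domain
        q = np.linspace(lo, hi, 101)
        years = model.year_at(q)
        assert np.all(np.diff(years) < 0)


class TestAssignAges:
    def test_constant_rate_tree_recovers_true_ages_exactly(self, world):
        tid = "DFS"
        model = fit_age_model(world.tie_points[tid])
        dated = assign_ages(model, world.trees[tid])
        np.testing.assert_allclose(
            np.sort(dated.years), np.sort(world.true_ages[tid]), atol=1e-9)

    def test_no_sample_dated_inside_hiatus(self, world):
        model = fit_age_model(world.tie_points["GTR"])
        dated = assign_ages(model, world.trees["GTR"])
        h = model.hiatus
        inside = (dated.years > h.year_stop) & (dated.years < h.year_resume)
        assert inside.sum() == 0

    def test_sample_outside_domain_errors(self):
        model = fit_age_model(dfl_tie_points())
        series = IsotopeSeries("DFL", np.array([5, 20]),
                               np.array([-25.0, -25.1]))
        with pytest.raises(ValidationError, match="outside"):
            assign_ages(model, series)


def _interval_date(tree_id, sample_number, start_ce, end_ce, flagged=False):
    """A calibrated-date stub carrying only its HPD interval."""
    return CalibratedDate(tree_id=tree_id, sample_number=sample_number,
                          year_ce=np.array([]), density=np.array([]),
                          hpd_intervals=[(start_ce, end_ce)],
                          flagged_outlier=flagged)


class TestValidateModel:
    def test_model_through_every_interval_scores_100(self):
        model = fit_age_model(dfl_tie_points())
        dates = [_interval_date("DFL", s, model.year_at(s) - 20,
                                model.year_at(s) + 20)
                 for s in (10, 100, 250, 400)]
        rep = validate_model(model, dates)
        assert rep.fraction_inside == 1.0
        assert all(r["distance_to_nearest_interval"] == 0.0
                   for r in rep.records)

    def test_distance_to_missed_interval(self):
        model = fit_age_model(dfl_tie_points())
        y = model.year_at(100)
        rep = validate_model(model, [_interval_date("DFL", 100,
                                                    y + 10, y + 30)])
        assert not rep.records[0]["inside_1sigma"]
        assert rep.records[0]["distance_to_nearest_interval"] == pytest.approx(10.0)

    def test_flagged_outliers_reported_but_not_counted(self):
        model = fit_age_model(dfl_tie_points())
        y = model.year_at(100)
        dates = [_interval_date("DFL", 100, y - 5, y + 5),
                 _interval_date("DFL", 200, 0, 10, flagged=True)]
        rep = validate_model(model, dates)
        assert rep.n_checked == 1
        assert rep.fraction_inside == 1.0
        assert len(rep.records) == 2

    def test_no_dates_rejected(self):
        with pytest.raises(ValidationError, match="no calibrated dates"):
            validate_model(fit_age_model(dfl_tie_points()), [])

    def test_true_model_coverage_at_one_sigma(self):
        """Dating many synthetic cores and validating the *true* age model:
        roughly the nominal 68% of unflagged dates should sit inside their
        1-sigma HPD intervals (coverage simulation)."""
        from dendroiso import calibrate, fit_age_model
        from dendroiso.synthetic import (generate_rainfall, rainfall_to_d13c,
                                         synth_calibration_curve,
                                         true_tie_points)
        total = inside = 0
        for rep in range(40):
            curve = synth_calibration_curve(span=(1200, 1940), seed=rep)
            rain = generate_rainfall(span=(1200, 1940), seed=rep)
            signal = rainfall_to_d13c(rain, seed=rep)
            series, ages = simulate_tree(signal, growth_rate=0.7, seed=rep)
            dates = simulate_radiocarbon_dates(ages, curve, n_dates=5,
                                               seed=rep)
            model = fit_age_model(true_tie_points("SYN", ages))
            cals = [calibrate(d, curve) for d in dates]
            report = validate_model(model, cals)
            inside += report.n_inside
            total += report.n_checked
        assert total == 200
        assert 0.58 <= inside / total <= 0.78

    def test_inside_implies_zero_distance_invariant(self, world):
        from dendroiso import calibrate_any, fit_age_model
        tid = "DFL"
        model = fit_age_model(world.tie_points[tid])
        cals = [calibrate_any(d, world.curve, world.curve.bomb_segment)
                for d in world.dates[tid]]
        rep = validate_model(model, cals)
        for r in rep.records:
            if r["inside_1sigma"]:
                assert r["distance_to_nearest_interval"] == 0.0


class TestDetectInversions:
    def test_overlapping_intervals_in_order_not_flagged(self):
        dates = [_interval_date("X", 10, 1800, 1850),
                 _interval_date("X", 50, 1780, 1820)]
        assert detect_inversions(dates) == []

    def test_disjoint_reversed_intervals_flagged(self):
        dates = [_interval_date("X", 10, 1500, 1550),   # shallow but old
                 _interval_date("X", 50, 1800, 1850)]   # deep but young
        flagged = detect_inversions(dates)
        assert len(flagged) == 1
        assert flagged[0][0].sample_number == 10
        assert flagged[0][1].sample_number == 50

    def test_injected_label_swap_is_flagged(self):
        """A mislabeled pair injected by the date simulator shows up as a
        stratigraphic inversion, and clean runs stay clean."""
        from dendroiso import calibrate
        from dendroiso.synthetic import (generate_rainfall, rainfall_to_d13c,
                                         synth_calibration_curve)
        curve = synth_calibration_curve(span=(1200, 1940), wiggle_amp_14cyr=5,
                                        seed=11)
        rain = generate_rainfall(span=(1200, 1940), seed=11)
        signal = rainfall_to_d13c(rain, seed=11)
        series, ages = simulate_tree(signal, growth_rate=0.7, seed=11)
        clean = [calibrate(d, curve) for d in simulate_radiocarbon_dates(
            ages, curve, n_dates=8, lab_sigma=15, seed=11)]
        assert detect_inversions(clean) == []
        swapped = [calibrate(d, curve) for d in simulate_radiocarbon_dates(
            ages, curve, n_dates=8, lab_sigma=15, outlier_rate=1.0, seed=11)]
        flagged = detect_inversions(swapped)
        assert len(flagged) >= 1
        flagged_samples = {d.sample_number for pair in flagged for d in pair}
        # the simulator swaps the 2nd and 2nd-to-last dated samples
        dated_numbers = sorted({d.sample_number for d in swapped})
        assert dated_numbers[1] in flagged_samples
        assert dated_numbers[-2] in flagged_samples


def test_jittered_tie_points_keep_age_error_within_jitter(world):
    """Anchors perturbed by ±5 years bound the assigned-age error by 5
    years on linear-growth trees (linear interpolation between knots)."""
    rng = np.random.default_rng(0)
    tid = "DFS"
    truth = world.true_ages[tid]
    pts = [TiePoint(p.tree_id, p.sample_number,
                    p.year_ce + rng.uniform(-5, 5))
           for p in world.tie_points[tid]]
    # keep the jittered chronology stratigraphically valid
    model = fit_age_model(pts)
    dated = assign_ages(model, world.trees[tid])
    err = np.abs(np.sort(dated.years) - np.sort(truth))
    assert err.mean() <= 5.0
    assert err.max() <= 5.0 + 1e-9
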