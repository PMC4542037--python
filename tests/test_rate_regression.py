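"""Excess computation, slope regression and accumulation detection."""

import numpy as np
import pytest

from n2part import (
    InsufficientDataError,
    InvalidInputError,
    LabelFractions,
    SimulationScenario,
    SlopeFit,
    VialSeries,
    compute_excess,
    detect_accumulation,
    fit_production_rate,
    pairing_forward,
    simulate_vial,
)


def make_series(time_h, excess29, excess30=None, replicate=None, **kw):
    time_h = np.asarray(time_h, float)
    excess29 = np.asarray(excess29, float)
    if excess30 is None:
        excess30 = np.zeros_like(excess29)
    if replicate is None:
        replicate = np.ones(time_h.size, int)
    defaults = dict(sample_id="S", zone="rhizosphere",
                    fertilization="control", treatment="nit15")
    defaults.update(kw)
    return VialSeries(time_h=time_h, replicate=replicate,
                      excess29=excess29, excess30=np.asarray(excess30, float),
                      **defaults)


class TestComputeExcess:
    def test_t0_mean_baseline_shift(self):
        s = make_series([0, 3, 6], [5, 8, 11])
        out = compute_excess(s)
        assert out.excess29 == pytest.approx([0, 3, 6])

    def test_constant_series_becomes_zero(self):
        s = make_series([0, 3, 6, 12], [7, 7, 7, 7])
        assert compute_excess(s).excess29 == pytest.approx([0, 0, 0, 0])

    def test_mean_of_multiple_t0_replicates(self):
        s = make_series([0, 0, 6], [4, 6, 10], replicate=[1, 2, 1])
        assert compute_excess(s).excess29 == pytest.approx([-1, 1, 5])

    def test_missing_t0_raises(self):
        s = make_series([3, 6, 12], [1, 2, 3])
        with pytest.raises(InsufficientDataError):
            compute_excess(s)

    def test_natural_abundance_policy_is_identity(self):
        s = make_series([3, 6, 12], [1, 2, 3])
        assert compute_excess(s, "natural_abundance").excess29 == pytest.approx(
            [1, 2, 3]
        )

    def test_slope_invariant_to_baseline_shift(self):
        t = [0, 0, 3, 3, 6, 6, 12, 12, 24, 24]
        rng = np.random.default_rng(0)
        y = 0.4 * np.asarray(t, float) + rng.normal(0, 0.3, 10)
        s_shifted = compute_excess(make_series(t, y + 17.3))
        s_plain = make_series(t, y - np.mean(y[:2]))
        f1 = fit_production_rate(s_shifted)
        f2 = fit_production_rate(s_plain)
        assert f1.slope == pytest.approx(f2.slope, rel=1e-12)


class TestFitProductionRate:
    def test_perfect_line(self):
        s = make_series([0, 3, 6, 12, 24], [0, 3, 6, 12, 24])
        fit = fit_production_rate(s)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_series_not_significant(self):
        s = make_series([0, 3, 6, 12, 24], [0, 0, 0, 0, 0])
        fit = fit_production_rate(s)
        assert fit.slope == 0.0
        assert not detect_accumulation(fit)

    def test_doubling_values_doubles_slope(self):
        t = [0, 3, 6, 12, 24]
        y = [0.1, 1.4, 3.2, 5.9, 12.4]
        f1 = fit_production_rate(make_series(t, y))
        f2 = fit_production_rate(make_series(t, np.asarray(y) * 2))
        assert f2.slope == pytest.approx(2 * f1.slope, rel=1e-12)

    def test_noisy_slope_within_three_se_of_truth(self, rng):
        times = np.repeat([0.0, 3, 6, 12, 24], 3)
        y = 0.5 * times + rng.normal(0, 0.1, times.size)
        fit = fit_production_rate(
            make_series(times, y, replicate=np.tile([1, 2, 3], 5))
        )
        assert abs(fit.slope - 0.5) < 3 * fit.se_slope

    def test_slope_estimates_unbiased_on_forward_model(self):
        # mean slope over many simulated vials matches the generating flux
        scen = SimulationScenario(seed=7)
        flux = pairing_forward(0.33, 0.74,
                               LabelFractions(scen.f_no3_stock, 0.0))
        rng = scen.rng()
        slopes = []
        for _ in range(200):
            v = simulate_vial(scen, ("rhizosphere", "control"), "nit15", rng=rng)
            slopes.append(fit_production_rate(v, 29).slope)
        mc_se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert np.mean(slopes) == pytest.approx(flux.p29, abs=3 * mc_se)

    def test_time_window_restricts_points(self):
        t = [0, 3, 6, 12, 24]
        y = [0, 3, 6, 12, 100]  # nonlinear tail
        full = fit_production_rate(make_series(t, y))
        windowed = fit_production_rate(make_series(t, y), time_window=(0, 12))
        assert windowed.slope == pytest.approx(1.0)
        assert full.slope > windowed.slope
        assert windowed.n_points == 4

    def test_nan_dropped_pairwise(self):
        t = [0, 3, 6, 12, 24]
        y = [0, 3, np.nan, 12, 24]
        fit = fit_production_rate(make_series(t, y))
        assert fit.n_points == 4
        assert fit.slope == pytest.approx(1.0)

    def test_too_few_time_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_production_rate(make_series([0, 3], [0, 1]))

    def test_bad_isotopologue_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_production_rate(make_series([0, 3, 6], [0, 1, 2]), 28)


class TestDetectAccumulation:
    def test_clear_accumulation(self):
        fit = SlopeFit(1.0, 0.0, 0.01, 0.99, 1e-6, 2e-6, 15)
        assert detect_accumulation(fit, 0.05)

    def test_flat_not_detected(self):
        fit = SlopeFit(0.0, 0.0, 0.01, 0.0, 0.5, 1.0, 15)
        assert not detect_accumulation(fit, 0.05)

    @pytest.mark.parametrize("p,expected", [(0.049, True), (0.051, False)])
    def test_threshold_boundary(self, p, expected):
        fit = SlopeFit(0.2, 0.0, 0.1, 0.3, p, 2 * p, 15)
        assert detect_accumulation(fit, 0.05) is expected


class TestVialSeriesValidation:
    def test_unknown_treatment_rejected(self):
        with pytest.raises(InvalidInputError):
            make_series([0, 3], [0, 1], treatment="no3_15")

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            VialSeries(
                sample_id="S", zone="rhizosphere", fertilization="control",
                treatment="nit15", time_h=[0, 3, 6], replicate=[1, 1],
                excess29=[0, 1, 2], excess30=[0, 0, 0],
            )

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            make_series([-1, 3, 6], [0, 1, 2])
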