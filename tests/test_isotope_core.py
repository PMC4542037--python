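"""Pairing model, IPT inversion, contribution and spike arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from n2part import (
    InvalidInputError,
    LabelFractions,
    ProductionRates,
    UndefinedContributionError,
    contribution,
    display_percent,
    ipt_invert,
    pairing_forward,
    spike_concentration,
)

rates_st = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)
frac_st = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
fn_pos_st = st.floats(min_value=1e-3, max_value=1.0, allow_nan=False)


class TestPairingForward:
    def test_zero_rates_give_zero_fluxes(self):
        flux = pairing_forward(0.0, 0.0, LabelFractions(0.5, 0.5))
        assert flux.p28 == flux.p29 == flux.p30 == 0.0

    def test_fully_labeled_nitrate_unlabeled_ammonium(self):
        # anammox pairs one labeled + one unlabeled atom -> all mass 29
        flux = pairing_forward(1.0, 0.0, LabelFractions(f_no3=1.0, f_nh4=0.0))
        assert flux.p29 == pytest.approx(1.0)
        assert flux.p28 == 0.0 and flux.p30 == 0.0

    def test_closed_form_values(self):
        flux = pairing_forward(0.5, 4.0, LabelFractions(f_no3=0.9815, f_nh4=0.0))
        assert flux.p30 == pytest.approx(3.85337, abs=5e-6)
        assert flux.p29 == pytest.approx(0.63601, abs=5e-6)

    @given(a=rates_st, d=rates_st, fn=frac_st, fa=frac_st)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_conservation_per_pathway(self, a, d, fn, fa):
        flux = pairing_forward(a, d, LabelFractions(fn, fa))
        assert flux.anammox_total == pytest.approx(a, rel=1e-12, abs=1e-12)
        assert flux.denit_total == pytest.approx(d, rel=1e-12, abs=1e-12)
        assert min(
            flux.anammox_p28, flux.anammox_p29, flux.anammox_p30,
            flux.denit_p28, flux.denit_p29, flux.denit_p30,
        ) >= 0.0

    @pytest.mark.parametrize("a,d", [(-1.0, 0.0), (0.0, -0.1)])
    def test_negative_rate_rejected(self, a, d):
        with pytest.raises(InvalidInputError):
            pairing_forward(a, d, LabelFractions(0.5))

    @pytest.mark.parametrize("fn,fa", [(-0.1, 0.0), (1.1, 0.0), (0.5, 2.0)])
    def test_fraction_outside_unit_interval_rejected(self, fn, fa):
        with pytest.raises(InvalidInputError):
            LabelFractions(fn, fa)


class TestIptInvert:
    def test_full_labeling_is_identity(self):
        proc = ipt_invert(ProductionRates(p29=0.7, p30=2.5),
                          LabelFractions(f_no3=1.0))
        assert proc.anammox == pytest.approx(0.7)
        assert proc.denitrification == pytest.approx(2.5)

    def test_roundtrip_of_forward_example(self):
        proc = ipt_invert(ProductionRates(p29=0.63601, p30=3.85337),
                          LabelFractions(f_no3=0.9815))
        assert proc.anammox == pytest.approx(0.5, abs=1e-4)
        assert proc.denitrification == pytest.approx(4.0, abs=1e-4)

    @pytest.mark.parametrize("fn", [0.1, 0.5, 0.9815])
    def test_pure_denitrification_gives_zero_anammox(self, fn):
        p30 = 1.7
        p29 = 2.0 * p30 * (1.0 - fn) / fn
        proc = ipt_invert(ProductionRates(p29=p29, p30=p30), LabelFractions(fn))
        assert proc.anammox == pytest.approx(0.0, abs=1e-12)

    @given(a=rates_st, d=rates_st, fn=fn_pos_st)
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_exact_roundtrip(self, a, d, fn):
        labels = LabelFractions(f_no3=fn, f_nh4=0.0)
        flux = pairing_forward(a, d, labels)
        proc = ipt_invert(ProductionRates(p29=flux.p29, p30=flux.p30), labels)
        assert proc.anammox == pytest.approx(a, rel=1e-10, abs=1e-10)
        assert proc.denitrification == pytest.approx(d, rel=1e-10, abs=1e-10)

    def test_limit_f_no3_to_one(self):
        # as f_no3 -> 1 the inversion tends to A = p29, D = p30
        p29, p30 = 0.4, 1.2
        # A converges linearly in (1 - f_no3): error ~ (1-f)(p29 + 2 p30)
        for fn, tol in [(0.99, 0.08), (0.9999, 8e-4)]:
            proc = ipt_invert(ProductionRates(p29=p29, p30=p30),
                              LabelFractions(fn), clamp=False)
            assert proc.anammox == pytest.approx(p29, rel=tol)
            assert proc.denitrification == pytest.approx(p30, rel=tol)

    def test_anammox_strictly_increasing_in_p29(self):
        fn = 0.9815
        p30 = 1.0
        a_vals = [
            ipt_invert(ProductionRates(p29=p, p30=p30), LabelFractions(fn)).anammox
            for p in np.linspace(0.2, 2.0, 10)
        ]
        assert all(x < y for x, y in zip(a_vals, a_vals[1:]))

    def test_negative_solution_clamped_and_flagged(self):
        # p29 far below the pure-denitrification line forces raw A < 0
        proc = ipt_invert(ProductionRates(p29=0.0, p30=1.0),
                          LabelFractions(0.9815))
        assert proc.anammox == 0.0
        assert proc.clamped
        assert proc.raw_anammox < 0
        assert 0 <= proc.ra <= 100

    def test_f_no3_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            ipt_invert(ProductionRates(p29=1.0, p30=1.0), LabelFractions(0.0))

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            ProductionRates(p29=math.nan, p30=1.0)


class TestContribution:
    @pytest.mark.parametrize(
        "a,d,expected,displayed",
        [
            (0.33, 0.74, 30.84, 31),   # control rhizosphere
            (0.64, 0.92, 41.03, 41),   # fertilized rhizosphere
            (0.08, 3.66, 2.14, 2),     # control bulk soil
            (0.26, 9.42, 2.69, 3),     # fertilized bulk soil
        ],
    )
    def test_reported_shares(self, a, d, expected, displayed):
        ra = contribution(a, d)
        assert ra == pytest.approx(expected, abs=0.005)
        assert display_percent(ra) == displayed

    def test_no_denitrification_gives_100_percent(self):
        assert contribution(0.01, 0.0) == 100.0

    @given(a=rates_st, d=rates_st, c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_scale_invariance(self, a, d, c):
        if a + d == 0:
            return
        assert contribution(c * a, c * d) == pytest.approx(
            contribution(a, d), rel=1e-9
        )

    def test_both_zero_is_undefined_not_zero(self):
        with pytest.raises(UndefinedContributionError):
            contribution(0.0, 0.0)

    def test_display_rounds_half_away_from_zero(self):
        assert display_percent(30.5) == 31
        assert display_percent(2.49) == 2


class TestSpikeConcentration:
    def test_study_dose(self):
        assert spike_concentration(12.0, 100.0, 12.0) == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "stock,ul,ml,expected", [(12.0, 0.0, 12.0, 0.0), (1.0, 12.0, 12.0, 1.0)]
    )
    def test_unit_scaling(self, stock, ul, ml, expected):
        assert spike_concentration(stock, ul, ml) == pytest.approx(expected)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(InvalidInputError):
            spike_concentration(12.0, 100.0, 0.0)
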