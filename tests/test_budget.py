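"""SST regimes, annual influxes, NCP closure, demand and recycling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnpbudget.budget import (
    REGIMES,
    AtmosphericForcing,
    StoichiometryRange,
    annual_atmospheric_influx,
    annual_upward_influx,
    classify_sst_regime,
    microbial_demand,
    ncp_requirement,
    recycling_factor,
    regime_days,
    stoichiometric_ratio,
)
from cnpbudget.synthetic import ScenarioConfig, generate_forcing
from cnpbudget.uncertainty import UncertainValue, round_sig


def make_clim(monthly_sst):
    return regime_days(monthly_sst)


def sst_series(counts):
    """A 12-month series with the given regime month counts."""
    vals = {"SST<24": 21.0, "24-26": 25.0, "26-28": 27.0, "SST>28": 29.0}
    out = []
    for regime, n in zip(REGIMES, counts):
        out += [vals[regime]] * n
    assert len(out) == 12
    return out


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "sst,regime",
        [
            (23.9, "SST<24"),
            (24.0, "24-26"),  # lower edge inclusive
            (25.99, "24-26"),
            (26.0, "26-28"),
            (28.0, "SST>28"),
            (30.51, "SST>28"),  # warmest observed month
            (20.21, "SST<24"),  # coolest observed month
        ],
    )
    def test_bin_assignment(self, sst, regime):
        assert classify_sst_regime(sst) == regime

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_sst_regime(float("nan"))


class TestRegimeDays:
    def test_all_warm_year(self):
        clim = make_clim([29.0] * 12)
        assert clim.days["SST>28"] == pytest.approx(365.0)
        assert sum(clim.months.values()) == 12

    def test_four_three_two_three_split(self):
        clim = make_clim(sst_series([4, 3, 2, 3]))
        assert clim.days["SST<24"] == pytest.approx(121.6667, abs=1e-3)
        assert clim.days["24-26"] == pytest.approx(91.25)
        assert clim.days["26-28"] == pytest.approx(60.8333, abs=1e-3)
        assert clim.days["SST>28"] == pytest.approx(91.25)

    @given(st.lists(st.floats(15, 33), min_size=12, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_days_always_sum_to_365(self, series):
        clim = make_clim(series)
        assert sum(clim.days.values()) == pytest.approx(365.0, abs=1e-9)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            make_clim([25.0] * 11)


class TestAnnualUpwardInflux:
    def test_single_regime_whole_year(self):
        clim = make_clim([29.0] * 12)
        fup = annual_upward_influx({"SST>28": [1e-6, 1e-6]}, clim)
        assert fup.m == pytest.approx(3.65e-4)
        assert fup.e == pytest.approx(0.0, abs=1e-15)

    def test_zero_flux_everywhere(self):
        clim = make_clim(sst_series([3, 3, 3, 3]))
        fup = annual_upward_influx({r: [0.0, 0.0] for r in REGIMES}, clim)
        assert fup.m == 0.0

    def test_regime_without_data_contributes_zero_with_warning(self, caplog):
        clim = make_clim(sst_series([6, 0, 0, 6]))
        with caplog.at_level("WARNING"):
            fup = annual_upward_influx({"SST<24": [2e-6, 2e-6]}, clim)
        assert fup.m == pytest.approx(2e-6 * 182.5)
        assert any("no flux data" in r.message for r in caplog.records)

    def test_all_regimes_empty_rejected(self):
        clim = make_clim(sst_series([6, 0, 0, 6]))
        with pytest.raises(ValueError):
            annual_upward_influx({}, clim)


class TestAtmosphericInflux:
    FORCING = generate_forcing(ScenarioConfig())

    def test_phosphorus_deposition_times_365(self):
        clim = make_clim(sst_series([3, 3, 3, 3]))
        fat = annual_atmospheric_influx("P", self.FORCING, clim)
        assert fat.m == pytest.approx(8.4e-8 * 365, rel=1e-12)  # 3.066e-5

    def test_nitrogen_fixation_plus_deposition_times_365(self):
        clim = make_clim(sst_series([3, 3, 3, 3]))
        fat = annual_atmospheric_influx("N", self.FORCING, clim)
        assert fat.m == pytest.approx((2.2e-4 + 2.7e-5) * 365, rel=1e-12)  # 9.02e-2

    def test_carbon_sums_monthly_flux_by_regime_months(self):
        clim = make_clim(sst_series([4, 3, 2, 3]))
        fat = annual_atmospheric_influx("C", self.FORCING, clim)
        co2 = {r: m for r, m, _ in ScenarioConfig().co2_flux_monthly}
        expected = 4 * co2["SST<24"] + 3 * co2["24-26"] + 2 * co2["26-28"] + 3 * co2["SST>28"]
        assert fat.m == pytest.approx(expected, rel=1e-12)

    def test_zero_forcing_gives_zero(self):
        forcing = AtmosphericForcing(
            co2_flux_monthly={r: UncertainValue(0, 0) for r in REGIMES},
            n2_fixation_rate=UncertainValue(0, 0),
            n_deposition_rate=UncertainValue(0, 0),
            p_deposition_rate=UncertainValue(0, 0),
        )
        clim = make_clim(sst_series([3, 3, 3, 3]))
        for el in "CNP":
            assert annual_atmospheric_influx(el, forcing, clim).m == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            AtmosphericForcing(
                co2_flux_monthly={r: UncertainValue(0, 0) for r in REGIMES},
                n2_fixation_rate=UncertainValue(-1e-5, 0),
                n_deposition_rate=UncertainValue(0, 0),
                p_deposition_rate=UncertainValue(0, 0),
            )


class TestNCPAndRatios:
    def test_reconstructs_reported_phosphorus_requirement(self):
        # upward 2.89e-4 plus deposition 8.4e-8 * 365 -> 3.2e-4 at 2 s.f.
        ncp = ncp_requirement(UncertainValue(2.89e-4, 0), UncertainValue(8.4e-8 * 365, 0))
        assert round_sig(ncp.m, 2) == pytest.approx(3.2e-4)

    def test_identity_with_zero_term(self):
        a = UncertainValue(0.4, 0.0)
        ncp = ncp_requirement(a, UncertainValue(0, 0))
        assert (ncp.m, ncp.e) == (0.4, 0.0)

    def test_closure_is_exact_for_any_inputs(self):
        fup, fat = UncertainValue(3, 4), UncertainValue(4, 3)
        ncp = ncp_requirement(fup, fat)
        assert ncp.m - fup.m - fat.m == 0.0
        assert ncp.e == 5.0

    def test_ratio_simple(self):
        c, n, p = (UncertainValue(v, 0) for v in (2.0, 2.0, 1.0))
        rc, rn, rp = stoichiometric_ratio(c, n, p)
        assert (rc.m, rn.m, rp) == (2.0, 2.0, 1.0)

    def test_ratio_of_reported_rounded_ncp_values(self):
        c, n, p = (UncertainValue(v, 0) for v in (7.5e-1, 9.5e-2, 3.2e-4))
        rc, rn, _ = stoichiometric_ratio(c, n, p)
        assert rc.m == pytest.approx(2344, rel=5e-3)
        assert rn.m == pytest.approx(297, rel=5e-3)

    def test_ratio_scale_invariant(self):
        vals = (7.5e-1, 9.5e-2, 3.2e-4)
        base = stoichiometric_ratio(*(UncertainValue(v, 0) for v in vals))
        scaled = stoichiometric_ratio(*(UncertainValue(13.7 * v, 0) for v in vals))
        assert scaled[0].m == pytest.approx(base[0].m, rel=1e-12)
        assert scaled[1].m == pytest.approx(base[1].m, rel=1e-12)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            stoichiometric_ratio(
                UncertainValue(1, 0), UncertainValue(1, 0), UncertainValue(0, 0)
            )


class TestDemandAndRecycling:
    NCP_C = UncertainValue(7.5e-1, 1.5e-1)

    def test_nitrogen_demand_from_cn_range(self):
        md_n, _ = microbial_demand(self.NCP_C, StoichiometryRange())
        assert round_sig(md_n[0], 2) == pytest.approx(6.8e-2)
        assert round_sig(md_n[1], 2) == pytest.approx(1.2e-1)

    def test_phosphorus_demand_from_cp_range(self):
        _, md_p = microbial_demand(self.NCP_C, StoichiometryRange())
        assert round_sig(md_p[0], 2) == pytest.approx(3.1e-3)
        assert round_sig(md_p[1], 2) == pytest.approx(7.0e-3)

    def test_degenerate_range_gives_point_interval(self):
        md_n, _ = microbial_demand(self.NCP_C, StoichiometryRange(cn=(10, 10)))
        assert md_n[0] == md_n[1] == pytest.approx(0.075)

    def test_recycling_factor_from_reported_bounds(self):
        rf = recycling_factor((3.1e-3, 7.0e-3), UncertainValue(3.2e-4, 0))
        assert round_sig(rf[0], 2) == pytest.approx(9.7)
        assert round_sig(rf[1], 2) == pytest.approx(22.0)

    def test_nitrogen_recycling_near_unity(self):
        rf = recycling_factor((6.8e-2, 1.2e-1), UncertainValue(9.5e-2, 0))
        assert round_sig(rf[0], 2) == pytest.approx(0.72)
        assert round_sig(rf[1], 2) == pytest.approx(1.3)

    def test_demand_equal_to_ncp_gives_unit_factor(self):
        assert recycling_factor((0.3, 0.3), UncertainValue(0.3, 0)) == (1.0, 1.0)

    @given(ncp_c=st.floats(0.1, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_demand_and_rf_monotone_in_ncp_c(self, ncp_c):
        stoich = StoichiometryRange()
        md_n, md_p = microbial_demand(UncertainValue(ncp_c, 0), stoich)
        md_n2, md_p2 = microbial_demand(UncertainValue(ncp_c * 1.5, 0), stoich)
        assert md_n2[0] > md_n[0] and md_n2[1] > md_n[1]
        assert md_p2[0] > md_p[0] and md_p2[1] > md_p[1]
        rf = recycling_factor(md_p, UncertainValue(3.2e-4, 0))
        assert rf[0] <= rf[1]

    def test_nonpositive_ncp_rejected(self):
        with pytest.raises(ValueError):
            microbial_demand(UncertainValue(0, 0), StoichiometryRange())
        with pytest.raises(ValueError):
            recycling_factor((1e-3, 2e-3), UncertainValue(0, 0))
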