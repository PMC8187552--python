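"""MLD/EZD criteria, density and N^2, normalisation, inventories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnpbudget.hydrography import (
    Cast,
    NormalizationConfig,
    compute_ezd,
    compute_mld,
    density_sigma0,
    depth_integrate,
    n_sq_from_density,
    normalize_to_reference_salinity,
    regime_inventory_difference,
    substitute_below_detection,
)


def make_cast(depth, temp=None, sal=None, par=None, conc=None, sst=25.0):
    depth = np.asarray(depth, dtype=float)
    return Cast(
        station="T", date="2017-01-01", sst=sst, depth=depth,
        temperature=np.asarray(temp, dtype=float) if temp is not None else np.full(depth.size, 20.0),
        salinity=np.asarray(sal, dtype=float) if sal is not None else np.full(depth.size, 34.91),
        par=np.asarray(par, dtype=float) if par is not None else None,
        concentrations=conc or {},
    )


class TestMLD:
    def test_isothermal_profile_never_reaches_criterion(self):
        cast = make_cast([0, 10, 50, 100, 200], temp=[25] * 5)
        mld, flag = compute_mld(cast)
        assert mld == 200.0 and flag

    def test_linear_thermocline_interpolates_to_hand_value(self):
        # theta(10)=28, linear 28 -> 26 over 30 -> 50 m: 27.8 degC at 32 m
        cast = make_cast([0, 10, 30, 50], temp=[28, 28, 28, 26])
        mld, flag = compute_mld(cast)
        assert not flag and mld == pytest.approx(32.0, abs=1e-9)

    def test_exact_threshold_at_sampled_depth(self):
        cast = make_cast([0, 10, 40, 80], temp=[28, 28, 27.8, 26])
        mld, flag = compute_mld(cast)
        assert not flag and mld == 40.0

    def test_no_data_below_10m_rejected(self):
        with pytest.raises(ValueError):
            compute_mld(make_cast([0, 5], temp=[28, 28]))

    def test_invariant_to_redundant_interpolated_levels(self):
        z = np.array([0.0, 10, 30, 50, 100])
        t = np.array([28.0, 28, 28, 26, 24])
        base, _ = compute_mld(make_cast(z, temp=t))
        z2 = np.sort(np.concatenate([z, [20.0, 40.0, 75.0]]))
        t2 = np.interp(z2, z, t)
        dense, _ = compute_mld(make_cast(z2, temp=t2))
        assert dense == pytest.approx(base, abs=1e-9)


class TestEZD:
    def test_exponential_decay_recovers_analytic_depth(self):
        z = [0, 10, 25, 50, 75, 100, 125, 150, 200]
        par = 1500.0 * np.exp(-0.046 * np.asarray(z, dtype=float))
        ezd, flag = compute_ezd(make_cast(z, par=par))
        assert not flag
        assert ezd == pytest.approx(math.log(100) / 0.046, rel=1e-6)  # 100.1 m

    def test_constant_par_never_reaches_one_percent(self):
        cast = make_cast([0, 50, 100, 200], par=[500.0] * 4)
        ezd, flag = compute_ezd(cast)
        assert flag and ezd == 200.0

    def test_exact_one_percent_at_sample(self):
        cast = make_cast([0, 50, 100], par=[1000.0, 100.0, 10.0])
        ezd, flag = compute_ezd(cast)
        assert not flag and ezd == 100.0

    def test_nonpositive_surface_par_rejected(self):
        with pytest.raises(ValueError):
            compute_ezd(make_cast([0, 50], par=[0.0, 0.0]))

    def test_invariant_to_redundant_geometric_levels(self):
        z = np.array([0.0, 50, 100, 150, 200])
        par = 1000.0 * np.exp(-0.05 * z)
        base, _ = compute_ezd(make_cast(z, par=par))
        z2 = np.sort(np.concatenate([z, [25.0, 75.0, 125.0]]))
        par2 = 1000.0 * np.exp(-0.05 * z2)  # log-linear in z, so redundant
        dense, _ = compute_ezd(make_cast(z2, par=par2))
        assert dense == pytest.approx(base, rel=1e-12)


class TestDetectionSubstitution:
    CONFIG = NormalizationConfig()

    @pytest.mark.parametrize(
        "name,raw_nm,expected_nm",
        [("N+N", 1.0, 5.0), ("PO4", 2.0, 3.0), ("N+N", 10.0, 10.0), ("PO4", 3.0, 3.0)],
    )
    def test_substitution_rule(self, name, raw_nm, expected_nm):
        cast = make_cast([0, 100], conc={name: np.array([raw_nm, 500.0]) * 1e-6})
        out = substitute_below_detection(cast, self.CONFIG)
        assert out.concentrations[name][0] == pytest.approx(expected_nm * 1e-6)
        assert out.concentrations[name][1] == pytest.approx(500e-6)

    def test_idempotent(self):
        cast = make_cast(
            [0, 100], conc={"N+N": np.array([1e-6, 2e-6]), "PO4": np.array([1e-6, 9e-5])}
        )
        once = substitute_below_detection(cast, self.CONFIG)
        twice = substitute_below_detection(once, self.CONFIG)
        for k in ("N+N", "PO4"):
            np.testing.assert_array_equal(once.concentrations[k], twice.concentrations[k])

    def test_other_constituents_untouched(self):
        cast = make_cast([0, 100], conc={"DIC": np.array([1e-9, 2.0])})
        out = substitute_below_detection(cast, self.CONFIG)
        np.testing.assert_array_equal(out.concentrations["DIC"], cast.concentrations["DIC"])


class TestSalinityNormalization:
    def test_identity_at_reference_salinity(self):
        assert normalize_to_reference_salinity(2.0, 34.91) == pytest.approx(2.0)

    def test_halved_salinity_doubles_concentration(self):
        assert normalize_to_reference_salinity(1.3, 17.455) == pytest.approx(2.6)

    def test_hand_arithmetic_example(self):
        assert normalize_to_reference_salinity(2.02, 35.26) == pytest.approx(2.0000, abs=1e-3)

    @given(x=st.floats(0, 10), s=st.floats(30, 38), k=st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_concentration(self, x, s, k):
        one = normalize_to_reference_salinity(x, s)
        scaled = normalize_to_reference_salinity(k * x, s)
        assert scaled == pytest.approx(k * one, rel=1e-12, abs=1e-12)

    def test_nonpositive_salinity_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference_salinity(1.0, 0.0)


class TestDensityAndN2:
    def test_uniform_water_column_is_neutrally_stable(self):
        cast = make_cast([0, 50, 100, 200], temp=[20] * 4, sal=[35] * 4)
        _, n_sq = __import__("cnpbudget").buoyancy_frequency_sq(cast)
        np.testing.assert_allclose(n_sq, 0.0, atol=1e-12)

    def test_warm_over_cold_is_stable(self):
        cast = make_cast([0, 50, 100, 200], temp=[28, 25, 20, 16], sal=[34.91] * 4)
        _, n_sq = __import__("cnpbudget").buoyancy_frequency_sq(cast)
        assert np.all(n_sq > 0)

    def test_two_level_density_finite_difference(self):
        # rho 1024.0 at 50 m, 1025.0 at 150 m: N^2 = 9.81/1025 * 0.01
        n_sq = n_sq_from_density([50.0, 150.0], [1024.0, 1025.0])
        np.testing.assert_allclose(n_sq, 9.81 / 1025.0 * 0.01, rtol=1e-12)

    def test_eos_density_is_physically_reasonable(self):
        # standard seawater near 25 degC, 35 psu: sigma-t about 23.3 kg m-3
        rho = density_sigma0(25.0, 35.0)
        assert 1022.0 < rho < 1025.0
        assert density_sigma0(5.0, 35.0) > rho  # colder is denser


class TestDepthIntegrate:
    def test_constant_profile(self):
        assert depth_integrate([0, 50, 100], [0.1] * 3, 0, 100) == pytest.approx(10.0)

    def test_linear_ramp(self):
        assert depth_integrate([0, 100], [0.0, 0.2], 0, 100) == pytest.approx(10.0)

    def test_matches_fine_grid_quadrature_oracle(self):
        rng = np.random.default_rng(3)
        z = np.array([0.0, 10, 25, 50, 75, 100, 125, 150, 200])
        v = rng.uniform(0, 2, z.size)
        got = depth_integrate(z, v, 0, 200)
        fine = np.linspace(0, 200, 400001)
        oracle = np.trapezoid(np.interp(fine, z, v), fine)
        assert got == pytest.approx(oracle, rel=1e-9)

    def test_additive_over_contiguous_layers(self):
        rng = np.random.default_rng(4)
        z = np.array([0.0, 10, 25, 50, 75, 100, 125, 150, 200])
        v = rng.uniform(0, 2, z.size)
        whole = depth_integrate(z, v, 0, 200)
        parts = depth_integrate(z, v, 0, 100) + depth_integrate(z, v, 100, 200)
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_endpoints_interpolated_between_samples(self):
        # linear 0 -> 0.2 over 0-100: integral over [25, 75] = 0.1 * 50
        assert depth_integrate([0, 100], [0.0, 0.2], 25, 75) == pytest.approx(5.0)

    def test_nearest_sample_extension_outside_range(self):
        # samples start at 10 m: [0, 10] uses the 10-m value as constant
        got = depth_integrate([10, 100], [0.1, 0.1], 0, 100)
        assert got == pytest.approx(10.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            depth_integrate([], [], 0, 100)


class TestRegimeInventoryDifference:
    def test_identical_regimes_give_zero_mean(self):
        inv = [10.0, 10.0, 10.0, 10.0]
        sst = [21.0, 22.0, 29.0, 30.0]
        d = regime_inventory_difference(inv, sst, "SST<24", "SST>28")
        assert d.m == pytest.approx(0.0) and d.e == pytest.approx(0.0)

    def test_hand_arithmetic_difference(self):
        inv = [10.0, 12.0, 8.0, 8.0]
        sst = [21.0, 22.0, 29.0, 30.0]
        d = regime_inventory_difference(inv, sst, "SST<24", "SST>28")
        assert d.m == pytest.approx(3.0)
        # cool CI = t(0.975,1)*sd/sqrt(2) with sd=sqrt(2); warm CI = 0
        assert d.e == pytest.approx(12.7062 * 1.0, rel=1e-3)

    def test_single_cast_regime_rejected(self):
        with pytest.raises(ValueError):
            regime_inventory_difference([1.0, 2.0], [21.0, 30.0], "SST<24", "SST>28")
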