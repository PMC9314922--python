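import numpy as np
import pytest

from isoscape.sections import (
    SectionSeries,
    attribution_pct,
    aw_mask,
    decadal_trend,
    integrate_npp,
    masked_mean,
    nitrate_flux,
    regional_upper_mean,
    transport,
    transport_decomposition,
    trend_map,
)
from isoscape.synthetic import AWCore, SectionSpec, gen_region_fields, gen_section_series


def _uniform_section(n_years=12, n_depth=4, n_lat=5, u=0.1, no3=8.0,
                     cell_area=5.0e4):
    shape = (n_years, n_depth, n_lat)
    return SectionSeries(
        years=np.arange(n_years, dtype=float),
        u=np.full(shape, u),
        theta=np.full(shape, 4.0),
        salinity=np.full(shape, 35.0),
        no3=np.full(shape, no3),
        d15n_no3=np.full(shape, 5.0),
        cell_area=np.full((n_depth, n_lat), cell_area),
    )


class TestAwMask:
    @pytest.mark.parametrize(
        "theta, sal, expected",
        [(3.0, 35.0, True), (1.0, 35.0, False), (3.0, 34.0, False),
         (2.0, 34.5, False), (2.0, 35.0, False), (3.0, 34.5, False)],
    )
    def test_definition_with_strict_boundaries(self, theta, sal, expected):
        assert aw_mask(np.array([theta]), np.array([sal]))[0] == expected

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aw_mask(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_idempotent_and_scale_commuting(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(-1, 6, (5, 6))
        sal = rng.uniform(33, 36, (5, 6))
        m = aw_mask(theta, sal)
        assert np.array_equal(m, aw_mask(theta, sal))
        field = rng.normal(size=(5, 6))
        assert np.allclose((3.0 * field)[m], 3.0 * field[m])


class TestTransport:
    def test_uniform_velocity_unit_case(self):
        # 0.1 m/s over 20 cells x 5e4 m2 = 1e6 m2 -> 0.1 Sv
        sec = _uniform_section()
        assert np.allclose(transport(sec), 0.1)

    def test_zero_velocity(self):
        sec = _uniform_section(u=0.0)
        assert np.allclose(transport(sec), 0.0)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(1)
        sec = _uniform_section()
        sec.u[:] = rng.normal(0.1, 0.05, sec.u.shape)
        sec.theta[:] = rng.uniform(0, 6, sec.theta.shape)
        got = transport(sec)
        mask = aw_mask(sec.theta, sec.salinity)
        for t in range(len(sec.years)):
            total = 0.0
            for i in range(sec.u.shape[1]):
                for j in range(sec.u.shape[2]):
                    if mask[t, i, j]:
                        total += sec.u[t, i, j] * sec.cell_area[i, j]
            assert got[t] == pytest.approx(total / 1e6, rel=1e-12)


class TestNitrateFlux:
    def test_uniform_concentration_factorises(self):
        sec = _uniform_section(no3=8.0)
        flux, _ = nitrate_flux(sec)
        # flux = c * T with c in mol m-3 and T in m3/s
        assert np.allclose(flux, 8.0e-3 * transport(sec) * 1e6)

    def test_zero_velocity_zero_flux(self):
        sec = _uniform_section(u=0.0)
        flux, cum = nitrate_flux(sec)
        assert np.allclose(flux, 0.0) and np.allclose(cum, 0.0)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(2)
        sec = _uniform_section()
        sec.u[:] = rng.normal(0.1, 0.05, sec.u.shape)
        sec.no3[:] = rng.uniform(2, 12, sec.no3.shape)
        flux, _ = nitrate_flux(sec)
        mask = aw_mask(sec.theta, sec.salinity)
        for t in range(len(sec.years)):
            total = sum(
                sec.no3[t, i, j] * 1e-3 * sec.u[t, i, j] * sec.cell_area[i, j]
                for i in range(sec.u.shape[1])
                for j in range(sec.u.shape[2])
                if mask[t, i, j]
            )
            assert flux[t] == pytest.approx(total, rel=1e-12)


class TestMaskedMean:
    def test_uniform_field(self):
        sec = _uniform_section()
        m = aw_mask(sec.theta, sec.salinity)
        assert np.allclose(masked_mean(sec.d15n_no3, m, sec.cell_area), 5.0)

    def test_two_equal_cells(self):
        field = np.array([[[4.0, 6.0]]])
        mask = np.array([[[True, True]]])
        area = np.array([[1.0, 1.0]])
        assert masked_mean(field, mask, area)[0] == pytest.approx(5.0)

    def test_empty_mask_gives_nan(self):
        field = np.ones((2, 2, 2))
        mask = np.zeros((2, 2, 2), dtype=bool)
        out = masked_mean(field, mask, np.ones((2, 2)))
        assert np.isnan(out).all()

    def test_area_weighting_matches_loop(self):
        rng = np.random.default_rng(3)
        field = rng.normal(5, 1, (3, 4, 5))
        mask = rng.random((3, 4, 5)) > 0.4
        area = rng.uniform(1, 3, (4, 5))
        got = masked_mean(field, mask, area)
        for t in range(3):
            num = den = 0.0
            for i in range(4):
                for j in range(5):
                    if mask[t, i, j]:
                        num += field[t, i, j] * area[i, j]
                        den += area[i, j]
            expected = num / den if den else np.nan
            if np.isnan(expected):
                assert np.isnan(got[t])
            else:
                assert got[t] == pytest.approx(expected, rel=1e-12)

    def test_flux_weighted_option(self):
        sec = _uniform_section()
        sec.d15n_no3[:, :, 0] = 7.0
        sec.u[:, :, 0] = 0.3  # faster cells dominate the transport-weighted mean
        m = aw_mask(sec.theta, sec.salinity)
        aw = masked_mean(sec.d15n_no3, m, sec.cell_area)
        fw = masked_mean(sec.d15n_no3, m, sec.cell_area, velocity=sec.u,
                         flux_weighted=True)
        assert fw[0] > aw[0]


class TestDecomposition:
    def test_pure_volume_change(self):
        """Constant uniform velocity, trending AW area: the velocity
        contribution is exactly zero."""
        spec = SectionSpec(n_years=20, aw_cells0=10,
                           aw_core=AWCore(u0=0.1, u_trend=0.0, area_trend=0.1))
        sec, truth = gen_section_series(spec)
        dec = transport_decomposition(sec)
        assert dec.trend_velocity == pytest.approx(0.0, abs=1e-12)
        assert dec.trend_volume == pytest.approx(dec.trend_total, abs=1e-12)

    def test_pure_velocity_change(self):
        spec = SectionSpec(n_years=20, aw_cells0=10,
                           aw_core=AWCore(u0=0.1, u_trend=0.002, area_trend=0.0))
        sec, truth = gen_section_series(spec)
        dec = transport_decomposition(sec)
        assert dec.trend_volume == pytest.approx(0.0, abs=1e-12)

    def test_mixed_case_recovers_generator_truth(self):
        spec = SectionSpec(n_years=50, aw_cells0=20,
                           aw_core=AWCore(u0=0.1, u_trend=0.001, area_trend=0.02))
        sec, truth = gen_section_series(spec)
        dec = transport_decomposition(sec)
        assert dec.trend_total == pytest.approx(truth["trend_total"], abs=1e-8)
        assert dec.trend_velocity == pytest.approx(truth["trend_velocity"], abs=1e-8)
        assert dec.trend_volume == pytest.approx(truth["trend_volume"], abs=1e-8)

    def test_identity_holds_for_random_fields(self):
        rng = np.random.default_rng(4)
        sec = _uniform_section(n_years=15)
        sec.u[:] = rng.normal(0.1, 0.02, sec.u.shape)
        dec = transport_decomposition(sec)
        assert dec.trend_velocity + dec.trend_volume == pytest.approx(
            dec.trend_total, abs=1e-14)

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            transport_decomposition(_uniform_section(n_years=5))


class TestDecadalTrend:
    def test_exact_line(self):
        years = np.arange(2000, 2020)
        res = decadal_trend(years, 3.0 + 0.07 * years)
        assert res.slope_per_decade == pytest.approx(0.7, abs=1e-12)

    def test_constant_series(self):
        res = decadal_trend(np.arange(10), np.full(10, 2.0))
        assert res.slope_per_decade == pytest.approx(0.0, abs=1e-12)

    def test_matches_polyfit_oracle(self):
        rng = np.random.default_rng(5)
        years = np.arange(1970, 2020)
        vals = rng.normal(0, 1, 50)
        res = decadal_trend(years, vals)
        assert res.slope_per_decade == pytest.approx(
            10 * np.polyfit(years, vals, 1)[0], abs=1e-12)

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError):
            decadal_trend([2000, 2000, 2000], [1, 2, 3])


class TestTrendMap:
    def test_prescribed_uniform_trend_exact(self):
        cubes, truth = gen_region_fields(4, 5, 12, 30,
                                         trend_map_per_decade=-0.05)
        trends, summary = trend_map(cubes["years"], cubes["d15n_pom"][:, 0])
        assert np.allclose(trends, -0.05, atol=1e-12)
        assert summary["min"] == pytest.approx(-0.05)
        assert summary["max"] == pytest.approx(-0.05)
        assert summary["mean"] == pytest.approx(-0.05)

    def test_constant_field_zero_trend(self):
        cubes, _ = gen_region_fields(3, 3, 2, 20)
        trends, _ = trend_map(cubes["years"], cubes["no3"][:, 0])
        assert np.allclose(trends, 0.0, atol=1e-12)

    def test_noisy_recovery_unbiased(self):
        """Across 200 noisy cells the mean trend error is ~0."""
        rng = np.random.default_rng(6)
        truth_map = rng.uniform(-0.1, 0.1, (10, 20))
        cubes, _ = gen_region_fields(20, 10, 1, 40,
                                     trend_map_per_decade=truth_map,
                                     noise_sd=0.2, seed=8)
        trends, _ = trend_map(cubes["years"], cubes["d15n_pom"][:, 0])
        err = trends - truth_map
        assert abs(err.mean()) < 3 * err.std(ddof=1) / np.sqrt(err.size)

    def test_missing_cells_flagged_and_excluded(self):
        cubes, _ = gen_region_fields(2, 2, 1, 10, trend_map_per_decade=0.1)
        cube = cubes["d15n_pom"][:, 0]
        cube[3, 0, 0] = np.nan
        trends, summary = trend_map(cubes["years"], cube)
        assert np.isnan(trends[0, 0])
        assert summary["n_cells"] == 3
        assert summary["mean"] == pytest.approx(0.1)


class TestRegionalMeans:
    def test_uniform_cube(self):
        cube = np.full((3, 12, 4, 5), 6.0)
        th = np.where(np.arange(12) < 10, 10.0, 50.0)
        mask = np.ones((4, 5), dtype=bool)
        mean, per_cell = regional_upper_mean(cube, th, mask)
        assert np.allclose(mean, 6.0)
        assert np.allclose(per_cell, 6.0)

    def test_deep_signal_excluded(self):
        cube = np.zeros((2, 12, 3, 3))
        cube[:, 10:] = 99.0  # below 100 m only
        th = np.where(np.arange(12) < 10, 10.0, 50.0)
        mean, _ = regional_upper_mean(cube, th, np.ones((3, 3), bool))
        assert np.allclose(mean, 0.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        cube = rng.normal(5, 1, (2, 12, 3, 4))
        th = np.where(np.arange(12) < 10, 10.0, 50.0)
        mask = rng.random((3, 4)) > 0.3
        area = rng.uniform(1, 2, (3, 4))
        mean, per_cell = regional_upper_mean(cube, th, mask, cell_area=area)
        for t in range(2):
            num = den = 0.0
            for i in range(3):
                for j in range(4):
                    col = sum(cube[t, k, i, j] * th[k] for k in range(10)) / th[:10].sum()
                    assert per_cell[t, i, j] == pytest.approx(col, rel=1e-12)
                    if mask[i, j]:
                        num += col * area[i, j]
                        den += area[i, j]
            assert mean[t] == pytest.approx(num / den, rel=1e-12)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            regional_upper_mean(np.ones((1, 12, 2, 2)), np.full(12, 10.0),
                                np.zeros((2, 2), bool))

    def test_31_level_grid_uses_first_10_levels(self):
        cube = np.zeros((1, 31, 2, 2))
        cube[:, :10] = 1.0
        cube[:, 10] = 50.0  # level 11 would contaminate a depth-based rule
        th = np.full(31, 5.0)  # bottoms of first 20 levels are <= 100 m
        mean, _ = regional_upper_mean(cube, th, np.ones((2, 2), bool))
        assert mean[0] == pytest.approx(1.0)


class TestIntegrateNpp:
    def test_uniform_rate_over_100m(self):
        cube = np.zeros((2, 12, 3, 3))
        cube[:, :10] = 0.5  # g C m-3 yr-1 in the upper 100 m
        th = np.where(np.arange(12) < 10, 10.0, 50.0)
        out = integrate_npp(cube, th, np.ones((3, 3), bool))
        assert np.allclose(out, 0.5 * 100.0)

    def test_zero_field(self):
        th = np.full(5, 10.0)
        out = integrate_npp(np.zeros((3, 5, 2, 2)), th, np.ones((2, 2), bool))
        assert np.allclose(out, 0.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        cube = rng.uniform(0, 1, (2, 6, 3, 3))
        th = rng.uniform(5, 20, 6)
        mask = np.ones((3, 3), bool)
        out = integrate_npp(cube, th, mask)
        for t in range(2):
            cols = [
                sum(cube[t, k, i, j] * th[k] for k in range(6))
                for i in range(3) for j in range(3)
            ]
            assert out[t] == pytest.approx(np.mean(cols), rel=1e-12)


class TestAttribution:
    def test_identical_series_zero(self):
        s = np.array([1.0, 2.0, 3.0])
        assert np.allclose(attribution_pct(s, s), 0.0)

    def test_five_percent(self):
        s = np.array([1.0, 2.0, 3.0])
        assert np.allclose(attribution_pct(1.05 * s, s), 5.0)

    def test_cumulative_vs_instantaneous_consistency(self):
        """The cumulative flavour equals the instantaneous flavour applied to
        pre-integrated series."""
        rng = np.random.default_rng(9)
        wo = rng.uniform(1, 2, 20)
        w = wo * rng.uniform(1.0, 1.1, 20)
        direct = attribution_pct(w, wo, cumulative=True)
        oracle = attribution_pct(np.cumsum(w), np.cumsum(wo), cumulative=False)
        assert np.allclose(direct, oracle)

    def test_zero_denominator_missing(self):
        out = attribution_pct(np.array([1.0]), np.array([0.0]), cumulative=False)
        assert np.isnan(out[0])
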