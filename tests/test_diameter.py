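"""Apparent-diameter fitting, scaling, regression, and fraction matching."""

import numpy as np
import pandas as pd
import pytest

from fiberlysis import (
    FiberMeasurement,
    IntensityProfile,
    apparent_diameter,
    make_profile_fixture,
    match_fractions,
    ols_fit,
    scale_diameters,
)


class TestProfileFixture:
    def test_noiseless_profile_is_exact_gaussian(self):
        p = make_profile_fixture(true_sigma_nm=25, amplitude=500,
                                 background=80, noise_sd=0)
        x, y = p.positions_nm, p.intensities
        expected = 500 * np.exp(-(x**2) / (2 * 25**2)) + 80
        assert np.allclose(y, expected)

    def test_seed_repeatability(self):
        a = make_profile_fixture(noise_sd=30, seed=5)
        b = make_profile_fixture(noise_sd=30, seed=5)
        c = make_profile_fixture(noise_sd=30, seed=6)
        assert np.array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_residual_sd_matches_noise_level(self):
        clean = make_profile_fixture(noise_sd=0)
        resid = np.concatenate([
            make_profile_fixture(noise_sd=40, seed=s).intensities
            - clean.intensities
            for s in range(30)
        ])
        assert np.std(resid) == pytest.approx(40, rel=0.1)

    def test_validation(self):
        with pytest.raises(ValueError):
            make_profile_fixture(true_sigma_nm=-1)
        with pytest.raises(ValueError):
            IntensityProfile(np.array([0, 1, 2, 1.5, 3]), np.zeros(5))


class TestApparentDiameter:
    def test_noiseless_gaussian_recovers_four_sigma(self):
        p = make_profile_fixture(true_sigma_nm=25, background=0, noise_sd=0)
        assert apparent_diameter(p) == pytest.approx(100.0, rel=1e-6)

    def test_constant_background_does_not_bias(self):
        p = make_profile_fixture(true_sigma_nm=25, background=50, noise_sd=0)
        assert apparent_diameter(p) == pytest.approx(100.0, rel=1e-6)

    def test_noisy_recovery_within_two_percent(self):
        # SNR 10: amplitude 1000, noise sd 100; mean recovered diameter
        # over 100 independent profiles within 2% of the true 4*sigma
        d = [
            apparent_diameter(
                make_profile_fixture(
                    true_sigma_nm=25, amplitude=1000, background=100,
                    noise_sd=100, seed=s,
                )
            )
            for s in range(100)
        ]
        assert np.mean(d) == pytest.approx(100.0, rel=0.02)

    def test_flat_profile_rejected(self):
        with pytest.raises((ValueError, RuntimeError)):
            apparent_diameter(
                IntensityProfile(np.linspace(0, 100, 11), np.full(11, 7.0))
            )


class TestScaleDiameters:
    def _m(self, d):
        return FiberMeasurement(apparent_diameter_nm=d, cleavage_time_s=10.0)

    def test_second_smallest_becomes_unity(self):
        out = scale_diameters([self._m(60), self._m(100), self._m(200)])
        assert [m.scaled_diameter for m in out] == pytest.approx([0.6, 1.0, 2.0])

    def test_two_equal_fibers_both_unity(self):
        out = scale_diameters([self._m(80), self._m(80)])
        assert [m.scaled_diameter for m in out] == pytest.approx([1.0, 1.0])

    def test_matches_sort_and_divide_oracle(self):
        rng = np.random.RandomState(0)
        d = rng.uniform(50, 300, size=12)
        out = scale_diameters([self._m(x) for x in d])
        ref = np.sort(d)[1]
        assert [m.scaled_diameter for m in out] == pytest.approx(list(d / ref))

    def test_scale_invariance(self):
        d = [70.0, 110.0, 150.0]
        a = scale_diameters([self._m(x) for x in d])
        b = scale_diameters([self._m(3.7 * x) for x in d])
        for ma, mb in zip(a, b):
            assert ma.scaled_diameter == pytest.approx(mb.scaled_diameter)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            scale_diameters([self._m(80)])


class TestOlsFit:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1, 2, 3])
        slope, intercept = ols_fit(x, 2 * x + 1)
        assert (slope, intercept) == pytest.approx((2.0, 1.0))

    def test_two_points_interpolate(self):
        slope, intercept = ols_fit([1, 3], [10, 20])
        assert slope == pytest.approx(5.0)
        assert intercept == pytest.approx(5.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.RandomState(1)
        x = rng.uniform(0, 5, 40)
        y = 3.2 * x - 1.4 + rng.normal(0, 0.5, 40)
        A = np.vstack([x, np.ones_like(x)]).T
        ref = np.linalg.solve(A.T @ A, A.T @ y)
        got = ols_fit(x, y)
        assert got == pytest.approx(tuple(ref), abs=1e-10)

    def test_slope_recovery_on_synthetic_cohort(self):
        # linear time-vs-diameter law plus noise at n=50: recovered slope
        # within its own 95% CI of the truth
        rng = np.random.RandomState(7)
        x = rng.uniform(0.8, 4.0, 50)
        y = 18.5 * x + 5 + rng.normal(0, 4, 50)
        slope, _ = ols_fit(x, y)
        resid = y - np.polyval(np.polyfit(x, y, 1), x)
        se = np.sqrt(resid.var(ddof=2) / ((x - x.mean()) ** 2).sum())
        assert abs(slope - 18.5) < 2 * se

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            ols_fit([2, 2, 2], [1, 2, 3])


class TestMatchFractions:
    def _table(self):
        # synthetic monotone time table: T(f, d) = 40 * f * d
        fractions = np.round(np.arange(0.05, 1.001, 0.05), 2)
        diam = [1.0, 2.0, 4.0]
        return pd.DataFrame(
            {d: 40 * fractions * d for d in diam}, index=fractions
        )

    def test_zero_slope_returns_anchor_scaled_fraction(self):
        table = self._table()
        out = match_fractions(table, slope=0.0, anchor=(1.0, 0.5))
        # target time 20 s at every diameter: fraction 20/(40 d)
        assert out["matched_fraction"].to_numpy() == pytest.approx(
            [0.5, 0.25, 0.125]
        )
        assert out["in_range"].all()

    def test_line_through_tabulated_cell(self):
        table = self._table()
        # line hits T(0.25, 2.0) = 20 exactly at d=2 when anchored there
        out = match_fractions(table, slope=0.0, anchor=(2.0, 0.25))
        row = out[out.scaled_diameter == 2.0].iloc[0]
        assert row.matched_fraction == pytest.approx(0.25)

    def test_out_of_range_flagged(self):
        table = self._table()
        out = match_fractions(table, slope=100.0, anchor=(1.0, 0.95))
        far = out[out.scaled_diameter == 4.0].iloc[0]
        assert not far.in_range

    def test_missing_anchor_rejected(self):
        table = self._table()
        with pytest.raises(ValueError):
            match_fractions(table, 18.5, anchor=(3.0, 0.5))
        with pytest.raises(ValueError):
            match_fractions(table, 18.5, anchor=(1.0, 0.51))
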