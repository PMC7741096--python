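import numpy as np
import pytest

from paleodem import (
    DensityModel,
    extract_phases,
    growth_rate,
    index_dates,
    kde_model,
)
from paleodem.kdegrowth import reliability_floor

from conftest import make_dates, singleton_bins


class TestKdeModel:
    def test_point_mass_gives_gaussian_kernel(self, identity_curve):
        # two near-identical tight dates -> every draw lands at ~8000, and the
        # mean KDE is a single Gaussian kernel at the shared year
        dates = make_dates([8000, 8000], errors=[1.0, 1.0])
        dates[1].site_id = "S2"
        bins = singleton_bins(dates)
        grid = np.arange(7000.0, 9001.0, 10.0)
        kde = kde_model(bins, index_dates(dates), identity_curve, bandwidth=150.0,
                        n_boot=30, seed=0, grid=grid)
        expect = np.exp(-0.5 * ((grid - 8000.0) / 150.0) ** 2)
        expect /= expect.sum() * 10.0
        # draws jitter by ~1 yr (tiny lab error + 1-yr density cells)
        assert np.max(np.abs(kde.mean - expect)) < 5e-3 * expect.max()

    def test_replicates_integrate_to_one(self, identity_curve):
        rng = np.random.default_rng(1)
        dates = make_dates(rng.uniform(7000, 9000, 15), errors=[40.0] * 15)
        for i, d in enumerate(dates):
            d.site_id = f"S{i}"
        bins = singleton_bins(dates)
        grid = np.arange(6000.0, 10001.0, 10.0)
        kde = kde_model(bins, index_dates(dates), identity_curve, n_boot=40, seed=2, grid=grid)
        np.testing.assert_allclose(kde.replicates.sum(axis=1) * 10.0, 1.0, atol=1e-6)

    def test_fixed_seed_reproducible(self, identity_curve):
        dates = make_dates([7500, 8200, 8900], errors=[40.0] * 3)
        for i, d in enumerate(dates):
            d.site_id = f"S{i}"
        bins = singleton_bins(dates)
        idx = index_dates(dates)
        grid = np.arange(6500.0, 9501.0, 10.0)
        a = kde_model(bins, idx, identity_curve, n_boot=15, seed=9, grid=grid)
        b = kde_model(bins, idx, identity_curve, n_boot=15, seed=9, grid=grid)
        np.testing.assert_array_equal(a.replicates, b.replicates)


class TestGrowthRate:
    def test_exponential_closed_form(self):
        """K ~ exp(-rho tau) must give r = +100 rho %/yr at interior cells
        exactly (log-space central differences are exact for exponentials)."""
        grid = np.arange(0.0, 5001.0, 10.0)
        k = np.exp(-0.004 * grid)
        g = growth_rate(k[None, :], grid)
        interior = g.mean[1:-1]
        np.testing.assert_allclose(interior, 0.4, rtol=1e-6)

    def test_gaussian_kde_crosses_zero_at_mode(self):
        grid = np.arange(6000.0, 10001.0, 10.0)
        mode = 8000.0
        k = np.exp(-0.5 * ((grid - mode) / 300.0) ** 2)
        g = growth_rate(k[None, :], grid)
        # r = (tau - mode)/sd^2 for a Gaussian: zero exactly at the mode,
        # positive while approaching it from the past (older side)
        at_mode = g.mean[grid == mode]
        assert abs(at_mode[0]) < 1e-9
        assert np.all(g.mean[(grid > mode) & (grid < mode + 900)] > 0)
        assert np.all(g.mean[(grid < mode) & (grid > mode - 900)] < 0)

    def test_matches_halfstep_finite_difference_oracle(self):
        """Richardson check: the step-h log-derivative of a smooth density
        is closer to the analytic rate at h/2 than at h."""
        rho = 0.0007
        def series(step):
            grid = np.arange(5000.0, 9001.0, step)
            k = np.exp(-rho * grid) * (1.2 + np.sin(grid / 800.0))
            exact = (rho - np.cos(grid / 800.0) / (800.0 * (1.2 + np.sin(grid / 800.0)))) * 100.0
            g = growth_rate(k[None, :], grid)
            return np.max(np.abs(g.mean[1:-1] - exact[1:-1]))
        assert series(5.0) < series(10.0)

    def test_masks_below_floor(self):
        grid = np.arange(0.0, 1001.0, 10.0)
        k = np.full(grid.size, 1e-15)
        k[40:60] = 1e-3
        g = growth_rate(k[None, :], grid, floor=1e-12)
        assert np.all(np.isnan(g.mean[:39]))
        assert np.any(np.isfinite(g.mean[41:58]))

    def test_nonuniform_grid_rejected(self):
        grid = np.array([0.0, 10.0, 30.0])
        with pytest.raises(ValueError, match="uniform"):
            growth_rate(np.ones((2, 3)), grid)

    def test_reliability_floor_formula(self):
        assert reliability_floor(100, 150.0, min_events=2.0) == pytest.approx(
            2.0 / (2.0 * 150.0 * 100)
        )
        with pytest.raises(ValueError):
            reliability_floor(0, 150.0)


def growth_model(r_rows, grid, coverage=0.954):
    r = np.atleast_2d(np.asarray(r_rows, float))
    return DensityModel(
        grid=grid,
        mean=np.nanmean(r, axis=0),
        lower=np.nanmin(r, axis=0),
        upper=np.nanmax(r, axis=0),
        coverage=coverage,
        n_boot=r.shape[0],
        kind="growth",
        replicates=r,
    )


class TestExtractPhases:
    grid = np.arange(8000.0, 11001.0, 10.0)

    def test_single_block_phase_descriptors(self):
        r = np.where((self.grid >= 9000.0) & (self.grid <= 10000.0), 0.3, -0.1)
        phases = extract_phases(growth_model(r, self.grid))
        assert len(phases) == 1
        p = phases.phases[0]
        assert p.start == 10000.0
        assert p.t_pop_max == 9000.0
        assert p.duration == 1000.0
        assert p.max_rate == pytest.approx(0.3)
        assert p.start_sd == 0.0

    def test_all_negative_growth_gives_empty_report(self):
        r = np.full(self.grid.size, -0.2)
        assert len(extract_phases(growth_model(r, self.grid))) == 0

    def test_short_spurts_below_min_span_ignored(self):
        r = np.full(self.grid.size, -0.1)
        r[50:55] = 0.5  # 40-yr spurt < 200-yr minimum
        assert len(extract_phases(growth_model(r, self.grid))) == 0

    def test_two_booms_matched_in_order_with_replicate_sds(self):
        rng = np.random.default_rng(4)
        def rep():
            r = np.full(self.grid.size, -0.1)
            j1 = int(rng.integers(-3, 4))
            j2 = int(rng.integers(-3, 4))
            b1 = (self.grid >= 10000.0 + 10 * j1) & (self.grid <= 10600.0 + 10 * j1)
            b2 = (self.grid >= 8400.0 + 10 * j2) & (self.grid <= 8900.0 + 10 * j2)
            r[b1] = 0.35 + rng.normal(0, 0.02)
            r[b2] = 0.2 + rng.normal(0, 0.02)
            return r
        rows = np.array([rep() for _ in range(40)])
        phases = extract_phases(growth_model(rows, self.grid))
        assert len(phases) == 2
        first, second = phases.phases
        assert first.start > second.start  # oldest phase first
        assert abs(first.start - 10600.0) < 50.0
        assert abs(second.start - 8900.0) < 50.0
        assert first.max_rate == pytest.approx(0.35, abs=0.03)
        assert first.start_sd > 0.0
        assert first.support > 0.9

    def test_requires_growth_kind(self):
        m = DensityModel(grid=self.grid, mean=np.zeros(self.grid.size),
                         lower=np.zeros(self.grid.size), upper=np.zeros(self.grid.size),
                         kind="kde")
        with pytest.raises(ValueError, match="growth"):
            extract_phases(m)
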