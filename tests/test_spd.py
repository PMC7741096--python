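import numpy as np
import pytest

from paleodem import (
    C14Date,
    CalDensity,
    PhaseBin,
    bootstrap_spd,
    build_spd,
    calibrate_date,
    index_dates,
    sum_densities,
    taphonomic_survival,
    uncalibrate,
)
from paleodem.calibrate import density_rows
from paleodem.spd import TAPHONOMIC_A, TAPHONOMIC_B, TAPHONOMIC_C, DensityModel

from conftest import make_dates, singleton_bins


class TestSumDensities:
    def test_two_identical_unit_densities(self):
        grid = np.arange(5000.0, 5010.0)
        mass = np.full(10, 0.1)
        d = CalDensity(grid=grid, mass=mass)
        out = sum_densities([d, d], grid)
        assert out.sum() == pytest.approx(2.0)
        np.testing.assert_allclose(out, 0.2)

    def test_single_density_is_identity(self):
        grid = np.arange(5000.0, 5010.0)
        mass = np.linspace(1, 10, 10)
        mass /= mass.sum()
        d = CalDensity(grid=grid, mass=mass)
        np.testing.assert_allclose(sum_densities([d], grid), mass)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(0)
        grid = np.arange(4000.0, 4200.0)
        ds = []
        for _ in range(8):
            lo = float(rng.integers(4000, 4150))
            g = np.arange(lo, lo + 50.0)
            m = rng.random(50)
            ds.append(CalDensity(grid=g, mass=m / m.sum()))
        out = sum_densities(ds, grid)
        expect = np.zeros_like(grid)
        for d in ds:
            expect += sum_densities([d], grid)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_empty_input_gives_zero_vector(self):
        grid = np.arange(0.0, 10.0)
        np.testing.assert_array_equal(sum_densities([], grid), np.zeros(10))


class TestTaphonomicSurvival:
    def test_value_at_zero_from_logspace_evaluation(self):
        expect = np.exp(np.log(TAPHONOMIC_A) + TAPHONOMIC_C * np.log(TAPHONOMIC_B))
        assert taphonomic_survival(0.0) == pytest.approx(expect, rel=1e-12)

    def test_strictly_decreasing(self):
        t = np.linspace(0, 20000, 500)
        assert np.all(np.diff(taphonomic_survival(t)) < 0)

    def test_ratio_matches_logspace_oracle(self):
        ratio = taphonomic_survival(10000.0) / taphonomic_survival(1000.0)
        oracle = np.exp(
            TAPHONOMIC_C * (np.log(10000.0 + TAPHONOMIC_B) - np.log(1000.0 + TAPHONOMIC_B))
        )
        assert ratio == pytest.approx(oracle, rel=1e-12)

    def test_undefined_below_minus_b(self):
        with pytest.raises(ValueError):
            taphonomic_survival(-TAPHONOMIC_B)


class TestBuildSpd:
    def setup_case(self, identity_curve, site_type):
        dates = make_dates([8000, 8400, 9000], errors=[30, 30, 30], site_type=site_type)
        for i, d in enumerate(dates):
            d.site_id = f"S{i}"
        bins = singleton_bins(dates)
        return dates, bins, index_dates(dates)

    def test_all_closed_equals_plain_sum(self, identity_curve):
        dates, bins, idx = self.setup_case(identity_curve, "closed")
        grid = np.arange(7500.0, 9501.0)
        spd = build_spd(bins, idx, identity_curve, grid=grid)
        plain = sum_densities([calibrate_date(d, identity_curve) for d in dates], grid)
        # per-date densities differ only by the 1e-6 tail truncation
        np.testing.assert_allclose(spd.mean, plain, atol=1e-5)

    def test_flag_off_equals_plain_sum(self, identity_curve):
        dates, bins, idx = self.setup_case(identity_curve, "open_air")
        grid = np.arange(7500.0, 9501.0)
        spd = build_spd(bins, idx, identity_curve, correct_open_air=False, grid=grid)
        plain = sum_densities([calibrate_date(d, identity_curve) for d in dates], grid)
        np.testing.assert_allclose(spd.mean, plain, atol=1e-5)

    def test_single_open_air_density_scaled_by_inverse_survival(self, identity_curve):
        dates = make_dates([8000], errors=[40], site_type="open_air")
        bins = singleton_bins(dates)
        grid = np.arange(7500.0, 8501.0)
        spd = build_spd(bins, index_dates(dates), identity_curve, grid=grid)
        row = density_rows(dates, identity_curve, None, grid)[0]
        expect = row / taphonomic_survival(grid)
        expect /= expect.sum()  # rescaled back to unit mass for one bin
        np.testing.assert_allclose(spd.mean, expect, atol=1e-12)
        assert spd.mean.sum() == pytest.approx(1.0)

    def test_mass_conservation_mixed_types(self, identity_curve):
        open_d = make_dates([8000, 8800], errors=[30, 30], site="O", site_type="open_air")
        closed_d = make_dates([8300, 9000, 9400], errors=[30, 30, 30], site="C")
        dates = open_d + closed_d
        bins = singleton_bins(dates)
        grid = np.arange(7000.0, 10001.0)
        spd = build_spd(bins, index_dates(dates), identity_curve, grid=grid)
        assert spd.mean.sum() == pytest.approx(len(bins), rel=1e-9)


class TestBootstrapSpd:
    def test_degenerate_identical_bins_collapse_envelope(self, identity_curve):
        dates = make_dates([8000, 8000], errors=[30, 30])
        dates[1].site_id = "S2"
        bins = singleton_bins(dates)
        out = bootstrap_spd(bins, index_dates(dates), identity_curve, n_boot=10, seed=0,
                            grid=np.arange(7500.0, 8501.0))
        np.testing.assert_allclose(out.lower, out.upper, atol=1e-12)
        np.testing.assert_allclose(out.lower, out.mean, atol=1e-12)

    def test_fixed_seed_bit_reproducible(self, identity_curve):
        rng = np.random.default_rng(9)
        dates = make_dates(rng.uniform(7000, 9000, 12), errors=[40.0] * 12)
        for i, d in enumerate(dates):
            d.site_id = f"S{i % 4}"
        bins = singleton_bins(dates)
        idx = index_dates(dates)
        grid = np.arange(6500.0, 9501.0, 5.0)
        a = bootstrap_spd(bins, idx, identity_curve, n_boot=25, seed=7, grid=grid)
        b = bootstrap_spd(bins, idx, identity_curve, n_boot=25, seed=7, grid=grid)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_envelope_widens_with_fewer_bins(self, identity_curve):
        rng = np.random.default_rng(10)
        def width(n):
            dates = make_dates(rng.uniform(7500, 8500, n), errors=[40.0] * n)
            for i, d in enumerate(dates):
                d.site_id = f"S{i}"
            bins = singleton_bins(dates)
            grid = np.arange(7000.0, 9001.0, 10.0)
            out = bootstrap_spd(bins, index_dates(dates), identity_curve,
                                n_boot=150, seed=1, grid=grid)
            # normalize per bin so widths are comparable across n
            return np.mean(out.upper - out.lower) / n
        assert width(10) > width(80)

    def test_envelope_covers_true_curve_on_interior(self, wiggly_curves):
        """Data simulated from a known flat curve: the true (normalized)
        expectation lies inside the bootstrap envelope at >= 90% of interior
        grid cells (interior excludes the hard edges of the simulation
        window, where the truth is discontinuous)."""
        atm, _ = wiggly_curves
        rng = np.random.default_rng(11)
        old, young = 9000.0, 7500.0
        years = rng.uniform(young, old, 200)
        cras, errs = uncalibrate(years, atm, rng.choice([30.0, 40.0, 50.0], 200), rng)
        dates = [
            C14Date(f"d{i}", float(cras[i]), float(errs[i]), site_id=f"s{i}")
            for i in range(200)
        ]
        bins = singleton_bins(dates)
        grid = np.arange(7000.0, 9501.0, 10.0)
        env = bootstrap_spd(bins, index_dates(dates), atm, n_boot=200, seed=2, grid=grid)
        truth = np.where((grid >= young) & (grid <= old), 1.0, 0.0)
        truth = truth / truth.sum() * len(bins)
        interior = (grid >= young + 150) & (grid <= old - 150)
        covered = (truth[interior] >= env.lower[interior]) & (
            truth[interior] <= env.upper[interior]
        )
        assert covered.mean() >= 0.90

    def test_nboot_below_two_rejected(self, identity_curve):
        dates = make_dates([8000, 8200], errors=[30, 30])
        bins = singleton_bins(dates)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_spd(bins, index_dates(dates), identity_curve, n_boot=1)


class TestDensityModel:
    def test_envelope_widened_to_contain_mean(self):
        grid = np.arange(3.0)
        m = DensityModel(grid=grid, mean=[1.0, 2.0, 3.0], lower=[1.5, 1.0, 1.0],
                         upper=[2.0, 2.0, 2.0])
        assert np.all(m.lower <= m.mean)
        assert np.all(m.upper >= m.mean)

    def test_coverage_validated(self):
        grid = np.arange(3.0)
        with pytest.raises(ValueError, match="coverage"):
            DensityModel(grid=grid, mean=grid, lower=grid, upper=grid, coverage=1.5)
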