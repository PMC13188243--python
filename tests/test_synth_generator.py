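"""Sampling intervals, noise semantics and dataset generation."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from synthtl.ode_library import OdeSystem
from synthtl.synth_generator import (DiversityConfig, GenerationError,
                                     IntervalSpec, NoiseConfig, TimeGrid,
                                     Trajectory, apply_measurement_noise,
                                     generate_dataset, generate_fixture_target,
                                     resolve_interval, sample_configuration,
                                     sigma_from_iqr, simulate_trajectory)


ZERO_SYS = OdeSystem("zero_rhs", ("u",), ("k",),
                     lambda y, t, th: np.zeros_like(y),
                     {"u": 1.0, "k": 1.0}, nonneg=False)


class TestIntervals:
    def test_degenerate_interval(self):
        assert resolve_interval(IntervalSpec(2.0, half_width_fraction=0.0)) == (2.0, 2.0)

    def test_symmetric_interval(self):
        lo, hi = resolve_interval(IntervalSpec(1.0, half_width_fraction=0.2))
        assert (lo, hi) == pytest.approx((0.8, 1.2))

    def test_full_width_rejected(self):
        with pytest.raises(ValueError):
            resolve_interval(IntervalSpec(1.0, half_width_fraction=1.0))

    def test_width_classes_are_ordered(self):
        widths = [IntervalSpec(1.0, c).resolved_width() for c in ("S", "M", "L", "XL")]
        assert widths == sorted(widths) and len(set(widths)) == 4


class TestSampling:
    def test_zero_width_returns_centers(self, sir, rng):
        div = DiversityConfig(
            ic_specs={v: IntervalSpec(sir.default_centers[v], half_width_fraction=0.0)
                      for v in sir.variables},
            kp_specs={p: IntervalSpec(sir.default_centers[p], half_width_fraction=0.0)
                      for p in sir.parameters})
        theta, ics = sample_configuration(sir, div, rng)
        assert theta == pytest.approx(sir.center_theta())
        assert ics == pytest.approx(sir.center_ics())

    def test_uniform_sampling_statistics(self, lv, rng):
        div = DiversityConfig.from_classes(lv, "M", "M")  # +-20%
        draws = np.array([sample_configuration(lv, div, rng)[0][0]
                          for _ in range(10_000)])
        lo, hi = 1.1 * 0.8, 1.1 * 1.2
        assert draws.min() >= lo and draws.max() <= hi
        mc_se = (hi - lo) / np.sqrt(12 * draws.size)
        assert abs(draws.mean() - 1.1) < 3 * mc_se

    def test_seeded_determinism(self, sir):
        div = DiversityConfig.from_classes(sir, "L", "L")
        a = sample_configuration(sir, div, np.random.default_rng(5))
        b = sample_configuration(sir, div, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestSigmaFromIqr:
    def test_zero_iqr(self):
        assert sigma_from_iqr(0.0) == 0.0

    def test_negative_iqr_rejected(self):
        with pytest.raises(ValueError):
            sigma_from_iqr(-0.1)

    @pytest.mark.parametrize("iqr", [0.01, 0.05, 0.1, 0.2, 0.5, 1.0])
    def test_matches_numeric_quantile_root(self, iqr):
        # independent oracle: solve exp(s*q75) - exp(-s*q75) = iqr for s
        q75 = norm.ppf(0.75)
        oracle = brentq(lambda s: np.exp(s * q75) - np.exp(-s * q75) - iqr,
                        0.0, 10.0, xtol=1e-14)
        assert sigma_from_iqr(iqr) == pytest.approx(oracle, abs=1e-10)

    def test_known_value(self):
        assert sigma_from_iqr(0.1) == pytest.approx(0.07410, abs=5e-5)

    def test_empirical_iqr_of_draws(self, rng):
        for iqr in (0.1, 0.5):
            draws = rng.lognormal(0.0, sigma_from_iqr(iqr), size=100_000)
            q1, q3 = np.quantile(draws, [0.25, 0.75])
            assert (q3 - q1) == pytest.approx(iqr, rel=0.02)


class TestEnvironmentalNoise:
    def test_additive_piecewise_hand_integration(self, monkeypatch):
        # zero-RHS system: the state integrates the piecewise-constant
        # noise slopes exactly: y(t_{i+1}) = y(t_i) + e_i * dt
        grid = TimeGrid(np.array([0.0, 1.0, 2.0]))
        noise = NoiseConfig(kind="environmental", operation="additive", level=1.0)

        class FixedDraws:
            def normal(self, loc, scale, size):
                return np.array([[0.5], [-0.2]])
            def lognormal(self, *a, **k):  # pragma: no cover
                raise AssertionError

        # derivative scale of the clean (constant) trajectory is floored at
        # 1e-12; inject draws already scaled to (0.5, -0.2)
        import synthtl.synth_generator as sg
        monkeypatch.setattr(sg, "_derivative_scales",
                            lambda clean, grid: np.ones(1))
        traj = simulate_trajectory(ZERO_SYS, np.array([1.0]), np.array([0.0]),
                                   grid, noise, FixedDraws())
        assert traj.values[:, 0] == pytest.approx([0.0, 0.5, 0.3], abs=1e-9)

    def test_multiplicative_identity_factors(self, sir, sir_grid):
        noise = NoiseConfig(kind="environmental", operation="multiplicative",
                            level=0.2)

        class OnesRng:
            def lognormal(self, mean, sigma, size):
                return np.ones(size)

        clean = simulate_trajectory(sir, sir.center_theta(), sir.center_ics(),
                                    sir_grid, NoiseConfig(kind="none"))
        noisy = simulate_trajectory(sir, sir.center_theta(), sir.center_ics(),
                                    sir_grid, noise, OnesRng())
        assert np.allclose(noisy.values, clean.values, rtol=1e-6, atol=1e-6)

    def test_level_zero_is_clean_solve(self, sir, sir_grid):
        noise = NoiseConfig(kind="environmental", operation="additive", level=0.0)
        clean = simulate_trajectory(sir, sir.center_theta(), sir.center_ics(),
                                    sir_grid, NoiseConfig(kind="none"))
        noisy = simulate_trajectory(sir, sir.center_theta(), sir.center_ics(),
                                    sir_grid, noise, np.random.default_rng(0))
        assert np.array_equal(noisy.values, clean.values)

    def test_deviation_shrinks_with_level(self, sir, sir_grid):
        clean = simulate_trajectory(sir, sir.center_theta(), sir.center_ics(),
                                    sir_grid, NoiseConfig(kind="none"))
        devs = []
        for level in (1e-1, 1e-2, 1e-3):
            noise = NoiseConfig(kind="environmental", operation="multiplicative",
                                level=level)
            traj = simulate_trajectory(sir, sir.center_theta(), sir.center_ics(),
                                       sir_grid, noise, np.random.default_rng(3))
            devs.append(np.max(np.abs(traj.values - clean.values)))
        assert devs[0] > devs[1] > devs[2]


@pytest.fixture(scope="module")
def clean(sir, sir_grid):
    return simulate_trajectory(sir, sir.center_theta(), sir.center_ics(),
                               sir_grid, NoiseConfig(kind="none"))


class TestMeasurementNoise:

    def test_level_zero_identity(self, clean, rng):
        noise = NoiseConfig(kind="measurement", operation="multiplicative", level=0.0)
        out = apply_measurement_noise(clean, noise, rng)
        assert np.array_equal(out.values, clean.values)

    def test_wrong_kind_rejected(self, clean, rng):
        with pytest.raises(ValueError):
            apply_measurement_noise(clean, NoiseConfig(kind="none"), rng)

    def test_multiplicative_ratio_median(self, rng):
        grid = TimeGrid(np.linspace(0, 1, 10_000))
        traj = Trajectory("t", grid, np.full((10_000, 1), 5.0), ("u",))
        noise = NoiseConfig(kind="measurement", operation="multiplicative", level=0.2)
        out = apply_measurement_noise(traj, noise, rng)
        ratios = out.values / traj.values
        assert np.median(ratios) == pytest.approx(1.0, rel=0.01)

    def test_additive_sd_scaling(self, rng):
        # variable with clean sd 4.0 and level 0.5 -> noise sd 2.0
        grid = TimeGrid(np.linspace(0, 1, 10_000))
        vals = rng.normal(10.0, 4.0, size=(10_000, 1))
        vals = (vals - vals.mean()) / vals.std() * 4.0 + 10.0
        traj = Trajectory("t", grid, vals, ("u",))
        noise = NoiseConfig(kind="measurement", operation="additive", level=0.5)
        out = apply_measurement_noise(traj, noise, rng)
        assert np.std(out.values - traj.values) == pytest.approx(2.0, rel=0.05)


class TestGenerateDataset:
    def test_zero_width_noise_free_is_center_simulation(self, sir, sir_grid):
        div = DiversityConfig(
            ic_specs={v: IntervalSpec(sir.default_centers[v], half_width_fraction=0.0)
                      for v in sir.variables},
            kp_specs={p: IntervalSpec(sir.default_centers[p], half_width_fraction=0.0)
                      for p in sir.parameters})
        ds = generate_dataset(sir, div, NoiseConfig(kind="none"), 1, sir_grid, seed=0)
        center = simulate_trajectory(sir, sir.center_theta(), sir.center_ics(),
                                     sir_grid, NoiseConfig(kind="none"))
        assert ds.n_series == 1
        assert np.allclose(ds.trajectories[0].values, center.values, rtol=1e-9)

    def test_seeded_reproducibility(self, sir, sir_grid):
        div = DiversityConfig.from_classes(sir, "M", "M")
        a = generate_dataset(sir, div, NoiseConfig(kind="none"), 10, sir_grid, seed=7)
        b = generate_dataset(sir, div, NoiseConfig(kind="none"), 10, sir_grid, seed=7)
        assert np.array_equal(a.stacked(), b.stacked())

    def test_wide_lv_trajectories_distinct_and_finite(self, lv):
        grid = TimeGrid.regular(0.0, 30.0, 61)
        div = DiversityConfig.from_classes(lv, "S", "L")
        ds = generate_dataset(lv, div, NoiseConfig(kind="none"), 10, grid, seed=3)
        stacked = ds.stacked()
        assert np.all(np.isfinite(stacked))
        for i in range(10):
            for j in range(i + 1, 10):
                assert not np.allclose(stacked[i], stacked[j])

    def test_provenance_allows_regeneration(self, sir, sir_grid):
        div = DiversityConfig.from_classes(sir, "M", "L")
        ds = generate_dataset(sir, div, NoiseConfig(kind="none"), 3, sir_grid, seed=9)
        tr = ds.trajectories[1]
        regen = simulate_trajectory(sir, np.array(tr.provenance["theta"]),
                                    np.array(tr.provenance["ics"]), sir_grid,
                                    NoiseConfig(kind="none"))
        assert np.allclose(regen.values, tr.values, rtol=1e-9, atol=1e-9)

    def test_retry_cap_raises_generation_error(self):
        # constant decline drives the state negative on every draw, so a
        # nonneg system exhausts its retry budget
        declining = OdeSystem("declining_test_gen", ("u",), ("k",),
                              lambda y, t, th: np.full_like(y, -th[0]),
                              {"u": 1.0, "k": 5.0}, nonneg=True)
        div = DiversityConfig.from_classes(declining, "S", "S")
        with pytest.raises(GenerationError, match="retries"):
            generate_dataset(declining, div, NoiseConfig(kind="none"), 1,
                             TimeGrid.regular(0, 10, 11), seed=0,
                             max_retries_per_slot=2)

    def test_additive_env_noise_averages_to_clean_for_linear_system(self):
        # mean-zero rate noise on a linear system: the mean of M noisy
        # trajectories converges to the clean one roughly like 1/sqrt(M)
        lin = OdeSystem("linear_test_avg", ("u",), ("k",),
                        lambda y, t, th: -th[0] * y, {"u": 10.0, "k": 0.3},
                        nonneg=False)
        grid = TimeGrid.regular(0.0, 5.0, 26)
        clean = simulate_trajectory(lin, np.array([0.3]), np.array([10.0]),
                                    grid, NoiseConfig(kind="none"))
        noise = NoiseConfig(kind="environmental", operation="additive", level=0.5)
        rng = np.random.default_rng(21)
        sims = np.stack([
            simulate_trajectory(lin, np.array([0.3]), np.array([10.0]), grid,
                                noise, rng).values for _ in range(160)])
        err_40 = np.abs(sims[:40].mean(axis=0) - clean.values).max()
        err_160 = np.abs(sims.mean(axis=0) - clean.values).max()
        assert err_160 < err_40


class TestFixtureTargets:
    def test_coherent_noiseless_is_clean(self, sir, sir_grid, rng):
        fix = generate_fixture_target(sir, sir.center_theta(), sir.center_ics(),
                                      sir_grid, 0.0, True, rng)
        clean = simulate_trajectory(sir, sir.center_theta(), sir.center_ics(),
                                    sir_grid, NoiseConfig(kind="none"))
        assert np.array_equal(fix.values, clean.values)

    def test_incoherent_differs_substantially(self, sir, sir_grid, rng):
        clean = simulate_trajectory(sir, sir.center_theta(), sir.center_ics(),
                                    sir_grid, NoiseConfig(kind="none"))
        fix = generate_fixture_target(sir, sir.center_theta(), sir.center_ics(),
                                      sir_grid, 0.0, False, rng)
        sds = np.maximum(np.std(clean.values, axis=0), 1e-12)
        deviates = np.abs(fix.values - clean.values) > sds
        frac_points = deviates.any(axis=1).mean()
        assert frac_points > 0.5

    def test_reproducible_from_seed(self, sir, sir_grid):
        a = generate_fixture_target(sir, sir.center_theta(), sir.center_ics(),
                                    sir_grid, 0.1, True, np.random.default_rng(2))
        b = generate_fixture_target(sir, sir.center_theta(), sir.center_ics(),
                                    sir_grid, 0.1, True, np.random.default_rng(2))
        assert np.array_equal(a.values, b.values)
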