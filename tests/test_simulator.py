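import numpy as np
import pytest

from metapva import (
    DemographyParams,
    Landscape,
    MigrationParams,
    ModelParams,
    Patch,
    SimConfig,
    estimate_te,
    response_variables,
    run_simulation,
    run_trial,
)


def single_patch(k=50.0, depth=2.0):
    return Landscape([Patch(1, k / (17.0 * depth), depth, 0.0, 0.0)])


def quiet_params(**kw):
    """Deterministic demography (no noise) with migration off by default."""
    demo = DemographyParams(r_d=kw.pop("r_d", 0.01), v_r=kw.pop("v_r", 0.0))
    mig = MigrationParams(alpha=kw.pop("alpha", 0.01), beta=kw.pop("beta", 0.0))
    return ModelParams(demography=demo, migration=mig, k_volume=kw.pop("k_volume", 17.0))


class TestRunTrial:
    def test_deterministic_fixed_point_never_goes_extinct(self):
        land = single_patch(50.0)
        hist = run_trial(land, quiet_params(), SimConfig(tmax=101, trials=1, seed=0), 0)
        np.testing.assert_allclose(hist.n[:, 0], 50.0)
        assert hist.extinct_year is None

    def test_no_habitat_is_extinct_at_year_one(self):
        land = Landscape([Patch(1, 1.0, 0.0, 0, 0), Patch(2, 2.0, 0.0, 50, 0)])
        hist = run_trial(land, quiet_params(), SimConfig(tmax=10, trials=1, seed=0), 0)
        assert hist.extinct_year == 1
        assert hist.total.sum() == 0.0

    def test_empty_patch_is_recolonized_quickly(self, two_patch):
        # one patch at K=100, the other seeded empty; lambda = 0.5*100*e^-1
        # ~ 18.4/yr, so P(no colonist in 5 yr) ~ e^-92: every trial occupies
        params = quiet_params(r_d=0.5, beta=0.5)
        occupied = 0
        trials = 300
        for t in range(trials):
            hist = run_trial(
                two_patch,
                params,
                SimConfig(tmax=5, trials=1, seed=0),
                t,
                n0=np.array([100.0, 0.0]),
            )
            if np.any(hist.n[1:6, 1] >= 1.0):
                occupied += 1
        assert occupied / trials >= 0.99

    def test_extinction_is_absorbing(self):
        land = single_patch(3.0)
        params = ModelParams(
            demography=DemographyParams(r_d=0.01, v_r=2.0),
            migration=MigrationParams(beta=0.0),
        )
        for seed in range(20):
            hist = run_trial(land, params, SimConfig(tmax=60, trials=1, seed=0), seed)
            if hist.extinct_year is not None:
                assert np.all(hist.total[hist.extinct_year :] == 0.0)

    def test_migrant_counts_are_integers_and_nonnegative(self, two_patch):
        params = quiet_params(v_r=1.0, beta=0.2)
        hist = run_trial(two_patch, params, SimConfig(tmax=30, trials=1, seed=0), 4)
        assert hist.migrants.dtype.kind == "i"
        assert np.all(hist.migrants >= 0)
        assert np.all(hist.n >= 0)

    def test_event_order_oracle_with_injected_migrants(self, two_patch):
        # hand recursion with the same yearly event order: growth at zero
        # noise -> ceiling at K -> extinction below 1 -> deterministic
        # floor(lambda) "migrants" added
        params = quiet_params(r_d=0.3, beta=0.05, alpha=0.01)
        config = SimConfig(tmax=12, trials=1, seed=0)

        def floor_sampler(lam, rng):
            return np.floor(lam).astype(int)

        hist = run_trial(
            two_patch, params, config, 0, migrant_sampler=floor_sampler,
            n0=np.array([100.0, 2.0]),
        )

        k = two_patch.carrying_capacities(17.0)
        d = two_patch.d
        n = np.array([100.0, 2.0])
        for t in range(1, 13):
            grown = np.where(k > 0, n * np.exp(0.3 * (1 - n / k)), 0.0)
            grown = np.minimum(grown, k)
            grown = np.where(grown < 1.0, 0.0, grown)
            lam = np.array(
                [
                    0.05 * grown[1] * np.exp(-0.01 * d[0, 1]),
                    0.05 * grown[0] * np.exp(-0.01 * d[1, 0]),
                ]
            )
            n = grown + np.floor(lam)
            np.testing.assert_allclose(hist.n[t], n, rtol=1e-12)


class TestEstimateTe:
    def test_all_immediately_extinct(self):
        assert estimate_te([1, 1, 1], tmax=101) == 1.0

    def test_censored_trials_contribute_tmax(self):
        assert estimate_te([5.0, 10.0, np.nan], tmax=101) == pytest.approx(116 / 3)

    def test_all_censored_gives_tmax(self):
        assert estimate_te([np.nan, np.nan], tmax=101) == 101.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_te([], tmax=101)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_te([0.5], tmax=101)


class TestRunSimulation:
    def test_single_trial_matches_run_trial(self):
        land = single_patch(20.0)
        params = quiet_params(v_r=1.0)
        config = SimConfig(tmax=40, trials=1, seed=123)
        summary = run_simulation(land, params, config)
        child = np.random.SeedSequence(123).spawn(1)[0]
        hist = run_trial(land, params, config, np.random.default_rng(child))
        np.testing.assert_allclose(summary.mean_n[:, 0], hist.n[:, 0])
        expected_te = hist.extinct_year if hist.extinct_year is not None else 40
        assert summary.te == expected_te

    def test_deterministic_persistent_setup_is_censored(self):
        land = single_patch(50.0)
        summary = run_simulation(land, quiet_params(), SimConfig(tmax=101, trials=5, seed=0))
        assert summary.te == 101.0
        assert np.all(np.isnan(summary.extinction_years))
        np.testing.assert_allclose(summary.occupancy, 1.0)

    def test_same_seed_bit_identical(self, preset, defaults):
        params, _ = defaults
        config = SimConfig(tmax=101, trials=40, seed=2024)
        a = run_simulation(preset, params, config)
        b = run_simulation(preset, params, config)
        np.testing.assert_array_equal(a.mean_n, b.mean_n)
        np.testing.assert_array_equal(a.var_n, b.var_n)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)
        np.testing.assert_array_equal(a.extinction_years, b.extinction_years)
        assert a.te == b.te

    def test_trial_streams_stable_under_partitioning(self):
        # first trials of a longer run replicate a shorter run exactly
        land = single_patch(10.0)
        params = quiet_params(v_r=1.0)
        few = run_simulation(land, params, SimConfig(tmax=50, trials=3, seed=7))
        many = run_simulation(land, params, SimConfig(tmax=50, trials=6, seed=7))
        np.testing.assert_array_equal(
            few.extinction_years, many.extinction_years[:3]
        )

    def test_variance_nonnegative_and_occupancy_bounded(self, preset, defaults):
        params, _ = defaults
        summary = run_simulation(preset, params, SimConfig(tmax=101, trials=30, seed=5))
        assert np.all(summary.var_n >= 0)
        assert np.all((summary.occupancy >= 0) & (summary.occupancy <= 1))
        assert summary.te <= 101


class TestResponseVariables:
    def test_persistent_single_patch(self):
        land = single_patch(50.0)
        summary = run_simulation(land, quiet_params(), SimConfig(tmax=101, trials=10, seed=0))
        resp = response_variables(summary, t=25)
        assert resp["mvte"] == 101.0
        assert resp["mvp25"] == 1.0
        assert resp["mN25"] == pytest.approx(50.0)

    def test_everything_extinct_before_t(self):
        land = Landscape([Patch(1, 1.0, 0.0, 0, 0)])
        summary = run_simulation(land, quiet_params(), SimConfig(tmax=30, trials=5, seed=0))
        resp = response_variables(summary, t=25)
        assert resp["mvte"] == 1.0
        assert resp["mvp25"] == 0.0
        assert resp["mN25"] == 0.0

    def test_two_patch_migrant_mean_matches_poisson_rate(self, two_patch):
        # stationary N = K = 100 in both patches (growth then cap pins N at
        # K when v_r = 0), so yearly total migrants ~ Poisson(2 * lambda)
        params = quiet_params(r_d=0.5, beta=0.03)
        trials = 300
        summary = run_simulation(two_patch, params, SimConfig(tmax=30, trials=trials, seed=9))
        lam = 0.03 * 100.0 * np.exp(-0.01 * 100.0)
        resp = response_variables(summary, t=25)
        se = np.sqrt(2 * lam / trials)
        assert abs(resp["mcol25"] - 2 * lam) < 3 * se

    def test_out_of_range_year_rejected(self):
        land = single_patch(50.0)
        summary = run_simulation(land, quiet_params(), SimConfig(tmax=20, trials=2, seed=0))
        with pytest.raises(ValueError):
            response_variables(summary, t=25)


class TestSaveRun:
    def test_writes_all_outputs(self, tmp_path):
        land = single_patch(50.0)
        params = quiet_params()
        config = SimConfig(tmax=30, trials=4, seed=0)
        summary = run_simulation(land, params, config)
        from metapva import save_run

        save_run(summary, tmp_path, params=params, config=config)
        for name in (
            "summary.csv",
            "occupancy.csv",
            "extinction_years.csv",
            "response.json",
            "run_log.json",
        ):
            assert (tmp_path / name).exists()
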