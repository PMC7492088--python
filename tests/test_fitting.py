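import math

import numpy as np
import pytest

from shoalforage.environments import generate_random_field
from shoalforage.fitting import (CellEnsemble, ObservedGroup, _standardize,
                                 combined_error_and_select,
                                 consumption_log_likelihood, fit_model,
                                 simulate_parameter_grid, statistic_errors)
from shoalforage.simulate import SimulationConfig, run_simulation


class TestStatisticErrors:
    def test_exact_match_zero_error(self):
        assert statistic_errors(np.array([0.4, 0.5, 0.6]), 0.5) == 0.0

    def test_one_sd_deviation_equals_sd(self, rng):
        sim = rng.normal(0.5, 0.1, 2000)
        sd = sim.std(ddof=1)
        err = statistic_errors(sim, sim.mean() + sd)
        assert err == pytest.approx(sd, rel=1e-9)

    def test_always_non_negative(self, rng):
        for _ in range(20):
            sim = rng.normal(rng.uniform(-2, 2), rng.uniform(0.01, 1), 50)
            assert statistic_errors(sim, rng.uniform(-3, 3)) >= 0

    def test_zero_variance_sentinel(self):
        assert statistic_errors(np.array([1.0, 1.0]), 2.0) == math.inf
        assert statistic_errors(np.array([1.0, 1.0]), 1.0) == 0.0


class TestConsumptionLikelihood:
    def _ensemble(self, rng, reps=200, n_flakes=5):
        return [np.sort(10.0 + 5.0 * np.arange(n_flakes) + rng.normal(0, 1.0, n_flakes))
                for _ in range(reps)]

    def test_data_at_mode_beats_shifted_data(self, rng):
        sims = self._ensemble(rng)
        center = np.mean(sims, axis=0)
        sd = np.std(sims, axis=0)
        assert (consumption_log_likelihood(sims, center)
                > consumption_log_likelihood(sims, center + 3 * sd))

    def test_degenerate_ensemble_finite_at_point_mass(self):
        sims = [np.array([7.0])] * 50
        ll = consumption_log_likelihood(sims, np.array([7.0]))
        assert np.isfinite(ll)
        assert ll > consumption_log_likelihood(sims, np.array([8.0]))

    def test_shift_scan_maximized_at_zero(self, rng):
        sims = self._ensemble(rng, reps=500)
        data = np.mean(sims, axis=0)
        shifts = np.linspace(-3, 3, 61)
        lls = [consumption_log_likelihood(sims, data + s) for s in shifts]
        assert abs(shifts[int(np.argmax(lls))]) <= 0.2

    def test_rep_count_convergence(self, rng):
        data = np.array([10.0, 15.0, 20.0])
        def draw(reps, r):
            return [np.sort(data + r.normal(0, 1.0, 3)) for _ in range(reps)]
        a = consumption_log_likelihood(draw(1000, np.random.default_rng(1)), data)
        b = consumption_log_likelihood(draw(2000, np.random.default_rng(2)), data)
        assert a == pytest.approx(b, abs=0.5)

    def test_unreached_flake_index_floored(self):
        sims = [np.array([5.0]), np.array([5.5])]
        ll_full = consumption_log_likelihood(sims, np.array([5.2]))
        ll_extra = consumption_log_likelihood(sims, np.array([5.2, 9.0]))
        assert ll_extra < ll_full + math.log(1e-11)


def _fake_cell(df, dn, data_times, pol, dnn, rng, off=0.0):
    times = [np.sort(data_times + rng.normal(off, 1.0, data_times.size))
             for _ in range(40)]
    return CellEnsemble(df, dn, times,
                        rng.normal(pol + off / 10, 0.02, 40),
                        rng.normal(dnn + off, 0.1, 40))


class TestCombinedSelection:
    def test_dominating_cell_selected(self, rng):
        data = np.array([10.0, 20.0, 30.0])
        obs = ObservedGroup(
            field=generate_random_field(3, seed=0),
            step_dists=None, consumption_times_s=data,
            polarity=0.5, dnn=5.0, k=3,
            polarity_sd=0.1, dnn_sd=1.0)
        cells = {
            (2.0, 5.0): _fake_cell(2.0, 5.0, data, 0.5, 5.0, rng, off=0.0),
            (3.0, 5.0): _fake_cell(3.0, 5.0, data, 0.5, 5.0, rng, off=4.0),
            (2.0, 10.0): _fake_cell(2.0, 10.0, data, 0.5, 5.0, rng, off=6.0),
        }
        surface = combined_error_and_select(cells, obs, model="test")
        assert (surface.best_df, surface.best_dn) == (2.0, 5.0)
        assert surface.table["is_best"].sum() == 1

    def test_standardized_grids_zero_mean_unit_sd(self, rng):
        data = np.array([10.0, 20.0])
        obs = ObservedGroup(
            field=generate_random_field(2, seed=1),
            step_dists=None, consumption_times_s=data,
            polarity=0.5, dnn=5.0, k=3, polarity_sd=0.1, dnn_sd=1.0)
        cells = {(float(df), 5.0): _fake_cell(float(df), 5.0, data, 0.45, 4.0,
                                              rng, off=df / 2)
                 for df in range(1, 7)}
        surface = combined_error_and_select(cells, obs)
        for col in ("z_cons", "z_pol", "z_dnn"):
            assert surface.table[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert surface.table[col].std(ddof=0) == pytest.approx(1.0, rel=1e-9)

    def test_standardization_affine_invariant(self, rng):
        x = rng.normal(0, 1, 30)
        np.testing.assert_allclose(_standardize(x), _standardize(3.5 * x + 10.0),
                                   atol=1e-9)


class TestGridSimulation:
    def _observed(self, seed=0):
        field = generate_random_field(6, seed=3)
        cfg = SimulationConfig(k=3, model="ind", df=4, seed=seed, max_ticks=4000)
        rec = run_simulation(cfg, field, record_trajectory=True)
        return ObservedGroup.from_record(rec)

    def test_ind_grid_is_dn_zero_column(self):
        obs = self._observed()
        cells = simulate_parameter_grid(obs, "ind", df_grid=(2, 4), reps=3, seed=1)
        assert set(cells) == {(2.0, 0.0), (4.0, 0.0)}

    def test_social_grid_cartesian(self):
        obs = self._observed()
        cells = simulate_parameter_grid(obs, "att_feed_align", df_grid=(2, 3),
                                        dn_grid=(5, 10), reps=2, seed=1)
        assert len(cells) == 4

    def test_same_master_seed_identical_ensembles(self):
        obs = self._observed()
        a = simulate_parameter_grid(obs, "ind", df_grid=(3,), reps=4, seed=9)
        b = simulate_parameter_grid(obs, "ind", df_grid=(3,), reps=4, seed=9)
        for key in a:
            for ta, tb in zip(a[key].times, b[key].times):
                np.testing.assert_array_equal(ta, tb)

    def test_empty_consumption_log_rejected(self):
        field = generate_random_field(6, seed=3)
        with pytest.raises(ValueError, match="empty"):
            ObservedGroup(field=field, step_dists=None,
                          consumption_times_s=np.array([]),
                          polarity=0.5, dnn=3.0, k=3)


class TestModelPreference:
    def test_ind_generated_group_prefers_ind_over_social(self):
        """The combined report error of the IND fit beats Att_feed+Align on
        IND-generated data in a majority of seeds."""
        field = generate_random_field(12, seed=2)
        wins = 0
        n_seeds = 3
        for seed in range(n_seeds):
            cfg = SimulationConfig(k=3, model="ind", df=3, seed=100 + seed)
            obs = ObservedGroup.from_record(
                run_simulation(cfg, field, record_trajectory=True))
            fit_ind = fit_model(obs, "ind", df_grid=(2, 3, 4), reps=10,
                                seed=200 + seed)
            fit_soc = fit_model(obs, "att_feed_align", df_grid=(2, 3, 4),
                                dn_grid=(6, 12, 18), reps=10, seed=300 + seed)
            def report(surface):
                row = surface.table[surface.table["is_best"]].iloc[0]
                return (abs(row["report_e_pol"]) + abs(row["report_e_dnn"])
                        + row["report_e_cons"])
            wins += report(fit_ind) <= report(fit_soc)
        assert wins >= 2
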