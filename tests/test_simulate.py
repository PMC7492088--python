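import math
import random

import numpy as np
import pytest

from shoalforage.environments import FlakeField, generate_clustered_field
from shoalforage.kinematics import StepDistributions
from shoalforage.simulate import (MODELS, SimulationConfig, _SimState,
                                  advance_group, bouts_to_seconds, draw_bout,
                                  flake_response, make_mixed_group,
                                  run_ensemble, run_simulation, social_response)


def single_sample_dist(L=3.0, theta=10.0):
    return StepDistributions.from_samples(np.array([L]), np.array([theta]))


class TestDrawBout:
    def test_single_sample_is_deterministic(self):
        dist = single_sample_dist(3.0, 10.0)
        rng = random.Random(0)
        assert draw_bout(dist, rng) == (3.0, 10.0)

    def test_empirical_resampling_consistency(self, rng):
        samples = rng.gamma(2.0, 1.5, 500)
        dist = StepDistributions.from_samples(samples, rng.normal(0, 50, 500))
        r = random.Random(1)
        draws = [dist.draw_length(r) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(samples.mean(), rel=0.03)

    def test_parametric_draws_strictly_positive(self):
        dist = StepDistributions.from_moments(2.85, 1.7, 50.0)
        r = random.Random(2)
        assert all(dist.draw_length(r) > 0 for _ in range(5000))


class TestFlakeResponse:
    def test_zero_distance_always_fires(self):
        rng = random.Random(0)
        for _ in range(200):
            resp = flake_response(1.0, 1.0, [1.0], [1.0], [0], 3.0, rng)
            assert resp is not None

    def test_beyond_range_never_fires(self):
        rng = random.Random(0)
        for _ in range(200):
            assert flake_response(0.0, 0.0, [10.0], [0.0], [0], 3.0, rng) is None

    def test_fire_rate_at_df_is_exp_minus_one(self):
        rng = random.Random(3)
        n = 20_000
        hits = sum(flake_response(0.0, 0.0, [3.0 - 1e-9], [0.0], [0], 3.0, rng)
                   is not None for _ in range(n))
        assert hits / n == pytest.approx(math.exp(-1), abs=0.01)


class TestSocialResponse:
    def test_align_averages_neighbor_headings(self):
        rng = random.Random(0)
        got = None
        for _ in range(500):
            got = social_response(0, [0.0, 1.0, -1.0], [0.0, 0.0, 0.0],
                                  [0.0, 1.0, 0.0], [0.0, 0.0, 1.0],
                                  10.0, "align", rng)
            if got is not None:
                break
        assert got is not None
        assert got[0] == pytest.approx(math.sqrt(0.5))
        assert got[1] == pytest.approx(math.sqrt(0.5))

    def test_no_neighbor_within_range(self):
        rng = random.Random(0)
        for mode in ("att", "align", "zoned"):
            assert social_response(0, [0.0, 50.0], [0.0, 0.0],
                                   [1.0, 1.0], [0.0, 0.0], 5.0, mode, rng) is None

    def test_att_points_to_center_of_mass(self):
        rng = random.Random(1)
        got = None
        for _ in range(500):
            got = social_response(0, [0.0, 2.0, 2.0], [0.0, 1.0, -1.0],
                                  [1.0, 1.0, 1.0], [0.0, 0.0, 0.0],
                                  30.0, "att", rng)
            if got is not None:
                break
        assert got == pytest.approx((1.0, 0.0))


def small_field(n=6, seed=0, radius=32.0):
    rng = np.random.default_rng(seed)
    r = radius * 0.8 * np.sqrt(rng.random(n))
    phi = 2 * np.pi * rng.random(n)
    return FlakeField(x=r * np.cos(phi), y=r * np.sin(phi), arena_radius=radius)


class TestAdvanceAndRun:
    def test_seed_determinism(self):
        field = small_field()
        cfg = SimulationConfig(k=3, model="att_feed_align", df=3, dn=10, seed=5)
        a = run_simulation(cfg, field, record_trajectory=False)
        b = run_simulation(cfg, field, record_trajectory=False)
        assert a.consumptions == b.consumptions
        assert a.n_ticks == b.n_ticks

    def test_zero_flakes_terminates_at_max_ticks(self):
        field = FlakeField(x=np.array([]), y=np.array([]))
        cfg = SimulationConfig(k=2, model="ind", df=3, max_ticks=50, seed=0)
        rec = run_simulation(cfg, field, record_trajectory=False)
        assert rec.consumptions == []
        assert rec.n_ticks == 50

    def test_agents_stay_inside_arena(self):
        cfg = SimulationConfig(
            k=2, model="ind", df=3, max_ticks=300, seed=1,
            initial_positions=np.array([[31.5, 0.0], [0.0, -31.5]]))
        rec = run_simulation(cfg, small_field(), record_trajectory=True)
        radii = np.linalg.norm(rec.positions, axis=-1)
        assert np.all(radii < cfg.arena_radius)

    def test_near_flake_consumed_with_high_probability(self):
        # one IND agent, flake 0.3 BL ahead, Df = 3, step length >= distance:
        # orientation fires w.p. exp(-0.1) ~ 0.905 and capture is then certain
        field = FlakeField(x=np.array([0.3]), y=np.array([0.0]))
        hits = 0
        n = 1000
        for s in range(n):
            cfg = SimulationConfig(
                k=1, model="ind", df=3.0, max_ticks=1, seed=s,
                step_dists=single_sample_dist(3.0, 0.0),
                initial_positions=np.array([[0.0, 0.0]]))
            rec = run_simulation(cfg, field, record_trajectory=False)
            hits += len(rec.consumptions)
        assert hits / n >= 0.88

    def test_flake_conservation_every_tick(self):
        field = FlakeField(x=[3.0, -4.0, 0.0, 5.0], y=[0.0, 2.0, -3.0, 5.0],
                           parent=[-1, -1, 0, 1])
        cfg = SimulationConfig(k=3, model="att_feed", df=8, dn=10, seed=2,
                               max_ticks=2000)
        rng = random.Random(7)
        state = _SimState(cfg, field, rng)
        strategies = [MODELS[s] for s in cfg.agent_strategies()]
        dists = cfg.agent_step_dists()
        for _ in range(cfg.max_ticks):
            advance_group(state, cfg, strategies, dists)
            pending = sum(1 for s in state.status if s == 0)
            live = sum(1 for s in state.status if s == 1)
            consumed = sum(1 for s in state.status if s == 2)
            assert pending + live + consumed == field.n_flakes
            assert live == len(state.live)
            assert consumed == state.consumed_count
            if state.consumed_count == field.n_flakes:
                break
        assert state.consumed_count == field.n_flakes

    def test_child_flake_waits_for_parent(self):
        field = FlakeField(x=[3.0, 10.0], y=[0.0, 0.0], parent=[-1, 0])
        cfg = SimulationConfig(k=1, model="ind", df=20, seed=3, max_ticks=500)
        rec = run_simulation(cfg, field, record_trajectory=False)
        assert [c.flake for c in rec.consumptions] == [0, 1]

    def test_ind_results_independent_of_stored_dn(self):
        field = small_field(8, seed=4)
        base = dict(k=3, df=2, seed=9, max_ticks=3000,
                    strategies=["ind", "ind", "ind"])
        a = run_simulation(SimulationConfig(dn=0.0, **base), field,
                           record_trajectory=False)
        b = run_simulation(SimulationConfig(dn=17.0, **base), field,
                           record_trajectory=False)
        assert a.consumptions == b.consumptions

    def test_completion_monotone_in_df(self):
        field = small_field(6, seed=6)
        ticks = {}
        for df in (2.0, 40.0):
            cfg = SimulationConfig(k=1, model="ind", df=df, seed=0)
            recs = run_ensemble(cfg, field, 100, master_seed=55)
            assert all(r.all_consumed for r in recs)
            ticks[df] = np.mean([r.n_ticks for r in recs])
        assert ticks[40.0] < ticks[2.0]

    def test_social_range_speeds_up_clustered_foraging(self):
        # for small Df the consumption rate increases with Dn under
        # Att_feed+Align on clustered flakes
        field = generate_clustered_field(1, 18, seed=1)
        mean_ticks = {}
        for dn in (5.0, 25.0):
            cfg = SimulationConfig(k=3, model="att_feed_align", df=2, dn=dn, seed=0)
            recs = run_ensemble(cfg, field, 40, master_seed=77)
            mean_ticks[dn] = np.mean([r.n_ticks for r in recs])
        assert mean_ticks[25.0] < mean_ticks[5.0]


class TestTimeConversion:
    def test_single_bout_arithmetic(self):
        field = FlakeField(x=np.array([1.0]), y=np.array([0.0]))
        cfg = SimulationConfig(k=1, model="ind", df=20, seed=0, max_ticks=50,
                               step_dists=single_sample_dist(3.0, 0.0),
                               initial_positions=np.array([[0.0, 0.0]]))
        rec = run_simulation(cfg, field, record_trajectory=False)
        assert rec.all_consumed
        t6 = bouts_to_seconds(rec, 6.0)
        t12 = bouts_to_seconds(rec, 12.0)
        np.testing.assert_allclose(t6, 2 * t12)

    def test_rejects_nonpositive_speed(self):
        field = small_field(2)
        cfg = SimulationConfig(k=1, model="ind", df=3, seed=0, max_ticks=10)
        rec = run_simulation(cfg, field, record_trajectory=False)
        with pytest.raises(ValueError):
            bouts_to_seconds(rec, 0.0)

    def test_empty_record_empty_times(self):
        field = FlakeField(x=np.array([]), y=np.array([]))
        cfg = SimulationConfig(k=1, model="ind", df=3, seed=0, max_ticks=5)
        rec = run_simulation(cfg, field, record_trajectory=False)
        assert bouts_to_seconds(rec, 4.0).size == 0


class TestMixedGroups:
    def test_extremes(self):
        cfg = SimulationConfig(k=3, model="att_feed_align", df=3, dn=10, seed=0)
        all_ind = make_mixed_group(cfg, 0)
        assert all_ind.agent_strategies() == ["ind"] * 3
        assert all_ind.dn == 0.0
        all_social = make_mixed_group(cfg, 3)
        assert all_social.agent_strategies() == ["att_feed_align"] * 3

    def test_one_social_of_three_attributable(self):
        cfg = SimulationConfig(k=3, model="att_feed_align", df=3, dn=10, seed=4)
        mixed = make_mixed_group(cfg, 1, seed=8)
        assert sum(s != "ind" for s in mixed.strategies) == 1
        rec = run_simulation(mixed, generate_clustered_field(1, 18, seed=2),
                             record_trajectory=False)
        assert rec.per_agent_counts().sum() == len(rec.consumptions)

    def test_invalid_counts_rejected(self):
        cfg = SimulationConfig(k=3, model="att_feed_align", df=3, dn=10)
        with pytest.raises(ValueError):
            make_mixed_group(cfg, 4)


class TestConfigValidation:
    def test_dn_zero_iff_ind(self):
        with pytest.raises(ValueError):
            SimulationConfig(k=3, model="ind", df=3, dn=5)
        with pytest.raises(ValueError):
            SimulationConfig(k=3, model="att", df=3, dn=0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(k=3, model="flock", df=3)
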