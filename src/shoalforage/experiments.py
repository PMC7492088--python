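"""Canned simulation experiments over the (Df, Dn) interaction-range grid.

These drive the package-level analyses: exponential consumption-curve
quality across models and flake distributions, the individual advantage of
a lone social forager in mixed-strategy groups, and parameter recovery of
the fitting pipeline on simulated ground truth.  Scales (grid extents,
repetition counts) default to desk-size versions of the full sweeps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .environments import generate_clustered_field, generate_random_field
from .fitting import ObservedGroup, fit_model
from .simulate import (SimulationConfig, make_mixed_group, run_ensemble,
                       run_simulation)
from .stats import fit_consumption_curve


def consumption_curve_grid(seed: int = 0, group_sizes=(3, 6),
                           df_grid=(1, 2, 3, 4, 5),
                           dn_grid=(0, 5, 10, 15, 20, 25),
                           n_flakes: int = 18, reps: int = 20,
                           max_ticks: int = 20_000) -> pd.DataFrame:
    """Fit log T(n) = n*b + a to mean consumption times for every cell of a
    simulator sweep (IND at Dn = 0, Att_feed+Align at Dn > 0) over clustered
    and random flake fields.

    Mean times are taken per flake index over the repetitions (restricted
    to the indices all repetitions reached).  Returns one row per cell with
    the fitted slope b, intercept a, and r^2.
    """
    rng_seed = np.random.SeedSequence(seed)
    field_seeds = rng_seed.generate_state(2)
    fields = {
        "clustered": generate_clustered_field(1, n_flakes,
                                              seed=int(field_seeds[0]) & 0x7FFFFFFF),
        "random": generate_random_field(n_flakes,
                                        seed=int(field_seeds[1]) & 0x7FFFFFFF),
    }
    rows = []
    cell_seed = 0
    for field_name, field in fields.items():
        for k in group_sizes:
            for df in df_grid:
                for dn in dn_grid:
                    cell_seed += 1
                    model = "ind" if dn == 0 else "att_feed_align"
                    cfg = SimulationConfig(k=k, model=model, df=float(df),
                                           dn=float(dn), seed=seed,
                                           max_ticks=max_ticks)
                    recs = run_ensemble(cfg, field, reps,
                                        master_seed=seed * 100_003 + cell_seed)
                    n_common = min(len(r.consumptions) for r in recs)
                    times = np.array([r.consumption_times_s()[:n_common]
                                      for r in recs]).mean(axis=0)
                    fit = fit_consumption_curve(times)
                    rows.append({
                        "field": field_name, "k": k, "model": model,
                        "df": df, "dn": dn, "b": fit.slope, "a": fit.intercept,
                        "r2": fit.r_squared, "n_fitted": n_common,
                        "mean_time": float(np.mean(times)),
                        "completed": all(r.all_consumed for r in recs),
                    })
    return pd.DataFrame(rows)


def mixed_group_advantage(seed: int = 0, group_sizes=(3, 6),
                          df_grid=(1, 2, 3, 4, 5),
                          dn_grid=(5, 10, 15, 20, 25),
                          n_flakes: int = 18, reps: int = 100,
                          max_ticks: int = 20_000) -> pd.DataFrame:
    """Per-capita advantage of a lone Att_feed+Align forager over its
    independent companions in mixed-strategy groups on a clustered field.

    For each (k, Df, Dn) cell, ``reps`` seeded simulations are run with one
    social agent; the excess is the social agent's mean flake count divided
    by the companions' mean count, minus one, in percent.
    """
    field = generate_clustered_field(
        1, n_flakes, seed=int(np.random.SeedSequence(seed).generate_state(1)[0]) & 0x7FFFFFFF)
    rows = []
    cell_seed = 0
    for k in group_sizes:
        for df in df_grid:
            for dn in dn_grid:
                cell_seed += 1
                cfg = SimulationConfig(k=k, model="att_feed_align",
                                       df=float(df), dn=float(dn), seed=seed,
                                       max_ticks=max_ticks)
                mixed = make_mixed_group(cfg, 1, seed=seed * 7919 + cell_seed)
                social = next(i for i, s in enumerate(mixed.strategies)
                              if s != "ind")
                recs = run_ensemble(mixed, field, reps,
                                    master_seed=seed * 99_991 + cell_seed)
                counts = np.array([r.per_agent_counts() for r in recs])
                others = [i for i in range(k) if i != social]
                social_mean = counts[:, social].mean()
                ind_mean = counts[:, others].mean()
                rows.append({
                    "k": k, "df": df, "dn": dn,
                    "social_mean": social_mean, "ind_mean": ind_mean,
                    "excess_pct": 100.0 * (social_mean / ind_mean - 1.0),
                })
    return pd.DataFrame(rows)


def parameter_recovery(seed: int = 0, n_replicates: int = 10,
                       true_df: float = 3.0, true_dn: float = 12.0,
                       df_grid=tuple(range(1, 8)),
                       dn_grid=tuple(range(4, 21, 2)),
                       k: int = 3, n_flakes: int = 18,
                       reps: int = 20) -> pd.DataFrame:
    """Ground-truth recovery of the fitting pipeline.

    Each replicate synthesizes an "observed" Att_feed+Align group at
    (true_df, true_dn) on a CSR-certified random field (where both ranges
    shape the observables throughout the run), fits the full pipeline over
    the reduced grid, and records the selected cell and its grid-index
    distance from the truth.
    """
    field = generate_random_field(
        n_flakes, seed=int(np.random.SeedSequence(seed).generate_state(1)[0]) & 0x7FFFFFFF)
    df_list, dn_list = list(df_grid), list(dn_grid)
    i_df, i_dn = df_list.index(true_df), dn_list.index(true_dn)
    rows = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(k=k, model="att_feed_align", df=true_df,
                               dn=true_dn, seed=seed * 1009 + rep)
        obs = ObservedGroup.from_record(
            run_simulation(cfg, field, record_trajectory=True))
        surface = fit_model(obs, "att_feed_align", df_grid=df_grid,
                            dn_grid=dn_grid, reps=reps,
                            seed=seed * 2003 + rep)
        d_df = abs(df_list.index(surface.best_df) - i_df)
        d_dn = abs(dn_list.index(surface.best_dn) - i_dn)
        rows.append({"replicate": rep, "best_df": surface.best_df,
                     "best_dn": surface.best_dn, "cells_off_df": d_df,
                     "cells_off_dn": d_dn,
                     "recovered": d_df <= 2 and d_dn <= 2})
    return pd.DataFrame(rows)
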