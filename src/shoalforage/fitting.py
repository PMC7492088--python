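"""Simulation-based fitting of foraging models to observed groups.

For every cell of a (Df, Dn) grid, an ensemble of simulations is run from
the observed group's initial conditions, flake field and per-fish step
distributions.  Three errors are computed per cell:

* ``e_cons``: minus the log-likelihood of the observed consumption-time
  sequence.  The likelihood of the i-th observed time is the kernel-smoothed
  density of the i-th consumption time across the simulation ensemble, and
  the sequence likelihood is the product over events.
* ``e_pol`` / ``e_dnn``: normalized squared errors of group polarity and
  nearest-neighbor distance, E = (<S_sim> - S_obs)^2 / SD(S_sim).

The three error surfaces are standardized across grid cells (mean 0, SD 1
over finite cells) and summed into a combined error whose grid argmin is
the selected fit (ties broken toward smaller Dn, then smaller Df).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .environments import FlakeField
from .kinematics import StepDistributions
from .simulate import (SimulationConfig, SimulationRecord, ensemble_seeds,
                       run_simulation)
from .stats import group_polarity_and_cohesion

DF_GRID_DEFAULT = tuple(range(1, 21))
DN_GRID_DEFAULT = tuple(range(1, 26))
DENSITY_FLOOR = 1e-12


@dataclass
class ObservedGroup:
    """The data a fit conditions on: initial positions, flake field, step
    distributions, the ordered consumption times, and swimming statistics
    (with their across-frame SDs, used by the reporting metrics)."""

    field: FlakeField
    step_dists: StepDistributions | list[StepDistributions]
    consumption_times_s: np.ndarray
    polarity: float
    dnn: float
    k: int
    initial_positions: np.ndarray | None = None
    avg_speed: float = 4.0
    polarity_sd: float = float("nan")
    dnn_sd: float = float("nan")

    def __post_init__(self) -> None:
        self.consumption_times_s = np.sort(np.asarray(self.consumption_times_s, dtype=float))
        if self.consumption_times_s.size == 0:
            raise ValueError("observed group has an empty consumption log")

    @classmethod
    def from_record(cls, record: SimulationRecord) -> "ObservedGroup":
        """Treat a simulation record as the observed group (used for
        parameter-recovery experiments on synthetic ground truth)."""
        gs = group_polarity_and_cohesion(record)
        pol_series = np.linalg.norm(record.headings.mean(axis=1), axis=1)
        diff = record.positions[:, :, None, :] - record.positions[:, None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        kk = record.config.k
        d[:, np.arange(kk), np.arange(kk)] = np.inf
        dnn_series = d.min(axis=2).mean(axis=1)
        return cls(
            field=record.field,
            step_dists=record.config.step_dists,
            consumption_times_s=record.consumption_times_s(),
            polarity=gs.polarity, dnn=gs.dnn, k=kk,
            initial_positions=record.positions[0].copy(),
            avg_speed=record.config.avg_speed,
            polarity_sd=float(pol_series.std(ddof=1)),
            dnn_sd=float(dnn_series.std(ddof=1)),
        )


@dataclass
class CellEnsemble:
    """Per-(Df, Dn) simulation ensemble summaries."""

    df: float
    dn: float
    times: list[np.ndarray]      # ordered consumption times per repetition
    polarity: np.ndarray
    dnn: np.ndarray


@dataclass
class FitSurface:
    """Error grids and the selected best fit of one model."""

    model: str
    table: pd.DataFrame
    best_df: float = float("nan")
    best_dn: float = float("nan")
    ensembles: dict = dc_field(default_factory=dict)


def simulate_parameter_grid(observed: ObservedGroup, model: str,
                            df_grid=DF_GRID_DEFAULT, dn_grid=None,
                            reps: int = 100, seed: int = 0,
                            tau: int = 5, max_ticks: int = 10_000,
                            arena_radius: float | None = None) -> dict[tuple[float, float], CellEnsemble]:
    """Simulation ensembles for every (Df, Dn) grid cell.

    The IND model has no neighbor detection, so its grid is the Dn = 0
    column only.  The same master seed yields identical ensembles.
    """
    if dn_grid is None:
        dn_grid = (0,) if model == "ind" else DN_GRID_DEFAULT
    arena = arena_radius if arena_radius is not None else observed.field.arena_radius
    cells: dict[tuple[float, float], CellEnsemble] = {}
    seeds = ensemble_seeds(seed, reps)
    for df in df_grid:
        for dn in dn_grid:
            cfg = SimulationConfig(
                k=observed.k, model=model, df=float(df), dn=float(dn), tau=tau,
                arena_radius=arena, step_dists=observed.step_dists,
                avg_speed=observed.avg_speed, max_ticks=max_ticks,
                initial_positions=observed.initial_positions, seed=seed,
            )
            times, pol, dnn = [], [], []
            for s in seeds:
                rec = run_simulation(cfg, observed.field, seed=s,
                                     record_trajectory=True)
                times.append(rec.consumption_times_s())
                gs = group_polarity_and_cohesion(rec)
                pol.append(gs.polarity)
                dnn.append(gs.dnn)
            cells[(float(df), float(dn))] = CellEnsemble(
                float(df), float(dn), times, np.array(pol), np.array(dnn))
    return cells


def _kde_log_density(samples: np.ndarray, x: float) -> float:
    """Gaussian kernel density at x with Silverman bandwidth, floored at 1%
    of the sample median (degenerate zero-variance ensembles stay finite)."""
    n = samples.size
    sd = samples.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2) if spread > 0 else 0.0
    h = max(h, 0.01 * float(np.median(samples)), 1e-9)
    dens = float(np.mean(np.exp(-0.5 * ((x - samples) / h) ** 2))) / (h * math.sqrt(2 * math.pi))
    return math.log(max(dens, DENSITY_FLOOR))


def consumption_log_likelihood(sim_times: list[np.ndarray],
                               data_times: np.ndarray) -> float:
    """log P(T_data) = sum_i log P(T_data(i)) where P is the kernel-smoothed
    density of the i-th consumption time over the simulation repetitions.

    Flake indices that fewer than two repetitions ever reached contribute
    the floored density (the model effectively rules them out).
    """
    data_times = np.asarray(data_times, dtype=float)
    total = 0.0
    for i, t in enumerate(data_times):
        samples = np.array([rep[i] for rep in sim_times if len(rep) > i])
        if samples.size < 2:
            total += math.log(DENSITY_FLOOR)
        else:
            total += _kde_log_density(samples, float(t))
    return total


def statistic_errors(sim_values: np.ndarray, observed: float) -> float:
    """Normalized squared error E = (<S_sim> - S_obs)^2 / SD(S_sim); a
    zero-variance ensemble yields +inf (the cell cannot explain any
    deviation)."""
    sim_values = np.asarray(sim_values, dtype=float)
    sd = float(sim_values.std(ddof=1)) if sim_values.size > 1 else 0.0
    if sd <= 0:
        return math.inf if abs(float(sim_values.mean()) - observed) > 0 else 0.0
    return (float(sim_values.mean()) - observed) ** 2 / sd


def _standardize(values: np.ndarray) -> np.ndarray:
    """Z-score over finite cells; infinite cells pass through untouched."""
    out = np.array(values, dtype=float)
    finite = np.isfinite(out)
    if not np.any(finite):
        raise ValueError("error grid is entirely non-finite")
    mu = out[finite].mean()
    sd = out[finite].std()
    if sd > 0:
        out[finite] = (out[finite] - mu) / sd
    else:
        out[finite] = 0.0
    return out


def combined_error_and_select(cells: dict[tuple[float, float], CellEnsemble],
                              observed: ObservedGroup,
                              model: str = "") -> FitSurface:
    """Standardize the three error grids, sum them, and select the argmin
    cell (ties toward smaller Dn, then smaller Df).

    The table also carries the report-style metrics: signed polarity / Dnn
    deviations scaled by the observed across-frame SD, and the mean squared
    log-time error of the mean simulated consumption curve.
    """
    keys = sorted(cells.keys(), key=lambda c: (c[0], c[1]))
    e_cons, e_pol, e_dnn, rep_pol, rep_dnn, rep_cons = [], [], [], [], [], []
    for key in keys:
        cell = cells[key]
        e_cons.append(-consumption_log_likelihood(cell.times, observed.consumption_times_s))
        e_pol.append(statistic_errors(cell.polarity, observed.polarity))
        e_dnn.append(statistic_errors(cell.dnn, observed.dnn))
        # reporting metrics (not used for selection)
        p_sd = observed.polarity_sd if observed.polarity_sd > 0 else float("nan")
        d_sd = observed.dnn_sd if observed.dnn_sd > 0 else float("nan")
        rep_pol.append((observed.polarity - cell.polarity.mean()) / p_sd)
        rep_dnn.append((observed.dnn - cell.dnn.mean()) / d_sd)
        n_data = observed.consumption_times_s.size
        mean_t = []
        for i in range(n_data):
            s = [rep[i] for rep in cell.times if len(rep) > i]
            mean_t.append(np.mean(s) if s else np.nan)
        mean_t = np.asarray(mean_t)
        good = np.isfinite(mean_t) & (mean_t > 0)
        if np.any(good):
            rep_cons.append(float(np.mean(
                (np.log(observed.consumption_times_s[good]) - np.log(mean_t[good])) ** 2)))
        else:
            rep_cons.append(float("nan"))

    z_cons = _standardize(np.array(e_cons))
    z_pol = _standardize(np.array(e_pol))
    z_dnn = _standardize(np.array(e_dnn))
    combined = z_cons + z_pol + z_dnn

    finite = np.isfinite(combined)
    if not np.any(finite):
        raise ValueError("combined error grid entirely non-finite")
    order = sorted(range(len(keys)),
                   key=lambda i: (not finite[i],
                                  combined[i] if finite[i] else math.inf,
                                  keys[i][1], keys[i][0]))
    best_i = order[0]
    table = pd.DataFrame({
        "df": [k[0] for k in keys], "dn": [k[1] for k in keys],
        "e_cons": e_cons, "e_pol": e_pol, "e_dnn": e_dnn,
        "z_cons": z_cons, "z_pol": z_pol, "z_dnn": z_dnn,
        "e_combined": combined,
        "report_e_pol": rep_pol, "report_e_dnn": rep_dnn,
        "report_e_cons": rep_cons,
    })
    table["is_best"] = False
    table.loc[best_i, "is_best"] = True
    return FitSurface(model=model, table=table,
                      best_df=keys[best_i][0], best_dn=keys[best_i][1],
                      ensembles=cells)


def fit_model(observed: ObservedGroup, model: str,
              df_grid=DF_GRID_DEFAULT, dn_grid=None,
              reps: int = 100, seed: int = 0, tau: int = 5,
              max_ticks: int = 10_000) -> FitSurface:
    """Full pipeline: simulate the grid, score every cell, select the fit."""
    cells = simulate_parameter_grid(observed, model, df_grid=df_grid,
                                    dn_grid=dn_grid, reps=reps, seed=seed,
                                    tau=tau, max_ticks=max_ticks)
    return combined_error_and_select(cells, observed, model=model)


def combine_report_errors(per_model: dict[str, tuple[float, float, float]]) -> pd.DataFrame:
    """[0,1]-scaled combined reporting error across models:
    each of (e_pol, e_dnn, e_cons) is divided by its largest observed
    magnitude across models and the three are averaged."""
    models = list(per_model)
    arr = np.array([[abs(v) for v in per_model[m]] for m in models], dtype=float)
    scale = arr.max(axis=0)
    scale[scale == 0] = 1.0
    scaled = arr / scale
    return pd.DataFrame({
        "model": models,
        "e_pol_scaled": scaled[:, 0], "e_dnn_scaled": scaled[:, 1],
        "e_cons_scaled": scaled[:, 2],
        "e_combined": scaled.mean(axis=1),
    })
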