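"""Group-level foraging statistics.

* Consumption-curve fitting: the time for a group of k fish to consume its
  n-th flake is well described by log T_k(n) = n*b_k + a_k, with b_k the
  consumption-rate slope (log-seconds per flake; smaller = faster) and a_k
  the log time to the first detection.  Natural logarithms throughout.
* Polarity P = time-average of the norm of the mean heading unit vector
  (1 = fully aligned school, 0 = balanced opposition) and cohesion Dnn =
  time-average of the distance to the nearest neighbor.
* Income equality from the Theil index of the per-fish consumption counts:
  I = (1/k) * sum_i (n_i/mu) log(n_i/mu), equality = 1 - I/log k, ranging
  from 0 (one fish ate everything) to 1 (full equality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import TrajectoryRecording
from .simulate import SimulationRecord


@dataclass
class ConsumptionCurveFit:
    slope: float        # b_k, per-flake log-time slope
    intercept: float    # a_k, log-seconds
    r_squared: float
    n_events: int

    def predict(self, n: np.ndarray) -> np.ndarray:
        """Predicted consumption times T(n) in seconds."""
        return np.exp(self.intercept + self.slope * np.asarray(n, dtype=float))


@dataclass
class GroupStats:
    polarity: float
    dnn: float          # mean nearest-neighbor distance, BL
    mean_speed: float   # BL/s (or BL/tick for simulation records)
    flagged: bool = False


@dataclass
class EqualityResult:
    counts: np.ndarray
    mean: float
    theil: float
    equality: float


def fit_consumption_curve(times: np.ndarray) -> ConsumptionCurveFit:
    """Least-squares fit of log T(n) = n*b + a, flake index n starting at 1.

    Requires at least two strictly positive, non-decreasing times; the
    reported r-squared is that of the log-time regression (1.0 for a
    degenerate zero-variance fit that the line matches exactly).
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 consumption events to fit")
    if np.any(times <= 0):
        raise ValueError("consumption times must be strictly positive")
    if np.any(np.diff(times) < -1e-9):
        raise ValueError("consumption times must be non-decreasing")
    n = np.arange(1, times.size + 1, dtype=float)
    logt = np.log(times)
    slope, intercept = np.polyfit(n, logt, 1)
    resid = logt - (intercept + slope * n)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((logt - logt.mean()) ** 2))
    r2 = 1.0 if ss_tot < 1e-30 else max(0.0, 1.0 - ss_res / ss_tot)
    return ConsumptionCurveFit(float(slope), float(intercept), r2, times.size)


def _polarity_dnn_series(positions: np.ndarray, headings: np.ndarray):
    """Per-frame polarity and mean nearest-neighbor distance."""
    mean_head = headings.mean(axis=1)
    pol = np.linalg.norm(mean_head, axis=1)
    diff = positions[:, :, None, :] - positions[:, None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    k = positions.shape[1]
    d[:, np.arange(k), np.arange(k)] = np.inf
    dnn = d.min(axis=2).mean(axis=1)
    return pol, dnn


def group_polarity_and_cohesion(rec: TrajectoryRecording | SimulationRecord) -> GroupStats:
    """Time-averaged polarity and nearest-neighbor distance of a group.

    For a single fish Dnn is undefined (NaN) and P is trivially 1; the
    result is flagged.  Frame-level statistics are averaged over all frames
    (ticks) of the epoch.
    """
    if isinstance(rec, SimulationRecord):
        if rec.positions is None:
            raise ValueError("simulation was run without trajectory recording")
        positions, headings = rec.positions, rec.headings
        speed = None
    else:
        if rec.heading is None or rec.speed is None:
            raise ValueError("kinematics missing; run compute_kinematics first")
        positions, headings, speed = rec.positions, rec.heading, rec.speed
    k = positions.shape[1]
    if k < 2:
        mean_speed = float(np.mean(speed)) if speed is not None else float("nan")
        return GroupStats(polarity=1.0, dnn=float("nan"),
                          mean_speed=mean_speed, flagged=True)
    pol, dnn = _polarity_dnn_series(positions, headings)
    if speed is not None:
        mean_speed = float(np.mean(speed))
    else:
        steps = np.linalg.norm(np.diff(positions, axis=0), axis=-1)
        mean_speed = float(np.mean(steps))
    return GroupStats(float(pol.mean()), float(dnn.mean()), mean_speed)


def theil_equality(counts: np.ndarray) -> EqualityResult:
    """Theil-index equality of per-fish consumption counts (natural log,
    0*log 0 := 0); equality = 1 - I/log k in [0, 1]."""
    counts = np.asarray(counts, dtype=float)
    k = counts.size
    if k < 2:
        raise ValueError("equality needs at least 2 fish")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("equality undefined when no flakes were consumed")
    mu = total / k
    ratios = counts / mu
    terms = np.where(ratios > 0, ratios * np.log(np.maximum(ratios, 1e-300)), 0.0)
    theil = float(terms.sum() / k)
    equality = 1.0 - theil / math.log(k)
    # clip the exact analytic bounds against float rounding
    equality = min(1.0, max(0.0, equality))
    return EqualityResult(counts=counts, mean=mu, theil=theil, equality=equality)


def efficiency_comparison(social_fits: pd.DataFrame, ind_fits: pd.DataFrame,
                          df_max: float = 5.0) -> pd.DataFrame:
    """Relative foraging improvement of a social model over matched IND runs.

    Both inputs carry one row per parameter cell with columns ``df`` (and
    ``dn`` for the social model), ``b`` (Eq.-style consumption-rate slope)
    and optionally ``mean_time`` (mean time per flake).  Improvement per
    (Df, Dn) cell is the relative reduction of the social slope against the
    IND slope at the same Df: (b_ind - b_soc)/|b_ind| (positive = social
    faster); analogously for mean time per flake.  The returned frame also
    carries a ``df_le_max`` mask used to average over Df <= 5, the range
    where real groups were matched by simulations.
    """
    for frame, cols in ((social_fits, {"df", "dn", "b"}), (ind_fits, {"df", "b"})):
        missing = cols - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
    ind_by_df = ind_fits.set_index("df")
    if set(social_fits["df"].unique()) - set(ind_by_df.index):
        raise ValueError("social and IND ensembles have mismatched Df grids")
    rows = []
    for _, row in social_fits.iterrows():
        ind_row = ind_by_df.loc[row["df"]]
        b_ind = float(ind_row["b"])
        rel_b = (b_ind - float(row["b"])) / abs(b_ind) if b_ind != 0 else np.nan
        rec: dict = {"df": row["df"], "dn": row["dn"], "b_social": row["b"],
                     "b_ind": b_ind, "rate_improvement": rel_b,
                     "df_le_max": row["df"] <= df_max}
        if "mean_time" in social_fits.columns and "mean_time" in ind_fits.columns:
            t_ind = float(ind_row["mean_time"])
            rec["time_improvement"] = (t_ind - float(row["mean_time"])) / t_ind
        rows.append(rec)
    return pd.DataFrame(rows)
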