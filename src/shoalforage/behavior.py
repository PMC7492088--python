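"""Consumption-maneuver analysis.

Fish perform a stereotyped maneuver when consuming food: a transient speed
increase followed by a sharp decrease together with a spike in trajectory
curvature.  This module characterizes that maneuver (event-aligned mean
speed/curvature profiles vs profiles at random trajectory points),
quantifies how strongly the maneuver attracts neighbors to the consumption
location against a resampled null (crossing probabilities), and detects
"pseudo consumption" episodes -- food-free moments whose speed profile
matches the consumption template -- by normalized template correlation.

Events are passed as DataFrames with columns ``fish_id``, ``time_s`` and,
where a location is needed, ``x_bl``/``y_bl``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .kinematics import TrajectoryRecording


@dataclass
class SpeedProfileTemplate:
    """Time-aligned mean speed and curvature around consumption (t = 0).

    Curvature is reported relative to the recording mean so that the average
    curvature is zero.  ``ref_speed``/``ref_curvature`` are matched profiles
    from random trajectory points unrelated to events.
    """

    lag_s: np.ndarray
    mean_speed: np.ndarray
    sem_speed: np.ndarray
    mean_curvature: np.ndarray
    sem_curvature: np.ndarray
    ref_speed: np.ndarray
    ref_curvature: np.ndarray
    n_events: int

    @property
    def n_frames(self) -> int:
        return self.lag_s.size


@dataclass
class CrossingStats:
    """Neighbor attraction to consumption locations vs a resampled null."""

    p_crossing: float
    null_samples: np.ndarray
    attraction: float            # p_crossing - mean(null)
    n_events: int
    radius_bl: float = 2.0
    window_s: tuple[float, float] = (1.0, 4.0)
    exclusion_s: float = 8.0

    @property
    def null_mean(self) -> float:
        return float(self.null_samples.mean())

    def null_quantile(self, q: float) -> float:
        return float(np.quantile(self.null_samples, q))


def _event_frames(rec: TrajectoryRecording, events: pd.DataFrame) -> np.ndarray:
    t0 = rec.times[0]
    return np.round((events["time_s"].to_numpy() - t0) / rec.dt).astype(int)


def event_aligned_profiles(rec: TrajectoryRecording, events: pd.DataFrame,
                           window_s: float = 2.0, n_reference: int = 200,
                           seed: int | None = 0) -> SpeedProfileTemplate:
    """Mean speed/curvature profiles in a +/- ``window_s`` window around
    consumption events, with reference profiles from random points at least
    one window away from any event."""
    if rec.speed is None or rec.curvature is None:
        raise ValueError("kinematics missing; run compute_kinematics first")
    half = int(round(window_s / rec.dt))
    frames = _event_frames(rec, events)
    fish = events["fish_id"].to_numpy().astype(int)
    ok = (frames - half >= 0) & (frames + half < rec.n_frames)
    if not np.any(ok):
        raise ValueError("no event lies fully inside the recording with margin")
    frames, fish = frames[ok], fish[ok]

    curv_offset = float(np.mean(rec.curvature))
    speeds, curvs = [], []
    for f, j in zip(frames, fish):
        speeds.append(rec.speed[f - half:f + half + 1, j])
        curvs.append(rec.curvature[f - half:f + half + 1, j] - curv_offset)
    speeds = np.array(speeds)
    curvs = np.array(curvs)

    rng = np.random.default_rng(seed)
    ref_s, ref_c = [], []
    candidates = np.arange(half, rec.n_frames - half)
    # points unrelated to events: at least one window away from all of them
    far = np.array([np.all(np.abs(frames - c) > 2 * half) for c in candidates])
    candidates = candidates[far] if np.any(far) else candidates
    for _ in range(n_reference):
        c = int(rng.choice(candidates))
        j = int(rng.integers(rec.n_fish))
        ref_s.append(rec.speed[c - half:c + half + 1, j])
        ref_c.append(rec.curvature[c - half:c + half + 1, j] - curv_offset)

    sem = lambda a: a.std(axis=0, ddof=1) / np.sqrt(a.shape[0]) if a.shape[0] > 1 else np.zeros(a.shape[1])
    return SpeedProfileTemplate(
        lag_s=np.arange(-half, half + 1) * rec.dt,
        mean_speed=speeds.mean(axis=0), sem_speed=sem(speeds),
        mean_curvature=curvs.mean(axis=0), sem_curvature=sem(curvs),
        ref_speed=np.array(ref_s).mean(axis=0),
        ref_curvature=np.array(ref_c).mean(axis=0),
        n_events=len(frames),
    )


def crossing_attraction(rec: TrajectoryRecording, events: pd.DataFrame,
                        radius_bl: float = 2.0,
                        window_s: tuple[float, float] = (1.0, 4.0),
                        exclusion_s: float = 8.0,
                        n_null: int = 10_000,
                        seed: int | None = 0) -> CrossingStats:
    """Probability that a neighbor passes within ``radius_bl`` of a
    consumption location 1-4 s after the event, against a null built by
    resampling random fish positions from food-free times.

    Null positions are drawn only from frames at least ``exclusion_s`` away
    from every event; each null draw mimics the real number of events and
    yields one resampled crossing probability.
    """
    if rec.n_fish < 2:
        raise ValueError("crossing analysis needs at least 2 fish")
    dt = rec.dt
    w0 = int(round(window_s[0] / dt))
    w1 = int(round(window_s[1] / dt))
    frames = _event_frames(rec, events)
    fish = events["fish_id"].to_numpy().astype(int)
    locs = events[["x_bl", "y_bl"]].to_numpy(dtype=float)
    pos = rec.positions
    n = rec.n_frames

    def crossed(frame: int, who: int, loc: np.ndarray) -> bool:
        lo, hi = frame + w0, min(frame + w1 + 1, n)
        if lo >= n:
            return False
        others = [j for j in range(rec.n_fish) if j != who]
        d = np.linalg.norm(pos[lo:hi][:, others, :] - loc, axis=-1)
        return bool(np.any(d <= radius_bl))

    hits = sum(crossed(f, w, l) for f, w, l in zip(frames, fish, locs))
    p_crossing = hits / len(frames)

    excl = int(round(exclusion_s / dt))
    eligible = np.array([
        t for t in range(0, n - w1 - 1)
        if np.all(np.abs(frames - t) >= excl)
    ])
    if eligible.size == 0:
        raise ValueError("no null-eligible times (recording saturated with events)")
    rng = np.random.default_rng(seed)
    k_events = len(frames)
    null = np.empty(n_null)
    for i in range(n_null):
        ts = rng.choice(eligible, size=k_events)
        js = rng.integers(rec.n_fish, size=k_events)
        c = sum(crossed(int(t), int(j), pos[int(t), int(j)]) for t, j in zip(ts, js))
        null[i] = c / k_events
    return CrossingStats(
        p_crossing=p_crossing, null_samples=null,
        attraction=p_crossing - float(null.mean()),
        n_events=k_events, radius_bl=radius_bl,
        window_s=window_s, exclusion_s=exclusion_s,
    )


def _sliding_correlation(series: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized, mean-removed sliding cross-correlation.

    Value i scores the window starting at frame i; zero-variance windows
    score 0.  Invariant to adding a constant to the series.
    """
    m = template.size
    tz = template - template.mean()
    tnorm = np.linalg.norm(tz)
    if tnorm < 1e-12:
        return np.zeros(series.size - m + 1)
    num = np.correlate(series, tz, mode="valid")
    csum = np.concatenate([[0.0], np.cumsum(series)])
    csum2 = np.concatenate([[0.0], np.cumsum(series**2)])
    wsum = csum[m:] - csum[:-m]
    wsum2 = csum2[m:] - csum2[:-m]
    var = np.maximum(wsum2 - wsum**2 / m, 0.0)
    denom = np.sqrt(var) * tnorm
    out = np.zeros_like(num)
    good = denom > 1e-12
    out[good] = num[good] / denom[good]
    return np.clip(out, -1.0, 1.0)


def detect_pseudo_consumptions(rec: TrajectoryRecording,
                               template: SpeedProfileTemplate,
                               quantile: float = 0.975,
                               eligible: np.ndarray | None = None) -> pd.DataFrame:
    """Food-free episodes whose speed profile matches the consumption
    template.

    The per-fish speed series is scanned with the template's mean-speed
    profile (normalized, mean-removed correlation); correlation values are
    pooled over the group, the (1 - quantile) upper tail sets the threshold,
    and local correlation maxima strictly above it -- separated by at least
    one template width, so that two detections never explain the same data
    window -- are returned as events.  ``eligible`` is an
    optional boolean frame mask (e.g. "no flakes present nearby for 8 s");
    detections outside it are dropped.

    Returns a DataFrame (fish_id, frame, time_s, score) with a boolean
    ``degenerate`` attribute flagging a zero-variance correlation pool.
    """
    if rec.speed is None:
        raise ValueError("speed missing; run compute_kinematics first")
    m = template.n_frames
    if rec.n_frames < m:
        raise ValueError("recording shorter than the template")
    half = m // 2
    corr = np.column_stack([
        _sliding_correlation(rec.speed[:, j], template.mean_speed)
        for j in range(rec.n_fish)
    ])
    centers = np.arange(corr.shape[0]) + half
    if eligible is not None:
        mask = np.asarray(eligible, dtype=bool)[centers]
    else:
        mask = np.ones(corr.shape[0], dtype=bool)
    pooled = corr[mask].ravel()
    if pooled.size == 0:
        raise ValueError("no eligible times for pseudo-event detection")
    degenerate = float(pooled.std()) < 1e-12
    threshold = float(np.quantile(pooled, quantile))

    rows = []
    if not degenerate:
        for j in range(rec.n_fish):
            peaks, props = find_peaks(corr[:, j], height=threshold,
                                      distance=max(1, m))
            for p, h in zip(peaks, props["peak_heights"]):
                if h > threshold and mask[p]:
                    rows.append({"fish_id": j, "frame": int(centers[p]),
                                 "time_s": float(rec.times[centers[p]]),
                                 "score": float(h)})
    out = pd.DataFrame(rows, columns=["fish_id", "frame", "time_s", "score"])
    out.attrs["degenerate"] = degenerate
    out.attrs["threshold"] = threshold
    return out
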