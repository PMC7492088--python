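"""Frame-level trajectory kinematics and bout segmentation.

Recorded fish trajectories (50 frames/s by default) are smoothed with a
Savitzky-Golay filter, differentiated into velocity/speed/heading, assigned a
local curvature from least-squares circle fits, and segmented into discrete
swimming bouts delimited by local minima of the speed profile.  Each bout is
summarized by its path length ``L`` (body lengths, BL) and the signed turning
angle ``theta`` (degrees) between successive bout displacement vectors; the
per-fish empirical distributions of ``(L, theta)`` are the motion engine of
the foraging simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

#: spatial unit conversion: the 95 cm arena diameter spans 32 body lengths
CM_PER_BL = 95.0 / 32.0
DEFAULT_FRAME_RATE = 50.0
DEFAULT_ARENA_RADIUS_BL = 32.0


@dataclass
class TrajectoryRecording:
    """Positions (and derived kinematics) of a group of fish.

    Attributes
    ----------
    times : (n_frames,) array, seconds at a fixed frame interval.
    positions : (n_frames, k, 2) array, BL, arena-centered.
    velocity, speed, heading, curvature : filled by :func:`compute_kinematics`.
    heading_valid : boolean mask; False where speed was zero and the heading
        was carried forward from the last moving frame.
    """

    times: np.ndarray
    positions: np.ndarray
    arena_radius: float = DEFAULT_ARENA_RADIUS_BL
    velocity: np.ndarray | None = None
    speed: np.ndarray | None = None
    heading: np.ndarray | None = None
    heading_valid: np.ndarray | None = None
    curvature: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim == 2:  # single fish convenience
            self.positions = self.positions[:, None, :]
        if self.times.shape[0] != self.positions.shape[0]:
            raise ValueError("times and positions disagree on frame count")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame interval must be constant")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_fish(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0 / DEFAULT_FRAME_RATE

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.dt


@dataclass
class BoutSequence:
    """Discrete steps of one fish: contiguous, non-overlapping bouts.

    ``theta`` is signed (CCW positive) in (-180, 180]; the first bout has no
    predecessor and carries ``theta = nan``.
    """

    fish_id: int
    start_frames: np.ndarray
    end_frames: np.ndarray
    lengths: np.ndarray
    thetas: np.ndarray

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass
class StepDistributions:
    """Per-fish step-length / turning-angle distributions.

    Either carries empirical samples (bout segmentation output) or acts as a
    parametric surrogate: step lengths from a gamma distribution matched to
    (mean, SD) and turning angles from a wrapped normal with the given SD.
    """

    lengths: np.ndarray | None = None
    thetas: np.ndarray | None = None
    length_mean: float = 0.0
    length_sd: float = 0.0
    theta_mean: float = 0.0
    theta_sd: float = 0.0
    parametric: bool = False
    # gamma parameters, filled for parametric surrogates
    _gamma_shape: float = field(default=0.0, repr=False)
    _gamma_scale: float = field(default=0.0, repr=False)

    @classmethod
    def from_samples(cls, lengths: np.ndarray, thetas: np.ndarray) -> "StepDistributions":
        lengths = np.asarray(lengths, dtype=float)
        thetas = np.asarray(thetas, dtype=float)
        thetas = thetas[np.isfinite(thetas)]
        if lengths.size == 0:
            raise ValueError("empty step-length sample")
        if np.any(lengths <= 0):
            raise ValueError("step lengths must be positive")
        return cls(
            lengths=lengths,
            thetas=thetas,
            length_mean=float(np.mean(lengths)),
            length_sd=float(np.std(lengths, ddof=1)) if lengths.size > 1 else 0.0,
            theta_mean=float(np.mean(thetas)) if thetas.size else 0.0,
            theta_sd=float(np.std(thetas, ddof=1)) if thetas.size > 1 else 0.0,
        )

    @classmethod
    def from_moments(cls, length_mean: float = 2.85, length_sd: float = 1.7,
                     theta_sd: float = 50.0) -> "StepDistributions":
        if length_mean <= 0 or length_sd <= 0 or theta_sd <= 0:
            raise ValueError("moments must be positive")
        shape = (length_mean / length_sd) ** 2
        scale = length_sd**2 / length_mean
        return cls(
            length_mean=length_mean, length_sd=length_sd,
            theta_mean=0.0, theta_sd=theta_sd,
            parametric=True, _gamma_shape=shape, _gamma_scale=scale,
        )

    # fast scalar draws used in the simulator's inner loop (stdlib random.Random)
    def draw_length(self, rng) -> float:
        if self.parametric:
            L = rng.gammavariate(self._gamma_shape, self._gamma_scale)
            return L if L > 1e-9 else 1e-9
        samples = self.lengths
        return float(samples[rng.randrange(len(samples))])

    def draw_theta(self, rng) -> float:
        """Turning angle in degrees, wrapped to (-180, 180]."""
        if self.parametric or self.thetas is None or len(self.thetas) == 0:
            theta = rng.gauss(0.0, self.theta_sd)
        else:
            theta = float(self.thetas[rng.randrange(len(self.thetas))])
        theta = (theta + 180.0) % 360.0 - 180.0
        return 180.0 if theta == -180.0 else theta


def smooth_positions(raw: TrajectoryRecording, window_frames: int = 17,
                     polyorder: int = 2) -> TrajectoryRecording:
    """Savitzky-Golay smoothing of the raw positions (default 17-frame window,
    about a third of a second at 50 fps).

    Edge frames take their value from the polynomial fitted to the terminal
    full window, so the output has the same length as the input and constants
    and low-degree polynomial motion pass through unchanged.
    """
    if window_frames < 5 or window_frames % 2 == 0:
        raise ValueError("window_frames must be odd and >= 5")
    if raw.n_frames < window_frames:
        raise ValueError(
            f"recording has {raw.n_frames} frames, shorter than the "
            f"{window_frames}-frame smoothing window"
        )
    smoothed = savgol_filter(raw.positions, window_frames, polyorder,
                             axis=0, mode="interp")
    return TrajectoryRecording(times=raw.times.copy(), positions=smoothed,
                               arena_radius=raw.arena_radius)


def _circle_curvature(x: np.ndarray, y: np.ndarray) -> float:
    """Curvature 1/R of the least-squares (Kasa) circle through the points.

    Collinear (or numerically degenerate) windows have infinite radius and
    return 0 rather than raising.
    """
    x = x - x.mean()
    y = y - y.mean()
    # collinear windows are rank-deficient for the circle system and the
    # minimal-norm solution is a spurious small circle: guard via PCA
    cov = np.cov(np.column_stack([x, y]), rowvar=False)
    evals = np.linalg.eigvalsh(cov)
    if evals[1] <= 0 or evals[0] / evals[1] < 1e-9:
        return 0.0
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return 0.0
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if not np.isfinite(r2) or r2 <= 1e-12:
        return 0.0
    # residual check: collinear points fit an arbitrarily large circle
    radius = np.sqrt(r2)
    if radius > 1e6:
        return 0.0
    return float(1.0 / radius)


def compute_kinematics(rec: TrajectoryRecording,
                       curvature_window_s: float = 0.6,
                       with_curvature: bool = True) -> TrajectoryRecording:
    """Derive velocity, speed, heading and curvature from (smoothed) positions.

    Velocity is the central difference (x(t+dt) - x(t-dt)) / 2dt with dt of one
    frame (one-sided at the ends); the heading is the unit velocity, carried
    forward through zero-speed frames and flagged invalid there.  Curvature
    c(t) = 1/R(t) comes from the best-fit circle on a window of
    ``curvature_window_s`` seconds centered on t.
    """
    pos = rec.positions
    n, k, _ = pos.shape
    dt = rec.dt
    vel = np.empty_like(pos)
    vel[1:-1] = (pos[2:] - pos[:-2]) / (2.0 * dt)
    vel[0] = (pos[1] - pos[0]) / dt
    vel[-1] = (pos[-1] - pos[-2]) / dt
    speed = np.linalg.norm(vel, axis=2)

    heading = np.zeros_like(pos)
    valid = speed > 1e-12
    heading[valid] = vel[valid] / speed[valid][:, None]
    # carry heading forward through stationary frames, flagged via `valid`
    for j in range(k):
        last = None
        for t in range(n):
            if valid[t, j]:
                last = heading[t, j]
            elif last is not None:
                heading[t, j] = last

    curv = None
    if with_curvature:
        half = max(1, int(round(curvature_window_s / dt / 2)))
        curv = np.zeros((n, k))
        for j in range(k):
            xs, ys = pos[:, j, 0], pos[:, j, 1]
            for t in range(n):
                lo, hi = max(0, t - half), min(n, t + half + 1)
                if hi - lo >= 3:
                    curv[t, j] = _circle_curvature(xs[lo:hi], ys[lo:hi])
    return TrajectoryRecording(
        times=rec.times.copy(), positions=pos.copy(), arena_radius=rec.arena_radius,
        velocity=vel, speed=speed, heading=heading, heading_valid=valid,
        curvature=curv,
    )


def _speed_minima(speed: np.ndarray, prominence_frac: float,
                  min_separation: int) -> np.ndarray:
    """Bout delimiters: interior speed minima plus qualifying endpoints.

    Interior minima require a prominence of ``prominence_frac`` of the median
    speed and a minimum separation; a recording endpoint counts as a delimiter
    when its speed is below that of its interior neighbor.
    """
    med = float(np.median(speed))
    prom = prominence_frac * med if med > 0 else None
    idx, _ = find_peaks(-speed, prominence=prom, distance=min_separation)
    delim = list(idx)
    if len(speed) >= 2 and speed[0] < speed[1]:
        delim.insert(0, 0)
    if len(speed) >= 2 and speed[-1] < speed[-2]:
        delim.append(len(speed) - 1)
    return np.array(sorted(set(delim)), dtype=int)


def _signed_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Signed angle (degrees, CCW positive) from vector u to vector v."""
    ang = np.degrees(np.arctan2(u[0] * v[1] - u[1] * v[0],
                                u[0] * v[0] + u[1] * v[1]))
    return 180.0 if ang == -180.0 else float(ang)


def segment_bouts(rec: TrajectoryRecording, fish_id: int = 0,
                  prominence_frac: float = 0.05,
                  min_separation: int = 5) -> BoutSequence:
    """Segment one fish's trajectory into bouts at local speed minima.

    Bout length L is the path length between consecutive delimiting minima;
    theta is the signed angle between successive bout displacement vectors.
    Fewer than three delimiting minima yield an empty sequence (with warning):
    a single bout has no defined turning angle.
    """
    if rec.speed is None:
        raise ValueError("speed series missing; run compute_kinematics first")
    speed = rec.speed[:, fish_id]
    minima = _speed_minima(speed, prominence_frac, min_separation)
    if len(minima) < 3:
        warnings.warn("fewer than 3 speed minima: no bouts segmented")
        empty = np.array([])
        return BoutSequence(fish_id, empty.astype(int), empty.astype(int), empty, empty)

    pos = rec.positions[:, fish_id, :]
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(step)])

    starts = minima[:-1]
    ends = minima[1:]
    lengths = cum[ends] - cum[starts]
    disp = pos[ends] - pos[starts]
    thetas = np.full(len(starts), np.nan)
    for i in range(1, len(starts)):
        thetas[i] = _signed_angle_deg(disp[i - 1], disp[i])
    keep = lengths > 0
    return BoutSequence(fish_id, starts[keep], ends[keep],
                        lengths[keep], thetas[keep])


def estimate_step_distributions(bouts: BoutSequence) -> StepDistributions:
    """Empirical (L, theta) distributions of one fish's bouts."""
    if len(bouts) == 0:
        raise ValueError("empty bout sequence")
    if len(bouts) < 30:
        warnings.warn(f"only {len(bouts)} bouts; step distributions will be noisy")
    return StepDistributions.from_samples(bouts.lengths, bouts.thetas)
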