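"""Synthetic frame-level group recordings with known ground truth.

The generator emulates the recorded data end to end: each fish is a
bout-level correlated random walk (gamma step lengths, wrapped-normal
turning angles, defaults matched to the recorded bout statistics of
foraging zebrafish groups), rendered to 50-fps positions with a smooth
within-bout speed profile whose minima at bout boundaries make the
trajectory segmentable by the same pipeline as real data.  Optional planted
structure provides positives for the analysis modules: stereotyped
consumption maneuvers (a triangular speed bump followed by a sharp turn),
and neighbor attraction (after an event, nearby fish reroute toward the
event location with a configurable probability).

What this generator does NOT emulate: tracking noise and identity swaps,
wall-following and thigmotaxis, speed/heading autocorrelation within bouts
beyond the imposed profile, and any flake physics (flakes exist only as
ground-truth markers of planted events).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .environments import FlakeField
from .kinematics import (DEFAULT_ARENA_RADIUS_BL, DEFAULT_FRAME_RATE,
                         StepDistributions, TrajectoryRecording)


@dataclass
class FixtureSpec:
    """Ground-truth parameters of one synthetic group recording."""

    k: int = 3
    step_mean: float = 2.85      # BL; 3.1 for six-fish groups
    step_sd: float = 1.7         # BL; 1.9 for six-fish groups
    theta_sd: float = 50.0       # degrees; 46 for six-fish groups
    arena_radius: float = DEFAULT_ARENA_RADIUS_BL
    frame_rate: float = DEFAULT_FRAME_RATE
    duration_s: float = 120.0
    swim_speed: float = 4.0      # mean within-bout speed, BL/s
    n_events: int = 0            # planted consumption maneuvers (on fish 0)
    attraction_prob: float = 0.0  # chance a neighbor reroutes to an event
    attraction_range: float = 10.0  # BL; reroutes only start within this range
    seed: int = 0


@dataclass
class SyntheticRecording:
    """Bundle of the rendered recording and its ground truth."""

    recording: TrajectoryRecording
    events: pd.DataFrame          # fish_id, time_s, x_bl, y_bl, kind
    field: FlakeField
    truth: dict = dc_field(default_factory=dict)


def _bout_weights(length: float, speed: float, frame_rate: float,
                  profile: str = "bump") -> np.ndarray:
    """Per-frame displacements of one bout; they sum exactly to ``length``.

    The 'bump' profile rises and falls (half-sine), putting speed minima at
    bout boundaries; 'constant' renders uniform motion.
    """
    m = max(2, int(round(length / speed * frame_rate)))
    if profile == "constant":
        w = np.ones(m)
    else:
        w = np.sin(math.pi * (np.arange(m) + 0.5) / m)
    return w * (length / w.sum())


def _maneuver_weights(base_speed: float, frame_rate: float,
                      bump: float = 2.0, rise_s: float = 0.45,
                      fall_s: float = 0.15) -> np.ndarray:
    """Consumption-maneuver displacements: speed ramps from base to
    base+bump over ``rise_s`` then collapses sharply (the capture)."""
    m1 = max(2, int(round(rise_s * frame_rate)))
    m2 = max(2, int(round(fall_s * frame_rate)))
    sp = np.concatenate([
        np.linspace(base_speed, base_speed + bump, m1),
        np.linspace(base_speed + bump, 0.05 * base_speed, m2),
    ])
    return sp / frame_rate


def render_bouts_to_frames(bouts, frame_rate: float = DEFAULT_FRAME_RATE,
                           speed_profile: str = "bump",
                           swim_speed: float = 4.0,
                           start=(0.0, 0.0), initial_heading_deg: float = 0.0,
                           arena_radius: float = DEFAULT_ARENA_RADIUS_BL) -> TrajectoryRecording:
    """Render a sequence of (L, theta_deg) bouts of a single fish to frames.

    Positions are piecewise linear along each bout heading with the chosen
    within-bout speed profile; the rendered path length of each bout equals
    L exactly.  A bout that would exit the arena is reflected off the wall
    normal (so overflow is impossible by construction).
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    x, y = float(start[0]), float(start[1])
    ang = math.radians(initial_heading_deg)
    hx, hy = math.cos(ang), math.sin(ang)
    frames = [(x, y)]
    for L, theta in bouts:
        if L <= 0:
            raise ValueError("bout lengths must be positive")
        if np.isfinite(theta):
            th = math.radians(theta)
            c, s = math.cos(th), math.sin(th)
            hx, hy = hx * c - hy * s, hx * s + hy * c
        hx, hy, _ = _keep_inside(x, y, hx, hy, L, arena_radius)
        w = _bout_weights(L, swim_speed, frame_rate, speed_profile)
        for d in w:
            x += hx * d
            y += hy * d
            frames.append((x, y))
    pos = np.array(frames)
    times = np.arange(len(frames)) / frame_rate
    return TrajectoryRecording(times=times, positions=pos[:, None, :],
                               arena_radius=arena_radius)


def _keep_inside(x: float, y: float, hx: float, hy: float, L: float,
                 radius: float) -> tuple[float, float, bool]:
    """Reflect a heading off the radial wall normal until the bout endpoint
    stays inside; falls back to heading at the arena center."""
    margin = radius * (1 - 1e-9)
    reflected = False
    for _ in range(4):
        if (x + hx * L) ** 2 + (y + hy * L) ** 2 < margin * margin:
            return hx, hy, reflected
        r = math.hypot(x, y)
        if r < 1e-9:
            break
        nx, ny = x / r, y / r
        dot = hx * nx + hy * ny
        hx, hy = hx - 2 * dot * nx, hy - 2 * dot * ny
        reflected = True
    d = math.hypot(x, y)
    if d > 1e-9:
        return -x / d, -y / d, True
    return 1.0, 0.0, True


def generate_synthetic_recording(spec: FixtureSpec) -> SyntheticRecording:
    """Render a synthetic group recording with the requested planted
    structure; fully reproducible under ``spec.seed``.

    Planted consumption maneuvers occur on fish 0 at evenly spaced times;
    each becomes an event (and a ground-truth flake consumed at that time).
    With ``attraction_prob`` > 0, every other fish within
    ``attraction_range`` of a fresh event reroutes toward its location with
    that probability, producing a measurable crossing attraction.
    """
    if spec.k < 1:
        raise ValueError("need at least one fish")
    rng = random.Random(spec.seed)
    dist = StepDistributions.from_moments(spec.step_mean, spec.step_sd, spec.theta_sd)
    fps = spec.frame_rate
    n_target = int(round(spec.duration_s * fps))

    event_times: list[float] = []
    if spec.n_events > 0:
        lo, hi = 10.0, max(spec.duration_s - 10.0, 11.0)
        event_times = list(np.linspace(lo, hi, spec.n_events))

    events: list[dict] = []
    all_pos = []
    truth_L: list[list[float]] = []
    truth_theta: list[list[float]] = []
    n_attracted = 0

    for j in range(spec.k):
        x = 0.3 * spec.arena_radius * math.cos(2 * math.pi * j / spec.k)
        y = 0.3 * spec.arena_radius * math.sin(2 * math.pi * j / spec.k)
        ang = rng.random() * 2 * math.pi
        hx, hy = math.cos(ang), math.sin(ang)
        frames = [(x, y)]
        Ls: list[float] = []
        thetas: list[float] = []
        next_event = 0          # fish 0: index of the next planted maneuver
        reacted: set[int] = set()   # fish > 0: events already responded to
        chasing: tuple[float, float, float] | None = None  # (ex, ey, deadline)
        post_maneuver = False

        while len(frames) <= n_target:
            t_now = (len(frames) - 1) / fps
            if j == 0 and next_event < len(event_times) and t_now >= event_times[next_event]:
                # planted consumption maneuver: speed bump, then sharp turn
                w = _maneuver_weights(spec.swim_speed, fps)
                L = float(w.sum())
                hx, hy, _ = _keep_inside(x, y, hx, hy, L, spec.arena_radius)
                for d in w:
                    x += hx * d
                    y += hy * d
                    frames.append((x, y))
                events.append({"fish_id": 0, "time_s": (len(frames) - 1) / fps,
                               "x_bl": x, "y_bl": y, "kind": "consumption"})
                next_event += 1
                post_maneuver = True
                continue
            if j > 0 and spec.attraction_prob > 0 and chasing is None:
                for ei, ev in enumerate(events):
                    if ei in reacted or ev["fish_id"] == j:
                        continue
                    if not (ev["time_s"] <= t_now <= ev["time_s"] + 2.0):
                        continue
                    reacted.add(ei)
                    d_ev = math.hypot(ev["x_bl"] - x, ev["y_bl"] - y)
                    if d_ev <= spec.attraction_range and rng.random() < spec.attraction_prob:
                        chasing = (ev["x_bl"], ev["y_bl"], ev["time_s"] + 3.8)
                        n_attracted += 1
                    break
            if chasing is not None:
                ex, ey, deadline = chasing
                d_ev = math.hypot(ex - x, ey - y)
                if t_now > deadline or d_ev < 1.0:
                    chasing = None
            if chasing is not None:
                # directed reroute toward the event location
                L = min(dist.draw_length(rng), d_ev + 0.2)
                hx, hy = (ex - x) / d_ev, (ey - y) / d_ev
                hx, hy, _ = _keep_inside(x, y, hx, hy, L, spec.arena_radius)
                theta = math.nan
            else:
                # random bout; a movement that would exit the arena is
                # discarded and redrawn (same rule as the simulator)
                bx, by = hx, hy
                for _ in range(200):
                    L = dist.draw_length(rng)
                    if post_maneuver:
                        theta = math.copysign(rng.uniform(90.0, 170.0),
                                              1.0 if rng.random() < 0.5 else -1.0)
                    else:
                        theta = dist.draw_theta(rng)
                    th = math.radians(theta)
                    c, s = math.cos(th), math.sin(th)
                    hx, hy = bx * c - by * s, bx * s + by * c
                    if (x + hx * L) ** 2 + (y + hy * L) ** 2 < (spec.arena_radius * (1 - 1e-9)) ** 2:
                        break
                else:
                    d0 = math.hypot(x, y)
                    hx, hy = -x / d0, -y / d0
                post_maneuver = False
            Ls.append(L)
            thetas.append(theta)
            w = _bout_weights(L, spec.swim_speed, fps, "bump")
            for d in w:
                x += hx * d
                y += hy * d
                frames.append((x, y))
        all_pos.append(np.array(frames[:n_target + 1]))
        truth_L.append(Ls)
        truth_theta.append(thetas)

    positions = np.stack(all_pos, axis=1)
    times = np.arange(n_target + 1) / fps
    rec = TrajectoryRecording(times=times, positions=positions,
                              arena_radius=spec.arena_radius)
    ev_df = pd.DataFrame(events, columns=["fish_id", "time_s", "x_bl", "y_bl", "kind"])
    if len(ev_df):
        field = FlakeField(
            x=ev_df["x_bl"].to_numpy(), y=ev_df["y_bl"].to_numpy(),
            arena_radius=spec.arena_radius,
            t_consumed=ev_df["time_s"].to_numpy(),
        )
    else:
        field = FlakeField(x=np.array([]), y=np.array([]),
                           arena_radius=spec.arena_radius)
    truth = {
        "lengths": [np.array(v) for v in truth_L],
        "thetas": [np.array(v) for v in truth_theta],
        "n_attracted": n_attracted,
        "spec": spec,
    }
    return SyntheticRecording(recording=rec, events=ev_df, field=field, truth=truth)
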