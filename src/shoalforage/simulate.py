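"""Bout-based agent simulator of independent and social group foraging.

Each simulated fish is a correlated random walker: on every discrete time
step (tick) it draws a step length L and a turning angle theta from its
(empirical or surrogate) bout distributions.  Individual foraging is
modulated by flake detection -- if a live flake lies within the detection
range Df, the fish orients straight at it with probability exp(-df/Df).
Social models add responses to neighbors within the neighbor detection
range Dn, applied in a strict hierarchy per tick:

1. orient to the nearest live flake within Df, w.p. exp(-df/Df);
2. otherwise (models with Att_feed) orient to the nearest location where a
   neighbor consumed a flake in the last tau ticks, w.p. exp(-dn/Dn);
3. otherwise attract to the neighbors' center of mass (Att), align with
   their mean heading (Align), or combine both in inner/outer half-zones of
   Dn (the zoned Att+Align response), each firing w.p. exp(-d_com/Dn);
4. otherwise take a random bout from the turning-angle distribution.

Step lengths are always drawn from the step-length distribution.  A step
that would end outside the circular arena is discarded and redrawn (bounded
attempts, then a deterministic fallback toward the arena center).  A flake
is consumed when the straight bout segment passes within the capture radius
(0.25 BL) of it; the bout then ends at the capture point, one consumption
per fish per tick.  Consumed flakes can spawn child flakes (disintegration
parentage of the field).  Simulated tick time converts to seconds by
dividing traveled path length by the average swimming speed of real fish.
"""

from __future__ import annotations

import math
import random
from collections import deque
from dataclasses import dataclass, field as dc_field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .environments import FlakeField
from .kinematics import DEFAULT_ARENA_RADIUS_BL, StepDistributions

#: model name -> (responds to neighbor consumptions, social swimming response)
MODELS: dict[str, tuple[bool, str | None]] = {
    "ind": (False, None),
    "att_feed": (True, None),
    "att": (False, "att"),
    "align": (False, "align"),
    "att_feed_align": (True, "align"),
    "att_align": (False, "zoned"),
    "att_feed_att_align": (True, "zoned"),
}

#: recorded group-level bout statistics used for surrogate distributions
GROUP_STEP_MOMENTS = {3: (2.85, 1.7, 50.0), 6: (3.1, 1.9, 46.0)}


def default_step_distributions(k: int) -> StepDistributions:
    """Parametric surrogate matched to the recorded bout statistics: groups of
    up to three fish use mean 2.85 +/- 1.7 BL with 50 deg turning SD, larger
    groups 3.1 +/- 1.9 BL with 46 deg."""
    mean, sd, tsd = GROUP_STEP_MOMENTS[3] if k <= 3 else GROUP_STEP_MOMENTS[6]
    return StepDistributions.from_moments(mean, sd, tsd)


@dataclass
class SimulationConfig:
    """Parameters of one simulated foraging group.

    ``df`` (flake detection range) and ``dn`` (neighbor detection range) are
    in BL; the fitted grids are Df in 1..20 and Dn in 1..25 (Dn = 0 if and
    only if the model is IND).  ``tau`` is the memory horizon, in ticks, of
    neighbor consumption events.  ``strategies`` optionally assigns a model
    per agent (mixed-strategy groups); ``model`` is then the default label.
    """

    k: int
    model: str = "ind"
    df: float = 3.0
    dn: float = 0.0
    tau: int = 5
    arena_radius: float = DEFAULT_ARENA_RADIUS_BL
    step_dists: StepDistributions | Sequence[StepDistributions] | None = None
    avg_speed: float = 4.0
    capture_radius: float = 0.25
    max_ticks: int = 10_000
    boundary_attempts: int = 100
    initial_positions: np.ndarray | None = None
    strategies: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; one of {sorted(MODELS)}")
        if self.df < 1:
            raise ValueError("Df must be >= 1")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.strategies is not None:
            if len(self.strategies) != self.k:
                raise ValueError("strategies must list one model per agent")
            for s in self.strategies:
                if s not in MODELS:
                    raise ValueError(f"unknown strategy {s!r}")
        social = any(s != "ind" for s in self.agent_strategies())
        if social and self.dn <= 0:
            raise ValueError("social models require Dn >= 1")
        if not social and self.strategies is None and self.dn != 0:
            # Dn = 0 <=> IND for homogeneous groups; explicit per-agent
            # strategies may carry a (unused) Dn for IND agents.
            raise ValueError("IND groups must have Dn = 0")
        if self.step_dists is None:
            self.step_dists = default_step_distributions(self.k)

    def agent_strategies(self) -> list[str]:
        return list(self.strategies) if self.strategies is not None else [self.model] * self.k

    def agent_step_dists(self) -> list[StepDistributions]:
        if isinstance(self.step_dists, StepDistributions):
            return [self.step_dists] * self.k
        dists = list(self.step_dists)
        if len(dists) != self.k:
            raise ValueError("need one StepDistributions per agent")
        return dists


@dataclass
class AgentState:
    """Snapshot of one agent (position and heading in BL / unit vector)."""

    x: float
    y: float
    hx: float
    hy: float
    strategy: str


class Consumption(NamedTuple):
    tick: int
    agent: int
    flake: int
    x: float
    y: float
    path_bl: float  # consumer's cumulative path length at capture
    mode: str       # 'flake' (individual detection) or 'feed'/'social'/'random'/'fallback'


@dataclass
class SimulationRecord:
    """Full history of one simulated run."""

    config: SimulationConfig
    field: FlakeField
    seed: int
    n_ticks: int
    consumptions: list[Consumption]
    positions: np.ndarray | None = None   # (n_ticks+1, k, 2) incl. initial
    headings: np.ndarray | None = None
    final_state: list[AgentState] = dc_field(default_factory=list)

    @property
    def all_consumed(self) -> bool:
        return len(self.consumptions) == self.field.n_flakes

    def per_agent_counts(self) -> np.ndarray:
        counts = np.zeros(self.config.k, dtype=int)
        for c in self.consumptions:
            counts[c.agent] += 1
        return counts

    def consumption_times_s(self, avg_speed: float | None = None) -> np.ndarray:
        """Ordered consumption times T(n) in seconds (ascending)."""
        return np.sort(bouts_to_seconds(self, avg_speed or self.config.avg_speed))


def draw_bout(dist: StepDistributions, rng: random.Random) -> tuple[float, float]:
    """One (L, theta) draw from a fish's step distributions."""
    return dist.draw_length(rng), dist.draw_theta(rng)


def flake_response(x: float, y: float, fx: Sequence[float], fy: Sequence[float],
                   live: Sequence[int], df_range: float,
                   rng: random.Random) -> tuple[float, float, int] | None:
    """Orientation toward the nearest live flake within Df, w.p. exp(-df/Df).

    Returns (ux, uy, flake_index) or None; (0, 0) as the direction signals a
    flake at the agent's own position (keep the current heading).
    """
    best = -1
    bd2 = df_range * df_range
    for j in live:
        dx = fx[j] - x
        dy = fy[j] - y
        d2 = dx * dx + dy * dy
        if d2 < bd2:
            bd2 = d2
            best = j
    if best < 0:
        return None
    d = math.sqrt(bd2)
    if rng.random() >= math.exp(-d / df_range):
        return None
    if d < 1e-12:
        return (0.0, 0.0, best)
    return ((fx[best] - x) / d, (fy[best] - y) / d, best)


def feed_response(i: int, x: float, y: float, events, dn_range: float,
                  rng: random.Random) -> tuple[float, float] | None:
    """Orientation toward the nearest remembered neighbor-consumption
    location within Dn, w.p. exp(-dn/Dn).  ``events`` holds (tick, x, y,
    agent) tuples already restricted to the last tau ticks."""
    best_d2 = dn_range * dn_range
    bx = by = 0.0
    found = False
    for (_, ex, ey, ea) in events:
        if ea == i:
            continue
        dx = ex - x
        dy = ey - y
        d2 = dx * dx + dy * dy
        if d2 < best_d2:
            best_d2 = d2
            bx, by = dx, dy
            found = True
    if not found:
        return None
    d = math.sqrt(best_d2)
    if rng.random() >= math.exp(-d / dn_range):
        return None
    if d < 1e-12:
        return (0.0, 0.0)
    return (bx / d, by / d)


def social_response(i: int, px: Sequence[float], py: Sequence[float],
                    hx: Sequence[float], hy: Sequence[float],
                    dn_range: float, mode: str,
                    rng: random.Random) -> tuple[float, float] | None:
    """Attraction/alignment response to neighbors within Dn.

    All variants fire w.p. exp(-d_com/Dn) with d_com the distance to the
    neighbors' center of mass.  'att' heads to the center of mass, 'align'
    adopts the normalized mean neighbor heading, and 'zoned' aligns with
    neighbors closer than Dn/2 while attracting to the center of mass of
    those between Dn/2 and Dn, averaging the two unit responses when both
    zones are occupied.  A zero-norm direction falls through (None).
    """
    k = len(px)
    x, y = px[i], py[i]
    dn2 = dn_range * dn_range
    idx: list[int] = []
    dists: list[float] = []
    for j in range(k):
        if j == i:
            continue
        dx = px[j] - x
        dy = py[j] - y
        d2 = dx * dx + dy * dy
        if d2 < dn2:
            idx.append(j)
            dists.append(math.sqrt(d2))
    if not idx:
        return None
    cx = sum(px[j] for j in idx) / len(idx) - x
    cy = sum(py[j] for j in idx) / len(idx) - y
    d_com = math.hypot(cx, cy)
    if rng.random() >= math.exp(-d_com / dn_range):
        return None
    if mode == "att":
        vx, vy = cx, cy
    elif mode == "align":
        vx = sum(hx[j] for j in idx)
        vy = sum(hy[j] for j in idx)
    else:  # zoned att+align
        half = dn_range / 2.0
        inner = [j for j, d in zip(idx, dists) if d <= half]
        outer = [j for j, d in zip(idx, dists) if d > half]
        vx = vy = 0.0
        n_parts = 0
        if inner:
            ax = sum(hx[j] for j in inner)
            ay = sum(hy[j] for j in inner)
            norm = math.hypot(ax, ay)
            if norm > 1e-12:
                vx += ax / norm
                vy += ay / norm
                n_parts += 1
        if outer:
            ox = sum(px[j] for j in outer) / len(outer) - x
            oy = sum(py[j] for j in outer) / len(outer) - y
            norm = math.hypot(ox, oy)
            if norm > 1e-12:
                vx += ox / norm
                vy += oy / norm
                n_parts += 1
        if n_parts == 0:
            return None
    norm = math.hypot(vx, vy)
    if norm < 1e-12:
        return None
    return (vx / norm, vy / norm)


class _SimState:
    """Mutable running state of one simulation (plain lists for speed)."""

    __slots__ = ("tick", "px", "py", "hx", "hy", "path", "status", "live",
                 "children_of", "appear_at", "events", "consumed_count",
                 "consumptions", "rng", "fx", "fy")

    def __init__(self, config: SimulationConfig, field: FlakeField, rng: random.Random):
        k = config.k
        self.rng = rng
        self.tick = 0
        if config.initial_positions is not None:
            init = np.asarray(config.initial_positions, dtype=float)
            if init.shape != (k, 2):
                raise ValueError("initial_positions must have shape (k, 2)")
            self.px = [float(v) for v in init[:, 0]]
            self.py = [float(v) for v in init[:, 1]]
        else:
            # start at the arena center: a tight 0.5 BL ring, random phase
            phase = rng.random() * 2 * math.pi
            self.px = [0.5 * math.cos(phase + 2 * math.pi * i / k) for i in range(k)]
            self.py = [0.5 * math.sin(phase + 2 * math.pi * i / k) for i in range(k)]
        angles = [rng.random() * 2 * math.pi for _ in range(k)]
        self.hx = [math.cos(a) for a in angles]
        self.hy = [math.sin(a) for a in angles]
        self.path = [0.0] * k

        n = field.n_flakes
        self.fx = [float(v) for v in field.x]
        self.fy = [float(v) for v in field.y]
        # status: 0 pending, 1 live, 2 consumed
        self.status = [0] * n
        self.live: list[int] = []
        self.children_of: dict[int, list[int]] = {}
        tick_s = (config.step_dists.length_mean
                  if isinstance(config.step_dists, StepDistributions)
                  else config.agent_step_dists()[0].length_mean) / config.avg_speed
        self.appear_at: dict[int, list[int]] = {}
        for j in range(n):
            parent = int(field.parent[j])
            if parent >= 0:
                self.children_of.setdefault(parent, []).append(j)
            elif field.t_appear[j] <= 0:
                self.status[j] = 1
                self.live.append(j)
            else:
                t_app = int(math.ceil(field.t_appear[j] / tick_s))
                self.appear_at.setdefault(t_app, []).append(j)
        self.events: deque = deque()
        self.consumed_count = 0
        self.consumptions: list[Consumption] = []


def advance_group(state: _SimState, config: SimulationConfig,
                  strategies: list[tuple[bool, str | None]],
                  dists: list[StepDistributions]) -> list[Consumption]:
    """One synchronous tick: every agent completes one bout, in randomized
    order; returns the consumption events of this tick."""
    rng = state.rng
    state.tick += 1
    tick = state.tick
    px, py, hx, hy = state.px, state.py, state.hx, state.hy
    fx, fy, live, status = state.fx, state.fy, state.live, state.status
    events = state.events
    while events and events[0][0] < tick - config.tau:
        events.popleft()
    for j in state.appear_at.pop(tick, ()):
        status[j] = 1
        live.append(j)

    df_range = config.df
    dn_range = config.dn
    cr = config.capture_radius
    cr2 = cr * cr
    r_max = config.arena_radius
    r_max2 = r_max * r_max
    new_events: list[Consumption] = []

    order = list(range(config.k))
    rng.shuffle(order)
    for i in order:
        has_feed, social_mode = strategies[i]
        dist = dists[i]
        x, y = px[i], py[i]
        mode = "random"
        ux = uy = 0.0
        resp = flake_response(x, y, fx, fy, live, df_range, rng) if live else None
        if resp is not None:
            ux, uy, _ = resp
            if ux == 0.0 and uy == 0.0:
                ux, uy = hx[i], hy[i]
            mode = "flake"
        elif has_feed and events and dn_range > 0:
            r = feed_response(i, x, y, events, dn_range, rng)
            if r is not None:
                ux, uy = r
                if ux == 0.0 and uy == 0.0:
                    ux, uy = hx[i], hy[i]
                mode = "feed"
        if mode == "random" and social_mode is not None and dn_range > 0:
            r = social_response(i, px, py, hx, hy, dn_range, social_mode, rng)
            if r is not None:
                ux, uy = r
                mode = "social"

        # movement draw with boundary rejection
        L = dist.draw_length(rng)
        if mode == "random":
            theta = math.radians(dist.draw_theta(rng))
            c, s = math.cos(theta), math.sin(theta)
            ux = hx[i] * c - hy[i] * s
            uy = hx[i] * s + hy[i] * c
        ok = False
        for _ in range(config.boundary_attempts):
            ex = x + ux * L
            ey = y + uy * L
            if ex * ex + ey * ey < r_max2:
                ok = True
                break
            L = dist.draw_length(rng)
            if mode == "random":
                theta = math.radians(dist.draw_theta(rng))
                c, s = math.cos(theta), math.sin(theta)
                ux = hx[i] * c - hy[i] * s
                uy = hx[i] * s + hy[i] * c
        if not ok:
            # deterministic fallback: head straight for the arena center
            mode = "fallback"
            d0 = math.hypot(x, y)
            if d0 > 1e-9:
                ux, uy = -x / d0, -y / d0
            if L > d0 + r_max:  # cannot happen for sane L, kept for safety
                L = d0
            ex = x + ux * L
            ey = y + uy * L

        # segment capture: first live flake within cr of the bout segment
        hit = -1
        hit_t = L + cr
        for j in live:
            rx = fx[j] - x
            ry = fy[j] - y
            t = rx * ux + ry * uy
            if t < -cr or t > hit_t:
                continue
            tc = 0.0 if t < 0.0 else (L if t > L else t)
            ddx = rx - tc * ux
            ddy = ry - tc * uy
            if ddx * ddx + ddy * ddy <= cr2 and t < hit_t:
                hit_t = t
                hit = j
        if hit >= 0:
            t_stop = 0.0 if hit_t < 0.0 else (L if hit_t > L else hit_t)
            ex = x + ux * t_stop
            ey = y + uy * t_stop
            traveled = t_stop
            status[hit] = 2
            live.remove(hit)
            state.consumed_count += 1
            cons = Consumption(tick, i, hit, fx[hit], fy[hit],
                               state.path[i] + traveled, mode)
            state.consumptions.append(cons)
            new_events.append(cons)
            events.append((tick, fx[hit], fy[hit], i))
            for child in state.children_of.get(hit, ()):
                status[child] = 1
                live.append(child)
        else:
            traveled = L
        px[i], py[i] = ex, ey
        hx[i], hy[i] = ux, uy
        state.path[i] += traveled
    return new_events


def run_simulation(config: SimulationConfig, field: FlakeField,
                   seed: int | None = None,
                   record_trajectory: bool = True) -> SimulationRecord:
    """Run one foraging simulation until all flakes are consumed or
    ``config.max_ticks`` is reached; fully reproducible under the seed."""
    used_seed = config.seed if seed is None else seed
    rng = random.Random(used_seed)
    state = _SimState(config, field, rng)
    strategies = [MODELS[s] for s in config.agent_strategies()]
    dists = config.agent_step_dists()
    n_total = field.n_flakes

    pos_hist = [np.array([state.px, state.py]).T] if record_trajectory else None
    head_hist = [np.array([state.hx, state.hy]).T] if record_trajectory else None

    # an empty field has nothing to stop on: run out the clock
    while state.tick < config.max_ticks and (n_total == 0 or state.consumed_count < n_total):
        advance_group(state, config, strategies, dists)
        if record_trajectory:
            pos_hist.append(np.array([state.px, state.py]).T)
            head_hist.append(np.array([state.hx, state.hy]).T)

    final = [AgentState(state.px[i], state.py[i], state.hx[i], state.hy[i],
                        config.agent_strategies()[i]) for i in range(config.k)]
    return SimulationRecord(
        config=config, field=field, seed=used_seed, n_ticks=state.tick,
        consumptions=state.consumptions,
        positions=np.stack(pos_hist) if record_trajectory else None,
        headings=np.stack(head_hist) if record_trajectory else None,
        final_state=final,
    )


def bouts_to_seconds(record: SimulationRecord, avg_speed: float) -> np.ndarray:
    """Convert consumption events to seconds: each bout lasts L/avg_speed, so
    an event's time is the consumer's cumulative path length over its own
    bouts divided by the average real-fish speed.  Times are returned in
    consumption-log order."""
    if avg_speed <= 0:
        raise ValueError("avg_speed must be positive")
    return np.array([c.path_bl / avg_speed for c in record.consumptions])


def make_mixed_group(config: SimulationConfig, n_social: int,
                     social_model: str = "att_feed_align",
                     seed: int | None = None) -> SimulationConfig:
    """Mixed-strategy group: ``n_social`` agents use ``social_model``, the
    rest forage independently; which agents are social is a seeded draw."""
    if not 0 <= n_social <= config.k:
        raise ValueError("n_social must be between 0 and k")
    rng = random.Random(config.seed if seed is None else seed)
    idx = list(range(config.k))
    rng.shuffle(idx)
    strategies = ["ind"] * config.k
    for i in idx[:n_social]:
        strategies[i] = social_model
    dn = config.dn if n_social > 0 else 0.0
    model = social_model if n_social > 0 else "ind"
    return replace(config, model=model, dn=dn, strategies=strategies)


def ensemble_seeds(master_seed: int, reps: int) -> list[int]:
    """Per-repetition seeds derived from a master seed by a fixed counter
    scheme (kept below 2^31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(reps)]


def run_ensemble(config: SimulationConfig, field: FlakeField, reps: int,
                 master_seed: int | None = None,
                 record_trajectory: bool = False) -> list[SimulationRecord]:
    """``reps`` independent repetitions with per-rep seeds derived from the
    master seed."""
    seeds = ensemble_seeds(config.seed if master_seed is None else master_seed, reps)
    return [run_simulation(config, field, seed=s, record_trajectory=record_trajectory)
            for s in seeds]
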