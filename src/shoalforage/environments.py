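"""Spatial distributions of food flakes and their clustering statistics.

Simulated foraging runs on flake fields: clustered (flakes confined to one,
two or three small circles near the arena wall), random (uniform placements
accepted only when a Clark-Evans-type coefficient certifies no spatial
clustering), hexagonal-grid (an approximation of a uniform covering), or
empirical fields replayed from data, including disintegration parentage
(a consumed flake can spawn child flakes at recorded positions).

Distances are in body lengths (BL); the default arena radius is 32 BL
(95 cm diameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinematics import CM_PER_BL, DEFAULT_ARENA_RADIUS_BL

#: cluster circle diameter, 9.5 cm expressed in BL (~3.2 BL)
CLUSTER_DIAMETER_BL = 9.5 / CM_PER_BL
#: cluster centers sit 20 cm (~6.74 BL) from the arena wall
CLUSTER_WALL_OFFSET_BL = 20.0 / CM_PER_BL


@dataclass
class FlakeField:
    """Flake positions with appearance/consumption dynamics.

    ``parent`` holds, per flake, the id of the flake whose (partial)
    consumption spawned it, or -1; a child appears only once its parent has
    been consumed.  ``t_appear`` / ``t_consumed`` are in seconds (NaN for
    "never consumed"); generated fields appear at t = 0 with no parentage.
    """

    x: np.ndarray
    y: np.ndarray
    arena_radius: float = DEFAULT_ARENA_RADIUS_BL
    t_appear: np.ndarray = field(default=None)
    t_consumed: np.ndarray = field(default=None)
    parent: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.x.size
        if self.t_appear is None:
            self.t_appear = np.zeros(n)
        if self.t_consumed is None:
            self.t_consumed = np.full(n, np.nan)
        if self.parent is None:
            self.parent = np.full(n, -1, dtype=int)
        self.t_appear = np.asarray(self.t_appear, dtype=float)
        self.t_consumed = np.asarray(self.t_consumed, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        r = np.hypot(self.x, self.y)
        if np.any(r >= self.arena_radius):
            raise ValueError("all flakes must lie strictly inside the arena")

    @property
    def n_flakes(self) -> int:
        return self.x.size

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class ClusterScore:
    """Nearest-neighbor clustering summary of a flake field.

    ``coefficient`` is the Clark-Evans ratio minus one,
    C = NN1 / (0.5 / sqrt(rho)) - 1 = 2 * NN1 * sqrt(rho) - 1, which is ~0
    under complete spatial randomness, negative for clustered fields and
    positive for over-dispersed ones.  ``score`` is the Monte-Carlo z-score
    D(n) = (NN1 - mu_rand) / sigma_rand against uniform placements of the
    same flake count in the same arena.
    """

    nn1: float
    density: float
    coefficient: float
    score: float
    null_mean: float
    null_sd: float
    n_draws: int


def _mean_nn_distance(x: np.ndarray, y: np.ndarray) -> float:
    pts = np.column_stack([x, y])
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    return float(np.mean(np.sqrt(d2.min(axis=1))))


def clark_evans_coefficient(field: FlakeField) -> float:
    """C = 2 * NN1 * sqrt(rho) - 1; ~0 under complete spatial randomness."""
    if field.n_flakes < 2:
        raise ValueError("coefficient undefined for fewer than 2 flakes")
    rho = field.n_flakes / (math.pi * field.arena_radius**2)
    return 2.0 * _mean_nn_distance(field.x, field.y) * math.sqrt(rho) - 1.0


def _uniform_disc(n: int, radius: float, rng: np.random.Generator):
    r = radius * np.sqrt(rng.random(n))
    phi = 2.0 * math.pi * rng.random(n)
    return r * np.cos(phi), r * np.sin(phi)


def _cluster_centers(n_clusters: int, arena_radius: float) -> list[tuple[float, float]]:
    rc = arena_radius - CLUSTER_WALL_OFFSET_BL
    if n_clusters == 1:
        return [(rc, 0.0)]
    if n_clusters == 2:
        # on a diameter, maximally separated
        return [(rc, 0.0), (-rc, 0.0)]
    if n_clusters == 3:
        # vertices of an equilateral triangle
        angles = [math.pi / 2, math.pi / 2 + 2 * math.pi / 3, math.pi / 2 + 4 * math.pi / 3]
        return [(rc * math.cos(a), rc * math.sin(a)) for a in angles]
    raise ValueError("n_clusters must be 1, 2 or 3")


def generate_clustered_field(n_clusters: int, n_flakes: int = 18,
                             arena_radius: float = DEFAULT_ARENA_RADIUS_BL,
                             seed: int | None = 0) -> FlakeField:
    """Flakes uniformly placed inside 1-3 small circles (diameter 9.5 cm,
    centers 20 cm from the wall, maximally separated); counts divided as
    evenly as possible among clusters."""
    rng = np.random.default_rng(seed)
    r_cluster = CLUSTER_DIAMETER_BL / 2.0
    centers = _cluster_centers(n_clusters, arena_radius)
    for cx, cy in centers:
        if math.hypot(cx, cy) + r_cluster >= arena_radius:
            raise ValueError("cluster circle extends beyond the arena")
    base, extra = divmod(n_flakes, n_clusters)
    xs, ys = [], []
    for i, (cx, cy) in enumerate(centers):
        m = base + (1 if i < extra else 0)
        dx, dy = _uniform_disc(m, r_cluster, rng)
        xs.append(cx + dx)
        ys.append(cy + dy)
    return FlakeField(np.concatenate(xs), np.concatenate(ys), arena_radius)


def generate_random_field(n_flakes: int = 18,
                          arena_radius: float = DEFAULT_ARENA_RADIUS_BL,
                          seed: int | None = 0,
                          tolerance: float = 0.01,
                          max_attempts: int = 100_000) -> FlakeField:
    """Uniform placements re-drawn until |C| < tolerance, certifying the
    accepted field shows no spatial clustering."""
    rng = np.random.default_rng(seed)
    rho = n_flakes / (math.pi * arena_radius**2)
    for _ in range(max_attempts):
        x, y = _uniform_disc(n_flakes, arena_radius * (1 - 1e-9), rng)
        c = 2.0 * _mean_nn_distance(x, y) * math.sqrt(rho) - 1.0
        if abs(c) < tolerance:
            return FlakeField(x, y, arena_radius)
    raise RuntimeError(
        f"no field with |C| < {tolerance} found in {max_attempts} attempts "
        f"(n_flakes={n_flakes}, arena_radius={arena_radius})"
    )


def generate_hex_grid_field(n_flakes: int = 18,
                            arena_radius: float = DEFAULT_ARENA_RADIUS_BL) -> FlakeField:
    """N+1 sites of a triangular (hexagonal) lattice spread over the arena,
    with the center site removed so foragers can start at the arena center.

    The lattice constant is tuned so that exactly N+1 sites fall inside the
    arena; the construction is deterministic.
    """
    target = n_flakes + 1

    def sites(a: float) -> np.ndarray:
        m = int(arena_radius / a) + 2
        pts = []
        for i in range(-m, m + 1):
            for j in range(-m, m + 1):
                px = a * (i + 0.5 * j)
                py = a * (math.sqrt(3) / 2.0) * j
                if math.hypot(px, py) < arena_radius * (1 - 1e-9):
                    pts.append((px, py))
        return np.array(pts)

    lo, hi = arena_radius / 50.0, 2.0 * arena_radius
    for _ in range(200):
        a = 0.5 * (lo + hi)
        n = len(sites(a))
        if n == target:
            break
        if n > target:
            lo = a
        else:
            hi = a
    pts = sites(a)
    if len(pts) != target:
        raise ValueError(f"no lattice constant yields exactly {target} sites")
    r = np.hypot(pts[:, 0], pts[:, 1])
    center = int(np.argmin(r))
    if r[center] > 1e-9 * arena_radius:
        raise ValueError("lattice has no center site to remove")
    pts = np.delete(pts, center, axis=0)
    return FlakeField(pts[:, 0], pts[:, 1], arena_radius)


def clustering_score(field: FlakeField, n_draws: int = 100_000,
                     seed: int | None = 0) -> ClusterScore:
    """Monte-Carlo clustering z-score of a field's mean NN distance.

    The null distribution is built from ``n_draws`` uniform placements of the
    same flake count in the same arena (the production default of 100,000
    draws is scalable down for tests).
    """
    if field.n_flakes < 2:
        raise ValueError("clustering score undefined for a single flake")
    rng = np.random.default_rng(seed)
    nn1 = _mean_nn_distance(field.x, field.y)
    rho = field.n_flakes / (math.pi * field.arena_radius**2)
    null = np.empty(n_draws)
    for i in range(n_draws):
        x, y = _uniform_disc(field.n_flakes, field.arena_radius, rng)
        null[i] = _mean_nn_distance(x, y)
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    return ClusterScore(
        nn1=nn1, density=rho,
        coefficient=2.0 * nn1 * math.sqrt(rho) - 1.0,
        score=(nn1 - mu) / sd, null_mean=mu, null_sd=sd, n_draws=n_draws,
    )
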