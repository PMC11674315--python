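"""Dynamic axon growth under a distance-decaying chemoattractive force field.

Every node center exerts an attractive force on a growth cone at position
``s``; the net force is

    F(s) = sum_i (R_i - s) / |R_i - s|^(beta + 1)

so a single node at distance ``d`` pulls with magnitude ``d**(-beta)``.  The
exponent ``beta`` controls how steeply attraction decays with distance: large
``beta`` hands control to the nearest nodes and favors short connections.

Axons are seeded uniformly at random on the circumference and extended in
constant steps of length ``L_s`` along the (clamped) net-force direction.
From the second step onward the turn per step is limited to ``theta`` — a
regularity constraint that forbids biologically implausible sharp turns.  An
axon terminates successfully at the analytic intersection of its current step
segment with the circle; axons that fail to reach the circumference within
``S_max`` steps (e.g. trapped in the small-``beta`` "black hole" region) are
recorded as unsuccessful and excluded from network construction.

A constrained-random-walk null model replaces the force rule by i.i.d. turns
drawn from ``U(-theta, theta)``; everything else (seeding, step length,
termination) is identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import GeometryError, InvalidParameterError, SingularForceError
from .geometry import ON_CIRCLE_RTOL, NodeLayout, TWO_PI

#: Growth cones closer than this (relative to R) to a node center make the
#: force singular; such axons are terminated as unsuccessful.
SINGULAR_RTOL = 1e-12

#: Minimum along-segment parameter for a circle intersection to count as a
#: termination (relative to R); excludes the seed point itself at t = 0.
INTERSECT_RTOL = 1e-9

STATUS_SUCCESS = 0
STATUS_MAX_STEPS = 1
STATUS_SINGULAR = 2

_STATUS_NAMES = {
    STATUS_SUCCESS: "successful",
    STATUS_MAX_STEPS: "max_steps_exceeded",
    STATUS_SINGULAR: "singular",
}


@dataclass(frozen=True)
class GrowthConfig:
    """Parameters of one simulation run.

    ``s_max`` defaults to ``ceil(3 R / L_s)`` (the radius is supplied by the
    layout when the simulation starts); ``theta`` is stored in radians and
    defaults to 15 degrees.
    """

    beta: float
    step_length: float
    theta: float = math.radians(15.0)
    s_max: int | None = None
    n_axons: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.step_length > 0:
            raise InvalidParameterError(f"step_length must be > 0, got {self.step_length}")
        if not 0 < self.theta < math.pi:
            raise InvalidParameterError(f"theta must be in (0, pi), got {self.theta}")
        if self.s_max is not None and self.s_max < 1:
            raise InvalidParameterError(f"s_max must be >= 1, got {self.s_max}")
        if self.n_axons < 0:
            raise InvalidParameterError(f"n_axons must be >= 0, got {self.n_axons}")

    def resolve_s_max(self, radius: float) -> int:
        """``S_max = ceil(3 R / L_s)`` unless set explicitly."""
        if self.s_max is not None:
            return int(self.s_max)
        return int(math.ceil(3.0 * radius / self.step_length))


@dataclass(frozen=True)
class AxonTrajectory:
    """Full path of a single axon.

    ``positions`` holds the seed, every interior growth-cone position and —
    for successful axons — the terminal intersection point on the circle.
    ``step_directions`` holds the unit direction of each executed step.
    """

    seed_point: np.ndarray
    positions: np.ndarray
    step_directions: np.ndarray
    status: str

    @property
    def successful(self) -> bool:
        return self.status == "successful"

    @property
    def endpoint(self) -> np.ndarray | None:
        return self.positions[-1] if self.successful else None

    @property
    def n_steps(self) -> int:
        return len(self.step_directions)


@dataclass(frozen=True)
class SimulationResult:
    """Batch result of :func:`simulate_axons` / :func:`simulate_random_walk_null`.

    Stores per-axon seed points, endpoints (NaN for unsuccessful axons),
    integer status codes and step counts as flat arrays; full trajectories can
    be re-derived one axon at a time with :meth:`trajectory`.
    """

    layout: NodeLayout
    config: GrowthConfig
    kind: str  # "model" | "random_walk"
    seed_points: np.ndarray
    endpoints: np.ndarray
    status: np.ndarray
    n_steps: np.ndarray
    _turns: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_axons(self) -> int:
        return len(self.status)

    @property
    def success_mask(self) -> np.ndarray:
        return self.status == STATUS_SUCCESS

    @property
    def n_successful(self) -> int:
        return int(self.success_mask.sum())

    @property
    def n_unsuccessful(self) -> int:
        return self.n_axons - self.n_successful

    def status_names(self) -> list[str]:
        return [_STATUS_NAMES[int(s)] for s in self.status]

    def trajectory(self, axon_id: int) -> AxonTrajectory:
        """Re-propagate axon ``axon_id`` with the scalar stepper, recording its path."""
        if self.kind == "model":
            return grow_axon(self.seed_points[axon_id], self.layout, self.config)
        return _grow_random_walk_scalar(
            self.seed_points[axon_id], self.layout, self.config, self._turns[axon_id]
        )


# ---------------------------------------------------------------------------
# Force field and direction clamping (public, vectorized over nodes)
# ---------------------------------------------------------------------------


def net_force(point: np.ndarray, layout: NodeLayout, beta: float) -> np.ndarray:
    """Net attractive force ``sum_i (R_i - s)/|R_i - s|**(beta+1)`` at ``point``.

    Raises :class:`SingularForceError` when ``point`` lies within tolerance of
    a node center (magnitude diverges there).
    """
    s = np.asarray(point, dtype=float)
    diff = layout.center_coords - s[None, :]
    d = np.hypot(diff[:, 0], diff[:, 1])
    if np.any(d < SINGULAR_RTOL * layout.radius):
        raise SingularForceError(f"point {s} coincides with a node center")
    w = d ** (-(beta + 1.0))
    return (diff * w[:, None]).sum(axis=0)


def clamp_direction(prev_dir: np.ndarray, desired_dir: np.ndarray, theta: float) -> np.ndarray:
    """Limit the turn from ``prev_dir`` to ``desired_dir`` to at most ``theta``.

    Both inputs are unit vectors.  If the angle between them exceeds ``theta``
    the previous direction is rotated by exactly ``theta`` toward the desired
    one; an exactly antiparallel desired direction rotates counterclockwise by
    convention, and a zero desired direction falls back to ``prev_dir``.
    """
    p = np.asarray(prev_dir, dtype=float)
    w = np.asarray(desired_dir, dtype=float)
    if np.hypot(w[0], w[1]) == 0.0:
        return p.copy()
    x, y = _clamp_scalar(p[0], p[1], w[0], w[1], theta)
    return np.array([x, y])


def _clamp_scalar(px: float, py: float, wx: float, wy: float, theta: float):
    """Pure-Python twin of the kernel clamp; shared by the scalar stepper."""
    cross = px * wy - py * wx
    dot = px * wx + py * wy
    ang = math.atan2(cross, dot)
    if abs(ang) <= theta:
        return wx, wy
    if cross == 0.0:
        s = 1.0  # antiparallel: counterclockwise by convention
    else:
        s = 1.0 if ang > 0.0 else -1.0
    ca = math.cos(theta)
    sa = math.sin(theta) * s
    return px * ca - py * sa, px * sa + py * ca


def _force_seq(px: float, py: float, cx: np.ndarray, cy: np.ndarray, beta: float, radius: float):
    """Sequential (left-to-right) force summation, mirroring the numba kernel
    term for term so scalar and batch propagation agree bitwise."""
    e = -(beta + 1.0) / 2.0
    sing_d2 = (SINGULAR_RTOL * radius) ** 2
    fx = 0.0
    fy = 0.0
    for i in range(len(cx)):
        dx = cx[i] - px
        dy = cy[i] - py
        d2 = dx * dx + dy * dy
        if d2 < sing_d2:
            return 0.0, 0.0, True
        if beta == 1.0:
            w = 1.0 / d2
        else:
            w = d2**e
        fx += dx * w
        fy += dy * w
    return fx, fy, False


# ---------------------------------------------------------------------------
# Numba batch kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _propagate_batch(
    seeds: np.ndarray,
    cx: np.ndarray,
    cy: np.ndarray,
    radius: float,
    beta: float,
    ls: float,
    theta: float,
    s_max: int,
    turns: np.ndarray,
    use_force: bool,
):  # pragma: no cover - exercised via simulate_axons
    n = seeds.shape[0]
    n_nodes = cx.shape[0]
    endpoints = np.full((n, 2), np.nan)
    status = np.full(n, STATUS_MAX_STEPS, dtype=np.int8)
    n_steps = np.zeros(n, dtype=np.int64)
    e = -(beta + 1.0) / 2.0
    sing_d2 = (SINGULAR_RTOL * radius) ** 2
    t_min = INTERSECT_RTOL * radius
    r2 = radius * radius
    for a in range(n):
        px = seeds[a, 0]
        py = seeds[a, 1]
        dirx = 0.0
        diry = 0.0
        for step in range(s_max):
            if use_force:
                fx = 0.0
                fy = 0.0
                singular = False
                for i in range(n_nodes):
                    dx = cx[i] - px
                    dy = cy[i] - py
                    d2 = dx * dx + dy * dy
                    if d2 < sing_d2:
                        singular = True
                        break
                    if beta == 1.0:
                        w = 1.0 / d2
                    else:
                        w = d2**e
                    fx += dx * w
                    fy += dy * w
                if singular:
                    status[a] = STATUS_SINGULAR
                    break
                fm = math.sqrt(fx * fx + fy * fy)
                if step == 0:
                    if fm == 0.0:
                        dirx = -px / radius
                        diry = -py / radius
                    else:
                        dirx = fx / fm
                        diry = fy / fm
                elif fm > 0.0:
                    wx = fx / fm
                    wy = fy / fm
                    cr = dirx * wy - diry * wx
                    dt = dirx * wx + diry * wy
                    ang = math.atan2(cr, dt)
                    if abs(ang) <= theta:
                        dirx = wx
                        diry = wy
                    else:
                        if cr == 0.0:
                            s = 1.0
                        else:
                            s = 1.0 if ang > 0.0 else -1.0
                        ca = math.cos(theta)
                        sa = math.sin(theta) * s
                        ndx = dirx * ca - diry * sa
                        ndy = dirx * sa + diry * ca
                        dirx = ndx
                        diry = ndy
            else:
                u = turns[a, step]
                if step == 0:
                    nx = -px / radius
                    ny = -py / radius
                    dirx = nx * math.cos(u) - ny * math.sin(u)
                    diry = nx * math.sin(u) + ny * math.cos(u)
                else:
                    ndx = dirx * math.cos(u) - diry * math.sin(u)
                    ndy = dirx * math.sin(u) + diry * math.cos(u)
                    dirx = ndx
                    diry = ndy
            # segment-circle intersection: |p + t*dir| = R, take smallest t > t_min
            b = px * dirx + py * diry
            c = px * px + py * py - r2
            disc = b * b - c
            terminated = False
            if disc > 0.0:
                root = math.sqrt(disc)
                t = -b - root
                if t <= t_min:
                    t = -b + root
                if t_min < t <= ls:
                    endpoints[a, 0] = px + t * dirx
                    endpoints[a, 1] = py + t * diry
                    status[a] = STATUS_SUCCESS
                    n_steps[a] = step + 1
                    terminated = True
            if terminated:
                break
            px += ls * dirx
            py += ls * diry
            n_steps[a] = step + 1
    return endpoints, status, n_steps


# ---------------------------------------------------------------------------
# Scalar reference stepper
# ---------------------------------------------------------------------------


def _on_circle_or_raise(point: np.ndarray, layout: NodeLayout) -> None:
    r = math.hypot(point[0], point[1])
    if abs(r - layout.radius) > max(ON_CIRCLE_RTOL * layout.radius, 1e-12):
        raise GeometryError(f"seed point {point} is not on the circumference")


def _intersect(px, py, dirx, diry, radius, ls):
    """Smallest admissible t with |p + t*dir| = R, or None."""
    t_min = INTERSECT_RTOL * radius
    b = px * dirx + py * diry
    c = px * px + py * py - radius * radius
    disc = b * b - c
    if disc <= 0.0:
        return None
    root = math.sqrt(disc)
    t = -b - root
    if t <= t_min:
        t = -b + root
    if t_min < t <= ls:
        return t
    return None


def grow_axon(seed_point: np.ndarray, layout: NodeLayout, config: GrowthConfig) -> AxonTrajectory:
    """Propagate one axon with the scalar reference stepper, recording its path.

    The first step follows the (unclamped) normalized net force at the seed;
    subsequent steps clamp the turn to ``theta``.  Mirrors the batch kernel's
    arithmetic exactly, so it doubles as its independent reference.
    """
    seed = np.asarray(seed_point, dtype=float)
    _on_circle_or_raise(seed, layout)
    coords = layout.center_coords
    cx = np.ascontiguousarray(coords[:, 0])
    cy = np.ascontiguousarray(coords[:, 1])
    radius = layout.radius
    ls = config.step_length
    s_max = config.resolve_s_max(radius)
    px, py = seed
    dirx = diry = 0.0
    positions = [seed.copy()]
    directions = []
    status = STATUS_MAX_STEPS
    for step in range(s_max):
        fx, fy, singular = _force_seq(px, py, cx, cy, config.beta, radius)
        if singular:
            status = STATUS_SINGULAR
            break
        fm = math.sqrt(fx * fx + fy * fy)
        if step == 0:
            if fm == 0.0:
                dirx, diry = -px / radius, -py / radius
            else:
                dirx, diry = fx / fm, fy / fm
        elif fm > 0.0:
            dirx, diry = _clamp_scalar(dirx, diry, fx / fm, fy / fm, config.theta)
        t = _intersect(px, py, dirx, diry, radius, ls)
        directions.append((dirx, diry))
        if t is not None:
            positions.append(np.array([px + t * dirx, py + t * diry]))
            status = STATUS_SUCCESS
            break
        px += ls * dirx
        py += ls * diry
        positions.append(np.array([px, py]))
    return AxonTrajectory(
        seed_point=seed,
        positions=np.array(positions),
        step_directions=np.array(directions) if directions else np.empty((0, 2)),
        status=_STATUS_NAMES[status],
    )


def _grow_random_walk_scalar(
    seed_point: np.ndarray, layout: NodeLayout, config: GrowthConfig, turns: np.ndarray
) -> AxonTrajectory:
    """Scalar random-walk stepper sharing axon-specific ``turns`` with the batch."""
    seed = np.asarray(seed_point, dtype=float)
    _on_circle_or_raise(seed, layout)
    radius = layout.radius
    ls = config.step_length
    s_max = config.resolve_s_max(radius)
    px, py = seed
    dirx = diry = 0.0
    positions = [seed.copy()]
    directions = []
    status = STATUS_MAX_STEPS
    for step in range(s_max):
        u = turns[step]
        if step == 0:
            nx, ny = -px / radius, -py / radius
            dirx = nx * math.cos(u) - ny * math.sin(u)
            diry = nx * math.sin(u) + ny * math.cos(u)
        else:
            dirx, diry = (
                dirx * math.cos(u) - diry * math.sin(u),
                dirx * math.sin(u) + diry * math.cos(u),
            )
        t = _intersect(px, py, dirx, diry, radius, ls)
        directions.append((dirx, diry))
        if t is not None:
            positions.append(np.array([px + t * dirx, py + t * diry]))
            status = STATUS_SUCCESS
            break
        px += ls * dirx
        py += ls * diry
        positions.append(np.array([px, py]))
    return AxonTrajectory(
        seed_point=seed,
        positions=np.array(positions),
        step_directions=np.array(directions) if directions else np.empty((0, 2)),
        status=_STATUS_NAMES[status],
    )


# ---------------------------------------------------------------------------
# Batch simulation
# ---------------------------------------------------------------------------

_NULL_CHUNK = 50_000  # axons per random-walk chunk (bounds the turn matrix)


def _seed_points(layout: NodeLayout, n_axons: int, rng: np.random.Generator) -> np.ndarray:
    phi = rng.uniform(0.0, TWO_PI, size=n_axons)
    return layout.radius * np.column_stack((np.cos(phi), np.sin(phi)))


def simulate_axons(layout: NodeLayout, config: GrowthConfig) -> SimulationResult:
    """Seed ``n_axons`` axons uniformly on the circumference and grow them all.

    Growth is deterministic given the seed points (the force field contains no
    noise), so the only randomness is the seeding itself, drawn from a
    substream of ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    seeds = _seed_points(layout, config.n_axons, rng)
    coords = layout.center_coords
    endpoints, status, n_steps = _propagate_batch(
        seeds,
        np.ascontiguousarray(coords[:, 0]),
        np.ascontiguousarray(coords[:, 1]),
        layout.radius,
        float(config.beta),
        float(config.step_length),
        float(config.theta),
        config.resolve_s_max(layout.radius),
        np.empty((0, 0)),
        True,
    )
    return SimulationResult(
        layout=layout,
        config=config,
        kind="model",
        seed_points=seeds,
        endpoints=endpoints,
        status=status,
        n_steps=n_steps,
    )


def simulate_random_walk_null(layout: NodeLayout, config: GrowthConfig) -> SimulationResult:
    """Constrained-random-walk null: turns ``~ U(-theta, theta)`` replace the
    force rule; the first direction is uniform over the inward semicircle.

    Per-axon turn sequences are materialized as rows of a turns matrix so that
    scalar re-propagation of any axon reproduces the batch result exactly.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(1,))
    rng_seed = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    rng_turn = np.random.default_rng(ss)
    seeds = _seed_points(layout, config.n_axons, rng_seed)
    coords = layout.center_coords
    cx = np.ascontiguousarray(coords[:, 0])
    cy = np.ascontiguousarray(coords[:, 1])
    s_max = config.resolve_s_max(layout.radius)
    endpoints = np.full((config.n_axons, 2), np.nan)
    status = np.full(config.n_axons, STATUS_MAX_STEPS, dtype=np.int8)
    n_steps = np.zeros(config.n_axons, dtype=np.int64)
    all_turns = np.empty((config.n_axons, s_max)) if config.n_axons <= _NULL_CHUNK else None
    for lo in range(0, config.n_axons, _NULL_CHUNK):
        hi = min(lo + _NULL_CHUNK, config.n_axons)
        turns = np.empty((hi - lo, s_max))
        turns[:, 0] = rng_turn.uniform(-math.pi / 2, math.pi / 2, size=hi - lo)
        if s_max > 1:
            turns[:, 1:] = rng_turn.uniform(-config.theta, config.theta, size=(hi - lo, s_max - 1))
        ep, st, ns = _propagate_batch(
            seeds[lo:hi],
            cx,
            cy,
            layout.radius,
            float(config.beta),
            float(config.step_length),
            float(config.theta),
            s_max,
            turns,
            False,
        )
        endpoints[lo:hi] = ep
        status[lo:hi] = st
        n_steps[lo:hi] = ns
        if all_turns is not None:
            all_turns[lo:hi] = turns
    return SimulationResult(
        layout=layout,
        config=config,
        kind="random_walk",
        seed_points=seeds,
        endpoints=endpoints,
        status=status,
        n_steps=n_steps,
        _turns=all_turns,
    )
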