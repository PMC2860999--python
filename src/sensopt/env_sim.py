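"""Maze geometries and the agent's noisy motion primitives.

The simulated agent lives in a bounded two-dimensional arena and moves by
executing one of eight action primitives: travel a fixed distance
(``step_length``) in one of eight compass directions spaced 45 degrees
apart.  Both the travelled distance and the heading receive additive
Gaussian noise.  When the straight-line path would leave the arena the
agent reflects off the wall specularly (reflection angle equals incidence
angle), possibly repeatedly within a single step.

Three canonical arenas are provided, all with bounding boxes of roughly
20 x 20 step units: a circle, an axis-aligned square and a fixed
irregular polygon that perturbs a square.  All arenas are centred on the
origin and angles are measured counterclockwise from the +x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path

__all__ = [
    "Maze",
    "MotorParams",
    "make_maze",
    "sample_action_outcome",
    "reflect_move",
    "CANONICAL_STEP_LENGTHS",
    "CANONICAL_SIGMA_SL",
    "CANONICAL_SIGMA_A",
]

# Canonical motor-parameter grids used throughout the study.
CANONICAL_STEP_LENGTHS = (1.0, 2.0, 3.0, 4.0)
CANONICAL_SIGMA_SL = (1 / 15, 2 / 15, 3 / 15)
CANONICAL_SIGMA_A = (2.0, 6.0, 12.3)

# Fixed irregular arena: a 16-vertex star-shaped (hence simple) polygon on
# [-1, 1]^2, scaled by scale/2 at construction.  Versioned: changing these
# vertices changes every downstream result for the irregular maze.
_IRREGULAR_UNIT = np.array(
    [
        (1.00, -0.10),
        (0.92, 0.35),
        (1.02, 0.78),
        (0.55, 0.95),
        (0.12, 0.88),
        (-0.30, 1.00),
        (-0.75, 0.92),
        (-1.00, 0.60),
        (-0.88, 0.18),
        (-1.02, -0.25),
        (-0.80, -0.70),
        (-0.45, -1.00),
        (-0.05, -0.85),
        (0.40, -0.98),
        (0.78, -0.82),
        (0.95, -0.45),
    ]
)


@dataclass
class Maze:
    """A simply connected 2-D arena: a circle or a simple polygon.

    Parameters
    ----------
    kind
        One of ``"circular"``, ``"square"``, ``"irregular"``.
    radius
        Circle radius (``kind == "circular"`` only).
    vertices
        ``(V, 2)`` array of polygon vertices in counterclockwise order
        (polygonal kinds only).  The polygon must be simple and closed
        (first vertex implicitly follows the last).
    """

    kind: str
    radius: float | None = None
    vertices: np.ndarray | None = None
    _path: Path | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.vertices is not None:
            v = np.asarray(self.vertices, dtype=float)
            if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
                raise ValueError("polygon needs at least 3 (x, y) vertices")
            # canonicalize to counterclockwise orientation
            area2 = np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
            if area2 < 0:
                v = v[::-1]
            self.vertices = v
            self._path = Path(v, closed=False)
        elif self.radius is None:
            raise ValueError("maze needs either a radius or vertices")
        elif self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def bbox(self) -> tuple[float, float]:
        """(width, height) of the bounding box in step units."""
        if self.vertices is None:
            return (2 * self.radius, 2 * self.radius)
        span = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return (float(span[0]), float(span[1]))

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        if self.vertices is None:
            r = self.radius
            return (-r, -r, r, r)
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return (float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1]))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized interior test for an ``(N, 2)`` array of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        if self.vertices is None:
            inside = pts[:, 0] ** 2 + pts[:, 1] ** 2 < self.radius**2
        else:
            inside = self._path.contains_points(pts)
        return bool(inside[0]) if single else inside

    def contains_point(self, x: float, y: float) -> bool:
        if self.vertices is None:
            return x * x + y * y < self.radius**2
        return bool(self._path.contains_point((x, y)))

    def sample_interior(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Uniform interior points by rejection from the bounding box."""
        xmin, ymin, xmax, ymax = self.bounds()
        out = np.empty((n, 2))
        have = 0
        while have < n:
            cand = rng.uniform((xmin, ymin), (xmax, ymax), size=(2 * (n - have) + 8, 2))
            cand = cand[self.contains(cand)]
            take = min(len(cand), n - have)
            out[have : have + take] = cand[:take]
            have += take
        return out[0] if n == 1 else out


@dataclass(frozen=True)
class MotorParams:
    """Parameters of the eight noisy action primitives.

    ``step_length`` and ``sigma_sl`` are in step units, ``sigma_a_deg`` in
    degrees.  The eight movement directions are k * 45 degrees for
    k = 0..7, counterclockwise from +x.
    """

    step_length: float = 1.0
    sigma_sl: float = 2 / 15
    sigma_a_deg: float = 6.0

    n_actions: int = 8

    def __post_init__(self) -> None:
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.sigma_sl < 0 or self.sigma_a_deg < 0:
            raise ValueError("noise SDs must be nonnegative")

    def directions(self) -> np.ndarray:
        """The eight nominal headings in radians."""
        return np.deg2rad(45.0 * np.arange(self.n_actions))


def make_maze(kind: str, scale: float = 20.0) -> Maze:
    """Build one of the three canonical arenas with bbox ~ scale x scale."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if kind == "circular":
        return Maze(kind="circular", radius=scale / 2)
    if kind == "square":
        h = scale / 2
        verts = np.array([(-h, -h), (h, -h), (h, h), (-h, h)])
        return Maze(kind="square", vertices=verts)
    if kind == "irregular":
        return Maze(kind="irregular", vertices=_IRREGULAR_UNIT * (scale / 2))
    raise ValueError(f"unknown maze kind: {kind!r}")


# ---------------------------------------------------------------------------
# Specular reflection geometry


def _first_hit_circle(p: np.ndarray, d: np.ndarray, radius: float):
    # smallest t in (0, 1] with |p + t d| = R, for p inside
    a = d @ d
    if a == 0.0:
        return None
    b = 2.0 * (p @ d)
    c = p @ p - radius * radius
    disc = b * b - 4 * a * c
    if disc < 0:
        return None
    t = (-b + np.sqrt(disc)) / (2 * a)
    if t <= 1e-12 or t > 1.0:
        return None
    hit = p + t * d
    n_in = -hit / np.linalg.norm(hit)
    return t, hit, n_in


def _first_hit_polygon(p: np.ndarray, d: np.ndarray, verts: np.ndarray):
    # segment p -> p+d against each edge; edges are ccw so the inward
    # normal of edge e = v2 - v1 is (-e_y, e_x)
    v1 = verts
    v2 = np.roll(verts, -1, axis=0)
    e = v2 - v1
    w = v1 - p
    denom = d[0] * (-e[:, 1]) + d[1] * e[:, 0]  # cross(d, -e) per edge
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * (-e[:, 1]) + w[:, 1] * e[:, 0]) / denom
        s = (d[0] * w[:, 1] - d[1] * w[:, 0]) / denom
    valid = (np.abs(denom) > 1e-300) & (t > 1e-12) & (t <= 1.0) & (s >= -1e-12) & (s <= 1 + 1e-12)
    if not valid.any():
        return None
    idx = np.flatnonzero(valid)
    best = idx[np.argmin(t[idx])]
    tb = t[best]
    hit = p + tb * d
    eb = e[best]
    n_in = np.array([-eb[1], eb[0]])
    n_in = n_in / np.linalg.norm(n_in)
    return tb, hit, n_in


def reflect_move(maze: Maze, pos: np.ndarray, disp: np.ndarray, max_reflections: int = 10) -> np.ndarray:
    """Move from ``pos`` by ``disp`` with specular wall reflection.

    The path is traced segment by segment: when it crosses the boundary,
    the remaining length is reflected about the wall (angle of reflection
    equals angle of incidence).  At polygon corners the first edge hit is
    used; if the reflected ray immediately exits again the procedure
    iterates, up to ``max_reflections`` times, after which the agent stops
    at the last interior point.  Total path length is preserved up to a
    tiny inward nudge applied at each bounce for numerical robustness.
    """
    p = np.asarray(pos, dtype=float).copy()
    d = np.asarray(disp, dtype=float).copy()
    for _ in range(max_reflections):
        target = p + d
        if maze.contains_point(target[0], target[1]):
            return target
        if maze.vertices is None:
            hit_info = _first_hit_circle(p, d, maze.radius)
        else:
            hit_info = _first_hit_polygon(p, d, maze.vertices)
        if hit_info is None:
            # numerically degenerate (e.g. grazing contact): stay put
            return p
        t, hit, n_in = hit_info
        rest = (1.0 - t) * d
        rest = rest - 2.0 * (rest @ n_in) * n_in
        p = hit + 1e-9 * n_in
        d = rest
    return p


def sample_action_outcome(
    pose: np.ndarray,
    action: int,
    mp: MotorParams,
    maze: Maze,
    rng: np.random.Generator,
) -> np.ndarray:
    """Execute one noisy action primitive and return the new position.

    The travelled length is drawn from N(step_length, sigma_sl^2), clipped
    at zero (a step cannot be negative); the heading from
    N(direction[action], sigma_a^2).  Wall contact is resolved by specular
    reflection.
    """
    pose = np.asarray(pose, dtype=float)
    if not maze.contains_point(pose[0], pose[1]):
        raise ValueError("pose is outside the maze")
    if not 0 <= action < mp.n_actions:
        raise ValueError(f"action index {action} out of range")
    length = max(0.0, rng.normal(mp.step_length, mp.sigma_sl))
    theta = mp.directions()[action] + np.deg2rad(rng.normal(0.0, mp.sigma_a_deg))
    disp = length * np.array([np.cos(theta), np.sin(theta)])
    return reflect_move(maze, pose, disp)
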