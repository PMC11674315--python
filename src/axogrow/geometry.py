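"""Circular domain geometry: node placement, perturbation, and 1D Voronoi regions.

The model domain is a circle of radius ``R``: the circumference stands in for
gray matter and the interior for white matter.  ``N_n`` node centers are placed
at equal angular spacing on the circumference and then perturbed along it by a
uniform angular displacement ``eps ~ rho * U(-pi/N_n, pi/N_n)``, which
introduces nodal heterogeneity while preserving the cyclic order of nodes.
Each point of the perimeter belongs to the region of its nearest (perturbed)
node center — a 1D Voronoi tessellation whose region boundaries are the
angular midpoints between cyclically adjacent centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeometryError, InvalidParameterError

TWO_PI = 2.0 * np.pi

#: Relative tolerance for "point lies on the circumference" checks.  Boundary
#: points are produced analytically (segment-circle intersections), so only
#: accumulated rounding error needs to be absorbed.
ON_CIRCLE_RTOL = 1e-9


@dataclass(frozen=True)
class NodeLayout:
    """Node centers on the circumference of a circle of radius ``radius``.

    Angles are stored unwrapped: ``base_angles[k] = 2*pi*k / n_nodes`` and the
    perturbed angle of node ``k`` is ``base_angles[k] + perturbations[k]``,
    which may leave ``[0, 2*pi)`` by less than ``pi/n_nodes`` at either end.
    """

    radius: float
    n_nodes: int
    rho: float
    base_angles: np.ndarray
    perturbations: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_angles", np.asarray(self.base_angles, dtype=float))
        object.__setattr__(self, "perturbations", np.asarray(self.perturbations, dtype=float))

    @property
    def angles(self) -> np.ndarray:
        """Perturbed node-center angles (radians, unwrapped)."""
        return self.base_angles + self.perturbations

    @property
    def center_coords(self) -> np.ndarray:
        """(n_nodes, 2) Cartesian coordinates of the perturbed centers."""
        a = self.angles
        return self.radius * np.column_stack((np.cos(a), np.sin(a)))

    @property
    def region_boundaries(self) -> np.ndarray:
        """Angular cut points between cyclically adjacent regions; see
        :func:`voronoi_regions`."""
        return voronoi_regions(self)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "radius": self.radius,
            "n_nodes": self.n_nodes,
            "rho": self.rho,
            "seed": self.seed,
            "perturbations": self.perturbations.tolist(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "NodeLayout":
        base = place_nodes(d["radius"], d["n_nodes"])
        return cls(
            radius=float(d["radius"]),
            n_nodes=int(d["n_nodes"]),
            rho=float(d["rho"]),
            base_angles=base.base_angles,
            perturbations=np.asarray(d["perturbations"], dtype=float),
            seed=d.get("seed"),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "NodeLayout":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def place_nodes(radius: float, n_nodes: int) -> NodeLayout:
    """Place ``n_nodes`` unperturbed centers at equal angular spacing.

    The first node sits at angle 0 by convention (the model is rotation
    invariant), so node ``k`` sits at angle ``2*pi*k / n_nodes``.
    """
    if not radius > 0:
        raise InvalidParameterError(f"radius must be positive, got {radius}")
    if int(n_nodes) != n_nodes or n_nodes < 2:
        raise InvalidParameterError(f"n_nodes must be an integer >= 2, got {n_nodes}")
    n_nodes = int(n_nodes)
    base = TWO_PI * np.arange(n_nodes) / n_nodes
    return NodeLayout(
        radius=float(radius),
        n_nodes=n_nodes,
        rho=0.0,
        base_angles=base,
        perturbations=np.zeros(n_nodes),
        seed=None,
    )


def perturb_nodes(
    layout: NodeLayout, rho: float, seed: int | np.random.Generator
) -> NodeLayout:
    """Apply angular displacements ``eps ~ rho * U(-pi/N_n, pi/N_n)`` per node.

    ``rho`` in [0, 1] scales heterogeneity; at ``rho = 1`` the displacement can
    reach half the inter-node gap, which maximizes heterogeneity while still
    preserving the cyclic node order along the perimeter.
    """
    if not 0.0 <= rho <= 1.0:
        raise InvalidParameterError(f"rho must be in [0, 1], got {rho}")
    if isinstance(seed, np.random.Generator):
        rng, stored_seed = seed, None
    else:
        rng, stored_seed = np.random.default_rng(seed), int(seed)
    half_gap = np.pi / layout.n_nodes
    eps = rho * rng.uniform(-half_gap, half_gap, size=layout.n_nodes)
    return NodeLayout(
        radius=layout.radius,
        n_nodes=layout.n_nodes,
        rho=float(rho),
        base_angles=layout.base_angles,
        perturbations=eps,
        seed=stored_seed,
    )


def voronoi_regions(layout: NodeLayout) -> np.ndarray:
    """Angular cut points of the 1D Voronoi tessellation of the circumference.

    Returns an array ``cuts`` of length ``n_nodes`` where ``cuts[i]`` is the
    midpoint angle between the centers of node ``i`` and node ``i+1`` (cyclic),
    reduced to ``[0, 2*pi)``.  The region of node ``i`` is the arc from
    ``cuts[i-1]`` to ``cuts[i]``; together the regions partition the perimeter
    with no gaps or overlaps because perturbation preserves node order.
    """
    a = layout.angles
    nxt = np.roll(a, -1)
    nxt[-1] += TWO_PI  # unwrap the last->first gap
    cuts = (a + nxt) / 2.0
    return np.mod(cuts, TWO_PI)


def region_arc_lengths(layout: NodeLayout) -> np.ndarray:
    """Arc length of every Voronoi region (sums to the full circumference)."""
    a = layout.angles
    gaps_fwd = np.diff(np.append(a, a[0] + TWO_PI))  # gap i -> i+1
    gaps_bwd = np.roll(gaps_fwd, 1)
    return layout.radius * (gaps_fwd + gaps_bwd) / 2.0


def assign_to_region(
    points: np.ndarray, layout: NodeLayout, *, rtol: float = ON_CIRCLE_RTOL
) -> np.ndarray | int:
    """Map circumference points to the index of their nearest node center.

    Arc distance and Euclidean (chord) distance are monotonically related on a
    circle, so nearest-center assignment uses arc distance.  Exact midpoint
    ties go to the lower node index (argmin convention).  Accepts one point
    ``(x, y)`` or an ``(m, 2)`` array; raises :class:`GeometryError` when a
    point is off the circumference beyond ``rtol * radius``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    single = np.asarray(points).ndim == 1
    r = np.hypot(pts[:, 0], pts[:, 1])
    # Absolute floor keeps the check meaningful for very small radii.
    tol = max(rtol * layout.radius, 1e-12)
    off = np.abs(r - layout.radius) > tol
    if np.any(off):
        worst = float(np.abs(r - layout.radius).max())
        raise GeometryError(
            f"{int(off.sum())} point(s) off the circumference "
            f"(max |r - R| = {worst:.3e}, tolerance {tol:.3e})"
        )
    idx = _nearest_center(pts, layout)
    return int(idx[0]) if single else idx


def _nearest_center(pts: np.ndarray, layout: NodeLayout, chunk: int = 65536) -> np.ndarray:
    """Vectorized arc-distance argmin, chunked to bound the (m, n_nodes) temporary."""
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    centers = layout.angles
    out = np.empty(len(pts), dtype=np.int64)
    for lo in range(0, len(pts), chunk):
        block = phi[lo : lo + chunk, None] - centers[None, :]
        d = np.abs((block + np.pi) % TWO_PI - np.pi)
        out[lo : lo + chunk] = np.argmin(d, axis=1)
    return out
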