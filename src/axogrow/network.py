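"""Weighted undirected networks from axon counts, plus density/weight controls.

The connectivity weight between two regions is the number of successful axons
whose two endpoints (seed and terminal intersection, both on the hypothetical
gray matter) map to those regions.  Within-region (self) connections are
discarded but counted.  Downstream analyses control for density by keeping the
``m`` strongest edges and for total connectivity by linear rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DensityError, InvalidParameterError
from .geometry import NodeLayout, _nearest_center
from .growth import STATUS_SUCCESS, SimulationResult


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative adjacency with zero diagonal.

    ``meta`` carries bookkeeping from construction (self-connection and
    unsuccessful-axon counts) and is not part of the network's identity.
    """

    weights: np.ndarray
    node_coords: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidParameterError(f"adjacency must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, rtol=1e-10, atol=1e-10):
            raise InvalidParameterError("adjacency must be symmetric")
        if np.any(w < 0):
            raise InvalidParameterError("adjacency must be nonnegative")
        w = (w + w.T) / 2.0  # absorb rounding asymmetry
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def degree(self) -> np.ndarray:
        """Number of nonzero neighbors per node."""
        return (self.weights > 0).sum(axis=1)

    @property
    def strength(self) -> np.ndarray:
        """Row sums of the adjacency."""
        return self.weights.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int((np.triu(self.weights, 1) > 0).sum())

    @property
    def density(self) -> float:
        """Nonzero upper-triangle pairs over ``n (n - 1) / 2``."""
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    @property
    def total_connectivity(self) -> float:
        """Sum of upper-triangle weights."""
        return float(np.triu(self.weights, 1).sum())

    def edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle nonzero edges as ``(i, j, w)`` in row-major order."""
        iu, ju = np.triu_indices(self.n_nodes, 1)
        w = self.weights[iu, ju]
        keep = w > 0
        return iu[keep], ju[keep], w[keep]

    def edge_distances(self) -> np.ndarray:
        """Euclidean center-to-center distance of every existing edge."""
        if self.node_coords is None:
            raise InvalidParameterError("network has no node coordinates")
        i, j, _ = self.edges()
        d = self.node_coords[i] - self.node_coords[j]
        return np.hypot(d[:, 0], d[:, 1])

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(
            self.weights.copy(),
            None if self.node_coords is None else self.node_coords.copy(),
            dict(self.meta),
        )


def build_network(result: SimulationResult, layout: NodeLayout | None = None) -> WeightedNetwork:
    """Tally successful axons into an axon-count adjacency matrix.

    Seed and endpoint of every successful axon are assigned to their nearest
    node centers; same-region pairs are discarded (counted in
    ``meta['self_connections']``) and unsuccessful axons are excluded
    (``meta['unsuccessful']``).
    """
    layout = layout if layout is not None else result.layout
    n = layout.n_nodes
    ok = result.status == STATUS_SUCCESS
    src = _nearest_center(result.seed_points[ok], layout)
    dst = _nearest_center(result.endpoints[ok], layout)
    self_mask = src == dst
    src, dst = src[~self_mask], dst[~self_mask]
    counts = np.bincount(src * n + dst, minlength=n * n).reshape(n, n).astype(float)
    w = counts + counts.T
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(
        w,
        node_coords=layout.center_coords,
        meta={
            "self_connections": int(self_mask.sum()),
            "unsuccessful": int(result.n_unsuccessful),
            "n_axons": int(result.n_axons),
        },
    )


def normalize_weights(net: WeightedNetwork) -> np.ndarray:
    """Strength-normalized edge weights ``w_ij / ((s_i + s_j) / 2)``.

    Returned in the same order as :meth:`WeightedNetwork.edges`.  These are
    the weights used for distribution fitting; they are invariant to a global
    rescaling of the raw counts.
    """
    i, j, w = net.edges()
    if len(w) == 0:
        raise InvalidParameterError("network has no edges")
    s = net.strength
    return w / ((s[i] + s[j]) / 2.0)


def threshold_to_density(
    net: WeightedNetwork, target_density: float, binarize: bool = False
) -> WeightedNetwork:
    """Keep the ``m`` strongest edges, ``m = round(target * n(n-1)/2)``.

    Ties are broken by stable lexicographic ``(i, j)`` order so the surviving
    edge set is deterministic and nested across densities.  Raises
    :class:`DensityError` when the network has fewer than ``m`` edges.
    """
    if not 0 < target_density <= 1:
        raise InvalidParameterError(f"target_density must be in (0, 1], got {target_density}")
    n = net.n_nodes
    m = int(round(target_density * n * (n - 1) / 2))
    i, j, w = net.edges()
    if len(w) < m:
        raise DensityError(
            f"network density {net.density:.4f} below target {target_density:.4f} "
            f"({len(w)} edges < {m} required)"
        )
    order = np.lexsort((j, i, -w))[:m]
    out = np.zeros_like(net.weights)
    vals = 1.0 if binarize else w[order]
    out[i[order], j[order]] = vals
    out[j[order], i[order]] = vals
    return WeightedNetwork(out, node_coords=net.node_coords, meta=dict(net.meta))


def rescale_total_connectivity(net: WeightedNetwork, total: float = 2e5) -> WeightedNetwork:
    """Linearly scale weights so the upper-triangle sum equals ``total``."""
    current = net.total_connectivity
    if current == 0:
        raise InvalidParameterError("cannot rescale an empty network")
    out = net.copy()
    out.weights = out.weights * (total / current)
    return out


# ---------------------------------------------------------------------------
# Adjacency / edge-list I/O (delimited text)
# ---------------------------------------------------------------------------


def write_adjacency(net: WeightedNetwork, path: str | Path) -> None:
    """Write the adjacency as a tab-delimited square matrix with an index
    header row and column."""
    df = pd.DataFrame(net.weights)
    df.to_csv(path, sep="\t", index=True, header=True)


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    """Write nonzero upper-triangle edges as a 3-column ``i j weight`` table."""
    i, j, w = net.edges()
    pd.DataFrame({"i": i, "j": j, "weight": w}).to_csv(path, sep="\t", index=False)


def read_network(path: str | Path, node_coords: np.ndarray | None = None) -> WeightedNetwork:
    """Read a network from either a square adjacency matrix (index header) or
    a 3-column edge list; symmetry and nonnegativity are validated."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if set(map(str, df.columns)) == {"j", "weight"} or list(df.columns) == ["j", "weight"]:
        # edge list written by write_edge_list (index column is i)
        df = df.reset_index()
        n = int(max(df["i"].max(), df["j"].max())) + 1
        w = np.zeros((n, n))
        w[df["i"], df["j"]] = df["weight"]
        w[df["j"], df["i"]] = df["weight"]
        return WeightedNetwork(w, node_coords=node_coords)
    return WeightedNetwork(df.to_numpy(dtype=float), node_coords=node_coords)
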