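"""Weighted global topology against degree- and strength-preserving nulls.

Metrics follow the Brain Connectivity Toolbox conventions for weighted
undirected graphs: clustering uses the geometric-mean triangle intensity on
max-normalized weights, the characteristic path length uses the ``1/w``
connection-length transform, small-worldness is the ratio of null-normalized
clustering to null-normalized path length, and modularity is Newman's
weighted Q maximized by Louvain restarts.  Null networks preserve the degree
sequence exactly (double-edge swaps) and the weight multiset exactly, with
weights reassigned by iterative rank-matching so null strengths track the
originals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .errors import InvalidParameterError
from .network import WeightedNetwork, rescale_total_connectivity, threshold_to_density


@dataclass(frozen=True)
class TopologyReport:
    cc: float
    cpl: float
    q: float
    cc_null: float
    cpl_null: float
    q_null: float
    n_nulls: int
    disconnected: bool

    @property
    def cc_normalized(self) -> float:
        return self.cc / self.cc_null

    @property
    def cpl_normalized(self) -> float:
        return self.cpl / self.cpl_null

    @property
    def q_normalized(self) -> float:
        return self.q / self.q_null

    @property
    def sw(self) -> float:
        """Small-worldness: (CC/CC_null) / (CPL/CPL_null)."""
        return self.cc_normalized / self.cpl_normalized


def weighted_clustering(net: WeightedNetwork) -> tuple[np.ndarray, float]:
    """Per-node geometric-mean weighted clustering and its network mean.

    Weights are rescaled by the network maximum; the coefficient of node ``i``
    is ``sum_{j,h} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1))`` and nodes with
    fewer than two neighbors score 0.
    """
    w = net.weights
    if np.any(w < 0):
        raise InvalidParameterError("weights must be nonnegative")
    wmax = w.max()
    if wmax == 0:
        return np.zeros(net.n_nodes), 0.0
    cr = np.cbrt(w / wmax)
    triangles = np.diagonal(cr @ cr @ cr)  # 2x the triangle intensity per node
    k = net.degree.astype(float)
    denom = k * (k - 1)
    coeffs = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return coeffs, float(coeffs.mean())


def _length_distances(net: WeightedNetwork) -> np.ndarray:
    """All-pairs shortest path distances on the 1/w length transform."""
    w = net.weights
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    return shortest_path(lengths, method="D", directed=False)


def weighted_cpl(net: WeightedNetwork) -> float:
    """Characteristic path length: mean shortest 1/w-length over finite
    ordered node pairs.  Disconnected pairs are excluded (callers can detect
    them via :func:`topology_report`'s ``disconnected`` flag)."""
    d = _length_distances(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise InvalidParameterError("network has no finite paths")
    return float(d[finite].mean())


def modularity(
    net: WeightedNetwork, n_runs: int = 10, seed: int = 0
) -> tuple[float, list[set[int]]]:
    """Best-of-``n_runs`` Louvain maximization of Newman's weighted Q."""
    if net.n_edges == 0:
        raise InvalidParameterError("modularity of an empty network is undefined")
    g = nx.from_numpy_array(net.weights)
    rng = np.random.default_rng(seed)
    best_q, best_part = -np.inf, None
    for _ in range(n_runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        part = nx.community.louvain_communities(g, weight="weight", seed=run_seed)
        q = nx.community.modularity(g, part, weight="weight")
        if q > best_q:
            best_q, best_part = q, part
    return float(best_q), best_part


def degree_strength_preserving_null(
    net: WeightedNetwork, swap_factor: int = 10, seed: int = 0
) -> WeightedNetwork:
    """Surrogate preserving the degree sequence and weight multiset exactly.

    Topology is randomized by double-edge swaps (``swap_factor * m`` attempted
    swaps); the original weights are then reassigned to the rewired edges by
    iterative rank-matching against residual strengths, so null strengths
    correlate highly with the originals.
    """
    i, j, w = net.edges()
    m = len(w)
    rng = np.random.default_rng(seed)
    g = nx.from_numpy_array((net.weights > 0).astype(int))
    try:
        nx.double_edge_swap(
            g,
            nswap=swap_factor * m,
            max_tries=100 * swap_factor * m,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    except nx.NetworkXException:
        warnings.warn("too few edges to rewire; returning a weight-shuffled original")
        g = nx.from_numpy_array((net.weights > 0).astype(int))
    edges = np.array(sorted(g.edges()))
    # Rank-matching weight reassignment: repeatedly hand the largest remaining
    # weight to the unassigned edge with the largest expected weight under the
    # residual strength product.
    strengths = net.strength.copy()
    order = np.argsort(-w, kind="stable")
    sorted_w = w[order]
    assigned = np.zeros(m)
    remaining = np.ones(m, dtype=bool)
    for wt in sorted_w:
        exp = strengths[edges[:, 0]] * strengths[edges[:, 1]]
        exp[~remaining] = -np.inf
        e = int(np.argmax(exp))
        assigned[e] = wt
        remaining[e] = False
        strengths[edges[e, 0]] -= wt
        strengths[edges[e, 1]] -= wt
    out = np.zeros_like(net.weights)
    out[edges[:, 0], edges[:, 1]] = assigned
    out[edges[:, 1], edges[:, 0]] = assigned
    return WeightedNetwork(out, node_coords=net.node_coords)


def topology_report(
    net: WeightedNetwork,
    n_nulls: int = 20,
    seed: int = 0,
    n_runs: int = 10,
    null_networks: list[WeightedNetwork] | None = None,
) -> TopologyReport:
    """All four weighted metrics, normalized to null-network means.

    ``null_networks`` can inject precomputed surrogates (e.g. for testing);
    otherwise ``n_nulls`` independent degree/strength-preserving nulls are
    generated from substreams of ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    d = _length_distances(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    disconnected = bool(np.isinf(d[off]).any())
    cpl = float(d[off][np.isfinite(d[off])].mean())
    _, cc = weighted_clustering(net)
    q, _ = modularity(net, n_runs=n_runs, seed=int(ss.generate_state(1)[0] % (2**31)))
    if null_networks is None:
        null_networks = [
            degree_strength_preserving_null(net, seed=np.random.SeedSequence(seed, spawn_key=(k,)))
            for k in range(n_nulls)
        ]
    ccs, cpls, qs = [], [], []
    for k, nn in enumerate(null_networks):
        _, c = weighted_clustering(nn)
        ccs.append(c)
        cpls.append(weighted_cpl(nn))
        qn, _ = modularity(nn, n_runs=n_runs, seed=int(np.random.SeedSequence(seed, spawn_key=(k, 1)).generate_state(1)[0] % (2**31)))
        qs.append(qn)
    return TopologyReport(
        cc=cc,
        cpl=cpl,
        q=q,
        cc_null=float(np.mean(ccs)),
        cpl_null=float(np.mean(cpls)),
        q_null=float(np.mean(qs)),
        n_nulls=len(null_networks),
        disconnected=disconnected,
    )


def landscape(
    betas,
    ls_values,
    n_landscapes: int = 1,
    *,
    radius: float = 30.0,
    n_nodes: int = 84,
    rho: float = 1.0,
    theta: float | None = None,
    n_axons: int = 200_000,
    density: float = 0.10,
    total: float = 2e5,
    n_nulls: int = 20,
    n_runs: int = 10,
    seed: int = 0,
):
    """Evaluate topology over a (beta, L_s) grid, averaged over landscapes.

    One network is simulated per grid cell per landscape; within a landscape
    every cell shares the same node perturbation and axon seeding (common
    random numbers), which suppresses simulation noise in cross-cell
    comparisons.  Cells whose raw density falls below ``density`` are flagged
    ``ignored`` (NaN metrics).  Returns a long-format DataFrame with one row
    per (landscape, beta, L_s) cell.
    """
    import math as _math

    import pandas as pd

    from .geometry import perturb_nodes, place_nodes
    from .growth import GrowthConfig, simulate_axons
    from .network import build_network

    if theta is None:
        theta = _math.radians(15.0)
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    ls_values = np.atleast_1d(np.asarray(ls_values, dtype=float))
    if betas.size == 0 or ls_values.size == 0:
        raise InvalidParameterError("parameter grid must be non-empty")
    base = place_nodes(radius, n_nodes)
    rows = []
    for land in range(n_landscapes):
        land_ss = np.random.SeedSequence(seed, spawn_key=(land,))
        sim_seed = int(land_ss.generate_state(1)[0] % (2**31))
        layout = perturb_nodes(base, rho, np.random.default_rng(land_ss))
        for beta in betas:
            for ls in ls_values:
                cfg = GrowthConfig(
                    beta=float(beta), step_length=float(ls), theta=theta,
                    n_axons=n_axons, seed=sim_seed,
                )
                net = build_network(simulate_axons(layout, cfg))
                row = {
                    "beta": float(beta),
                    "step_length": float(ls),
                    "landscape": land,
                    "raw_density": net.density,
                }
                if net.density < density:
                    row.update(
                        ignored=True, cc=np.nan, cpl=np.nan, sw=np.nan, q=np.nan,
                        cc_normalized=np.nan, cpl_normalized=np.nan, q_normalized=np.nan,
                    )
                else:
                    prepped = prepare_for_topology(net, density, total)
                    rep = topology_report(
                        prepped, n_nulls=n_nulls, n_runs=n_runs, seed=sim_seed
                    )
                    row.update(
                        ignored=False,
                        cc=rep.cc, cpl=rep.cpl, sw=rep.sw, q=rep.q,
                        cc_normalized=rep.cc_normalized,
                        cpl_normalized=rep.cpl_normalized,
                        q_normalized=rep.q_normalized,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def prepare_for_topology(
    net: WeightedNetwork, density: float = 0.10, total: float = 2e5
) -> WeightedNetwork:
    """Threshold to the analysis density, then rescale total connectivity.

    This is the standard preprocessing applied before topology metrics so
    that networks of different raw density and scale are comparable.
    """
    return rescale_total_connectivity(threshold_to_density(net, density), total)
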