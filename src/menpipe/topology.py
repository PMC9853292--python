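"""Global network properties, vulnerability, and robustness to node removal.

All metrics are unweighted.  Global efficiency E = mean over ordered node
pairs of 1/d(i,j) (0 for disconnected pairs); vulnerability is the maximal
relative efficiency loss from deleting a single node; robustness is the mean
proportion of taxa surviving removal of a fraction of nodes followed by
secondary extinction of taxa that lose all their links.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger("menpipe")


def _adjacency(net: nx.Graph) -> tuple[list, csr_matrix]:
    nodes = sorted(net.nodes)
    adj = nx.to_scipy_sparse_array(net, nodelist=nodes, weight=None, format="csr")
    return nodes, csr_matrix(adj)


def _distances(adj: csr_matrix) -> np.ndarray:
    return shortest_path(adj, method="D", directed=False, unweighted=True)


def _efficiency_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(net: nx.Graph) -> float:
    """E = (1/(N(N-1))) * sum_{i != j} 1/d_ij, with 1/inf = 0."""
    _, adj = _adjacency(net)
    return _efficiency_from_distances(_distances(adj))


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_clustering: float
    average_path_distance: float
    density: float
    modularity: float
    vulnerability: float
    largest_component_connectance: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def global_properties(net: nx.Graph, compute_vulnerability: bool = True) -> TopologySummary:
    """Topology summary of a thresholded association network.

    avgCC counts degree < 2 nodes as 0; average path distance (GD) is the
    mean shortest-path length over connected node pairs only.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    from .module_traits import detect_modules

    n = net.number_of_nodes()
    m = net.number_of_edges()
    _, adj = _adjacency(net)
    dist = _distances(adj)
    off = dist[~np.eye(n, dtype=bool)] if n > 1 else np.array([])
    finite = off[np.isfinite(off)]
    gd = float(finite.mean()) if finite.size else np.nan
    giant = max(nx.connected_components(net), key=len)
    sub = net.subgraph(giant)
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        average_degree=2 * m / n,
        average_clustering=nx.average_clustering(net, count_zeros=True),
        average_path_distance=gd,
        density=nx.density(net),
        modularity=detect_modules(net).q,
        vulnerability=vulnerability(net) if compute_vulnerability and n >= 3 else np.nan,
        largest_component_connectance=nx.density(sub) if len(giant) > 1 else 0.0,
    )


def vulnerability(net: nx.Graph) -> float:
    """V = max_i (E - E_i)/E with E_i the efficiency of the graph with node i
    removed, renormalized over the remaining N-1 nodes."""
    n = net.number_of_nodes()
    if n < 3:
        raise ValueError("vulnerability needs at least 3 nodes")
    _, adj = _adjacency(net)
    e_full = _efficiency_from_distances(_distances(adj))
    if e_full == 0:
        raise ValueError("graph has no edges")
    worst = -np.inf
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        sub = adj[mask][:, mask]
        e_i = _efficiency_from_distances(_distances(sub))
        worst = max(worst, (e_full - e_i) / e_full)
        mask[i] = True
    return float(worst)


@dataclass
class RobustnessResult:
    mean: float
    sd: float
    values: np.ndarray
    strategy: str
    removal_fraction: float


def _surviving_fraction(adj: csr_matrix, keep: np.ndarray) -> float:
    """Fraction of the original nodes still linked after removing ~keep and
    the secondary extinction of nodes left with zero links."""
    n = adj.shape[0]
    if keep.sum() == 0:
        return 0.0
    sub = adj[keep][:, keep]
    degrees = np.asarray(sub.sum(axis=1)).ravel()
    # removing an isolated node cannot isolate anyone else, so one pass settles
    return float((degrees > 0).sum() / n)


def robustness(
    net: nx.Graph,
    removal_fraction: float = 0.5,
    strategy: str = "random",
    replicates: int = 100,
    seed: int | None = None,
    hubs: list | None = None,
    exhaustive: bool = False,
) -> RobustnessResult:
    """Mean proportion of taxa remaining after removing floor(f*N) nodes.

    ``strategy="random"`` removes uniformly; ``strategy="target_hubs"``
    removes module hubs first (falling back to random with a warning when no
    hubs exist), padding with random non-hub nodes.  ``exhaustive=True``
    averages over every removal set instead of Monte Carlo replicates (only
    sensible on small graphs).
    """
    if not 0 <= removal_fraction <= 1:
        raise ValueError("removal_fraction must be in [0, 1]")
    if strategy not in ("random", "target_hubs"):
        raise ValueError(f"unknown strategy {strategy!r}")
    nodes, adj = _adjacency(net)
    n = len(nodes)
    n_remove = int(np.floor(removal_fraction * n))
    index = {v: i for i, v in enumerate(nodes)}

    if strategy == "target_hubs":
        if not hubs:
            from .module_traits import detect_modules, zi_pi

            roles = zi_pi(net, detect_modules(net))
            hubs = [
                v
                for v, r in roles.roles.items()
                if r.role in ("module hub", "network hub")
            ]
        if not hubs:
            logger.warning("no module hubs found; falling back to random removal")
            strategy = "random"

    def keep_mask(removed_idx) -> np.ndarray:
        keep = np.ones(n, dtype=bool)
        keep[list(removed_idx)] = False
        return keep

    if exhaustive:
        if strategy != "random":
            raise ValueError("exhaustive enumeration applies to random removal")
        values = np.array(
            [
                _surviving_fraction(adj, keep_mask(combo))
                for combo in itertools.combinations(range(n), n_remove)
            ]
        )
    else:
        rng = np.random.default_rng(seed)
        values = np.empty(replicates)
        hub_idx = [index[v] for v in hubs] if strategy == "target_hubs" else []
        for r in range(replicates):
            if strategy == "random":
                removed = rng.choice(n, size=n_remove, replace=False)
            else:
                take_hubs = hub_idx[:n_remove]
                rest = [i for i in range(n) if i not in set(take_hubs)]
                pad = rng.choice(
                    rest, size=n_remove - len(take_hubs), replace=False
                ) if n_remove > len(take_hubs) else []
                removed = list(take_hubs) + list(pad)
            values[r] = _surviving_fraction(adj, keep_mask(removed))
    return RobustnessResult(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        values=values,
        strategy=strategy,
        removal_fraction=removal_fraction,
    )
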