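"""Module detection, Zi/Pi node roles, module eigengenes and their
correlation with environmental traits, and guild-centred subnetworks.

Roles follow the standard keystone-taxon plane: module hubs (Zi > 0.25,
Pi <= 0.62), connectors (Zi <= 0.25, Pi > 0.62), network hubs (both above),
everything else peripheral.  A module eigengene is the leading right
singular vector (sample space) of the module's standardized abundance
matrix, signed to correlate positively with the module's mean profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountTable, SampleMetadata

logger = logging.getLogger("menpipe")

ZI_CUTOFF = 0.25
PI_CUTOFF = 0.62

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class ModulePartition:
    """node -> module id (0-based, modules ordered by size descending)."""

    assignment: dict
    q: float

    @property
    def modules(self) -> list[list]:
        out: dict[int, list] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, []).append(node)
        return [sorted(out[m]) for m in sorted(out)]

    def members(self, module_id: int) -> list:
        return [n for n, m in self.assignment.items() if m == module_id]


def detect_modules(net: nx.Graph) -> ModulePartition:
    """Fast-greedy (CNM) modularity optimization; signs are ignored, the
    unweighted Newman-Girvan Q is maximized.  Edgeless graphs give singleton
    modules with Q = 0.  Module ids are assigned by size descending, ties
    broken by smallest member node id."""
    nodes = sorted(net.nodes)
    if net.number_of_edges() == 0:
        return ModulePartition({n: i for i, n in enumerate(nodes)}, 0.0)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in net.edges))
    communities = nx.community.greedy_modularity_communities(graph, weight=None)
    q = nx.community.modularity(graph, communities, weight=None)
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment = {node: i for i, comm in enumerate(ordered) for node in comm}
    return ModulePartition(assignment, float(q))


@dataclass
class NodeRole:
    zi: float
    pi: float
    role: str


@dataclass
class NodeRoles:
    roles: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Zi": {n: r.zi for n, r in self.roles.items()},
                "Pi": {n: r.pi for n, r in self.roles.items()},
                "role": {n: r.role for n, r in self.roles.items()},
            }
        )


def classify_role(zi: float, pi: float) -> str:
    if zi > ZI_CUTOFF and pi > PI_CUTOFF:
        return "network hub"
    if zi > ZI_CUTOFF:
        return "module hub"
    if pi > PI_CUTOFF:
        return "connector"
    return "peripheral"


def zi_pi(net: nx.Graph, partition: ModulePartition) -> NodeRoles:
    """Within-module degree z-score and among-module connectivity.

    Zi = (k_is - mean_s) / sd_s over the node's own module (Zi = 0 when the
    module's within-degrees have zero spread); Pi = 1 - sum_t (k_it/k_i)^2
    (Pi = 0 for isolated nodes).
    """
    missing = [n for n in net.nodes if n not in partition.assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    within = {}
    module_links: dict = {}
    for node in net.nodes:
        own = partition.assignment[node]
        per_module: dict[int, int] = {}
        for nb in net.neighbors(node):
            m = partition.assignment[nb]
            per_module[m] = per_module.get(m, 0) + 1
        module_links[node] = per_module
        within[node] = per_module.get(own, 0)
    # module-wise z-scores of within-module degree
    zi = {}
    for members in partition.modules:
        members_in_net = [n for n in members if n in net]
        if not members_in_net:
            continue
        k = np.array([within[n] for n in members_in_net], dtype=float)
        sd = k.std()  # population sd: Zi has mean 0, sd 1 per module
        for n, ki in zip(members_in_net, k):
            zi[n] = float((ki - k.mean()) / sd) if sd > 0 else 0.0
    roles = {}
    for node in net.nodes:
        k_i = net.degree(node)
        if k_i == 0:
            pi = 0.0
        else:
            pi = 1.0 - sum((k / k_i) ** 2 for k in module_links[node].values())
        roles[node] = NodeRole(zi[node], float(pi), classify_role(zi[node], pi))
    return NodeRoles(roles)


# ---------------------------------------------------------------------------
# module eigengenes
# ---------------------------------------------------------------------------

@dataclass
class Eigengene:
    module_id: int
    vector: pd.Series  # per-sample, unit norm
    explained_variance: float


@dataclass
class EigengeneSet:
    eigengenes: dict

    def matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m: e.vector for m, e in self.eigengenes.items()}
        )


def module_eigengene(
    table: CountTable, partition: ModulePartition, module_id: int
) -> Eigengene:
    """First right singular vector of the module's standardized relative
    abundance matrix; sign fixed so it correlates non-negatively with the
    module's mean standardized profile.  Explained variance = s1^2 / sum s^2.
    """
    members = [m for m in partition.members(module_id) if m in table.counts.index]
    rel = table.relative_abundance().loc[members]
    sd = rel.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "module %d: excluding %d constant OTU profiles",
            module_id,
            int(constant.sum()),
        )
        rel = rel.loc[~constant]
        sd = sd.loc[~constant]
    if rel.shape[0] < 2:
        raise ValueError(
            f"module {module_id} has fewer than 2 usable OTUs in the table"
        )
    z = rel.sub(rel.mean(axis=1), axis=0).div(sd, axis=0)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0).to_numpy()
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return Eigengene(
        module_id,
        pd.Series(eig, index=z.columns, name=f"M{module_id}"),
        float(s[0] ** 2 / (s**2).sum()),
    )


def eigengene_set(
    table: CountTable, partition: ModulePartition, min_size: int = 2
) -> EigengeneSet:
    out = {}
    for module_id in sorted(set(partition.assignment.values())):
        members = [
            m for m in partition.members(module_id) if m in table.counts.index
        ]
        if len(members) < min_size:
            continue
        try:
            out[module_id] = module_eigengene(table, partition, module_id)
        except ValueError:
            continue
    return EigengeneSet(out)


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for cut, stars in STAR_THRESHOLDS:
        if p < cut:
            return stars
    return ""


def eigengene_trait_correlation(
    eigengenes: EigengeneSet,
    metadata: SampleMetadata,
    traits: list[str] | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Pearson r (two-sided t-test p) between each module eigengene and each
    trait, with the printed star convention (0.05 / 0.01 / 0.001).

    Constant traits are reported with missing r/p.  ``adjust=True`` adds a
    Benjamini-Hochberg column.
    """
    trait_table = metadata.trait_table(traits)
    rows = []
    for module_id, eig in eigengenes.eigengenes.items():
        aligned = trait_table.loc[eig.vector.index]
        for trait in aligned.columns:
            y = aligned[trait].to_numpy(dtype=float)
            ok = np.isfinite(y)
            x = eig.vector.to_numpy()[ok]
            y = y[ok]
            if len(y) < 3 or np.std(y) == 0 or np.std(x) == 0:
                r = p = np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append(
                {
                    "module": module_id,
                    "trait": trait,
                    "r": r,
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m:
        order = np.argsort(p[ok])
        ranked = p[ok][order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.empty(m)
        vals[order] = np.minimum(ranked, 1.0)
        adj[ok] = vals
    return adj


def guild_subnetwork(net: nx.Graph, guild: str) -> nx.Graph:
    """Induced subgraph on the guild's nodes plus their first neighbours
    (edge signs retained)."""
    seeds = [n for n, d in net.nodes(data=True) if d.get("guild") == guild]
    if not seeds:
        logger.warning("guild %r absent from network", guild)
        return nx.Graph()
    keep = set(seeds)
    for node in seeds:
        keep.update(net.neighbors(node))
    return net.subgraph(keep).copy()
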