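"""FDR-filtered co-occurrence networks, modules, topology and Zi-Pi roles.

Edges are pairwise rank correlations between taxon relative-abundance
profiles that survive both an effect-size filter (|rho| >= r_min, default
0.7) and a Benjamini-Hochberg adjusted p-value cutoff.  Modules come from
Louvain community detection; node roles follow the within-module degree
z-score (Zi) and among-module participation coefficient (Pi), with the
conventional keystone rule Zi >= 2.5 and/or Pi >= 0.62.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import CommunityTable, to_relative_abundance
from .multivariate import bh_adjust

logger = logging.getLogger("ecoassembly")

__all__ = [
    "CoNetwork",
    "NodeRole",
    "build_network",
    "detect_modules",
    "topology",
    "zi_pi",
]

ZI_CUT = 2.5
PI_CUT = 0.62


@dataclass
class CoNetwork:
    graph: nx.Graph                 # nodes: taxon ids; edge attrs rho, p_adj, sign
    edges: pd.DataFrame             # source, target, rho, p_adj, sign
    r_min: float
    alpha: float
    n_tested: int
    modules: dict[str, int] | None = None
    modularity: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NodeRole:
    taxon_id: str
    zi: float
    pi: float
    role: str
    keystone: bool
    degree: int
    module: int


def build_network(table: CommunityTable, method: str = "spearman",
                  r_min: float = 0.7, alpha: float = 0.05,
                  min_prevalence: float = 0.2) -> CoNetwork:
    """All-pairs correlation network over prevalent taxa.

    Taxa present in fewer than ``min_prevalence`` of samples are excluded
    before testing (set to 0 to test everything); constant taxa are skipped
    with a warning.  BH adjustment runs over every tested pair; an edge is
    kept iff |rho| >= r_min and adjusted p < alpha, retaining the sign.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples to test correlations")
    rel = to_relative_abundance(table)
    prevalence = (rel.counts > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    constant = np.ptp(rel.counts, axis=0) == 0
    if (keep & constant).any():
        logger.warning("build_network: skipping %d constant taxa",
                       int((keep & constant).sum()))
        keep &= ~constant
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    x = rel.counts[:, keep]
    S = len(taxa)
    if S < 2:
        raise ValueError("fewer than 2 taxa pass the prevalence filter")

    if method == "spearman":
        rho, p = stats.spearmanr(x)
        if S == 2:  # scipy returns scalars for a single pair
            rho = np.array([[1.0, rho], [rho, 1.0]])
            p = np.array([[0.0, p], [p, 0.0]])
    else:
        n = x.shape[0]
        rho = np.corrcoef(x, rowvar=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)

    iu = np.triu_indices(S, k=1)
    pvals = p[iu]
    rhos = rho[iu]
    p_adj = bh_adjust(pvals)
    keep_edge = (np.abs(rhos) >= r_min) & (p_adj < alpha)

    g = nx.Graph()
    g.add_nodes_from(taxa)
    recs = []
    for a, b, r_, q in zip(iu[0][keep_edge], iu[1][keep_edge],
                           rhos[keep_edge], p_adj[keep_edge]):
        sign = 1 if r_ > 0 else -1
        g.add_edge(taxa[a], taxa[b], rho=float(r_), p_adj=float(q), sign=sign,
                   weight=abs(float(r_)))
        recs.append({"source": taxa[a], "target": taxa[b], "rho": float(r_),
                     "p_adj": float(q), "sign": sign})
    edges = pd.DataFrame(recs, columns=["source", "target", "rho", "p_adj",
                                        "sign"])
    return CoNetwork(graph=g, edges=edges, r_min=r_min, alpha=alpha,
                     n_tested=len(pvals))


def detect_modules(net: CoNetwork, seed: int = 0,
                   resolution: float = 1.0) -> tuple[dict[str, int], float]:
    """Louvain modules on absolute edge weights; deterministic given seed."""
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("cannot detect modules on an edgeless graph")
    comms = nx.community.louvain_communities(g, weight="weight",
                                             resolution=resolution, seed=seed)
    assignment = {}
    for k, comm in enumerate(sorted(comms, key=lambda c: sorted(c)[0])):
        for node in comm:
            assignment[node] = k
    q = nx.community.modularity(g, comms, weight="weight",
                                resolution=resolution)
    net.modules = assignment
    net.modularity = float(q)
    return assignment, float(q)


def topology(net: CoNetwork) -> dict:
    """Unweighted topology summary of the simple graph.

    Average path length is computed over the largest connected component
    only; its coverage (fraction of nodes in that component) is reported
    alongside.  Counts are given both including and excluding isolated
    nodes.
    """
    g = net.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    isolated = sum(1 for v in g if g.degree(v) == 0)
    out = {
        "n_nodes": n,
        "n_nodes_nonisolated": n - isolated,
        "n_edges": e,
        "avg_degree": 2 * e / n if n else 0.0,
        "avg_clustering_coefficient": nx.average_clustering(g) if n else 0.0,
        "avg_path_length": 0.0,
        "largest_component_coverage": 0.0,
        "positive_edge_fraction": (
            float((net.edges["sign"] > 0).mean()) if e else np.nan),
        "empty": n == 0 or e == 0,
    }
    if e:
        comp = max(nx.connected_components(g), key=len)
        out["largest_component_coverage"] = len(comp) / n
        if len(comp) > 1:
            out["avg_path_length"] = nx.average_shortest_path_length(
                g.subgraph(comp))
    return out


def zi_pi(net: CoNetwork, modules: dict[str, int] | None = None
          ) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi = (k_own - mean(k_own over the module)) / sd(k_own over the module);
    modules whose within-degree is constant (sd = 0) get Zi = 0 by
    convention, flagged.  Pi = 1 - sum_s (k_s / k)^2 over modules s;
    isolated nodes get Pi = 0.  Roles: module hub (Zi >= 2.5), connector
    (Pi >= 0.62), network hub (both), else peripheral; keystone iff
    Zi >= 2.5 or Pi >= 0.62.
    """
    if modules is None:
        modules = net.modules
    if modules is None:
        raise ValueError("run detect_modules first or pass a module assignment")
    g = net.graph
    missing = set(g.nodes) - set(modules)
    if missing:
        raise ValueError(f"nodes without module assignment: {sorted(missing)[:5]}")

    within_degree = {v: sum(1 for u in g.neighbors(v)
                            if modules[u] == modules[v]) for v in g.nodes}
    by_module: dict[int, list[str]] = {}
    for v, mod in modules.items():
        if v in g.nodes:
            by_module.setdefault(mod, []).append(v)

    rows = []
    for v in g.nodes:
        mod = modules[v]
        members = by_module[mod]
        ks = np.array([within_degree[u] for u in members], dtype=float)
        sd = ks.std(ddof=0)
        zi = (within_degree[v] - ks.mean()) / sd if sd > 0 else 0.0
        k = g.degree(v)
        if k == 0:
            pi = 0.0
        else:
            per_mod: dict[int, int] = {}
            for u in g.neighbors(v):
                per_mod[modules[u]] = per_mod.get(modules[u], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
        hub = zi >= ZI_CUT
        conn = pi >= PI_CUT
        role = ("network_hub" if hub and conn else
                "module_hub" if hub else
                "connector" if conn else "peripheral")
        rows.append({"taxon_id": v, "zi": float(zi), "pi": float(pi),
                     "role": role, "keystone": bool(hub or conn),
                     "degree": int(k), "module": mod,
                     "zero_sd_module": sd == 0})
    return pd.DataFrame(rows).set_index("taxon_id")
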