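"""Global and nodal graph metrics for binary brain graphs.

The six global measures conventionally reported for functional
connectomes: mean clustering coefficient C, characteristic path length
L, global efficiency E, modularity Q of the best partition found,
degree assortativity r, and the small-world index sigma computed
against degree-preserving rewired null graphs.  Nodal degree and
betweenness centrality support hub mapping.  AUC summaries integrate a
metric over the density sweep so that group comparisons do not hinge on
any single threshold.

Conventions for disconnected graphs (common at low densities): L is
averaged over connected pairs only, with the number of disconnected
pairs reported alongside; E handles disconnection natively (1/inf = 0);
sigma is computed on the largest connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectome import BinaryGraph

__all__ = [
    "PathStats",
    "SigmaResult",
    "MetricProfile",
    "clustering_coefficient",
    "path_length_and_efficiency",
    "modularity",
    "assortativity",
    "betweenness",
    "small_world_sigma",
    "auc_over_densities",
    "metric_profile",
]


def _adjacency(g: BinaryGraph | np.ndarray) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return g.adjacency.astype(float)
    return np.asarray(g, dtype=float)


def clustering_coefficient(g: BinaryGraph) -> tuple[float, np.ndarray]:
    """Watts-Strogatz local clustering; C is its unweighted node mean.

    A node's coefficient is the number of triangles through it divided
    by the number of neighbor pairs k(k-1)/2; nodes of degree < 2 score 0.
    """
    a = _adjacency(g)
    k = a.sum(axis=0)
    triangles = np.diag(a @ a @ a) / 2.0
    possible = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        per_node = np.where(possible > 0, triangles / np.where(
            possible > 0, possible, 1.0), 0.0)
    return float(per_node.mean()), per_node


@dataclass
class PathStats:
    """Characteristic path length and global efficiency.

    ``L`` is NaN when no pair is connected (edgeless graph); the
    ``n_disconnected_pairs`` count flags partial disconnection.
    """

    L: float
    E: float
    n_disconnected_pairs: int

    @property
    def l_defined(self) -> bool:
        return not np.isnan(self.L)


def path_length_and_efficiency(g: BinaryGraph) -> PathStats:
    """BFS shortest paths over all unordered pairs."""
    a = _adjacency(g)
    n = a.shape[0]
    if n < 2:
        return PathStats(np.nan, 0.0, 0)
    dist = shortest_path(csr_matrix(a), method="D", unweighted=True,
                         directed=False)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    finite = np.isfinite(d)
    n_disc = int((~finite).sum())
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
    E = float(inv.mean())
    L = float(d[finite].mean()) if finite.any() else float("nan")
    return PathStats(L, E, n_disc)


def modularity(g: BinaryGraph, n_restarts: int = 10,
               seed: int = 0) -> tuple[float, dict[str, int]]:
    """Best Newman-Girvan modularity over seeded Louvain restarts.

    Louvain is a stochastic greedy heuristic, so the best Q over
    ``n_restarts`` independently seeded runs is kept.  Deterministic for
    a fixed seed.  Returns Q and a ROI-label -> community-index map.
    """
    if g.n_edges == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    G = g.to_networkx()
    best_q = -np.inf
    best: list[set] | None = None
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(G, seed=seed + r)
        q = nx.community.modularity(G, comms)
        if q > best_q:
            best_q, best = q, comms
    assert best is not None
    partition = {}
    for c_idx, members in enumerate(best):
        for node in members:
            partition[g.roi_labels[node]] = c_idx
    return float(best_q), partition


def assortativity(g: BinaryGraph) -> float:
    """Pearson correlation of degrees across edge endpoints.

    Each undirected edge contributes both orderings.  Returns NaN (with
    a warning) when all endpoint degrees are equal — e.g. on a regular
    graph — where the correlation is undefined.
    """
    a = _adjacency(g)
    deg = a.sum(axis=0)
    i, j = np.nonzero(np.triu(a, k=1))
    if i.size < 2:
        warnings.warn("assortativity undefined: fewer than 2 edges",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    x = np.concatenate([deg[i], deg[j]])
    y = np.concatenate([deg[j], deg[i]])
    if x.std() == 0 or y.std() == 0:
        warnings.warn(
            "assortativity undefined: zero degree variance at edge endpoints",
            RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def betweenness(g: BinaryGraph) -> np.ndarray:
    """Exact shortest-path betweenness, normalized by (n-1)(n-2)/2.

    Endpoints are excluded, so a star's center scores exactly 1.
    """
    G = g.to_networkx()
    bc = nx.betweenness_centrality(G, normalized=True)
    return np.array([bc[i] for i in range(g.n_nodes)])


@dataclass
class SigmaResult:
    """Small-world index against a degree-preserving null ensemble."""

    sigma: float
    c: float
    l: float
    c_null_mean: float
    l_null_mean: float
    n_null: int


def _largest_component(g: BinaryGraph) -> BinaryGraph:
    a = g.adjacency
    n_comp, labels = connected_components(csr_matrix(a), directed=False)
    if n_comp == 1:
        return g
    sizes = np.bincount(labels)
    keep = np.nonzero(labels == sizes.argmax())[0]
    sub = a[np.ix_(keep, keep)]
    m_total = len(keep) * (len(keep) - 1) // 2
    return BinaryGraph(sub, int(sub.sum()) / 2 / max(m_total, 1),
                       [g.roi_labels[i] for i in keep])


def small_world_sigma(
    g: BinaryGraph,
    n_null: int = 20,
    n_rewires_per_edge: int = 10,
    seed: int = 0,
) -> SigmaResult:
    """sigma = (C / <C_null>) / (L / <L_null>).

    Null graphs share the node count, edge count and exact degree
    sequence of the observed graph: each is produced by Maslov-Sneppen
    double-edge swaps (``n_rewires_per_edge * |E|`` accepted swaps).
    sigma > 1 indicates clustering in excess of what the degree sequence
    alone produces, at comparable path length — the small-world regime.

    Computed on the largest connected component when the graph is
    disconnected at sparse densities.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    comp = _largest_component(g)
    m = comp.n_edges
    if m < 2:
        raise ValueError("graph too sparse to rewire (fewer than 2 edges)")
    c_obs, _ = clustering_coefficient(comp)
    l_obs = path_length_and_efficiency(comp).L
    G = comp.to_networkx()
    rng = np.random.default_rng(seed)
    c_null = np.empty(n_null)
    l_null = np.empty(n_null)
    nswap = n_rewires_per_edge * m
    for b in range(n_null):
        H = G.copy()
        try:
            nx.double_edge_swap(H, nswap=nswap, max_tries=100 * nswap,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXException as exc:
            # the attempt budget ran out; every *accepted* swap preserves
            # the degree sequence, so a partially rewired graph is still a
            # valid null — but an unchanged graph means no swap exists
            if nx.utils.graphs_equal(H, G):
                raise RuntimeError(
                    "graph cannot be rewired: no valid double-edge swap "
                    f"found within the attempt budget ({exc})") from exc
            warnings.warn(
                "double-edge swap budget exhausted; using a partially "
                "rewired null graph", RuntimeWarning, stacklevel=2)
        a_null = nx.to_numpy_array(H, nodelist=range(comp.n_nodes))
        null_graph = BinaryGraph(a_null.astype(np.int8),
                                 comp.density, list(comp.roi_labels))
        c_null[b], _ = clustering_coefficient(null_graph)
        l_null[b] = path_length_and_efficiency(null_graph).L
    c_bar = float(c_null.mean())
    l_bar = float(np.nanmean(l_null))
    if c_bar == 0 or l_bar == 0 or np.isnan(l_obs):
        sigma = float("nan")
    else:
        sigma = (c_obs / c_bar) / (l_obs / l_bar)
    return SigmaResult(sigma, c_obs, l_obs, c_bar, l_bar, n_null)


def auc_over_densities(values: Sequence[float],
                       densities: Sequence[float]) -> float:
    """Trapezoidal integral of a metric over the density axis.

    NaN entries (e.g. undefined assortativity at some density) restrict
    the integral to the longest contiguous finite stretch, with a
    warning; fewer than 2 finite points yield NaN.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(densities, dtype=float)
    if v.shape != d.shape:
        raise ValueError("values and densities must align")
    if len(d) < 2:
        raise ValueError("need at least 2 densities for an AUC")
    finite = np.isfinite(v)
    if finite.all():
        return float(np.trapezoid(v, d))
    warnings.warn("non-finite metric values: AUC restricted to the longest "
                  "contiguous finite range", RuntimeWarning, stacklevel=2)
    best_len, best_start, run_start = 0, 0, None
    for idx in range(len(v) + 1):
        if idx < len(v) and finite[idx]:
            if run_start is None:
                run_start = idx
        else:
            if run_start is not None and idx - run_start > best_len:
                best_len, best_start = idx - run_start, run_start
            run_start = None
    if best_len < 2:
        return float("nan")
    sl = slice(best_start, best_start + best_len)
    return float(np.trapezoid(v[sl], d[sl]))


@dataclass
class MetricProfile:
    """All global metrics and nodal centralities of one graph."""

    C: float
    L: float
    E: float
    Q: float
    r: float
    sigma: float
    density: float
    nodal_degree: np.ndarray
    nodal_betweenness: np.ndarray
    n_null: int
    n_disconnected_pairs: int = 0

    GLOBAL_METRICS = ("C", "L", "E", "Q", "r", "sigma")

    def globals_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in self.GLOBAL_METRICS}


def metric_profile(
    g: BinaryGraph,
    n_null: int = 20,
    n_rewires_per_edge: int = 10,
    seed: int = 0,
    compute_sigma: bool = True,
    modularity_restarts: int = 10,
) -> MetricProfile:
    """Compute the full metric profile of one binary graph."""
    c, _ = clustering_coefficient(g)
    ps = path_length_and_efficiency(g)
    q, _ = modularity(g, n_restarts=modularity_restarts, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = assortativity(g)
    if compute_sigma:
        sig = small_world_sigma(g, n_null=n_null,
                                n_rewires_per_edge=n_rewires_per_edge,
                                seed=seed).sigma
    else:
        sig, n_null = float("nan"), 0
    return MetricProfile(
        C=c, L=ps.L, E=ps.E, Q=q, r=r, sigma=sig, density=g.density,
        nodal_degree=g.degrees().astype(float),
        nodal_betweenness=betweenness(g),
        n_null=n_null, n_disconnected_pairs=ps.n_disconnected_pairs)
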