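"""Network-property comparisons between interactomes.

Covers the topology summaries used to compare database releases: the
largest connected component, a log-log power-law fit to the degree
distribution (scale-free check), the 90th-percentile *effective diameter*
of the shortest-path-length distribution, and Spearman rank correlation
of hub-protein degree rankings between two databases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .core import InputError, InteractionKey, ProteinId
from .quality import degree_map, hub_set


def build_graph(db: Iterable[InteractionKey], keep_self: bool = False) -> nx.Graph:
    """Undirected graph of the pair set; self-loops dropped unless asked for."""
    g = nx.Graph()
    for key in db:
        if key.is_self and not keep_self:
            continue
        g.add_edge(key.a, key.b)
    return g


def largest_component(db: Iterable[InteractionKey]) -> nx.Graph:
    """Subgraph on the largest connected component.

    Ties on component size break toward the component containing the
    lexicographically smallest node, for determinism.
    """
    g = build_graph(db)
    if g.number_of_nodes() == 0:
        raise InputError("empty database")
    comps = list(nx.connected_components(g))
    max_size = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == max_size), key=min)
    return g.subgraph(best).copy()


@dataclass(frozen=True)
class DegreeFit:
    """Least-squares log10(count) ~ log10(degree) fit of the degree histogram."""

    slope: float
    intercept: float
    r_squared: float
    degrees: np.ndarray
    counts: np.ndarray


def degree_fit(db: Iterable[InteractionKey], log_binned: bool = False) -> DegreeFit:
    """Fit the node-degree distribution on log-log scales.

    Zero-degree nodes are excluded (they carry no edges); by default the
    raw degree histogram is fitted, with logarithmic binning available as
    an option. A scale-free network yields slope < 0 with high R².
    """
    deg = degree_map(db)
    values = np.array([d for d in deg.values() if d > 0], dtype=float)
    uniq, counts = np.unique(values, return_counts=True)
    if log_binned and len(uniq) >= 3:
        edges = np.geomspace(uniq.min(), uniq.max() + 1, num=max(4, int(np.log2(len(uniq))) + 2))
        counts, edges = np.histogram(values, bins=edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
        keep = counts > 0
        uniq, counts = centers[keep], counts[keep]
    if len(uniq) < 3:
        raise InputError("need at least 3 distinct degrees for a log-log fit")
    res = stats.linregress(np.log10(uniq), np.log10(counts))
    return DegreeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        degrees=uniq,
        counts=np.asarray(counts),
    )


def effective_diameter(
    graph: nx.Graph,
    percentile: float = 0.9,
    n_sources: int = 100,
    seed: int = 0,
    exact_below: int = 2000,
) -> float:
    """Interpolated percentile of the shortest-path-length distribution.

    Exact over all node pairs when the graph is small (≤ ``exact_below``
    nodes), otherwise estimated from BFS over ``n_sources`` uniformly
    sampled source nodes. Linear interpolation between integer distances
    at the target percentile, clamped below at 1.0 (distinct connected
    nodes are never closer than one hop).
    """
    if graph.number_of_nodes() == 0:
        raise InputError("empty graph")
    if not nx.is_connected(graph):
        raise InputError("graph is disconnected; run largest_component first")
    nodes = sorted(graph.nodes)
    if len(nodes) == 1:
        return 0.0
    dist_counts: dict[int, int] = {}
    if len(nodes) <= exact_below:
        for src in nodes:
            for dst, d in nx.single_source_shortest_path_length(graph, src).items():
                if dst > src:  # unordered distinct pairs once
                    dist_counts[d] = dist_counts.get(d, 0) + 1
    else:
        rng = np.random.default_rng(seed)
        srcs = rng.choice(len(nodes), size=min(n_sources, len(nodes)), replace=False)
        for i in srcs:
            for dst, d in nx.single_source_shortest_path_length(graph, nodes[i]).items():
                if d > 0:
                    dist_counts[d] = dist_counts.get(d, 0) + 1
    total = sum(dist_counts.values())
    cum = 0.0
    prev_cdf = 0.0
    for d in sorted(dist_counts):
        cum += dist_counts[d]
        cdf = cum / total
        if cdf >= percentile:
            eff = (d - 1) + (percentile - prev_cdf) / (cdf - prev_cdf)
            return max(1.0, eff)
        prev_cdf = cdf
    return float(max(dist_counts))  # pragma: no cover - percentile <= 1 always hits


@dataclass(frozen=True)
class RankCorrelation:
    """Spearman's rho over the items shared by two rankings."""

    rho: float
    n: int
    d_i: Optional[tuple[int, ...]]  # rank differences; None when ties forced averaging
    tie_corrected: bool


def spearman_rho(ranking_a: Sequence, ranking_b: Sequence) -> RankCorrelation:
    """Spearman rank correlation between two orderings of the same items.

    In the tie-free case this is exactly rho = 1 - 6 Σ d_i² / (n(n²-1))
    with d_i the per-item rank difference. Inputs may be given as ordered
    item sequences (best first); only items present in both are used.
    """
    pos_a = {item: i + 1 for i, item in enumerate(ranking_a)}
    pos_b = {item: i + 1 for i, item in enumerate(ranking_b)}
    shared = [item for item in ranking_a if item in pos_b]
    n = len(shared)
    if n < 2:
        raise InputError("need at least 2 shared items for a rank correlation")
    ra = [pos_a[i] for i in shared]
    rb = [pos_b[i] for i in shared]
    # re-rank within the shared subset so ranks are 1..n on both sides
    ra = stats.rankdata(ra)
    rb = stats.rankdata(rb)
    return _rho_from_ranks(ra, rb)


def _rho_from_ranks(ra: np.ndarray, rb: np.ndarray) -> RankCorrelation:
    n = len(ra)
    tie_free = len(set(ra)) == n and len(set(rb)) == n
    if tie_free:
        d = np.asarray(ra) - np.asarray(rb)
        rho = 1.0 - 6.0 * float(np.sum(d * d)) / (n * (n * n - 1))
        return RankCorrelation(
            rho=rho, n=n, d_i=tuple(int(x) for x in d), tie_corrected=False
        )
    # ties: average ranks + product-moment correlation of the ranks
    ra = np.asarray(ra, dtype=float)
    rb = np.asarray(rb, dtype=float)
    va = ra - ra.mean()
    vb = rb - rb.mean()
    denom = math.sqrt(float(va @ va) * float(vb @ vb))
    rho = float(va @ vb) / denom if denom > 0 else math.nan
    return RankCorrelation(rho=rho, n=n, d_i=None, tie_corrected=True)


def hub_rank_correlation(
    db_a: Iterable[InteractionKey],
    db_b: Iterable[InteractionKey],
    k: int = 100,
) -> Optional[RankCorrelation]:
    """Correlation of hub-degree rankings between two databases.

    Takes the row database's top-k hubs, keeps those present in both
    networks, ranks them by degree (descending, average ranks on ties)
    within each database, and correlates the rankings. Returns ``None``
    (an undefined marker) when fewer than 2 hubs are shared.
    """
    hubs = hub_set(db_a, k=k)
    deg_a = degree_map(db_a)
    deg_b = degree_map(db_b)
    shared = [p for p in hubs if p in deg_b]
    if len(shared) < 2:
        return None
    ra = stats.rankdata([-deg_a[p] for p in shared])
    rb = stats.rankdata([-deg_b[p] for p in shared])
    return _rho_from_ranks(ra, rb)
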