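"""Graph data model, I/O and global structural descriptors.

The package compares cellular networks — gene regulatory (GRN),
transcriptional regulatory (TRN) and protein-protein (PPN) — all treated as
undirected simple graphs over gene identifiers.  This module holds the
:class:`Network` container, edge-list/SIF readers and writers, summary
statistics (edge density, giant component, assortativity), the degree
distribution with its log-log power-law fit, and the five node centrality
measures used throughout the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Tuple

import networkx as nx
import numpy as np

logger = logging.getLogger("netcompare")

#: Marker for quantities that are undefined for a node/network (e.g. the
#: local clustering coefficient of a degree-1 node).
UNDEFINED = float("nan")

CENTRALITY_MEASURES = ("degree", "betweenness", "transitivity", "hubscore", "closeness")


def canonical_edge(a: str, b: str) -> Tuple[str, str]:
    """Order-independent representation of an undirected edge."""
    return (a, b) if a <= b else (b, a)


class Network:
    """Undirected simple graph over gene identifiers.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node; the edge (a, b) is identical to (b, a).
    """

    def __init__(self, edges: Iterable[Tuple[str, str]] = (), nodes: Iterable[str] = (),
                 name: str = ""):
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        dropped = 0
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                dropped += 1
                continue
            g.add_edge(a, b)
        if dropped:
            logger.warning("%s: dropped %d self-loop(s)", name or "network", dropped)
        self.graph = g
        self.name = name
        self.n_selfloops_dropped = dropped

    # -- basic views --------------------------------------------------------
    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {canonical_edge(a, b) for a, b in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def subgraph(self, nodes: Iterable[str], name: str | None = None) -> "Network":
        nodes = set(nodes)
        sub = self.graph.subgraph(nodes)
        net = Network(name=name if name is not None else self.name)
        g = nx.Graph()
        g.add_nodes_from(sub.nodes)
        g.add_edges_from(sub.edges)
        net.graph = g
        return net

    def copy(self, name: str | None = None) -> "Network":
        net = Network(name=name if name is not None else self.name)
        net.graph = self.graph.copy()
        return net

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"Network(name={self.name!r}, n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class NetworkStats:
    """Summary row: node/edge counts, giant component size, density, assortativity."""
    name: str
    n_nodes: int
    n_edges: int
    gcc_size: int
    edge_density: float
    assortativity: float  # NaN when undefined (degenerate degree variance)


@dataclass
class PowerLawFit:
    """OLS fit of log10 p_k = -alpha * log10 k + c over the degree histogram."""
    alpha: float
    c: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    pass


def read_network(path, format: str = "edgelist", name: str | None = None) -> Network:
    """Read a network from a whitespace edge list or a SIF file.

    Edge list rows have >= 2 columns (extra columns ignored); '#' lines are
    comments.  SIF rows are ``source interaction target [target ...]``.
    Self-loops are dropped with a warning and duplicate edges collapse.
    """
    if format not in ("edgelist", "sif"):
        raise ValueError(f"unknown format {format!r}")
    edges = []
    nodes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if format == "edgelist":
                if len(cols) < 2:
                    raise ParseError(f"{path}:{lineno}: expected >= 2 columns, got {len(cols)}")
                edges.append((cols[0], cols[1]))
            else:  # sif
                if len(cols) == 1:
                    nodes.append(cols[0])  # isolated node
                    continue
                if len(cols) < 3:
                    raise ParseError(f"{path}:{lineno}: SIF row needs 'a relation b'")
                src = cols[0]
                for tgt in cols[2:]:
                    edges.append((src, tgt))
    return Network(edges, nodes=nodes, name=name if name is not None else str(path))


def write_network(net: Network, path) -> None:
    """Write a sorted two-column edge list (bit-stable output)."""
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")
        for n in sorted(net.nodes - {x for e in net.edges for x in e}):
            fh.write(f"# isolated\t{n}\n")


# ---------------------------------------------------------------------------
# Global descriptors
# ---------------------------------------------------------------------------

def edge_density(n_nodes: int | Network, n_edges: int | None = None) -> float:
    """Edge density 2E / (N (N - 1)).

    Accepts either a :class:`Network` or explicit ``(n_nodes, n_edges)``
    counts (so printed summary-table counts can be checked directly).
    """
    if isinstance(n_nodes, Network):
        net = n_nodes
        n_nodes, n_edges = net.n_nodes, net.n_edges
    if n_nodes < 2:
        raise ValueError("edge density undefined for networks with < 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def giant_component(net: Network) -> Network:
    """Induced subgraph on the largest connected node set (GCC).

    Ties are broken deterministically by the lexicographically smallest
    member node.
    """
    if net.n_nodes == 0:
        return Network(name=net.name)
    comps = list(nx.connected_components(net.graph))
    best = max(comps, key=lambda c: (len(c), min(c)))
    # max() on (size, min-name) prefers *larger* min name; invert for ties:
    best_size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == best_size]
    if len(tied) > 1:
        best = min(tied, key=lambda c: min(c))
        logger.info("%s: GCC tie among %d components, kept the one containing %r",
                    net.name, len(tied), min(best))
    return net.subgraph(best)


def assortativity(net: Network) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees.

    Computed over the doubled edge list (each edge contributes both
    orderings).  Returns NaN when either marginal variance is zero
    (e.g. regular graphs).
    """
    if net.n_edges == 0:
        raise ValueError("assortativity undefined for edgeless networks")
    deg = dict(net.graph.degree)
    xs, ys = [], []
    for a, b in net.graph.edges:
        xs.extend((deg[a], deg[b]))
        ys.extend((deg[b], deg[a]))
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return UNDEFINED
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def network_stats(net: Network) -> NetworkStats:
    gcc = giant_component(net)
    try:
        kappa = assortativity(net)
    except ValueError:
        kappa = UNDEFINED
    return NetworkStats(
        name=net.name,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        gcc_size=gcc.n_nodes,
        edge_density=edge_density(net),
        assortativity=kappa,
    )


def degree_histogram(net: Network) -> Dict[int, float]:
    """Relative frequency p_k of each observed degree k >= 1.

    Degree-0 nodes are excluded (log k is undefined on the log-log plot the
    fit operates on); frequencies sum to 1 over the remaining nodes.
    """
    if net.n_edges == 0:
        raise ValueError("degree histogram undefined for edgeless networks")
    degs = [d for _, d in net.graph.degree if d >= 1]
    n_zero = net.n_nodes - len(degs)
    if n_zero:
        logger.info("%s: excluded %d degree-0 node(s) from degree histogram",
                    net.name, n_zero)
    total = len(degs)
    counts: Dict[int, int] = {}
    for d in degs:
        counts[d] = counts.get(d, 0) + 1
    return {k: counts[k] / total for k in sorted(counts)}


def fit_power_law(hist: Mapping[int, float]) -> PowerLawFit:
    """Least-squares line of log10 p_k on log10 k; the scaling exponent is -slope.

    All observed (k, p_k) points enter the fit without tail truncation, each
    weighted by its relative frequency: sparsely populated tail degrees are
    only ever observed when their empirical frequency overshoots the law
    (zero-count degrees are unobservable), so an unweighted fit is biased
    shallow; frequency weights remove that selection effect while leaving
    exact (collinear) histograms fitted exactly.
    """
    ks = np.array(sorted(hist), dtype=float)
    if len(ks) < 2:
        raise ValueError("power-law fit needs >= 2 distinct degrees")
    ps = np.array([hist[int(k)] for k in ks], dtype=float)
    logk = np.log10(ks)
    logp = np.log10(ps)
    slope, intercept = np.polyfit(logk, logp, 1, w=ps)
    return PowerLawFit(alpha=float(-slope), c=float(intercept))


# ---------------------------------------------------------------------------
# Centrality measures
# ---------------------------------------------------------------------------

def _closeness(net: Network) -> Dict[str, float]:
    # 1 / sum_j d(i, j), with d = N for unreachable pairs (self excluded).
    n = net.n_nodes
    out = {}
    for v in net.graph.nodes:
        lengths = nx.single_source_shortest_path_length(net.graph, v)
        total = sum(lengths.values())  # d(v, v) = 0
        total += (n - len(lengths)) * n  # unreachable nodes count as N
        out[v] = 1.0 / total if total > 0 else UNDEFINED
    return out


def _transitivity(net: Network) -> Dict[str, float]:
    # local clustering coefficient; undefined for degree < 2
    cc = nx.clustering(net.graph)
    deg = dict(net.graph.degree)
    return {v: (cc[v] if deg[v] >= 2 else UNDEFINED) for v in net.graph.nodes}


def _hubscore(net: Network) -> Dict[str, float]:
    # Principal eigenvector of A.A^T, scaled so the maximum entry is 1.
    # For a symmetric A the top eigenspace of A.A^T is spanned by A's
    # eigenvectors of extremal eigenvalue; when it is degenerate (bipartite
    # components give a +/-lambda spectrum) the canonical nonnegative
    # representative is A's Perron eigenvector, so compute that directly.
    nodes = sorted(net.graph.nodes)
    a = nx.to_numpy_array(net.graph, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, -1])  # eigh sorts ascending; last = Perron root of A
    top = vec.max()
    if top > 0:
        vec = vec / top
    return dict(zip(nodes, vec.tolist()))


def centrality(net: Network, measure: str) -> Dict[str, float]:
    """One of the five node centralities as a gene-id -> score mapping.

    degree: number of direct neighbors.  closeness: inverse of the summed
    shortest-path lengths to all other nodes, unreachable pairs contributing
    N.  transitivity: local clustering coefficient, NaN for degree < 2.
    hubscore: principal eigenvector of A.A^T normalized to max 1.
    betweenness: unnormalized shortest-path betweenness with even split over
    equal-length paths.
    """
    if net.n_nodes == 0:
        raise ValueError("centrality undefined for the empty network")
    if measure == "degree":
        return {v: float(d) for v, d in net.graph.degree}
    if measure == "betweenness":
        return dict(nx.betweenness_centrality(net.graph, normalized=False))
    if measure == "transitivity":
        return _transitivity(net)
    if measure == "hubscore":
        return _hubscore(net)
    if measure == "closeness":
        return _closeness(net)
    raise ValueError(f"unknown centrality measure {measure!r}; "
                     f"expected one of {CENTRALITY_MEASURES}")
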