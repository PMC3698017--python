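"""Seeded generators for synthetic networks, annotations, loci and expression.

Every generator is a pure function of its configuration and seed.  Together
they produce fixtures with the statistical structure the pipeline stages
assume: scale-free-ish sparse networks (configuration model over a truncated
power-law degree sequence), annotation tables with planted enriched modules,
gene loci with planted cis-structure (edges preferentially connecting nearby
genes), and expression matrices sampled from a linear-Gaussian system over a
known dependency network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np

from .chromosome import ChromosomeMap, GeneLocus, relative_distance
from .enrichment import AnnotationSet
from .grn_inference import ExpressionMatrix
from .netcore import Network, canonical_edge

logger = logging.getLogger("netcompare")

_RETRY_CAP = 20


@dataclass
class SyntheticTruth:
    """Ground truth underlying a generated fixture set."""
    network: Network
    planted_terms: List[str] = field(default_factory=list)
    planted_overlap: float = float("nan")
    cis_strength: float = 0.0
    seed: int = 0


def _gene_ids(n: int) -> List[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def _zeta_mean(exponent: float, kmax: int) -> float:
    ks = np.arange(1, kmax + 1)
    pk = ks ** (-float(exponent))
    pk /= pk.sum()
    return float((ks * pk).sum())


def natural_edge_count(n_genes: int, exponent: float) -> int:
    """Edge count implied by a pure power law with minimum degree 1.

    The degree cutoff is the structural one, kmax = sqrt(2E), found by a
    short fixed-point iteration.  Requesting this count from
    :func:`gen_network` keeps the generated degree sequence an undistorted
    power law; other counts are honored by nudging degrees, which bends the
    distribution's head away from the pure law.
    """
    e = n_genes
    for _ in range(4):
        kmax = max(3, min(n_genes - 1, int(round(np.sqrt(2 * e)))))
        e = int(round(n_genes * _zeta_mean(exponent, kmax) / 2))
    return e


def _powerlaw_degrees(n: int, target_sum: int, exponent: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Degree sequence from a truncated power law, repaired to a target sum.

    Degrees are drawn from p_k ∝ k^-exponent on k = 1..kmax with the cutoff
    chosen (up to the structural cap sqrt(target_sum)) so the law's mean is
    as close as possible to target_sum / n; residual mass is moved with
    unit nudges at uniformly chosen nodes.
    """
    cap = max(3, min(n - 1, int(round(np.sqrt(target_sum)))))
    target_mean = target_sum / n
    if _zeta_mean(exponent, cap) <= target_mean:
        kmax = cap
    else:
        lo, hi = 2, cap
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if _zeta_mean(exponent, mid) < target_mean:
                lo = mid
            else:
                hi = mid
        kmax = hi
    ks = np.arange(1, kmax + 1)
    pk = ks ** (-float(exponent))
    pk /= pk.sum()
    deg = rng.choice(ks, size=n, p=pk).astype(int)
    diff = int(target_sum - deg.sum())
    while diff != 0:
        i = int(rng.integers(n))
        if diff > 0 and deg[i] < n - 1:
            deg[i] += 1
            diff -= 1
        elif diff < 0 and deg[i] > 1:
            deg[i] -= 1
            diff += 1
    return deg


def gen_network(n_genes: int, n_edges: int | None = None, exponent: float = 2.5,
                seed: int = 0, name: str = "synthetic") -> Network:
    """Configuration-model network with a truncated power-law degree sequence.

    Self-loops and multi-edges created by the stub matching are removed and
    the lost edges are topped up between endpoints sampled proportionally to
    their remaining stub deficit, so the realized edge count equals the
    request.  With ``n_edges=None`` the count defaults to
    :func:`natural_edge_count`, which keeps the degree law undistorted.
    """
    if n_edges is None:
        n_edges = natural_edge_count(n_genes, exponent)
    max_edges = n_genes * (n_genes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds C({n_genes}, 2)={max_edges}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g = None
    for attempt in range(_RETRY_CAP):
        deg = _powerlaw_degrees(n_genes, 2 * n_edges, exponent, rng)
        g = nx.configuration_model(deg.tolist(), seed=int(rng.integers(2 ** 31)))
        g = nx.Graph(g)  # collapse multi-edges
        g.remove_edges_from(nx.selfloop_edges(g))
        lost = n_edges - g.number_of_edges()
        if lost <= 0.2 * n_edges:
            break
    else:
        raise RuntimeError(f"degree sequence unrealizable near {n_edges} edges "
                           f"after {_RETRY_CAP} attempts")
    if lost:
        logger.info("%s: topping up %d edge(s) lost to simplification", name, lost)
    guard = 0
    while g.number_of_edges() < n_edges:
        cur = np.array([g.degree(i) if g.has_node(i) else 0 for i in range(n_genes)])
        deficit = np.maximum(deg - cur, 0) + 0.1
        p = deficit / deficit.sum()
        need = n_edges - g.number_of_edges()
        for i, j in zip(rng.choice(n_genes, size=2 * need + 8, p=p),
                        rng.choice(n_genes, size=2 * need + 8, p=p)):
            if i != j and not g.has_edge(int(i), int(j)):
                g.add_edge(int(i), int(j))
                if g.number_of_edges() >= n_edges:
                    break
        guard += 1
        if guard > 200:
            raise RuntimeError("edge top-up failed to converge")
    genes = _gene_ids(n_genes)
    net = Network(((genes[a], genes[b]) for a, b in g.edges),
                  nodes=genes, name=name)
    logger.info("%s: requested %d edges, realized %d", name, n_edges, net.n_edges)
    return net


def gen_network_pair(base: Network, overlap_fraction: float, seed: int = 0,
                     name: str = "synthetic_pair") -> Network:
    """Second network sharing a requested fraction of the base's edges.

    The retained edges are a uniform sample of the base's; the remainder are
    rewired to uniform non-base pairs over the same node set, keeping the
    edge count equal.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    edges = sorted(base.edges)
    nodes = sorted(base.nodes)
    n_keep = int(round(overlap_fraction * len(edges)))
    keep_idx = rng.choice(len(edges), size=n_keep, replace=False)
    kept = {edges[i] for i in keep_idx}
    new_edges = set(kept)
    base_edges = set(edges)
    n_nodes = len(nodes)
    while len(new_edges) < len(edges):
        a, b = rng.integers(0, n_nodes, size=2)
        if a == b:
            continue
        e = canonical_edge(nodes[a], nodes[b])
        if e in base_edges or e in new_edges:
            continue
        new_edges.add(e)
    return Network(new_edges, nodes=nodes, name=name)


def gen_annotations(genes: Sequence[str], n_terms: int,
                    size_range: Tuple[int, int] = (5, 30),
                    planted_terms: int = 0, net: Network | None = None,
                    seed: int = 0, category: str = "BP") -> AnnotationSet:
    """Annotation table with optional planted connected modules.

    Background terms are uniform gene samples; planted terms grow along the
    network's edges (repeatedly absorbing neighbors of already-included
    genes), so their internal edge count exceeds the hypergeometric
    expectation for a random gene set of equal size.
    """
    if planted_terms > n_terms:
        raise ValueError("planted_terms cannot exceed n_terms")
    if planted_terms > 0 and net is None:
        raise ValueError("planting enriched terms requires a network")
    lo, hi = size_range
    genes = [str(g) for g in genes]
    if not (1 <= lo <= hi <= len(genes)):
        raise ValueError(f"size_range {size_range} infeasible for {len(genes)} genes")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mapping: Dict[str, set] = {}
    width = len(str(max(n_terms - 1, 1)))
    for t in range(planted_terms):
        size = int(rng.integers(lo, hi + 1))
        adj = {g: sorted(net.graph.neighbors(g)) for g in net.nodes}
        seed_edges = sorted(net.edges)
        a, b = seed_edges[rng.integers(len(seed_edges))]
        members = {a, b}
        while len(members) < size:
            frontier = sorted({nb for g in members for nb in adj[g]} - members)
            if frontier:
                members.add(frontier[rng.integers(len(frontier))])
            else:  # component exhausted: jump to a fresh edge
                a, b = seed_edges[rng.integers(len(seed_edges))]
                members |= {a, b}
        mapping[f"PLANTED:{t:0{width}d}"] = members
    for t in range(n_terms - planted_terms):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(genes, size=size, replace=False).tolist())
        mapping[f"TERM:{t:0{width}d}"] = members
    return AnnotationSet(mapping, category=category)


def gen_loci(genes: Sequence[str], n_chromosomes: int = 3,
             lengths: Sequence[float] | None = None, cis_strength: float = 0.0,
             net: Network | None = None, seed: int = 0,
             topology: str = "circular", gene_length: float = 1000.0,
             rewire_fraction: float = 0.6) -> Tuple[ChromosomeMap, Network | None]:
    """Place genes uniformly on chromosomes; optionally plant cis-structure.

    With ``cis_strength > 0`` (an exponential decay scale on the relative
    distance delta) a ``rewire_fraction`` of the network's edges is
    re-targeted to same-chromosome partners sampled with weight
    exp(-delta / cis_strength), so interacting genes end up closer than
    random gene pairs.  Returns the map and the (possibly rewired) network;
    the input network is never modified.
    """
    genes = [str(g) for g in genes]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if lengths is None:
        lengths = [1_000_000.0] * n_chromosomes
    if len(lengths) != n_chromosomes or any(L <= 0 for L in lengths):
        raise ValueError("need one positive length per chromosome")
    chrom_ids = [f"chr{i + 1}" for i in range(n_chromosomes)]
    cmap = ChromosomeMap(lengths=dict(zip(chrom_ids, map(float, lengths))),
                         topology={c: topology for c in chrom_ids})
    for g in genes:
        c = chrom_ids[int(rng.integers(n_chromosomes))]
        L = cmap.lengths[c]
        glen = min(gene_length, L / 2)
        start = float(rng.uniform(1, L - glen))
        cmap.loci[g] = GeneLocus(gene=g, chromosome=c, start=start, end=start + glen)
    cmap.__post_init__()

    if net is None or cis_strength <= 0:
        return cmap, (net.copy() if net is not None else None)

    by_chrom: Dict[str, List[str]] = {}
    for g in genes:
        by_chrom.setdefault(cmap.loci[g].chromosome, []).append(g)
    for c in by_chrom:
        by_chrom[c].sort()
    out = net.copy()
    edges = sorted(out.edges)
    n_rewire = int(round(rewire_fraction * len(edges)))
    chosen = rng.choice(len(edges), size=n_rewire, replace=False)
    for i in sorted(chosen):
        a, b = edges[i]
        anchor = a if rng.random() < 0.5 else b
        cands = [g for g in by_chrom[cmap.loci[anchor].chromosome]
                 if g != anchor and not out.has_edge(anchor, g)]
        if not cands:
            continue
        deltas = np.array([relative_distance(cmap.loci[anchor], cmap.loci[g], cmap)
                           for g in cands])
        w = np.exp(-deltas / cis_strength)
        if w.sum() <= 0:
            continue
        new_partner = cands[int(rng.choice(len(cands), p=w / w.sum()))]
        out.graph.remove_edge(a, b)
        out.graph.add_edge(anchor, new_partner)
    return cmap, out


def gen_expression(truth_net: Network, n_samples: int, noise_sd: float = 1.5,
                   seed: int = 0, weight_range: Tuple[float, float] = (0.5, 1.0),
                   standardize: bool = True) -> ExpressionMatrix:
    """Linear-Gaussian sampling over a random orientation of the truth network.

    A uniform node permutation orients every edge from earlier to later,
    giving a DAG; parentless genes are standard normal and every other gene
    is the signed weighted sum of its parents plus Gaussian noise, with
    weights of magnitude in ``weight_range`` and random sign.  Every gene is
    rescaled to unit variance as soon as it is generated, so ``noise_sd`` is
    the noise level relative to unit-variance regulatory input at every
    depth of the cascade (and the noise_sd -> infinity limit decouples all
    genes).  Rows are mean-centered at the end unless ``standardize`` is
    disabled.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = sorted(truth_net.nodes)
    n_genes = len(genes)
    order = rng.permutation(n_genes)
    rank = {genes[i]: int(np.where(order == i)[0][0]) for i in range(n_genes)}
    parents: Dict[str, List[str]] = {g: [] for g in genes}
    for a, b in sorted(truth_net.edges):
        child, parent = (a, b) if rank[a] > rank[b] else (b, a)
        parents[child].append(parent)
    weights = {}
    for child, ps in parents.items():
        for p in ps:
            w = rng.uniform(*weight_range) * (1 if rng.random() < 0.5 else -1)
            weights[(child, p)] = w
    x = np.zeros((n_genes, n_samples))
    idx = {g: i for i, g in enumerate(genes)}
    for g in sorted(genes, key=lambda g: rank[g]):
        noise = rng.normal(0.0, max(noise_sd, 1e-12), size=n_samples)
        if parents[g]:
            signal = sum(weights[(g, p)] * x[idx[p]] for p in parents[g])
            row = signal + noise
        else:
            row = rng.normal(0.0, 1.0, size=n_samples)
        sd = row.std()
        x[idx[g]] = row / sd if sd > 0 else row
    if standardize:
        x = x - x.mean(axis=1, keepdims=True)
    samples = [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(genes=genes, samples=samples, values=x)
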