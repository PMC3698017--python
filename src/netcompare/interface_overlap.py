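"""Structural interfaces between pairs of networks.

The interface of two networks is the subgraph induced by their shared edges.
Overlap is summarized by the shared-edge percentage
s = 100 * |E_a ∩ E_b| / |E_a ∪ E_b| and tested with a hypergeometric
upper tail: among the N = C(p, 2) possible pairs over the p common genes,
network a marks m pairs, network b draws n pairs, and k pairs land in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Set, Tuple

from scipy.stats import hypergeom

from .netcore import Network

logger = logging.getLogger("netcompare")


@dataclass
class InterfaceResult:
    """Shared-edge subgraph of two networks plus overlap statistics."""
    shared_edges: Set[Tuple[str, str]]
    shared_genes: Set[str]
    percent_shared: float          # s in [0, 100]
    overlap_p: float               # hypergeometric upper tail P(X >= k)
    counts: Tuple[int, int, int, int]  # (N possible pairs, m, n, k)

    @property
    def interface(self) -> Network:
        return Network(self.shared_edges, name="interface")


def restrict_to_common_genes(a: Network, b: Network) -> Tuple[Network, Network]:
    """Induce both networks on their node intersection."""
    common = a.nodes & b.nodes
    if not common:
        raise ValueError("networks share no genes")
    return a.subgraph(common), b.subgraph(common)


def shared_edge_percentage(a: Network, b: Network) -> float:
    """100 * |E_a ∩ E_b| / |E_a ∪ E_b|."""
    ea, eb = a.edges, b.edges
    union = ea | eb
    if not union:
        raise ValueError("both edge sets are empty")
    return 100.0 * len(ea & eb) / len(union)


def overlap_test(a: Network, b: Network) -> InterfaceResult:
    """Hypergeometric significance of the edge overlap of two networks.

    Expects networks already restricted to their common genes (the
    population of possible pairs is defined over those genes only).
    """
    genes = a.nodes | b.nodes
    p = len(genes)
    n_possible = p * (p - 1) // 2
    ea, eb = a.edges, b.edges
    shared = ea & eb
    m, n, k = len(ea), len(eb), len(shared)
    if k > min(m, n):
        raise RuntimeError("internal consistency error: k > min(m, n)")
    pval = 1.0 if k == 0 else float(hypergeom.sf(k - 1, n_possible, m, n))
    return InterfaceResult(
        shared_edges=shared,
        shared_genes={g for e in shared for g in e},
        percent_shared=shared_edge_percentage(a, b),
        overlap_p=pval,
        counts=(n_possible, m, n, k),
    )
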