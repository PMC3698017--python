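"""Structural similarity of two networks on the pathway (gene-set) level.

For each annotation term, the centrality values of the term's genes in the
two networks form two vectors that are compared by Spearman rank
correlation; a BH adjustment across terms controls the false discovery
rate.  Centralities are computed on the full common-gene networks first and
then subset to the term's genes (not on term-induced subgraphs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.stats import spearmanr

from .enrichment import AnnotationSet, adjust
from .netcore import Network, centrality

logger = logging.getLogger("netcompare")


@dataclass
class TermCorrelation:
    term: str
    size: int
    rho: float      # NaN when the term's vectors are constant (untestable)
    p_raw: float
    p_fdr: float
    significant: bool = False


def _paired_values(values_a: Dict[str, float], values_b: Dict[str, float],
                   genes) -> Tuple[np.ndarray, np.ndarray]:
    """Aligned value pairs over genes, dropping undefined entries pairwise."""
    xs, ys = [], []
    for g in sorted(genes):
        va = values_a.get(g)
        vb = values_b.get(g)
        if va is None or vb is None or math.isnan(va) or math.isnan(vb):
            continue
        xs.append(va)
        ys.append(vb)
    return np.asarray(xs), np.asarray(ys)


def global_centrality_correlation(a: Network, b: Network,
                                  measure: str) -> Tuple[float, float]:
    """Spearman rho and two-sided p of one centrality over the common genes."""
    common = a.nodes & b.nodes
    if len(common) < 3:
        raise ValueError("need >= 3 common genes")
    va = centrality(a, measure)
    vb = centrality(b, measure)
    x, y = _paired_values(va, vb, common)
    if len(x) < 3:
        raise ValueError("fewer than 3 usable gene pairs after dropping undefined values")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


def per_term_centrality_correlation(a: Network, b: Network, ann: AnnotationSet,
                                    measure: str, min_size: int = 11,
                                    max_size: int = 1000,
                                    fdr_level: float = 0.05,
                                    on_term_subgraph: bool = False
                                    ) -> List[TermCorrelation]:
    """Per-term Spearman correlation of a centrality between two networks.

    Terms are filtered by the count of their genes present in both networks;
    terms whose centrality vector is constant in either network cannot be
    rank-correlated and are reported with NaN, excluded from the FDR family.
    By default centralities describe each gene's role in the whole
    (common-gene) network and are merely subset to the term's genes;
    ``on_term_subgraph=True`` recomputes them on the term-induced subgraphs
    instead.
    """
    common = a.nodes & b.nodes
    va = vb = None
    if not on_term_subgraph:
        va = centrality(a, measure)
        vb = centrality(b, measure)
    rows: List[TermCorrelation] = []
    for term in ann.terms:
        genes = ann.genes_of(term) & common
        size = len(genes)
        if not (min_size <= size <= max_size):
            continue
        if on_term_subgraph:
            va = centrality(a.subgraph(genes), measure)
            vb = centrality(b.subgraph(genes), measure)
        x, y = _paired_values(va, vb, genes)
        if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
            rows.append(TermCorrelation(term=term, size=size, rho=float("nan"),
                                        p_raw=float("nan"), p_fdr=float("nan")))
            logger.info("term %s untestable (constant or too few values)", term)
            continue
        rho, p = spearmanr(x, y)
        rows.append(TermCorrelation(term=term, size=size, rho=float(rho),
                                    p_raw=float(p), p_fdr=float("nan")))
    testable = [r for r in rows if not math.isnan(r.p_raw)]
    if not rows:
        logger.warning("no qualifying terms for per-term centrality correlation")
    if testable:
        for r, padj in zip(testable, adjust([r.p_raw for r in testable], "bh")):
            r.p_fdr = float(padj)
            r.significant = padj <= fdr_level
    return rows
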