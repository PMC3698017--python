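"""Gene Ontology annotation model and enrichment tests.

Three hypergeometric tests share one result record:

* GEA — over-representation of a gene set within a term against a background
  universe (N = genes, m = term genes, n = set size, k = overlap).
* global GPEA — over-representation of a single network's edges among the
  gene pairs internal to a term: N = C(p, 2) possible pairs over the p
  network genes, m = C(p_GO, 2) pairs internal to the term, n = network
  edges, k = edges with both endpoints in the term.
* interface GPEA — the same test on the shared edges of two networks:
  N = |E_a ∪ E_b|, n = |E_a ∩ E_b|, m = term-internal edges of the union,
  k = term-internal shared edges.

Defaults follow the three regimes used throughout the pipeline: global GPEA
Bonferroni alpha 1e-4, interface GPEA BH fdr 0.01, per-chromosome GEA
nominal alpha 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .netcore import Network

logger = logging.getLogger("netcompare")

CATEGORIES = ("BP", "MF", "CC")

#: significance regimes (config-exposed defaults)
GPEA_GLOBAL_ALPHA = 1e-4      # Bonferroni
GPEA_INTERFACE_FDR = 0.01     # Benjamini-Hochberg
CHROM_GEA_ALPHA = 0.01        # nominal


class AnnotationSet:
    """term -> gene-set mapping for one GO category."""

    def __init__(self, term_to_genes: Dict[str, Set[str]], category: str = "BP",
                 labels: Dict[str, str] | None = None):
        if category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        for t, gs in term_to_genes.items():
            if not gs:
                raise ValueError(f"term {t!r} has no genes")
        self.category = category
        self.term_to_genes = {t: set(map(str, gs)) for t, gs in term_to_genes.items()}
        self.labels = labels or {}

    @property
    def terms(self) -> List[str]:
        return sorted(self.term_to_genes)

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for gs in self.term_to_genes.values():
            out |= gs
        return out

    def genes_of(self, term: str) -> Set[str]:
        return self.term_to_genes[term]

    def terms_of(self, gene: str) -> Set[str]:
        return {t for t, gs in self.term_to_genes.items() if gene in gs}

    def restrict(self, genes: Iterable[str]) -> "AnnotationSet":
        """Keep only the given genes; terms left empty are dropped."""
        genes = set(genes)
        mapping = {t: gs & genes for t, gs in self.term_to_genes.items()}
        mapping = {t: gs for t, gs in mapping.items() if gs}
        return AnnotationSet(mapping, category=self.category, labels=self.labels)

    def relabel(self, mapping: Dict[str, str]) -> "AnnotationSet":
        """Apply a gene-id permutation (used by label randomization)."""
        return AnnotationSet(
            {t: {mapping.get(g, g) for g in gs} for t, gs in self.term_to_genes.items()},
            category=self.category, labels=self.labels)


def read_annotations(path, category: str = "BP", format: str = "tsv") -> AnnotationSet:
    """Read a 2-column (gene, term) TSV or a GAF 2.x file.

    For GAF, column 2 (gene id) and column 5 (term) are used; rows with a
    NOT qualifier (column 4) are dropped, other qualifiers are ignored.
    """
    mapping: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            cols = line.split("\t")
            if format == "tsv":
                if len(cols) < 2:
                    raise ValueError(f"annotation row needs 2 columns: {line!r}")
                gene, term = cols[0], cols[1]
            elif format == "gaf":
                if len(cols) < 5:
                    continue
                if "NOT" in cols[3].split("|"):
                    continue
                gene, term = cols[1], cols[4]
            else:
                raise ValueError(f"unknown annotation format {format!r}")
            mapping.setdefault(term, set()).add(gene)
    return AnnotationSet(mapping, category=category)


def write_annotations(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for term in ann.terms:
            for gene in sorted(ann.genes_of(term)):
                fh.write(f"{gene}\t{term}\n")


@dataclass
class EnrichmentResult:
    """Per-term hypergeometric counts and p-values (raw and adjusted)."""
    term: str
    size: int        # annotated genes considered for this term
    N: int           # population (genes for GEA, pairs for GPEA)
    m: int           # successes in population
    n: int           # draws
    k: int           # observed successes
    p_raw: float
    p_adj: float = float("nan")


def _upper_tail(k: int, N: int, m: int, n: int) -> float:
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def adjust(pvalues: Sequence[float], method: str = "bh") -> List[float]:
    """Multiple-testing adjustment preserving input order.

    bonferroni: min(1, p * M).  bh: Benjamini-Hochberg step-up with
    monotonicity enforcement.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return list(np.minimum(1.0, p * p.size))
    if method == "bh":
        return list(multipletests(p, method="fdr_bh")[1])
    raise ValueError(f"unknown adjustment method {method!r}")


def _adjusted(results: List[EnrichmentResult], method: str) -> List[EnrichmentResult]:
    adj = adjust([r.p_raw for r in results], method=method)
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results


def gea(genes_of_interest: Iterable[str], universe: Iterable[str], ann: AnnotationSet,
        min_size: int = 3, max_size: int = 999, method: str = "bh",
        annotated_only: bool = True) -> List[EnrichmentResult]:
    """Gene-set enrichment: hypergeometric upper tail per term.

    The universe is restricted to annotated genes (unannotatable genes carry
    no information for the test); term sizes are counted within the
    universe and filtered to [min_size, max_size].
    """
    interest = set(map(str, genes_of_interest))
    universe = set(map(str, universe))
    if not universe:
        raise ValueError("empty universe")
    if not interest <= universe:
        raise ValueError("genes of interest must be a subset of the universe")
    if annotated_only:
        universe = universe & ann.genes
        interest = interest & universe
    results: List[EnrichmentResult] = []
    for term in ann.terms:
        term_genes = ann.genes_of(term) & universe
        m = len(term_genes)
        if not (min_size <= m <= max_size):
            continue
        k = len(term_genes & interest)
        results.append(EnrichmentResult(
            term=term, size=m, N=len(universe), m=m, n=len(interest), k=k,
            p_raw=_upper_tail(k, len(universe), m, len(interest))))
    return _adjusted(results, method)


def gpea_global(net: Network, ann: AnnotationSet, min_size: int = 3,
                max_size: int = 999, method: str = "bonferroni") -> List[EnrichmentResult]:
    """Gene-pair enrichment of one network's edges inside each term.

    The network should already be restricted to the annotated universe
    (use ``net.subgraph(ann.genes & net.nodes)``).
    """
    p = net.n_nodes
    n_pairs = p * (p - 1) // 2
    n_edges = net.n_edges
    node_set = net.nodes
    results: List[EnrichmentResult] = []
    for term in ann.terms:
        term_genes = ann.genes_of(term) & node_set
        size = len(term_genes)
        if size > p:
            logger.warning("term %s larger than network, skipped", term)
            continue
        if not (min_size <= size <= max_size):
            continue
        m = size * (size - 1) // 2
        k = sum(1 for a, b in net.edges if a in term_genes and b in term_genes)
        results.append(EnrichmentResult(
            term=term, size=size, N=n_pairs, m=m, n=n_edges, k=k,
            p_raw=_upper_tail(k, n_pairs, m, n_edges)))
    return _adjusted(results, method)


def gpea_interface(a: Network, b: Network, ann: AnnotationSet, min_size: int = 3,
                   max_size: int = 499, method: str = "bh") -> List[EnrichmentResult]:
    """Gene-pair enrichment of the shared edges of two networks.

    Population = edges of the union network, draws = shared edges; per term,
    m counts term-internal union edges and k term-internal shared edges.
    Both networks should already be restricted to common annotated genes.
    """
    ea, eb = a.edges, b.edges
    union = ea | eb
    shared = ea & eb
    N = len(union)
    n = len(shared)
    if n == 0:
        logger.warning("gpea_interface: no shared edges, all p-values are 1")
    results: List[EnrichmentResult] = []
    node_set = a.nodes | b.nodes
    for term in ann.terms:
        term_genes = ann.genes_of(term) & node_set
        size = len(term_genes)
        if not (min_size <= size <= max_size):
            continue
        m = sum(1 for x, y in union if x in term_genes and y in term_genes)
        k = sum(1 for x, y in shared if x in term_genes and y in term_genes)
        p_raw = 1.0 if n == 0 else _upper_tail(k, N, m, n)
        results.append(EnrichmentResult(
            term=term, size=size, N=N, m=m, n=n, k=k, p_raw=p_raw))
    return _adjusted(results, method)


def results_frame(results: List[EnrichmentResult]):
    """Results as a pandas DataFrame (term, size, N, m, n, k, p_raw, p_adj)."""
    import pandas as pd

    return pd.DataFrame([{
        "term": r.term, "size": r.size, "N": r.N, "m": r.m, "n": r.n,
        "k": r.k, "p_raw": r.p_raw, "p_adj": r.p_adj} for r in results])
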