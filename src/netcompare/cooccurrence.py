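"""Functional co-occurrence of annotation terms along network edges.

For every edge (g_i, g_j) the raw score d counts the terms annotating both
endpoints; scores are normalized to [0, 1] by the maximum over edges and
summarized as an empirical CDF.  Reference ensembles come from uniform
permutations of the gene labels over the fixed topology, so a biologically
wired network's CDF sits to the right of its randomized references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .enrichment import AnnotationSet
from .netcore import Network

logger = logging.getLogger("netcompare")


@dataclass
class CooccurrenceProfile:
    """Per-edge co-occurrence counts and normalized scores."""
    raw: Dict[Tuple[str, str], int]
    normalized: Dict[Tuple[str, str], float]

    @property
    def max_raw(self) -> int:
        return max(self.raw.values(), default=0)


@dataclass
class RandomizationEnsemble:
    """Co-occurrence profiles from R gene-label permutations of one topology."""
    profiles: List[CooccurrenceProfile]
    R: int
    seed: int


def cooccurrence_counts(net: Network, ann: AnnotationSet) -> CooccurrenceProfile:
    """Count, per edge, the terms containing both endpoints; normalize by max."""
    gene_terms = {g: frozenset() for g in net.nodes}
    for term, genes in ann.term_to_genes.items():
        for g in genes:
            if g in gene_terms:
                gene_terms[g] = gene_terms[g] | {term}
    raw = {e: len(gene_terms[e[0]] & gene_terms[e[1]]) for e in net.edges}
    mx = max(raw.values(), default=0)
    normalized = {e: (d / mx if mx else 0.0) for e, d in raw.items()}
    return CooccurrenceProfile(raw=raw, normalized=normalized)


def cooccurrence_cdf(profile: CooccurrenceProfile,
                     use_raw: bool = False) -> List[Tuple[float, float]]:
    """Empirical CDF over edge scores (zero-score edges included).

    Returns sorted (score, cumulative fraction) step points ending at 1.
    """
    scores = list((profile.raw if use_raw else profile.normalized).values())
    if not scores:
        raise ValueError("empty co-occurrence profile")
    values, counts = np.unique(np.asarray(scores, dtype=float), return_counts=True)
    cum = np.cumsum(counts) / len(scores)
    return list(zip(values.tolist(), cum.tolist()))


def cdf_at(cdf: List[Tuple[float, float]], x: float) -> float:
    """Evaluate a step CDF at x (right-continuous)."""
    out = 0.0
    for v, c in cdf:
        if v <= x:
            out = c
        else:
            break
    return out


def randomize_labels(net: Network, ann: AnnotationSet, R: int = 100,
                     seed: int = 0) -> RandomizationEnsemble:
    """R co-occurrence profiles under uniform gene-label permutation.

    Node identities are permuted over the same topology — equivalent to
    permuting the annotation assignment — so degree sequences and the
    annotation multiset are preserved in every replicate.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    profiles = []
    for _ in range(R):
        perm = rng.permutation(len(nodes))
        mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
        relabeled = Network(((mapping[a], mapping[b]) for a, b in net.edges),
                            nodes=nodes, name=net.name)
        profiles.append(cooccurrence_counts(relabeled, ann))
    return RandomizationEnsemble(profiles=profiles, R=R, seed=seed)


def ensemble_mean_cdf(ensemble: RandomizationEnsemble,
                      grid: np.ndarray | None = None,
                      use_raw: bool = False) -> List[Tuple[float, float]]:
    """Pointwise mean of the ensemble's CDFs on a common score grid."""
    cdfs = [cooccurrence_cdf(p, use_raw=use_raw) for p in ensemble.profiles]
    if grid is None:
        pts = sorted({v for cdf in cdfs for v, _ in cdf})
        grid = np.asarray(pts)
    means = [float(np.mean([cdf_at(cdf, x) for cdf in cdfs])) for x in grid]
    return list(zip(grid.tolist(), means))
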