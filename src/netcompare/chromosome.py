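"""Chromosomal co-location and distance analysis of interacting genes.

A gene's position is its midpoint m = start + (end - start) / 2; two
co-chromosomal genes are separated by the relative distance
delta = min(|m2 - m1| / L, 1 - |m2 - m1| / L) on a circular chromosome of
length L (so delta <= 0.5), or |m2 - m1| / L on a linear one.  The module
computes co-location fractions, per-chromosome degree ranks, edge-distance
profiles with their Kolmogorov-Smirnov comparisons, and one-way ANOVA of
mean distances across networks per chromosome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, ks_2samp, rankdata, spearmanr

from .netcore import Network

logger = logging.getLogger("netcompare")


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    chromosome: str
    start: float  # bp, 1-based inclusive
    end: float

    def __post_init__(self):
        if self.end < self.start or self.start < 0:
            raise ValueError(f"invalid locus for {self.gene}: [{self.start}, {self.end}]")


def midpoint(locus: GeneLocus) -> float:
    """Midpoint coordinate start + (end - start) / 2 in bp."""
    return locus.start + (locus.end - locus.start) / 2.0


@dataclass
class ChromosomeMap:
    """Chromosome lengths/topologies plus per-gene loci."""
    lengths: Dict[str, float]
    topology: Dict[str, str]               # chromosome -> {circular, linear}
    loci: Dict[str, GeneLocus] = field(default_factory=dict)

    def __post_init__(self):
        for c, t in self.topology.items():
            if t not in ("circular", "linear"):
                raise ValueError(f"chromosome {c}: topology must be circular or linear")
        for locus in self.loci.values():
            L = self.lengths.get(locus.chromosome)
            if L is None:
                raise ValueError(f"gene {locus.gene} on unknown chromosome {locus.chromosome}")
            if locus.end > L:
                raise ValueError(f"gene {locus.gene} exceeds chromosome length {L}")

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self.lengths)

    def add(self, locus: GeneLocus) -> None:
        self.loci[locus.gene] = locus
        self.__post_init__()


def read_chromosome_map(map_path, loci_path, loci_format: str = "tsv") -> ChromosomeMap:
    """Read a chromosome table (id, length, topology) and a loci table.

    Loci are 4-column ``chrom start end gene``; BED input (0-based
    half-open) is converted to 1-based inclusive coordinates.
    """
    lengths: Dict[str, float] = {}
    topo: Dict[str, str] = {}
    with open(map_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, length, topology = line.split()[:3]
            lengths[cid] = float(length)
            topo[cid] = topology
    cmap = ChromosomeMap(lengths=lengths, topology=topo)
    with open(loci_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, gene = line.split()[:4]
            start_f, end_f = float(start), float(end)
            if loci_format == "bed":
                start_f += 1  # 0-based half-open -> 1-based inclusive
            cmap.loci[gene] = GeneLocus(gene=gene, chromosome=chrom,
                                        start=start_f, end=end_f)
    cmap.__post_init__()
    return cmap


def write_chromosome_map(cmap: ChromosomeMap, map_path, loci_path) -> None:
    with open(map_path, "w") as fh:
        for c in cmap.chromosomes:
            fh.write(f"{c}\t{cmap.lengths[c]:.0f}\t{cmap.topology[c]}\n")
    with open(loci_path, "w") as fh:
        for gene in sorted(cmap.loci):
            l = cmap.loci[gene]
            fh.write(f"{l.chromosome}\t{l.start:.0f}\t{l.end:.0f}\t{gene}\n")


NOT_COLOCATED = None  # sentinel for gene pairs on different chromosomes


def relative_distance(g1: GeneLocus, g2: GeneLocus,
                      cmap: ChromosomeMap) -> Optional[float]:
    """Relative midpoint distance of two co-located genes, or None.

    Circular chromosomes: min(|dm| / L, 1 - |dm| / L) in [0, 0.5]; linear:
    |dm| / L in [0, 1].  Genes on different chromosomes return None (a
    not-co-located signal, not an error).
    """
    if g1.chromosome != g2.chromosome:
        return NOT_COLOCATED
    L = cmap.lengths[g1.chromosome]
    d = abs(midpoint(g2) - midpoint(g1)) / L
    if cmap.topology[g1.chromosome] == "circular":
        return min(d, 1.0 - d)
    return d


@dataclass
class DistanceProfile:
    """Relative distances of co-located edges plus co-location bookkeeping."""
    distances: List[float]                       # one delta per co-located edge
    by_chromosome: Dict[str, List[float]]
    colocation_fraction: float                   # percent of mapped edges
    n_mapped_edges: int
    n_unmapped_edges: int


def edge_distance_profile(net: Network, cmap: ChromosomeMap) -> DistanceProfile:
    """Relative distances over the network's co-located, mapped edges."""
    distances: List[float] = []
    by_chrom: Dict[str, List[float]] = {}
    n_mapped = 0
    n_unmapped = 0
    for a, b in sorted(net.edges):
        la, lb = cmap.loci.get(a), cmap.loci.get(b)
        if la is None or lb is None:
            n_unmapped += 1
            continue
        n_mapped += 1
        d = relative_distance(la, lb, cmap)
        if d is not None:
            distances.append(d)
            by_chrom.setdefault(la.chromosome, []).append(d)
    if n_mapped == 0:
        raise ValueError("no edges with both endpoints mapped")
    frac = 100.0 * len(distances) / n_mapped
    if n_unmapped:
        logger.info("%s: %d unmapped edge(s) excluded from distance profile",
                    net.name, n_unmapped)
    return DistanceProfile(distances=distances, by_chromosome=by_chrom,
                           colocation_fraction=frac, n_mapped_edges=n_mapped,
                           n_unmapped_edges=n_unmapped)


def colocation_fraction(net: Network, cmap: ChromosomeMap) -> float:
    """Percent of mapped edges whose endpoints share a chromosome."""
    return edge_distance_profile(net, cmap).colocation_fraction


def chromosome_degree_ranks(net: Network, cmap: ChromosomeMap) -> pd.DataFrame:
    """Per-chromosome degree sums with average-rank ties (rank 1 = largest)."""
    sums: Dict[str, float] = {c: 0.0 for c in cmap.chromosomes}
    any_mapped = False
    for gene in net.nodes:
        locus = cmap.loci.get(gene)
        if locus is not None:
            sums[locus.chromosome] += net.degree(gene)
            any_mapped = True
    if not any_mapped:
        logger.warning("no mapped genes for chromosome degree ranks")
    chroms = sorted(sums)
    values = np.array([sums[c] for c in chroms])
    ranks = rankdata(-values, method="average")
    return pd.DataFrame({"chromosome": chroms, "degree_sum": values, "rank": ranks})


def chromosome_rank_correlation(net_a: Network, net_b: Network,
                                cmap: ChromosomeMap) -> Tuple[float, float]:
    """Spearman correlation of per-chromosome degree sums of two networks,
    computed over the genes present in both networks."""
    common = net_a.nodes & net_b.nodes
    ra = chromosome_degree_ranks(net_a.subgraph(common), cmap)
    rb = chromosome_degree_ranks(net_b.subgraph(common), cmap)
    rho, p = spearmanr(ra["degree_sum"], rb["degree_sum"])
    return float(rho), float(p)


def compare_distance_distributions(d1: Iterable[float],
                                   d2: Iterable[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: sup |ECDF1 - ECDF2| and its p."""
    x = np.asarray(list(d1), dtype=float)
    y = np.asarray(list(d2), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty distance profile")
    stat, p = ks_2samp(x, y, method="asymp")
    return float(stat), float(p)


def per_chromosome_anova(profiles: Dict[str, DistanceProfile]) -> pd.DataFrame:
    """One-way ANOVA of mean relative distances across networks per chromosome.

    ``profiles`` maps network name -> DistanceProfile.  Chromosomes with
    fewer than 2 groups of >= 2 values are skipped with a warning.
    Bonferroni correction is applied over the tested chromosomes.
    """
    chroms = sorted({c for p in profiles.values() for c in p.by_chromosome})
    rows = []
    for c in chroms:
        groups = [p.by_chromosome.get(c, []) for p in profiles.values()]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2 or any(np.ptp(g) == 0 for g in groups):
            logger.warning("chromosome %s: degenerate groups, ANOVA skipped", c)
            continue
        f, p = f_oneway(*groups)
        rows.append({"chromosome": c, "F": float(f), "p": float(p)})
    df = pd.DataFrame(rows, columns=["chromosome", "F", "p"])
    if len(df):
        df["p_bonf"] = np.minimum(1.0, df["p"] * len(df))
    else:
        df["p_bonf"] = []
    return df


def reference_distances(cmap: ChromosomeMap) -> Dict[str, float]:
    """Mean adjacent-pair and mean all-pair relative distances.

    'adjacent' averages delta over consecutive genes sorted by midpoint per
    chromosome; 'global' averages delta over all same-chromosome gene pairs.
    """
    adjacent: List[float] = []
    global_: List[float] = []
    by_chrom: Dict[str, List[GeneLocus]] = {}
    for locus in cmap.loci.values():
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    for c, loci in by_chrom.items():
        loci = sorted(loci, key=midpoint)
        for l1, l2 in zip(loci, loci[1:]):
            adjacent.append(relative_distance(l1, l2, cmap))
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                global_.append(relative_distance(loci[i], loci[j], cmap))
    return {
        "adjacent": float(np.mean(adjacent)) if adjacent else math.nan,
        "global": float(np.mean(global_)) if global_ else math.nan,
    }
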