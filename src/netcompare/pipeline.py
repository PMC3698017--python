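"""End-to-end orchestration of the four analysis blocks.

``run_structural`` produces per-network summary statistics, power-law fits
and pairwise global centrality correlations; ``run_functional`` the
interface overlap tests, interface and global GPEA, common-significant-term
fractions and co-occurrence CDFs with randomized references;
``run_chromosomal`` the co-location fractions, distance ECDFs and their KS
comparisons against label-randomized references, per-chromosome ANOVA,
chromosome degree-rank correlations and per-chromosome GEA/GPEA.  All
randomness flows from the single configured seed.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import chromosome as chrom
from . import cooccurrence as cooc
from .enrichment import (AnnotationSet, CHROM_GEA_ALPHA, GPEA_GLOBAL_ALPHA,
                         GPEA_INTERFACE_FDR, gea, gpea_global, gpea_interface,
                         read_annotations, results_frame)
from .interface_overlap import overlap_test, restrict_to_common_genes
from .netcore import (CENTRALITY_MEASURES, Network, degree_histogram,
                      fit_power_law, network_stats, read_network)
from .pathway_centrality import global_centrality_correlation

logger = logging.getLogger("netcompare")


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run (YAML-loadable)."""
    networks: Dict[str, str] = field(default_factory=dict)  # name -> path
    annotation: Optional[str] = None
    annotation_category: str = "BP"
    loci: Optional[str] = None
    chromosome_map: Optional[str] = None
    expression: Optional[str] = None
    outdir: str = "netcompare_out"
    seed: int = 0
    # per-stage thresholds (package defaults mirror the analysis regimes)
    gpea_global_alpha: float = GPEA_GLOBAL_ALPHA
    gpea_interface_fdr: float = GPEA_INTERFACE_FDR
    chrom_gea_alpha: float = CHROM_GEA_ALPHA
    term_min_size: int = 3
    term_max_size: int = 999
    interface_term_max_size: int = 499
    randomizations: int = 100   # R, label-permutation replicates
    bootstrap_B: int = 100      # BC3NET ensemble size
    inference_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for alpha in (cfg.gpea_global_alpha, cfg.gpea_interface_fdr,
                      cfg.chrom_gea_alpha, cfg.inference_alpha):
            if not 0 < alpha <= 1:
                raise ValueError(f"threshold {alpha} outside (0, 1]")
        return cfg

    def load_networks(self) -> Dict[str, Network]:
        if len(self.networks) < 2:
            raise ValueError("need at least 2 networks")
        out = {}
        for name, path in self.networks.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"network {name}: {path}")
            out[name] = read_network(path, name=name)
        return out

    def load_annotation(self) -> AnnotationSet:
        if self.annotation is None:
            raise ValueError("no annotation configured")
        return read_annotations(self.annotation, category=self.annotation_category)

    def load_chromosome_map(self) -> chrom.ChromosomeMap:
        if self.loci is None or self.chromosome_map is None:
            raise ValueError("loci / chromosome map not configured")
        return chrom.read_chromosome_map(self.chromosome_map, self.loci)


def _ensure_outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "effective_config.json").write_text(
        json.dumps({k: v for k, v in vars(cfg).items()}, indent=2, default=str))
    return out


def run_structural(cfg: RunConfig, networks: Dict[str, Network] | None = None
                   ) -> Dict[str, pd.DataFrame]:
    """Summary stats, power-law fits and pairwise centrality correlations."""
    nets = networks if networks is not None else cfg.load_networks()
    out = _ensure_outdir(cfg)
    stats_rows = []
    for name in sorted(nets):
        s = network_stats(nets[name])
        fit = fit_power_law(degree_histogram(nets[name]))
        stats_rows.append({"network": name, "n_nodes": s.n_nodes,
                           "n_edges": s.n_edges, "gcc_size": s.gcc_size,
                           "edge_density": s.edge_density,
                           "assortativity": s.assortativity,
                           "powerlaw_alpha": fit.alpha, "powerlaw_c": fit.c})
    stats = pd.DataFrame(stats_rows)

    corr_rows = []
    for a, b in itertools.combinations(sorted(nets), 2):
        for measure in CENTRALITY_MEASURES:
            try:
                rho, p = global_centrality_correlation(nets[a], nets[b], measure)
            except ValueError:
                rho, p = math.nan, math.nan
            corr_rows.append({"network_a": a, "network_b": b,
                              "measure": measure, "rho": rho, "p": p})
    corr = pd.DataFrame(corr_rows)
    stats.to_csv(out / "structural_stats.tsv", sep="\t", index=False)
    corr.to_csv(out / "structural_correlations.tsv", sep="\t", index=False)
    return {"stats": stats, "correlations": corr}


def _common_significant_fraction(res_a, res_b, alpha: float) -> float:
    """Fraction of significant terms shared by both networks.

    Jaccard of the two adjusted-significant term sets: terms significant in
    both, over terms significant in either.  NaN when neither network has a
    significant term.
    """
    terms_a = {r.term for r in res_a if r.p_adj <= alpha}
    terms_b = {r.term for r in res_b if r.p_adj <= alpha}
    union = terms_a | terms_b
    if not union:
        return math.nan
    return len(terms_a & terms_b) / len(union)


def run_functional(cfg: RunConfig, networks: Dict[str, Network] | None = None,
                   ann: AnnotationSet | None = None) -> Dict[str, object]:
    """Interface overlap, interface/global GPEA, co-occurrence CDFs."""
    nets = networks if networks is not None else cfg.load_networks()
    annotation = ann if ann is not None else cfg.load_annotation()
    if len(annotation.terms) < 10:
        logger.warning("annotation category has < 10 terms, functional stage skipped")
        return {"skipped": True}
    out = _ensure_outdir(cfg)

    # global GPEA per network, restricted to annotated genes
    global_results = {}
    for name in sorted(nets):
        net = nets[name]
        annotated = net.subgraph(net.nodes & annotation.genes)
        global_results[name] = gpea_global(
            annotated, annotation, min_size=cfg.term_min_size,
            max_size=cfg.term_max_size, method="bonferroni")
        results_frame(global_results[name]).to_csv(
            out / f"gpea_global_{name}.tsv", sep="\t", index=False)

    interface_rows = []
    interface_tables = {}
    fractions = {}
    for a, b in itertools.combinations(sorted(nets), 2):
        ra, rb = restrict_to_common_genes(nets[a], nets[b])
        res = overlap_test(ra, rb)
        interface_rows.append({
            "network_a": a, "network_b": b,
            "n_shared_edges": len(res.shared_edges),
            "n_shared_genes": len(res.shared_genes),
            "percent_shared": round(res.percent_shared, 1),
            "overlap_p": res.overlap_p})
        common_ann = annotation.restrict(ra.nodes | rb.nodes)
        ga = ra.subgraph(ra.nodes & common_ann.genes)
        gb = rb.subgraph(rb.nodes & common_ann.genes)
        itab = gpea_interface(ga, gb, common_ann, min_size=cfg.term_min_size,
                              max_size=cfg.interface_term_max_size)
        interface_tables[(a, b)] = itab
        results_frame(itab).to_csv(out / f"gpea_interface_{a}_{b}.tsv",
                                   sep="\t", index=False)
        fractions[(a, b)] = _common_significant_fraction(
            global_results[a], global_results[b], cfg.gpea_global_alpha)
    interfaces = pd.DataFrame(interface_rows)
    interfaces.to_csv(out / "interfaces.tsv", sep="\t", index=False)

    # co-occurrence CDFs with randomized references
    cdf_rows = []
    cooc_summary = {}
    rng_seed = np.random.SeedSequence(cfg.seed).spawn(len(nets))
    for i, name in enumerate(sorted(nets)):
        profile = cooc.cooccurrence_counts(nets[name], annotation)
        cdf = cooc.cooccurrence_cdf(profile)
        ensemble = cooc.randomize_labels(
            nets[name], annotation, R=cfg.randomizations,
            seed=int(rng_seed[i].generate_state(1)[0] % (2 ** 31)))
        ref = cooc.ensemble_mean_cdf(ensemble)
        cooc_summary[name] = {"observed": cdf, "randomized_mean": ref}
        for score, frac in cdf:
            cdf_rows.append({"network": name, "kind": "observed",
                             "score": score, "cum_fraction": frac})
        for score, frac in ref:
            cdf_rows.append({"network": name, "kind": "randomized_mean",
                             "score": score, "cum_fraction": frac})
    pd.DataFrame(cdf_rows).to_csv(out / "cooccurrence_cdfs.tsv", sep="\t", index=False)

    frac_df = pd.DataFrame([{"network_a": a, "network_b": b, "fraction": f}
                            for (a, b), f in fractions.items()])
    frac_df.to_csv(out / "common_significant_fractions.tsv", sep="\t", index=False)
    return {"interfaces": interfaces, "gpea_global": global_results,
            "gpea_interface": interface_tables,
            "common_significant_fractions": fractions,
            "cooccurrence": cooc_summary, "skipped": False}


def run_chromosomal(cfg: RunConfig, networks: Dict[str, Network] | None = None,
                    cmap: chrom.ChromosomeMap | None = None,
                    ann: AnnotationSet | None = None) -> Dict[str, object]:
    """Co-location, distance distributions, ANOVA, ranks, per-chromosome enrichment."""
    nets = networks if networks is not None else cfg.load_networks()
    cmap = cmap if cmap is not None else cfg.load_chromosome_map()
    out = _ensure_outdir(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 77]))

    profiles = {}
    coloc_rows = []
    ks_rows = []
    for name in sorted(nets):
        net = nets[name]
        prof = chrom.edge_distance_profile(net, cmap)
        profiles[name] = prof
        coloc_rows.append({"network": name,
                           "colocation_percent": prof.colocation_fraction,
                           "n_mapped_edges": prof.n_mapped_edges})
        # randomized reference: permute gene labels of the mapped genes
        mapped = sorted(g for g in net.nodes if g in cmap.loci)
        perm = rng.permutation(len(mapped))
        mapping = {mapped[i]: mapped[perm[i]] for i in range(len(mapped))}
        rand_net = Network(((mapping.get(a, a), mapping.get(b, b))
                            for a, b in net.edges), nodes=net.nodes, name=name)
        rand_prof = chrom.edge_distance_profile(rand_net, cmap)
        if prof.distances and rand_prof.distances:
            stat, p = chrom.compare_distance_distributions(
                prof.distances, rand_prof.distances)
        else:
            stat, p = math.nan, math.nan
        ks_rows.append({"network": name, "ks_stat": stat, "ks_p": p})
    coloc = pd.DataFrame(coloc_rows)
    ks = pd.DataFrame(ks_rows)

    n_chrom = len(cmap.chromosomes)
    anova = chrom.per_chromosome_anova(profiles) if n_chrom >= 2 else pd.DataFrame()
    rank_rows = []
    if n_chrom >= 2:
        for a, b in itertools.combinations(sorted(nets), 2):
            rho, p = chrom.chromosome_rank_correlation(nets[a], nets[b], cmap)
            rank_rows.append({"network_a": a, "network_b": b, "rho": rho, "p": p})
    else:
        logger.warning("single chromosome: ANOVA and rank stages skipped")
    ranks = pd.DataFrame(rank_rows)

    gea_tables = {}
    if ann is None and cfg.annotation is not None:
        ann = cfg.load_annotation()
    if ann is not None:
        for name in sorted(nets):
            net = nets[name]
            universe = {g for g in net.nodes if g in cmap.loci}
            rows = []
            for c in cmap.chromosomes:
                genes_c = {g for g in universe if cmap.loci[g].chromosome == c}
                if not genes_c:
                    continue
                res = gea(genes_c, universe, ann, min_size=cfg.term_min_size,
                          max_size=cfg.term_max_size, method="bh")
                n_sig = sum(1 for r in res if r.p_raw <= cfg.chrom_gea_alpha)
                sub = net.subgraph(genes_c & ann.genes)
                pres = gpea_global(sub, ann, min_size=cfg.term_min_size,
                                   max_size=cfg.term_max_size, method="bonferroni")
                n_sig_gpea = sum(1 for r in pres if r.p_adj <= 0.05)
                rows.append({"chromosome": c, "n_genes": len(genes_c),
                             "gea_significant": n_sig, "gea_tested": len(res),
                             "gpea_significant": n_sig_gpea, "gpea_tested": len(pres)})
            gea_tables[name] = pd.DataFrame(rows)
            gea_tables[name].to_csv(out / f"chromosome_enrichment_{name}.tsv",
                                    sep="\t", index=False)

    coloc.to_csv(out / "colocation.tsv", sep="\t", index=False)
    ks.to_csv(out / "distance_ks.tsv", sep="\t", index=False)
    if len(anova):
        anova.to_csv(out / "distance_anova.tsv", sep="\t", index=False)
    if len(ranks):
        ranks.to_csv(out / "chromosome_rank_correlations.tsv", sep="\t", index=False)
    return {"colocation": coloc, "ks": ks, "anova": anova, "ranks": ranks,
            "profiles": profiles, "chromosome_enrichment": gea_tables,
            "reference_distances": chrom.reference_distances(cmap)}


def run_all(cfg: RunConfig) -> Dict[str, object]:
    nets = cfg.load_networks()
    results: Dict[str, object] = {"structural": run_structural(cfg, nets)}
    if cfg.annotation:
        results["functional"] = run_functional(cfg, nets)
    if cfg.loci and cfg.chromosome_map:
        results["chromosomal"] = run_chromosomal(cfg, nets)
    return results
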