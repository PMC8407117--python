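"""End-to-end analysis: simulate (or load) a panel, run the k-mer GWAS,
fit the predictive model and map the best k-mers back onto the genomes.

All stages are deterministic given the configuration seed; outputs are
written with fixed orderings and float formats so that two runs with
the same seed are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import association, io, kmers, mapping, model, phenotype, structure
from .simulate import SimConfig, simulate_study, write_simulation


@dataclass
class PipelineResult:
    cfg: SimConfig
    truth: object
    pheno: pd.Series
    counts: pd.DataFrame
    occupancy: phenotype.OccupancyMatrix
    matrix: kmers.KmerPresenceMatrix
    filtered: kmers.KmerPresenceMatrix
    distances: pd.DataFrame
    tree: structure.StrainTree
    weights: pd.Series
    assoc: pd.DataFrame
    best: pd.DataFrame
    exact: pd.DataFrame
    report: model.ModelReport
    hits: pd.DataFrame
    summary: mapping.HitSummary
    regions: list[dict]


def run_pipeline(cfg: SimConfig, outdir: str | Path | None = None,
                 alpha: float = 0.05, top_n: int = 1000,
                 upstream: int = mapping.DEFAULT_UPSTREAM,
                 mode: str = "single") -> PipelineResult:
    """Run the full synthetic-study analysis.

    The phenotype used for association is the per-strain mean
    single-nodule occupancy computed from the simulated nodule counts
    (mode 'single'), normalized into [0, 1].
    """
    genomes, annotations, truth, _, counts = simulate_study(cfg)
    occ = phenotype.mean_occupancy(counts, mode=mode)
    pheno = phenotype.normalize_for_gwas(occ, cfg.competition_id)

    matrix = kmers.count_kmers(genomes, k=cfg.k)
    dist = kmers.kmer_distance(matrix)
    tree = structure.upgma(dist)
    weights = structure.gsc_weights(tree)
    filtered = kmers.filter_kmers(matrix)
    assoc = association.run_association(filtered, pheno, weights,
                                        alpha=alpha)
    carriers = truth.carrier_map[cfg.causal_block_id]
    best, exact = association.select_best_kmers(
        assoc, p_cut=alpha, carrier_set=carriers)

    feats = model.select_top(assoc, top_n)
    fmat = filtered.to_frame().T[feats].astype(float)
    report = model.nested_cv(fmat, pheno,
                             model.ModelSpec(top_n=top_n, seed=cfg.seed))

    query = list(exact["kmer"]) if len(exact) else list(best["kmer"])
    occ_list = mapping.locate_kmers(query, genomes)
    hits = mapping.classify_hits(occ_list, annotations, upstream=upstream)
    summary = mapping.summarize_hits(hits, annotations)
    regions = mapping.carrier_exclusive_region(
        hits[hits["strain"].isin(carriers)], annotations, carriers)

    result = PipelineResult(
        cfg=cfg, truth=truth, pheno=pheno, counts=counts, occupancy=occ,
        matrix=matrix, filtered=filtered, distances=dist, tree=tree,
        weights=weights, assoc=assoc, best=best, exact=exact,
        report=report, hits=hits, summary=summary, regions=regions)
    if outdir is not None:
        write_outputs(result, genomes, annotations, Path(outdir))
    return result


def write_outputs(res: PipelineResult, genomes, annotations,
                  outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_simulation(outdir / "sim", genomes, annotations, res.truth,
                     res.counts)
    occ = res.occupancy.values.copy()
    occ.index.name = "strain_id"
    io.write_tsv(occ.reset_index(), outdir / f"occupancy_{res.occupancy.mode}.tsv")
    ph = res.pheno.rename("phenotype").rename_axis("strain_id")
    io.write_tsv(ph.reset_index(), outdir / "phenotype.tsv")
    d = res.distances.copy()
    d.index.name = "strain_id"
    io.write_tsv(d.reset_index(), outdir / "kmer_jaccard.tsv")
    (outdir / "strain_tree.nwk").write_text(res.tree.to_newick() + "\n")
    w = res.weights.rename("weight").rename_axis("strain_id")
    io.write_tsv(w.reset_index(), outdir / "gsc_weights.tsv")
    io.write_tsv(res.assoc, outdir / "association.tsv")
    io.write_tsv(res.best, outdir / "best_kmers.tsv")
    io.write_tsv(res.exact, outdir / "best_kmers_exact_carriers.tsv")
    (outdir / "model.json").write_text(
        json.dumps(model.report_to_json(res.report), indent=1,
                   sort_keys=True))
    io.write_tsv(res.hits, outdir / "kmer_hits.tsv")
    frac = res.summary.ortholog_replicon_fractions.copy()
    if not frac.empty:
        frac.index.name = "strain_id"
        io.write_tsv(frac.reset_index(), outdir / "ortholog_replicon_fractions.tsv")
    (outdir / "regions.json").write_text(
        json.dumps(res.regions, indent=1, sort_keys=True))
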