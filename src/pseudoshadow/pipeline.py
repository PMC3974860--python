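"""End-to-end wiring: simulate (or load), filter, quantify, characterize.

``run_pipeline`` executes the stages in dependency order — read filtering,
FPKM quantification, transcribed calls, tissue-specificity and correlation
statistics, small-RNA classification, chromatin densities, diversity and
conservation — and writes one TSV per report plus a manifest capturing the
seed, config hash and row counts so a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import (
    chromatin_analysis,
    evolution_metrics,
    expression_stats,
    pseudoquant,
    srna_analysis,
    synthetic_data,
)
from . import io as psio

log = logging.getLogger("pseudoshadow")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, defaulted to the published values."""

    fpkm_transcribed: float = 1.0
    fpkm_high: float = 10.0
    parent_js_min: float = 0.1
    distance_cutoff: int = 20_000
    srna_exonic_min: float = 5.0
    srna_flank_hi: float = 5.0
    strand_ratio: float = 10.0
    kd_fold: float = 1.3
    seed: int = 0
    # synthetic-run sizes
    n_expression_pairs: int = 200
    reads_per_gene: int = 600
    reads_per_pg: int = 150

    def __post_init__(self) -> None:
        for name in ("fpkm_transcribed", "fpkm_high", "parent_js_min",
                     "distance_cutoff", "srna_exonic_min", "srna_flank_hi",
                     "strand_ratio", "kd_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def canonical_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-14s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a simulated dataset; return the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    t0 = time.perf_counter()

    # ---- simulate genome and reads
    spec = synthetic_data.ToyGenomeSpec(
        identity_targets=(0.85, 0.90, 0.95), seed=int(seeds[0]))
    genome, annotation, truth = synthetic_data.build_toy_genome(spec)
    psio.write_fasta(genome, out / "genome.fa")
    psio.write_annotation_bed12(annotation, out / "annotation.bed")
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    expression = {g.feature_id: config.reads_per_gene for g in annotation.genes}
    expression.update({p.feature_id: config.reads_per_pg
                       for p in annotation.pseudogenes})
    reads, genome_recs, cdna_recs, read_truth = synthetic_data.simulate_rnaseq_reads(
        genome, annotation, expression, seed=int(seeds[1]))
    t0 = _stage("simulate", t0)

    # ---- filter
    candidates = pseudoquant.collect_candidate_reads(genome_recs, annotation)
    kept, removed, decisions = pseudoquant.filter_pseudogene_reads(
        candidates, cdna_recs)
    filtered = pseudoquant.rewrite_alignments(genome_recs, removed)
    psio.write_sam(filtered, chrom_sizes, out / "filtered.sam")
    pseudoquant.decisions_table(decisions).to_csv(
        out / "decisions.tsv", sep="\t", index=False)
    t0 = _stage("filter", t0)

    # ---- quantify + call
    column = pseudoquant.compute_fpkm(filtered, annotation, "sim_tissue")
    column.fpkm.to_csv(out / "fpkm.tsv", sep="\t")
    calls = pseudoquant.call_transcribed(column, config.fpkm_transcribed)
    calls.to_csv(out / "calls.tsv", sep="\t")
    t0 = _stage("quant", t0)

    # ---- multi-tissue statistics on simulated profiles
    pg_m, parent_m, expr_truth = synthetic_data.simulate_expression_profiles(
        config.n_expression_pairs, planted_rho=(0.8, 0.0, -0.8),
        seed=int(seeds[2]))
    pg_m.fpkm.to_csv(out / "pg_expression.tsv", sep="\t")
    parent_m.fpkm.to_csv(out / "parent_expression.tsv", sep="\t")
    js = expression_stats.js_specificity_table(pg_m)
    js.to_csv(out / "js_scores.tsv", sep="\t")
    parent_js = expression_stats.js_specificity_table(parent_m)
    pairs = [(f"pg{k:04d}", f"g{k:04d}")
             for k in range(config.n_expression_pairs)]
    pairs = [(p, g) for p, g in pairs
             if parent_js.loc[g, "js_score"] > config.parent_js_min]
    corr = expression_stats.pg_parent_spearman(pg_m, parent_m, pairs)
    pd.DataFrame([(c.pg_id, c.parent_id, c.rho, c.p) for c in corr],
                 columns=["pg_id", "parent_id", "rho", "p"]).to_csv(
        out / "correlations.tsv", sep="\t", index=False)
    splits = [
        expression_stats.tissue_split_mean_variance(
            pg_m.fpkm.loc[p].to_numpy(), parent_m.fpkm.loc[g].to_numpy(),
            pg_m.tissues, p)
        for p, g in pairs
    ]
    pd.DataFrame([(s.pg_id, s.mu_h, s.mu_l, s.s_h, s.s_l, s.delta_mu,
                   s.delta_s) for s in splits],
                 columns=["pg_id", "mu_h", "mu_l", "s_h", "s_l", "delta_mu",
                          "delta_s"]).to_csv(out / "split.tsv", sep="\t",
                                             index=False)
    groups = expression_stats.distance_groups(
        annotation.pseudogenes, annotation.genes, config.distance_cutoff)
    pd.Series(groups, name="distance_group").to_csv(
        out / "distance_groups.tsv", sep="\t")
    t0 = _stage("stats", t0)

    # ---- small RNA
    pgs = [f.feature_id for f in annotation.pseudogenes]
    labels = {fid: ("I" if i % 3 == 0 else "II" if i % 3 == 1 else "none")
              for i, fid in enumerate(pgs)}
    srna_bed, srna_truth = synthetic_data.simulate_srna_reads(
        annotation, labels, seed=int(seeds[3]))
    psio.write_bed6(srna_bed, out / "srna_reads.bed")
    srna_tags = psio.tagset_from_bed(srna_bed)
    genome_kb = sum(chrom_sizes.values()) / 1000.0
    background = srna_tags.count() / genome_kb
    density = srna_analysis.srna_density(srna_tags, annotation,
                                         chrom_sizes=chrom_sizes,
                                         features=pgs)
    calls_srna = srna_analysis.classify_srna_groups(
        density, config.srna_exonic_min, config.srna_flank_hi, background)
    pd.DataFrame([(c.feature_id, c.call, c.poisson_p) for c in calls_srna],
                 columns=["pg_id", "call", "poisson_p"]).to_csv(
        out / "srna_calls.tsv", sep="\t", index=False)
    t0 = _stage("srna", t0)

    # ---- chromatin
    transcribed_pgs = [p for p in pgs if calls.loc[p, "transcribed"]]
    enrichment = {p: 5.0 for p in transcribed_pgs}
    tags = synthetic_data.simulate_chip_tags(
        annotation, chrom_sizes, enrichment, background_rate=0.02,
        seed=int(seeds[4]))
    intervals = [(f.chrom, max(0, f.tss - 2500), f.tss + 2500, f.feature_id)
                 for f in annotation.pseudogenes]
    dens = chromatin_analysis.window_tag_count(tags, intervals)
    dens.to_csv(out / "chip_density.tsv", sep="\t")
    profile = chromatin_analysis.anchored_profile(
        tags, [(f.chrom, f.tss, f.strand) for f in annotation.pseudogenes],
        flank=2500, bin_width=500)
    pd.DataFrame({"offset": profile.bin_starts,
                  "tags_per_bin_per_anchor": profile.values}).to_csv(
        out / "chip_profile.tsv", sep="\t", index=False)
    t0 = _stage("chromatin", t0)

    # ---- evolution
    div_rows = []
    for i, pg in enumerate(pgs):
        hs, true_pi = synthetic_data.simulate_population_haplotypes(
            1000, 20, target_pi=0.0005 * (1 + i), seed=int(seeds[5]) + i,
            locus_id=pg)
        res = evolution_metrics.nucleotide_diversity(hs)
        div_rows.append([pg, res.pi, true_pi, res.n])
    pd.DataFrame(div_rows, columns=["pg_id", "pi", "planted_pi", "n"]).to_csv(
        out / "diversity.tsv", sep="\t", index=False)
    rng = np.random.default_rng(int(seeds[6]))
    cons_rows = []
    for chrom, size in chrom_sizes.items():
        scores = rng.uniform(0.0, 1.0, size=size)
        track = evolution_metrics.ConservationTrack(chrom, scores)
        for f in annotation.pseudogenes:
            mean, nb = evolution_metrics.mean_conservation(
                track, [(s, e) for s, e in f.blocks])
            cons_rows.append([f.feature_id, mean, nb])
    pd.DataFrame(cons_rows, columns=["pg_id", "mean_phastcons", "n_bases"]
                 ).to_csv(out / "conservation.tsv", sep="\t", index=False)
    t0 = _stage("evolution", t0)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.canonical_hash(),
        "n_reads": len(reads),
        "n_candidates": len(candidates),
        "n_kept": len(kept),
        "n_removed": len(removed),
        "n_transcribed": int(calls["transcribed"].sum()),
        "n_pairs": len(pairs),
        "n_srna_reads": int(len(srna_bed)),
        "n_chip_tags": tags.count(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
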