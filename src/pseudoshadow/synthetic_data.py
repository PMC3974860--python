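"""Synthetic genomes, reads, tags, haplotypes and expression profiles.

Every generator here emits ground truth (:class:`~pseudoshadow.models.PlantedTruth`)
alongside its data, so each downstream stage of the pipeline can be tested
without any external dataset.  The toy genome contains genes with introns and
processed / duplicated / unitary pseudogene copies of them at controlled
sequence identity; the read simulator plants exactly the failure mode the
read filter exists for: exon-exon junction reads of a parent gene whose best
contiguous genomic hit is the intron-less processed pseudogene.

Randomness: every operation takes a single integer seed and derives
independent child streams from ``numpy.random.SeedSequence(seed).spawn``,
so a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    DUPLICATED_PG,
    GENE,
    PROCESSED_PG,
    UNITARY_PG,
    AlignmentRecord,
    AnnotationModel,
    ExpressionMatrix,
    Feature,
    HaplotypeSet,
    PlantedTruth,
    TagSet,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class ToyGenomeSpec:
    """Layout and identity parameters for a toy genome.

    ``identity_targets`` cycles over the processed+duplicated pseudogenes in
    placement order; unitary pseudogenes have no parent to be mutated from.
    """

    n_genes: int = 2
    exons_per_gene: int = 4
    exon_len: int = 300
    intron_len: int = 200
    n_processed: int = 2
    n_duplicated: int = 1
    n_unitary: int = 1
    identity_targets: tuple[float, ...] = (0.90,)
    chrom_len: int = 60_000
    intergenic_gap: int = 3_000
    seed: int = 0
    indel_rate: float = 0.0  # substitutions only by default
    chrom: str = "chrT"

    def __post_init__(self) -> None:
        for name in ("n_genes", "exons_per_gene", "exon_len", "intron_len",
                     "n_processed", "n_duplicated", "n_unitary",
                     "chrom_len", "intergenic_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for t in self.identity_targets:
            if not (0.5 < t <= 1.0):
                raise ValueError(f"identity target {t} outside (0.5, 1.0]")
        if self.indel_rate != 0.0:
            raise NotImplementedError("indel simulation is not supported")

    @property
    def gene_span(self) -> int:
        return (self.exons_per_gene * self.exon_len
                + (self.exons_per_gene - 1) * self.intron_len)

    @property
    def transcript_len(self) -> int:
        return self.exons_per_gene * self.exon_len


def _mutate_copy(seq: np.ndarray, identity: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Substitute bases in a copy so realized identity hits the target."""
    out = seq.copy()
    n_sub = round((1.0 - identity) * len(seq))
    if n_sub:
        pos = rng.choice(len(seq), size=n_sub, replace=False)
        for p in pos:
            choices = BASES[BASES != out[p]]
            out[p] = rng.choice(choices)
    return out, 1.0 - n_sub / len(seq)


def build_toy_genome(
    spec: ToyGenomeSpec,
) -> tuple[dict[str, str], AnnotationModel, PlantedTruth]:
    """Lay out genes and pseudogene copies on one toy chromosome.

    Pseudogene sequences are mutated copies of the parent transcript
    (processed: introns removed, single block) or of the parent locus
    (duplicated: introns retained, blocks mirror the parent's exons).
    Parents are assigned round-robin over the genes.
    """
    rng_seq, rng_mut = _rngs(spec.seed, 2)
    genome = rng_seq.choice(BASES, size=spec.chrom_len)
    truth = PlantedTruth()
    feats: list[Feature] = []

    # required length check up front
    spans = ([spec.gene_span] * spec.n_genes
             + [spec.transcript_len] * spec.n_processed
             + [spec.gene_span] * spec.n_duplicated
             + [spec.exon_len] * spec.n_unitary)
    required = spec.intergenic_gap + sum(s + spec.intergenic_gap for s in spans)
    if required > spec.chrom_len:
        raise ValueError(
            f"features do not fit: chrom_len must be >= {required} "
            f"(got {spec.chrom_len})"
        )

    cursor = spec.intergenic_gap
    gene_feats: list[Feature] = []
    for g in range(spec.n_genes):
        start = cursor
        blocks = tuple(
            (start + i * (spec.exon_len + spec.intron_len),
             start + i * (spec.exon_len + spec.intron_len) + spec.exon_len)
            for i in range(spec.exons_per_gene)
        )
        f = Feature(f"gene{g}", spec.chrom, start, start + spec.gene_span,
                    "+", GENE, blocks)
        gene_feats.append(f)
        feats.append(f)
        cursor = f.end + spec.intergenic_gap

    if (spec.n_processed or spec.n_duplicated) and not spec.n_genes:
        raise ValueError("parented pseudogenes require at least one gene")

    def _transcript(f: Feature) -> np.ndarray:
        return np.concatenate([genome[s:e] for s, e in f.blocks])

    identities = list(spec.identity_targets) or [1.0]
    pg_index = 0
    for p in range(spec.n_processed):
        parent = gene_feats[p % spec.n_genes]
        target = identities[pg_index % len(identities)]
        pg_index += 1
        seq, realized = _mutate_copy(_transcript(parent), target, rng_mut)
        start = cursor
        end = start + len(seq)
        genome[start:end] = seq
        fid = f"ppg{p}"
        feats.append(Feature(fid, spec.chrom, start, end, "+", PROCESSED_PG,
                             ((start, end),), parent.feature_id))
        truth.pg_identity[fid] = realized
        truth.pg_strand[fid] = "+"
        cursor = end + spec.intergenic_gap

    for d in range(spec.n_duplicated):
        parent = gene_feats[d % spec.n_genes]
        target = identities[pg_index % len(identities)]
        pg_index += 1
        locus = genome[parent.start:parent.end].copy()
        seq, realized = _mutate_copy(locus, target, rng_mut)
        start = cursor
        end = start + len(seq)
        genome[start:end] = seq
        blocks = tuple((start + s - parent.start, start + e - parent.start)
                       for s, e in parent.blocks)
        fid = f"dpg{d}"
        feats.append(Feature(fid, spec.chrom, start, end, "+", DUPLICATED_PG,
                             blocks, parent.feature_id))
        truth.pg_identity[fid] = realized
        truth.pg_strand[fid] = "+"
        cursor = end + spec.intergenic_gap

    for u in range(spec.n_unitary):
        start = cursor
        end = start + spec.exon_len
        fid = f"upg{u}"
        feats.append(Feature(fid, spec.chrom, start, end, "+", UNITARY_PG,
                             ((start, end),)))
        truth.pg_strand[fid] = "+"
        cursor = end + spec.intergenic_gap

    seq_str = genome.tobytes().decode("ascii")
    return {spec.chrom: seq_str}, AnnotationModel(feats), truth


# ------------------------------------------------------------------ RNA-Seq


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def best_offset_mismatches(read: np.ndarray, target: np.ndarray) -> tuple[int, int, str]:
    """Minimum Hamming distance of ``read`` over all offsets of ``target``.

    Both strands are searched.  Returns (mismatches, offset, strand); the
    reported offset/strand is the first best on the forward strand, then
    reverse.  Uses a vectorized sliding-window comparison.
    """
    L = len(read)
    best = (L + 1, -1, "+")
    for strand, r in (("+", read), ("-", _revcomp(read))):
        if len(target) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(target, L)
        mm = (win != r).sum(axis=1)
        i = int(mm.argmin())
        if mm[i] < best[0]:
            best = (int(mm[i]), i, strand)
    return best


def simulate_rnaseq_reads(
    genome: dict[str, str],
    annotation: AnnotationModel,
    expression: dict[str, int],
    read_len: int = 50,
    junction_fraction: float = 0.1,
    error_rate: float = 0.0,
    seed: int = 0,
    cdna_max_mm: int = 3,
) -> tuple[list[tuple[str, str]], list[AlignmentRecord], list[AlignmentRecord], PlantedTruth]:
    """Simulate single-end transcriptome reads plus their alignments.

    The emulated genome aligner reports one best location per read.  Gene
    junction reads have no contiguous genomic placement, so their best hit
    is the intron-less processed pseudogene copy (the paper's yellow-arrow
    case); all other reads are adjudicated between their true locus and the
    homologous parent/pseudogene locus by Hamming distance, with ties
    assigned to the pseudogene locus (worst-case contamination).  The cDNA
    aligner searches every coding transcript on both strands and reports the
    best hit when it has at most ``cdna_max_mm`` mismatches.
    """
    for fid in expression:
        if fid not in annotation.by_id:
            raise KeyError(f"expression references unknown feature {fid!r}")
    rng_start, rng_err = _rngs(seed, 2)
    chrom_arr = {c: _encode(s) for c, s in genome.items()}
    truth = PlantedTruth()

    def tx_seq(f: Feature) -> np.ndarray:
        return np.concatenate([chrom_arr[f.chrom][s:e] for s, e in f.blocks])

    cdnas = {g.feature_id: tx_seq(g) for g in annotation.genes}

    def genome_mm(read: np.ndarray, f: Feature, tstart: int) -> tuple[int, tuple]:
        blocks = f.read_blocks(tstart, len(read))
        ref = np.concatenate([chrom_arr[f.chrom][s:e] for s, e in blocks])
        return int((ref != read).sum()), blocks

    reads: list[tuple[str, str]] = []
    genome_recs: list[AlignmentRecord] = []
    cdna_recs: list[AlignmentRecord] = []
    rid = 0

    for fid in sorted(expression):
        f = annotation.by_id[fid]
        tlen = f.exon_length
        if read_len > tlen:
            raise ValueError(f"read_len {read_len} exceeds transcript of {fid}")
        tx = tx_seq(f)
        junctions = []
        acc = 0
        for s, e in f.blocks[:-1]:
            acc += e - s
            junctions.append(acc)
        # homologs: parent for pseudogenes, pseudogene children for genes
        if f.is_pseudogene and f.parent_id:
            homologs = [annotation.by_id[f.parent_id]]
        elif f.feat_class == GENE:
            homologs = annotation.children_of(fid)
        else:
            homologs = []
        processed_children = [h for h in homologs if h.feat_class == PROCESSED_PG]

        for _ in range(expression[fid]):
            name = f"r{rid:06d}"
            rid += 1
            is_junction = (f.feat_class == GENE and junctions
                           and rng_start.random() < junction_fraction)
            if is_junction:
                j = junctions[rng_start.integers(len(junctions))]
                lo = max(0, j - read_len + 1)
                hi = min(j - 1, tlen - read_len)
                tstart = int(rng_start.integers(lo, hi + 1))
            elif f.feat_class == GENE:
                # stay inside one exon so junction_fraction is exact
                widths = np.array([e - s - read_len + 1 for s, e in f.blocks])
                widths = np.clip(widths, 0, None)
                b = rng_start.choice(len(f.blocks), p=widths / widths.sum())
                off = int(rng_start.integers(widths[b]))
                tstart = sum(e - s for s, e in f.blocks[:b]) + off
            else:
                tstart = int(rng_start.integers(tlen - read_len + 1))

            read = tx[tstart:tstart + read_len].copy()
            n_err = 0
            if error_rate > 0:
                hit = rng_err.random(read_len) < error_rate
                n_err = int(hit.sum())
                for p in np.nonzero(hit)[0]:
                    read[p] = rng_err.choice(BASES[BASES != read[p]])
            seq = read.tobytes().decode("ascii")
            reads.append((name, seq))
            truth.read_origin[name] = fid
            truth.read_detail[name] = (fid, tstart, bool(is_junction), n_err)

            # ---- genomic placement
            candidates: list[tuple[int, str, Feature, tuple]] = []
            if is_junction and processed_children:
                for h in processed_children:
                    mm, blocks = genome_mm(read, h, tstart)
                    candidates.append((mm, h.feature_id, h, blocks))
            else:
                mm, blocks = genome_mm(read, f, tstart)
                candidates.append((mm, fid, f, blocks))
                for h in homologs:
                    if h.exon_length == tlen:
                        hmm, hblocks = genome_mm(read, h, tstart)
                        candidates.append((hmm, h.feature_id, h, hblocks))
            best_mm = min(c[0] for c in candidates)
            at_best = [c for c in candidates if c[0] == best_mm]
            # ties resolve to a pseudogene placement when one is tied
            pg_best = [c for c in at_best if c[2].is_pseudogene]
            mm, _, placed, blocks = (pg_best or at_best)[0]
            genome_recs.append(
                AlignmentRecord(name, placed.chrom, blocks[0][0], "+", mm,
                                blocks, seq)
            )

            # ---- cDNA placement (best coding transcript, both strands)
            best = (read_len + 1, "", 0, "+")
            for gid in sorted(cdnas):
                mmc, off, strand = best_offset_mismatches(read, cdnas[gid])
                if mmc < best[0]:
                    best = (mmc, gid, off, strand)
            if best[0] <= cdna_max_mm:
                cdna_recs.append(
                    AlignmentRecord(name, best[1], best[2], best[3], best[0],
                                    ((best[2], best[2] + read_len),), seq)
                )

    return reads, genome_recs, cdna_recs, truth


def leakage_fixture(
    seed: int = 0,
) -> tuple[dict[str, str], AnnotationModel, PlantedTruth,
           list[tuple[str, str]], list[AlignmentRecord],
           list[AlignmentRecord], PlantedTruth]:
    """A read set with realistic parent-to-pseudogene contamination.

    Six processed pseudogenes span identities 0.85-0.95 (the range holding
    most annotated pseudogenes) and parent genes are sequenced ~13x deeper
    than the pseudogenes, mirroring the abundance gap between coding genes
    and pseudogene ncRNAs.  Ambiguous ties and junction reads pile onto the
    high-identity pseudogene windows, which is exactly the signal the
    identity-window diagnostic must see before filtering and not after.
    """
    gseed, rseed = (int(s) for s in
                    np.random.SeedSequence(seed).generate_state(2) % (2**31))
    spec = ToyGenomeSpec(
        n_genes=2, exons_per_gene=6, exon_len=400, intron_len=200,
        n_processed=6, n_duplicated=0, n_unitary=0,
        identity_targets=(0.85, 0.87, 0.89, 0.91, 0.93, 0.95),
        chrom_len=120_000, intergenic_gap=3_000, seed=gseed)
    genome, annotation, truth = build_toy_genome(spec)
    expression = {g.feature_id: 2000 for g in annotation.genes}
    for f in annotation.pseudogenes:
        expression[f.feature_id] = 150
    reads, grecs, crecs, read_truth = simulate_rnaseq_reads(
        genome, annotation, expression, seed=rseed, junction_fraction=0.1)
    return genome, annotation, truth, reads, grecs, crecs, read_truth


# ------------------------------------------------------------------ small RNA


def simulate_srna_reads(
    annotation: AnnotationModel,
    group_labels: dict[str, str],
    exonic_density: float = 8.0,
    flank_density: float = 8.0,
    len_medians: tuple[int, int] = (22, 25),
    flank: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Plant small-RNA reads with group I / group II density patterns.

    Group I features receive >= ``exonic_density`` reads/kb over their exon
    union and none in the +/-1 kb flanks; group II additionally receive
    >= ``flank_density`` reads/kb in the flanks.  Read lengths are drawn
    symmetrically around the per-group median.
    """
    if exonic_density < 0 or flank_density < 0:
        raise ValueError("densities must be >= 0")
    (rng,) = _rngs(seed, 1)
    truth = PlantedTruth()
    rows = []
    rid = 0
    spans = {f.feature_id: (f.chrom, f.start, f.end) for f in annotation.features}

    for fid in sorted(group_labels):
        label = group_labels[fid]
        truth.srna_group[fid] = label
        if label == "none":
            continue
        if label not in ("I", "II"):
            raise ValueError(f"unknown group label {label!r} for {fid}")
        f = annotation.by_id[fid]
        lo, hi = f.start - flank, f.end + flank
        for oid, (c, s, e) in spans.items():
            if oid != fid and c == f.chrom and s < hi and e > lo:
                raise ValueError(
                    f"flank of {fid} overlaps {oid}; space features further apart"
                )
        median = len_medians[0] if label == "I" else len_medians[1]

        def emit(n: int, positions: np.ndarray, region: str) -> None:
            nonlocal rid
            lengths = median + rng.integers(-2, 3, size=n)
            for p, ln in zip(positions, lengths):
                name = f"s{rid:06d}"
                rid += 1
                rows.append([f.chrom, int(p), int(p + ln), name, 0, "+"])
                truth.read_origin[name] = fid
                truth.read_detail[name] = (fid, int(p), False, 0)

        exon_positions = np.concatenate(
            [np.arange(s, e) for s, e in f.blocks])
        n_ex = math.ceil(exonic_density * f.exon_length / 1000.0)
        emit(n_ex, rng.choice(exon_positions, size=n_ex), "exon")
        if label == "II":
            flank_positions = np.concatenate(
                [np.arange(max(0, lo), f.start), np.arange(f.end, hi)])
            n_fl = math.ceil(flank_density * len(flank_positions) / 1000.0)
            emit(n_fl, rng.choice(flank_positions, size=n_fl), "flank")

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                     "strand"])
    return df, truth


# ------------------------------------------------------------------ ChIP tags


def simulate_chip_tags(
    annotation: AnnotationModel,
    chrom_sizes: dict[str, int],
    enrichment: dict[str, float],
    background_rate: float,
    anchor: str = "tss",
    flank: int = 2500,
    seed: int = 0,
) -> TagSet:
    """Poisson tag sampling with fold enrichment in anchor windows.

    ``enrichment`` maps a feature id or a feature class to a fold; ids take
    precedence.  An enriched window (anchor +/- ``flank``) receives
    Poisson(fold x rate x length) tags; everything else receives the
    background rate, so fold=1 reduces to a homogeneous Poisson process.
    """
    for fold in enrichment.values():
        if fold < 0:
            raise ValueError("fold must be >= 0")
    (rng,) = _rngs(seed, 1)
    windows: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_sizes}
    for f in annotation.features:
        fold = enrichment.get(f.feature_id,
                              enrichment.get(f.feat_class, 1.0))
        if fold == 1.0:
            continue
        a = f.tss if anchor == "tss" else (f.start + f.end) // 2
        s = max(0, a - flank)
        e = min(chrom_sizes[f.chrom], a + flank)
        windows[f.chrom].append((s, e, fold))

    positions: dict[str, np.ndarray] = {}
    for chrom, size in sorted(chrom_sizes.items()):
        segs: list[np.ndarray] = []
        wins = sorted(windows[chrom])
        cursor = 0
        for s, e, fold in wins:
            # overlapping enrichment windows: the earlier window wins the
            # shared stretch, the later one is clipped
            s = max(s, cursor)
            if e <= s:
                continue
            for lo, hi, lam_rate in ((cursor, s, background_rate),
                                     (s, e, background_rate * fold)):
                n = rng.poisson(lam_rate * (hi - lo))
                if n:
                    segs.append(rng.integers(lo, hi, size=n))
            cursor = e
        n = rng.poisson(background_rate * (size - cursor))
        if n:
            segs.append(rng.integers(cursor, size, size=n))
        positions[chrom] = (np.sort(np.concatenate(segs))
                            if segs else np.empty(0, dtype=np.int64))
    return TagSet(positions)


# ------------------------------------------------------------------ haplotypes


def simulate_population_haplotypes(
    locus_len: int,
    n_individuals: int,
    target_pi: float,
    seed: int = 0,
    locus_id: str = "locus",
) -> tuple[HaplotypeSet, float]:
    """Plant singleton segregating sites to realize a target diversity.

    Each planted site is carried by one haplotype, contributing
    2(1/n)(1-1/n)/L to pi; the site count is rounded so the realized value
    matches ``target_pi`` up to that granularity.  Truth pi is recomputed by
    exhaustive enumeration of ordered haplotype pairs (independent of the
    estimator in :mod:`pseudoshadow.evolution_metrics`).
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if target_pi * locus_len < 0:
        raise ValueError("target_pi and locus_len must be non-negative")
    (rng,) = _rngs(seed, 1)
    base = rng.choice(BASES, size=locus_len)
    haps = np.tile(base, (n_individuals, 1))
    n = n_individuals
    per_site = 2.0 * (1.0 / n) * (1.0 - 1.0 / n) / locus_len
    n_sites = round(target_pi / per_site) if target_pi > 0 else 0
    if n_sites > locus_len:
        raise ValueError("target_pi too large for locus length")
    sites = rng.choice(locus_len, size=n_sites, replace=False)
    for site in sites:
        carrier = rng.integers(n)
        haps[carrier, site] = rng.choice(BASES[BASES != haps[carrier, site]])

    seqs = tuple(row.tobytes().decode("ascii") for row in haps)
    # exhaustive ordered-pair truth computation
    L = locus_len
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = sum(1 for a, b in zip(seqs[i], seqs[j]) if a != b)
            total += (1.0 / n) * (1.0 / n) * d / L
    return HaplotypeSet(locus_id, seqs), total


# ------------------------------------------------------------------ expression


def _js_of_mixture(a: float, n: int) -> float:
    """JS specificity score of (1-a)*onehot + a*uniform over n tissues."""
    p = np.full(n, a / n)
    p[0] += 1.0 - a
    e = np.zeros(n)
    e[0] = 1.0
    m = 0.5 * (p + e)

    def h(v: np.ndarray) -> float:
        nz = v[v > 0]
        return float(-(nz * np.log2(nz)).sum())

    jsd = h(m) - 0.5 * (h(p) + h(e))
    return 1.0 - math.sqrt(max(jsd, 0.0))


def _mixture_for_js(target: float, n: int) -> np.ndarray:
    """Invert the one-hot/uniform mixture for a JS score by bisection."""
    lo, hi = 0.0, 1.0  # a=0 -> score 1; a=1 -> uniform score
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _js_of_mixture(mid, n) > target:
            lo = mid
        else:
            hi = mid
    a = 0.0 if target >= 1.0 else 0.5 * (lo + hi)
    p = np.full(n, a / n)
    p[0] += 1.0 - a
    return p


def simulate_expression_profiles(
    n_pairs: int,
    n_tissues: int = 16,
    planted_rho: tuple[float, ...] = (0.8,),
    planted_js: tuple[float, ...] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
    tissue_names: list[str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PlantedTruth]:
    """Pseudogene/parent FPKM matrices with planted Spearman correlations.

    Pairs are drawn from a Gaussian copula whose Pearson parameter is
    ``2 sin(pi * rho_s / 6)`` so the expected Spearman correlation equals the
    planted value; the monotone exp transform to the FPKM scale preserves
    ranks.  Parents are scaled ~20x higher than pseudogenes, mirroring the
    observed abundance gap.  Profiles with planted JS specificity targets are
    appended to the pseudogene matrix as standalone features.
    """
    for r in planted_rho:
        if abs(r) > 1:
            raise ValueError("planted rho must be in [-1, 1]")
    rng_z, rng_noise = _rngs(seed, 2)
    tissues = tissue_names or [f"tissue{i:02d}" for i in range(n_tissues)]
    truth = PlantedTruth()

    pg_rows, parent_rows, pg_ids, parent_ids = [], [], [], []
    for k in range(n_pairs):
        rho_s = planted_rho[k % len(planted_rho)]
        rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
        z1 = rng_z.normal(size=n_tissues)
        eps = rng_z.normal(size=n_tissues)
        z2 = rho_p * z1 + math.sqrt(max(0.0, 1.0 - rho_p**2)) * eps
        if noise_sd > 0:
            z1 = z1 + noise_sd * rng_noise.normal(size=n_tissues)
            z2 = z2 + noise_sd * rng_noise.normal(size=n_tissues)
        pg_id, g_id = f"pg{k:04d}", f"g{k:04d}"
        pg_rows.append(np.exp(z1) * 2.0)
        parent_rows.append(np.exp(z2) * 40.0)
        pg_ids.append(pg_id)
        parent_ids.append(g_id)
        truth.pair_rho[pg_id] = rho_s

    for k, target in enumerate(planted_js):
        prof = _mixture_for_js(target, n_tissues)
        hot = k % n_tissues
        prof = np.roll(prof, hot) * 100.0
        fid = f"jspg{k:04d}"
        pg_rows.append(prof)
        pg_ids.append(fid)
        truth.pair_js[fid] = target

    pg_df = pd.DataFrame(pg_rows, index=pg_ids, columns=tissues)
    parent_df = pd.DataFrame(parent_rows, index=parent_ids, columns=tissues)
    return ExpressionMatrix(pg_df), ExpressionMatrix(parent_df), truth
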