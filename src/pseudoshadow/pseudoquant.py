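"""Read re-attribution at pseudogene loci, FPKM quantification and QC.

The central rule: a read aligned inside a pseudogene is kept as a
"pseudogene read" only if it has strictly fewer mismatches to the
pseudogene locus than to any coding cDNA (no competitor found counts as
infinitely many cDNA mismatches).  Equal-mismatch ties remove the read —
the conservative reading of a strict "fewer" requirement.  All remaining
alignments are quantified with deterministic union-exon counting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    AlignmentRecord,
    AnnotationModel,
    ExpressionMatrix,
    FilterDecision,
)


@dataclass(frozen=True)
class Candidate:
    read_id: str
    pg_id: str
    mm_pg: int


def _validate_single_location(alignments: list[AlignmentRecord]) -> None:
    seen: set[str] = set()
    for a in alignments:
        if a.read_id in seen:
            raise ValueError(
                f"read {a.read_id} has multiple genomic locations; the filter "
                "expects one pre-resolved placement per read"
            )
        seen.add(a.read_id)


def collect_candidate_reads(
    genome_alignments: list[AlignmentRecord],
    annotation: AnnotationModel,
) -> list[Candidate]:
    """Reads whose genomic alignment overlaps a pseudogene block by >= 1 bp.

    A read overlapping several pseudogenes is attributed to the one with the
    greatest block overlap (ties broken by smallest feature id).
    """
    _validate_single_location(genome_alignments)
    pg_ids = {f.feature_id for f in annotation.pseudogenes}
    out = []
    for a in genome_alignments:
        if a.target_id not in annotation.chroms:
            raise KeyError(f"read {a.read_id} on unknown chrom {a.target_id!r}")
        hits: dict[str, int] = {}
        for s, e in a.blocks:
            for fid, ov in annotation.overlapping_blocks(a.target_id, s, e):
                if fid in pg_ids:
                    hits[fid] = hits.get(fid, 0) + ov
        if hits:
            best = max(sorted(hits), key=lambda k: hits[k])
            out.append(Candidate(a.read_id, best, a.mismatches))
    return out


def filter_pseudogene_reads(
    candidates: list[Candidate],
    cdna_alignments: list[AlignmentRecord],
) -> tuple[set[str], set[str], list[FilterDecision]]:
    """Adjudicate each candidate read against its best coding-cDNA hit.

    Returns (kept read ids, removed read ids, decision table).  kept iff
    mm_pg < min cDNA mismatch count (infinity when no cDNA hit exists).
    """
    best_cdna: dict[str, float] = {}
    for a in cdna_alignments:
        cur = best_cdna.get(a.read_id, math.inf)
        if a.mismatches < cur:
            best_cdna[a.read_id] = a.mismatches
    decisions = []
    kept: set[str] = set()
    removed: set[str] = set()
    for c in candidates:
        mm_c = best_cdna.get(c.read_id, math.inf)
        keep = c.mm_pg < mm_c
        decisions.append(FilterDecision(c.read_id, c.pg_id, c.mm_pg, mm_c, keep))
        (kept if keep else removed).add(c.read_id)
    return kept, removed, decisions


def rewrite_alignments(
    genome_alignments: list[AlignmentRecord],
    removed: set[str],
) -> list[AlignmentRecord]:
    """Drop the alignment records of removed reads, preserving order.

    Records of reads not in ``removed`` pass through untouched, so the
    conservation |input| = |output| + |removed records| holds exactly.
    """
    return [a for a in genome_alignments if a.read_id not in removed]


def decisions_table(decisions: list[FilterDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.read_id, d.locus_pg_id, d.mm_pg,
          -1 if math.isinf(d.mm_cdna_best) else int(d.mm_cdna_best), d.kept)
         for d in decisions],
        columns=["read_id", "pg_id", "mm_pg", "mm_cdna_best", "kept"],
    )


# ------------------------------------------------------------------ FPKM


def assign_fragments(
    alignments: list[AlignmentRecord],
    annotation: AnnotationModel,
) -> dict[str, int]:
    """Per-feature fragment counts by greatest exon-union overlap.

    Each fragment is counted once; it goes to the feature whose exon union
    it overlaps the most, ties to the lexicographically smallest feature id.
    """
    counts: dict[str, int] = {f.feature_id: 0 for f in annotation.features}
    for a in alignments:
        hits: dict[str, int] = {}
        for s, e in a.blocks:
            for fid, ov in annotation.overlapping_blocks(a.target_id, s, e):
                hits[fid] = hits.get(fid, 0) + ov
        if hits:
            best = max(sorted(hits), key=lambda k: hits[k])
            counts[best] += 1
    return counts


def compute_fpkm(
    filtered_alignments: list[AlignmentRecord],
    annotation: AnnotationModel,
    tissue: str,
) -> ExpressionMatrix:
    """One FPKM column: count / (exon_kb x mapped fragments / 1e6).

    ``total_mapped`` is the number of mapped fragments remaining after
    filtering (every input record counts, assigned to a feature or not).
    """
    total = len(filtered_alignments)
    counts = assign_fragments(filtered_alignments, annotation)
    fids = [f.feature_id for f in annotation.features]
    if total == 0:
        warnings.warn("no mapped fragments; FPKM column is all zero")
        fpkm = pd.DataFrame({tissue: 0.0}, index=fids)
    else:
        vals = {
            fid: counts[fid] / (annotation.by_id[fid].exon_length / 1000.0)
            / (total / 1e6)
            for fid in fids
        }
        fpkm = pd.DataFrame({tissue: pd.Series(vals)}).loc[fids]
    return ExpressionMatrix(
        fpkm,
        totals=pd.Series({tissue: total}),
        counts=pd.DataFrame({tissue: pd.Series(counts)}).loc[fids],
    )


def combine_tissues(columns: list[ExpressionMatrix]) -> ExpressionMatrix:
    fpkm = pd.concat([c.fpkm for c in columns], axis=1)
    totals = pd.concat([c.totals for c in columns])
    counts = pd.concat([c.counts for c in columns], axis=1)
    return ExpressionMatrix(fpkm, totals=totals, counts=counts)


def call_transcribed(matrix: ExpressionMatrix, threshold: float = 1.0) -> pd.DataFrame:
    """Per-feature transcribed call: max FPKM strictly above the threshold."""
    if matrix.fpkm.shape[1] < 1:
        raise ValueError("need at least one tissue column")
    max_fpkm = matrix.fpkm.max(axis=1)
    return pd.DataFrame(
        {
            "max_fpkm": max_fpkm,
            "transcribed": max_fpkm > threshold,
            "tissue_of_max": matrix.fpkm.idxmax(axis=1),
        }
    )


# ------------------------------------------------------------------ identity-window QC


@dataclass
class IdentityWindowReport:
    """Per-window identity/read-count table with the Pearson diagnostic.

    ``r`` and ``p`` are None (``r_defined`` False) when fewer than 3 usable
    windows exist or the identity values have zero variance.
    """

    pg_id: str
    windows: pd.DataFrame  # window_start, identity_pct, read_count
    r: float | None
    p: float | None
    r_defined: bool


def _window_table(
    pg_aligned: str,
    parent_aligned: str,
    read_starts: np.ndarray,
    window: int,
) -> pd.DataFrame:
    if len(pg_aligned) != len(parent_aligned):
        raise ValueError("aligned sequences must have equal length")
    rows = []
    pg_pos = 0  # pseudogene coordinate of the next non-gap pg column
    starts = np.sort(np.asarray(read_starts))
    for wstart in range(0, len(pg_aligned), window):
        wseq_pg = pg_aligned[wstart:wstart + window]
        wseq_par = parent_aligned[wstart:wstart + window]
        aligned_cols = sum(1 for a, b in zip(wseq_pg, wseq_par)
                           if a != "-" and b != "-")
        matches = sum(1 for a, b in zip(wseq_pg, wseq_par)
                      if a != "-" and b != "-" and a == b)
        pg_bases = sum(1 for a in wseq_pg if a != "-")
        if aligned_cols == 0:
            pg_pos += pg_bases
            continue  # window skipped
        lo, hi = pg_pos, pg_pos + pg_bases
        n_reads = int(np.searchsorted(starts, hi, "left")
                      - np.searchsorted(starts, lo, "left"))
        rows.append([wstart, 100.0 * matches / aligned_cols, n_reads])
        pg_pos += pg_bases
    return pd.DataFrame(rows, columns=["window_start", "identity_pct",
                                       "read_count"])


def identity_read_correlation(
    pg_aligned: str,
    parent_aligned: str,
    read_starts: np.ndarray,
    window: int = 200,
    pg_id: str = "pg",
) -> IdentityWindowReport:
    """Read count vs parent identity in fixed windows across an alignment.

    ``read_starts`` are kept-read 5' positions in pseudogene coordinates.
    Identity = matching columns / aligned (gap-free in both) columns x 100;
    a window with zero aligned columns is skipped.  Pearson r and its
    t-distribution p-value (n-2 df) are computed across windows.
    """
    table = _window_table(pg_aligned, parent_aligned,
                          np.asarray(read_starts), window)
    return _report_from_windows(table, pg_id)


def _report_from_windows(table: pd.DataFrame, pg_id: str) -> IdentityWindowReport:
    usable = len(table)
    if usable < 3 or table["identity_pct"].nunique() < 2 \
            or table["read_count"].nunique() < 2:
        return IdentityWindowReport(pg_id, table, None, None, False)
    r, p = stats.pearsonr(table["identity_pct"], table["read_count"])
    return IdentityWindowReport(pg_id, table, float(r), float(p), True)


def identity_reports_from_alignments(
    genome: dict[str, str],
    annotation: AnnotationModel,
    genome_alignments: list[AlignmentRecord],
    kept: set[str] | None = None,
    window: int = 200,
) -> list[IdentityWindowReport]:
    """Per-pseudogene identity diagnostics straight from alignments.

    Pseudogene-parent alignments are taken positionally (exon-union to
    exon-union), which is exact for substitution-only pseudogene copies.
    Read starts come from candidate reads at each pseudogene, optionally
    restricted to a kept set (post-filter view).
    """
    candidates = collect_candidate_reads(genome_alignments, annotation)
    pos = {a.read_id: a.blocks[0][0] for a in genome_alignments}
    by_pg: dict[str, list[str]] = {}
    for c in candidates:
        by_pg.setdefault(c.pg_id, []).append(c.read_id)

    def tx(fid: str) -> str:
        f = annotation.by_id[fid]
        return "".join(genome[f.chrom][s:e] for s, e in f.blocks)

    reports = []
    for f in annotation.pseudogenes:
        if f.parent_id is None:
            continue
        parent_tx = tx(f.parent_id)
        pg_tx = tx(f.feature_id)
        if len(parent_tx) != len(pg_tx):
            continue  # positional alignment unavailable
        rids = by_pg.get(f.feature_id, [])
        if kept is not None:
            rids = [r for r in rids if r in kept]

        def to_tx(gpos: int) -> int:
            acc = 0
            for s, e in f.blocks:
                if gpos < e:
                    return acc + max(0, gpos - s)
                acc += e - s
            return acc

        starts = np.array([to_tx(pos[r]) for r in rids])
        reports.append(identity_read_correlation(
            pg_tx, parent_tx, starts, window, f.feature_id))
    return reports


def pooled_identity_report(
    reports: list[IdentityWindowReport], pg_id: str = "pooled"
) -> IdentityWindowReport:
    """Pool the window tables of several pseudogenes into one diagnostic.

    This mirrors genome-wide practice: the identity/read-count relationship
    is assessed over all pseudogene-parent alignments at once.
    """
    table = pd.concat([r.windows for r in reports], ignore_index=True)
    return _report_from_windows(table, pg_id)
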