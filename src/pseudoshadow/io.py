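"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, SAM via pysam, BED/TSV via pandas.  Annotation travels
as BED12 with two extra columns (feature class, parent id); tags and small
RNA reads as BED6; expression and report tables as TSV.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignmentRecord, AnnotationModel, Feature, TagSet

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------- FASTA

def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- BED12 annotation

def write_annotation_bed12(annotation: AnnotationModel, path: str | Path) -> None:
    rows = []
    for f in annotation.features:
        sizes = ",".join(str(e - s) for s, e in f.blocks)
        starts = ",".join(str(s - f.start) for s, e in f.blocks)
        rows.append(
            [
                f.chrom, f.start, f.end, f.feature_id, 0, f.strand,
                f.start, f.end, "0,0,0", len(f.blocks), sizes, starts,
                f.feat_class, f.parent_id if f.parent_id is not None else ".",
            ]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed12(path: str | Path) -> AnnotationModel:
    feats = []
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    for row in df.itertuples(index=False):
        chrom, start, end, name = row[0], int(row[1]), int(row[2]), row[3]
        strand = row[5]
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        offs = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        blocks = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
        feat_class = row[12]
        parent = None if row[13] in (".", "", None) else row[13]
        feats.append(
            Feature(name, chrom, start, end, strand, feat_class, blocks, parent)
        )
    return AnnotationModel(feats)


# ---------------------------------------------------------------- SAM

def _cigar_from_blocks(blocks: tuple[tuple[int, int], ...]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def write_sam(
    records: list[AlignmentRecord],
    ref_lengths: dict[str, int],
    path: str | Path,
) -> None:
    header = pysam.AlignmentHeader.from_references(
        list(ref_lengths), [ref_lengths[r] for r in ref_lengths]
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for r in records:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.reference_id = list(ref_lengths).index(r.target_id)
            a.reference_start = r.pos
            a.flag = 16 if r.strand == "-" else 0
            a.mapping_quality = 255
            a.cigarstring = _cigar_from_blocks(r.blocks)
            if r.seq is not None:
                a.query_sequence = r.seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            a.set_tag("NM", r.mismatches)
            fh.write(a)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            blocks = tuple(a.get_blocks())
            out.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    target_id=a.reference_name,
                    pos=a.reference_start,
                    strand="-" if a.is_reverse else "+",
                    mismatches=int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                    blocks=blocks,
                    seq=a.query_sequence,
                )
            )
    return out


# ---------------------------------------------------------------- BED6

def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLS)


def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED6_COLS)


def tagset_from_bed(df: pd.DataFrame, use_factor: bool = False) -> TagSet:
    """Build a TagSet of 5'-end anchors from BED6 rows (strand-aware)."""
    pos = np.where(df["strand"] == "-", df["end"] - 1, df["start"]).astype(np.int64)
    positions: dict[str, np.ndarray] = {}
    factors: dict[str, np.ndarray] = {}
    for chrom, grp in pd.DataFrame({"chrom": df["chrom"], "pos": pos,
                                    "name": df["name"]}).groupby("chrom"):
        order = np.argsort(grp["pos"].to_numpy())
        positions[str(chrom)] = grp["pos"].to_numpy()[order]
        factors[str(chrom)] = grp["name"].to_numpy()[order]
    return TagSet(positions, factors if use_factor else None)


def tagset_to_bed(tags: TagSet) -> pd.DataFrame:
    rows = []
    for chrom in sorted(tags.positions):
        for i, p in enumerate(tags.positions[chrom]):
            name = tags.factors[chrom][i] if tags.factors else f"tag_{chrom}_{i}"
            rows.append([chrom, int(p), int(p) + 1, name, 0, "+"])
    return pd.DataFrame(rows, columns=BED6_COLS)


# ---------------------------------------------------------------- bedGraph

def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph into per-base score arrays (NaN where uncovered)."""
    tracks = {c: np.full(n, np.nan) for c, n in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "score"])
    for row in df.itertuples(index=False):
        tracks[row.chrom][row.start:row.end] = row.score
    return tracks


def write_bedgraph(tracks: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            arr = tracks[chrom]
            start = None
            for i in range(len(arr) + 1):
                cur = arr[i] if i < len(arr) else np.nan
                if start is not None and (i == len(arr) or cur != arr[start]
                                          or math.isnan(cur)):
                    if not math.isnan(arr[start]):
                        fh.write(f"{chrom}\t{start}\t{i}\t{arr[start]:g}\n")
                    start = None
                if start is None and i < len(arr) and not math.isnan(cur):
                    start = i
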