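"""Core data containers shared by all pipeline stages.

Coordinates are 0-based, half-open everywhere in memory; BED is the on-disk
convention, so no conversion happens except at (optional) GTF boundaries.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

# feature classes
GENE = "gene"
PROCESSED_PG = "processed_pg"
DUPLICATED_PG = "duplicated_pg"
UNITARY_PG = "unitary_pg"
LINCRNA = "lincRNA"

PSEUDOGENE_CLASSES = (PROCESSED_PG, DUPLICATED_PG, UNITARY_PG)
PARENTED_CLASSES = (PROCESSED_PG, DUPLICATED_PG)


@dataclass(frozen=True)
class Feature:
    """A gene or pseudogene with exon blocks.

    ``blocks`` are absolute genomic intervals, sorted and non-overlapping,
    contained in ``[start, end)``.  ``parent_id`` is present iff the feature
    is a processed or duplicated pseudogene.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    feat_class: str
    blocks: tuple[tuple[int, int], ...]
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"{self.feature_id}: bad span [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.feature_id}: bad strand {self.strand!r}")
        prev_end = self.start
        for s, e in self.blocks:
            if s < self.start or e > self.end or e <= s:
                raise ValueError(f"{self.feature_id}: block ({s},{e}) outside span")
            if s < prev_end:
                raise ValueError(f"{self.feature_id}: blocks unsorted/overlapping")
            prev_end = e
        has_parent = self.parent_id is not None
        if has_parent != (self.feat_class in PARENTED_CLASSES):
            raise ValueError(
                f"{self.feature_id}: parent_id must be present iff class is "
                f"processed_pg or duplicated_pg (class={self.feat_class})"
            )

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def span_length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def is_pseudogene(self) -> bool:
        return self.feat_class in PSEUDOGENE_CLASSES

    def transcript_to_genome(self, tpos: int) -> int:
        """Map a forward-orientation transcript offset to a genomic position."""
        off = tpos
        for s, e in self.blocks:
            if off < e - s:
                return s + off
            off -= e - s
        raise IndexError(f"transcript offset {tpos} beyond {self.feature_id}")

    def read_blocks(self, tstart: int, length: int) -> tuple[tuple[int, int], ...]:
        """Genomic block spans of a transcript slice ``[tstart, tstart+length)``."""
        out: list[tuple[int, int]] = []
        remaining = length
        off = tstart
        for s, e in self.blocks:
            blen = e - s
            if off >= blen:
                off -= blen
                continue
            take = min(blen - off, remaining)
            out.append((s + off, s + off + take))
            remaining -= take
            off = 0
            if remaining == 0:
                break
        if remaining:
            raise IndexError(f"slice [{tstart},{tstart + length}) beyond {self.feature_id}")
        return tuple(out)


class AnnotationModel:
    """Container for features with per-chromosome block indexes."""

    def __init__(self, features: list[Feature] | tuple[Feature, ...]):
        self.features: tuple[Feature, ...] = tuple(features)
        self.by_id: dict[str, Feature] = {}
        for f in self.features:
            if f.feature_id in self.by_id:
                raise ValueError(f"duplicate feature id {f.feature_id}")
            self.by_id[f.feature_id] = f
        for f in self.features:
            if f.parent_id is not None and f.parent_id not in self.by_id:
                raise ValueError(f"{f.feature_id}: unknown parent {f.parent_id}")
        # per-chrom sorted block index: (start, end, feature_id)
        self._block_index: dict[str, list[tuple[int, int, str]]] = {}
        for f in self.features:
            lst = self._block_index.setdefault(f.chrom, [])
            for s, e in f.blocks:
                lst.append((s, e, f.feature_id))
        for lst in self._block_index.values():
            lst.sort()
        self._starts = {c: [b[0] for b in lst] for c, lst in self._block_index.items()}

    @property
    def chroms(self) -> set[str]:
        return set(self._block_index)

    def of_class(self, *classes: str) -> list[Feature]:
        return [f for f in self.features if f.feat_class in classes]

    @property
    def genes(self) -> list[Feature]:
        return self.of_class(GENE)

    @property
    def pseudogenes(self) -> list[Feature]:
        return self.of_class(*PSEUDOGENE_CLASSES)

    def children_of(self, gene_id: str) -> list[Feature]:
        return [f for f in self.features if f.parent_id == gene_id]

    def overlapping_blocks(
        self, chrom: str, start: int, end: int
    ) -> list[tuple[str, int]]:
        """Feature ids whose blocks overlap ``[start, end)`` with overlap bp.

        Overlap is summed over all of a feature's blocks.
        """
        if chrom not in self._block_index:
            raise KeyError(f"unknown chromosome {chrom!r}")
        lst = self._block_index[chrom]
        hits: dict[str, int] = {}
        # blocks are short; scan a window around the insertion point
        i = bisect_left(self._starts[chrom], end)
        for s, e, fid in lst[:i]:
            ov = min(e, end) - max(s, start)
            if ov > 0:
                hits[fid] = hits.get(fid, 0) + ov
        return sorted(hits.items())


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's placement on a target (chromosome or cDNA).

    ``blocks`` are half-open intervals on the target; a spliced placement has
    more than one block.  ``mismatches`` is the edit count of the placement
    (substitutions only in the synthetic pipeline).
    """

    read_id: str
    target_id: str
    pos: int
    strand: str
    mismatches: int
    blocks: tuple[tuple[int, int], ...]
    seq: str | None = None

    def __post_init__(self) -> None:
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass(frozen=True)
class FilterDecision:
    read_id: str
    locus_pg_id: str
    mm_pg: int
    mm_cdna_best: float  # math.inf when no competitor was found
    kept: bool

    def __post_init__(self) -> None:
        if self.kept != (self.mm_pg < self.mm_cdna_best):
            raise ValueError("kept flag inconsistent with mismatch counts")


@dataclass
class ExpressionMatrix:
    """Feature x tissue FPKM table.

    ``totals`` holds the per-tissue mapped fragment counts used for the
    FPKM denominator; ``counts`` the raw per-feature fragment counts.  Both
    are optional for matrices that were simulated rather than quantified.
    """

    fpkm: "pd.DataFrame"
    totals: "pd.Series | None" = None
    counts: "pd.DataFrame | None" = None

    def __post_init__(self) -> None:
        if (np.asarray(self.fpkm.values, dtype=float) < 0).any():
            raise ValueError("FPKM values must be >= 0")

    @property
    def tissues(self) -> list[str]:
        return list(self.fpkm.columns)


@dataclass
class TagSet:
    """Single-base tag anchors (e.g. ChIP-Seq read 5' ends) per chromosome."""

    positions: dict[str, np.ndarray]  # sorted int arrays
    factors: dict[str, np.ndarray] | None = None  # optional per-tag labels

    def __post_init__(self) -> None:
        for c, p in self.positions.items():
            arr = np.asarray(p, dtype=np.int64)
            if arr.size and (np.diff(arr) < 0).any():
                arr = np.sort(arr)
            self.positions[c] = arr

    def count(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    def in_window(self, chrom: str, start: int, end: int) -> int:
        p = self.positions.get(chrom)
        if p is None:
            return 0
        return int(np.searchsorted(p, end, "left") - np.searchsorted(p, start, "left"))


@dataclass
class HaplotypeSet:
    """Aligned individual sequences over one locus, with frequencies x_i."""

    locus_id: str
    sequences: tuple[str, ...]
    frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("need at least 2 haplotypes")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("sequences must be aligned to equal length")
        if self.frequencies is None:
            n = len(self.sequences)
            self.frequencies = np.full(n, 1.0 / n)
        else:
            self.frequencies = np.asarray(self.frequencies, dtype=float)
            if len(self.frequencies) != len(self.sequences):
                raise ValueError("one frequency per sequence required")
            if not math.isclose(float(self.frequencies.sum()), 1.0, abs_tol=1e-9):
                raise ValueError("frequencies must sum to 1")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass
class PlantedTruth:
    """Ground truth emitted by the synthetic generators.

    Every simulated read, tag or haplotype is traceable here; downstream
    tests compare recovered quantities against these plantings.
    """

    read_origin: dict[str, str] = field(default_factory=dict)
    # read_id -> (feature_id, transcript_start, is_junction, n_errors)
    read_detail: dict[str, tuple[str, int, bool, int]] = field(default_factory=dict)
    pg_identity: dict[str, float] = field(default_factory=dict)
    pg_strand: dict[str, str] = field(default_factory=dict)
    srna_group: dict[str, str] = field(default_factory=dict)
    pair_rho: dict[str, float] = field(default_factory=dict)
    pair_js: dict[str, float] = field(default_factory=dict)
    locus_pi: dict[str, float] = field(default_factory=dict)


# imported late to keep pandas optional at type-checking time
import pandas as pd  # noqa: E402,F401
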