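"""Nucleotide diversity and cross-species conservation over pseudogene loci.

Diversity follows the frequency-weighted average pairwise difference,
``pi = sum_i sum_j x_i x_j pi_ij`` over ordered pairs, where pi_ij is the
per-site Hamming distance between individual sequences i and j (self pairs
contribute zero).  No sample-size correction is applied by default because
the weighted form already carries the frequencies; an optional flag adds
the n/(n-1) factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import HaplotypeSet

MISSING = frozenset("N-?.")


@dataclass(frozen=True)
class DiversityResult:
    locus_id: str
    pi: float
    n: int
    length: int


def nucleotide_diversity(hapset: HaplotypeSet, unbiased: bool = False) -> DiversityResult:
    """Frequency-weighted nucleotide diversity of an aligned haplotype set.

    Sites with a missing call (N, -, ?, .) in either sequence of a pair are
    excluded from both that pair's difference count and its site total; a
    pair with no comparable site is skipped with a warning.
    """
    seqs = [np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            for s in hapset.sequences]
    miss = np.zeros(256, dtype=bool)
    for ch in MISSING:
        miss[ord(ch)] = True
    valid = [~miss[s] for s in seqs]
    x = hapset.frequencies
    n = hapset.n
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            L = int(both.sum())
            if L == 0:
                warnings.warn(f"pair ({i},{j}) has no comparable site; skipped")
                continue
            d = int((seqs[i][both] != seqs[j][both]).sum())
            total += 2.0 * x[i] * x[j] * d / L  # ordered pairs, both directions
    if unbiased and n > 1:
        total *= n / (n - 1)
    return DiversityResult(hapset.locus_id, total, n, hapset.length)


def exclude_zero_diversity(
    pop_a: list[DiversityResult],
    pop_b: list[DiversityResult],
) -> list[str]:
    """Locus ids with non-zero diversity in both populations.

    Loci at pi = 0 in either population are dropped before comparing
    transcribed vs non-transcribed groups, so recently fixed (very young)
    pseudogenes do not masquerade as constrained ones.
    """
    a = {r.locus_id: r.pi for r in pop_a}
    b = {r.locus_id: r.pi for r in pop_b}
    return sorted(k for k in a.keys() & b.keys() if a[k] > 0 and b[k] > 0)


@dataclass
class ConservationTrack:
    """Per-base conservation probabilities with a missing-data mask."""

    chrom: str
    scores: np.ndarray
    mask: np.ndarray | None = None  # True where data is missing

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.mask is None:
            self.mask = np.isnan(self.scores)
        else:
            self.mask = np.asarray(self.mask, dtype=bool) | np.isnan(self.scores)
        present = self.scores[~self.mask]
        if present.size and ((present < 0) | (present > 1)).any():
            raise ValueError("conservation scores must lie in [0, 1]")


def mean_conservation(
    track: ConservationTrack,
    blocks: list[tuple[int, int]],
) -> tuple[float, int]:
    """Mean score over the non-missing bases of a block union.

    Redundantly passed or overlapping blocks count each base once.
    Returns (mean, n_bases); the mean is NaN with a warning when no
    non-missing base falls in the union.
    """
    union = np.zeros(len(track.scores), dtype=bool)
    for s, e in blocks:
        if s < 0 or e > len(track.scores):
            raise ValueError(f"block ({s},{e}) outside track")
        union[s:e] = True
    usable = union & ~track.mask
    n = int(usable.sum())
    if n == 0:
        warnings.warn("no non-missing base in block union; mean undefined")
        return float("nan"), 0
    return float(track.scores[usable].mean()), n


def haplotypes_from_variant_table(
    locus_id: str,
    locus_len: int,
    positions: list[int],
    ref_alleles: list[str],
    alt_alleles: list[str],
    genotypes: np.ndarray,
) -> HaplotypeSet:
    """Expand a biallelic variant table into two haplotypes per individual.

    ``genotypes`` is (n_sites, n_individuals) with values 0, 1, 2 (alt
    allele dosage) or -1 for missing.  Heterozygotes put the alt allele on
    the second haplotype; missing calls become N on both.  Monomorphic
    reference background is written as 'A'.
    """
    genotypes = np.asarray(genotypes)
    n_ind = genotypes.shape[1]
    haps = np.full((2 * n_ind, locus_len), ord("A"), dtype=np.uint8)
    for k, pos in enumerate(positions):
        ref, alt = ord(ref_alleles[k]), ord(alt_alleles[k])
        haps[:, pos] = ref
        for i in range(n_ind):
            g = genotypes[k, i]
            if g == -1:
                haps[2 * i, pos] = haps[2 * i + 1, pos] = ord("N")
            elif g == 1:
                haps[2 * i + 1, pos] = alt
            elif g == 2:
                haps[2 * i, pos] = haps[2 * i + 1, pos] = alt
    seqs = tuple(r.tobytes().decode("ascii") for r in haps)
    return HaplotypeSet(locus_id, seqs)
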