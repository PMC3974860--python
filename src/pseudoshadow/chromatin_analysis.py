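"""ChIP tag densities, anchored meta-profiles and overlap enrichment.

Tags are single-base anchors (the 5' end of each read; no fragment-shift
extension is applied).  Profiles are averaged over anchors with
minus-strand anchors mirrored so that upstream/downstream keeps its
biological meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import Feature, TagSet


def window_tag_count(
    tags: TagSet,
    intervals: list[tuple[str, int, int, str]],
    normalize_per: int = 500,
) -> pd.DataFrame:
    """Tag counts and per-``normalize_per``-bp densities for intervals.

    ``intervals`` rows are (chrom, start, end, name).  A tag counts when its
    position lies in [start, end).
    """
    rows = []
    for chrom, start, end, name in intervals:
        if end <= start:
            raise ValueError(f"zero-length interval {name}")
        n = tags.in_window(chrom, start, end)
        rows.append([name, chrom, start, end, n,
                     n * normalize_per / (end - start)])
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end",
                                       "count", "density"]).set_index("name")


@dataclass
class ProfileResult:
    """Average tag count per bin per anchor over [-flank, +flank)."""

    bin_width: int
    flank: int
    n_anchors: int
    bin_starts: np.ndarray  # signed offsets of bin left edges
    values: np.ndarray  # tags per bin per anchor


def anchored_profile(
    tags: TagSet,
    anchors: list[tuple[str, int, str]],
    flank: int = 2500,
    bin_width: int = 100,
) -> ProfileResult:
    """Meta-profile of tag counts around (position, strand) anchors.

    The signed offset of a tag is (tag - anchor) for plus-strand anchors and
    (anchor - tag) for minus-strand ones; offsets in [-flank, flank) are
    accumulated into ``flank*2/bin_width`` bins and divided by the anchor
    count.
    """
    if not anchors:
        raise ValueError("need at least one anchor")
    if (2 * flank) % bin_width:
        raise ValueError("2*flank must be a multiple of bin_width")
    nbins = 2 * flank // bin_width
    acc = np.zeros(nbins)
    for chrom, pos, strand in anchors:
        p = tags.positions.get(chrom)
        if p is None or p.size == 0:
            continue
        lo = np.searchsorted(p, pos - flank, "left")
        hi = np.searchsorted(p, pos + flank + 1, "left")
        off = p[lo:hi] - pos
        if strand == "-":
            off = -off
        off = off[(off >= -flank) & (off < flank)]
        idx = (off + flank) // bin_width
        np.add.at(acc, idx, 1)
    starts = np.arange(-flank, flank, bin_width)
    return ProfileResult(bin_width, flank, len(anchors), starts,
                         acc / len(anchors))


def promoter_interval(f: Feature, upstream: int = 2000) -> tuple[str, int, int]:
    """The [TSS - upstream, TSS) window, strand-aware."""
    if f.strand == "+":
        return f.chrom, max(0, f.start - upstream), f.start
    return f.chrom, f.end, f.end + upstream


def promoter_distinct_factor_count(
    peaks: pd.DataFrame,
    features: list[Feature],
    upstream: int = 2000,
) -> pd.Series:
    """Distinct TF labels with >= 1 bp peak overlap of each promoter.

    ``peaks`` needs columns chrom, start, end, factor.  Multiple peaks of
    the same factor count once.
    """
    out = {}
    for f in features:
        chrom, pstart, pend = promoter_interval(f, upstream)
        sel = peaks[(peaks["chrom"] == chrom)
                    & (peaks["start"] < pend)
                    & (peaks["end"] > pstart)]
        out[f.feature_id] = int(sel["factor"].nunique())
    return pd.Series(out)


def genome_covered_fraction(
    targets: list[tuple[str, int, int]],
    chrom_sizes: dict[str, int],
    extend: int = 0,
) -> float:
    """Fraction of the genome covered by targets extended by ``extend`` bp."""
    total = sum(chrom_sizes.values())
    covered = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in targets:
        by_chrom.setdefault(chrom, []).append(
            (max(0, s - extend), min(chrom_sizes[chrom], e + extend)))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    return covered / total


def interval_overlap_binomial(
    query_features: list[Feature],
    target_intervals: list[tuple[str, int, int]],
    flank: int = 0,
    background_prob: float | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[int, float]:
    """Count features overlapping any target and test against a binomial null.

    Success for a feature means its span extended by ``flank`` intersects at
    least one target interval.  p = P(X >= k) with X ~ Binomial(n, p0);
    when ``background_prob`` is not given it defaults to the genome fraction
    covered by the targets extended by the mean feature span.
    """
    n = len(query_features)
    if n == 0:
        raise ValueError("no query features")
    if background_prob is None:
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required to derive background_prob")
        mean_len = int(np.mean([f.span_length for f in query_features]))
        background_prob = genome_covered_fraction(
            target_intervals, chrom_sizes, extend=mean_len // 2 + flank)
    if not 0 <= background_prob <= 1:
        raise ValueError("background_prob must be in [0, 1]")
    k = 0
    for f in query_features:
        lo, hi = f.start - flank, f.end + flank
        hit = any(c == f.chrom and s < hi and e > lo
                  for c, s, e in target_intervals)
        k += hit
    if k == 0:
        return 0, 1.0
    return k, float(stats.binom.sf(k - 1, n, background_prob))
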