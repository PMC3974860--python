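"""Small-RNA densities over features, enrichment testing and grouping.

A pseudogene producing >= 5 sRNA reads/kb over its exon union is a
candidate sRNA producer; candidates split into group I (zero flank reads,
interpreted as parent-interactive biogenesis through dsRNA) and group II
(flank density > 5/kb, parent-independent, heterochromatin-like) on the
+/-1 kb flank density.  Everything in between stays unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import AnnotationModel, TagSet


@dataclass(frozen=True)
class SrnaDensityRecord:
    feature_id: str
    exonic_reads: int
    exonic_kb: float
    exonic_density: float
    flank_reads: int
    flank_kb: float
    flank_density: float


def srna_density(
    reads: TagSet,
    annotation: AnnotationModel,
    flank: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
    features: list[str] | None = None,
) -> list[SrnaDensityRecord]:
    """Reads/kb over each feature's exon union and its +/-1 kb flanks.

    A read counts toward a region when its 5' end lies inside it.  Flanks
    are clipped at chromosome edges and the realized flank length is the
    density denominator.
    """
    out = []
    feats = (annotation.features if features is None
             else [annotation.by_id[f] for f in features])
    for f in feats:
        ex_reads = sum(reads.in_window(f.chrom, s, e) for s, e in f.blocks)
        ex_kb = f.exon_length / 1000.0
        size = chrom_sizes.get(f.chrom) if chrom_sizes else None
        lo = max(0, f.start - flank)
        hi = f.end + flank if size is None else min(size, f.end + flank)
        fl_reads = (reads.in_window(f.chrom, lo, f.start)
                    + reads.in_window(f.chrom, f.end, hi))
        fl_len = (f.start - lo) + (hi - f.end)
        fl_kb = fl_len / 1000.0
        out.append(SrnaDensityRecord(
            f.feature_id, ex_reads, ex_kb, ex_reads / ex_kb,
            fl_reads, fl_kb, fl_reads / fl_kb if fl_kb > 0 else 0.0,
        ))
    return out


def poisson_enrichment(count: int, region_kb: float, background_rate: float) -> float:
    """Upper-tail Poisson p-value P(X >= count) at rate*kb expectation.

    Survival-function evaluation keeps the summation stable in log space.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    lam = background_rate * region_kb
    if count == 0:
        return 1.0
    return float(stats.poisson.sf(count - 1, lam))


@dataclass(frozen=True)
class SrnaGroupCall:
    feature_id: str
    call: str  # not_candidate | group_I | group_II | candidate_unassigned
    poisson_p: float | None


def classify_srna_groups(
    records: list[SrnaDensityRecord],
    exonic_min: float = 5.0,
    flank_hi: float = 5.0,
    background_rate: float = 0.0,
) -> list[SrnaGroupCall]:
    """Call group I / group II sRNA-producing pseudogenes.

    Exonic density below ``exonic_min`` -> not a candidate.  Candidates with
    exactly zero flank reads are group I; flank density above ``flank_hi``
    is group II; the rest stay unassigned.  Candidates get an upper-tail
    Poisson p-value for their exonic count against ``background_rate``
    (reads/kb, typically the genome-wide rate of the same library).
    """
    out = []
    for r in records:
        if r.exonic_density < exonic_min:
            out.append(SrnaGroupCall(r.feature_id, "not_candidate", None))
            continue
        p = poisson_enrichment(r.exonic_reads, r.exonic_kb, background_rate)
        if r.flank_reads == 0:
            call = "group_I"
        elif r.flank_density > flank_hi:
            call = "group_II"
        else:
            call = "candidate_unassigned"
        out.append(SrnaGroupCall(r.feature_id, call, p))
    return out


def _low_median(values: np.ndarray) -> float:
    """Median taking the lower of the two middle values for even n."""
    v = np.sort(np.asarray(values))
    return float(v[(len(v) - 1) // 2])


@dataclass(frozen=True)
class SizeComparison:
    median_i: float
    median_ii: float
    delta_median: float
    ks_stat: float
    p: float
    reliable: bool


def srna_size_comparison(lengths_i: np.ndarray, lengths_ii: np.ndarray) -> SizeComparison:
    """Compare read-length distributions of group I vs group II sRNAs.

    Reports low-medians, their difference (II - I) and a two-sample KS test
    with asymptotic p; fewer than 5 reads on either side flags the p-value
    as unreliable.
    """
    li, lii = np.asarray(lengths_i), np.asarray(lengths_ii)
    if len(li) == 0 or len(lii) == 0:
        raise ValueError("both length sets must be non-empty")
    mi, mii = _low_median(li), _low_median(lii)
    ks = stats.ks_2samp(li, lii, method="asymp")
    return SizeComparison(mi, mii, mii - mi, float(ks.statistic),
                          float(ks.pvalue), len(li) >= 5 and len(lii) >= 5)


def condition_reduction_fraction(
    counts_control: dict[str, int],
    counts_kd: dict[str, int],
    min_reads: int = 1,
) -> tuple[float, pd.DataFrame]:
    """Fraction of sRNA-bearing pseudogenes with fewer reads after treatment.

    The universe is pseudogenes with >= ``min_reads`` control reads; a
    pseudogene is reduced iff its treated count is strictly below control
    (ties count as not reduced).
    """
    universe = sorted(k for k, v in counts_control.items() if v >= min_reads)
    if not universe:
        raise ValueError("no pseudogene meets the control read minimum")
    rows = []
    reduced = 0
    for k in universe:
        kd = counts_kd.get(k, 0)
        is_red = kd < counts_control[k]
        reduced += is_red
        rows.append([k, counts_control[k], kd, is_red])
    table = pd.DataFrame(rows, columns=["pg_id", "control", "kd", "reduced"])
    return reduced / len(universe), table
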