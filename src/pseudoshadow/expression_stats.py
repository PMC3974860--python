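"""Tissue specificity, pseudogene-parent correlation and strand inference.

The tissue-specificity score of a profile p over T tissues is
``max_t [1 - sqrt(JS(p, e_t))]`` with the Jensen-Shannon divergence in
base-2 logs and the convention 0*log0 = 0; e_t is the one-hot profile of
tissue t.  The score is 1 for a perfectly tissue-specific profile and falls
toward ~0.09 (T=16) for a uniform one.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix, Feature


@dataclass(frozen=True)
class SpecificityResult:
    feature_id: str
    score: float
    argmax_tissue: str


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def js_specificity(profile: np.ndarray, tissues: list[str] | None = None,
                   feature_id: str = "feature") -> SpecificityResult:
    """JS tissue-specificity score of one expression profile.

    The profile is normalized to sum 1 (scores are scale invariant).  An
    all-zero profile has no defined specificity and raises instead of
    silently scoring 0.
    """
    v = np.asarray(profile, dtype=float)
    if (v < 0).any():
        raise ValueError("expression values must be >= 0")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero profile has no defined JS score")
    p = v / total
    n = len(p)
    hp = _entropy_bits(p)
    best, best_t = -1.0, 0
    for t in range(n):
        m = p / 2.0
        m[t] += 0.5
        jsd = _entropy_bits(m) - 0.5 * hp  # H(e_t) = 0
        m[t] -= 0.5
        score = 1.0 - math.sqrt(max(jsd, 0.0))
        if score > best:
            best, best_t = score, t
    names = tissues or [str(i) for i in range(n)]
    return SpecificityResult(feature_id, best, names[best_t])


def js_specificity_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Scores for every feature; all-zero profiles are excluded with a flag."""
    rows = []
    for fid, row in matrix.fpkm.iterrows():
        v = row.to_numpy(dtype=float)
        if v.sum() == 0:
            rows.append([fid, np.nan, "", False])
            continue
        res = js_specificity(v, matrix.tissues, str(fid))
        rows.append([fid, res.score, res.argmax_tissue, True])
    return pd.DataFrame(rows, columns=["feature_id", "js_score",
                                       "argmax_tissue", "defined"]
                        ).set_index("feature_id")


def expression_matched_control(
    pg_max_fpkm: pd.Series,
    pool_max_fpkm: pd.Series,
    seed: int = 0,
    bin_width: float = 0.5,
) -> pd.Series:
    """Sample one coding gene per pseudogene from the same log2-FPKM bin.

    Sampling is uniform without replacement within a bin; an exhausted or
    empty bin falls back to the nearest non-empty one with a warning.
    Returns a Series mapping pseudogene id -> matched gene id.
    """
    rng = np.random.default_rng(seed)
    pool_bins = np.floor(np.log2(pool_max_fpkm.clip(lower=1e-12)) / bin_width)
    available: dict[float, list[str]] = {}
    for gid, b in pool_bins.items():
        available.setdefault(float(b), []).append(gid)
    for b in available:
        available[b] = list(rng.permutation(available[b]))

    matched = {}
    for pgid, fpkm in pg_max_fpkm.items():
        b = float(np.floor(np.log2(max(fpkm, 1e-12)) / bin_width))
        if not available.get(b):
            nonempty = [k for k, v in available.items() if v]
            if not nonempty:
                raise ValueError("coding-gene pool exhausted")
            nearest = min(nonempty, key=lambda k: (abs(k - b), k))
            warnings.warn(
                f"log2-FPKM bin {b} empty for {pgid}; using bin {nearest}")
            b = nearest
        matched[pgid] = available[b].pop()
    return pd.Series(matched)


# ------------------------------------------------------------------ correlation


@dataclass(frozen=True)
class CorrelationRecord:
    pg_id: str
    parent_id: str
    rho: float
    p: float
    distance_group: str | None = None
    strand_call: str | None = None


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p-value for |rho| >= |observed| (n <= 8)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def pg_parent_spearman(
    pg_matrix: ExpressionMatrix,
    parent_matrix: ExpressionMatrix,
    pairs: list[tuple[str, str]],
) -> list[CorrelationRecord]:
    """Spearman rho of the per-tissue FPKM profiles for each pair.

    Parents with all-zero profiles are excluded.  Ties use average ranks.
    The p-value is an exact permutation tail for <= 8 shared tissues and the
    t-approximation otherwise.
    """
    shared = [t for t in pg_matrix.tissues if t in parent_matrix.tissues]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared tissue columns")
    out = []
    for pg_id, parent_id in pairs:
        x = pg_matrix.fpkm.loc[pg_id, shared].to_numpy(dtype=float)
        y = parent_matrix.fpkm.loc[parent_id, shared].to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        rho, p_t = stats.spearmanr(x, y)
        if len(shared) <= 8:
            p = _spearman_exact_p(x, y, rho)
        else:
            p = float(p_t)
        out.append(CorrelationRecord(pg_id, parent_id, float(rho), p))
    return out


def distance_groups(
    pg_features: list[Feature],
    gene_features: list[Feature],
    cutoff: int = 20_000,
) -> dict[str, str]:
    """Label each pseudogene t1 (within ``cutoff`` of a coding gene) or t2.

    Distance is the minimum span gap to the nearest coding gene, 0 when
    overlapping; a distance exactly equal to the cutoff is t1.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in gene_features:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    labels = {}
    for pg in pg_features:
        best = math.inf
        for s, e in by_chrom.get(pg.chrom, []):
            if e > pg.start and s < pg.end:
                gap = 0
            elif s >= pg.end:
                gap = s - pg.end
            else:
                gap = pg.start - e
            best = min(best, gap)
        labels[pg.feature_id] = "t1" if best <= cutoff else "t2"
    return labels


@dataclass(frozen=True)
class SplitResult:
    pg_id: str
    mu_h: float
    mu_l: float
    s_h: float
    s_l: float

    @property
    def delta_mu(self) -> float:
        return self.mu_h - self.mu_l

    @property
    def delta_s(self) -> float:
        return self.s_h - self.s_l


def tissue_split_mean_variance(
    pg_profile: np.ndarray,
    parent_profile: np.ndarray,
    tissues: list[str] | None = None,
    pg_id: str = "pg",
) -> SplitResult:
    """Split tissues into halves by pseudogene level; summarize the parent.

    Tissues are sorted by pseudogene FPKM descending, ties broken by the
    fixed tissue-name order; the parent's mean and unbiased (n-1) variance
    are computed in the high and low halves.
    """
    x = np.asarray(pg_profile, dtype=float)
    y = np.asarray(parent_profile, dtype=float)
    n = len(x)
    if n % 2 or len(y) != n:
        raise ValueError("need an even tissue count shared by both profiles")
    names = tissues or [f"{i:04d}" for i in range(n)]
    order = sorted(range(n), key=lambda i: (-x[i], names[i]))
    half = n // 2
    hi, lo = order[:half], order[half:]
    return SplitResult(
        pg_id,
        float(y[hi].mean()), float(y[lo].mean()),
        float(y[hi].var(ddof=1)), float(y[lo].var(ddof=1)),
    )


def infer_strand(
    sense_value: float,
    antisense_value: float,
    min_expr: float = 0.0,
    ratio: float = 10.0,
) -> str:
    """Call the transcribed strand from strand-specific expression values.

    The dominant strand must be >= ``ratio`` times the other; a zero lesser
    strand counts as dominated.  Both values at or below ``min_expr`` give
    no call.
    """
    if sense_value < 0 or antisense_value < 0:
        raise ValueError("expression values must be >= 0")
    if sense_value <= min_expr and antisense_value <= min_expr:
        return "no_call"
    hi, lo = max(sense_value, antisense_value), min(sense_value, antisense_value)
    dominant = "sense" if sense_value >= antisense_value else "antisense"
    if lo == 0 or hi / lo >= ratio:
        return dominant
    return "both"


@dataclass
class MirnaBinnedResult:
    bins: pd.DataFrame  # bin_lo, bin_hi, n, mean_rho_pg_g, sd_rho_pg_g
    r: float
    p: float


def mirna_binned_correlation(
    triples: pd.DataFrame,
    bin_width: float = 0.1,
) -> MirnaBinnedResult:
    """Bin (rho_pg:g, rho_miRNA:g) pairs on the miRNA axis.

    ``triples`` needs columns ``rho_pg_g`` and ``rho_mirna_g``.  Bins are
    half-open [lo, hi) covering [-1, 1] with the last bin closed; per-bin
    mean and n-1 sd of rho_pg:g are reported along with the overall Pearson
    correlation over the raw pairs.
    """
    if len(triples) == 0:
        raise ValueError("empty input")
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    rows = []
    x = triples["rho_mirna_g"].to_numpy(dtype=float)
    y = triples["rho_pg_g"].to_numpy(dtype=float)
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        last = i == len(edges) - 2
        sel = (x >= lo) & ((x <= hi) if last else (x < hi))
        vals = y[sel]
        rows.append([lo, hi, len(vals),
                     float(vals.mean()) if len(vals) else np.nan,
                     float(vals.std(ddof=1)) if len(vals) > 1 else np.nan])
    bins = pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n",
                                       "mean_rho_pg_g", "sd_rho_pg_g"])
    if len(triples) > 2 and np.std(x) > 0 and np.std(y) > 0:
        r, p = stats.pearsonr(x, y)
    else:
        r, p = np.nan, np.nan
    return MirnaBinnedResult(bins, float(r), float(p))


def kd_upregulation_comparison(
    fold_changes: dict[str, float],
    classes: dict[str, str],
    threshold: float = 1.3,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Compare knockdown fold-change distributions across gene classes.

    Genes with fold change <= ``threshold`` are excluded; remaining classes
    are compared pairwise with the two-sided Wilcoxon rank-sum test.  An
    empty class yields undefined (NaN) p-values for its comparisons.
    """
    for g, f in fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold change for {g} must be > 0")
    dists: dict[str, list[float]] = {}
    for g, f in fold_changes.items():
        if f > threshold:
            dists.setdefault(classes[g], []).append(f)
    arrays = {k: np.asarray(sorted(v)) for k, v in dists.items()}
    names = sorted(set(classes.values()))
    rows = []
    for a, b in itertools.combinations(names, 2):
        xa, xb = arrays.get(a, np.array([])), arrays.get(b, np.array([]))
        if len(xa) == 0 or len(xb) == 0:
            rows.append([a, b, np.nan])
        else:
            rows.append([a, b, float(stats.ranksums(xa, xb).pvalue)])
    table = pd.DataFrame(rows, columns=["class_a", "class_b", "p"])
    return arrays, table
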