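"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's code paths: mismatch counting
uses big-int XOR over byte strings instead of numpy sliding windows, and
diversity uses a plain double loop over ordered pairs.
"""

from __future__ import annotations

import numpy as np
import pytest

from pseudoshadow import pseudoquant as pq
from pseudoshadow import synthetic_data as sd

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def brute_force_best_cdna_mm(read: str, cdnas: dict[str, str]) -> int:
    """Minimum Hamming distance of a read over every cDNA offset and strand.

    Pure-Python enumeration: per offset, XOR the byte strings as big
    integers and count the non-zero bytes.
    """
    L = len(read)
    best = L + 1
    for seq in cdnas.values():
        sb = seq.encode()
        for q in (read, revcomp(read)):
            qi = int.from_bytes(q.encode(), "big")
            for off in range(len(sb) - L + 1):
                x = qi ^ int.from_bytes(sb[off:off + L], "big")
                mm = L - x.to_bytes(L, "big").count(0)
                if mm < best:
                    best = mm
    return best


def brute_force_pi(sequences, frequencies=None):
    """Exhaustive ordered-pair nucleotide diversity with missing-site masking."""
    n = len(sequences)
    x = frequencies if frequencies is not None else [1.0 / n] * n
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = L = 0
            for a, b in zip(sequences[i], sequences[j]):
                if a in "N-?." or b in "N-?.":
                    continue
                L += 1
                d += a != b
            if L:
                total += x[i] * x[j] * d / L
    return total


def informative_sites_in_span(pg_tx: str, parent_tx: str, start: int,
                              length: int) -> int:
    return sum(1 for a, b in zip(pg_tx[start:start + length],
                                 parent_tx[start:start + length]) if a != b)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def toy():
    """Default toy genome: 2 genes, processed/duplicated/unitary copies."""
    spec = sd.ToyGenomeSpec(seed=1)
    genome, annotation, truth = sd.build_toy_genome(spec)
    return spec, genome, annotation, truth


@pytest.fixture(scope="session")
def rnaseq(toy):
    """Error-free reads at identity 0.90 with planted junction reads."""
    spec, genome, annotation, truth = toy
    expression = {f.feature_id: 300 for f in annotation.features
                  if f.feat_class != "unitary_pg"}
    reads, grecs, crecs, read_truth = sd.simulate_rnaseq_reads(
        genome, annotation, expression, read_len=50, junction_fraction=0.2,
        error_rate=0.0, seed=2)
    return genome, annotation, dict(reads), grecs, crecs, read_truth


@pytest.fixture(scope="session")
def oracle_genome():
    """Small genome sized so the pure-Python filter oracle stays fast."""
    spec = sd.ToyGenomeSpec(
        n_genes=2, exons_per_gene=3, exon_len=100, intron_len=50,
        n_processed=2, n_duplicated=1, n_unitary=1,
        identity_targets=(0.90, 0.95, 0.85), chrom_len=10_000,
        intergenic_gap=700, seed=7)
    genome, annotation, truth = sd.build_toy_genome(spec)
    expression = {"gene0": 700, "gene1": 700, "ppg0": 150, "ppg1": 150,
                  "dpg0": 150, "upg0": 150}
    reads, grecs, crecs, read_truth = sd.simulate_rnaseq_reads(
        genome, annotation, expression, read_len=50, junction_fraction=0.15,
        error_rate=0.0, seed=8)
    assert len(reads) == 2000
    return genome, annotation, dict(reads), grecs, crecs, read_truth


@pytest.fixture(scope="session")
def leakage():
    """Realistic contamination fixture plus its filter outcome."""
    genome, annotation, truth, reads, grecs, crecs, read_truth = \
        sd.leakage_fixture(seed=0)
    candidates = pq.collect_candidate_reads(grecs, annotation)
    kept, removed, decisions = pq.filter_pseudogene_reads(candidates, crecs)
    return genome, annotation, grecs, crecs, kept, removed, decisions


def transcript_of(genome, feature) -> str:
    return "".join(genome[feature.chrom][s:e] for s, e in feature.blocks)
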