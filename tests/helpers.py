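"""Shared test helpers: record factories and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: the chain
mapper walks blocks base by base, and the alignment oracle enumerates every
global alignment recursively.
"""

from __future__ import annotations

import numpy as np

from trhkit.chain_lift import ChainAlignment
from trhkit.homology import AlignmentScoring
from trhkit.tr_catalog import TRRecord


def make_tr(
    chrom: str = "chr1",
    start: int = 0,
    end: int = 12,
    motif: str = "ACGT",
    copy_number: float = 3.0,
    score: int = 24,
    sequence: str | None = None,
) -> TRRecord:
    return TRRecord(
        chrom=chrom,
        start=start,
        end=end,
        period_size=len(motif),
        copy_number=copy_number,
        consensus_size=len(motif),
        percent_matches=100.0,
        percent_indels=0.0,
        alignment_score=score,
        motif=motif,
        sequence=sequence,
    )


# ---------------------------------------------------------------------------
# Liftover oracle
# ---------------------------------------------------------------------------


def brute_force_lift(chain: ChainAlignment, start: int, end: int):
    """Per-base mapper: returns ((q_start, q_end) plus-strand or None, n_mapped)."""
    target_to_query: dict[int, int] = {}
    t, q = chain.t_start, chain.q_start
    for size, dt, dq in chain.blocks:
        for k in range(size):
            target_to_query[t + k] = q + k
        t += size + dt
        q += size + dq
    hits = [target_to_query[p] for p in range(start, end) if p in target_to_query]
    if not hits:
        return None, 0
    lo, hi = min(hits), max(hits) + 1
    if chain.q_strand == "-":
        lo, hi = chain.q_size - hi, chain.q_size - lo
    return (lo, hi), len(hits)


def random_chain(
    rng: np.random.Generator,
    t_name: str = "chrA",
    q_name: str = "chrB",
    max_blocks: int = 6,
    chain_id: int = 1,
    strand: str | None = None,
) -> ChainAlignment:
    n_blocks = int(rng.integers(1, max_blocks + 1))
    blocks = []
    for i in range(n_blocks):
        size = int(rng.integers(1, 31))
        if i == n_blocks - 1:
            blocks.append((size, 0, 0))
        else:
            blocks.append((size, int(rng.integers(0, 16)), int(rng.integers(0, 16))))
    t_span = sum(s + dt for s, dt, _ in blocks)
    q_span = sum(s + dq for s, _, dq in blocks)
    t_start = int(rng.integers(0, 20))
    q_start = int(rng.integers(0, 20))
    if strand is None:
        strand = "+" if rng.integers(0, 2) else "-"
    chain = ChainAlignment(
        score=int(rng.integers(1, 10_000)),
        t_name=t_name,
        t_size=t_start + t_span + int(rng.integers(0, 20)),
        t_strand="+",
        t_start=t_start,
        t_end=t_start + t_span,
        q_name=q_name,
        q_size=q_start + q_span + int(rng.integers(0, 20)),
        q_strand=strand,
        q_start=q_start,
        q_end=q_start + q_span,
        chain_id=chain_id,
        blocks=tuple(blocks),
    )
    chain.validate()
    return chain


def invert_plus_chain(chain: ChainAlignment) -> ChainAlignment:
    """Exact inverse of a plus-strand chain (target and query swapped)."""
    assert chain.q_strand == "+"
    inverse = ChainAlignment(
        score=chain.score,
        t_name=chain.q_name,
        t_size=chain.q_size,
        t_strand="+",
        t_start=chain.q_start,
        t_end=chain.q_end,
        q_name=chain.t_name,
        q_size=chain.t_size,
        q_strand="+",
        q_start=chain.t_start,
        q_end=chain.t_end,
        chain_id=chain.chain_id,
        blocks=tuple((s, dq, dt) for s, dt, dq in chain.blocks),
    )
    inverse.validate()
    return inverse


# ---------------------------------------------------------------------------
# Global alignment oracle: explicit enumeration of all alignments
# ---------------------------------------------------------------------------


def enumerate_alignment_score(a: str, b: str, scoring: AlignmentScoring) -> int:
    """Best score over every global alignment, by exhaustive path recursion."""

    def rec(i: int, j: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = None
        if i < len(a) and j < len(b):
            step = scoring.match if a[i] == b[j] else scoring.mismatch
            best = step + rec(i + 1, j + 1)
        if i < len(a):
            candidate = scoring.gap + rec(i + 1, j)
            best = candidate if best is None else max(best, candidate)
        if j < len(b):
            candidate = scoring.gap + rec(i, j + 1)
            best = candidate if best is None else max(best, candidate)
        return best

    return rec(0, 0)
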