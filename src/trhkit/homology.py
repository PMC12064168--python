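"""Putatively homologous TR pair identification.

Pipeline: lift catalog A onto assembly B, intersect the lifted intervals with
catalog B at an overlap threshold, gate candidate pairs by global motif
alignment similarity, repeat in the opposite direction, and keep pairs
supported by both directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence, TextIO

import pandas as pd

from .chain_lift import ChainSet, LiftedInterval, lift_catalog
from .errors import ConfigurationError, ParameterError
from .tr_catalog import TRRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True, slots=True)
class AlignmentScoring:
    """Global alignment scores: match reward, mismatch and linear gap penalties."""

    match: int = 1
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ParameterError("match score must exceed mismatch score")
        if self.gap >= 0:
            raise ParameterError("gap penalty must be negative")


@dataclass(frozen=True, slots=True)
class HomologPair:
    """A reciprocally supported homologous TR pair."""

    record_a: TRRecord
    record_b: TRRecord
    overlap_fraction_ab: float
    overlap_fraction_ba: float
    motif_similarity: float


def needleman_wunsch(
    a: str, b: str, scoring: AlignmentScoring | None = None
) -> tuple[int, str, str]:
    """Optimal global alignment of two motifs under linear gap costs.

    Returns ``(score, aligned_a, aligned_b)``.  The traceback breaks ties
    deterministically, preferring diagonal, then a gap in ``b`` (consume
    ``a``), then a gap in ``a``.
    """
    if not a or not b:
        raise ParameterError("motifs must be non-empty")
    scoring = scoring or AlignmentScoring()
    a, b = a.upper(), b.upper()
    m, n = len(a), len(b)
    # DP over python lists: motifs are short (period size <= 2000).
    prev = [j * scoring.gap for j in range(n + 1)]
    ptr = [[0] * (n + 1) for _ in range(m + 1)]  # 1=diag, 2=up, 3=left
    for j in range(1, n + 1):
        ptr[0][j] = 3
    for i in range(1, m + 1):
        cur = [i * scoring.gap] + [0] * n
        ptr[i][0] = 2
        ai = a[i - 1]
        for j in range(1, n + 1):
            diag = prev[j - 1] + (scoring.match if ai == b[j - 1] else scoring.mismatch)
            up = prev[j] + scoring.gap
            left = cur[j - 1] + scoring.gap
            best = diag
            move = 1
            if up > best:
                best, move = up, 2
            if left > best:
                best, move = left, 3
            cur[j] = best
            ptr[i][j] = move
        prev = cur
    score = prev[n]

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        move = ptr[i][j]
        if move == 1:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif move == 2:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def reverse_complement(motif: str) -> str:
    return motif.upper().translate(_COMPLEMENT)[::-1]


SimilarityMode = Literal["plain", "best_rotation_revcomp"]


def motif_similarity(
    a: str,
    b: str,
    scoring: AlignmentScoring | None = None,
    mode: SimilarityMode = "plain",
) -> float:
    """Percent identity of the global motif alignment.

    Identity counts matched columns over the full alignment length (gap
    columns included in the denominator).  ``best_rotation_revcomp`` takes the
    maximum over all cyclic rotations of ``b`` and of its reverse complement,
    which makes the measure phase- and strand-insensitive.
    """

    def plain(x: str, y: str) -> float:
        _, ax, ay = needleman_wunsch(x, y, scoring)
        matches = sum(1 for ca, cb in zip(ax, ay) if ca == cb and ca != "-")
        return 100.0 * matches / len(ax)

    if mode == "plain":
        return plain(a, b)
    if mode != "best_rotation_revcomp":
        raise ParameterError(f"unknown similarity mode {mode!r}")
    b = b.upper()
    candidates = {b[i:] + b[:i] for i in range(len(b))}
    rc = reverse_complement(b)
    candidates |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return max(plain(a, variant) for variant in candidates)


# ---------------------------------------------------------------------------
# Intersection and reciprocal reconciliation
# ---------------------------------------------------------------------------


def intersect_with_overlap(
    lifted: Sequence[LiftedInterval],
    query_catalog: Sequence[TRRecord],
    min_overlap: float,
    reciprocal: bool = False,
) -> list[tuple[LiftedInterval, TRRecord, float]]:
    """Pair lifted intervals with catalog records they sufficiently overlap.

    The overlap fraction is measured relative to the lifted interval's length
    (as with ``bedtools intersect -f`` on the lifted file).  With
    ``reciprocal`` the fraction relative to the catalog record must also reach
    the threshold.  One lifted interval may pair with several records.
    """
    if not 0.0 < min_overlap <= 1.0:
        raise ParameterError(f"min_overlap must be in (0, 1], got {min_overlap}")
    by_chrom: dict[str, list[TRRecord]] = {}
    for record in query_catalog:
        by_chrom.setdefault(record.chrom, []).append(record)
    for records in by_chrom.values():
        records.sort(key=lambda r: r.start)

    out: list[tuple[LiftedInterval, TRRecord, float]] = []
    for item in lifted:
        for record in by_chrom.get(item.chrom, ()):
            if record.start >= item.end:
                break
            overlap = min(item.end, record.end) - max(item.start, record.start)
            if overlap <= 0:
                continue
            fraction = overlap / (item.end - item.start)
            if fraction < min_overlap:
                continue
            if reciprocal and overlap / record.length < min_overlap:
                continue
            out.append((item, record, fraction))
    return out


def _directional_candidates(
    catalog_from: Sequence[TRRecord],
    catalog_to: Sequence[TRRecord],
    chains: ChainSet,
    min_overlap: float,
    min_match: float,
    reciprocal_overlap: bool,
) -> dict[tuple[str, str], float]:
    """Map (from-locus, to-locus) -> overlap fraction for one lift direction."""
    lifted, _ = lift_catalog(catalog_from, chains, min_match=min_match)
    hits = intersect_with_overlap(
        lifted, catalog_to, min_overlap, reciprocal=reciprocal_overlap
    )
    candidates: dict[tuple[str, str], float] = {}
    for item, record, fraction in hits:
        key = (item.source_id, record.locus_id)
        candidates[key] = max(candidates.get(key, 0.0), fraction)
    return candidates


def reciprocal_homologs(
    catalog_a: Sequence[TRRecord],
    catalog_b: Sequence[TRRecord],
    chain_ab: ChainSet,
    chain_ba: ChainSet,
    min_overlap: float = 0.10,
    min_similarity: float = 95.0,
    scoring: AlignmentScoring | None = None,
    mode: SimilarityMode = "plain",
    min_match: float = 0.95,
    reciprocal_overlap: bool = False,
    best_hit: bool = False,
) -> list[HomologPair]:
    """Identify homologous TR pairs supported by both lift directions.

    Candidates from A->B and B->A are each filtered by overlap then by motif
    similarity; the final set contains the locus pairs present in both
    directions, sorted by the A member's coordinates.
    """
    if not catalog_a or not catalog_b:
        return []
    chroms_a = {r.chrom for r in catalog_a}
    chroms_b = {r.chrom for r in catalog_b}
    if chroms_a.isdisjoint(chain_ab.target_names) or chroms_b.isdisjoint(
        chain_ab.query_names
    ):
        raise ConfigurationError("chain A->B does not match the catalog assemblies")
    if chroms_b.isdisjoint(chain_ba.target_names) or chroms_a.isdisjoint(
        chain_ba.query_names
    ):
        raise ConfigurationError("chain B->A does not match the catalog assemblies")

    ab = _directional_candidates(
        catalog_a, catalog_b, chain_ab, min_overlap, min_match, reciprocal_overlap
    )
    ba_raw = _directional_candidates(
        catalog_b, catalog_a, chain_ba, min_overlap, min_match, reciprocal_overlap
    )
    ba = {(id_a, id_b): frac for (id_b, id_a), frac in ba_raw.items()}

    index_a = {r.locus_id: r for r in catalog_a}
    index_b = {r.locus_id: r for r in catalog_b}
    similarity_cache: dict[tuple[str, str], float] = {}

    def similarity(motif_a: str, motif_b: str) -> float:
        key = (motif_a, motif_b)
        if key not in similarity_cache:
            similarity_cache[key] = motif_similarity(motif_a, motif_b, scoring, mode)
        return similarity_cache[key]

    pairs: list[HomologPair] = []
    for key in ab.keys() & ba.keys():
        rec_a, rec_b = index_a[key[0]], index_b[key[1]]
        sim = similarity(rec_a.motif, rec_b.motif)
        if sim < min_similarity:
            continue
        pairs.append(
            HomologPair(
                record_a=rec_a,
                record_b=rec_b,
                overlap_fraction_ab=ab[key],
                overlap_fraction_ba=ba[key],
                motif_similarity=sim,
            )
        )

    if best_hit:
        best: dict[str, HomologPair] = {}
        for pair in pairs:
            incumbent = best.get(pair.record_a.locus_id)
            if incumbent is None or _best_hit_key(pair) > _best_hit_key(incumbent):
                best[pair.record_a.locus_id] = pair
        pairs = list(best.values())

    pairs.sort(key=lambda p: (p.record_a.chrom, p.record_a.start, p.record_b.start))
    return pairs


def _best_hit_key(pair: HomologPair) -> tuple[float, float, int]:
    return (pair.motif_similarity, pair.overlap_fraction_ab, -pair.record_b.start)


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

PHTR_COLUMNS = (
    "chrom_a",
    "start_a",
    "end_a",
    "motif_a",
    "motif_len_a",
    "tr_len_a",
    "chrom_b",
    "start_b",
    "end_b",
    "motif_b",
    "motif_len_b",
    "tr_len_b",
    "overlap_ab",
    "overlap_ba",
    "similarity",
    "gc_a",
    "gc_b",
)


def _gc_fraction(motif: str) -> float:
    gc = sum(1 for base in motif.upper() if base in "GC")
    return gc / len(motif)


def phtr_table(pairs: Sequence[HomologPair]) -> pd.DataFrame:
    """phTR catalog as a dataframe in the fixed :data:`PHTR_COLUMNS` order."""
    rows = [
        (
            p.record_a.chrom,
            p.record_a.start,
            p.record_a.end,
            p.record_a.motif,
            len(p.record_a.motif),
            p.record_a.length,
            p.record_b.chrom,
            p.record_b.start,
            p.record_b.end,
            p.record_b.motif,
            len(p.record_b.motif),
            p.record_b.length,
            round(p.overlap_fraction_ab, 4),
            round(p.overlap_fraction_ba, 4),
            round(p.motif_similarity, 4),
            round(_gc_fraction(p.record_a.motif), 4),
            round(_gc_fraction(p.record_b.motif), 4),
        )
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=list(PHTR_COLUMNS))


def write_phtr(pairs: Sequence[HomologPair], stream: TextIO) -> None:
    phtr_table(pairs).to_csv(stream, sep="\t", index=False)


def shared_length_table(pairs: Sequence[HomologPair]) -> pd.DataFrame:
    """Plot-ready table of member total lengths, one row per homolog pair."""
    rows = [
        (p.record_a.locus_id, p.record_a.length, p.record_b.locus_id, p.record_b.length)
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["locus_a", "length_a", "locus_b", "length_b"])


def plot_shared_lengths(pairs: Sequence[HomologPair], path: str) -> None:
    """Scatter of member lengths for each shared TR pair (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = shared_length_table(pairs)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(table["length_a"], table["length_b"], s=8, alpha=0.6)
    lim = max(table[["length_a", "length_b"]].max().max(), 1) if len(table) else 1
    ax.plot([0, lim], [0, lim], lw=0.8, color="grey", ls="--")
    ax.set_xlabel("TR length in A (bp)")
    ax.set_ylabel("TR length in B (bp)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
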