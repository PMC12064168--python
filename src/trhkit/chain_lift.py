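"""Native UCSC chain-file parsing and interval liftover.

Chain semantics follow the UCSC format description: a chain header gives the
target and query spans, followed by ungapped alignment blocks of the form
``size dt dq`` where ``dt``/``dq`` are the gaps to the next block on the
target/query side; the last block is a bare ``size``.  Query coordinates in
the file are strand-local; all coordinates emitted by this module are
plus-strand 0-based half-open.
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

from .errors import FormatError, ParseError, ValidationError
from .tr_catalog import TRRecord

UNMAPPED_NO_CHAIN = "no_chain"
UNMAPPED_PARTIALLY_DELETED = "partially_deleted"
UNMAPPED_SPLIT = "split_across_chains"


@dataclass(frozen=True, slots=True)
class ChainAlignment:
    """One scored chain of ungapped blocks between a target and a query."""

    score: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    #: (size, dt, dq) triples; the final block carries dt = dq = 0.
    blocks: tuple[tuple[int, int, int], ...]

    def validate(self) -> None:
        if self.t_strand != "+":
            raise ValidationError(f"chain {self.chain_id}: t_strand must be '+'")
        if self.q_strand not in "+-":
            raise ValidationError(f"chain {self.chain_id}: bad q_strand {self.q_strand!r}")
        if not (0 <= self.t_start < self.t_end <= self.t_size):
            raise ValidationError(f"chain {self.chain_id}: bad target span")
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise ValidationError(f"chain {self.chain_id}: bad query span")
        if not self.blocks:
            raise ValidationError(f"chain {self.chain_id}: no blocks")
        t_sum = q_sum = 0
        for i, (size, dt, dq) in enumerate(self.blocks):
            last = i == len(self.blocks) - 1
            if size < 1 or dt < 0 or dq < 0:
                raise ValidationError(f"chain {self.chain_id}: negative/zero block field")
            if last and (dt or dq):
                raise ValidationError(f"chain {self.chain_id}: trailing gap on last block")
            t_sum += size + dt
            q_sum += size + dq
        if t_sum != self.t_end - self.t_start:
            raise ValidationError(
                f"chain {self.chain_id}: target block sum {t_sum} != span "
                f"{self.t_end - self.t_start}"
            )
        if q_sum != self.q_end - self.q_start:
            raise ValidationError(
                f"chain {self.chain_id}: query block sum {q_sum} != span "
                f"{self.q_end - self.q_start}"
            )

    def mapped_target_segments(
        self, start: int, end: int
    ) -> list[tuple[int, int, int]]:
        """Intersections of [start, end) with aligned blocks.

        Returns ``(t_lo, t_hi, q_lo)`` per overlapped block, where ``q_lo`` is
        the strand-local query coordinate of ``t_lo``.
        """
        out: list[tuple[int, int, int]] = []
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            lo, hi = max(start, t), min(end, t + size)
            if lo < hi:
                out.append((lo, hi, q + (lo - t)))
            t += size + dt
            q += size + dq
            if t >= end:
                break
        return out


@dataclass(frozen=True, slots=True)
class LiftedInterval:
    """A source interval successfully mapped onto the query assembly."""

    source: tuple[str, int, int]
    chrom: str
    start: int
    end: int
    strand: str
    mapped_fraction: float
    chain_id: int
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("lifted interval must be non-empty")
        if not 0.0 <= self.mapped_fraction <= 1.0:
            raise ValidationError("mapped_fraction must be in [0, 1]")


@dataclass(frozen=True, slots=True)
class UnmappedInterval:
    """A source interval that could not be lifted, with the failure reason."""

    source: tuple[str, int, int]
    reason: str
    source_id: str | None = None


LiftResult = Union[LiftedInterval, UnmappedInterval]


class ChainSet:
    """Validated chains indexed by target sequence name."""

    def __init__(self, chains: Iterable[ChainAlignment]):
        self.chains: list[ChainAlignment] = list(chains)
        self._by_target: dict[str, list[ChainAlignment]] = {}
        for chain in self.chains:
            chain.validate()
            self._by_target.setdefault(chain.t_name, []).append(chain)

    def __len__(self) -> int:
        return len(self.chains)

    def __iter__(self) -> Iterator[ChainAlignment]:
        return iter(self.chains)

    @property
    def target_names(self) -> set[str]:
        return set(self._by_target)

    @property
    def query_names(self) -> set[str]:
        return {c.q_name for c in self.chains}

    def overlapping(self, chrom: str, start: int, end: int) -> list[ChainAlignment]:
        return [
            c
            for c in self._by_target.get(chrom, ())
            if c.t_start < end and start < c.t_end
        ]


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: str | Path) -> TextIO:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def parse_chain(source: Union[str, Path, Iterable[str]]) -> ChainSet:
    """Parse a UCSC chain file (path, possibly gzipped, or line iterable).

    Every chain is validated eagerly: block sums must reproduce the header
    spans, otherwise a :class:`ValidationError` naming the chain id is raised.
    """
    if isinstance(source, (str, Path)):
        with _open_maybe_gzip(source) as handle:
            return parse_chain(handle)

    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []
    header_line = 0

    def finish(line_number: int) -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] or blocks[-1][2]:
            raise ParseError("chain not terminated by a bare size line", line_number)
        try:
            chain = ChainAlignment(
                score=int(header[1]),
                t_name=header[2],
                t_size=int(header[3]),
                t_strand=header[4],
                t_start=int(header[5]),
                t_end=int(header[6]),
                q_name=header[7],
                q_size=int(header[8]),
                q_strand=header[9],
                q_start=int(header[10]),
                q_end=int(header[11]),
                chain_id=int(header[12]),
                blocks=tuple(blocks),
            )
        except ValueError as exc:
            raise ParseError(f"non-numeric chain header field: {exc}", header_line)
        chain.validate()
        chains.append(chain)
        header, blocks = None, []

    line_number = 0
    for line_number, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            finish(line_number)
            fields = line.split()
            if len(fields) != 13:
                raise ParseError(
                    f"chain header must have 13 fields, got {len(fields)}", line_number
                )
            header, header_line = fields, line_number
            continue
        if header is None:
            raise FormatError(f"line {line_number}: block line outside any chain")
        parts = line.split()
        try:
            nums = [int(p) for p in parts]
        except ValueError:
            raise ParseError(f"non-numeric block line {line!r}", line_number) from None
        if len(nums) == 3:
            if min(nums) < 0:
                raise ParseError("negative block field", line_number)
            blocks.append((nums[0], nums[1], nums[2]))
        elif len(nums) == 1:
            if nums[0] < 0:
                raise ParseError("negative block size", line_number)
            blocks.append((nums[0], 0, 0))
        else:
            raise ParseError(f"block line must have 1 or 3 fields: {line!r}", line_number)
    finish(line_number + 1)
    return ChainSet(chains)


def write_chain(chains: Iterable[ChainAlignment], stream: TextIO) -> None:
    """Write chains in canonical UCSC format (blank line after each chain)."""
    for c in chains:
        stream.write(
            f"chain {c.score} {c.t_name} {c.t_size} {c.t_strand} "
            f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
            f"{c.q_start} {c.q_end} {c.chain_id}\n"
        )
        for i, (size, dt, dq) in enumerate(c.blocks):
            if i == len(c.blocks) - 1:
                stream.write(f"{size}\n")
            else:
                stream.write(f"{size} {dt} {dq}\n")
        stream.write("\n")


# ---------------------------------------------------------------------------
# Lifting
# ---------------------------------------------------------------------------


def lift_interval(
    chains: ChainSet,
    interval: tuple[str, int, int],
    min_match: float = 0.95,
    source_id: str | None = None,
) -> LiftResult:
    """Map one target interval to query coordinates through the best chain.

    The single highest-scoring chain overlapping the interval is used (no
    multi-chain stitching).  The emitted query span bridges the first to the
    last mapped base; it is reported only when the fraction of source bases
    inside aligned blocks reaches ``min_match``.  Failures carry a reason:
    ``no_chain``, ``partially_deleted`` or ``split_across_chains``.
    """
    chrom, start, end = interval
    if start >= end:
        raise ValidationError(f"empty interval {chrom}:{start}-{end}")
    candidates = chains.overlapping(chrom, start, end)
    if not candidates:
        return UnmappedInterval(interval, UNMAPPED_NO_CHAIN, source_id)
    best = max(candidates, key=lambda c: (c.score, -c.chain_id))
    segments = best.mapped_target_segments(start, end)
    mapped = sum(hi - lo for lo, hi, _ in segments)
    fraction = mapped / (end - start)
    if mapped and fraction >= min_match:
        q_lo = min(q for _, _, q in segments)
        q_hi = max(q + (hi - lo) for lo, hi, q in segments)
        if best.q_strand == "-":
            q_lo, q_hi = best.q_size - q_hi, best.q_size - q_lo
        return LiftedInterval(
            source=interval,
            chrom=best.q_name,
            start=q_lo,
            end=q_hi,
            strand=best.q_strand,
            mapped_fraction=fraction,
            chain_id=best.chain_id,
            source_id=source_id,
        )
    # Distinguish bases lost to deletions in the best chain from bases that
    # are aligned, but by other chains.
    covered = {
        pos
        for lo, hi, _ in segments
        for pos in range(lo, hi)
    }
    for other in candidates:
        if other is best:
            continue
        for lo, hi, _ in other.mapped_target_segments(start, end):
            for pos in range(lo, hi):
                if pos not in covered:
                    return UnmappedInterval(interval, UNMAPPED_SPLIT, source_id)
    return UnmappedInterval(interval, UNMAPPED_PARTIALLY_DELETED, source_id)


def lift_catalog(
    catalog: Sequence[TRRecord],
    chains: ChainSet,
    min_match: float = 0.95,
) -> tuple[list[LiftedInterval], Counter]:
    """Lift every catalog record; return mapped intervals and a failure tally."""
    lifted: list[LiftedInterval] = []
    report: Counter = Counter()
    for record in catalog:
        result = lift_interval(
            chains,
            (record.chrom, record.start, record.end),
            min_match=min_match,
            source_id=record.locus_id,
        )
        if isinstance(result, LiftedInterval):
            lifted.append(result)
            report["mapped"] += 1
        else:
            report[result.reason] += 1
    return lifted, report


def write_lifted_bed(lifted: Iterable[LiftedInterval], stream: TextIO) -> None:
    """BED of lifted intervals: q_chrom, q_start, q_end, source id, fraction, strand."""
    for item in lifted:
        name = item.source_id or "{}_{}_{}".format(*item.source)
        stream.write(
            f"{item.chrom}\t{item.start}\t{item.end}\t{name}\t"
            f"{item.mapped_fraction:.4f}\t{item.strand}\n"
        )


def write_unmapped_report(report: Counter, stream: TextIO) -> None:
    stream.write("reason\tcount\n")
    for reason in (UNMAPPED_NO_CHAIN, UNMAPPED_PARTIALLY_DELETED, UNMAPPED_SPLIT):
        stream.write(f"{reason}\t{report.get(reason, 0)}\n")
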