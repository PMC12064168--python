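"""Tandem-repeat catalog ingestion, merging, filtering and BED round-tripping.

Catalogs originate from Tandem Repeat Finder (TRF) tables.  TRF reports
1-based inclusive coordinates; everything inside this package (and all BED
output) is 0-based half-open.  The conversion happens once, at ingest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping, TextIO

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

MOTIF_ALPHABET = frozenset("ACGTN")

#: Default TRF invocation parameters recorded as provenance metadata.  The
#: detector itself is never run here; these values only feed the analytic
#: minimum-length bound below.
TRF_DEFAULTS: Mapping[str, int] = {
    "match_score": 2,
    "mismatch_score": 5,
    "indel_score": 7,
    "matching_probability": 80,
    "indel_probability": 10,
    "minimum_alignment_score": 24,
    "maximum_period_size": 2000,
}

FLAG_PERIOD_EXCEEDS_MAX = "period_size_exceeds_max"


def min_perfect_repeat_length(
    minimum_alignment_score: int = TRF_DEFAULTS["minimum_alignment_score"],
    match_score: int = TRF_DEFAULTS["match_score"],
) -> int:
    """Shortest perfect repeat admissible at a given minimum alignment score.

    A perfect (gap- and mismatch-free) repeat of L matched bases scores
    ``L * match_score``; the smallest L reaching the reporting threshold is
    ``ceil(minimum_alignment_score / match_score)`` — 12 bp at the defaults.
    """
    if match_score <= 0:
        raise ValueError("match_score must be positive")
    return math.ceil(minimum_alignment_score / match_score)


@dataclass(frozen=True, slots=True)
class TRRecord:
    """One tandem-repeat locus (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    period_size: int
    copy_number: float
    consensus_size: int
    percent_matches: float
    percent_indels: float
    alignment_score: int
    motif: str
    sequence: str | None = None
    flags: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.period_size < 1:
            raise ValidationError(f"period_size must be >=1, got {self.period_size}")
        if self.copy_number < 0:
            raise ValidationError(f"copy_number must be >=0, got {self.copy_number}")
        if self.alignment_score < 0:
            raise ValidationError(
                f"alignment_score must be >=0, got {self.alignment_score}"
            )
        if not self.motif:
            raise ValidationError("motif must be non-empty")
        bad = set(self.motif.upper()) - MOTIF_ALPHABET
        if bad:
            raise ValidationError(f"motif contains invalid characters {sorted(bad)}")
        if self.consensus_size >= 1 and len(self.motif) != self.consensus_size:
            raise ValidationError(
                f"motif length {len(self.motif)} != consensus_size "
                f"{self.consensus_size}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}_{self.start}_{self.end}"


@dataclass(frozen=True, slots=True)
class FilterPolicy:
    """Catalog retention policy: length cap, copy-number floor, length floor."""

    max_total_length: int = 10_000
    min_copy_number: float = 2.5
    min_total_length: int = 0

    def __post_init__(self) -> None:
        if self.min_total_length < 0:
            raise ValidationError("min_total_length must be >= 0")
        if self.max_total_length <= self.min_total_length:
            raise ValidationError("max_total_length must exceed min_total_length")

    def keeps(self, record: TRRecord) -> bool:
        return (
            record.length <= self.max_total_length
            and record.length >= self.min_total_length
            and record.copy_number >= self.min_copy_number
        )


# ---------------------------------------------------------------------------
# TRF table parsing
# ---------------------------------------------------------------------------

# Columns of a TRF data row (both the -d "Data file" and -ngs dialects):
# start end period_size copy_number consensus_size percent_matches
# percent_indels score A C G T entropy motif sequence [left_flank right_flank]
_TRF_MIN_COLUMNS = 15


def _parse_trf_row(
    fields: list[str], chrom: str, line_number: int
) -> TRRecord:
    try:
        start_1b = int(fields[0])
        end_1b = int(fields[1])
        period_size = int(fields[2])
        copy_number = float(fields[3])
        consensus_size = int(fields[4])
        percent_matches = float(fields[5])
        percent_indels = float(fields[6])
        score = int(fields[7])
    except ValueError as exc:
        raise ParseError(f"non-numeric field in TRF row: {exc}", line_number) from None
    motif = fields[13].upper()
    sequence = fields[14].upper()
    flags: tuple[str, ...] = ()
    if period_size > TRF_DEFAULTS["maximum_period_size"]:
        flags = (FLAG_PERIOD_EXCEEDS_MAX,)
        logger.warning(
            "line %d: period size %d exceeds maximum %d",
            line_number,
            period_size,
            TRF_DEFAULTS["maximum_period_size"],
        )
    try:
        return TRRecord(
            chrom=chrom,
            start=start_1b - 1,  # 1-based inclusive -> 0-based half-open
            end=end_1b,
            period_size=period_size,
            copy_number=copy_number,
            consensus_size=consensus_size,
            percent_matches=percent_matches,
            percent_indels=percent_indels,
            alignment_score=score,
            motif=motif,
            sequence=sequence,
            flags=flags,
        )
    except ValidationError as exc:
        raise ParseError(str(exc), line_number) from None


def parse_trf_dat(
    stream: Iterable[str],
    chrom_resolver: Callable[[str], str] | Mapping[str, str] | None = None,
) -> list[TRRecord]:
    """Parse TRF output in either the classic ``-d`` or the ``-ngs`` dialect.

    The dialect is auto-detected: ``-ngs`` sequence headers begin with ``@``,
    classic "Data file" output carries ``Sequence:`` header lines.  Rows
    belong to the most recent sequence header.  ``chrom_resolver`` optionally
    remaps sequence names (mapping or callable); by default the first
    whitespace-separated token of the header is used verbatim.
    """
    if chrom_resolver is None:
        resolve: Callable[[str], str] = lambda name: name
    elif callable(chrom_resolver):
        resolve = chrom_resolver
    else:
        resolve = lambda name: chrom_resolver.get(name, name)  # type: ignore[union-attr]

    records: list[TRRecord] = []
    chrom: str | None = None
    dialect: str | None = None
    for line_number, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if dialect is None:
            dialect = "ngs" if line.startswith("@") else "dat"
        if line.startswith("@"):
            chrom = resolve(line[1:].split()[0])
            continue
        if line.startswith("Sequence:"):
            name = line.split(":", 1)[1].strip()
            if not name:
                raise ParseError("empty Sequence: header", line_number)
            chrom = resolve(name.split()[0])
            continue
        if not line[0].isdigit():
            if dialect == "ngs":
                raise FormatError(
                    f"line {line_number}: unexpected line in -ngs dialect: {line!r}"
                )
            continue  # classic .dat preamble (program banner, Parameters:, ...)
        fields = line.split()
        if len(fields) < _TRF_MIN_COLUMNS:
            raise ParseError(
                f"expected >= {_TRF_MIN_COLUMNS} columns, got {len(fields)}",
                line_number,
            )
        if chrom is None:
            raise FormatError(
                f"line {line_number}: TRF data row before any sequence header "
                "(unknown dialect?)"
            )
        records.append(_parse_trf_row(fields, chrom, line_number))
    logger.info("parsed %d TRF records", len(records))
    return records


# ---------------------------------------------------------------------------
# Merge & filter
# ---------------------------------------------------------------------------


def _representative(members: list[TRRecord]) -> TRRecord:
    # Highest score wins; ties broken by smaller start, then lexicographically
    # smallest motif, for determinism.
    return min(members, key=lambda r: (-r.alignment_score, r.start, r.motif))


def merge_overlapping(records: Iterable[TRRecord]) -> list[TRRecord]:
    """Collapse same-chromosome overlapping records into their union span.

    Overlap is strict under half-open semantics (``start2 < end1``); abutting
    intervals are left separate.  The merged record inherits motif, scores and
    copy number from the member with the highest alignment score.  Output is
    sorted and non-overlapping.
    """
    ordered = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
    merged: list[TRRecord] = []
    cluster: list[TRRecord] = []
    cluster_end = -1

    def flush() -> None:
        if not cluster:
            return
        if len(cluster) == 1:
            merged.append(cluster[0])
        else:
            rep = _representative(cluster)
            merged.append(
                replace(
                    rep,
                    start=min(r.start for r in cluster),
                    end=max(r.end for r in cluster),
                    sequence=None,
                    flags=tuple(
                        sorted({flag for r in cluster for flag in r.flags})
                    ),
                )
            )

    for record in ordered:
        if cluster and record.chrom == cluster[0].chrom and record.start < cluster_end:
            cluster.append(record)
            cluster_end = max(cluster_end, record.end)
        else:
            flush()
            cluster = [record]
            cluster_end = record.end
    flush()
    if len(ordered) != len(merged):
        logger.info("merged %d records away", len(ordered) - len(merged))
    return merged


def filter_catalog(
    records: Iterable[TRRecord], policy: FilterPolicy | None = None
) -> list[TRRecord]:
    """Retain records passing the policy (defaults: length <= 10 kbp, copies >= 2.5)."""
    policy = policy or FilterPolicy()
    kept, dropped_len, dropped_copy = [], 0, 0
    for record in records:
        if record.length > policy.max_total_length or (
            record.length < policy.min_total_length
        ):
            dropped_len += 1
        elif record.copy_number < policy.min_copy_number:
            dropped_copy += 1
        else:
            kept.append(record)
    logger.info(
        "filter: kept %d, dropped %d by length, %d by copy number",
        len(kept),
        dropped_len,
        dropped_copy,
    )
    return kept


# ---------------------------------------------------------------------------
# Catalog BED I/O
# ---------------------------------------------------------------------------

#: Fixed catalog BED column order (tab-separated, '#' comments allowed).
BED_COLUMNS = (
    "chrom",
    "start",
    "end",
    "motif",
    "period_size",
    "copy_number",
    "consensus_size",
    "percent_matches",
    "percent_indels",
    "alignment_score",
    "sequence",
)


def _fmt_float(value: float) -> str:
    return repr(float(value))


def write_catalog_bed(
    records: Iterable[TRRecord], stream: TextIO, header: bool = False
) -> None:
    """Write a catalog as BED + TSV extras in the :data:`BED_COLUMNS` order."""
    if header:
        stream.write("#" + "\t".join(BED_COLUMNS) + "\n")
    for r in records:
        stream.write(
            "\t".join(
                (
                    r.chrom,
                    str(r.start),
                    str(r.end),
                    r.motif,
                    str(r.period_size),
                    _fmt_float(r.copy_number),
                    str(r.consensus_size),
                    _fmt_float(r.percent_matches),
                    _fmt_float(r.percent_indels),
                    str(r.alignment_score),
                    r.sequence if r.sequence is not None else ".",
                )
            )
            + "\n"
        )


def read_catalog_bed(stream: Iterable[str]) -> list[TRRecord]:
    """Read a catalog written by :func:`write_catalog_bed` (round-trip inverse)."""
    records: list[TRRecord] = []
    for line_number, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(BED_COLUMNS):
            raise ParseError(
                f"expected {len(BED_COLUMNS)} columns, got {len(fields)}", line_number
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError("non-integer coordinates", line_number) from None
        if start >= end:
            raise ParseError(f"start {start} >= end {end}", line_number)
        try:
            records.append(
                TRRecord(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    motif=fields[3],
                    period_size=int(fields[4]),
                    copy_number=float(fields[5]),
                    consensus_size=int(fields[6]),
                    percent_matches=float(fields[7]),
                    percent_indels=float(fields[8]),
                    alignment_score=int(fields[9]),
                    sequence=None if fields[10] == "." else fields[10],
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(str(exc), line_number) from None
    return records
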