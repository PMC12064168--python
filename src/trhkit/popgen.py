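"""Population-genetic summaries of tandem-repeat genotype VCFs.

Input is a multi-sample diploid VCF whose REF/ALT fields carry full allele
sequences (TRGT-style).  Alleles are distinguished by their full sequence
string by default, so composition variants at equal length remain distinct;
``by_length`` collapses them to lengths.  Gene diversity uses Nei's unbiased
estimator (2n/(2n-1)) * (1 - sum p_i^2) over the 2n called chromosomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd
import pysam

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """One sample's diploid genotype at one TR locus; ``None`` fields = missing."""

    sample: str
    locus_id: str
    allele_indices: tuple[int, int] | None
    allele_sequences: tuple[str, str] | None
    allele_lengths: tuple[int, int] | None

    @property
    def missing(self) -> bool:
        return self.allele_indices is None

    @property
    def heterozygous(self) -> bool:
        if self.missing:
            return False
        return self.allele_sequences[0] != self.allele_sequences[1]


@dataclass(frozen=True, slots=True)
class LocusStats:
    """Per-locus summary; statistic fields are ``None`` when nothing was called."""

    locus_id: str
    n_called: int
    obs_het: float | None
    gene_diversity: float | None
    n_unique_alleles: int | None
    min_allele_len: int | None
    max_allele_len: int | None


@dataclass(slots=True)
class TRGenotypeData:
    """Parsed cohort: loci in VCF order, samples in VCF order, calls per locus."""

    samples: list[str]
    loci: list[tuple[str, str, int]]  # (locus_id, chrom, 0-based pos)
    calls: dict[str, list[GenotypeCall]]


def read_tr_vcf(path: str | Path, length_field: str = "AL") -> TRGenotypeData:
    """Parse a TR genotype VCF (plain or bgzipped) into per-locus calls.

    Allele sequences are resolved from GT indices against REF/ALT.  Allele
    lengths come from the per-allele ``length_field`` FORMAT tag when present,
    otherwise from the sequence lengths.  Locus ids come from the ID column
    when set, else ``chrom_pos``.
    """
    vcf = pysam.VariantFile(str(path))
    if "GT" not in vcf.header.formats:
        raise FormatError("VCF has no GT FORMAT field")
    has_length = length_field in vcf.header.formats
    samples = list(vcf.header.samples)
    loci: list[tuple[str, str, int]] = []
    calls: dict[str, list[GenotypeCall]] = {}
    for rec in vcf:
        locus_id = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
        alleles = rec.alleles  # REF first
        locus_calls: list[GenotypeCall] = []
        for sample in samples:
            data = rec.samples[sample]
            gt = data.get("GT")
            if gt is None or all(a is None for a in gt):
                locus_calls.append(GenotypeCall(sample, locus_id, None, None, None))
                continue
            if len(gt) != 2:
                raise ValidationError(
                    f"{locus_id}: sample {sample} is not diploid (GT ploidy {len(gt)})"
                )
            if any(a is None for a in gt):
                locus_calls.append(GenotypeCall(sample, locus_id, None, None, None))
                continue
            if max(gt) >= len(alleles):
                raise ValidationError(
                    f"{locus_id}: GT index {max(gt)} exceeds ALT count for {sample}"
                )
            seqs = (alleles[gt[0]], alleles[gt[1]])
            lengths = (len(seqs[0]), len(seqs[1]))
            if has_length:
                al = data.get(length_field)
                if al is not None and len(al) == 2 and None not in al:
                    lengths = (int(al[0]), int(al[1]))
            locus_calls.append(
                GenotypeCall(sample, locus_id, (gt[0], gt[1]), seqs, lengths)
            )
        loci.append((locus_id, rec.chrom, rec.pos - 1))
        calls[locus_id] = locus_calls
    return TRGenotypeData(samples=samples, loci=loci, calls=calls)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def locus_stats(
    locus_id: str,
    calls: Iterable[GenotypeCall],
    by_length: bool = False,
    unbiased: bool = True,
) -> LocusStats:
    """Observed heterozygosity, gene diversity, allele count and length range.

    Missing genotypes are excluded from every denominator.  ``unbiased``
    applies the 2n/(2n-1) small-sample correction to gene diversity.
    """
    called = [c for c in calls if not c.missing]
    n = len(called)
    if n == 0:
        return LocusStats(locus_id, 0, None, None, None, None, None)

    def ident(call: GenotypeCall) -> tuple:
        if by_length:
            return call.allele_lengths
        return call.allele_sequences

    het = sum(1 for c in called if ident(c)[0] != ident(c)[1])
    obs_het = het / n

    counts: dict[object, int] = {}
    for c in called:
        for allele in ident(c):
            counts[allele] = counts.get(allele, 0) + 1
    two_n = 2 * n
    sum_p2 = sum((k / two_n) ** 2 for k in counts.values())
    diversity = 1.0 - sum_p2
    if unbiased and two_n > 1:
        diversity *= two_n / (two_n - 1)

    lengths = [l for c in called for l in c.allele_lengths]
    return LocusStats(
        locus_id=locus_id,
        n_called=n,
        obs_het=obs_het,
        gene_diversity=diversity,
        n_unique_alleles=len(counts),
        min_allele_len=min(lengths),
        max_allele_len=max(lengths),
    )


def gene_diversity_from_frequencies(
    frequencies: Sequence[float], n_diploid: int | None = None
) -> float:
    """Closed-form gene diversity 1 - sum p^2, optionally unbiased for 2n chromosomes."""
    if abs(sum(frequencies) - 1.0) > 1e-8:
        raise ValidationError("allele frequencies must sum to 1")
    h = 1.0 - sum(p * p for p in frequencies)
    if n_diploid is not None:
        two_n = 2 * n_diploid
        h *= two_n / (two_n - 1)
    return h


def cohort_stats(
    data: TRGenotypeData, by_length: bool = False, unbiased: bool = True
) -> list[LocusStats]:
    return [
        locus_stats(locus_id, data.calls[locus_id], by_length, unbiased)
        for locus_id, _, _ in data.loci
    ]


STAT_FIELDS = (
    "n_called",
    "obs_het",
    "gene_diversity",
    "n_unique_alleles",
    "min_allele_len",
    "max_allele_len",
)


def stats_table(stats: Sequence[LocusStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"locus_id": s.locus_id, **{f: getattr(s, f) for f in STAT_FIELDS}}
            for s in stats
        ]
    )


def read_pop_map(stream: Iterable[str] | str | Path) -> dict[str, str]:
    """Read sample<TAB>population lines; '#' comments and blanks are skipped."""
    if isinstance(stream, (str, Path)):
        with open(stream) as handle:
            return read_pop_map(handle)
    mapping: dict[str, str] = {}
    for line_number, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"line {line_number}: expected sample<TAB>population")
        mapping[parts[0]] = parts[1]
    return mapping


def population_summary(
    data: TRGenotypeData,
    pop_map: Mapping[str, str],
    by_length: bool = False,
    unbiased: bool = True,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-population locus statistics in long format.

    Statistics are recomputed per population from that population's samples
    only.  Samples absent from ``pop_map`` are an error in strict mode, and
    are dropped with a warning otherwise.
    """
    unknown = [s for s in data.samples if s not in pop_map]
    if unknown:
        if strict:
            raise ValidationError(
                f"samples missing from population map: {', '.join(unknown)}"
            )
        warnings.warn(f"dropping {len(unknown)} samples absent from population map")
    populations: dict[str, set[str]] = {}
    for sample in data.samples:
        if sample in pop_map:
            populations.setdefault(pop_map[sample], set()).add(sample)

    rows: list[tuple[str, str, str, float | int | None]] = []
    for pop in sorted(populations):
        members = populations[pop]
        if not members:
            warnings.warn(f"population {pop} is empty after mapping; omitted")
            continue
        for locus_id, _, _ in data.loci:
            calls = [c for c in data.calls[locus_id] if c.sample in members]
            stats = locus_stats(locus_id, calls, by_length, unbiased)
            for field_name in STAT_FIELDS:
                rows.append((pop, locus_id, field_name, getattr(stats, field_name)))
    return pd.DataFrame(rows, columns=["population", "locus_id", "statistic", "value"])


def genotype_matrix(data: TRGenotypeData) -> pd.DataFrame:
    """Wide loci x samples table of allele-length genotypes ("len1/len2" or "./.")."""
    ordered = sorted(data.loci, key=lambda t: (t[1], t[2]))
    rows = []
    for locus_id, _, _ in ordered:
        by_sample = {c.sample: c for c in data.calls[locus_id]}
        row = {}
        for sample in data.samples:
            call = by_sample.get(sample)
            if call is None or call.missing:
                row[sample] = "./."
            else:
                row[sample] = f"{call.allele_lengths[0]}/{call.allele_lengths[1]}"
        rows.append(row)
    return pd.DataFrame(
        rows, index=pd.Index([l for l, _, _ in ordered], name="locus_id"),
        columns=data.samples,
    )


def plot_heterozygosity(summary: pd.DataFrame, path: str) -> None:
    """Violin plot of per-locus observed heterozygosity by population."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    het = summary[summary["statistic"] == "obs_het"].dropna(subset=["value"])
    fig, ax = plt.subplots(figsize=(6, 4))
    sns.violinplot(
        data=het, x="population", y="value", cut=0, inner="quartile", ax=ax
    )
    ax.set_ylabel("Observed heterozygosity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
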