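"""Self-consistent synthetic fixtures: paired toy genomes with planted
homologous tandem repeats, exact chain files in both directions, catalogs,
and multi-sample TR genotype VCFs with known allele frequencies.

Genome B is derived from genome A through an explicit edit plan (aligned
segments, insertions, deletions), so the emitted chains are exact by
construction and every planted homolog is recoverable ground truth.  Motif
divergence applies substitutions only — the number of substituted bases per
shared motif is ``round(divergence * motif_length)`` — so the planted percent
similarity has the closed form ``100 * (1 - substitutions / motif_length)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chain_lift import ChainAlignment, write_chain
from .errors import GenerationError, ValidationError
from .tr_catalog import TRRecord, write_catalog_bed

BASES = "ACGT"


@dataclass(frozen=True, slots=True)
class FixtureSpec:
    """Parameters for one deterministic fixture bundle."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 20_000
    n_shared_trs: int = 10
    n_private_trs: int = 4
    motif_length: tuple[int, int] = (4, 12)
    copy_number: tuple[float, float] = (3.0, 10.0)
    motif_divergence: float = 0.0
    indel_blocks: int = 2
    indel_size: tuple[int, int] = (50, 200)
    n_samples: int = 12
    allele_count: tuple[int, int] = (1, 4)
    n_populations: int = 2
    min_spacing: int = 50
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.motif_divergence <= 0.2:
            raise ValidationError("motif_divergence must be in [0, 0.2]")
        if self.motif_length[0] < 1 or self.motif_length[0] > self.motif_length[1]:
            raise ValidationError("bad motif_length range")
        if self.copy_number[0] < 2.5:
            raise ValidationError("copy_number floor must be >= 2.5")
        if self.allele_count[0] < 1 or self.allele_count[0] > self.allele_count[1]:
            raise ValidationError("bad allele_count range")
        if self.n_chroms < 1 or self.n_samples < 1 or self.n_populations < 1:
            raise ValidationError("counts must be positive")
        if self.min_spacing < 50:
            raise ValidationError("min_spacing must be >= 50")


#: Presets used by the CLI and the test suite.
PRESETS: Mapping[str, FixtureSpec] = {
    "small": FixtureSpec(),
    "medium": FixtureSpec(
        n_chroms=3,
        chrom_length=25_000,
        n_shared_trs=50,
        n_private_trs=20,
        motif_length=(10, 30),
        copy_number=(3.0, 8.0),
        motif_divergence=0.03,
        indel_blocks=4,
        n_samples=24,
    ),
}


@dataclass(slots=True)
class GenomePairBundle:
    """All artifacts of one planted genome pair."""

    spec: FixtureSpec
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    catalog_a: list[TRRecord]
    catalog_b: list[TRRecord]
    chains_ab: list[ChainAlignment]
    chains_ba: list[ChainAlignment]
    truth: pd.DataFrame  # one row per planted homolog pair


@dataclass(slots=True)
class CohortBundle:
    """A synthetic genotype cohort over a catalog."""

    vcf_text: str
    pop_map: dict[str, str]
    truth_frequencies: pd.DataFrame  # population, locus_id, allele, frequency
    genotypes: dict[tuple[str, str], tuple[int, int]]  # (locus_id, sample) -> GT


# ---------------------------------------------------------------------------
# Genome pair construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate_motif(rng: np.random.Generator, motif: str, divergence: float) -> str:
    n_subs = round(divergence * len(motif))
    if n_subs == 0:
        return motif
    positions = rng.choice(len(motif), size=n_subs, replace=False)
    out = list(motif)
    for pos in positions:
        choices = [b for b in BASES if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def _tr_array(motif: str, total_len: int) -> str:
    reps = math.ceil(total_len / len(motif))
    return (motif * reps)[:total_len]


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def make_genome_pair(spec: FixtureSpec) -> GenomePairBundle:
    """Generate the paired-genome bundle for ``spec`` (same seed, same bytes)."""
    rng = np.random.default_rng(spec.seed)
    genome_a: dict[str, str] = {}
    genome_b: dict[str, str] = {}
    catalog_a: list[TRRecord] = []
    catalog_b: list[TRRecord] = []
    chains_ab: list[ChainAlignment] = []
    chains_ba: list[ChainAlignment] = []
    truth_rows: list[dict] = []

    shared_per_chrom = _split_counts(spec.n_shared_trs, spec.n_chroms)
    private_per_chrom = _split_counts(spec.n_private_trs, spec.n_chroms)
    indels_per_chrom = _split_counts(spec.indel_blocks, spec.n_chroms)

    for chrom_index in range(spec.n_chroms):
        chrom = f"chr{chrom_index + 1}"
        slots = (
            ["shared"] * shared_per_chrom[chrom_index]
            + ["private_a"] * private_per_chrom[chrom_index]
            + ["private_b"] * private_per_chrom[chrom_index]
        )
        rng.shuffle(slots)

        # Edit plan: ("aligned", seq_a, seq_b, slot_kind, payload) |
        # ("a_only", seq) | ("b_only", seq).  Plan starts and ends aligned.
        ops: list[tuple] = []

        def add_background() -> None:
            length = int(rng.integers(spec.min_spacing, spec.min_spacing * 3))
            seq = _random_seq(rng, length)
            ops.append(("aligned", seq, seq, "bg", None))

        add_background()
        for kind in slots:
            motif_len = int(rng.integers(spec.motif_length[0], spec.motif_length[1] + 1))
            motif = _random_seq(rng, motif_len)
            copies = float(rng.uniform(*spec.copy_number))
            total_len = int(round(motif_len * copies))
            array = _tr_array(motif, total_len)
            if kind == "shared":
                motif_b = _mutate_motif(rng, motif, spec.motif_divergence)
                ops.append(("aligned", array, _tr_array(motif_b, total_len), kind,
                            (motif, motif_b, total_len)))
            elif kind == "private_a":
                ops.append(("aligned", array, _random_seq(rng, total_len), kind,
                            (motif, None, total_len)))
            else:  # private_b
                ops.append(("aligned", _random_seq(rng, total_len), array, kind,
                            (None, motif, total_len)))
            add_background()

        # Unaligned blocks: deletions ("a_only") and insertions ("b_only")
        # spliced between interior segments so the plan stays aligned-bounded.
        for _ in range(indels_per_chrom[chrom_index]):
            size = int(rng.integers(spec.indel_size[0], spec.indel_size[1] + 1))
            kind = "a_only" if rng.integers(0, 2) else "b_only"
            where = int(rng.integers(1, len(ops)))
            ops.insert(where, (kind, _random_seq(rng, size)))

        length_a = sum(
            len(op[1]) for op in ops if op[0] in ("aligned", "a_only")
        )
        if length_a > spec.chrom_length:
            raise GenerationError(
                f"{chrom}: placed segments span {length_a} bp, exceeding "
                f"chrom_length {spec.chrom_length}; cannot place all TRs"
            )
        pad = _random_seq(rng, spec.chrom_length - length_a)
        if pad:
            ops.append(("aligned", pad, pad, "bg", None))

        seq_a, seq_b, records_a, records_b, rows = _realise_plan(chrom, ops)
        genome_a[chrom], genome_b[chrom] = seq_a, seq_b
        catalog_a.extend(records_a)
        catalog_b.extend(records_b)
        truth_rows.extend(rows)

        ab, ba = _plan_to_chains(chrom, ops, len(seq_a), len(seq_b), chrom_index + 1)
        chains_ab.append(ab)
        chains_ba.append(ba)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "locus_a",
            "start_a",
            "end_a",
            "locus_b",
            "start_b",
            "end_b",
            "motif_a",
            "motif_b",
            "n_substitutions",
            "divergence",
            "expected_similarity",
        ],
    )
    return GenomePairBundle(
        spec=spec,
        genome_a=genome_a,
        genome_b=genome_b,
        catalog_a=catalog_a,
        catalog_b=catalog_b,
        chains_ab=chains_ab,
        chains_ba=chains_ba,
        truth=truth,
    )


def _planted_record(
    chrom: str, start: int, motif: str, total_len: int, array: str
) -> TRRecord:
    return TRRecord(
        chrom=chrom,
        start=start,
        end=start + total_len,
        period_size=len(motif),
        copy_number=total_len / len(motif),
        consensus_size=len(motif),
        percent_matches=100.0,
        percent_indels=0.0,
        alignment_score=2 * total_len,
        motif=motif,
        sequence=array,
    )


def _realise_plan(chrom: str, ops: list[tuple]):
    parts_a: list[str] = []
    parts_b: list[str] = []
    records_a: list[TRRecord] = []
    records_b: list[TRRecord] = []
    rows: list[dict] = []
    pos_a = pos_b = 0
    for op in ops:
        if op[0] == "a_only":
            parts_a.append(op[1])
            pos_a += len(op[1])
            continue
        if op[0] == "b_only":
            parts_b.append(op[1])
            pos_b += len(op[1])
            continue
        _, seq_a, seq_b, kind, payload = op
        if kind in ("shared", "private_a"):
            motif_a, _, total_len = payload
            records_a.append(_planted_record(chrom, pos_a, motif_a, total_len, seq_a))
        if kind in ("shared", "private_b"):
            _, motif_b, total_len = payload
            records_b.append(_planted_record(chrom, pos_b, motif_b, total_len, seq_b))
        if kind == "shared":
            motif_a, motif_b, total_len = payload
            n_subs = sum(1 for x, y in zip(motif_a, motif_b) if x != y)
            rows.append(
                {
                    "chrom": chrom,
                    "locus_a": f"{chrom}_{pos_a}_{pos_a + total_len}",
                    "start_a": pos_a,
                    "end_a": pos_a + total_len,
                    "locus_b": f"{chrom}_{pos_b}_{pos_b + total_len}",
                    "start_b": pos_b,
                    "end_b": pos_b + total_len,
                    "motif_a": motif_a,
                    "motif_b": motif_b,
                    "n_substitutions": n_subs,
                    "divergence": n_subs / len(motif_a),
                    "expected_similarity": 100.0 * (1 - n_subs / len(motif_a)),
                }
            )
        parts_a.append(seq_a)
        parts_b.append(seq_b)
        pos_a += len(seq_a)
        pos_b += len(seq_b)
    return "".join(parts_a), "".join(parts_b), records_a, records_b, rows


def _plan_to_chains(
    chrom: str, ops: list[tuple], len_a: int, len_b: int, chain_id: int
) -> tuple[ChainAlignment, ChainAlignment]:
    blocks: list[tuple[int, int, int]] = []
    size = dt = dq = 0
    for op in ops:
        if op[0] == "aligned":
            if dt or dq:
                blocks.append((size, dt, dq))
                size = dt = dq = 0
            size += len(op[1])
        elif op[0] == "a_only":
            dt += len(op[1])
        else:
            dq += len(op[1])
    blocks.append((size, 0, 0))
    aligned_total = sum(b[0] for b in blocks)
    ab = ChainAlignment(
        score=aligned_total,
        t_name=chrom,
        t_size=len_a,
        t_strand="+",
        t_start=0,
        t_end=len_a,
        q_name=chrom,
        q_size=len_b,
        q_strand="+",
        q_start=0,
        q_end=len_b,
        chain_id=chain_id,
        blocks=tuple(blocks),
    )
    ba = ChainAlignment(
        score=aligned_total,
        t_name=chrom,
        t_size=len_b,
        t_strand="+",
        t_start=0,
        t_end=len_b,
        q_name=chrom,
        q_size=len_a,
        q_strand="+",
        q_start=0,
        q_end=len_a,
        chain_id=chain_id,
        blocks=tuple((s, q, t) for s, t, q in blocks),
    )
    ab.validate()
    ba.validate()
    return ab, ba


# ---------------------------------------------------------------------------
# Cohort VCF construction
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=END,Number=1,Type=Integer,Description="End coordinate of the repeat">
##INFO=<ID=MOTIF,Number=1,Type=String,Description="Repeat motif">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AL,Number=2,Type=Integer,Description="Allele lengths">
"""


def make_cohort_vcf(
    spec: FixtureSpec,
    catalog: Sequence[TRRecord],
    fixed_frequencies: Sequence[float] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> CohortBundle:
    """Simulate a diploid genotype cohort over a catalog.

    Per locus the allele pool consists of the reference repeat array plus
    whole-copy-number variants of it; population allele frequencies are drawn
    from a flat Dirichlet (or pinned to ``fixed_frequencies``) and recorded as
    ground truth.  Same spec, same bytes.
    """
    if fixed_frequencies is not None and (
        len(fixed_frequencies) < 1 or abs(sum(fixed_frequencies) - 1.0) > 1e-9
    ):
        raise ValidationError("fixed_frequencies must be non-empty and sum to 1")
    for record in catalog:
        if record.sequence is None:
            raise ValidationError(f"{record.locus_id}: catalog record lacks sequence")

    rng = np.random.default_rng([spec.seed, 1])
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    pops = [f"pop{i + 1}" for i in range(spec.n_populations)]
    pop_map = {s: pops[i % spec.n_populations] for i, s in enumerate(samples)}

    freq_rows: list[dict] = []
    genotypes: dict[tuple[str, str], tuple[int, int]] = {}
    body_lines: list[str] = []

    ordered = sorted(catalog, key=lambda r: (r.chrom, r.start))
    for record in ordered:
        ref = record.sequence
        motif = record.motif
        base_copies = max(2, (record.end - record.start) // len(motif))
        if fixed_frequencies is not None:
            n_alleles = len(fixed_frequencies)
        else:
            n_alleles = int(rng.integers(spec.allele_count[0], spec.allele_count[1] + 1))
        alleles = [ref]
        deltas = [d for d in (-2, -1, 1, 2, 3, 4) if base_copies + d >= 2]
        rng.shuffle(deltas)
        for delta in deltas:
            if len(alleles) == n_alleles:
                break
            candidate = motif * (base_copies + delta)
            if candidate not in alleles:
                alleles.append(candidate)
        if len(alleles) < n_alleles:
            raise GenerationError(
                f"{record.locus_id}: cannot build {n_alleles} distinct alleles"
            )

        if fixed_frequencies is not None:
            pop_freqs = {pop: list(fixed_frequencies) for pop in pops}
        else:
            pop_freqs = {
                pop: list(rng.dirichlet(np.ones(n_alleles))) for pop in pops
            }
        for pop in pops:
            for idx, freq in enumerate(pop_freqs[pop]):
                freq_rows.append(
                    {
                        "population": pop,
                        "locus_id": record.locus_id,
                        "allele_index": idx,
                        "allele": alleles[idx],
                        "frequency": freq,
                    }
                )

        cells = []
        for sample in samples:
            if spec.missing_rate and rng.random() < spec.missing_rate:
                cells.append("./.:.")
                continue
            freqs = pop_freqs[pop_map[sample]]
            i, j = rng.choice(n_alleles, size=2, p=freqs)
            genotypes[(record.locus_id, sample)] = (int(i), int(j))
            cells.append(f"{i}/{j}:{len(alleles[i])},{len(alleles[j])}")

        alt = ",".join(alleles[1:]) if len(alleles) > 1 else "."
        body_lines.append(
            "\t".join(
                [
                    record.chrom,
                    str(record.start + 1),
                    record.locus_id,
                    ref,
                    alt,
                    ".",
                    "PASS",
                    f"END={record.end};MOTIF={motif}",
                    "GT:AL",
                    *cells,
                ]
            )
        )

    chroms = sorted({r.chrom for r in catalog})
    if chrom_lengths is None:
        chrom_lengths = {
            c: max(r.end for r in catalog if r.chrom == c) + 1000 for c in chroms
        }
    contig_lines = "".join(
        f"##contig=<ID={c},length={chrom_lengths[c]}>\n" for c in chroms
    )
    header = (
        _VCF_HEADER
        + contig_lines
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    return CohortBundle(
        vcf_text=header + "\n".join(body_lines) + ("\n" if body_lines else ""),
        pop_map=pop_map,
        truth_frequencies=pd.DataFrame(freq_rows),
        genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for name in genome:
            handle.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_genome_pair(bundle: GenomePairBundle, outdir: str | Path) -> dict[str, Path]:
    """Write all genome-pair artifacts; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_a": outdir / "genome_a.fa",
        "genome_b": outdir / "genome_b.fa",
        "catalog_a": outdir / "catalog_a.bed",
        "catalog_b": outdir / "catalog_b.bed",
        "chain_ab": outdir / "a_to_b.chain",
        "chain_ba": outdir / "b_to_a.chain",
        "truth": outdir / "truth_homologs.tsv",
    }
    write_fasta(bundle.genome_a, paths["genome_a"])
    write_fasta(bundle.genome_b, paths["genome_b"])
    with open(paths["catalog_a"], "w") as handle:
        write_catalog_bed(bundle.catalog_a, handle)
    with open(paths["catalog_b"], "w") as handle:
        write_catalog_bed(bundle.catalog_b, handle)
    with open(paths["chain_ab"], "w") as handle:
        write_chain(bundle.chains_ab, handle)
    with open(paths["chain_ba"], "w") as handle:
        write_chain(bundle.chains_ba, handle)
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "pop_map": outdir / "pop_map.tsv",
        "truth_frequencies": outdir / "truth_allele_frequencies.tsv",
    }
    paths["vcf"].write_text(bundle.vcf_text)
    with open(paths["pop_map"], "w") as handle:
        for sample, pop in bundle.pop_map.items():
            handle.write(f"{sample}\t{pop}\n")
    bundle.truth_frequencies.to_csv(paths["truth_frequencies"], sep="\t", index=False)
    return paths
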