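"""Readers and writers for the formats the pipeline touches.

Internal coordinate convention: every interval is 0-based half-open.
VCF positions (1-based) and GFF3 intervals (1-based inclusive) are
converted at the boundary, never carried around internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from Bio import SeqIO
from cyvcf2 import VCF

log = logging.getLogger("xprime")

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class GenomeSequence:
    """Ordered map of sequence id -> uppercase A/C/G/T/N string."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains invalid symbol(s) "
                    f"{''.join(sorted(bad))!r}"
                )

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass
class VariantRecord:
    """One ALT allele at one site, with the genotype relative to that ALT.

    ``pos`` follows the VCF convention (1-based; indels anchored on the
    preceding base).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: Genotype = Genotype.HET
    sample_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref/alt alleles must be nonempty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class GeneModel:
    """A protein-coding gene as an ordered list of CDS segments.

    ``cds_segments`` are stored in 5'->3' transcription order: ascending
    genomic coordinates on the + strand, descending on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[GenomicInterval]
    phases: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.cds_segments:
            raise ValueError(f"gene {self.gene_id} has no CDS segments")
        ordered = sorted(self.cds_segments, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"gene {self.gene_id}: overlapping CDS segments "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        if self.cds_length < 3:
            raise ValueError(f"gene {self.gene_id}: CDS shorter than one codon")
        if not self.phases:
            self.phases = [0] * len(self.cds_segments)

    @property
    def cds_length(self) -> int:
        return sum(len(s) for s in self.cds_segments)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(s.start for s in self.cds_segments),
            max(s.end for s in self.cds_segments),
        )

    def genome_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcription order."""
        pos: list[int] = []
        for seg in self.cds_segments:
            if self.strand == "+":
                pos.extend(range(seg.start, seg.end))
            else:
                pos.extend(range(seg.end - 1, seg.start - 1, -1))
        return pos

    def cds_index_of(self) -> dict[int, int]:
        """Map genomic position -> 0-based index into the coding sequence."""
        return {p: i for i, p in enumerate(self.genome_positions())}

    def cds_sequence(self, genome: GenomeSequence) -> str:
        chrom = genome[self.chrom]
        parts = []
        for seg in self.cds_segments:
            parts.append(chrom[seg.start : seg.end])
        if self.strand == "+":
            return "".join(parts)
        return revcomp("".join(parts[::-1]))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file; lowercase is normalized, non-ACGTN rejected."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {rec.id!r} in {path} contains invalid symbol(s) "
                f"{''.join(sorted(bad))!r}"
            )
        if not seq:
            raise FormatError(f"record {rec.id!r} in {path} has an empty sequence")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"no records in {path}")
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (4-line records)
# ---------------------------------------------------------------------------


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as 4-line FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    reads: list[tuple[str, str]] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FormatError(f"truncated FASTQ record in {path}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FormatError(f"malformed FASTQ record in {path}")
            reads.append((header[1:].rstrip("\n").split()[0], seq.upper()))
    return reads


def iter_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, str]]:
    """Yield (pair id, mate1 seq, mate2 seq) from a pair of FASTQ files."""
    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise FormatError("mate files differ in read count")
    for (id1, s1), (_id2, s2) in zip(r1, r2):
        yield id1, s1, s2


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def read_vcf(
    path: str | Path, sample_id: str = "", replicate: int = 0
) -> list[VariantRecord]:
    """Read a single-sample VCF into VariantRecords.

    Multi-allelic sites are split into one record per ALT allele, with the
    genotype evaluated against that ALT only.
    """
    out: list[VariantRecord] = []
    vcf = VCF(str(path))
    for v in vcf:
        gt = v.genotypes[0] if v.genotypes else None
        alleles = gt[:-1] if gt else []
        for j, alt in enumerate(v.ALT, start=1):
            if not alleles or any(a < 0 for a in alleles):
                genotype = Genotype.MISSING
            else:
                n_alt = sum(1 for a in alleles if a == j)
                if n_alt == len(alleles):
                    genotype = Genotype.HOM_ALT
                elif n_alt >= 1:
                    genotype = Genotype.HET
                else:
                    genotype = Genotype.HOM_REF
            out.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    genotype=genotype,
                    sample_id=sample_id,
                    replicate=replicate,
                )
            )
    return out


def write_vcf(
    variants: Iterable[VariantRecord],
    path: str | Path,
    contigs: dict[str, int],
    sample: str = "sample",
) -> None:
    """Write biallelic records as a minimal single-sample VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for v in sorted(variants, key=lambda r: (r.chrom, r.pos, r.alt)):
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                f"{_GT_STRING[v.genotype]}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features into GeneModels.

    CDS segments are grouped per gene and returned in transcription order.
    A CDS whose parent chain does not reach a gene feature is an error;
    a CDS total length not divisible by 3 is kept with a warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene_ids = {g.id for g in db.features_of_type("gene")}
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds))
        if not any(p.featuretype == "gene" for p in parents):
            raise FormatError(f"CDS {cds.id or cds.start} has no parent gene")
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        segs: list[GenomicInterval] = []
        phases: list[int] = []
        for cds in db.children(gene, featuretype="CDS", order_by="start"):
            segs.append(GenomicInterval(gene.seqid, cds.start - 1, cds.end))
            phases.append(0 if cds.frame in (None, ".") else int(cds.frame))
        if not segs:
            continue
        if gene.strand == "-":
            segs = segs[::-1]
            phases = phases[::-1]
        model = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            cds_segments=segs, phases=phases,
        )
        if model.cds_length % 3 != 0:
            log.warning(
                "gene %s: CDS length %d not divisible by 3",
                model.gene_id, model.cds_length,
            )
        genes.append(model)
    if not gene_ids and not genes:
        log.warning("no gene features found in %s", path)
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span
            fh.write(
                f"{g.chrom}\txprime\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\txprime\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n"
            )
            for seg, phase in zip(g.cds_segments, g.phases):
                fh.write(
                    f"{g.chrom}\txprime\tCDS\t{seg.start + 1}\t{seg.end}\t.\t"
                    f"{g.strand}\t{phase}\tID={mrna_id}.cds;Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# BED (strata output)
# ---------------------------------------------------------------------------


def write_bed(
    intervals: Iterable[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Tunable knobs shared across the pipeline, with field-level defaults.

    A flat ``key = value`` text file can override any field; unknown keys
    are rejected so typos fail loudly.
    """

    k: int = 27
    window_bp: int = 100_000
    p0: float = 0.2
    w0: float = 0.2
    mcmc_iterations: int = 500
    mcmc_burnin: int = 50
    silencing_quantile: float = 0.001
    dc_log2fc_threshold: float = 0.5
    min_kmer_hits: int = 1
    syn_sites: str = "fractional"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.window_bp <= 0 or self.min_kmer_hits < 1:
            raise ValueError("k, window_bp and min_kmer_hits must be positive")
        if not (0 < self.p0 <= 1 and 0 < self.w0 <= 1):
            raise ValueError("p0 and w0 must lie in (0, 1]")
        if not (0 < self.silencing_quantile < 1):
            raise ValueError("silencing_quantile must lie in (0, 1)")
        if self.mcmc_burnin >= self.mcmc_iterations:
            raise ValueError("burn-in must be smaller than iteration count")
        if self.syn_sites not in ("fractional", "fourfold_only"):
            raise ValueError("syn_sites must be 'fractional' or 'fourfold_only'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kinds = {f.name: f.type for f in fields(cls)}
        kwargs: dict[str, object] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise FormatError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in kinds:
                    raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
                caster = {"int": int, "float": float, "str": str}[kinds[key]]
                kwargs[key] = caster(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")
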