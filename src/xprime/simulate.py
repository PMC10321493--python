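"""Synthetic study generator with machine-readable ground truth.

Emulates the data structure the pipeline consumes: an ancestral X
chromosome plus an autosome; a derived, female-limited X' carrying
piecewise-constant divergence (evolutionary strata); genes with intact
codon structure of which configurable fractions are pseudogenized
(frameshift, premature stop, start/stop loss) or transcriptionally
silenced; genotype-resolved paired-end reads (X0 haploid X, XX diploid,
X'X carrying one X and one X'); replicate variant-call files with
false-negative/false-positive noise and shared background polymorphisms;
and a negative-binomial expression matrix across life stages.

Stratum substitutions inside coding sequence are constrained to changes
that neither create nor destroy start/stop codons, so the disrupted-gene
truth set is exactly the set of injected disruption events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .effects import CODON_TO_AA, START_CODON
from .io import (
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    Genotype,
    VariantRecord,
    complement,
    revcomp,
    write_vcf,
)

BASES = "ACGT"
STOP_CODONS = tuple(sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] == "*"))
_NONSTOP_CODONS = tuple(
    sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*" and c != START_CODON)
)


@dataclass
class StratumSpec:
    """A stratum on the X with its per-site substitution probability."""

    interval: GenomicInterval
    divergence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.05):
            raise ValueError("divergence must lie in [0, 0.05]")


@dataclass
class TruthSet:
    """Ground truth of one synthetic run, for parameter-recovery tests."""

    strata: list[StratumSpec]
    realized_divergence: list[float]
    variants: dict[int, tuple[str, str]]  # X pos0 -> (ref, alt)
    background: list[tuple[int, str, str]]
    disrupted_genes: set[str]
    silenced_genes: set[str]
    ortholog_pairs: dict[str, str]
    events: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "strata": [
                {
                    "start": s.interval.start,
                    "end": s.interval.end,
                    "divergence": s.divergence,
                    "realized": r,
                }
                for s, r in zip(self.strata, self.realized_divergence)
            ],
            "variants": [[p, r, a] for p, (r, a) in sorted(self.variants.items())],
            "background": [list(b) for b in self.background],
            "disrupted_genes": sorted(self.disrupted_genes),
            "silenced_genes": sorted(self.silenced_genes),
            "ortholog_pairs": self.ortholog_pairs,
            "events": self.events,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path, chrom: str = "X") -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            strata=[
                StratumSpec(
                    GenomicInterval(chrom, s["start"], s["end"]), s["divergence"]
                )
                for s in d["strata"]
            ],
            realized_divergence=[s["realized"] for s in d["strata"]],
            variants={p: (r, a) for p, r, a in d["variants"]},
            background=[tuple(b) for b in d["background"]],
            disrupted_genes=set(d["disrupted_genes"]),
            silenced_genes=set(d["silenced_genes"]),
            ortholog_pairs=d["ortholog_pairs"],
            events=d["events"],
        )


@dataclass
class StudyConfig:
    """Desk-scale study conditions for the generator."""

    x_length: int = 2_000_000
    autosome_length: int = 2_000_000
    n_genes: int = 300
    mean_cds_codons: int = 250
    strata: list[StratumSpec] | None = None
    disrupted_fraction: float = 0.053
    silenced_fraction: float = 0.02
    coverage: float = 20.0
    read_len: int = 150
    insert: int = 350
    error_rate: float = 0.0
    fn_rate: float = 0.02
    fp_rate: float = 1e-6
    n_background: int = 50
    stages: int = 4
    dispersion: float = 0.1
    seed: int = 0


# published relative stratum lengths (Mb at full scale) and a divergence
# sequence in the observed range arranged so adjacent contrasts are >= 3x
_LAYOUT_LENGTHS_MB = (
    9.00, 0.50, 23.80, 1.00, 1.65, 0.10, 9.40, 0.10,
    2.55, 0.40, 1.50, 1.90, 1.30, 1.20, 3.50, 0.95,
)
_LAYOUT_DIVERGENCES = (
    0.0150, 0.0050, 0.0150, 0.0040, 0.0120, 0.0006, 0.0040, 0.0006,
    0.0130, 0.0040, 0.0130, 0.0040, 0.0140, 0.0045, 0.0140, 0.0045,
)


def default_strata(x_length: int = 2_000_000, chrom: str = "X") -> list[StratumSpec]:
    """Sixteen strata mirroring the published relative lengths, scaled
    1:30 onto a 2-Mb X (proportionally for other lengths)."""
    scale = x_length / 2_000_000
    lengths = [int(round(mb * 1e6 / 30 * scale)) for mb in _LAYOUT_LENGTHS_MB]
    total = sum(lengths)
    if total >= x_length:
        raise ValueError("chromosome too short for the stratum layout")
    offset = (x_length - total) // 2
    strata = []
    pos = offset
    for length, div in zip(lengths, _LAYOUT_DIVERGENCES):
        strata.append(StratumSpec(GenomicInterval(chrom, pos, pos + length), div))
        pos += length
    return strata


# ---------------------------------------------------------------------------
# genome and genes
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, length)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + internal non-stop codons + stop; translatable by construction."""
    body = "".join(
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), n_codons - 2)
    )
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    return START_CODON + body + stop


def simulate_genome(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    n_genes: int = 0,
    mean_cds_codons: int = 250,
    gene_chrom: str = "X",
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Random genome with non-overlapping, translatable genes on one
    chromosome; about half of the genes land on the minus strand."""
    records = {name: _random_sequence(rng, n) for name, n in chrom_lengths.items()}
    genes: list[GeneModel] = []
    if n_genes > 0:
        chrom_len = chrom_lengths[gene_chrom]
        chrom = list(records[gene_chrom])
        placed: list[tuple[int, int]] = []
        for g in range(n_genes):
            n_codons = max(10, int(rng.poisson(mean_cds_codons)))
            cds = _random_cds(rng, n_codons)
            length = len(cds)
            start = None
            for _ in range(500):
                cand = int(rng.integers(0, chrom_len - length))
                if all(
                    cand + length + 10 <= s or cand >= e + 10 for s, e in placed
                ):
                    start = cand
                    break
            if start is None:
                raise ValueError(
                    f"could not place gene {g + 1}/{n_genes} without overlap; "
                    "lower the gene density or enlarge the chromosome"
                )
            placed.append((start, start + length))
            strand = "+" if rng.random() < 0.5 else "-"
            insert_seq = cds if strand == "+" else revcomp(cds)
            chrom[start : start + length] = list(insert_seq)
            genes.append(
                GeneModel(
                    gene_id=f"g{len(genes) + 1:04d}",
                    chrom=gene_chrom,
                    strand=strand,
                    cds_segments=[GenomicInterval(gene_chrom, start, start + length)],
                )
            )
        records[gene_chrom] = "".join(chrom)
        genes.sort(key=lambda g: g.span.start)
    return GenomeSequence(records), genes


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------


def _allowed_substitutions(cds_seq: str, cds_idx: int) -> str:
    """Alternative CDS bases at a site that keep start/stop structure.

    Changes in the start codon, stop-destroying changes at the terminal
    codon and stop-creating changes anywhere are excluded so background
    divergence never pseudogenizes a gene.
    """
    codon_idx, within = divmod(cds_idx, 3)
    if codon_idx == 0:
        return ""
    codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    aa = CODON_TO_AA[codon]
    allowed = []
    for b in BASES:
        if b == codon[within]:
            continue
        alt = codon[:within] + b + codon[within + 1 :]
        alt_aa = CODON_TO_AA[alt]
        if aa == "*" and alt_aa != "*":
            continue
        if aa != "*" and alt_aa == "*":
            continue
        allowed.append(b)
    return "".join(allowed)


def apply_strata(
    x_seq: str,
    genes: list[GeneModel],
    strata: list[StratumSpec],
    rng: np.random.Generator,
) -> tuple[str, dict[int, tuple[str, str]], list[float]]:
    """Derive the X' sequence by substituting sites inside each stratum.

    Each site mutates independently with probability equal to the
    stratum divergence, choosing uniformly among the allowed alternative
    bases.  Sites outside every stratum are never touched.
    """
    for a, b in zip(strata, strata[1:]):
        if a.interval.end > b.interval.start:
            raise ValueError("strata must be sorted and non-overlapping")
    if strata and strata[-1].interval.end > len(x_seq):
        raise ValueError("strata exceed chromosome bounds")
    xprime = list(x_seq)
    pos_to_gene: dict[int, tuple[GeneModel, int, str]] = {}
    for gene in genes:
        cds_seq = gene.cds_sequence(GenomeSequence({gene.chrom: x_seq}))
        for i, p in enumerate(gene.genome_positions()):
            pos_to_gene[p] = (gene, i, cds_seq)
    variants: dict[int, tuple[str, str]] = {}
    realized: list[float] = []
    for stratum in strata:
        iv = stratum.interval
        hits = np.nonzero(rng.random(len(iv)) < stratum.divergence)[0]
        applied = 0
        for off in hits:
            pos = iv.start + int(off)
            ref = x_seq[pos]
            if pos in pos_to_gene:
                gene, cds_idx, cds_seq = pos_to_gene[pos]
                allowed_cds = _allowed_substitutions(cds_seq, cds_idx)
                if gene.strand == "-":
                    allowed = "".join(complement(b) for b in allowed_cds)
                else:
                    allowed = allowed_cds
                if not allowed:
                    continue
                alt = allowed[rng.integers(0, len(allowed))]
            else:
                choices = [b for b in BASES if b != ref]
                alt = choices[rng.integers(0, 3)]
            xprime[pos] = alt
            variants[pos] = (ref, alt)
            applied += 1
        realized.append(applied / len(iv))
    return "".join(xprime), variants, realized


# ---------------------------------------------------------------------------
# disruptions
# ---------------------------------------------------------------------------


def inject_disruptions(
    x_seq: str,
    xprime_seq: str,
    genes: list[GeneModel],
    fraction: float,
    rng: np.random.Generator,
    variants: dict[int, tuple[str, str]] | None = None,
) -> tuple[str, set[str], list[dict], dict[int, tuple[str, str]]]:
    """Give a fraction of genes exactly one pseudogenizing event each.

    Event types (uniform, resampled if a gene cannot host one):
    frameshift indel of 1-2 bp, premature stop, start-codon loss,
    stop-codon loss.  Substitutions are applied in place; indels are
    recorded VCF-style (anchored on the preceding base) and applied to
    the X' sequence right-to-left at the end so earlier X coordinates
    stay valid.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    variants = dict(variants or {})
    xprime = list(xprime_seq)
    n_target = int(np.floor(fraction * len(genes)))
    if rng.random() < fraction * len(genes) - n_target:
        n_target += 1
    n_target = min(n_target, len(genes))
    chosen = (
        [genes[i] for i in rng.choice(len(genes), size=n_target, replace=False)]
        if n_target
        else []
    )
    disrupted: set[str] = set()
    events: list[dict] = []
    indel_edits: list[tuple[int, int, str]] = []  # (anchor pos0, del_len, insert)

    def site_free(lo: int, hi: int) -> bool:
        return all(p not in variants for p in range(lo, hi))

    for gene in chosen:
        positions = gene.genome_positions()
        n_codons = len(positions) // 3
        cds_now = "".join(
            xprime[p] if gene.strand == "+" else complement(xprime[p])
            for p in positions
        )
        event = None
        for _ in range(40):
            kind = ("frameshift", "premature_stop", "start_loss", "stop_loss")[
                rng.integers(0, 4)
            ]
            if kind == "premature_stop" and n_codons >= 4:
                order = rng.permutation(np.arange(1, n_codons - 1))
                for codon_idx in order:
                    codon = cds_now[codon_idx * 3 : codon_idx * 3 + 3]
                    if CODON_TO_AA[codon] == "*":
                        continue
                    subs = []
                    for within in range(3):
                        for b in BASES:
                            if b == codon[within]:
                                continue
                            alt = codon[:within] + b + codon[within + 1 :]
                            if CODON_TO_AA[alt] == "*":
                                subs.append((int(codon_idx) * 3 + within, b))
                    rng.shuffle(subs)
                    for cds_idx, b in subs:
                        pos = positions[cds_idx]
                        if pos in variants:
                            continue
                        alt_genome = b if gene.strand == "+" else complement(b)
                        event = ("stop_gain", pos, x_seq[pos], alt_genome)
                        break
                    if event:
                        break
            elif kind == "start_loss":
                within = int(rng.integers(0, 3))
                pos = positions[within]
                if pos not in variants:
                    cur = START_CODON[within]
                    others = [b for b in BASES if b != cur]
                    b = others[rng.integers(0, 3)]
                    alt_genome = b if gene.strand == "+" else complement(b)
                    event = ("start_loss", pos, x_seq[pos], alt_genome)
            elif kind == "stop_loss":
                codon = cds_now[-3:]
                subs = []
                for within in range(3):
                    for b in BASES:
                        if b == codon[within]:
                            continue
                        alt = codon[:within] + b + codon[within + 1 :]
                        if CODON_TO_AA[alt] != "*":
                            subs.append((len(cds_now) - 3 + within, b))
                rng.shuffle(subs)
                for cds_idx, b in subs:
                    pos = positions[cds_idx]
                    if pos in variants:
                        continue
                    alt_genome = b if gene.strand == "+" else complement(b)
                    event = ("stop_loss", pos, x_seq[pos], alt_genome)
                    break
            elif kind == "frameshift":
                length = int(rng.integers(1, 3))
                seg = gene.cds_segments[0]
                lo, hi = seg.start + 3, seg.end - 3 - length - 1
                if hi <= lo:
                    continue
                anchor = int(rng.integers(lo, hi))
                if rng.random() < 0.5:  # deletion
                    if (
                        site_free(anchor, anchor + length + 1)
                        and "".join(xprime[anchor : anchor + length + 1])
                        == x_seq[anchor : anchor + length + 1]
                    ):
                        event = (
                            "frameshift_del",
                            anchor,
                            x_seq[anchor : anchor + length + 1],
                            x_seq[anchor],
                        )
                else:  # insertion
                    if anchor not in variants and xprime[anchor] == x_seq[anchor]:
                        ins = _random_sequence(rng, length)
                        event = (
                            "frameshift_ins",
                            anchor,
                            x_seq[anchor],
                            x_seq[anchor] + ins,
                        )
            if event:
                break
        if event is None:
            raise ValueError(f"could not place a disruption in gene {gene.gene_id}")
        kind, pos, ref, alt = event
        if kind in ("stop_gain", "start_loss", "stop_loss"):
            xprime[pos] = alt
            variants[pos] = (ref, alt)
        elif kind == "frameshift_del":
            variants[pos] = (ref, alt)
            indel_edits.append((pos, len(ref) - 1, ""))
        else:  # insertion
            variants[pos] = (ref, alt)
            indel_edits.append((pos, 0, alt[1:]))
        disrupted.add(gene.gene_id)
        events.append({"gene_id": gene.gene_id, "kind": kind, "pos": pos,
                       "ref": ref, "alt": alt})
    for anchor, del_len, ins in sorted(indel_edits, reverse=True):
        if del_len:
            del xprime[anchor + 1 : anchor + 1 + del_len]
        if ins:
            xprime[anchor + 1 : anchor + 1] = list(ins)
    return "".join(xprime), disrupted, events, variants


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

PLOIDY = {
    "X0": {"X": 1, "autosome": 2},
    "XX": {"X": 2, "autosome": 2},
    "XprimeX": {"X": 1, "Xprime": 1, "autosome": 2},
}


def simulate_reads(
    genomes: dict[str, str],
    genotype: str,
    coverage: float,
    rng: np.random.Generator,
    read_len: int = 150,
    insert: int = 350,
    error_rate: float = 0.0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Paired-end reads with per-genotype ploidy.

    ``coverage`` is the per-copy depth, so diploid templates receive
    twice the haploid read mass.  Read ids carry provenance as
    genotype.serial:template:fragment_start:fragment_end.
    """
    if genotype not in PLOIDY:
        raise ValueError(f"unknown genotype {genotype!r}")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    ploidy = PLOIDY[genotype]
    templates: list[tuple[str, int]] = []
    for name in genomes:
        if name in ("X", "Xprime"):
            copies = ploidy.get(name, 0)
        else:
            copies = ploidy["autosome"]
        if copies:
            templates.append((name, copies))
    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    serial = 0
    base_arr = np.array(list(BASES))
    for name, copies in templates:
        seq = genomes[name]
        if read_len > len(seq):
            raise ValueError(f"read_len exceeds template {name!r}")
        if insert > len(seq) or insert < read_len:
            raise ValueError("insert must satisfy read_len <= insert <= template")
        n_pairs = int(round(copies * coverage * len(seq) / (2.0 * read_len)))
        starts = rng.integers(0, len(seq) - insert + 1, n_pairs)
        for s in starts:
            frag = seq[s : s + insert]
            m1 = frag[:read_len]
            m2 = revcomp(frag)[:read_len]
            if error_rate > 0:
                m1 = _with_errors(m1, error_rate, rng, base_arr)
                m2 = _with_errors(m2, error_rate, rng, base_arr)
            rid = f"{genotype}.{serial}:{name}:{s}:{s + insert}"
            r1.append((rid, m1))
            r2.append((rid, m2))
            serial += 1
    return r1, r2


def _with_errors(
    seq: str, rate: float, rng: np.random.Generator, base_arr: np.ndarray
) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def parse_read_id(rid: str) -> tuple[str, str, int, int]:
    """(genotype.serial, template, fragment start, fragment end)."""
    serial, template, start, end = rid.rsplit(":", 3)
    return serial, template, int(start), int(end)


# ---------------------------------------------------------------------------
# variant-call files
# ---------------------------------------------------------------------------


def emit_replicate_vcfs(
    truth_variants: dict[int, tuple[str, str]],
    background: list[tuple[int, str, str]],
    x_seq: str,
    outdir: str | Path,
    rng: np.random.Generator,
    chrom: str = "X",
    fn_rate: float = 0.02,
    fp_rate: float = 1e-6,
    replicates: int = 2,
) -> dict[tuple[str, int], Path]:
    """Noisy replicate call sets per genotype, against the X reference.

    The X'X genotype sees the true X-X' differences as het calls (each
    dropped independently at ``fn_rate``) plus the shared background;
    the X0 genotype sees only background.  Both gain Poisson false het
    calls at ``fp_rate`` per bp.
    """
    if not (0 <= fn_rate < 1 and 0 <= fp_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[tuple[str, int], Path] = {}
    occupied = set(truth_variants) | {p for p, _r, _a in background}
    for genotype in ("XprimeX", "X0"):
        for rep in range(1, replicates + 1):
            records: list[VariantRecord] = []
            if genotype == "XprimeX":
                for pos, (ref, alt) in truth_variants.items():
                    if rng.random() < fn_rate:
                        continue
                    records.append(
                        VariantRecord(chrom, pos + 1, ref, alt, Genotype.HET,
                                      genotype, rep)
                    )
            for pos, ref, alt in background:
                if rng.random() < fn_rate:
                    continue
                records.append(
                    VariantRecord(chrom, pos + 1, ref, alt, Genotype.HET,
                                  genotype, rep)
                )
            n_fp = rng.poisson(fp_rate * len(x_seq))
            for _ in range(n_fp):
                pos = int(rng.integers(0, len(x_seq)))
                if pos in occupied:
                    continue
                ref = x_seq[pos]
                alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
                records.append(
                    VariantRecord(chrom, pos + 1, ref, alt, Genotype.HET,
                                  genotype, rep)
                )
            path = outdir / f"{genotype}_rep{rep}.vcf"
            write_vcf(records, path, contigs={chrom: len(x_seq)},
                      sample=f"{genotype}_rep{rep}")
            paths[(genotype, rep)] = path
    return paths


def draw_background(
    x_seq: str,
    n_background: int,
    rng: np.random.Generator,
    exclude: set[int] | None = None,
) -> list[tuple[int, str, str]]:
    """Shared X polymorphisms seen by every genotype (het in all calls)."""
    exclude = exclude or set()
    out: list[tuple[int, str, str]] = []
    taken: set[int] = set()
    while len(out) < n_background:
        pos = int(rng.integers(0, len(x_seq)))
        if pos in exclude or pos in taken:
            continue
        ref = x_seq[pos]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        out.append((pos, ref, alt))
        taken.add(pos)
    return sorted(out)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: list[GeneModel],
    ortholog_pairs: dict[str, str],
    silenced_genes: set[str],
    rng: np.random.Generator,
    stages: int = 4,
    dispersion: float = 0.1,
    mean_expression: float = 200.0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial counts for X and X' gene copies across stages.

    Columns cover the X'X carrier (read counts binned by chromosome of
    origin, one haploid copy each) and the XX reference karyotype
    (diploid X).  Silenced genes have zero counts in every X'-origin
    sample.  Returns (counts, gene lengths, sample metadata).
    """
    if stages < 1:
        raise ValueError("need at least one stage")
    n_nb = 1.0 / dispersion
    gene_ids = [g.gene_id for g in genes]
    xp_ids = [ortholog_pairs[g] for g in gene_ids]
    mu = mean_expression * rng.lognormal(0.0, 0.7, len(genes))
    stage_factor = rng.lognormal(0.0, 0.2, stages)
    lengths = pd.Series(
        {**{g.gene_id: g.cds_length for g in genes},
         **{ortholog_pairs[g.gene_id]: g.cds_length for g in genes}},
        name="length",
    )
    index = gene_ids + xp_ids
    counts: dict[str, np.ndarray] = {}
    meta_rows = []

    def nb(mean_vec: np.ndarray) -> np.ndarray:
        p = n_nb / (n_nb + mean_vec)
        return rng.negative_binomial(n_nb, p)

    silenced_mask = np.array([g in silenced_genes for g in gene_ids], dtype=bool)
    for s in range(stages):
        m = mu * stage_factor[s]
        col_x = f"XprimeX_s{s + 1}_X"
        counts[col_x] = np.concatenate([nb(m), np.zeros(len(genes), dtype=np.int64)])
        meta_rows.append(
            {"sample": col_x, "genotype": "XprimeX", "stage": f"s{s + 1}",
             "origin": "X"}
        )
        col_xp = f"XprimeX_s{s + 1}_Xp"
        xp_counts = nb(m)
        xp_counts[silenced_mask] = 0
        counts[col_xp] = np.concatenate(
            [np.zeros(len(genes), dtype=np.int64), xp_counts]
        )
        meta_rows.append(
            {"sample": col_xp, "genotype": "XprimeX", "stage": f"s{s + 1}",
             "origin": "Xprime"}
        )
        col_xx = f"XX_s{s + 1}"
        counts[col_xx] = np.concatenate(
            [nb(2.0 * m), np.zeros(len(genes), dtype=np.int64)]
        )
        meta_rows.append(
            {"sample": col_xx, "genotype": "XX", "stage": f"s{s + 1}",
             "origin": "X"}
        )
    frame = pd.DataFrame(counts, index=index)
    return frame, lengths, pd.DataFrame(meta_rows)


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    config: StudyConfig
    genome: GenomeSequence  # X + autosome (the reference the calls are against)
    genes: list[GeneModel]
    xprime_seq: str
    truth: TruthSet
    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_meta: pd.DataFrame

    def reads(self, genotype: str, rng: np.random.Generator):
        genomes = dict(self.genome.records)
        if genotype == "XprimeX":
            genomes["Xprime"] = self.xprime_seq
        return simulate_reads(
            genomes,
            genotype,
            self.config.coverage,
            rng,
            read_len=self.config.read_len,
            insert=self.config.insert,
            error_rate=self.config.error_rate,
        )

    def write_vcfs(self, outdir: str | Path, rng: np.random.Generator):
        return emit_replicate_vcfs(
            self.truth.variants,
            self.truth.background,
            self.genome["X"],
            outdir,
            rng,
            fn_rate=self.config.fn_rate,
            fp_rate=self.config.fp_rate,
        )


def simulate_study(config: StudyConfig) -> SyntheticStudy:
    """Full deterministic study build from one seed."""
    rng = np.random.default_rng(config.seed)
    chrom_lengths = {"X": config.x_length}
    if config.autosome_length:
        chrom_lengths["A1"] = config.autosome_length
    genome, genes = simulate_genome(
        rng, chrom_lengths, config.n_genes, config.mean_cds_codons, gene_chrom="X"
    )
    strata = config.strata or default_strata(config.x_length)
    xprime, variants, realized = apply_strata(genome["X"], genes, strata, rng)
    xprime, disrupted, events, variants = inject_disruptions(
        genome["X"], xprime, genes, config.disrupted_fraction, rng, variants
    )
    pairs = {g.gene_id: f"{g.gene_id}_xp" for g in genes}
    remaining = [g.gene_id for g in genes if g.gene_id not in disrupted]
    n_sil = int(round(config.silenced_fraction * len(genes)))
    silenced = (
        set(np.array(remaining)[rng.choice(len(remaining), n_sil, replace=False)])
        if n_sil and remaining
        else set()
    )
    background = draw_background(
        genome["X"], config.n_background, rng, exclude=set(variants)
    )
    truth = TruthSet(
        strata=strata,
        realized_divergence=realized,
        variants=variants,
        background=background,
        disrupted_genes=disrupted,
        silenced_genes=silenced,
        ortholog_pairs=pairs,
        events=events,
    )
    counts, lengths, meta = simulate_expression(
        genes,
        pairs,
        silenced,
        rng,
        stages=config.stages,
        dispersion=config.dispersion,
    )
    return SyntheticStudy(
        config=config,
        genome=genome,
        genes=genes,
        xprime_seq=xprime,
        truth=truth,
        counts=counts,
        gene_lengths=lengths,
        sample_meta=meta,
    )
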