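"""Consequence annotation of SNVs and indels against gene models.

Classifies each (variant, gene) pair into a single effect under a fixed
severity order, and annotates per-site codon degeneracy so that per-gene
synonymous-site counts S can feed the neutral divergence clock.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import GeneModel, GenomeSequence, VariantRecord, complement

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

START_CODON = "ATG"
BASES = "ACGT"


class EffectType(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    START_LOSS = "start_loss"
    START_GAIN = "start_gain"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    NONCODING = "noncoding"


#: effects that pseudogenize a gene (loss/gain of start or stop, frameshift)
DISRUPTIVE = frozenset(
    {
        EffectType.FRAMESHIFT,
        EffectType.STOP_GAIN,
        EffectType.STOP_LOSS,
        EffectType.START_LOSS,
        EffectType.START_GAIN,
    }
)


@dataclass
class AnnotatedVariant:
    variant: VariantRecord
    gene_id: str | None
    effect: EffectType
    codon_change: tuple[str, str] | None = None


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the reference genome."""


def _check_reference(genome: GenomeSequence, variant: VariantRecord) -> None:
    chrom = genome[variant.chrom]
    pos0 = variant.pos - 1
    observed = chrom[pos0 : pos0 + len(variant.ref)]
    if observed != variant.ref:
        raise ReferenceMismatchError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"VCF says {variant.ref!r}, genome has {observed!r}"
        )


def classify_snv(
    gene: GeneModel,
    genome: GenomeSequence,
    variant: VariantRecord,
    cds_index: dict[int, int] | None = None,
    cds_seq: str | None = None,
) -> AnnotatedVariant:
    """Classify a single-base substitution against one gene.

    The variant's alleles are given on the genome (+) strand; they are
    complemented for minus-strand genes before codon lookup.  Severity
    order when several descriptions apply:
    start_loss > stop_gain > stop_loss > missense > synonymous.
    """
    if not variant.is_snv:
        raise ValueError("classify_snv expects a 1-bp substitution")
    _check_reference(genome, variant)
    pos0 = variant.pos - 1
    if cds_index is None:
        cds_index = gene.cds_index_of()
    if variant.chrom != gene.chrom or pos0 not in cds_index:
        return AnnotatedVariant(variant, gene.gene_id, EffectType.NONCODING)
    if cds_seq is None:
        cds_seq = gene.cds_sequence(genome)
    i = cds_index[pos0]
    codon_idx, within = divmod(i, 3)
    ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    alt_base = variant.alt if gene.strand == "+" else complement(variant.alt)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    change = (ref_codon, alt_codon)
    if codon_idx == 0 and ref_codon == START_CODON and alt_codon != START_CODON:
        return AnnotatedVariant(variant, gene.gene_id, EffectType.START_LOSS, change)
    aa_ref = CODON_TO_AA[ref_codon]
    aa_alt = CODON_TO_AA[alt_codon]
    if aa_alt == "*" and aa_ref != "*":
        effect = EffectType.STOP_GAIN
    elif aa_ref == "*" and aa_alt != "*":
        effect = EffectType.STOP_LOSS
    elif aa_ref == aa_alt:
        effect = EffectType.SYNONYMOUS
    else:
        effect = EffectType.MISSENSE
    return AnnotatedVariant(variant, gene.gene_id, effect, change)


def classify_indel(
    gene: GeneModel,
    genome: GenomeSequence,
    variant: VariantRecord,
    cds_positions: set[int] | None = None,
) -> AnnotatedVariant:
    """Classify a VCF-anchored insertion or deletion against one gene.

    The net CDS-overlapping length change L decides the effect:
    L == 0 -> noncoding, L % 3 != 0 -> frameshift, else inframe_indel.
    """
    if not variant.is_indel:
        raise ValueError("classify_indel expects an insertion or deletion")
    _check_reference(genome, variant)
    if cds_positions is None:
        cds_positions = set(gene.cds_index_of())
    if variant.chrom != gene.chrom:
        return AnnotatedVariant(variant, gene.gene_id, EffectType.NONCODING)
    pos0 = variant.pos - 1
    net = 0
    # bases deleted relative to the reference, after the anchor base
    for p in range(pos0 + 1, pos0 + len(variant.ref)):
        if p in cds_positions:
            net -= 1
    inserted = len(variant.alt) - 1 if len(variant.alt) > len(variant.ref) else 0
    if inserted and pos0 in cds_positions and pos0 + 1 in cds_positions:
        net += len(variant.alt) - len(variant.ref)
    if net == 0:
        return AnnotatedVariant(variant, gene.gene_id, EffectType.NONCODING)
    effect = EffectType.FRAMESHIFT if net % 3 != 0 else EffectType.INFRAME_INDEL
    return AnnotatedVariant(variant, gene.gene_id, effect)


def annotate_variant(
    gene: GeneModel, genome: GenomeSequence, variant: VariantRecord
) -> AnnotatedVariant:
    if variant.is_snv:
        return classify_snv(gene, genome, variant)
    return classify_indel(gene, genome, variant)


def annotate_variants(
    genes: list[GeneModel],
    genome: GenomeSequence,
    variants: list[VariantRecord],
) -> list[AnnotatedVariant]:
    """Annotate each variant against the gene whose span covers it.

    Variants outside every gene span are reported as noncoding with no
    gene id.  Gene spans are assumed non-overlapping (as in the
    synthetic annotations); the first covering gene wins otherwise.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: g.span.start)
    starts = {
        chrom: np.array([g.span.start for g in glist])
        for chrom, glist in by_chrom.items()
    }
    cache: dict[str, tuple[dict[int, int], str, set[int]]] = {}
    out: list[AnnotatedVariant] = []
    for v in variants:
        glist = by_chrom.get(v.chrom, [])
        gene = None
        if glist:
            i = int(np.searchsorted(starts[v.chrom], v.pos - 1, side="right")) - 1
            # an indel can reach into the next gene's span from upstream
            for j in (i, i + 1):
                if 0 <= j < len(glist):
                    g = glist[j]
                    lo, hi = v.pos - 1, v.pos - 1 + max(len(v.ref), 1)
                    if g.span.overlap(lo, hi) > 0:
                        gene = g
                        break
        if gene is None:
            out.append(AnnotatedVariant(v, None, EffectType.NONCODING))
            continue
        if gene.gene_id not in cache:
            idx = gene.cds_index_of()
            cache[gene.gene_id] = (idx, gene.cds_sequence(genome), set(idx))
        idx, cds_seq, pos_set = cache[gene.gene_id]
        if v.is_snv:
            out.append(classify_snv(gene, genome, v, idx, cds_seq))
        else:
            out.append(classify_indel(gene, genome, v, pos_set))
    return out


# ---------------------------------------------------------------------------
# degeneracy annotation and synonymous-site counting
# ---------------------------------------------------------------------------

_DEGENERACY_NAME = {0: "0-fold", 1: "2-fold", 2: "3-fold", 3: "4-fold"}


@dataclass
class DegeneracyAnnotation:
    """Per-CDS-site degeneracy and the gene's synonymous site count S.

    ``syn_alternatives[i]`` is the number of the 3 alternative bases at
    CDS site i that preserve the encoded amino acid (stop counted as an
    amino acid, so stop-retaining changes are synonymous).  Fractional
    counting: each site contributes syn_alternatives/3 to S.
    """

    gene_id: str
    syn_alternatives: np.ndarray
    S: float
    S_fourfold: float

    @property
    def site_classes(self) -> list[str]:
        return [_DEGENERACY_NAME[int(s)] for s in self.syn_alternatives]


def annotate_degeneracy(gene: GeneModel, genome: GenomeSequence) -> DegeneracyAnnotation:
    cds = gene.cds_sequence(genome)
    if len(cds) % 3 != 0:
        raise ValueError(
            f"gene {gene.gene_id}: CDS length {len(cds)} not divisible by 3"
        )
    syn = np.zeros(len(cds), dtype=np.int64)
    for codon_idx in range(len(cds) // 3):
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        aa = CODON_TO_AA[codon]
        for within in range(3):
            n_syn = 0
            for b in BASES:
                if b == codon[within]:
                    continue
                alt = codon[:within] + b + codon[within + 1 :]
                if CODON_TO_AA[alt] == aa:
                    n_syn += 1
            syn[codon_idx * 3 + within] = n_syn
    return DegeneracyAnnotation(
        gene_id=gene.gene_id,
        syn_alternatives=syn,
        S=float(syn.sum()) / 3.0,
        S_fourfold=float(np.count_nonzero(syn == 3)),
    )


def degeneracy_table(
    genes: list[GeneModel], genome: GenomeSequence
) -> dict[str, DegeneracyAnnotation]:
    """Annotate all genes, skipping (with a warning) broken CDS lengths."""
    import logging

    out: dict[str, DegeneracyAnnotation] = {}
    for gene in genes:
        try:
            out[gene.gene_id] = annotate_degeneracy(gene, genome)
        except ValueError as exc:
            logging.getLogger("xprime").warning("skipping gene: %s", exc)
    return out


def per_gene_synonymous(
    genes: list[GeneModel],
    genome: GenomeSequence,
    annotated: list[AnnotatedVariant],
    syn_sites: str = "fractional",
) -> pd.DataFrame:
    """Per-gene synonymous variant count V and synonymous site count S."""
    v_counts = Counter(
        a.gene_id for a in annotated if a.effect is EffectType.SYNONYMOUS and a.gene_id
    )
    degen = degeneracy_table(genes, genome)
    rows = []
    for gene in genes:
        if gene.gene_id not in degen:
            continue
        d = degen[gene.gene_id]
        s = d.S if syn_sites == "fractional" else d.S_fourfold
        rows.append(
            {"gene_id": gene.gene_id, "V": v_counts.get(gene.gene_id, 0), "S": s}
        )
    return pd.DataFrame(rows, columns=["gene_id", "V", "S"])
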