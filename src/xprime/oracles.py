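"""Brute-force reference implementations used only to check faster code.

These deliberately avoid the coordinate arithmetic of the production
annotator: the variant is applied to the coding sequence itself and the
effect is read off the translated proteins.
"""

from __future__ import annotations

from .effects import CODON_TO_AA, START_CODON, EffectType
from .io import GeneModel, GenomeSequence, complement


def translate(cds: str) -> str:
    """Translate a CDS (length divisible by 3) into amino acids, '*' = stop."""
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds) - 2, 3))


def _first_stop(protein: str) -> int:
    i = protein.find("*")
    return i if i >= 0 else len(protein)


def translation_effect(cds_ref: str, cds_alt: str) -> EffectType:
    """Effect of an edit, decided purely from the two coding sequences.

    Mirrors the production severity order but derives every call from a
    full translation of the edited CDS rather than codon arithmetic.
    """
    if cds_ref == cds_alt:
        raise ValueError("sequences are identical; no variant applied")
    if len(cds_alt) % 3 != 0:
        return EffectType.FRAMESHIFT
    if len(cds_alt) != len(cds_ref):
        return EffectType.INFRAME_INDEL
    if cds_ref[:3] == START_CODON and cds_alt[:3] != START_CODON:
        return EffectType.START_LOSS
    prot_ref = translate(cds_ref)
    prot_alt = translate(cds_alt)
    if _first_stop(prot_alt) < _first_stop(prot_ref):
        return EffectType.STOP_GAIN
    if prot_ref.endswith("*") and not prot_alt.endswith("*"):
        return EffectType.STOP_LOSS
    if prot_ref == prot_alt:
        return EffectType.SYNONYMOUS
    return EffectType.MISSENSE


def snv_effect_by_translation(
    gene: GeneModel, genome: GenomeSequence, pos0: int, alt: str
) -> EffectType:
    """Translation-oracle effect of a genome-strand substitution at pos0."""
    cds_index = gene.cds_index_of()
    if pos0 not in cds_index:
        return EffectType.NONCODING
    cds_ref = gene.cds_sequence(genome)
    i = cds_index[pos0]
    alt_base = alt if gene.strand == "+" else complement(alt)
    cds_alt = cds_ref[:i] + alt_base + cds_ref[i + 1 :]
    return translation_effect(cds_ref, cds_alt)


def synonymous_sites_by_enumeration(cds: str) -> float:
    """Gene S by exhaustively mutating every site to every alternative."""
    total = 0
    for i, base in enumerate(cds):
        codon_idx, within = divmod(i, 3)
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        aa = CODON_TO_AA[codon]
        for b in "ACGT":
            if b == base:
                continue
            alt = codon[:within] + b + codon[within + 1 :]
            if CODON_TO_AA[alt] == aa:
                total += 1
    return total / 3.0
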