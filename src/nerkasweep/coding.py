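"""Coding-effect annotation of SNPs and indels against an exon model.

The exon model is a set of ordered, non-overlapping intervals on the
reference allele (1-based, inclusive, GFF-style), a strand, and a
reading-frame offset (bases to skip at the CDS 5' end).  SNPs falling in
exons are translated through the standard genetic code; exonic indels
are flagged frameshift when their length is not a multiple of three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .variants import Indel, Snp, VariantSet

__all__ = ["ExonAnnotation", "SnpEffect", "IndelEffect", "CodingEffectReport", "coding_effect"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ExonAnnotation:
    """Exon intervals on the reference allele.

    intervals : ordered, non-overlapping (start, end) pairs, 1-based inclusive.
    strand : "+" or "-".
    frame : 0, 1 or 2 bases skipped at the CDS 5' end before the first codon.
    """

    intervals: tuple[tuple[int, int], ...]
    strand: str = "+"
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame}")
        prev_end = 0
        for start, end in self.intervals:
            if start < 1 or end < start:
                raise ValueError(f"bad exon interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError("exon intervals must be ordered and non-overlapping")
            prev_end = end
        if (self.coding_length - self.frame) % 3 != 0:
            raise ValueError(
                f"coding length {self.coding_length} minus frame {self.frame} "
                "is not divisible by 3"
            )

    @property
    def coding_length(self) -> int:
        return sum(end - start + 1 for start, end in self.intervals)

    def contains(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.intervals)

    def cds_index(self, position: int) -> int | None:
        """0-based index of a reference position within the (frame-trimmed) CDS.

        Returns None for non-exonic positions or positions inside the
        skipped frame offset.
        """
        offset = 0
        spliced = None
        for start, end in self.intervals:
            if start <= position <= end:
                spliced = offset + (position - start)
                break
            offset += end - start + 1
        if spliced is None:
            return None
        if self.strand == "-":
            spliced = self.coding_length - 1 - spliced
        spliced -= self.frame
        return spliced if spliced >= 0 else None


def _spliced_cds(ref_seq: str, exons: ExonAnnotation) -> str:
    for start, end in exons.intervals:
        if end > len(ref_seq):
            raise ValueError(
                f"exon interval ({start}, {end}) outside sequence of length {len(ref_seq)}"
            )
    cds = "".join(ref_seq[start - 1 : end] for start, end in exons.intervals)
    if exons.strand == "-":
        cds = cds.translate(_COMPLEMENT)[::-1]
    return cds[exons.frame :]


@dataclass(frozen=True)
class SnpEffect:
    snp: Snp
    effect: str  # "synonymous" | "non-synonymous" | "noncoding"
    codon_ref: str = ""
    codon_alt: str = ""
    aa_ref: str = ""
    aa_alt: str = ""


@dataclass(frozen=True)
class IndelEffect:
    indel: Indel
    exonic: bool
    frameshift: bool


@dataclass
class CodingEffectReport:
    snp_effects: list[SnpEffect]
    indel_effects: list[IndelEffect]

    @property
    def n_non_synonymous(self) -> int:
        return sum(e.effect == "non-synonymous" for e in self.snp_effects)

    @property
    def n_synonymous(self) -> int:
        return sum(e.effect == "synonymous" for e in self.snp_effects)

    @property
    def n_coding_snps(self) -> int:
        return sum(e.effect != "noncoding" for e in self.snp_effects)


def coding_effect(variants: VariantSet, exons: ExonAnnotation, ref_seq: str) -> CodingEffectReport:
    """Classify SNPs as synonymous/non-synonymous/noncoding; flag frameshifts.

    The alternate base is substituted into the spliced, strand-oriented
    CDS and both codons translated with the standard genetic code.
    """
    ref_seq = ref_seq.upper()
    cds = _spliced_cds(ref_seq, exons)

    snp_effects: list[SnpEffect] = []
    for snp in variants.snps:
        idx = exons.cds_index(snp.position)
        if idx is None:
            snp_effects.append(SnpEffect(snp=snp, effect="noncoding"))
            continue
        alt = snp.alt if exons.strand == "+" else snp.alt.translate(_COMPLEMENT)
        codon_i = idx // 3
        codon_ref = cds[codon_i * 3 : codon_i * 3 + 3]
        if len(codon_ref) < 3:  # trailing partial codon
            snp_effects.append(SnpEffect(snp=snp, effect="noncoding"))
            continue
        within = idx % 3
        codon_alt = codon_ref[:within] + alt + codon_ref[within + 1 :]
        aa_ref = str(Seq(codon_ref).translate())
        aa_alt = str(Seq(codon_alt).translate())
        effect = "synonymous" if aa_ref == aa_alt else "non-synonymous"
        snp_effects.append(
            SnpEffect(
                snp=snp,
                effect=effect,
                codon_ref=codon_ref,
                codon_alt=codon_alt,
                aa_ref=aa_ref,
                aa_alt=aa_alt,
            )
        )

    indel_effects = []
    for indel in variants.indels:
        # an indel touches the CDS if any affected/anchored position is exonic
        if indel.kind == "deletion":
            touched = range(indel.position + 1, indel.position + indel.length + 1)
            exonic = any(exons.contains(p) for p in touched)
        else:
            exonic = exons.contains(indel.position) and exons.contains(indel.position + 1)
        indel_effects.append(
            IndelEffect(indel=indel, exonic=exonic, frameshift=exonic and indel.length % 3 != 0)
        )

    return CodingEffectReport(snp_effects=snp_effects, indel_effects=indel_effects)
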