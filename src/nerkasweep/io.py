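"""Readers and writers for the text formats the pipeline exchanges.

FASTA via Bio.SeqIO; variants as minimal VCF (1-based positions, indels
anchored on the preceding base) and CSV; similarity tracks as fixedStep
WIG and CSV; genotype tables and event logs as CSV/TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variants import SimilarityTrack, VariantSet


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_event_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, sep="\t", index=False)


def write_genotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_genotype_table(path) -> pd.DataFrame:
    from .genotypes import validate_genotype_table

    return validate_genotype_table(pd.read_csv(path, dtype=str))


def write_vcf(variants: VariantSet, ref_name: str, ref_seq: str, path) -> None:
    """Minimal VCF 4.2: SNPs as REF/ALT bases, indels anchored on the
    preceding reference base (EVLEN carries the event length)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref_name},length={len(ref_seq)}>",
        '##INFO=<ID=EVLEN,Number=1,Type=Integer,Description="Indel event length">',
        '##INFO=<ID=EVTYPE,Number=1,Type=String,Description="snp|insertion|deletion">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    entries = []
    for snp in variants.snps:
        entries.append((snp.position, snp.ref, snp.alt, 1, "snp"))
    for ind in variants.indels:
        if ind.position >= 1:  # anchored on the preceding reference base
            anchor = ref_seq[ind.position - 1]
            if ind.kind == "deletion":
                entries.append((ind.position, anchor + ind.sequence, anchor, ind.length, "deletion"))
            else:
                entries.append((ind.position, anchor, anchor + ind.sequence, ind.length, "insertion"))
        else:  # event at the very start: anchor on the following base instead
            if ind.kind == "deletion":
                nxt = ref_seq[ind.length]
                entries.append((1, ind.sequence + nxt, nxt, ind.length, "deletion"))
            else:
                nxt = ref_seq[0]
                entries.append((1, nxt, ind.sequence + nxt, ind.length, "insertion"))
    for pos, ref, alt, length, kind in sorted(entries):
        lines.append(f"{ref_name}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tEVLEN={length};EVTYPE={kind}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_variants_csv(variants: VariantSet, path) -> None:
    variants.to_frame().to_csv(path, index=False)


def write_wig(track: SimilarityTrack, chrom: str, path) -> None:
    lines = [f"fixedStep chrom={chrom} start=1 step=1"]
    lines.extend(f"{v:.4f}" for v in track.values)
    Path(path).write_text("\n".join(lines) + "\n")


def write_track_csv(track: SimilarityTrack, path) -> None:
    track.to_frame().to_csv(path, index=False)
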