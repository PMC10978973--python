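"""Deterministic text writers for the simulator's FASTA / GFF3 / VCF output.

Writers are plain-text and fully deterministic so that identical
configuration + seed yields byte-identical files (a contract the test
suite asserts).  Reading goes through the established parsers
(cyvcf2, Bio.SeqIO, gffutils) elsewhere in the package.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .effects import TranscriptModel, _utr_intervals

__all__ = ["write_fasta", "write_gff3", "write_vcf"]


def write_fasta(path: str, seqs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(
    path: str,
    transcripts: Iterable[TranscriptModel],
    chrom_lengths: Mapping[str, int],
) -> None:
    """Emit gene/mRNA/exon/CDS/UTR features, grouped per gene."""
    lines = ["##gff-version 3"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##sequence-region {chrom} 1 {length}")

    def feat(chrom, ftype, start, end, strand, attrs):
        attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
        return f"{chrom}\tsibline\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attr_s}"

    for tx in transcripts:
        gid, tid = tx.gene_id, tx.transcript_id
        lines.append(
            feat(tx.chrom, "gene", tx.start, tx.end, tx.strand, {"ID": gid})
        )
        lines.append(
            feat(
                tx.chrom, "mRNA", tx.start, tx.end, tx.strand,
                {
                    "ID": tid,
                    "Parent": gid,
                    "has_start": int(tx.has_start),
                    "has_stop": int(tx.has_stop),
                },
            )
        )
        for i, (s, e) in enumerate(tx.exons, 1):
            lines.append(
                feat(tx.chrom, "exon", s, e, tx.strand,
                     {"ID": f"{tid}.exon{i}", "Parent": tid})
            )
        cds_i = 0
        for s, e in tx.exons:
            lo, hi = max(s, tx.cds_start), min(e, tx.cds_end)
            if lo <= hi:
                cds_i += 1
                lines.append(
                    feat(tx.chrom, "CDS", lo, hi, tx.strand,
                         {"ID": f"{tid}.cds{cds_i}", "Parent": tid})
                )
        for which, ftype in (("utr5", "five_prime_UTR"), ("utr3", "three_prime_UTR")):
            for i, (s, e) in enumerate(_utr_intervals(tx, which), 1):
                lines.append(
                    feat(tx.chrom, ftype, s, e, tx.strand,
                         {"ID": f"{tid}.{which}.{i}", "Parent": tid})
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


VCF_INFO_HEADER = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence normalized by unfiltered depth">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand-bias Fisher exact test">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Rank sum test of REF vs ALT mapping qualities">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Rank sum test of REF vs ALT read position">',
]


def write_vcf(
    path: str,
    chrom_lengths: Mapping[str, int],
    samples: Sequence[str],
    records: Iterable[tuple],
) -> None:
    """Write a VCF v4.2 with phased GT and per-sample DP.

    ``records`` yields ``(chrom, pos, ref, alt, info_str, gt_pairs, dps)``
    where ``gt_pairs`` is a sequence of (a, b) allele indices per
    sample and ``dps`` the matching depths.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sibline\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for line in VCF_INFO_HEADER:
            fh.write(line + "\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth of informative coverage for each sample">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alt, info, gt_pairs, dps in records:
            cols = [chrom, str(pos), ".", ref, alt, ".", ".", info, "GT:DP"]
            cols += [f"{a}|{b}:{d}" for (a, b), d in zip(gt_pairs, dps)]
            fh.write("\t".join(cols) + "\n")
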