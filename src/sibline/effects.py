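"""Mini variant-effect caller for biallelic SNPs on a GFF3 annotation.

Classifies each SNP into six mutually exclusive genomic-location
classes (protein-coding, 2-bp splice junction, 5'-UTR, 3'-UTR, intron,
intergenic) and calls codon-level consequences (stop-gained,
start-lost, stop-lost, 2-bp splice-junction disruption, missense,
synonymous) from the reference sequence and transcript models.  A gene
is reported as "disrupted" in a sample when that sample is homozygous
for the alternate allele at a SNP whose effect on at least one
transcript of the gene is gene-breaking; heterozygous carriers never
qualify.

Class priority (most severe first):
    splice_junction_2bp > protein_coding > utr5 > utr3 > intron > intergenic
A base overlapped by several transcripts takes the most severe class.
The 2-bp junction outranks coding sequence so that the six classes
partition the genome exactly.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

__all__ = [
    "REGION_CLASSES",
    "TranscriptModel",
    "Annotation",
    "EffectCall",
    "AnnotationError",
    "ReferenceMismatchError",
    "load_transcripts",
    "classify_region",
    "region_composition",
    "composition_percentages",
    "call_effect",
    "effect_table",
    "disrupted_genes",
    "DISRUPTING_EFFECTS",
]

# severity-ordered: index is also the painting level (higher wins)
REGION_CLASSES = (
    "intergenic",
    "intron",
    "utr3",
    "utr5",
    "protein_coding",
    "splice_junction_2bp",
)
_SEVERITY = {name: i for i, name in enumerate(REGION_CLASSES)}

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS = tuple(sorted(set(CODON_TO_AA) - STOP_CODONS))

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

DISRUPTING_EFFECTS = frozenset(
    {"stop_gained", "start_lost", "stop_lost", "splice2_disrupt"}
)


class AnnotationError(ValueError):
    """Transcript model inconsistent with the genome it is placed on."""


class ReferenceMismatchError(ValueError):
    """VCF REF allele disagrees with the FASTA base at that position."""


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon/CDS structure of one transcript.

    ``exons`` are sorted, disjoint, 1-based closed genomic intervals;
    ``cds_start``/``cds_end`` bound the coding region in genomic
    coordinates regardless of strand.  ``has_start``/``has_stop`` flag
    annotation completeness: a transcript lacking an annotated start
    codon still gets codon-level calls but they are frame-tentative.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    has_start: bool = True
    has_stop: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if not (0 < s <= e):
                raise AnnotationError(f"bad exon ({s},{e})")
            if s <= prev_end:
                raise AnnotationError("exons overlap or are unsorted")
            prev_end = e
        if not (self.start <= self.cds_start <= self.cds_end <= self.end):
            raise AnnotationError("CDS span outside exon span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] - self.exons[i][1] > 1
        )

    def splice_sites(self) -> set[int]:
        """Genomic positions of the first/last 2 bases of every intron."""
        sites: set[int] = set()
        for s, e in self.introns:
            sites.update(range(s, min(s + 2, e + 1)))
            sites.update(range(max(e - 1, s), e + 1))
        return sites

    def cds_positions(self) -> np.ndarray:
        """Ascending genomic positions of coding bases (exons ∩ CDS span)."""
        pos: list[int] = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                pos.extend(range(lo, hi + 1))
        return np.asarray(pos, dtype=np.int64)

    def spliced_cds(self, seq: str) -> str:
        """Strand-corrected coding sequence from a chromosome string."""
        bases = [seq[p - 1] for p in self.cds_positions()]
        cds = "".join(bases)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    def classify(self, pos: int) -> str | None:
        """Region class of ``pos`` with respect to this transcript only."""
        if not self.start <= pos <= self.end:
            return None
        if pos in self.splice_sites():
            return "splice_junction_2bp"
        in_exon = any(s <= pos <= e for s, e in self.exons)
        if not in_exon:
            return "intron"
        if self.cds_start <= pos <= self.cds_end:
            return "protein_coding"
        upstream_of_cds = pos < self.cds_start
        if self.strand == "+":
            return "utr5" if upstream_of_cds else "utr3"
        return "utr3" if upstream_of_cds else "utr5"


class Annotation:
    """Transcript collection indexed by chromosome for overlap queries."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: list[TranscriptModel] = list(transcripts)
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for tx in self.transcripts:
            self._by_chrom.setdefault(tx.chrom, []).append(tx)
        for txs in self._by_chrom.values():
            txs.sort(key=lambda t: (t.start, t.end))

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        return [
            tx
            for tx in self._by_chrom.get(chrom, [])
            if tx.start <= pos <= tx.end
        ]

    def genes(self) -> set[str]:
        return {tx.gene_id for tx in self.transcripts}


def load_transcripts(gff_path: str) -> Annotation:
    """Read transcript models from a GFF3 file (via gffutils).

    Expects gene/mRNA/exon/CDS features with Parent links.  Optional
    mRNA attributes ``has_start``/``has_stop`` ("0"/"1") mark
    annotation completeness; they default to complete.
    """
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as fh:
        dbfn = fh.name
    try:
        db = gffutils.create_db(
            gff_path, dbfn, force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        transcripts = []
        for mrna in db.features_of_type("mRNA"):
            exons = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            )
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            if not exons or not cds:
                continue
            gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
            transcripts.append(
                TranscriptModel(
                    transcript_id=mrna.id,
                    gene_id=gene_id,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    exons=tuple(exons),
                    cds_start=min(s for s, _ in cds),
                    cds_end=max(e for _, e in cds),
                    has_start=mrna.attributes.get("has_start", ["1"])[0] == "1",
                    has_stop=mrna.attributes.get("has_stop", ["1"])[0] == "1",
                )
            )
    finally:
        os.unlink(dbfn)
    return Annotation(transcripts)


def classify_region(chrom: str, pos: int, annotation: Annotation) -> str:
    """Most severe region class of a position across all transcripts."""
    best = "intergenic"
    for tx in annotation.overlapping(chrom, pos):
        cls = tx.classify(pos)
        if cls is not None and _SEVERITY[cls] > _SEVERITY[best]:
            best = cls
    return best


def _paint_chromosome(length: int, transcripts: Sequence[TranscriptModel]) -> np.ndarray:
    """uint8 class-code array (0-based) for one chromosome, max-severity."""
    arr = np.zeros(length, dtype=np.uint8)  # intergenic
    # ascending severity so np.maximum keeps the most severe class
    for level, picker in (
        (_SEVERITY["intron"], lambda tx: [(tx.start, tx.end)]),
        (_SEVERITY["utr3"], lambda tx: _utr_intervals(tx, "utr3")),
        (_SEVERITY["utr5"], lambda tx: _utr_intervals(tx, "utr5")),
        (_SEVERITY["protein_coding"],
         lambda tx: [(max(s, tx.cds_start), min(e, tx.cds_end))
                     for s, e in tx.exons
                     if max(s, tx.cds_start) <= min(e, tx.cds_end)]),
        (_SEVERITY["splice_junction_2bp"],
         lambda tx: [(p, p) for p in sorted(tx.splice_sites())]),
    ):
        for tx in transcripts:
            if tx.end > length:
                raise AnnotationError(
                    f"transcript {tx.transcript_id} exceeds chromosome "
                    f"bounds ({tx.end} > {length})"
                )
            for s, e in picker(tx):
                seg = arr[s - 1 : e]
                np.maximum(seg, np.uint8(level), out=seg)
    return arr


def _utr_intervals(tx: TranscriptModel, which: str) -> list[tuple[int, int]]:
    """Exonic intervals outside the CDS span, on the requested side."""
    left = "utr5" if tx.strand == "+" else "utr3"
    out = []
    for s, e in tx.exons:
        if s < tx.cds_start:
            lo, hi = s, min(e, tx.cds_start - 1)
            if which == left:
                out.append((lo, hi))
        if e > tx.cds_end:
            lo, hi = max(s, tx.cds_end + 1), e
            if which != left:
                out.append((lo, hi))
    return out


def region_composition(
    annotation: Annotation, chrom_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Nucleotide count and percentage of each region class, genome-wide.

    Every base is assigned exactly one class by the painting priority,
    so counts sum to the genome length exactly.
    """
    counts = {name: 0 for name in REGION_CLASSES}
    by_chrom: dict[str, list[TranscriptModel]] = {c: [] for c in chrom_lengths}
    for tx in annotation.transcripts:
        if tx.chrom not in by_chrom:
            raise AnnotationError(f"transcript on unknown chromosome {tx.chrom}")
        by_chrom[tx.chrom].append(tx)
    for chrom, length in chrom_lengths.items():
        arr = _paint_chromosome(length, by_chrom[chrom])
        binned = np.bincount(arr, minlength=len(REGION_CLASSES))
        for i, name in enumerate(REGION_CLASSES):
            counts[name] += int(binned[i])
    return composition_percentages(counts)


def composition_percentages(
    counts: Mapping[str, int], genome_length: int | None = None
) -> pd.DataFrame:
    """Percentage table from per-class nucleotide counts.

    ``genome_length`` defaults to the sum of the counts; percentages
    are 100*count/genome_length (report at 3 decimals downstream).
    """
    total = int(genome_length) if genome_length is not None else sum(counts.values())
    if total <= 0:
        raise ValueError("genome length must be positive")
    order = [c for c in REGION_CLASSES if c in counts] + [
        c for c in counts if c not in REGION_CLASSES
    ]
    df = pd.DataFrame(
        {
            "nucleotides": [int(counts[c]) for c in order],
            "percent": [100.0 * counts[c] / total for c in order],
        },
        index=pd.Index(order, name="region_class"),
    )
    return df


@dataclass(frozen=True)
class EffectCall:
    """Codon-level consequence of one SNP on one transcript."""

    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    gene_id: str
    effect: str  # stop_gained|start_lost|stop_lost|splice2_disrupt|missense|synonymous|non_coding
    codon_index: int | None = None  # 1-based codon number in the CDS
    ref_codon: str | None = None
    alt_codon: str | None = None
    frame_tentative: bool = False  # transcript lacks an annotated start codon

    @property
    def is_disrupting(self) -> bool:
        return self.effect in DISRUPTING_EFFECTS


def call_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    tx: TranscriptModel,
    seq: str,
) -> EffectCall:
    """Consequence of substituting ``alt`` for ``ref`` at ``pos`` on ``tx``.

    The spliced, strand-corrected CDS is rebuilt, the substituted codon
    compared against the reference codon under the standard nuclear
    genetic code.  Splice calls take precedence: a SNP in the first or
    last two intronic bases of the transcript is a splice disruption
    regardless of any coding overlap in other transcripts.
    """
    if seq[pos - 1] != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} REF {ref} != FASTA base {seq[pos - 1]}"
        )
    common = dict(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        transcript_id=tx.transcript_id, gene_id=tx.gene_id,
        frame_tentative=not tx.has_start,
    )
    if pos in tx.splice_sites():
        return EffectCall(effect="splice2_disrupt", **common)

    cds_pos = tx.cds_positions()
    i = int(np.searchsorted(cds_pos, pos))
    if i >= len(cds_pos) or cds_pos[i] != pos:
        return EffectCall(effect="non_coding", **common)

    n = len(cds_pos)
    cds_index = i if tx.strand == "+" else n - 1 - i  # 0-based coding offset
    codon_idx = cds_index // 3
    offset = cds_index % 3
    lo = codon_idx * 3
    codon_genomic = (
        cds_pos[lo : lo + 3] if tx.strand == "+" else cds_pos[n - lo - 3 : n - lo][::-1]
    )
    if len(codon_genomic) < 3:
        # trailing partial codon of an incomplete CDS
        return EffectCall(effect="non_coding", **common)

    def base(p: int, substitute: bool) -> str:
        b = alt if (substitute and p == pos) else seq[p - 1]
        return b if tx.strand == "+" else _COMPLEMENT[b]

    ref_codon = "".join(base(p, False) for p in codon_genomic)
    alt_codon = "".join(base(p, True) for p in codon_genomic)
    assert ref_codon != alt_codon and offset == list(codon_genomic).index(pos)

    if tx.has_start and codon_idx == 0 and ref_codon == "ATG":
        effect = "start_lost"  # Met has a single codon: any change is non-synonymous
    elif ref_codon in STOP_CODONS:
        # terminal stop in a complete CDS; an internal one is an annotation defect
        effect = "synonymous" if alt_codon in STOP_CODONS else "stop_lost"
    elif alt_codon in STOP_CODONS:
        effect = "stop_gained"
    elif CODON_TO_AA[ref_codon] == CODON_TO_AA[alt_codon]:
        effect = "synonymous"
    else:
        effect = "missense"
    return EffectCall(
        effect=effect, codon_index=codon_idx + 1,
        ref_codon=ref_codon, alt_codon=alt_codon, **common
    )


def effect_table(variants, annotation: Annotation, seqs: Mapping[str, str]) -> pd.DataFrame:
    """Per-SNP region class and per-transcript effect calls.

    ``variants`` is a :class:`sibline.hetmetrics.VariantTable` (or any
    object exposing ``chrom``/``pos``/``ref``/``alt`` arrays).  One row
    per overlapping transcript; intergenic SNPs get a single row with
    effect ``non_coding``.
    """
    rows = []
    for k in range(len(variants.pos)):
        chrom = variants.chrom[k]
        pos = int(variants.pos[k])
        ref, alt = variants.ref[k], variants.alt[k]
        region = classify_region(chrom, pos, annotation)
        txs = annotation.overlapping(chrom, pos)
        if not txs:
            rows.append((chrom, pos, ref, alt, region, ".", ".", "non_coding",
                         None, None, None, False))
            continue
        for tx in txs:
            call = call_effect(chrom, pos, ref, alt, tx, seqs[chrom])
            rows.append((chrom, pos, ref, alt, region, tx.transcript_id,
                         tx.gene_id, call.effect, call.codon_index,
                         call.ref_codon, call.alt_codon, call.frame_tentative))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "region_class", "transcript",
                 "gene", "effect", "codon_index", "ref_codon", "alt_codon",
                 "frame_tentative"],
    )


def disrupted_genes(
    variants, annotation: Annotation, seqs: Mapping[str, str]
) -> dict[str, set[str]]:
    """Per-sample sets of genes hit by a homozygous gene-breaking SNP.

    A gene qualifies for a sample iff the sample is hom-alt at >=1 SNP
    whose effect on >=1 transcript of the gene is stop-gained,
    start-lost, stop-lost or 2-bp splice disruption.  Heterozygous
    carriers are never counted.
    """
    from .hetmetrics import GT_HOM_ALT

    per_site_genes: list[set[str]] = []
    for k in range(len(variants.pos)):
        chrom = variants.chrom[k]
        pos = int(variants.pos[k])
        genes: set[str] = set()
        for tx in annotation.overlapping(chrom, pos):
            call = call_effect(chrom, pos, variants.ref[k], variants.alt[k], tx,
                               seqs[chrom])
            if call.is_disrupting:
                genes.add(tx.gene_id)
        per_site_genes.append(genes)

    out: dict[str, set[str]] = {s: set() for s in variants.samples}
    for j, sample in enumerate(variants.samples):
        hom = variants.gt[:, j] == GT_HOM_ALT
        for k in np.nonzero(hom)[0]:
            out[sample] |= per_site_genes[k]
    return out
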