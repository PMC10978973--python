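"""Independent brute-force oracles shared by the unit and acceptance
tests.  These re-derive expected values by a different route than the
implementation (set membership instead of interval logic; full-CDS
re-translation and protein diffing instead of codon-local inspection)."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from sibline.effects import TranscriptModel


def paint_oracle(tx: TranscriptModel, pos: int) -> str | None:
    """Set-membership re-derivation of the region class for one transcript."""
    if not tx.start <= pos <= tx.end:
        return None
    exonic = set()
    for s, e in tx.exons:
        exonic.update(range(s, e + 1))
    splice = set()
    for s, e in tx.introns:
        splice.update({s, s + 1, e - 1, e})
    if pos in splice:
        return "splice_junction_2bp"
    if pos not in exonic:
        return "intron"
    if tx.cds_start <= pos <= tx.cds_end:
        return "protein_coding"
    before = pos < tx.cds_start
    if tx.strand == "+":
        return "utr5" if before else "utr3"
    return "utr3" if before else "utr5"


def translation_oracle(tx: TranscriptModel, seq: str, pos: int, alt: str) -> str:
    """Re-translate the whole CDS before/after the substitution and diff."""
    if pos in tx.splice_sites():
        return "splice2_disrupt"
    mutated = seq[: pos - 1] + alt + seq[pos:]
    ref_cds = tx.spliced_cds(seq)
    alt_cds = tx.spliced_cds(mutated)
    if ref_cds == alt_cds:
        return "non_coding"
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    diff = [k for k in range(len(ref_prot)) if ref_prot[k] != alt_prot[k]]
    ref_codon = ref_cds[:3]
    if not diff:
        k = next(
            k for k in range(len(ref_cds) // 3)
            if ref_cds[3 * k : 3 * k + 3] != alt_cds[3 * k : 3 * k + 3]
        )
        if k == 0 and tx.has_start and ref_codon == "ATG":
            return "start_lost"
        return "synonymous"
    k = diff[0]
    if k == 0 and tx.has_start and ref_codon == "ATG":
        return "start_lost"
    if ref_prot[k] == "*":
        return "stop_lost"
    if alt_prot[k] == "*":
        return "stop_gained"
    return "missense"


def other_base(rng: np.random.Generator, b: str) -> str:
    return str(rng.choice([x for x in "ACGT" if x != b]))
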