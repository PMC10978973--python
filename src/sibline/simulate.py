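"""Gene-dropping simulator for full sib-pair inbreeding of diploid genomes.

Simulates a line founded by two unrelated outbred fish and propagated
by one brother x sister cross per generation, with Poisson
recombination (no interference), random sex assignment, and viability
selection against configured lethal genotypes.  Two lethal forms are
supported:

* ``recessive_lethal``: alt/alt at a single site is inviable;
* ``balanced_repulsion_pair``: two linked lethals on opposite founder
  haplotypes, so that only individuals heterozygous at *both* sites
  survive — the mechanism that keeps 100-kb "hotspot" windows
  heterozygous while the rest of the genome drifts to homozygosity.

The simulator also synthesises the surrounding genome — a random
reference with painted open reading frames, a transcript GFF3, and a
multi-sample VCF v4.2 with GATK-style INFO fields drawn from a
passing/failing mixture — so every downstream analysis stage can be
exercised without external data.  All randomness flows from one
integer seed; identical configuration + seed gives byte-identical
output files.

Default settings emulate the published breeding design at desk scale:
founder heterozygosity 0.5 per site (an outbred wild-type stock),
~1 SNP/kb on two 5-Mb stand-in chromosomes of 100 cM each (zebrafish
chromosomes average ~100 cM), clutches of 30 raised offspring per
pair, and 20 generations — the conventional threshold for declaring a
line inbred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .effects import SENSE_CODONS, STOP_CODONS, TranscriptModel, _COMPLEMENT

__all__ = [
    "ChromosomeSpec",
    "InfoNoise",
    "RecessiveLethal",
    "BalancedRepulsionPair",
    "LethalSpec",
    "SimConfig",
    "SitePanel",
    "Individual",
    "SyntheticGenome",
    "SiblineResult",
    "LineExtinctError",
    "synthesize_genome",
    "make_outbred",
    "make_founders",
    "make_gamete",
    "cross",
    "apply_viability",
    "run_sibline",
    "emit_dataset",
    "simulate_dataset",
    "het_trajectory",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length_bp: int
    map_length_cM: float

    def __post_init__(self):
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        if self.map_length_cM < 0:
            raise ValueError("map_length_cM must be >= 0")


@dataclass(frozen=True)
class InfoNoise:
    """Parameters of the VCF INFO/DP generator.

    Sites are drawn from a passing component with probability
    ``1 - failing_fraction``; passing draws are clipped inside the
    hard-filter acceptance region, failing draws violate exactly one
    randomly chosen criterion, so the filter stage has known work.
    """

    qd_mean: float = 25.0
    qd_sd: float = 5.0
    fs_mean: float = 3.0
    fs_sd: float = 2.0
    mq_pass: float = 60.0
    mqranksum_sd: float = 1.0
    readposranksum_sd: float = 1.0
    dp_mean: float = 30.0
    failing_fraction: float = 0.05


@dataclass(frozen=True)
class RecessiveLethal:
    chrom: str
    pos: int


@dataclass(frozen=True)
class BalancedRepulsionPair:
    chrom: str
    pos_a: int
    pos_b: int


@dataclass(frozen=True)
class LethalSpec:
    recessive: tuple[RecessiveLethal, ...] = ()
    balanced: tuple[BalancedRepulsionPair, ...] = ()

    def __bool__(self) -> bool:
        return bool(self.recessive or self.balanced)


def _default_chromosomes() -> tuple[ChromosomeSpec, ...]:
    return (
        ChromosomeSpec("chr1", 5_000_000, 100.0),
        ChromosomeSpec("chr2", 5_000_000, 100.0),
    )


@dataclass(frozen=True)
class SimConfig:
    chromosomes: tuple[ChromosomeSpec, ...] = field(
        default_factory=_default_chromosomes
    )
    snp_density: float = 1e-3  # expected SNPs per bp
    founder_het: float = 0.5  # probability a founder site is heterozygous
    clutch_size: int = 30  # offspring raised (and genotype-able) per cross
    generations: int = 20
    lethals: LethalSpec = field(default_factory=LethalSpec)
    seed: int = 0
    male_bias: float = 0.5  # P(offspring is male)
    max_clutch_attempts: int = 10  # re-draw cap before declaring extinction
    gene_spacing: int = 50_000  # one gene per this many bp of tile
    info_noise: InfoNoise = field(default_factory=InfoNoise)

    def __post_init__(self):
        if not 0.0 <= self.founder_het <= 1.0:
            raise ValueError("founder_het must be in [0, 1]")
        if self.clutch_size < 2:
            raise ValueError("clutch_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


class LineExtinctError(RuntimeError):
    """No viable opposite-sex breeding pair within the attempt bound."""

    def __init__(self, generation: int):
        self.generation = generation
        super().__init__(
            f"line extinct at generation {generation}: no viable "
            "opposite-sex pair within the attempt bound"
        )


@dataclass
class SitePanel:
    """Ordered biallelic SNP sites per chromosome."""

    positions: dict[str, np.ndarray]  # 1-based, strictly increasing
    ref: dict[str, np.ndarray]
    alt: dict[str, np.ndarray]

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.positions[chrom])
        return sum(len(p) for p in self.positions.values())

    def site_index(self, chrom: str, pos: int) -> int:
        arr = self.positions[chrom]
        i = int(np.searchsorted(arr, pos))
        if i >= len(arr) or arr[i] != pos:
            raise KeyError(f"no panel site at {chrom}:{pos}")
        return i


@dataclass
class SyntheticGenome:
    chromosomes: tuple[ChromosomeSpec, ...]
    reference: dict[str, str]
    transcripts: list[TranscriptModel]
    panel: SitePanel

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}


@dataclass
class Individual:
    """Phased diploid genome over the site panel, with pedigree links."""

    id: str
    sex: str  # 'F' or 'M'
    generation: int
    mother: str | None
    father: str | None
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]

    def genotype(self, chrom: str, idx: int) -> tuple[int, int]:
        h0, h1 = self.haplotypes[chrom]
        return int(h0[idx]), int(h1[idx])

    def het_mask(self, chrom: str) -> np.ndarray:
        h0, h1 = self.haplotypes[chrom]
        return h0 != h1

    def het_fraction(self) -> float:
        het = total = 0
        for chrom, (h0, h1) in self.haplotypes.items():
            het += int((h0 != h1).sum())
            total += len(h0)
        return het / total if total else 0.0


def _paint_genes(
    seq: np.ndarray, chrom: str, length: int, spacing: int, rng: np.random.Generator
) -> list[TranscriptModel]:
    """Place multi-exon coding genes on a chromosome and write their ORFs.

    Each gene gets 2-4 exons, 5'/3' UTRs in the terminal exons and a
    spliced CDS of whole codons: ATG, sense codons, one stop.  Strand
    is random; minus-strand ORFs are written as reverse complements.
    """
    sense = np.array(SENSE_CODONS)
    stops = np.array(sorted(STOP_CODONS))
    transcripts = []
    gene_no = 0
    for tile_start in range(0, length - spacing + 1, spacing):
        gene_no += 1
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(150, 400, n_exons)
        intron_lens = rng.integers(200, 2000, n_exons - 1)
        start = tile_start + int(rng.integers(100, 1000))
        end = start + int(exon_lens.sum() + intron_lens.sum()) - 1
        if end > length:
            continue
        exons = []
        s = start
        for i, el in enumerate(exon_lens):
            exons.append((s, s + int(el) - 1))
            if i < n_exons - 1:
                s += int(el) + int(intron_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        utr5 = int(rng.integers(30, 120))
        utr3 = int(rng.integers(30, 120))
        spliced = int(exon_lens.sum())
        cds_len = spliced - utr5 - utr3
        utr3 += cds_len % 3  # keep whole codons
        cds_len -= cds_len % 3
        assert cds_len >= 9

        # genomic extent of the CDS: trim UTRs off the spliced ends
        left_trim = utr5 if strand == "+" else utr3
        right_trim = utr3 if strand == "+" else utr5
        exonic = np.concatenate([np.arange(a, b + 1) for a, b in exons])
        cds_genomic = exonic[left_trim : len(exonic) - right_trim]
        cds_start, cds_end = int(cds_genomic[0]), int(cds_genomic[-1])

        n_codons = cds_len // 3
        body = rng.choice(sense, n_codons - 2)
        coding = "ATG" + "".join(body) + str(rng.choice(stops))
        order = cds_genomic if strand == "+" else cds_genomic[::-1]
        for p, b in zip(order, coding):
            seq[p - 1] = b if strand == "+" else _COMPLEMENT[b]

        gid = f"{chrom}_g{gene_no}"
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gid}.t1",
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return transcripts


def synthesize_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SyntheticGenome:
    """Random reference + gene annotation + SNP site panel.

    Panel REF alleles are read off the (gene-painted) reference so the
    emitted VCF and FASTA agree by construction; lethal positions from
    the config are inserted into the panel if not already sampled.
    """
    rng = rng or np.random.default_rng([int(config.seed), 0])
    reference: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    positions: dict[str, np.ndarray] = {}
    refs: dict[str, np.ndarray] = {}
    alts: dict[str, np.ndarray] = {}

    forced: dict[str, list[int]] = {c.name: [] for c in config.chromosomes}
    for rl in config.lethals.recessive:
        forced[rl.chrom].append(rl.pos)
    for bp in config.lethals.balanced:
        forced[bp.chrom].extend([bp.pos_a, bp.pos_b])

    for spec in config.chromosomes:
        seq = _BASES[rng.integers(0, 4, spec.length_bp)]
        transcripts.extend(
            _paint_genes(seq, spec.name, spec.length_bp, config.gene_spacing, rng)
        )
        hit = rng.random(spec.length_bp) < config.snp_density
        pos = np.nonzero(hit)[0] + 1
        if forced[spec.name]:
            pos = np.unique(np.concatenate([pos, np.array(forced[spec.name])]))
        if len(pos) == 0:
            raise ValueError(f"empty site panel on {spec.name}; raise snp_density")
        ref = seq[pos - 1].copy()
        # alternate allele: uniformly one of the three non-reference bases
        shift = rng.integers(1, 4, len(pos))
        base_idx = np.searchsorted(_BASES, ref)
        alt = _BASES[(base_idx + shift) % 4]
        positions[spec.name] = pos.astype(np.int64)
        refs[spec.name] = ref
        alts[spec.name] = alt
        reference[spec.name] = str(seq.view(f"<U{spec.length_bp}")[0])

    panel = SitePanel(positions=positions, ref=refs, alt=alts)
    return SyntheticGenome(
        chromosomes=tuple(config.chromosomes),
        reference=reference,
        transcripts=transcripts,
        panel=panel,
    )


def make_outbred(
    genome: SyntheticGenome,
    founder_het: float,
    rng: np.random.Generator,
    ind_id: str,
    sex: str,
    generation: int = 0,
) -> Individual:
    """One unrelated outbred individual.

    Each site is heterozygous with probability ``founder_het`` (phase
    randomised); otherwise homozygous ref or alt with equal chance.
    """
    haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for spec in genome.chromosomes:
        n = genome.panel.n_sites(spec.name)
        het = rng.random(n) < founder_het
        phase = rng.integers(0, 2, n).astype(np.uint8)
        hom_allele = rng.integers(0, 2, n).astype(np.uint8)
        h0 = np.where(het, phase, hom_allele).astype(np.uint8)
        h1 = np.where(het, 1 - phase, hom_allele).astype(np.uint8)
        haps[spec.name] = (h0, h1)
    return Individual(
        id=ind_id, sex=sex, generation=generation, mother=None, father=None,
        haplotypes=haps,
    )


def _force_lethal_genotypes(ind: Individual, genome: SyntheticGenome, lethals: LethalSpec) -> None:
    """Make a founder a carrier of every configured lethal.

    Balanced pairs are set in repulsion phase (hap0 carries lethal A,
    hap1 carries lethal B); single recessive lethals are set
    heterozygous.  Without this the line could not segregate the
    configured load at all.
    """
    for rl in lethals.recessive:
        i = genome.panel.site_index(rl.chrom, rl.pos)
        h0, h1 = ind.haplotypes[rl.chrom]
        h0[i], h1[i] = 1, 0
    for bp in lethals.balanced:
        ia = genome.panel.site_index(bp.chrom, bp.pos_a)
        ib = genome.panel.site_index(bp.chrom, bp.pos_b)
        h0, h1 = ind.haplotypes[bp.chrom]
        h0[ia], h0[ib] = 1, 0
        h1[ia], h1[ib] = 0, 1


def make_founders(
    config: SimConfig, genome: SyntheticGenome, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """The unrelated outbred stock pair (one female, one male).

    These are the fish taken from the heterogeneous stock; the line
    itself is founded by a brother-sister pair drawn from their cross
    (see :func:`run_sibline`), so that generation t of the line
    carries Wright's F_t exactly.
    """
    if genome.panel.n_sites() == 0:
        raise ValueError("empty site panel")
    mother = make_outbred(genome, config.founder_het, rng, "P_F", "F")
    father = make_outbred(genome, config.founder_het, rng, "P_M", "M")
    for ind in (mother, father):
        _force_lethal_genotypes(ind, genome, config.lethals)
    return mother, father


def make_gamete(
    parent: Individual,
    spec: ChromosomeSpec,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete for a chromosome.

    Crossover count ~ Poisson(map_length_cM / 100), breakpoints
    uniform along the chromosome, no interference; the gamete starts
    on a random parental haplotype and switches at each breakpoint.
    """
    h0, h1 = parent.haplotypes[spec.name]
    n = len(positions)
    n_x = int(rng.poisson(spec.map_length_cM / 100.0))
    start = int(rng.integers(0, 2))
    if n_x == 0:
        return (h0 if start == 0 else h1).copy()
    breaks = np.sort(rng.uniform(1.0, spec.length_bp, n_x))
    switch_at = np.searchsorted(positions, breaks)  # sites at/after a break switch
    flips = np.zeros(n + 1, dtype=np.int64)
    np.add.at(flips, switch_at, 1)
    phase = (start + np.cumsum(flips[:-1])) % 2
    return np.where(phase == 0, h0, h1).astype(np.uint8)


def cross(
    mother: Individual,
    father: Individual,
    n_offspring: int,
    genome: SyntheticGenome,
    rng: np.random.Generator,
    generation: int,
    id_prefix: str = "",
    male_bias: float = 0.5,
) -> list[Individual]:
    """Mendelian offspring: one maternal + one paternal gamete per chromosome."""
    if mother.sex != "F" or father.sex != "M":
        raise ValueError("cross requires mother.sex='F' and father.sex='M'")
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    out = []
    for k in range(n_offspring):
        haps = {}
        for spec in genome.chromosomes:
            pos = genome.panel.positions[spec.name]
            haps[spec.name] = (
                make_gamete(mother, spec, pos, rng),
                make_gamete(father, spec, pos, rng),
            )
        sex = "M" if rng.random() < male_bias else "F"
        out.append(
            Individual(
                id=f"G{generation}_{id_prefix}{k}",
                sex=sex,
                generation=generation,
                mother=mother.id,
                father=father.id,
                haplotypes=haps,
            )
        )
    return out


def apply_viability(
    ind: Individual, lethals: LethalSpec, panel: SitePanel
) -> bool:
    """False iff a recessive lethal is alt/alt or a balanced pair is
    not doubly heterozygous."""
    for rl in lethals.recessive:
        i = panel.site_index(rl.chrom, rl.pos)
        if ind.genotype(rl.chrom, i) == (1, 1):
            return False
    for bp in lethals.balanced:
        ia = panel.site_index(bp.chrom, bp.pos_a)
        ib = panel.site_index(bp.chrom, bp.pos_b)
        a = ind.genotype(bp.chrom, ia)
        b = ind.genotype(bp.chrom, ib)
        if a[0] == a[1] or b[0] == b[1]:
            return False
    return True


@dataclass
class SiblineResult:
    genome: SyntheticGenome
    stock_pair: tuple[Individual, Individual]  # outbred fish from the stock
    breeders: list[tuple[Individual, Individual]]  # index = generation; 0 = founding sib pair
    survivors: dict[int, list[Individual]]  # viable offspring per generation

    @property
    def founders(self) -> tuple[Individual, Individual]:
        """The founding brother-sister pair (generation 0, F = 0)."""
        return self.breeders[0]

    @property
    def generations(self) -> int:
        return len(self.breeders) - 1


def run_sibline(
    config: SimConfig, genome: SyntheticGenome | None = None
) -> SiblineResult:
    """Propagate one full-sib line for ``config.generations`` generations.

    The generation-0 breeding pair is a brother-sister pair sampled
    from a cross of the two unrelated stock fish, so that generation
    counting matches Wright's recursion: offspring of the t-th
    sib-pair mating are generation t with inbreeding coefficient F_t
    (F_1 = 1/4).  Per generation, clutches of ``clutch_size``
    offspring are drawn and inviable ones discarded until at least one
    viable female and one viable male exist (or
    ``max_clutch_attempts`` clutches are exhausted, raising
    :class:`LineExtinctError`); the next breeding pair is then chosen
    uniformly among viable candidates.
    """
    if genome is None:
        genome = synthesize_genome(config)
    rng = np.random.default_rng([int(config.seed), 1])
    stock = make_founders(config, genome, rng)
    mother, father = stock
    breeders: list[tuple[Individual, Individual]] = []
    survivors: dict[int, list[Individual]] = {}
    for gen in range(0, config.generations + 1):
        viable: list[Individual] = []
        for attempt in range(config.max_clutch_attempts):
            clutch = cross(
                mother, father, config.clutch_size, genome, rng,
                generation=gen, id_prefix=f"c{attempt}_",
                male_bias=config.male_bias,
            )
            viable.extend(
                o for o in clutch
                if apply_viability(o, config.lethals, genome.panel)
            )
            if any(o.sex == "F" for o in viable) and any(
                o.sex == "M" for o in viable
            ):
                break
        females = [o for o in viable if o.sex == "F"]
        males = [o for o in viable if o.sex == "M"]
        if not females or not males:
            raise LineExtinctError(gen)
        mother = females[int(rng.integers(0, len(females)))]
        father = males[int(rng.integers(0, len(males)))]
        survivors[gen] = viable
        breeders.append((mother, father))
    return SiblineResult(
        genome=genome,
        stock_pair=stock,
        breeders=breeders,
        survivors=survivors,
    )


def het_trajectory(result: SiblineResult) -> pd.DataFrame:
    """Mean realized heterozygosity of the breeding pair per generation."""
    rows = [
        (gen, np.mean([ind.het_fraction() for ind in pair]))
        for gen, pair in enumerate(result.breeders)
    ]
    return pd.DataFrame(rows, columns=["generation", "het_fraction"])


def _info_fields(noise: InfoNoise, rng: np.random.Generator) -> tuple[str, bool]:
    """One INFO string from the passing/failing mixture."""
    failing = rng.random() < noise.failing_fraction
    qd = max(noise.qd_mean + noise.qd_sd * rng.standard_normal(), 2.5)
    fs = float(np.clip(noise.fs_mean + noise.fs_sd * rng.standard_normal(), 0.0, 55.0))
    mq = noise.mq_pass
    mqrs = float(np.clip(noise.mqranksum_sd * rng.standard_normal(), -12.0, 12.0))
    rprs = float(
        np.clip(noise.readposranksum_sd * rng.standard_normal(), -7.5, 7.5)
    )
    if failing:
        which = int(rng.integers(0, 5))
        if which == 0:
            qd = rng.uniform(0.0, 1.9)
        elif which == 1:
            fs = rng.uniform(61.0, 200.0)
        elif which == 2:
            mq = rng.uniform(20.0, 59.0)
        elif which == 3:
            mqrs = rng.uniform(-30.0, -12.6)
        else:
            rprs = rng.uniform(-20.0, -8.1)
    info = (
        f"QD={qd:.2f};FS={fs:.3f};MQ={mq:.2f};"
        f"MQRankSum={mqrs:.3f};ReadPosRankSum={rprs:.3f}"
    )
    return info, failing


@dataclass
class DatasetPaths:
    fasta: Path
    gff3: Path
    vcf: Path
    n_failing_sites: int = 0


def emit_dataset(
    individuals: Sequence[Individual],
    genome: SyntheticGenome,
    out_dir: str | Path,
    info_noise: InfoNoise | None = None,
    seed: int = 0,
) -> DatasetPaths:
    """Write reference FASTA, transcript GFF3 and multi-sample VCF.

    Sample columns follow the order of ``individuals``; genotypes are
    phased from the stored haplotypes, per-sample DP is Poisson, and
    INFO fields come from the passing/failing mixture of
    ``info_noise``.
    """
    noise = info_noise or InfoNoise()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [ind.id for ind in individuals]
    if len(set(ids)) != len(ids):
        raise ValueError("individual ids must be unique")
    rng = np.random.default_rng([int(seed), 2])

    fasta = out / "reference.fa"
    gff3 = out / "annotation.gff3"
    vcf = out / "variants.vcf"
    sio.write_fasta(fasta, genome.reference)
    sio.write_gff3(gff3, genome.transcripts, genome.chrom_lengths)

    n_failing = 0

    def records():
        nonlocal n_failing
        for spec in genome.chromosomes:
            chrom = spec.name
            pos = genome.panel.positions[chrom]
            ref = genome.panel.ref[chrom]
            alt = genome.panel.alt[chrom]
            haps = [ind.haplotypes[chrom] for ind in individuals]
            for i in range(len(pos)):
                info, failing = _info_fields(noise, rng)
                n_failing += failing
                gt_pairs = [(int(h0[i]), int(h1[i])) for h0, h1 in haps]
                dps = rng.poisson(noise.dp_mean, len(individuals))
                yield (chrom, int(pos[i]), ref[i], alt[i], info, gt_pairs,
                       [int(d) for d in dps])

    sio.write_vcf(vcf, genome.chrom_lengths, ids, records())
    return DatasetPaths(fasta=fasta, gff3=gff3, vcf=vcf, n_failing_sites=n_failing)


def simulate_dataset(
    config: SimConfig,
    out_dir: str | Path,
    n_final_samples: int = 3,
) -> tuple[SiblineResult, DatasetPaths, list[str]]:
    """End-to-end convenience: run a line and emit its dataset.

    The emitted cohort is the two outbred stock fish plus the first
    ``n_final_samples`` viable individuals of the final generation —
    the outbred-vs-inbred contrast the analysis stages expect.
    """
    result = run_sibline(config)
    final = result.survivors[result.generations][:n_final_samples]
    if len(final) < n_final_samples:
        raise ValueError("not enough final-generation survivors to sample")
    cohort = list(result.stock_pair) + final
    paths = emit_dataset(
        cohort, result.genome, out_dir, config.info_noise, seed=config.seed
    )
    return result, paths, [ind.id for ind in cohort]
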