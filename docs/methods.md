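# Methods

This note documents the models, conventions and numerical choices
behind `sibline`, in the spirit of the methods documentation of
simulation and statistics packages.

## Inbreeding theory

The only theory object is Wright's recurrence for repeated full-sib
mating, `F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4` with `F_0 = F_{-1} = 0`.
It is evaluated iteratively in double precision; the error is far
below 1e-12 over any realistic horizon, so rational arithmetic is
unnecessary. The residual fraction `1 - F_t` decays asymptotically by
the factor `(1 + sqrt(5))/4 ≈ 0.809` per generation (the dominant root
of the characteristic polynomial), which the tests verify to 1e-6.

**Generation indexing.** Generation t denotes offspring of the t-th
sib-pair mating, so `F_1 = 1/4` and the residual at generation 20 is
1.3665% — consistent with the 20-generation / <1.4% benchmark for
declaring a line inbred. To make the simulator agree with this
convention *exactly*, the generation-0 breeding pair is a
brother–sister pair sampled from one cross of two unrelated outbred
stock fish (mirroring how real lines are founded from a stock tank).
Had the unrelated stock fish themselves been labelled generation 0,
every simulated generation would lag the recurrence by one, because
the first cross of unrelated fish performs no inbreeding.

## The gene-dropping simulator

`sibline.simulate` drops founder alleles through the sib-mating
pedigree, per chromosome:

* **Recombination.** Crossover count per meiosis is
  Poisson(map length in Morgans), breakpoints uniform along the
  chromosome, no interference, no obligate chiasma, sex-independent
  map. Interference changes the variance of shared segments but not
  expected heterozygosity decay, which is what the package validates.
* **Sex.** Assigned independently with P(male) = `male_bias`
  (default 0.5). Zebrafish sex determination is polygenic/environmental
  and unresolved; the male-bias knob exists because inbred zebrafish
  lines show male-biased clutches, but no genetic model of it is
  attempted.
* **Viability selection.** Two lethal forms: `recessive_lethal`
  (alt/alt inviable) and `balanced_repulsion_pair` (two linked lethals
  on opposite haplotypes; only double heterozygotes survive, locking
  the interval heterozygous — the mechanism behind persistent
  heterozygosity hotspots). Selection is rejection sampling: clutches
  of `clutch_size` are drawn up to `max_clutch_attempts` times until a
  viable female and male exist; otherwise the line is reported extinct
  at that generation, as happens to real sib-mating branches. Stock
  founders are forced to be carriers of every configured lethal
  (balanced pairs in repulsion phase) — otherwise the configured load
  could not segregate at all.
* **No de novo mutation.** The analysis concerns standing variation;
  new mutations over ~20 generations are negligible at this scale.

**Defaults as study conditions.** Two 5-Mb chromosomes of 100 cM
(zebrafish chromosomes average roughly one crossover per meiosis, which
the 100-cM map preserves), ~1 SNP per kb (10,000 sites), founder
heterozygosity 0.5 per site, clutches of 30 raised offspring (a
realistic number of fish raised to genotyping age per pair, ~20 larvae
per tank), 20 generations. The founder-heterozygosity caveat: the
*stock* fish are heterozygous at each site with probability
`founder_het`, but any offspring of two symmetric outbred parents is
heterozygous with probability 1/2 regardless, so the founding sib
pair's expected heterozygosity equals `founder_het` only at the
default 0.5. All decay validation therefore uses H0 = 0.5.

**What the synthetic data does and does not emulate.** The emitted
VCF contains called genotypes with GATK-style INFO annotations drawn
from a passing/failing mixture (`failing_fraction` of sites violate
exactly one hard-filter criterion) and Poisson per-sample depth. There
is no read-level error model, no genotyping uncertainty correlated
with depth, no multiallelic sites, no indels and no linkage to real
zebrafish coordinates. Passing tests on this data demonstrates the
*analysis arithmetic and bookkeeping* — not robustness to real
calling artefacts, reference bias or structural variation.

## Heterogeneity metrics

Hard filtering follows the standard GATK hard-filter thresholds
(QD < 2.0, FS > 60.0, MQ < 60, MQRankSum < −12.5,
ReadPosRankSum < −8.0; all strict inequalities, so boundary values
pass). An absent annotation never removes a site — this mirrors how
expression-based filtering treats undefined annotations — and is
tallied for auditability. DP < 10 is applied per sample (the genotype
becomes missing) rather than per site, because depth is a per-sample
quantity.

Two heterogeneity percentages are reported per sample: heterozygous
genotypes per genome nucleotide (denominator defaults to the GRCz11
chromosome total, 1,345,101,831 bp, overridable and taken from the
FASTA in pipeline runs) and per union SNP position (positions variant
in at least one sample). Missing genotypes never enter numerators.

The window scan bins sites into fixed windows (`[(k−1)W+1, kW]`,
default W = 100 kb, final partial window kept) and reports per-sample
percent heterozygous among the SNPs in the window; empty windows
report 0% with `n_sites = 0` so per-chromosome conservation
(window sums = chromosome totals) always holds. The per-window SNP
count is emitted alongside, so a per-kilobase normalisation is
recoverable if preferred. Hotspot flagging takes maximal runs of
windows at or above a percentage threshold; the default of 25%
(half the founder level, ~20× the genome-wide expectation after 20
generations) with `min_consecutive = 1` is a reporting convention,
not an estimate — persistent hotspots sit near 50% and the decayed
background near 0.7%, so the flagging is insensitive to the exact
threshold over a wide range.

## Effect classification

Six mutually exclusive region classes partition the genome:
2-bp splice junction > protein coding > 5'-UTR > 3'-UTR > intron >
intergenic, in that severity order; a base overlapped by several
transcripts takes the most severe class. Placing the splice junction
above coding sequence makes the six classes a true partition (the
class counts sum exactly to the genome length, asserted in tests);
whether published six-class tabulations resolved junction/CDS overlap
identically is not knowable from class totals alone.

Codon-level calls rebuild the spliced, strand-corrected CDS and
compare codons under the standard nuclear code: `stop_gained` (sense
codon → TAA/TAG/TGA), `start_lost` (any change in the initiator ATG;
alternative initiators are not modelled), `stop_lost` (terminal stop
becomes sense), `splice2_disrupt` (first/last two intronic bases),
otherwise missense/synonymous/non-coding. Transcripts lacking an
annotated start codon still get calls, flagged `frame_tentative`,
since incomplete annotations are common and a gene-disruption call on
one is weak evidence. A gene counts as disrupted for a sample when the
sample is homozygous-alt at a SNP that breaks *any* transcript of the
gene (heterozygous carriers never count); per-transcript detail is
retained in the effect table.

## Phylogeny

Genotypes are coded as characters (hom-ref → reference base, hom-alt
→ alternate base, het → two-base IUPAC code, missing → N). Invariant
columns — those whose non-N characters imply fewer than two distinct
bases, counting ambiguity codes for both bases — are removed before
tree building, as in SNP-ascertainment workflows.

The distance is an allele-sharing p-distance: per site, cost 0 for
identical characters, 1 for disjoint base sets, 0.5 when exactly one
base is shared; sites with N in either member of a pair are excluded.
The 0.5 cost is the expected allele-sharing mismatch between a
heterozygote and a carrier of one of its alleles, stated as a
convention. Trees are built with Saitou–Nei neighbor joining:
deterministic tie-breaking by the smallest index pair, negative
intermediate branch lengths clamped to zero with the total deficit
recorded on the tree. Maximum-likelihood inference (model selection,
TVM, heavy bootstrapping) is deliberately not reimplemented: the
claims of interest — strain samples forming clades, inbred strains on
shorter branches — are recoverable by distance methods at this scale,
and NJ is exact on additive matrices (verified against least-squares
topology fitting and scikit-bio's implementation). Bootstrap support
resamples alignment columns with replacement and reports the
percentage of replicate NJ trees containing each original bipartition.

## Pipeline and reproducibility

`run_pipeline` accepts exactly one input mode — files
(VCF + FASTA + GFF3) or a simulation configuration — and executes
read → filter → heterogeneity/windows → composition → effects →
disrupted genes → overlap → phylogeny, writing per-stage TSVs, a
Newick tree and a manifest (configuration hash, seed, per-stage row
counts and the filter tally). All randomness descends from a single
integer seed through named `numpy` generator streams (genome
synthesis, breeding, VCF noise, bootstrap), and the writers are plain
deterministic text emitters, so identical configuration + seed
reproduces every output byte-for-byte; the tests assert this.

## Problem sizes

Validation workloads were chosen to give tight statistical checks at
interactive runtimes: 50 replicate lines × 10 generations × 10,000
sites for decay recovery (3 standard errors per generation, empirical
between-line variance); a 25-chromosome × 2-Mb genome for the
balanced-lethal hotspot study, preserving the real karyotype so one
hotspot stays a realistically small fraction of the genome (on a
two-chromosome toy genome the hotspot's linkage drag alone is a
sizeable share of all sites and masks the genome-wide decay
contrast); 1,000 random SNPs for effect-caller oracle equivalence; and
100 bootstrap replicates on six-sample cohorts for the phylogeny
checks.

## Known limitations

* Genotypes are emitted error-free; filter annotations are synthetic
  noise, not functions of simulated reads.
* The balanced-lethal mechanism is generic; no attempt is made to
  model any specific embryonic-lethal phenotype's genetics.
* The six-class accounting ignores indels, multi-nucleotide variants,
  splice-region effects beyond 2 bp, regulatory annotation and
  nonsense-mediated-decay prediction.
* `neighbor_joining` for two taxa represents the single edge as two
  half-edges from a degree-2 root; path length between the leaves
  equals the input distance.
* With `founder_het ≠ 0.5` the founding sib pair's realized
  heterozygosity regresses to 1/2 (see above); decay validation is
  defined at H0 = 0.5.
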