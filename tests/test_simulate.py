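"""Gene-dropping simulator: Mendelian consistency, recombination model,
viability selection, dataset emission and determinism."""

import hashlib
from dataclasses import replace

import numpy as np
import pytest

from sibline.hetmetrics import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    apply_hard_filters,
    read_vcf,
)
from sibline.simulate import (
    BalancedRepulsionPair,
    ChromosomeSpec,
    InfoNoise,
    Individual,
    LethalSpec,
    LineExtinctError,
    RecessiveLethal,
    SimConfig,
    apply_viability,
    cross,
    emit_dataset,
    het_trajectory,
    make_founders,
    make_gamete,
    make_outbred,
    run_sibline,
    simulate_dataset,
    synthesize_genome,
)
from sibline.theory import inbreeding_trajectory

from conftest import flat_panel_genome


def _one_site_parent(genome, g0, g1, sex, ind_id="p"):
    return Individual(
        id=ind_id, sex=sex, generation=0, mother=None, father=None,
        haplotypes={"chr1": (np.array([g0], np.uint8), np.array([g1], np.uint8))},
    )


class TestFounders:
    @pytest.mark.parametrize("h0, expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_extreme_founder_het(self, small_genome, h0, expected):
        rng = np.random.default_rng(0)
        ind = make_outbred(small_genome, h0, rng, "x", "F")
        assert ind.het_fraction() == expected

    def test_founder_het_binomial(self, small_config, small_genome):
        rng = np.random.default_rng(1)
        ind = make_outbred(small_genome, 0.5, rng, "x", "F")
        n = small_genome.panel.n_sites()
        se = np.sqrt(0.25 / n)
        assert abs(ind.het_fraction() - 0.5) < 3 * se

    def test_lethal_carriers_forced(self):
        cfg = SimConfig(
            chromosomes=(ChromosomeSpec("chr1", 100_000, 10.0),),
            lethals=LethalSpec(
                recessive=(RecessiveLethal("chr1", 50_000),),
                balanced=(BalancedRepulsionPair("chr1", 20_000, 30_000),),
            ),
            generations=1,
            seed=5,
        )
        genome = synthesize_genome(cfg)
        rng = np.random.default_rng(5)
        for ind in make_founders(cfg, genome, rng):
            i = genome.panel.site_index("chr1", 50_000)
            assert sorted(ind.genotype("chr1", i)) == [0, 1]
            ia = genome.panel.site_index("chr1", 20_000)
            ib = genome.panel.site_index("chr1", 30_000)
            h0, h1 = ind.haplotypes["chr1"]
            assert (h0[ia], h0[ib]) == (1, 0) and (h1[ia], h1[ib]) == (0, 1)


class TestGamete:
    def test_zero_map_length_gives_intact_haplotype(self, small_genome):
        rng = np.random.default_rng(2)
        ind = make_outbred(small_genome, 0.5, rng, "x", "F")
        spec = ChromosomeSpec("chr1", 500_000, 0.0)
        pos = small_genome.panel.positions["chr1"]
        g = make_gamete(ind, spec, pos, rng)
        h0, h1 = ind.haplotypes["chr1"]
        assert np.array_equal(g, h0) or np.array_equal(g, h1)

    def test_crossover_count_poisson_mean(self):
        """1-Morgan chromosome: mean crossovers 1.0 within 3 SE at 10^4 draws.

        With a marker at every base and opposite-phase parental
        haplotypes, phase transitions along the gamete count the
        realized crossovers (two breakpoints in the same 1-bp gap are
        vanishingly rare).
        """
        m = 1000
        ind = Individual(
            id="p", sex="F", generation=0, mother=None, father=None,
            haplotypes={"chr1": (np.zeros(m, np.uint8), np.ones(m, np.uint8))},
        )
        spec = ChromosomeSpec("chr1", m, 100.0)
        positions = np.arange(1, m + 1, dtype=np.int64)
        rng = np.random.default_rng(3)
        n = 10_000
        switches = [
            int(np.count_nonzero(np.diff(make_gamete(ind, spec, positions, rng))))
            for _ in range(n)
        ]
        # Poisson(1): mean 1, variance 1
        assert abs(np.mean(switches) - 1.0) < 3 * np.sqrt(1.0 / n)
        # Haldane check on two ends: P(odd # of crossovers) over ~1 Morgan
        frac = np.mean([s % 2 for s in switches])
        assert abs(frac - 0.5 * (1 - np.exp(-2.0))) < 0.02

    def test_gamete_deterministic_under_seed(self, small_genome):
        spec = ChromosomeSpec("chr1", 500_000, 50.0)
        pos = small_genome.panel.positions["chr1"]
        parent = make_outbred(small_genome, 0.5, np.random.default_rng(4), "x", "F")
        g1 = make_gamete(parent, spec, pos, np.random.default_rng(99))
        g2 = make_gamete(parent, spec, pos, np.random.default_rng(99))
        assert np.array_equal(g1, g2)


class TestCross:
    def test_mendelian_trivial_cases(self):
        genome = flat_panel_genome([500], ["A"], ["C"])
        rng = np.random.default_rng(6)
        mm = _one_site_parent(genome, 0, 0, "F")
        ff = _one_site_parent(genome, 0, 0, "M")
        for o in cross(mm, ff, 20, genome, rng, 1):
            assert o.genotype("chr1", 0) == (0, 0)
        aa = _one_site_parent(genome, 1, 1, "M")
        for o in cross(mm, aa, 20, genome, rng, 1):
            assert sorted(o.genotype("chr1", 0)) == [0, 1]

    def test_het_cross_segregates_one_half(self):
        genome = flat_panel_genome([500], ["A"], ["C"])
        rng = np.random.default_rng(7)
        mo = _one_site_parent(genome, 0, 1, "F")
        fa = _one_site_parent(genome, 0, 1, "M")
        n = 10_000
        offs = cross(mo, fa, n, genome, rng, 1)
        het = np.mean([o.genotype("chr1", 0)[0] != o.genotype("chr1", 0)[1] for o in offs])
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_offspring_alleles_come_from_parents(self, small_config, small_genome):
        rng = np.random.default_rng(8)
        mo = make_outbred(small_genome, 0.5, rng, "m", "F")
        fa = make_outbred(small_genome, 0.5, rng, "f", "M")
        for o in cross(mo, fa, 5, small_genome, rng, 1):
            for chrom in ("chr1", "chr2"):
                cm, cf = o.haplotypes[chrom]
                m0, m1 = mo.haplotypes[chrom]
                f0, f1 = fa.haplotypes[chrom]
                assert np.all((cm == m0) | (cm == m1))
                assert np.all((cf == f0) | (cf == f1))

    def test_sex_and_parent_validation(self):
        genome = flat_panel_genome([500], ["A"], ["C"])
        rng = np.random.default_rng(9)
        mo = _one_site_parent(genome, 0, 1, "F")
        fa = _one_site_parent(genome, 0, 1, "M")
        with pytest.raises(ValueError):
            cross(fa, mo, 2, genome, rng, 1)
        with pytest.raises(ValueError):
            cross(mo, fa, 0, genome, rng, 1)


class TestViability:
    def test_rules(self):
        genome = flat_panel_genome([100, 200, 300], "AAA", "CCC")
        lethals = LethalSpec(
            recessive=(RecessiveLethal("chr1", 100),),
            balanced=(BalancedRepulsionPair("chr1", 200, 300),),
        )

        def ind(g):
            return Individual(
                id="x", sex="F", generation=1, mother="m", father="f",
                haplotypes={"chr1": (np.array([r[0] for r in g], np.uint8),
                                     np.array([r[1] for r in g], np.uint8))},
            )

        ok = ind([(0, 1), (0, 1), (1, 0)])
        assert apply_viability(ok, lethals, genome.panel)
        assert not apply_viability(ind([(1, 1), (0, 1), (1, 0)]), lethals, genome.panel)
        assert not apply_viability(ind([(0, 0), (1, 1), (1, 0)]), lethals, genome.panel)
        assert apply_viability(ind([(1, 1), (0, 1), (1, 0)]), LethalSpec(), genome.panel)


class TestSibline:
    def test_structure_and_pedigree(self, small_config, small_genome):
        res = run_sibline(replace(small_config, generations=2), small_genome)
        assert res.generations == 2
        sis, bro = res.founders
        assert sis.sex == "F" and bro.sex == "M"
        # founding pair are sibs from the stock cross
        assert sis.generation == 0 and bro.generation == 0
        g1_mother, g1_father = res.breeders[1]
        assert g1_mother.mother == sis.id and g1_mother.father == bro.id
        traj = het_trajectory(res)
        assert list(traj.generation) == [0, 1, 2]

    def test_heterozygosity_decay_tracks_wright(self, small_config, small_genome):
        """20 replicate lines, T=3: mean het within 3 empirical SE of
        H0*(1-F_t)."""
        per_gen = {t: [] for t in range(4)}
        base = replace(small_config, generations=3)
        for rep in range(20):
            res = run_sibline(replace(base, seed=300 + rep), small_genome)
            for t, h in zip(*map(het_trajectory(res).get, ["generation", "het_fraction"])):
                per_gen[t].append(h)
        traj = inbreeding_trajectory(3)
        for t in range(4):
            obs = np.array(per_gen[t])
            se = obs.std(ddof=1) / np.sqrt(len(obs))
            assert abs(obs.mean() - 0.5 * traj.residual[t]) < 3 * max(se, 1e-4)

    def test_balanced_pair_always_heterozygous(self):
        cfg = SimConfig(
            chromosomes=(ChromosomeSpec("chr1", 200_000, 20.0),),
            lethals=LethalSpec(
                balanced=(BalancedRepulsionPair("chr1", 90_000, 95_000),)
            ),
            generations=4,
            clutch_size=20,
            seed=13,
        )
        res = run_sibline(cfg)
        ia = res.genome.panel.site_index("chr1", 90_000)
        ib = res.genome.panel.site_index("chr1", 95_000)
        for gen, inds in res.survivors.items():
            for ind in inds:
                assert sorted(ind.genotype("chr1", ia)) == [0, 1]
                assert sorted(ind.genotype("chr1", ib)) == [0, 1]

    def test_extinction_raises_with_generation(self, small_config, small_genome):
        cfg = replace(small_config, male_bias=1.0, generations=3)
        with pytest.raises(LineExtinctError) as exc:
            run_sibline(cfg, small_genome)
        assert exc.value.generation == 0


class TestEmit:
    def test_round_trip_genotypes_and_reference(self, small_dataset):
        res = small_dataset["result"]
        paths = small_dataset["paths"]
        cohort_ids = small_dataset["cohort"]
        table = read_vcf(paths.vcf)
        assert table.samples == cohort_ids
        genome = res.genome
        individuals = list(res.stock_pair) + res.survivors[res.generations][:3]
        k = 0
        for spec in genome.chromosomes:
            pos = genome.panel.positions[spec.name]
            for i in range(len(pos)):
                assert table.chrom[k] == spec.name and table.pos[k] == pos[i]
                for j, ind in enumerate(individuals):
                    a, b = ind.genotype(spec.name, i)
                    expected = (
                        GT_HET if a != b else (GT_HOM_ALT if a == 1 else GT_HOM_REF)
                    )
                    assert table.gt[k, j] == expected
                k += 1
        assert k == table.n_sites

    def test_ref_allele_matches_fasta(self, small_dataset):
        from Bio import SeqIO

        paths = small_dataset["paths"]
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(paths.fasta), "fasta")}
        table = read_vcf(paths.vcf)
        for k in range(table.n_sites):
            assert seqs[table.chrom[k]][table.pos[k] - 1] == table.ref[k]

    def test_no_failing_component_passes_all_filters(self, small_config, small_genome, tmp_path):
        rng = np.random.default_rng(21)
        inds = [make_outbred(small_genome, 0.5, rng, f"i{i}", "F") for i in range(2)]
        paths = emit_dataset(
            inds, small_genome, tmp_path, InfoNoise(failing_fraction=0.0), seed=21
        )
        table = read_vcf(paths.vcf)
        kept, tally = apply_hard_filters(table)
        assert kept.n_sites == table.n_sites
        assert tally["sites_removed"] == 0

    def test_vcf_byte_identical_under_seed(self, small_config, tmp_path):
        cfg = replace(small_config, generations=2)
        h = []
        for sub in ("a", "b"):
            _, paths, _ = simulate_dataset(cfg, tmp_path / sub)
            h.append(hashlib.sha256(paths.vcf.read_bytes()).hexdigest())
        assert h[0] == h[1]
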