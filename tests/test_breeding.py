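"""Trait architecture, meiosis, family structure and selection response."""

import numpy as np
import pytest

import gblupsim as gs
from gblupsim.genome import gametes_from_parents

from conftest import make_population


class TestTraitArchitecture:
    def test_variance_partition(self):
        for h2, (vq, vp) in {0.05: (0.03, 0.02), 0.3: (0.2, 0.1), 0.5: (0.3, 0.2)}.items():
            arch = gs.TraitArchitecture.from_h2(h2)
            assert (arch.var_qtl, arch.var_poly) == (vq, vp)
            assert arch.var_qtl + arch.var_poly + arch.var_error == pytest.approx(1.0)
            assert arch.var_additive == pytest.approx(h2)
        with pytest.raises(ValueError):
            gs.TraitArchitecture.from_h2(0.42)

    def test_qtl_effect_scaling_identity(self, tiny_dataset):
        g0 = tiny_dataset.generations["G0"]
        arch = gs.assign_qtl_effects(g0, gs.TraitArchitecture.from_h2(0.3), seed=5)
        bv = g0.qtl_dosage() @ arch.qtl_effects
        assert np.var(bv, ddof=1) == pytest.approx(0.2, abs=1e-10)
        # centering: base-generation QTL breeding values average zero
        assert np.mean(bv + arch.qtl_offset) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_qtl_set_rejected(self):
        pop = make_population(20, seed=1)
        # single all-heterozygote QTL: zero variance before scaling
        object.__setattr__(pop.genome_map, "is_qtl", np.array([True]))
        pop.haplotypes[:, 0, 0] = 1
        pop.haplotypes[:, 1, 0] = 0
        with pytest.raises(ValueError, match="degenerate"):
            gs.assign_qtl_effects(pop, gs.TraitArchitecture.from_h2(0.3), seed=1)


class TestMeiosis:
    def _uniform_map(self, length, n_loci):
        config = gs.GenomeConfig(
            n_chromosomes=1, snps_per_chr=n_loci, qtls_per_chr=0,
            chr_length=length, mutation_rate=0.0,
        )
        return gs.GenomeMap(
            config=config,
            chrom=np.zeros(n_loci, dtype=np.int64),
            pos_cm=np.linspace(0.0, length, n_loci),
            is_qtl=np.zeros(n_loci, dtype=bool),
        )

    def test_mean_crossovers_match_map_length(self):
        # distinguishable strands: observed strand switches per gamete estimate
        # the crossover count; expectation per gap is the Haldane odd-count
        # probability (1 - exp(-2d))/2
        gmap = self._uniform_map(100.0, 201)
        haplos = np.zeros((1, 2, 201), dtype=np.uint8)
        haplos[0, 1] = 1
        rng = np.random.default_rng(0)
        gam = gametes_from_parents(haplos, np.zeros(100_000, dtype=int), gmap, rng)
        switches = (np.diff(gam.astype(np.int8), axis=1) != 0).sum(axis=1)
        gaps = np.diff(gmap.pos_cm) / 100.0
        expected = np.sum((1 - np.exp(-2 * gaps)) / 2)
        se = switches.std(ddof=1) / np.sqrt(switches.size)
        assert abs(switches.mean() - expected) < 3 * se
        assert expected == pytest.approx(1.0, rel=0.02)  # ~1 Morgan map

    def test_haldane_recombinant_fraction_at_10cm(self):
        gmap = self._uniform_map(10.0, 2)
        haplos = np.zeros((1, 2, 2), dtype=np.uint8)
        haplos[0, 1] = 1
        rng = np.random.default_rng(1)
        gam = gametes_from_parents(haplos, np.zeros(100_000, dtype=int), gmap, rng)
        r_obs = (gam[:, 0] != gam[:, 1]).mean()
        r_exp = (1 - np.exp(-0.2)) / 2  # 0.0906
        se = np.sqrt(r_exp * (1 - r_exp) / gam.shape[0])
        assert abs(r_obs - r_exp) < 3 * se

    def test_zero_length_chromosome_copies_one_strand(self):
        gmap = self._uniform_map(0.0, 50)
        rng = np.random.default_rng(2)
        haplos = rng.integers(0, 2, size=(1, 2, 50)).astype(np.uint8)
        gam = gs.meiosis(haplos[0], gmap, rng)
        assert np.array_equal(gam, haplos[0, 0]) or np.array_equal(gam, haplos[0, 1])


class TestFamilySizes:
    def test_equal_contribution(self):
        sizes = gs.draw_family_sizes(gs.FamilyContribution.equal(100), 50, seed=0)
        assert (sizes == 100).all() and sizes.sum() == 5000

    def test_unequal_expectation(self):
        contrib = gs.FamilyContribution.unequal()
        assert contrib.mean_size == pytest.approx(100.25)
        draws = gs.draw_family_sizes(contrib, 10_000, seed=1)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 100.25) < 3 * se

    def test_degenerate_distribution(self):
        contrib = gs.FamilyContribution.unequal(
            sizes=(5, 200), probs=(0.0, 1.0)
        )
        assert (gs.draw_family_sizes(contrib, 20, seed=2) == 200).all()

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            gs.FamilyContribution.unequal(sizes=(5, 10), probs=(0.5, 0.4))


class TestAdvanceGeneration:
    @pytest.fixture()
    def parents(self, tiny_dataset):
        return tiny_dataset.generations["G01"]

    def test_family_structure_and_size(self, parents, tiny_dataset):
        off = gs.advance_generation(
            parents, tiny_dataset.arch, gs.FamilyContribution.equal(10),
            n_families=20, seed=3,
        )
        assert off.n == 200
        fams = set(zip(off.sire.tolist(), off.dam.tolist()))
        assert len(fams) == 20  # 20 distinct full-sib matings
        sires = {s for s, _ in fams}
        dams = {d for _, d in fams}
        assert len(sires) == 20 and len(dams) == 20  # 1:1 mating ratio

    def test_selection_differential_positive(self, parents, tiny_dataset):
        off = gs.advance_generation(
            parents, tiny_dataset.arch, gs.FamilyContribution.equal(10),
            n_families=5, seed=4,
        )
        selected = np.isin(parents.ids, np.concatenate([off.sire, off.dam]))
        assert parents.tbv[selected].mean() > parents.tbv.mean()

    def test_zero_polygenic_variance_propagates_zeros(self, parents, tiny_dataset):
        import dataclasses

        arch = dataclasses.replace(
            tiny_dataset.arch, var_poly=0.0, var_qtl=tiny_dataset.arch.var_qtl
        )
        parents = dataclasses.replace(parents, poly_bv=np.zeros(parents.n))
        off = gs.advance_generation(
            parents, arch, gs.FamilyContribution.equal(5), n_families=10, seed=5
        )
        assert np.allclose(off.poly_bv, 0.0)

    def test_offspring_alleles_are_parental(self, parents, tiny_dataset):
        off = gs.advance_generation(
            parents, tiny_dataset.arch, gs.FamilyContribution.equal(5),
            n_families=10, seed=6,
        )
        pos = {int(i): k for k, i in enumerate(parents.ids)}
        for j in range(0, off.n, 7):
            s = parents.haplotypes[pos[int(off.sire[j])]]
            ok = (off.haplotypes[j, 0] == s[0]) | (off.haplotypes[j, 0] == s[1])
            assert ok.all()

    def test_equal_vs_unequal_share_parent_selection(self, parents, tiny_dataset):
        eq = gs.advance_generation(
            parents, tiny_dataset.arch, gs.FamilyContribution.equal(10),
            n_families=20, seed=7,
        )
        un = gs.advance_generation(
            parents, tiny_dataset.arch,
            gs.FamilyContribution.unequal(sizes=(5, 10, 15), probs=(0.3, 0.4, 0.3)),
            n_families=20, seed=7,
        )
        assert set(eq.sire) == set(un.sire)
        assert set(eq.dam) == set(un.dam)


class TestRunBreeding:
    def test_five_generations_and_determinism(self, tiny_dataset):
        cfg = gs.ScenarioConfig.tiny(master_seed=7)
        again = gs.run_breeding(
            genome=cfg.genome, hist=cfg.historical,
            arch=gs.TraitArchitecture.from_h2(0.3),
            contribution=cfg.contribution("S1"), seed=11,
            n_families=cfg.n_families, n_generations=cfg.n_generations,
        )
        assert tiny_dataset.generation_labels() == ["G01", "G02", "G03", "G04", "G05"]
        assert tiny_dataset.pedigree.equals(again.pedigree)
        assert np.array_equal(
            tiny_dataset.generations["G05"].tbv, again.generations["G05"].tbv
        )

    def test_phenotypic_variance_near_one_in_g01(self):
        cfg = gs.ScenarioConfig.tiny()
        variances = []
        for rep in range(3):
            res = gs.run_breeding(
                genome=cfg.genome, hist=cfg.historical,
                arch=gs.TraitArchitecture.from_h2(0.3),
                contribution=cfg.contribution("S1"), seed=500 + rep,
                n_families=cfg.n_families, n_generations=1,
            )
            variances.append(np.var(res.generations["G01"].phenotype, ddof=1))
        assert np.mean(variances) == pytest.approx(1.0, abs=0.25)

    def test_selection_response_mostly_positive(self):
        # truncation selection on a heritable trait raises mean TBV
        cfg = gs.ScenarioConfig.tiny()
        wins = 0
        for rep in range(10):
            res = gs.run_breeding(
                genome=cfg.genome, hist=cfg.historical,
                arch=gs.TraitArchitecture.from_h2(0.5),
                contribution=cfg.contribution("S1"), seed=900 + rep,
                n_families=cfg.n_families, n_generations=cfg.n_generations,
            )
            means = [res.generations[g].tbv.mean() for g in res.generation_labels()]
            if all(b >= a - 0.05 for a, b in zip(means, means[1:])):
                wins += 1
        assert wins >= 9

    def test_tbv_is_sum_of_components(self, tiny_dataset):
        for label in tiny_dataset.generation_labels():
            pop = tiny_dataset.generations[label]
            assert np.array_equal(pop.tbv, pop.qtl_bv + pop.poly_bv)

    def test_pedigree_parents_precede_offspring(self, tiny_dataset):
        ped = tiny_dataset.pedigree
        seen = set()
        for row in ped.itertuples():
            for p in (row.sire, row.dam):
                assert p == 0 or p in seen
            seen.add(row.id)
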