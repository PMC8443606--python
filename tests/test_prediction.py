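"""Train/test splitting and mixed-model prediction."""

import numpy as np
import pandas as pd
import pytest

import gblupsim as gs

from conftest import make_population
from test_genotyping import make_genotypes


class TestSplit:
    def test_thirty_percent_of_5000(self):
        pop = make_population(5000)
        plan = gs.split_train_test(pop, 0.30, seed=1)
        assert plan.n_test == 1500
        assert plan.n_train == 3500
        assert set(plan.test_ids).isdisjoint(plan.train_ids)
        assert set(plan.test_ids) | set(plan.train_ids) == set(pop.ids)

    def test_rounding_half_away_from_zero(self):
        assert gs.split_train_test(make_population(5), 0.30, seed=1).n_test == 2

    def test_degenerate_fractions_rejected(self):
        pop = make_population(10)
        for frac in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                gs.split_train_test(pop, frac, seed=1)
        with pytest.raises(ValueError, match="degenerate"):
            gs.split_train_test(make_population(4), 0.0003, seed=1)

    def test_deterministic(self):
        pop = make_population(100)
        a = gs.split_train_test(pop, 0.3, seed=5)
        b = gs.split_train_test(pop, 0.3, seed=5)
        assert np.array_equal(a.test_ids, b.test_ids)


def _simulated_fit_inputs(n, m, h2, seed, n_test=0):
    """Genotypes, a GRM, and phenotypes simulated under the GBLUP model."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    g = make_genotypes(dosage)
    grm = gs.compute_grm(g)
    if h2 > 0:
        beta = rng.standard_normal(m) * np.sqrt(h2 / grm.scale_c)
        w = dosage - dosage.mean(axis=0)
        u = w @ beta
    else:
        u = np.zeros(n)
    y = u + rng.standard_normal(n) * np.sqrt(1 - h2)
    train = grm.ids[: n - n_test]
    return g, grm, pd.Series(y[: n - n_test], index=train), u


class TestFitMixedModel:
    def test_identity_kernel_gives_zero_test_ebv(self):
        rng = np.random.default_rng(0)
        ids = np.arange(1, 31)
        relmat = gs.RelationshipMatrix(values=np.eye(30), ids=ids, kind="pedigree")
        y = pd.Series(rng.standard_normal(20), index=ids[:20])
        fit = gs.fit_mixed_model(y, relmat)
        assert np.allclose(fit.ebv.loc[ids[20:]], 0.0)

    def test_requires_training_records(self):
        relmat = gs.RelationshipMatrix(
            values=np.eye(5), ids=np.arange(5), kind="pedigree"
        )
        with pytest.raises(ValueError):
            gs.fit_mixed_model(pd.Series(np.zeros(5), index=np.arange(5)), relmat)

    def test_non_psd_kernel_rejected(self):
        n = 12
        vals = np.eye(n)
        vals[0, 1] = vals[1, 0] = 2.0  # eigenvalue -1
        relmat = gs.RelationshipMatrix(
            values=vals, ids=np.arange(n), kind="genomic"
        )
        y = pd.Series(np.random.default_rng(1).standard_normal(n), index=np.arange(n))
        with pytest.raises(ValueError, match="positive semidefinite"):
            gs.fit_mixed_model(y, relmat)

    def test_training_order_invariance(self):
        _, grm, y, _ = _simulated_fit_inputs(60, 80, 0.4, seed=2, n_test=10)
        fit1 = gs.fit_mixed_model(y, grm)
        fit2 = gs.fit_mixed_model(y.sample(frac=1.0, random_state=3), grm)
        assert np.allclose(fit1.ebv, fit2.ebv, atol=1e-8)

    def test_phenotype_shift_moves_intercept_only(self):
        _, grm, y, _ = _simulated_fit_inputs(50, 60, 0.4, seed=4, n_test=5)
        fit0 = gs.fit_mixed_model(y, grm)
        fit1 = gs.fit_mixed_model(y + 10.0, grm)
        assert fit1.intercept == pytest.approx(fit0.intercept + 10.0, abs=1e-6)
        assert np.allclose(fit0.ebv, fit1.ebv, atol=1e-6)

    def test_null_heritability_not_overestimated(self):
        # pure-noise phenotypes: the REML additive fraction stays near zero.
        # A low marker count keeps the GRM eigenvalue spread wide, which is
        # what lets REML separate the additive from the residual component.
        hits = 0
        for rep in range(100):
            _, grm, y, _ = _simulated_fit_inputs(500, 100, 0.0, seed=1000 + rep)
            fit = gs.fit_mixed_model(y, grm)
            if fit.h2 < 0.05:
                hits += 1
        assert hits >= 90


class TestPredictors:
    def test_full_sib_test_animals_share_pedigree_ebv(self):
        # A cannot distinguish unphenotyped members of the same full-sib family
        rows = []
        child = 10
        for f in range(3):
            s, d = 2 * f + 1, 2 * f + 2
            rows += [(s, 0, 0), (d, 0, 0)]
            for _ in range(8):
                rows.append((child, s, d))
                child += 1
        ped = pd.DataFrame(rows, columns=["id", "sire", "dam"])
        offspring = ped[ped["sire"] > 0]["id"].to_numpy()
        test_ids = offspring[[0, 1, 8, 9, 16, 17]]  # two sibs per family
        train_ids = np.setdiff1d(offspring, test_ids)
        rng = np.random.default_rng(5)
        y = pd.Series(rng.standard_normal(train_ids.size), index=train_ids)
        nrm = gs.compute_nrm(ped).subset(offspring)
        fit = gs.fit_mixed_model(y, nrm)
        assert fit.ebv.loc[test_ids[0]] == pytest.approx(fit.ebv.loc[test_ids[1]])
        assert fit.ebv.loc[test_ids[2]] == pytest.approx(fit.ebv.loc[test_ids[3]])

    def test_gblup_and_pblup_run_on_simulated_generation(self, tiny_dataset):
        from gblupsim.pipeline import _snp_genotypes

        pop = tiny_dataset.generations["G02"]
        split = gs.split_train_test(pop, 0.3, seed=6)
        panel = gs.sample_panel(gs.maf_filter(_snp_genotypes(pop)), 150, seed=7)
        gfit = gs.predict_gebv(pop, panel, split)
        pfit = gs.predict_ebv(pop, tiny_dataset.pedigree, split)
        tbv = pd.Series(pop.tbv, index=pop.ids).loc[split.test_ids]
        for fit in (gfit, pfit):
            assert fit.var_additive >= 0 and fit.var_residual >= 0
            acc = gs.accuracy(tbv.to_numpy(), fit.ebv.loc[split.test_ids].to_numpy())
            assert -1 <= acc <= 1
        # genomic information separates sibs: test accuracy should be real
        assert gs.accuracy(
            tbv.to_numpy(), gfit.ebv.loc[split.test_ids].to_numpy()
        ) > 0

    def test_gebv_deterministic_given_seeds(self, tiny_dataset):
        from gblupsim.pipeline import _snp_genotypes

        pop = tiny_dataset.generations["G03"]
        split = gs.split_train_test(pop, 0.3, seed=8)
        panel = gs.sample_panel(gs.maf_filter(_snp_genotypes(pop)), 120, seed=9)
        tm = gs.build_transition_matrix(0.05)
        f1 = gs.predict_gebv(pop, panel, split, transition=tm, seed=10)
        f2 = gs.predict_gebv(pop, panel, split, transition=tm, seed=10)
        assert np.array_equal(f1.ebv.to_numpy(), f2.ebv.to_numpy())
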