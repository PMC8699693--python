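import math

import numpy as np
import pandas as pd
import pytest

from gsikit import (
    CVGrid,
    GenotypeMatrix,
    Locus,
    MISSING,
    StratifiedBaseline,
    assign_novel,
    mc_cv_assign,
    rm_genotype_logprob,
    self_assign_loo,
    simulate_individuals,
)
from gsikit.assign import rm_loglik_matrix


def oracle_logprob(genotypes, alts, ns):
    """Independent scalar evaluation of the compound-Dirichlet genotype
    probability (uniform 1/k prior, k = 2 alleles)."""
    total = 0.0
    for g, n_alt, n in zip(genotypes, alts, ns):
        if g == MISSING:
            continue
        n_ref = n - n_alt
        if g == 0:
            p = ((n_ref + 0.5) / (n + 1)) * ((n_ref + 1.5) / (n + 2))
        elif g == 2:
            p = ((n_alt + 0.5) / (n + 1)) * ((n_alt + 1.5) / (n + 2))
        else:
            p = 2 * ((n_ref + 0.5) / (n + 1)) * ((n_alt + 0.5) / (n + 2))
        total += math.log(p)
    return total


def baseline_from(calls, populations):
    calls = np.asarray(calls, dtype=np.int16)
    loci = [Locus(f"L{j:03d}", f"c{j}", 45, "A", "G", 90)
            for j in range(calls.shape[1])]
    ids = [f"S{i:03d}" for i in range(calls.shape[0])]
    gm = GenotypeMatrix(ids, loci, calls)
    strata = pd.DataFrame(
        {"population": populations, "system": "sys", "basin": "Columbia",
         "form": "kokanee", "ecotype": "shore"},
        index=ids,
    )
    return StratifiedBaseline(gm, strata)


class TestRmLogprob:
    def test_worked_homozygote_case(self):
        # baseline of 9 alt among 10 alleles; homozygous-alt individual
        lp = rm_genotype_logprob(np.array([2]), np.array([9.0]), np.array([10.0]))
        assert math.exp(lp) == pytest.approx((9.5 / 11) * (10.5 / 12), abs=1e-12)
        assert math.exp(lp) == pytest.approx(0.7557, abs=5e-5)

    def test_prior_only_empty_baseline(self):
        hom = rm_genotype_logprob(np.array([0]), np.array([0.0]), np.array([0.0]))
        het = rm_genotype_logprob(np.array([1]), np.array([0.0]), np.array([0.0]))
        assert math.exp(hom) == pytest.approx(0.375, abs=1e-12)
        assert math.exp(het) == pytest.approx(0.25, abs=1e-12)

    def test_matches_oracle_on_1000_random_cases(self, rng):
        for _ in range(1000):
            L = int(rng.integers(1, 8))
            n = rng.integers(0, 30, size=L).astype(float) * 2
            alt = np.array([float(rng.integers(0, int(x) + 1)) for x in n])
            g = rng.integers(0, 3, size=L)
            g[rng.random(L) < 0.2] = MISSING
            lp = rm_genotype_logprob(g, alt, n)
            assert lp == pytest.approx(oracle_logprob(g, alt, n), abs=1e-12)

    def test_leave_one_out_subtracts_own_alleles(self):
        # pop of two hom-alt individuals: LOO for one leaves 2 alt of 2
        lp = rm_genotype_logprob(np.array([2]), np.array([4.0]), np.array([4.0]),
                                 leave_one_out=True)
        assert lp == pytest.approx(oracle_logprob([2], [2.0], [2.0]), abs=1e-12)

    def test_leave_one_out_underflow_is_an_error(self):
        with pytest.raises(RuntimeError):
            rm_genotype_logprob(np.array([2]), np.array([1.0]), np.array([2.0]),
                                leave_one_out=True)

    def test_matrix_scorer_agrees_with_scalar(self, rng):
        calls = rng.integers(0, 3, size=(6, 10)).astype(np.int16)
        calls[rng.random(calls.shape) < 0.2] = MISSING
        alt = rng.integers(0, 20, size=(3, 10)).astype(float)
        n = alt + rng.integers(0, 20, size=(3, 10)).astype(float)
        ll = rm_loglik_matrix(calls, alt, n)
        for i in range(6):
            for s in range(3):
                assert ll[i, s] == pytest.approx(
                    oracle_logprob(calls[i], alt[s], n[s]), abs=1e-10)


class TestSelfAssignment:
    def test_fixed_difference_groups_fully_separable(self):
        calls = np.vstack([np.zeros((10, 50)), np.full((10, 50), 2)])
        b = baseline_from(calls, ["PopA"] * 10 + ["PopB"] * 10)
        res = self_assign_loo(b)
        assert res.accuracy == 1.0
        assert np.allclose(res.posteriors.sum(axis=1), 1.0)

    def test_same_population_under_two_labels_near_half(self, rng):
        # one panmictic population sampled under two labels: by symmetry an
        # individual is equally likely to score higher under either label
        freqs = rng.uniform(0.2, 0.8, 40)
        calls = rng.binomial(2, freqs, size=(80, 40))
        b = baseline_from(calls, ["PopA"] * 40 + ["PopB"] * 40)
        res = self_assign_loo(b)
        assert 0.3 < res.accuracy < 0.7

    def test_singleton_group_excluded_with_warning(self, rng):
        calls = rng.integers(0, 3, size=(5, 10))
        with pytest.warns(UserWarning, match="singleton"):
            res = self_assign_loo(baseline_from(calls, ["A", "A", "A", "A", "B"]))
        assert len(res.table) == 4

    def test_posterior_invariant_to_loglik_shift(self, rng):
        from gsikit.assign import _posteriors_from_loglik

        ll = rng.normal(size=(5, 3)) * 10
        p1 = _posteriors_from_loglik(ll)
        p2 = _posteriors_from_loglik(ll + 123.4)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_default_world_self_assignment(self, default_world):
        cfg, baseline, _ = default_world
        from gsikit import pooled_labels

        res = self_assign_loo(baseline, pooled_labels(baseline.strata))
        assert res.accuracy >= 0.9


class TestAssignNovel:
    def test_novel_from_fixed_alleles_assigned_with_posterior_one(self):
        calls = np.vstack([np.zeros((10, 30)), np.full((10, 30), 2)])
        b = baseline_from(calls, ["PopA"] * 10 + ["PopB"] * 10)
        novel = GenotypeMatrix(
            ["N1"], list(b.genotypes.loci), np.zeros((1, 30), dtype=np.int16))
        res = assign_novel(novel, b, truth=["PopA"])
        assert res.table.loc[0, "assigned_group"] == "PopA"
        assert res.table.loc[0, "posterior_assigned"] > 0.999
        assert res.accuracy == 1.0

    def test_all_missing_individual_unassigned(self):
        calls = np.vstack([np.zeros((5, 10)), np.full((5, 10), 2)])
        b = baseline_from(calls, ["PopA"] * 5 + ["PopB"] * 5)
        novel = GenotypeMatrix(
            ["N1"], list(b.genotypes.loci),
            np.full((1, 10), MISSING, dtype=np.int16))
        res = assign_novel(novel, b)
        assert res.table.loc[0, "assigned_group"] == "unassigned"

    def test_loo_accuracy_not_above_non_loo(self, rng):
        # leave-one-out removes the individual's own contribution, so its
        # self-assignment accuracy cannot beat the optimistic non-LOO score
        calls = rng.binomial(2, rng.uniform(0.2, 0.8, 60), size=(30, 60))
        noise = rng.binomial(2, rng.uniform(0.2, 0.8, 60), size=(30, 60))
        b = baseline_from(np.vstack([calls, noise]), ["A"] * 30 + ["B"] * 30)
        loo = self_assign_loo(b)
        non_loo = assign_novel(b.genotypes, b,
                               truth=list(b.strata["population"]))
        assert loo.accuracy <= non_loo.accuracy + 1e-9


class TestSimulateIndividuals:
    def test_fixed_population_simulates_fixed_genotypes(self):
        calls = np.full((6, 12), 2)
        b = baseline_from(calls, ["A"] * 6)
        sim, truth = simulate_individuals(b, n_per_pop=20, seed=0)
        assert (sim.calls == 2).all()
        assert truth == ["A"] * 20

    def test_intermediate_frequency_mean_dosage(self):
        calls = np.tile([0, 1, 2, 1], (4, 1)).T  # alt freq 0.5 at 4 loci
        b = baseline_from(calls, ["A"] * 4)
        sim, _ = simulate_individuals(b, n_per_pop=2500, seed=1)
        m = sim.calls.mean()
        se = math.sqrt(0.5 / (2500 * 4)) * 2  # var of dosage = 2pq = 0.5
        assert abs(m - 1.0) < 3 * se

    def test_simulated_individuals_reassign_almost_perfectly(self, two_pop_world):
        b, fa, fb = two_pop_world
        sim, truth = simulate_individuals(b, n_per_pop=100, seed=2)
        res = assign_novel(sim, b, truth=truth)
        assert res.accuracy > 0.99


class TestMcCvAssign:
    def test_perfectly_separable_groups_score_one(self):
        calls = np.vstack([np.zeros((12, 30)), np.full((12, 30), 2)])
        b = baseline_from(calls, ["A"] * 12 + ["B"] * 12)
        grid = CVGrid((0.5,), (1.0,), 4)
        grid = mc_cv_assign(b, grid, seed=0)
        assert (grid.results["accuracy"] == 1.0).all()

    def test_shuffled_labels_score_near_chance(self, rng):
        calls = rng.binomial(2, rng.uniform(0.3, 0.7, 40), size=(60, 40))
        labels = ["A", "B"] * 30
        b = baseline_from(calls, labels)
        grid = mc_cv_assign(b, CVGrid((0.7,), (1.0,), 10), seed=3)
        assert abs(grid.results["accuracy"].mean() - 0.5) < 0.15

    def test_more_theta_ranked_loci_do_not_hurt(self, two_pop_world):
        b, *_ = two_pop_world
        grid = mc_cv_assign(b, CVGrid((0.7,), (0.5, 1.0), 8), seed=4)
        means = grid.results.groupby("loci_prop")["accuracy"].mean()
        assert means.loc[1.0] >= means.loc[0.5] - 0.02
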