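import math

import numpy as np
import pytest
from scipy import stats

from gsikit import GenotypeMatrix, Locus, MISSING, allele_frequencies, bh_fdr, ld_test, wc_theta
from gsikit.popgen import ld_test_pairs

from conftest import random_matrix


def scalar_wc_components(group_calls):
    """Independent straight-from-formula evaluation of the Weir–Cockerham
    variance components for one locus, written with plain Python scalars.

    ``group_calls`` is a list of per-group genotype lists (dosages, missing
    removed beforehand). Returns (a, b, c) or None where undefined.
    """
    r = len(group_calls)
    ns = [len(g) for g in group_calls]
    if any(n < 2 for n in ns):
        return None
    ps = [sum(g) / (2 * n) for g, n in zip(group_calls, ns)]
    hs = [sum(1 for x in g if x == 1) / n for g, n in zip(group_calls, ns)]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def make_gm(calls):
    calls = np.asarray(calls, dtype=np.int16)
    loci = [Locus(f"L{j:02d}", f"c{j}", 45, "A", "G", 90)
            for j in range(calls.shape[1])]
    return GenotypeMatrix([f"S{i:03d}" for i in range(calls.shape[0])], loci, calls)


class TestAlleleFrequencies:
    def test_simple_counts(self):
        gm = make_gm([[0], [1], [2]])
        af = allele_frequencies(gm)
        assert af.loc["L00", "alt_freq"] == 0.5
        assert af.loc["L00", "n"] == 6
        assert af.loc["L00", "het_count"] == 1

    def test_fixed_alt(self):
        gm = make_gm([[2], [2]])
        assert allele_frequencies(gm).loc["L00", "alt_freq"] == 1.0

    def test_all_missing_is_undefined(self):
        gm = make_gm([[MISSING], [MISSING]])
        af = allele_frequencies(gm)
        assert np.isnan(af.loc["L00", "alt_freq"]) and af.loc["L00", "n"] == 0

    def test_matches_naive_tally(self, rng):
        gm = random_matrix(rng, 15, 10, missing_rate=0.2)
        af = allele_frequencies(gm)
        for j, lid in enumerate(gm.locus_ids):
            col = [int(v) for v in gm.calls[:, j] if v != MISSING]
            if not col:
                assert np.isnan(af.loc[lid, "alt_freq"])
                continue
            assert af.loc[lid, "alt_freq"] == pytest.approx(sum(col) / (2 * len(col)))
            assert af.loc[lid, "het_count"] == sum(1 for v in col if v == 1)


class TestWcTheta:
    def test_fixed_difference_gives_theta_one(self):
        calls = [[0]] * 10 + [[2]] * 10
        gm = make_gm(calls)
        groups = {"A": gm.sample_ids[:10], "B": gm.sample_ids[10:]}
        res = wc_theta(gm, groups)
        assert res.theta[0] == pytest.approx(1.0)
        assert res.multilocus_theta == pytest.approx(1.0)

    def test_panmictic_split_theta_near_zero(self):
        rng = np.random.default_rng(42)
        n, L = 60, 1000
        freqs = rng.uniform(0.2, 0.8, L)
        calls = rng.binomial(2, freqs, size=(n, L)).astype(np.int16)
        gm = make_gm(calls)
        groups = {"A": gm.sample_ids[: n // 2], "B": gm.sample_ids[n // 2:]}
        res = wc_theta(gm, groups)
        vals = res.theta[res.defined]
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_components_match_scalar_oracle(self, rng):
        # 50 random small datasets, r in {2,3}, n <= 20, 5 loci
        for trial in range(50):
            r = int(rng.integers(2, 4))
            sizes = [int(rng.integers(2, 8)) for _ in range(r)]
            calls = rng.integers(0, 3, size=(sum(sizes), 5)).astype(np.int16)
            calls[rng.random(calls.shape) < 0.1] = MISSING
            gm = make_gm(calls)
            bounds = np.cumsum([0] + sizes)
            groups = {
                f"G{k}": gm.sample_ids[bounds[k]: bounds[k + 1]] for k in range(r)
            }
            res = wc_theta(gm, groups)
            for j in range(5):
                per_group = []
                for k in range(r):
                    rows = calls[bounds[k]: bounds[k + 1], j]
                    per_group.append([int(v) for v in rows if v != MISSING])
                expect = scalar_wc_components(per_group)
                if expect is None:
                    assert not res.defined[j] or any(len(g) < 2 for g in per_group) is False
                    continue
                a, b, c = expect
                if a + b + c == 0:
                    assert not res.defined[j]
                    continue
                assert res.a[j] == pytest.approx(a, abs=1e-12)
                assert res.b[j] == pytest.approx(b, abs=1e-12)
                assert res.c[j] == pytest.approx(c, abs=1e-12)
                assert res.theta[j] == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_invariant_to_group_order_and_allele_relabeling(self, rng):
        gm = random_matrix(rng, 20, 8, missing_rate=0.1)
        g1 = {"A": gm.sample_ids[:10], "B": gm.sample_ids[10:]}
        r1 = wc_theta(gm, g1)
        r2 = wc_theta(gm, {"B": g1["B"], "A": g1["A"]})
        np.testing.assert_allclose(r1.theta, r2.theta, equal_nan=True)
        flipped = gm.copy()
        mask = flipped.calls != MISSING
        flipped.calls[mask] = 2 - flipped.calls[mask]
        r3 = wc_theta(flipped, g1)
        np.testing.assert_allclose(r1.theta, r3.theta, atol=1e-12, equal_nan=True)

    def test_monomorphic_loci_excluded(self):
        gm = make_gm([[0, 0], [0, 2], [0, 0], [0, 2]])
        res = wc_theta(gm, {"A": gm.sample_ids[:2], "B": gm.sample_ids[2:]})
        assert not res.defined[0] and res.defined[1]

    def test_fewer_than_two_groups_rejected(self):
        gm = make_gm([[0], [1]])
        with pytest.raises(ValueError):
            wc_theta(gm, {"A": gm.sample_ids})


class TestLdTest:
    def test_perfect_association_significant(self):
        rng = np.random.default_rng(7)
        col = rng.integers(0, 3, size=50).astype(np.int16)
        gm = make_gm(np.column_stack([col, col]))
        res = ld_test(gm, "L00", "L01", {"pop": gm.sample_ids}, mc_reps=2000, seed=0)
        assert res.p_value < 0.01

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        for trial in range(40):
            calls = rng.binomial(2, 0.5, size=(40, 2)).astype(np.int16)
            gm = make_gm(calls)
            res = ld_test(gm, "L00", "L01", {"pop": gm.sample_ids},
                          mc_reps=1000, seed=trial)
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_table_gives_p_one(self):
        gm = make_gm([[0, 1]])
        res = ld_test(gm, "L00", "L01", {"pop": gm.sample_ids}, mc_reps=1000, seed=0)
        assert res.p_value == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        gm = make_gm(rng.integers(0, 3, size=(30, 2)))
        a = ld_test(gm, "L00", "L01", {"pop": gm.sample_ids}, mc_reps=1000, seed=5)
        b = ld_test(gm, "L00", "L01", {"pop": gm.sample_ids}, mc_reps=1000, seed=5)
        assert a.p_value == b.p_value

    def test_batch_pairs_include_fdr_columns(self, rng):
        gm = random_matrix(rng, 25, 4, missing_rate=0.0)
        pairs = [("L000", "L001"), ("L002", "L003")]
        df = ld_test_pairs(gm, pairs, {"pop": gm.sample_ids}, mc_reps=1000, seed=1)
        assert set(df.columns) == {"locus_i", "locus_j", "p", "adj_p", "significant"}


class TestBhFdr:
    def test_all_ones_no_rejections(self):
        reject, _ = bh_fdr([1, 1, 1], 0.05)
        assert not reject.any()

    def test_hand_worked_step_up(self):
        # each p_(k) <= 0.01 k, so the largest k is m and all are rejected
        reject, adj = bh_fdr([0.001, 0.01, 0.02, 0.04, 0.05], 0.05)
        assert reject.all()
        assert adj.max() <= 0.05 + 1e-12

    def test_matches_brute_force_scan(self, rng):
        for _ in range(30):
            p = rng.random(int(rng.integers(1, 25)))
            alpha = float(rng.uniform(0.01, 0.2))
            reject, _ = bh_fdr(p, alpha)
            m = len(p)
            order = np.argsort(p)
            kmax = 0
            for rank, idx in enumerate(order, start=1):
                if p[idx] <= rank * alpha / m:
                    kmax = rank
            expect = np.zeros(m, dtype=bool)
            expect[order[:kmax]] = True
            np.testing.assert_array_equal(reject, expect)

    def test_rejections_monotone_in_alpha(self, rng):
        p = rng.random(40)
        counts = [bh_fdr(p, a)[0].sum() for a in (0.01, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts)

    def test_empty_input(self):
        reject, adj = bh_fdr([], 0.05)
        assert reject.size == 0 and adj.size == 0
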