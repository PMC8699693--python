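"""Allele frequencies, Weir–Cockerham theta, linkage-disequilibrium exact
tests and FDR control.

Theta follows the two-allele variance-component estimator of Weir & Cockerham
(1984): per locus the components a (among populations), b (among individuals
within populations) and c (within individuals) are formed from group sizes,
allele frequencies and heterozygote frequencies; the per-locus estimate is
a/(a+b+c) and the multilocus estimate the ratio of sums. Negative per-locus
values are retained (the estimator is unbiased, not constrained to [0,1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(
    gm: GenotypeMatrix, group: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-locus alt-allele frequency, allele count n and het count.

    ``n`` is twice the number of non-missing samples; frequency is NaN where
    the group is entirely missing at a locus.
    """
    sub = gm if group is None else gm.subset_samples(group)
    if sub.n_samples == 0:
        raise ValueError("group is empty")
    calls = sub.calls
    called = calls != MISSING
    n = 2 * called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    het = ((calls == 1) & called).sum(axis=0)
    return pd.DataFrame(
        {"alt_freq": freq, "n": n, "het_count": het}, index=sub.locus_ids
    )


def baseline_allele_counts(
    gm: GenotypeMatrix, group: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, total allele count) per locus for a sample group."""
    sub = gm.subset_samples(group)
    called = sub.calls != MISSING
    n = 2 * called.sum(axis=0)
    alt = np.where(called, sub.calls, 0).sum(axis=0)
    return alt.astype(float), n.astype(float)


# ---------------------------------------------------------------------------
# Weir–Cockerham theta
# ---------------------------------------------------------------------------

@dataclass
class ThetaResult:
    """Variance components and theta, per locus and multilocus."""

    locus_ids: list[str]
    comparison: str
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray           # NaN where undefined
    defined: np.ndarray         # bool mask
    multilocus_theta: float     # sum(a)/sum(a+b+c) over defined loci
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "comparison": self.comparison,
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "theta": self.theta,
            }
        )


def wc_theta(
    gm: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    comparison: str = "",
) -> ThetaResult:
    """Weir–Cockerham theta across ``r = len(groups)`` sample groups.

    A locus contributes only where every group has >= 2 called samples and
    the variance-component denominator a+b+c is non-zero (polymorphic
    somewhere); other loci are flagged undefined and excluded from the
    multilocus ratio of sums.
    """
    r = len(groups)
    if r < 2:
        raise ValueError("wc_theta needs at least two groups")
    labels = sorted(groups)
    L = gm.n_loci

    n_i = np.zeros((r, L))      # diploid counts per group x locus
    p_i = np.zeros((r, L))      # alt-allele frequency
    h_i = np.zeros((r, L))      # heterozygote frequency
    for k, lab in enumerate(labels):
        sub = gm.subset_samples(groups[lab])
        called = sub.calls != MISSING
        cnt = called.sum(axis=0)
        n_i[k] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(cnt > 0, np.where(called, sub.calls, 0).sum(axis=0)
                              / np.maximum(2 * cnt, 1), np.nan)
            h_i[k] = np.where(cnt > 0, (sub.calls == 1).sum(axis=0)
                              / np.maximum(cnt, 1), np.nan)

    ok = (n_i >= 2).all(axis=0)
    a = np.full(L, np.nan)
    b = np.full(L, np.nan)
    c = np.full(L, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.mean(axis=0)
        rn = r * nbar
        nc = (rn - (n_i**2).sum(axis=0) / rn) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / rn
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / rn
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a_all = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b_all = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c_all = hbar / 2
    a[ok], b[ok], c[ok] = a_all[ok], b_all[ok], c_all[ok]

    denom = a + b + c
    defined = ok & np.isfinite(denom) & (denom != 0)
    theta = np.full(L, np.nan)
    theta[defined] = a[defined] / denom[defined]
    tot = denom[defined].sum()
    multi = float(a[defined].sum() / tot) if defined.any() and tot != 0 else np.nan
    return ThetaResult(
        gm.locus_ids, comparison, a, b, c, theta, defined, multi,
        empty=not bool(defined.any()),
    )


def pairwise_theta(
    gm: GenotypeMatrix, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Multilocus theta for every pair of groups (lower-triangle long form)."""
    labels = sorted(groups)
    rows = []
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            res = wc_theta(gm, {gi: groups[gi], gj: groups[gj]}, f"{gi}~{gj}")
            rows.append({"group_a": gi, "group_b": gj, "theta": res.multilocus_theta})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linkage-disequilibrium exact test (genotypic, fixed-margin Monte Carlo)
# ---------------------------------------------------------------------------

@dataclass
class LDTestResult:
    locus_i: str
    locus_j: str
    p_value: float
    per_population_p: dict[str, float] = field(default_factory=dict)
    tables: dict[str, np.ndarray] = field(default_factory=dict)
    significant: bool | None = None   # filled by FDR over a batch


def _table_logprob(table: np.ndarray) -> float:
    """Log probability of a contingency table under fixed margins."""
    rs, cs = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rs + 1).sum() + gammaln(cs + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def _mc_exact_p(table: np.ndarray, reps: int, rng: np.random.Generator) -> float:
    """Monte-Carlo exact p: share of fixed-margin tables no more probable
    than the observed one (add-one correction keeps p > 0)."""
    rs, cs = table.sum(axis=1), table.sum(axis=0)
    keep_r, keep_c = rs > 0, cs > 0
    t = table[np.ix_(keep_r, keep_c)]
    if t.shape[0] < 2 or t.shape[1] < 2 or t.sum() < 2:
        return 1.0
    obs = _table_logprob(t)
    draws = stats.random_table(t.sum(axis=1), t.sum(axis=0)).rvs(
        reps, random_state=rng
    )
    lp = np.array([_table_logprob(d) for d in draws])
    return float((1 + (lp <= obs + 1e-9).sum()) / (1 + reps))


def ld_test(
    gm: GenotypeMatrix,
    locus_i: str,
    locus_j: str,
    populations: Mapping[str, Sequence[str]],
    mc_reps: int = 2000,
    seed: int | None = 0,
) -> LDTestResult:
    """Genotypic LD exact test between two loci.

    Per population the 3x3 genotype-by-genotype table (missing pairs dropped)
    gets a Monte-Carlo exact p-value under fixed margins; population p-values
    are combined with Fisher's method. Deterministic given ``seed``.
    """
    if mc_reps < 1000:
        raise ValueError("mc_reps must be >= 1000")
    ji = gm.locus_ids.index(locus_i)
    jj = gm.locus_ids.index(locus_j)
    rng = np.random.default_rng(seed)
    per_pop: dict[str, float] = {}
    tables: dict[str, np.ndarray] = {}
    for pop in sorted(populations):
        sub = gm.subset_samples(populations[pop])
        gi, gj = sub.calls[:, ji], sub.calls[:, jj]
        ok = (gi != MISSING) & (gj != MISSING)
        table = np.zeros((3, 3), dtype=int)
        np.add.at(table, (gi[ok], gj[ok]), 1)
        tables[pop] = table
        per_pop[pop] = 1.0 if ok.sum() < 2 else _mc_exact_p(table, mc_reps, rng)
    if len(per_pop) == 1:
        combined = next(iter(per_pop.values()))
    else:
        combined = float(
            stats.combine_pvalues(list(per_pop.values()), method="fisher").pvalue
        )
    return LDTestResult(locus_i, locus_j, combined, per_pop, tables)


def ld_test_pairs(
    gm: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]],
    populations: Mapping[str, Sequence[str]],
    mc_reps: int = 2000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Batch LD tests with BH correction; columns
    locus_i,locus_j,p,adj_p,significant."""
    results = [
        ld_test(gm, i, j, populations, mc_reps, seed=None if seed is None else seed + k)
        for k, (i, j) in enumerate(pairs)
    ]
    p = np.array([r.p_value for r in results])
    if len(p):
        reject, adj = bh_fdr(p, alpha)
    else:
        reject, adj = np.array([], dtype=bool), np.array([])
    return pd.DataFrame(
        {
            "locus_i": [r.locus_i for r in results],
            "locus_j": [r.locus_j for r in results],
            "p": p,
            "adj_p": adj,
            "significant": reject,
        }
    )


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05):
    """Step-up BH procedure: (reject flags, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, adj
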