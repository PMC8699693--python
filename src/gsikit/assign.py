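"""Bayesian individual assignment and cross-validated classification.

The likelihood of an individual's genotype given a candidate baseline
population follows Rannala & Mountain (1997): allele frequencies get a
uniform Dirichlet prior (weight 1/k per allele, k = 2 for SNPs), so a
homozygote for allele x has per-locus probability
((n_x + 1/2)/(n + 1)) * ((n_x + 3/2)/(n + 2)) and a heterozygote
2 * ((n_x + 1/2)/(n + 1)) * ((n_y + 1/2)/(n + 2)), where n_x counts allele x
among the population's n sampled alleles. Self-assignment uses leave-one-out:
an individual's own two alleles are removed from its population's counts
before it is scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, StratifiedBaseline
from .popgen import wc_theta


# ---------------------------------------------------------------------------
# Rannala–Mountain genotype log-probability
# ---------------------------------------------------------------------------

def rm_genotype_logprob(
    genotypes: np.ndarray,
    baseline_alt: np.ndarray,
    baseline_n: np.ndarray,
    leave_one_out: bool = False,
) -> float:
    """Log probability of one individual's genotype vector given a baseline.

    ``baseline_alt``/``baseline_n`` are per-locus alt-allele counts and total
    allele counts of the candidate population. With ``leave_one_out`` the
    individual's own alleles are subtracted first (it must then be a member
    of that baseline). Missing loci are skipped.
    """
    g = np.asarray(genotypes)
    alt = np.asarray(baseline_alt, dtype=float).copy()
    n = np.asarray(baseline_n, dtype=float).copy()
    called = g != MISSING
    if leave_one_out:
        alt[called] -= g[called]
        n[called] -= 2
        if (alt < -1e-9).any() or (n < -1e-9).any() or ((n - alt) < -1e-9).any():
            raise RuntimeError("leave-one-out produced negative baseline counts")
    return float(_logprob_terms(g, alt, n)[called].sum())


def _logprob_terms(g: np.ndarray, alt: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-locus log probabilities (missing loci give arbitrary values)."""
    ref = n - alt
    lp = np.empty(g.shape, dtype=float)
    hom_ref = np.log(ref + 0.5) - np.log(n + 1) + np.log(ref + 1.5) - np.log(n + 2)
    hom_alt = np.log(alt + 0.5) - np.log(n + 1) + np.log(alt + 1.5) - np.log(n + 2)
    het = (
        np.log(2.0)
        + np.log(ref + 0.5) - np.log(n + 1)
        + np.log(alt + 0.5) - np.log(n + 2)
    )
    lp = np.where(g == 0, hom_ref, np.where(g == 2, hom_alt, het))
    return lp


def rm_loglik_matrix(
    calls: np.ndarray,
    group_alt: np.ndarray,
    group_n: np.ndarray,
    loo_group: np.ndarray | None = None,
) -> np.ndarray:
    """(n_individuals, n_groups) log-likelihood matrix.

    ``group_alt``/``group_n`` are (n_groups, n_loci); ``loo_group`` gives each
    individual's own-group index (or -1) for leave-one-out adjustment.
    """
    N, L = calls.shape
    G = group_alt.shape[0]
    called = calls != MISSING
    ll = np.zeros((N, G))
    # vectorized over groups via one-hot masks per genotype class
    for gidx in range(G):
        terms = _logprob_terms(calls, np.broadcast_to(group_alt[gidx], calls.shape),
                               np.broadcast_to(group_n[gidx], calls.shape))
        ll[:, gidx] = np.where(called, terms, 0.0).sum(axis=1)
    if loo_group is not None:
        for i in range(N):
            s = int(loo_group[i])
            if s < 0:
                continue
            ll[i, s] = rm_genotype_logprob(calls[i], group_alt[s], group_n[s],
                                           leave_one_out=True)
    return ll


# ---------------------------------------------------------------------------
# Assignment results
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    """Per-individual assignment with posteriors under a uniform prior."""

    table: pd.DataFrame          # sample,true_group,assigned_group,posterior_assigned,tie_flag,n_loci_used
    posteriors: pd.DataFrame     # sample x group
    log_likelihoods: pd.DataFrame
    groups: list[str]
    accuracy: float | None = None
    per_group_accuracy: pd.Series | None = None

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def _posteriors_from_loglik(ll: np.ndarray) -> np.ndarray:
    shifted = ll - ll.max(axis=1, keepdims=True)
    w = np.exp(shifted)
    return w / w.sum(axis=1, keepdims=True)


def _finalize(
    calls: np.ndarray,
    sample_ids: list[str],
    groups: list[str],
    ll: np.ndarray,
    truth: Sequence[str] | None,
) -> AssignmentResult:
    post = _posteriors_from_loglik(ll)
    n_used = (calls != MISSING).sum(axis=1)
    assigned, tie, p_assigned = [], [], []
    for i in range(len(sample_ids)):
        if n_used[i] == 0:
            assigned.append("unassigned")
            tie.append(False)
            p_assigned.append(np.nan)
            continue
        order = np.argsort(-ll[i], kind="stable")  # lexicographic on sorted groups
        best = order[0]
        is_tie = len(order) > 1 and np.isclose(ll[i, order[1]], ll[i, best],
                                               rtol=0, atol=1e-9)
        if is_tie:  # lexicographically first among the tied leaders
            tied = [j for j in range(len(groups))
                    if np.isclose(ll[i, j], ll[i, best], rtol=0, atol=1e-9)]
            best = min(tied, key=lambda j: groups[j])
        assigned.append(groups[best])
        tie.append(bool(is_tie))
        p_assigned.append(float(post[i, best]))
    table = pd.DataFrame(
        {
            "sample": sample_ids,
            "true_group": list(truth) if truth is not None else [""] * len(sample_ids),
            "assigned_group": assigned,
            "posterior_assigned": p_assigned,
            "tie_flag": tie,
            "n_loci_used": n_used,
        }
    )
    res = AssignmentResult(
        table,
        pd.DataFrame(post, index=sample_ids, columns=groups),
        pd.DataFrame(ll, index=sample_ids, columns=groups),
        groups,
    )
    if truth is not None:
        ok = table["assigned_group"] != "unassigned"
        correct = (table["assigned_group"] == table["true_group"]) & ok
        res.accuracy = float(correct.sum() / max(ok.sum(), 1))
        res.per_group_accuracy = correct.groupby(table["true_group"]).mean()
    return res


def _group_counts(gm: GenotypeMatrix, groups: Mapping[str, Sequence[str]]):
    # tolerates repeated sample ids within a group (bootstrap resampling)
    labels = sorted(groups)
    pos = {s: i for i, s in enumerate(gm.sample_ids)}
    alt = np.zeros((len(labels), gm.n_loci))
    n = np.zeros_like(alt)
    for k, lab in enumerate(labels):
        rows = gm.calls[[pos[s] for s in groups[lab]], :]
        called = rows != MISSING
        n[k] = 2 * called.sum(axis=0)
        alt[k] = np.where(called, rows, 0).sum(axis=0)
    return labels, alt, n


def _informative_loci(gm: GenotypeMatrix) -> list[int]:
    """Indices of loci polymorphic somewhere in the baseline."""
    called = gm.calls != MISSING
    alt = np.where(called, gm.calls, 0).sum(axis=0)
    n = 2 * called.sum(axis=0)
    return [j for j in range(gm.n_loci) if 0 < alt[j] < n[j]]


# ---------------------------------------------------------------------------
# Self-assignment and novel assignment
# ---------------------------------------------------------------------------

def resolve_grouping(
    baseline: StratifiedBaseline, grouping: str | pd.Series | Mapping[str, str]
) -> pd.Series:
    """Per-sample group labels from a strata field name or an explicit
    sample -> label mapping (e.g. pooled reference units)."""
    if isinstance(grouping, str):
        return baseline.labels(grouping).astype(str)
    lab = pd.Series(grouping, dtype=object)
    return lab.reindex(baseline.genotypes.sample_ids).astype(str)


def _groups_from_labels(labels: pd.Series) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for s, g in labels.items():
        out.setdefault(str(g), []).append(s)
    return out


def self_assign_loo(
    baseline: StratifiedBaseline,
    grouping: str | pd.Series | Mapping[str, str] = "population",
) -> AssignmentResult:
    """Leave-one-out self-assignment of every baseline individual.

    Each individual is scored against every group; only its own group's
    counts are leave-one-out adjusted. Singleton groups are excluded with a
    warning (their one member cannot be scored against a leave-one-out
    baseline of itself). ``grouping`` is a strata field or an explicit
    sample -> label mapping (pooled units).
    """
    labels_by_sample = resolve_grouping(baseline, grouping)
    groups = _groups_from_labels(labels_by_sample)
    singletons = [g for g, m in groups.items() if len(m) < 2]
    if singletons:
        warnings.warn(f"excluding singleton groups: {singletons}")
        keep = [s for g, m in groups.items() if g not in singletons for s in m]
        baseline = baseline.subset_samples(keep)
        labels_by_sample = labels_by_sample.loc[keep]
        groups = _groups_from_labels(labels_by_sample)
    gm = baseline.genotypes.take_loci(_informative_loci(baseline.genotypes))
    labels, alt, n = _group_counts(gm, groups)
    truth = [str(labels_by_sample[s]) for s in gm.sample_ids]
    own = np.array([labels.index(t) for t in truth])
    ll = rm_loglik_matrix(gm.calls, alt, n, loo_group=own)
    return _finalize(gm.calls, gm.sample_ids, labels, ll, truth)


def assign_novel(
    novel: GenotypeMatrix,
    baseline: StratifiedBaseline,
    grouping: str | pd.Series | Mapping[str, str] = "population",
    truth: Sequence[str] | None = None,
) -> AssignmentResult:
    """Assign individuals not in the baseline (no leave-one-out).

    Only loci shared between the novel matrix and the baseline are used;
    an individual with no called shared locus is reported unassigned.
    """
    shared = [l for l in novel.locus_ids if l in set(baseline.genotypes.locus_ids)]
    base_gm = baseline.genotypes.subset_loci(shared)
    keep = [shared[j] for j in _informative_loci(base_gm)]
    if not keep:
        raise ValueError("no shared informative loci between novel matrix and baseline")
    base_gm = base_gm.subset_loci(keep)
    nov = novel.subset_loci(keep)
    labels, alt, n = _group_counts(
        base_gm, _groups_from_labels(resolve_grouping(baseline, grouping))
    )
    ll = rm_loglik_matrix(nov.calls, alt, n)
    return _finalize(nov.calls, nov.sample_ids, labels, ll, truth)


def map_assignment(ar: AssignmentResult, mapping: Mapping[str, str]) -> AssignmentResult:
    """Collapse an assignment to a coarser identification (basin, migratory
    form, ecotype) by reading it off the assigned reference unit.

    This is how multi-scale identifications are made in practice: the
    likelihood assignment targets reference populations; the coarser label is
    that of the winning population. ``mapping`` maps every group label of
    ``ar`` to its coarser label; "unassigned" passes through.
    """
    table = ar.table.copy()
    for col in ("true_group", "assigned_group"):
        table[col] = table[col].map(lambda g: mapping.get(g, g))
    groups = sorted({mapping.get(g, g) for g in ar.groups})
    post = pd.DataFrame(
        {g: ar.posteriors[[c for c in ar.groups if mapping.get(c, c) == g]].sum(axis=1)
         for g in groups}
    )
    res = AssignmentResult(table, post, ar.log_likelihoods, groups)
    ok = table["assigned_group"] != "unassigned"
    correct = (table["assigned_group"] == table["true_group"]) & ok
    res.accuracy = float(correct.sum() / max(ok.sum(), 1))
    res.per_group_accuracy = correct.groupby(table["true_group"]).mean()
    return res


# ---------------------------------------------------------------------------
# Empirical-frequency individual simulation
# ---------------------------------------------------------------------------

def simulate_individuals(
    baseline: StratifiedBaseline,
    n_per_pop: int = 100,
    seed: int | None = 0,
    grouping: str = "population",
) -> tuple[GenotypeMatrix, list[str]]:
    """Draw individuals from each group's observed allele frequencies
    (linkage equilibrium; two independent allele draws per locus).

    Loci where a group is entirely missing stay missing for that group's
    simulated individuals.
    """
    rng = np.random.default_rng(seed)
    gm = baseline.genotypes
    groups = baseline.groups(grouping)
    rows, ids, truth = [], [], []
    for lab in sorted(groups):
        sub = gm.subset_samples(groups[lab])
        called = sub.calls != MISSING
        n = 2 * called.sum(axis=0)
        alt = np.where(called, sub.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        for k in range(n_per_pop):
            draw = rng.binomial(2, np.nan_to_num(freq)).astype(np.int16)
            draw[n == 0] = MISSING
            rows.append(draw)
            ids.append(f"sim_{lab}_{k:04d}")
            truth.append(lab)
    calls = np.vstack(rows) if rows else np.empty((0, gm.n_loci), dtype=np.int16)
    return GenotypeMatrix(ids, list(gm.loci), calls), truth


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validated classification
# ---------------------------------------------------------------------------

@dataclass
class CVGrid:
    """Grid of training-fraction x loci-fraction cells, each run for
    ``iterations`` stratified random splits."""

    train_props: tuple[float, ...] = (0.5, 0.7, 0.9)
    loci_props: tuple[float, ...] = (0.5, 0.75, 1.0)
    iterations: int = 30
    results: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for p in (*self.train_props, *self.loci_props):
            if not 0 < p <= 1:
                raise ValueError("grid proportions must lie in (0, 1]")

    def summary(self) -> pd.DataFrame:
        if self.results is None:
            raise ValueError("grid has not been evaluated")
        return (
            self.results.groupby(["train_prop", "loci_prop"])["accuracy"]
            .agg(["mean", "std", "min", "max"])
            .reset_index()
        )


def _default_classifier():
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))


def mc_cv_assign(
    baseline: StratifiedBaseline,
    grid: CVGrid | None = None,
    classifier_factory: Callable[[], object] | None = None,
    seed: int | None = 0,
    grouping: str | pd.Series | Mapping[str, str] = "population",
) -> CVGrid:
    """Monte-Carlo cross-validated assignment over a loci/training grid.

    Per iteration: stratified random train/test split; theta is recomputed on
    the training split only (avoiding high-grading bias) and the top fraction
    of loci retained; the classifier (linear SVM by default) is fit on
    standardized dosage features with missing values imputed to training
    locus means; accuracy is scored on the held-out individuals.
    """
    grid = grid or CVGrid()
    factory = classifier_factory or _default_classifier
    rng = np.random.default_rng(seed)
    gm = baseline.genotypes
    labels = np.array([str(v) for v in resolve_grouping(baseline, grouping)])
    calls = gm.calls.astype(float)
    calls[calls == MISSING] = np.nan
    group_names = sorted(set(labels))

    rows = []
    for tp in grid.train_props:
        for lp in grid.loci_props:
            it = 0
            attempts = 0
            while it < grid.iterations:
                attempts += 1
                if attempts > 10 * grid.iterations:
                    raise RuntimeError("could not build valid training splits")
                train_idx, test_idx = [], []
                for g in group_names:
                    members = np.flatnonzero(labels == g)
                    members = members[rng.permutation(len(members))]
                    k = max(1, int(round(tp * len(members))))
                    if k >= len(members):
                        k = len(members) - 1
                    train_idx.extend(members[:k])
                    test_idx.extend(members[k:])
                if not test_idx or len({labels[i] for i in train_idx}) < len(group_names):
                    warnings.warn("degenerate split resampled")
                    continue
                train_idx, test_idx = np.array(train_idx), np.array(test_idx)

                # theta-rank loci on the training split only
                train_gm = gm.take_samples(list(train_idx))
                train_groups = {
                    g: [train_gm.sample_ids[i] for i in
                        np.flatnonzero(labels[train_idx] == g)]
                    for g in group_names
                }
                theta = wc_theta(train_gm, train_groups).theta
                n_keep = max(1, int(round(lp * gm.n_loci)))
                order = sorted(
                    range(gm.n_loci),
                    key=lambda j: (not np.isfinite(theta[j]),
                                   -(theta[j] if np.isfinite(theta[j]) else 0.0),
                                   gm.locus_ids[j]),
                )
                keep = order[:n_keep]

                X_train = calls[np.ix_(train_idx, keep)]
                X_test = calls[np.ix_(test_idx, keep)]
                col_mean = np.nanmean(X_train, axis=0)
                col_mean = np.nan_to_num(col_mean, nan=1.0)
                X_train = np.where(np.isnan(X_train), col_mean, X_train)
                X_test = np.where(np.isnan(X_test), col_mean, X_test)

                clf = factory()
                clf.fit(X_train, labels[train_idx])
                acc = float((clf.predict(X_test) == labels[test_idx]).mean())
                rows.append(
                    {"train_prop": tp, "loci_prop": lp, "iteration": it,
                     "accuracy": acc}
                )
                it += 1
    grid.results = pd.DataFrame(rows)
    return grid
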