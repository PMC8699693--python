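"""Maximum-likelihood admixture clustering with replicate averaging and
Evanno-style model selection.

The model is the standard admixture likelihood: individual i carries ancestry
fractions q_ik over K clusters with cluster allele frequencies f_kl; each of
the two allele copies at locus l is alt with probability
sum_k q_ik f_kl. Fitting alternates closed-form EM updates of q and f and is
deterministic given a seed; restarts guard against local optima. This is a
desk-scale stand-in for MCMC samplers of the same likelihood family
(no correlated-frequency prior, no sampling-location prior).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import MISSING, GenotypeMatrix

_F_EPS = 1e-9


@dataclass
class ClusterResult:
    """One admixture fit: membership grid Q, cluster frequencies, likelihood."""

    K: int
    Q: pd.DataFrame              # individuals x K, rows on the simplex
    freqs: np.ndarray            # (K, n_loci)
    log_likelihood: float
    trace: list[float] = field(default_factory=list)


def admixture_fit(
    gm: GenotypeMatrix,
    K: int,
    seed: int | None = 0,
    n_restarts: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ClusterResult:
    """Fit the admixture model by EM; best of ``n_restarts`` by likelihood."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if gm.n_samples < K:
        raise ValueError("need at least K individuals")
    if K > np.unique(gm.calls, axis=0).shape[0]:
        warnings.warn("K exceeds the number of distinct genotype patterns")
    calls = gm.calls.astype(float)
    called = gm.calls != MISSING
    g = np.where(called, calls, 0.0)
    two = np.where(called, 2.0 - calls, 0.0)
    n_called = called.sum(axis=1)

    if K == 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = g.sum(axis=0) / np.maximum((g + two).sum(axis=0), 1e-300)
        f = np.clip(f, _F_EPS, 1 - _F_EPS)[None, :]
        ll = _admix_loglik(g, two, np.ones((gm.n_samples, 1)), f)
        return ClusterResult(
            1, pd.DataFrame(np.ones((gm.n_samples, 1)), index=gm.sample_ids,
                            columns=["cluster_1"]), f, ll, [ll]
        )

    rng = np.random.default_rng(seed)
    best: ClusterResult | None = None
    for _ in range(max(1, n_restarts)):
        q = rng.dirichlet(np.ones(K), size=gm.n_samples)
        f = np.clip(rng.uniform(0.05, 0.95, size=(K, gm.n_loci)), _F_EPS, 1 - _F_EPS)
        trace: list[float] = []
        for _sweep in range(max_iter):
            A = np.clip(q @ f, 1e-300, None)            # P(copy is alt)
            Bm = np.clip(q @ (1 - f), 1e-300, None)
            ll = _admix_loglik(g, two, q, f)
            if trace and ll < trace[-1] - 1e-8:
                raise RuntimeError("admixture EM log-likelihood decreased")
            done = bool(trace) and (ll - trace[-1] < tol)
            trace.append(ll)
            if done:
                break
            # expected alt / ref copy counts attributed to each cluster,
            # all sufficient statistics at the current (old) parameters
            alt_resp = q * ((g / A) @ f.T)              # (N, K)
            ref_resp = q * ((two / Bm) @ (1 - f).T)
            num = f * (q.T @ (g / A))                   # (K, L)
            den = num + (1 - f) * (q.T @ (two / Bm))
            q = (alt_resp + ref_resp) / np.maximum(2 * n_called, 1)[:, None]
            q[n_called == 0] = 1.0 / K  # all-missing individuals stay uniform
            q = q / q.sum(axis=1, keepdims=True)
            f = np.clip(num / np.maximum(den, 1e-300), _F_EPS, 1 - _F_EPS)
        res = ClusterResult(
            K,
            pd.DataFrame(q, index=gm.sample_ids,
                         columns=[f"cluster_{k + 1}" for k in range(K)]),
            f, trace[-1], trace,
        )
        if best is None or res.log_likelihood > best.log_likelihood:
            best = res
    return best


def _admix_loglik(g: np.ndarray, two: np.ndarray, q: np.ndarray, f: np.ndarray) -> float:
    A = np.clip(q @ f, 1e-300, None)
    Bm = np.clip(q @ (1 - f), 1e-300, None)
    het = (g == 1) & (two == 1)
    return float((g * np.log(A) + two * np.log(Bm)).sum() + np.log(2.0) * het.sum())


def align_replicates(Q_list: Sequence[pd.DataFrame | np.ndarray]) -> pd.DataFrame:
    """Permute each replicate's cluster columns onto the first replicate and
    average element-wise.

    The column matching minimizes total squared distance to the reference;
    because that cost separates by column pair it is an assignment problem,
    solved exactly for any K by the Hungarian algorithm.
    """
    if not Q_list:
        raise ValueError("empty replicate list")
    mats = [np.asarray(q, dtype=float) for q in Q_list]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("replicate Q matrices differ in shape")
    ref = mats[0]
    aligned = [ref]
    for m in mats[1:]:
        cost = ((ref[:, :, None] - m[:, None, :]) ** 2).sum(axis=0)
        _, perm = linear_sum_assignment(cost)
        aligned.append(m[:, perm])
    avg = np.mean(aligned, axis=0)
    index = Q_list[0].index if isinstance(Q_list[0], pd.DataFrame) else range(shape[0])
    cols = (Q_list[0].columns if isinstance(Q_list[0], pd.DataFrame)
            else [f"cluster_{k + 1}" for k in range(shape[1])])
    return pd.DataFrame(avg, index=index, columns=cols)


def _align_exhaustive(Q_list: Sequence[np.ndarray]) -> np.ndarray:
    """Brute-force over all K! column permutations (oracle for small K)."""
    ref = np.asarray(Q_list[0], dtype=float)
    K = ref.shape[1]
    aligned = [ref]
    for m in Q_list[1:]:
        m = np.asarray(m, dtype=float)
        best = min(
            itertools.permutations(range(K)),
            key=lambda perm: ((ref - m[:, list(perm)]) ** 2).sum(),
        )
        aligned.append(m[:, list(best)])
    return np.mean(aligned, axis=0)


def delta_k(logliks: dict[int, Sequence[float]]) -> pd.DataFrame:
    """Evanno's second-order statistic over a consecutive K range.

    DeltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)), defined
    only at interior K with sd > 0. Requires >= 2 replicates per K and >= 3
    consecutive K values.
    """
    ks = sorted(logliks)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    for k in ks:
        if len(logliks[k]) < 2:
            raise ValueError(f"K={k}: need >= 2 replicates")
    mean = {k: float(np.mean(logliks[k])) for k in ks}
    sd = {k: float(np.std(logliks[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            dk, defined = np.nan, False
        elif sd[k] == 0:
            dk, defined = np.nan, False
        else:
            dk = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
            defined = True
        rows.append({"K": k, "mean_loglik": mean[k], "sd_loglik": sd[k],
                     "delta_k": dk, "defined": defined})
    df = pd.DataFrame(rows)
    defined = df[df["defined"]]
    df.attrs["best_k"] = (
        int(defined.loc[defined["delta_k"].idxmax(), "K"]) if len(defined) else None
    )
    return df


def threshold_assign(
    Q: pd.DataFrame, threshold: float = 0.80, labels: Sequence[str] | None = None
) -> pd.Series:
    """Hard labels from averaged memberships: the argmax cluster when its
    membership strictly exceeds ``threshold``, otherwise "ambiguous"."""
    if not 0.5 < threshold <= 1:
        raise ValueError("threshold must lie in (0.5, 1]")
    q = np.asarray(Q, dtype=float)
    names = list(labels) if labels is not None else list(Q.columns)
    best = q.argmax(axis=1)
    out = [
        names[b] if q[i, b] > threshold else "ambiguous" for i, b in enumerate(best)
    ]
    return pd.Series(out, index=Q.index, name="label")
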