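"""Conditional-maximum-likelihood mixed-stock proportion estimation.

Baseline allele frequencies are held fixed; the stock proportions p_s are the
only free parameters. With per-individual, per-stock genotype likelihoods
L_is the EM iteration is

    E: z_is = p_s L_is / sum_t p_t L_it
    M: p_s  = mean_i z_is

starting from the uniform simplex point, stopping when the observed-data
log-likelihood gain falls below ``tol``. Percentile bootstrap confidence
intervals resample mixture individuals with replacement (optionally also the
baseline within stocks) and re-run the EM per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .assign import AssignmentResult, _group_counts, _informative_loci, rm_loglik_matrix
from .core import MISSING, GenotypeMatrix, StratifiedBaseline


@dataclass
class MixtureEstimate:
    """Stock proportions with EM diagnostics and optional bootstrap CIs."""

    stocks: list[str]
    proportions: np.ndarray
    log_likelihood_trace: list[float]
    iterations: int
    converged: bool
    posteriors: pd.DataFrame | None = None        # z_is
    ci: pd.DataFrame | None = None                # stock, ci_low, ci_high, n_boot, level
    excluded_samples: list[str] = field(default_factory=list)
    assignment_proportions: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"stock": self.stocks, "proportion": self.proportions})
        if self.ci is not None:
            df = df.merge(self.ci, on="stock")
        return df


def _em_from_loglik(
    ll: np.ndarray, tol: float = 1e-6, max_iter: int = 10000,
    p0: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float], int, bool, np.ndarray]:
    """Run the EM on a fixed (n_individuals, n_stocks) log-likelihood grid."""
    n, S = ll.shape
    p = np.full(S, 1.0 / S) if p0 is None else np.asarray(p0, dtype=float)
    trace: list[float] = []
    z = np.full((n, S), 1.0 / S)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logw = np.log(np.maximum(p, 1e-300)) + ll
        norm = logsumexp(logw, axis=1)
        trace.append(float(norm.sum()))
        z = np.exp(logw - norm[:, None])
        p_new = z.mean(axis=0)
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            if trace[-1] < trace[-2] - 1e-8:
                raise RuntimeError("EM log-likelihood decreased")
            converged = True
            p = p_new
            break
        p = p_new
    return p, trace, it, converged, z


def em_mixture(
    mix: GenotypeMatrix,
    baseline: StratifiedBaseline,
    stocks: Mapping[str, Sequence[str]] | str = "population",
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> MixtureEstimate:
    """Estimate stock proportions of a mixture sample against a fixed baseline.

    ``stocks`` is either a strata grouping name or an explicit mapping
    stock -> baseline sample ids. Mixture individuals with no called locus
    shared with the baseline are excluded with a warning.
    """
    groups = baseline.groups(stocks) if isinstance(stocks, str) else dict(stocks)
    ll, labels, kept, excluded = _mixture_loglik(mix, baseline.genotypes, groups)
    p, trace, iters, converged, z = _em_from_loglik(ll, tol, max_iter)
    return MixtureEstimate(
        labels, p, trace, iters, converged,
        posteriors=pd.DataFrame(z, index=kept, columns=labels),
        excluded_samples=excluded,
    )


def _mixture_loglik(
    mix: GenotypeMatrix, base_gm: GenotypeMatrix, groups: Mapping[str, Sequence[str]]
):
    shared = [l for l in mix.locus_ids if l in set(base_gm.locus_ids)]
    base = base_gm.subset_loci(shared)
    keep_loci = [shared[j] for j in _informative_loci(base)]
    if not keep_loci:
        raise ValueError("no shared informative loci between mixture and baseline")
    base = base.subset_loci(keep_loci)
    mix_sub = mix.subset_loci(keep_loci)
    called = (mix_sub.calls != MISSING).sum(axis=1)
    excluded = [s for s, c in zip(mix_sub.sample_ids, called) if c == 0]
    if excluded:
        warnings.warn(f"excluding mixture individuals with no usable loci: {excluded}")
        mix_sub = mix_sub.subset_samples(
            [s for s in mix_sub.sample_ids if s not in set(excluded)]
        )
    labels, alt, n = _group_counts(base, groups)
    ll = rm_loglik_matrix(mix_sub.calls, alt, n)
    return ll, labels, mix_sub.sample_ids, excluded


def bootstrap_ci(
    mix: GenotypeMatrix,
    baseline: StratifiedBaseline,
    stocks: Mapping[str, Sequence[str]] | str = "population",
    B: int = 10000,
    level: float = 0.95,
    seed: int | None = 0,
    resample_baseline: bool = False,
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> MixtureEstimate:
    """Point estimate plus percentile bootstrap CIs over ``B`` replicates.

    Mixture individuals are resampled with replacement; with
    ``resample_baseline`` the baseline is additionally resampled within each
    stock (recomputing its allele counts per replicate).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    groups = baseline.groups(stocks) if isinstance(stocks, str) else dict(stocks)
    est = em_mixture(mix, baseline, stocks, tol, max_iter)
    rng = np.random.default_rng(seed)
    n = len(est.posteriors)
    S = len(est.stocks)
    boots = np.empty((B, S))
    if not resample_baseline:
        ll, labels, kept, _ = _mixture_loglik(mix, baseline.genotypes, groups)
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            boots[b] = _em_from_loglik(ll[idx], tol, max_iter)[0]
    else:
        mix_kept = mix.subset_samples(est.posteriors.index)
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            bgroups = {
                g: [members[i] for i in rng.integers(0, len(members), len(members))]
                for g, members in groups.items()
            }
            ll_b, _, _, _ = _mixture_loglik(mix_kept, baseline.genotypes, bgroups)
            boots[b] = _em_from_loglik(ll_b[idx], tol, max_iter)[0]
    lo = (1 - level) / 2
    ci = pd.DataFrame(
        {
            "stock": est.stocks,
            "ci_low": np.quantile(boots, lo, axis=0),
            "ci_high": np.quantile(boots, 1 - lo, axis=0),
            "n_boot": B,
            "level": level,
        }
    )
    est.ci = ci
    return est


def proportion_from_assignment(ar: AssignmentResult) -> pd.Series:
    """Stock proportions implied by hard individual assignment.

    Proportion = assigned count / total assigned; the unassigned count is
    reported under the index entry "unassigned_n" for transparency.
    """
    assigned = ar.table[ar.table["assigned_group"] != "unassigned"]
    n = len(assigned)
    if n == 0:
        raise ValueError("no assigned individuals: proportions undefined")
    prop = (
        assigned["assigned_group"].value_counts().reindex(ar.groups, fill_value=0) / n
    )
    prop.loc["unassigned_n"] = float(len(ar.table) - n)
    return prop
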