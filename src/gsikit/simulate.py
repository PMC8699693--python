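"""Synthetic baselines, mixtures, read counts and replicates.

The generative model is a hierarchical Balding–Nichols construction: each
locus has an ancestral frequency p ~ U(0.05, 0.95); each basin draws its
frequency from Beta(p(1-F_basin)/F_basin, (1-p)(1-F_basin)/F_basin); each
population draws around its basin value with F_pop. A subset of "ecotype
loci" additionally carries a parallel allele-frequency shift of +/- delta/2
between reproductive ecotypes, applied with the same sign in every system,
so one panel can separate co-occurring ecotypes across lakes. Genotypes are
Binomial(2, freq) draws (linkage equilibrium).

The default world mirrors the 14-population, 3-basin British Columbia
O. nerka baseline (populations, lakes, basins, migratory forms, reproductive
ecotypes and reference sample sizes as published); every generator is a pure
function of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import ReadCountTable
from .core import MISSING, GenotypeMatrix, Locus, StratifiedBaseline


@dataclass(frozen=True)
class PopulationDef:
    name: str
    system: str
    basin: str
    form: str
    ecotype: str
    n_ref: int
    n_novel: int = 4


#: The published 14-population baseline structure and reference sample sizes.
TABLE1_POPULATIONS: tuple[PopulationDef, ...] = (
    PopulationDef("WoodLake_shore", "Wood Lake", "Columbia", "kokanee", "shore", 34, 4),
    PopulationDef("WoodLake_stream", "Wood Lake", "Columbia", "kokanee", "stream", 34, 4),
    PopulationDef("KootenayWest_shore", "Kootenay Lake", "Columbia", "kokanee", "shore", 45, 4),
    PopulationDef("KootenayWest_stream", "Kootenay Lake", "Columbia", "kokanee", "stream", 48, 4),
    PopulationDef("KootenayNorth_stream", "Kootenay Lake", "Columbia", "kokanee", "stream", 22, 4),
    PopulationDef("Okanagan_shore", "Okanagan Lake", "Columbia", "kokanee", "shore", 48, 4),
    PopulationDef("Okanagan_stream", "Okanagan Lake", "Columbia", "kokanee", "stream", 48, 4),
    PopulationDef("Skaha_stream", "Skaha Lake", "Columbia", "kokanee", "stream", 20, 4),
    PopulationDef("OkanaganRiver_sockeye", "Okanagan River", "Columbia", "sockeye", "stream", 35, 4),
    PopulationDef("PortageCreek_sockeye", "Portage Creek", "Fraser", "sockeye", "stream", 23, 4),
    PopulationDef("Anderson_deep", "Anderson Lake", "Fraser", "kokanee", "deep", 23, 4),
    PopulationDef("Seton_deep", "Seton Lake", "Fraser", "kokanee", "deep", 23, 4),
    PopulationDef("Tchesinkut_shore", "Tchesinkut Lake", "Skeena", "kokanee", "shore", 36, 4),
    PopulationDef("Tchesinkut_stream", "Tchesinkut Lake", "Skeena", "kokanee", "stream", 36, 4),
)

#: Reference populations pooled into single assignment units (within-system
#: pairs published as unstructured).
POOLED_UNITS: dict[str, str] = {
    "KootenayWest_shore": "KootenayWest",
    "KootenayWest_stream": "KootenayWest",
    "Anderson_deep": "AndersonSeton_deep",
    "Seton_deep": "AndersonSeton_deep",
    "Tchesinkut_shore": "Tchesinkut",
    "Tchesinkut_stream": "Tchesinkut",
}

#: Parallel shift direction per ecotype at ecotype loci (x delta/2).
ECOTYPE_SHIFT = {"stream": -1.0, "shore": 1.0, "deep": 1.0}


@dataclass(frozen=True)
class SimulationConfig:
    """The stated synthetic world; defaults are the package's standing choices.

    F parameters are Balding–Nichols differentiation levels; ``delta`` is the
    allele-frequency gap planted between co-occurring ecotypes at ecotype
    loci; depth follows a negative binomial with the given mean/dispersion;
    ``error_rate`` is the per-read allele error and ``missing_rate`` the
    fraction of genotype calls blanked by :func:`inject_missing`.
    """

    seed: int = 0
    populations: tuple[PopulationDef, ...] = TABLE1_POPULATIONS
    f_basin: float = 0.15
    f_pop: float = 0.08
    n_loci_neutral: int = 228
    n_loci_ecotype: int = 60
    delta: float = 0.5
    mixture_proportions: tuple[tuple[str, float], ...] = (
        ("WoodLake_shore", 0.39),
        ("WoodLake_stream", 0.61),
    )
    mixture_n: int = 150
    depth_mean: float = 118.0
    depth_dispersion: float = 3.0
    error_rate: float = 0.005
    missing_rate: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.f_basin < 1 and 0 < self.f_pop < 1):
            raise ValueError("F parameters must lie in (0, 1)")
        if not 0 <= self.delta < 0.98:
            raise ValueError("delta infeasible: shifted frequencies cannot stay in [0.01, 0.99]")
        props = dict(self.mixture_proportions)
        if props and abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def strong_divergence(cfg: SimulationConfig | None = None) -> SimulationConfig:
    """Preset with divergence high enough for near-perfect assignment."""
    return replace(cfg or SimulationConfig(), f_basin=0.30, f_pop=0.15, delta=0.8)


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

def _bn_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols Beta draw around ancestral/parent frequencies p."""
    scale = (1.0 - f) / f
    return rng.beta(np.clip(p * scale, 1e-6, None),
                    np.clip((1.0 - p) * scale, 1e-6, None))


def simulate_baseline(
    cfg: SimulationConfig,
) -> tuple[StratifiedBaseline, pd.DataFrame]:
    """Simulate the stratified baseline and return it with the true
    per-population allele frequencies (populations x loci)."""
    rng = np.random.default_rng(cfg.seed)
    n_loci = cfg.n_loci_neutral + cfg.n_loci_ecotype
    is_eco = np.zeros(n_loci, dtype=bool)
    is_eco[cfg.n_loci_neutral:] = True
    loci = [
        Locus(
            f"{'eco' if is_eco[j] else 'neu'}_{j:04d}",
            f"contig_{j:04d}",
            int(rng.integers(1, 91)),
            *rng.choice(list("ACGT"), size=2, replace=False),
            90,
        )
        for j in range(n_loci)
    ]

    anc = rng.uniform(0.05, 0.95, size=n_loci)
    basins = sorted({p.basin for p in cfg.populations})
    basin_freq = {b: np.clip(_bn_draw(rng, anc, cfg.f_basin), 0.01, 0.99)
                  for b in basins}
    pop_freq = {}
    for pop in cfg.populations:
        f = np.clip(_bn_draw(rng, basin_freq[pop.basin], cfg.f_pop), 0.01, 0.99)
        shift = ECOTYPE_SHIFT[pop.ecotype] * cfg.delta / 2.0
        f[is_eco] = np.clip(f[is_eco] + shift, 0.01, 0.99)
        pop_freq[pop.name] = f
    freqs = pd.DataFrame(pop_freq, index=[l.locus_id for l in loci]).T

    ids, rows, strata_rows = [], [], []
    for pop in cfg.populations:
        draws = rng.binomial(2, pop_freq[pop.name], size=(pop.n_ref, n_loci))
        for k in range(pop.n_ref):
            sid = f"{pop.name}_{k:03d}"
            ids.append(sid)
            rows.append(draws[k].astype(np.int16))
            strata_rows.append(
                {"sample": sid, "population": pop.name, "system": pop.system,
                 "basin": pop.basin, "form": pop.form, "ecotype": pop.ecotype}
            )
    gm = GenotypeMatrix(ids, loci, np.vstack(rows))
    strata = pd.DataFrame(strata_rows).set_index("sample")
    return StratifiedBaseline(gm, strata), freqs


def simulate_novel(
    cfg: SimulationConfig,
    freqs: pd.DataFrame,
    seed: int | None = None,
    loci: Sequence[Locus] | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Individuals from the true population frequencies, not in the baseline."""
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    if loci is None:
        loci = [Locus(lid, f"contig_{lid[-4:]}", 45, "A", "G", 90)
                for lid in freqs.columns]
    else:
        loci = list(loci)
    ids, rows, truth = [], [], []
    for pop in cfg.populations:
        f = freqs.loc[pop.name].to_numpy()
        for k in range(pop.n_novel):
            ids.append(f"novel_{pop.name}_{k:02d}")
            rows.append(rng.binomial(2, f).astype(np.int16))
            truth.append(pop.name)
    calls = np.vstack(rows) if rows else np.empty((0, len(loci)), dtype=np.int16)
    return GenotypeMatrix(ids, loci, calls), truth


def pooled_labels(strata: pd.DataFrame,
                  pools: Mapping[str, str] = POOLED_UNITS) -> pd.Series:
    """Population labels with the published pooled units collapsed."""
    return strata["population"].map(lambda p: pools.get(p, p))


# ---------------------------------------------------------------------------
# Mixtures
# ---------------------------------------------------------------------------

def simulate_mixture(
    freqs: pd.DataFrame,
    proportions: Mapping[str, float],
    n: int,
    seed: int | None = 0,
    loci: Sequence[Locus] | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Mixture individuals of hidden stock origin drawn from ``proportions``."""
    rng = np.random.default_rng(seed)
    stocks = sorted(proportions)
    p = np.array([proportions[s] for s in stocks], dtype=float)
    if abs(p.sum() - 1) > 1e-9 or (p < 0).any():
        raise ValueError("proportions must form a simplex")
    if loci is None:
        loci = [Locus(lid, f"contig_{lid[-4:]}", 45, "A", "G", 90)
                for lid in freqs.columns]
    else:
        loci = list(loci)
    origin = rng.choice(len(stocks), size=n, p=p)
    rows, truth = [], []
    for i in range(n):
        stock = stocks[origin[i]]
        rows.append(rng.binomial(2, freqs.loc[stock].to_numpy()).astype(np.int16))
        truth.append(stock)
    calls = np.vstack(rows) if rows else np.empty((0, len(loci)), dtype=np.int16)
    ids = [f"mix_{i:04d}" for i in range(n)]
    return GenotypeMatrix(ids, loci, calls), truth


# ---------------------------------------------------------------------------
# Read counts, replicates, missingness
# ---------------------------------------------------------------------------

def simulate_readcounts(
    gm: GenotypeMatrix,
    depth_mean: float = 118.0,
    dispersion: float = 3.0,
    error_rate: float = 0.005,
    seed: int | None = 0,
    zero_loci: Sequence[str] = (),
    overshare_loci: Sequence[str] = (),
    overshare_factor: float = 30.0,
) -> ReadCountTable:
    """Negative-binomial amplicon depths with per-read allele error.

    Cells with a missing genotype get zero reads (a failed amplicon is what
    missingness looks like upstream of the caller). ``zero_loci`` and
    ``overshare_loci`` plant primer-QC failure modes: no reads at all, or a
    depth inflated ``overshare_factor``-fold (overamplifying primer).
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    shape = gm.calls.shape
    p_nb = dispersion / (dispersion + depth_mean)
    depth = rng.negative_binomial(dispersion, p_nb, size=shape)
    depth[gm.calls == MISSING] = 0
    lpos = {l: j for j, l in enumerate(gm.locus_ids)}
    for l in overshare_loci:
        depth[:, lpos[l]] = (depth[:, lpos[l]] * overshare_factor).astype(depth.dtype)
    for l in zero_loci:
        depth[:, lpos[l]] = 0
    g = np.where(gm.calls == MISSING, 0, gm.calls)
    p_alt = (g / 2.0) * (1 - error_rate) + (1 - g / 2.0) * error_rate
    alt = rng.binomial(depth, p_alt)
    return ReadCountTable(list(gm.sample_ids), list(gm.locus_ids),
                          depth - alt, alt)


def simulate_replicates(
    gm: GenotypeMatrix, per_allele_error: float = 0.01, seed: int | None = 0
) -> GenotypeMatrix:
    """Re-measure every genotype with independent per-allele-copy error.

    Each of the two allele copies flips with probability ``per_allele_error``;
    missing calls stay missing. With error 0 the replicate is identical.
    """
    if not 0 <= per_allele_error < 1:
        raise ValueError("per_allele_error must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    g = gm.calls
    called = g != MISSING
    alt = np.where(called, g, 0)
    kept_alt = rng.binomial(alt, 1 - per_allele_error)
    flipped_ref = rng.binomial(np.where(called, 2 - alt, 0), per_allele_error)
    new = (kept_alt + flipped_ref).astype(np.int16)
    new[~called] = MISSING
    return GenotypeMatrix(list(gm.sample_ids), list(gm.loci), new)


def inject_missing(
    gm: GenotypeMatrix, rate: float, seed: int | None = 0
) -> GenotypeMatrix:
    """Blank calls uniformly at random at the given rate."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(gm.calls.shape) < rate
    calls = gm.calls.copy()
    calls[mask] = MISSING
    return GenotypeMatrix(list(gm.sample_ids), list(gm.loci), calls)
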