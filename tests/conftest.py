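import numpy as np
import pytest

from gsikit import (
    GenotypeMatrix,
    Locus,
    SimulationConfig,
    StratifiedBaseline,
    inject_missing,
    simulate_baseline,
)

ALLELES = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def random_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_loci: int,
    missing_rate: float = 0.1,
) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n_samples, n_loci)).astype(np.int16)
    calls[rng.random(calls.shape) < missing_rate] = -1
    loci = [
        Locus(f"L{j:03d}", f"ctg{j:03d}", int(rng.integers(1, 91)),
              *ALLELES[j % len(ALLELES)], 90)
        for j in range(n_loci)
    ]
    return GenotypeMatrix([f"S{i:03d}" for i in range(n_samples)], loci, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_world():
    """The stated synthetic world: the 14-population baseline with missing
    data injected at the configured rate, plus the true frequencies."""
    cfg = SimulationConfig(seed=1)
    baseline, freqs = simulate_baseline(cfg)
    observed = StratifiedBaseline(
        inject_missing(baseline.genotypes, cfg.missing_rate, seed=cfg.seed + 10),
        baseline.strata,
    )
    return cfg, observed, freqs


@pytest.fixture(scope="session")
def two_pop_world():
    """Two strongly diverged populations for separability checks."""
    rng = np.random.default_rng(777)
    n_loci = 100
    fa = rng.uniform(0.05, 0.3, n_loci)
    fb = rng.uniform(0.7, 0.95, n_loci)
    loci = [Locus(f"L{j:03d}", f"ctg{j}", 45, "A", "G", 90) for j in range(n_loci)]
    calls = np.vstack(
        [rng.binomial(2, fa, size=(30, n_loci)), rng.binomial(2, fb, size=(30, n_loci))]
    ).astype(np.int16)
    ids = [f"A{i:02d}" for i in range(30)] + [f"B{i:02d}" for i in range(30)]
    gm = GenotypeMatrix(ids, loci, calls)
    import pandas as pd

    strata = pd.DataFrame(
        {
            "population": ["PopA"] * 30 + ["PopB"] * 30,
            "system": "Lake X",
            "basin": "Columbia",
            "form": "kokanee",
            "ecotype": ["shore"] * 30 + ["stream"] * 30,
        },
        index=ids,
    )
    return StratifiedBaseline(gm, strata), fa, fb
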