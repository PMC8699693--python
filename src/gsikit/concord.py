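"""Genotype discordance between replicate samples and label concordance
between assignment methods."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


@dataclass
class DiscordanceReport:
    """Per-pair genotype mismatch rates between replicate samples.

    ``discordance_pct`` divides by loci called in both members of a pair;
    ``discordance_pct_all`` divides by the full shared-panel size, so both
    readings of the denominator are available.
    """

    pairs: pd.DataFrame
    mean_discordance_pct: float


def genotype_discordance(
    gm_a: GenotypeMatrix,
    gm_b: GenotypeMatrix,
    pair_map: Mapping[str, tuple[str, str]],
) -> DiscordanceReport:
    """Compare replicate genotypes across two matrices (e.g. two platforms).

    ``pair_map`` maps a pair name to (sample in gm_a, sample in gm_b). Cells
    missing in either member are excluded from the shared-called denominator;
    a pair with zero shared called loci is reported undefined (NaN).
    """
    shared = [l for l in gm_a.locus_ids if l in set(gm_b.locus_ids)]
    if not shared:
        raise ValueError("matrices share no loci")
    a = gm_a.subset_loci(shared)
    b = gm_b.subset_loci(shared)
    rows = []
    for name, (sa, sb) in pair_map.items():
        va = a.calls[a.sample_index(sa)]
        vb = b.calls[b.sample_index(sb)]
        both = (va != MISSING) & (vb != MISSING)
        n_shared = int(both.sum())
        mismatch = int(((va != vb) & both).sum())
        rows.append(
            {
                "pair": name,
                "sample_a": sa,
                "sample_b": sb,
                "shared_called": n_shared,
                "mismatches": mismatch,
                "discordance_pct": 100.0 * mismatch / n_shared if n_shared else np.nan,
                "discordance_pct_all": 100.0 * mismatch / len(shared),
            }
        )
    df = pd.DataFrame(rows)
    defined = df["discordance_pct"].dropna()
    return DiscordanceReport(df, float(defined.mean()) if len(defined) else np.nan)


def assignment_concordance(
    labels_a: Mapping[str, str] | pd.Series,
    labels_b: Mapping[str, str] | pd.Series,
    exclude: Sequence[str] = ("ambiguous", "unassigned"),
) -> dict:
    """Percent agreement between two label sets over the same samples.

    Samples labelled with any of ``exclude`` in either set are dropped from
    the denominator and counted separately. Returns a dict with
    ``percent_agreement``, ``n_compared``, ``n_excluded`` and the full
    ``cross_table``.
    """
    sa = pd.Series(labels_a, dtype=object)
    sb = pd.Series(labels_b, dtype=object)
    common = sa.index.intersection(sb.index)
    if len(common) == 0:
        raise ValueError("label sets share no samples")
    sa, sb = sa.loc[common], sb.loc[common]
    keep = ~(sa.isin(exclude) | sb.isin(exclude))
    n_comp = int(keep.sum())
    agree = int((sa[keep] == sb[keep]).sum())
    return {
        "percent_agreement": 100.0 * agree / n_comp if n_comp else np.nan,
        "n_compared": n_comp,
        "n_excluded": int(len(common) - n_comp),
        "cross_table": pd.crosstab(sa, sb, rownames=["method_a"],
                                   colnames=["method_b"]),
    }
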