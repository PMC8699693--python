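"""Genotype calling from per-locus allele read counts.

Mirrors the allele-ratio caller used by amplicon (GT-seq style) pipelines:
a cell with total depth below ``min_depth`` is a no-call; otherwise the
pseudocounted ref/alt ratio decides hom-ref, het, hom-alt, with an ambiguous
band between the het and hom cutoffs left missing rather than forced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, Locus


@dataclass
class ReadCountTable:
    """Per sample x locus reference/alternate read counts."""

    sample_ids: list[str]
    locus_ids: list[str]
    ref: np.ndarray  # (n_samples, n_loci) int64
    alt: np.ndarray
    library_total: int | None = None  # raw reads incl. off-target; >= on-target sum

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        shape = (len(self.sample_ids), len(self.locus_ids))
        if self.ref.shape != shape or self.alt.shape != shape:
            raise ValueError("count grids do not match id lists")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.library_total is None:
            self.library_total = int(self.ref.sum() + self.alt.sum())
        elif self.library_total < self.ref.sum() + self.alt.sum():
            raise ValueError("library total below on-target read sum")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    def sample_totals(self) -> np.ndarray:
        return self.depth.sum(axis=1)

    def locus_totals(self) -> np.ndarray:
        return self.depth.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, s in enumerate(self.sample_ids):
            for j, l in enumerate(self.locus_ids):
                recs.append((s, l, int(self.ref[i, j]), int(self.alt[i, j])))
        return pd.DataFrame(recs, columns=["sample", "locus", "ref_count", "alt_count"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, library_total: int | None = None) -> "ReadCountTable":
        df = pd.read_csv(path, dtype={"sample": str, "locus": str})
        need = {"sample", "locus", "ref_count", "alt_count"}
        if not need <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(need)}")
        samples = list(dict.fromkeys(df["sample"]))
        loci = list(dict.fromkeys(df["locus"]))
        si = {s: i for i, s in enumerate(samples)}
        lj = {l: j for j, l in enumerate(loci)}
        ref = np.zeros((len(samples), len(loci)), dtype=np.int64)
        alt = np.zeros_like(ref)
        ref[df["sample"].map(si), df["locus"].map(lj)] = df["ref_count"]
        alt[df["sample"].map(si), df["locus"].map(lj)] = df["alt_count"]
        return cls(samples, loci, ref, alt, library_total)


@dataclass
class GenotypeCallReport:
    """Calls plus the depth/rate summaries amplicon panels are judged on."""

    genotypes: GenotypeMatrix
    mean_depth: float              # over called cells
    genotyping_rate: float         # non-missing fraction over all cells
    locus_summary: pd.DataFrame    # mean_depth, genotyping_rate per locus
    sample_summary: pd.DataFrame


def call_genotypes(
    rc: ReadCountTable,
    min_depth: int = 10,
    hom_ratio: float = 10.0,
    het_low: float = 0.2,
    het_high: float = 5.0,
    loci: Sequence[Locus] | None = None,
) -> GenotypeCallReport:
    """Call dosages from allele counts with the ratio rule.

    For each cell with ``total = ref + alt``: total < min_depth -> MISSING;
    else with ``ratio = (ref + 0.1) / (alt + 0.1)``: ratio >= hom_ratio -> 0,
    ratio <= 1/hom_ratio -> 2, het_low <= ratio <= het_high -> 1, otherwise
    MISSING (ambiguous band). Thresholds must satisfy
    het_low < 1 < het_high < hom_ratio so the classes cannot overlap.
    """
    if not (min_depth > 0 and het_low < 1 < het_high < hom_ratio):
        raise ValueError("need min_depth > 0 and het_low < 1 < het_high < hom_ratio")
    total = rc.depth
    ratio = (rc.ref + 0.1) / (rc.alt + 0.1)
    calls = np.full(total.shape, MISSING, dtype=np.int16)
    deep = total >= min_depth
    calls[deep & (ratio >= hom_ratio)] = 0
    calls[deep & (ratio <= 1.0 / hom_ratio)] = 2
    calls[deep & (ratio >= het_low) & (ratio <= het_high)] = 1

    if loci is None:
        loci = [Locus(lid) for lid in rc.locus_ids]
    else:
        loci = list(loci)
        if [l.locus_id for l in loci] != list(rc.locus_ids):
            raise ValueError("loci do not match the count table columns")
    gm = GenotypeMatrix(list(rc.sample_ids), loci, calls)

    called = calls != MISSING
    mean_depth = float(total[called].mean()) if called.any() else np.nan
    rate = float(called.mean()) if called.size else np.nan

    def _summ(axis: int, ids: list[str]) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            dsum = np.where(called, total, 0).sum(axis=axis).astype(float)
            ncall = called.sum(axis=axis)
            md = np.where(ncall > 0, dsum / np.maximum(ncall, 1), np.nan)
            gr = called.mean(axis=axis) if called.shape[axis] else np.full(len(ids), np.nan)
        return pd.DataFrame({"mean_depth": md, "genotyping_rate": gr}, index=ids)

    return GenotypeCallReport(
        gm,
        mean_depth,
        rate,
        locus_summary=_summ(0, list(rc.locus_ids)),
        sample_summary=_summ(1, list(rc.sample_ids)),
    )


def summarize(report: GenotypeCallReport) -> dict[str, float]:
    """Headline depth/rate numbers from a call report."""
    return {
        "mean_depth": report.mean_depth,
        "genotyping_rate": report.genotyping_rate,
        "n_samples": report.genotypes.n_samples,
        "n_loci": report.genotypes.n_loci,
    }
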