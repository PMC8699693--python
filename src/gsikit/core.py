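"""Core containers for diploid biallelic SNP data.

Genotypes are stored as alt-allele dosages: 0 (hom ref), 1 (het), 2 (hom alt),
with :data:`MISSING` (-1) for no-calls. Allele order in text formats (PED) is
not meaningful and is normalized against the declared ref/alt on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1

#: Valid basin labels for the British Columbia O. nerka baseline hierarchy.
BASINS = ("Columbia", "Fraser", "Skeena")
FORMS = ("kokanee", "sockeye")
ECOTYPES = ("stream", "shore", "deep")


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP on an amplicon/RAD contig.

    ``snp_position`` is the 1-based offset of the SNP within the contig
    sequence (1-based closed conventions throughout).
    """

    locus_id: str
    contig_id: str = ""
    snp_position: int = 1
    ref_allele: str = "A"
    alt_allele: str = "G"
    contig_length: int = 90

    def __post_init__(self) -> None:
        if not (1 <= self.snp_position <= self.contig_length):
            raise ValueError(
                f"locus {self.locus_id}: snp_position {self.snp_position} outside "
                f"[1, {self.contig_length}]"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"locus {self.locus_id}: ref and alt alleles are equal")


@dataclass
class GenotypeMatrix:
    """Samples x loci grid of alt-allele dosages in {0, 1, 2, MISSING}."""

    sample_ids: list[str]
    loci: list[Locus]
    calls: np.ndarray  # (n_samples, n_loci) int16

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def locus_missing_fraction(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_loci)
        return (self.calls == MISSING).mean(axis=0)

    def sample_missing_fraction(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    # -- subsetting ------------------------------------------------------
    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in index], list(self.loci), self.calls[index, :]
        )

    def take_loci(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            list(self.sample_ids), [self.loci[j] for j in index], self.calls[:, index]
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.take_samples([pos[s] for s in sample_ids])

    def subset_loci(self, locus_ids: Iterable[str]) -> "GenotypeMatrix":
        pos = {l.locus_id: j for j, l in enumerate(self.loci)}
        return self.take_loci([pos[l] for l in locus_ids])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sample_ids), list(self.loci), self.calls.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.sample_ids, columns=self.locus_ids)


#: Required columns of a strata table, in order.
STRATA_COLUMNS = ("sample", "population", "system", "basin", "form", "ecotype")


@dataclass
class StratifiedBaseline:
    """A genotype baseline with the five per-sample strata labels.

    ``strata`` is indexed by sample id and carries columns
    population / system / basin / form / ecotype, aligned with
    ``genotypes.sample_ids``.
    """

    genotypes: GenotypeMatrix
    strata: pd.DataFrame

    def __post_init__(self) -> None:
        need = set(STRATA_COLUMNS[1:])
        missing = need - set(self.strata.columns)
        if missing:
            raise ValueError(f"strata table missing columns: {sorted(missing)}")
        if list(self.strata.index) != list(self.genotypes.sample_ids):
            self.strata = self.strata.loc[self.genotypes.sample_ids]
        if self.strata[list(need)].isna().any().any():
            raise ValueError("every sample must carry all strata labels")
        bad_basin = set(self.strata["basin"]) - set(BASINS)
        if bad_basin:
            raise ValueError(f"unknown basin labels: {sorted(bad_basin)}")
        bad_form = set(self.strata["form"]) - set(FORMS)
        if bad_form:
            raise ValueError(f"unknown migratory-form labels: {sorted(bad_form)}")
        bad_eco = set(self.strata["ecotype"]) - set(ECOTYPES)
        if bad_eco:
            raise ValueError(f"unknown ecotype labels: {sorted(bad_eco)}")

    def labels(self, grouping: str) -> pd.Series:
        """Per-sample group label for one of the strata fields.

        ``grouping`` is one of population / system / basin / form / ecotype.
        """
        if grouping not in STRATA_COLUMNS[1:]:
            raise ValueError(f"unknown grouping {grouping!r}")
        return self.strata[grouping]

    def groups(self, grouping: str) -> dict[str, list[str]]:
        """Group label -> ordered sample-id list."""
        lab = self.labels(grouping)
        out: dict[str, list[str]] = {}
        for s, g in lab.items():
            out.setdefault(str(g), []).append(s)
        return out

    def subset_samples(self, sample_ids: Iterable[str]) -> "StratifiedBaseline":
        ids = list(sample_ids)
        return StratifiedBaseline(self.genotypes.subset_samples(ids), self.strata.loc[ids])

    def subset_loci(self, locus_ids: Iterable[str]) -> "StratifiedBaseline":
        return StratifiedBaseline(self.genotypes.subset_loci(locus_ids), self.strata)
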