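"""Readers and writers for PED/MAP, VCF and strata tables, plus the
missing-data filter and replicate merging applied before any analysis.

PED/MAP is the PLINK text dialect (6 leading columns, two allele columns per
locus, "0 0" = missing). VCF support is restricted to biallelic SNP records;
reading goes through cyvcf2, writing emits a minimal VCF v4.2 by hand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, Locus, StratifiedBaseline, STRATA_COLUMNS


class FormatError(ValueError):
    """Malformed file structure (column counts, headers)."""


class DataError(ValueError):
    """Structurally valid file with inadmissible values."""


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def read_map(map_path: str | Path) -> list[Locus]:
    """Read a PLINK .map file into Locus records.

    Columns: chrom/contig, locus_id, genetic distance (ignored), position.
    Ref/alt alleles are not encoded in .map; we carry them in two optional
    trailing columns (written by :func:`write_ped`) and default to A/G.
    """
    loci: list[Locus] = []
    for k, line in enumerate(Path(map_path).read_text().splitlines()):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (4, 6):
            raise FormatError(f"{map_path}: row {k}: expected 4 or 6 columns, got {len(parts)}")
        contig, locus_id, _cm, pos = parts[:4]
        ref, alt = (parts[4], parts[5]) if len(parts) == 6 else ("A", "G")
        pos_i = int(pos)
        loci.append(
            Locus(locus_id, contig, max(pos_i, 1), ref, alt, max(pos_i, 1, 90))
        )
    return loci


def read_ped(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read PED/MAP into a GenotypeMatrix of alt-allele dosages.

    Allele pairs are recoded against the MAP-declared ref/alt; "0 0" becomes
    MISSING. Allele order within a pair is not meaningful.
    """
    loci = read_map(map_path)
    n_loci = len(loci)
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    for k, line in enumerate(Path(ped_path).read_text().splitlines()):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_loci:
            raise FormatError(
                f"{ped_path}: row {k}: expected {6 + 2 * n_loci} columns "
                f"(6 + 2x{n_loci} loci), got {len(parts)}"
            )
        sample_ids.append(parts[1])
        calls = np.empty(n_loci, dtype=np.int16)
        for j, loc in enumerate(loci):
            a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
            calls[j] = _recode_pair(a1, a2, loc)
        rows.append(calls)
    calls = np.vstack(rows) if rows else np.empty((0, n_loci), dtype=np.int16)
    return GenotypeMatrix(sample_ids, loci, calls)


def _recode_pair(a1: str, a2: str, loc: Locus) -> int:
    if a1 == "0" and a2 == "0":
        return MISSING
    dosage = 0
    for a in (a1, a2):
        if a == loc.alt_allele:
            dosage += 1
        elif a != loc.ref_allele:
            raise DataError(
                f"locus {loc.locus_id}: allele {a!r} not in "
                f"{{{loc.ref_allele}, {loc.alt_allele}, 0}}"
            )
    return dosage


def write_ped(gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path,
              family_id: str = "FAM") -> None:
    """Write PED/MAP; ref/alt are appended to the .map so round trips close."""
    with open(map_path, "w") as fh:
        for loc in gm.loci:
            fh.write(
                f"{loc.contig_id or '0'}\t{loc.locus_id}\t0\t{loc.snp_position}"
                f"\t{loc.ref_allele}\t{loc.alt_allele}\n"
            )
    code = {MISSING: ("0", "0")}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = [family_id, sid, "0", "0", "0", "-9"]
            for j, loc in enumerate(gm.loci):
                g = int(gm.calls[i, j])
                if g == MISSING:
                    pair = ("0", "0")
                elif g == 0:
                    pair = (loc.ref_allele, loc.ref_allele)
                elif g == 1:
                    pair = (loc.ref_allele, loc.alt_allele)
                else:
                    pair = (loc.alt_allele, loc.alt_allele)
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF (biallelic SNP subset)
# ---------------------------------------------------------------------------

def read_vcf(vcf_path: str | Path, strict: bool = True) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (GT 0/0 -> 0, 0/1 -> 1, 1/1 -> 2).

    Multi-allelic or non-SNP records raise under ``strict``; otherwise they
    are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    loci: list[Locus] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        snp = (
            len(rec.ALT) == 1
            and len(rec.REF) == 1
            and len(rec.ALT[0]) == 1
            and rec.REF != rec.ALT[0]
        )
        if not snp:
            if strict:
                raise DataError(
                    f"{vcf_path}: non-SNP or multi-allelic record at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            warnings.warn(f"skipping non-biallelic-SNP record {rec.CHROM}:{rec.POS}")
            continue
        lid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        loci.append(Locus(lid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                          max(rec.POS, 90)))
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = rec.gt_types
        col = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        cols.append(col.astype(np.int16))
    calls = (
        np.column_stack(cols) if cols else np.empty((len(sample_ids), 0), dtype=np.int16)
    )
    return GenotypeMatrix(sample_ids, loci, calls)


def write_vcf(gm: GenotypeMatrix, vcf_path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT fields only."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = []
        for loc in gm.loci:
            if loc.contig_id not in contigs:
                contigs.append(loc.contig_id)
        for c in contigs:
            length = max(l.contig_length for l in gm.loci if l.contig_id == c)
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, loc in enumerate(gm.loci):
            gts = "\t".join(gt_str[int(g)] for g in gm.calls[:, j])
            fh.write(
                f"{loc.contig_id}\t{loc.snp_position}\t{loc.locus_id}\t"
                f"{loc.ref_allele}\t{loc.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Strata tables
# ---------------------------------------------------------------------------

def read_strata(path: str | Path) -> pd.DataFrame:
    """Read a strata CSV (header sample,population,system,basin,form,ecotype)."""
    df = pd.read_csv(path, dtype=str)
    missing = set(STRATA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: strata table missing columns {sorted(missing)}")
    return df.set_index("sample")


def write_strata(strata: pd.DataFrame, path: str | Path) -> None:
    strata.reset_index(names="sample")[list(STRATA_COLUMNS)].to_csv(path, index=False)


def read_baseline(ped_path: str | Path, map_path: str | Path,
                  strata_path: str | Path) -> StratifiedBaseline:
    gm = read_ped(ped_path, map_path)
    return StratifiedBaseline(gm, read_strata(strata_path))


# ---------------------------------------------------------------------------
# Missing-data filter
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """What :func:`filter_missing` removed, and why."""

    removed_loci: dict[str, float] = field(default_factory=dict)
    removed_samples: dict[str, float] = field(default_factory=dict)
    empty_result: bool = False


def filter_missing(
    gm: GenotypeMatrix,
    max_locus_missing: float = 0.3,
    max_sample_missing: float = 0.3,
    order: str = "loci_first",
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop loci, then samples, whose missing fraction strictly exceeds the
    thresholds (the quoted rules are ">30%" and a "50%" threshold, hence
    strict inequality).

    Samples are re-evaluated on the surviving loci. ``order="samples_first"``
    runs the two passes the other way around.
    """
    if not (0 <= max_locus_missing <= 1 and 0 <= max_sample_missing <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if order not in ("loci_first", "samples_first"):
        raise ValueError(f"unknown filter order {order!r}")
    report = FilterReport()

    def drop_loci(m: GenotypeMatrix) -> GenotypeMatrix:
        frac = m.locus_missing_fraction()
        keep = [j for j in range(m.n_loci) if frac[j] <= max_locus_missing]
        for j in range(m.n_loci):
            if frac[j] > max_locus_missing:
                report.removed_loci[m.loci[j].locus_id] = float(frac[j])
        return m.take_loci(keep)

    def drop_samples(m: GenotypeMatrix) -> GenotypeMatrix:
        frac = m.sample_missing_fraction()
        keep = [i for i in range(m.n_samples) if frac[i] <= max_sample_missing]
        for i in range(m.n_samples):
            if frac[i] > max_sample_missing:
                report.removed_samples[m.sample_ids[i]] = float(frac[i])
        return m.take_samples(keep)

    if order == "loci_first":
        out = drop_samples(drop_loci(gm))
    else:
        out = drop_loci(drop_samples(gm))
    if out.n_samples == 0 or out.n_loci == 0:
        report.empty_result = True
        warnings.warn("filter_missing removed every sample or every locus")
    return out, report


# ---------------------------------------------------------------------------
# Replicate merging
# ---------------------------------------------------------------------------

def merge_replicates(
    gm: GenotypeMatrix,
    replicate_map: Mapping[str, Sequence[str]],
    policy: str = "fewest_missing",
) -> GenotypeMatrix:
    """Collapse replicate samples of the same individual to one row.

    Agreeing calls (ignoring missing) are kept. Under the default policy a
    disagreement is resolved in favour of the replicate with fewer missing
    calls overall (a proxy for library quality); ties become MISSING. Policy
    ``"strict"`` turns any disagreement into MISSING.
    """
    if policy not in ("fewest_missing", "strict"):
        raise ValueError(f"unknown merge policy {policy!r}")
    pos = {s: i for i, s in enumerate(gm.sample_ids)}
    for name, members in replicate_map.items():
        for m in members:
            if m not in pos:
                raise KeyError(f"replicate {m!r} (group {name!r}) absent from matrix")
    grouped = {m for members in replicate_map.values() for m in members}

    out_ids: list[str] = []
    out_rows: list[np.ndarray] = []
    for sid in gm.sample_ids:  # ungrouped samples pass through in order
        if sid not in grouped:
            out_ids.append(sid)
            out_rows.append(gm.calls[pos[sid]])
    for name, members in replicate_map.items():
        rows = gm.calls[[pos[m] for m in members], :]
        n_missing = (rows == MISSING).sum(axis=1)
        merged = np.full(gm.n_loci, MISSING, dtype=np.int16)
        for j in range(gm.n_loci):
            called = rows[rows[:, j] != MISSING, j]
            if called.size == 0:
                continue
            vals = set(int(v) for v in called)
            if len(vals) == 1:
                merged[j] = called[0]
            elif policy == "fewest_missing":
                best = np.flatnonzero(rows[:, j] != MISSING)
                best = best[np.argsort(n_missing[best], kind="stable")]
                top = [b for b in best if n_missing[b] == n_missing[best[0]]]
                top_vals = {int(rows[b, j]) for b in top}
                if len(top_vals) == 1:
                    merged[j] = rows[top[0], j]
        out_ids.append(name)
        out_rows.append(merged)
    return GenotypeMatrix(out_ids, list(gm.loci), np.vstack(out_rows))
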