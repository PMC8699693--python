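"""Multi-scale SNP panel construction.

The pipeline is: flanking-sequence filter (SNP must sit in a primer-design
window of the contig), theta-ranked selection with per-category slot targets
(basin / migratory form / ecotype), de-duplication of loci chosen by more
than one category, LD pruning of significantly associated pairs, and
read-count-based primer QC on a test library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import ReadCountTable
from .core import Locus

CATEGORIES = ("basin", "migratory", "ecotype")
DEFAULT_TARGETS = {"basin": 200, "migratory": 100, "ecotype": 250}

STATUS_CANDIDATE = "candidate"
STATUS_SELECTED = "selected"
STATUS_DROPPED_FLANK = "dropped_flank"
STATUS_DROPPED_LD = "dropped_ld"
STATUS_DROPPED_QC = "dropped_qc"


@dataclass
class PanelSpec:
    """Candidate loci with per-category theta, tags and selection status.

    ``table`` is indexed by locus_id with columns contig, pos, ref, alt,
    theta_basin, theta_migratory, theta_ecotype, tags (comma-joined), status,
    drop_reason.
    """

    table: pd.DataFrame
    loci: dict[str, Locus] = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("a locus appears more than once in the panel table")

    @classmethod
    def from_candidates(
        cls,
        loci: Sequence[Locus],
        theta_tables: Mapping[str, Mapping[str, float]] | None = None,
    ) -> "PanelSpec":
        theta_tables = theta_tables or {}
        rows = {}
        for loc in loci:
            rows[loc.locus_id] = {
                "contig": loc.contig_id,
                "pos": loc.snp_position,
                "ref": loc.ref_allele,
                "alt": loc.alt_allele,
                **{
                    f"theta_{c}": float(theta_tables.get(c, {}).get(loc.locus_id, np.nan))
                    for c in CATEGORIES
                },
                "tags": "",
                "status": STATUS_CANDIDATE,
                "drop_reason": "",
            }
        return cls(pd.DataFrame.from_dict(rows, orient="index"),
                   {l.locus_id: l for l in loci})

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.index[self.table["status"] == STATUS_SELECTED])

    def tags_of(self, locus_id: str) -> frozenset[str]:
        t = self.table.loc[locus_id, "tags"]
        return frozenset(t.split(",")) if t else frozenset()

    def max_theta(self, locus_id: str) -> float:
        """Informativeness: the locus's maximum theta across its tagged
        categories (all categories if untagged)."""
        tags = self.tags_of(locus_id) or set(CATEGORIES)
        vals = [self.table.loc[locus_id, f"theta_{c}"] for c in tags]
        vals = [v for v in vals if np.isfinite(v)]
        return max(vals) if vals else -np.inf

    def write_csv(self, path: str | Path) -> None:
        out = self.table.reset_index(names="locus_id")
        out.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Flanking filter
# ---------------------------------------------------------------------------

def flanking_filter(
    loci: Sequence[Locus], window_start: int = 40, window_end: int = 70
) -> tuple[list[Locus], list[Locus]]:
    """Partition loci by whether the SNP sits inside the primer-design window
    [window_start, window_end] of its contig (1-based, both ends included)."""
    passed = [l for l in loci if window_start <= l.snp_position <= window_end]
    dropped = [l for l in loci if not (window_start <= l.snp_position <= window_end)]
    return passed, dropped


def apply_flanking_filter(panel: PanelSpec, window_start: int = 40,
                          window_end: int = 70) -> PanelSpec:
    pos = panel.table["pos"]
    out = (pos < window_start) | (pos > window_end)
    panel.table.loc[out, "status"] = STATUS_DROPPED_FLANK
    panel.table.loc[out, "drop_reason"] = "SNP outside flanking window"
    panel.report["n_dropped_flank"] = int(out.sum())
    return panel


# ---------------------------------------------------------------------------
# Theta-ranked selection
# ---------------------------------------------------------------------------

def rank_and_select(
    panel: PanelSpec,
    targets: Mapping[str, int] = DEFAULT_TARGETS,
) -> PanelSpec:
    """Take the top-``target`` loci per category from a theta-descending rank.

    Undefined theta ranks last; ties break lexicographically on locus_id.
    Loci chosen by more than one category appear once and carry all their
    tags, so the panel can be smaller than the sum of slots.
    """
    tbl = panel.table
    eligible = tbl.index[tbl["status"] == STATUS_CANDIDATE]
    chosen_tags: dict[str, set[str]] = {}
    per_category: dict[str, list[str]] = {}
    for cat in CATEGORIES:
        if cat not in targets:
            continue
        target = int(targets[cat])
        theta = tbl.loc[eligible, f"theta_{cat}"]
        # sort: defined theta descending, NaN last, locus_id ascending
        order = sorted(
            eligible,
            key=lambda lid: (
                not np.isfinite(theta[lid]),
                -(theta[lid] if np.isfinite(theta[lid]) else 0.0),
                lid,
            ),
        )
        if target > len(order):
            warnings.warn(
                f"category {cat}: target {target} exceeds pool size {len(order)}"
            )
        take = order[:target]
        per_category[cat] = take
        for lid in take:
            chosen_tags.setdefault(lid, set()).add(cat)

    for lid, tags in chosen_tags.items():
        tbl.loc[lid, "status"] = STATUS_SELECTED
        tbl.loc[lid, "tags"] = ",".join(sorted(tags))
    slots = sum(int(targets[c]) for c in CATEGORIES if c in targets)
    panel.report.update(
        {
            "slots": slots,
            "panel_size": len(chosen_tags),
            "overlap": slots - len(chosen_tags)
            if all(int(targets.get(c, 0)) <= len(eligible) for c in CATEGORIES)
            else sum(len(v) for v in per_category.values()) - len(chosen_tags),
            "per_category_counts": {c: len(v) for c, v in per_category.items()},
            "multi_tag_counts": {
                k: sum(1 for t in chosen_tags.values() if len(t) == k)
                for k in (1, 2, 3)
            },
        }
    )
    return panel


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(panel: PanelSpec, ld_results: pd.DataFrame, alpha: float = 0.05) -> PanelSpec:
    """Drop the less informative member of each significant LD pair.

    ``ld_results`` has columns locus_i, locus_j, p and (optionally) adj_p and
    significant from :func:`gsikit.popgen.ld_test_pairs`; if absent, BH is
    applied here at ``alpha``. Pairs are processed in descending significance;
    a pair with an already-dropped member is skipped. Informativeness is the
    locus's maximum theta across its tagged categories.
    """
    from .popgen import bh_fdr

    df = ld_results.copy()
    if "significant" not in df.columns or "adj_p" not in df.columns:
        reject, adj = bh_fdr(df["p"].to_numpy(), alpha)
        df["adj_p"], df["significant"] = adj, reject
    sig = df[df["significant"]].sort_values(
        ["adj_p", "p", "locus_i", "locus_j"], kind="stable"
    )
    selected = set(panel.selected_ids)
    n_dropped = 0
    for _, row in sig.iterrows():
        a, b = row["locus_i"], row["locus_j"]
        if a not in selected or b not in selected:
            continue  # outside panel or already pruned
        ta, tb = panel.max_theta(a), panel.max_theta(b)
        # lower max-theta loses; exact tie falls to the lexicographically
        # later locus so the rule is deterministic
        if ta == tb:
            victim = max(a, b)
        elif tb < ta:
            victim = b
        else:
            victim = a
        panel.table.loc[victim, "status"] = STATUS_DROPPED_LD
        panel.table.loc[victim, "drop_reason"] = (
            f"LD with {a if victim == b else b} (adj_p={row['adj_p']:.3g})"
        )
        selected.discard(victim)
        n_dropped += 1
    panel.report["n_dropped_ld"] = n_dropped
    return panel


# ---------------------------------------------------------------------------
# Primer QC from a test library
# ---------------------------------------------------------------------------

def primer_qc(
    panel: PanelSpec,
    counts: ReadCountTable,
    probe_counts: Mapping[str, float] | None = None,
    artefact_flags: Mapping[str, bool] | None = None,
    dimer_flags: Mapping[str, bool] | None = None,
    on_target_threshold: float = 0.8,
    max_read_share: float = 0.02,
) -> tuple[PanelSpec, pd.DataFrame]:
    """Primer-dropout QC on a test library.

    A selected locus is dropped when any of these fire: (a) probe/primer
    count ratio below ``on_target_threshold`` (non-specific primers; only when
    ``probe_counts`` is supplied), (b) locus total reads exceeding
    ``max_read_share`` of the library total (overamplifier), (c) zero reads
    (off-target / failed primer), (d) external PCR-artefact flag, (e) external
    primer-dimer flag. Loci absent from the count table count as zero reads.
    """
    locus_total = dict(zip(counts.locus_ids, counts.locus_totals()))
    library_total = counts.library_total or 0
    rows = []
    n_dropped = 0
    for lid in panel.selected_ids:
        if lid not in locus_total:
            warnings.warn(f"locus {lid} missing from count table; treated as zero counts")
        total = int(locus_total.get(lid, 0))
        share = total / library_total if library_total else 0.0
        reasons = []
        if probe_counts is not None and total > 0:
            ratio = float(probe_counts.get(lid, 0.0)) / total
            if ratio < on_target_threshold:
                reasons.append("non-specific primers (low probe/primer ratio)")
        else:
            ratio = np.nan
        if share > max_read_share:
            reasons.append(f"read share {share:.3f} > {max_read_share}")
        if total == 0:
            reasons.append("no reads (off-target amplification)")
        if artefact_flags and artefact_flags.get(lid, False):
            reasons.append("PCR artefact")
        if dimer_flags and dimer_flags.get(lid, False):
            reasons.append("primer dimer")
        if reasons:
            panel.table.loc[lid, "status"] = STATUS_DROPPED_QC
            panel.table.loc[lid, "drop_reason"] = "; ".join(reasons)
            n_dropped += 1
        rows.append(
            {
                "locus_id": lid,
                "total_reads": total,
                "read_share": share,
                "probe_ratio": ratio,
                "dropped": bool(reasons),
                "reason": "; ".join(reasons),
            }
        )
    panel.report["n_dropped_qc"] = n_dropped
    return panel, pd.DataFrame(rows)
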