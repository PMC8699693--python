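import numpy as np
import pandas as pd
import pytest

from gsikit import Locus, PanelSpec, ReadCountTable, flanking_filter
from gsikit.panel import (
    STATUS_DROPPED_LD,
    STATUS_DROPPED_QC,
    STATUS_SELECTED,
    apply_flanking_filter,
    ld_prune,
    primer_qc,
    rank_and_select,
)


def loci_at(positions):
    return [Locus(f"L{j:03d}", f"c{j}", p, "A", "G", 90)
            for j, p in enumerate(positions)]


class TestFlankingFilter:
    @pytest.mark.parametrize("pos,passes", [(40, True), (70, True), (39, False),
                                            (71, False), (55, True)])
    def test_window_boundaries_inclusive(self, pos, passes):
        passed, dropped = flanking_filter(loci_at([pos]))
        assert (len(passed) == 1) == passes

    def test_random_positions_match_interval_check(self, rng):
        pos = rng.integers(1, 91, size=200)
        passed, dropped = flanking_filter(loci_at(pos))
        expect = {f"L{j:03d}" for j, p in enumerate(pos) if 40 <= p <= 70}
        assert {l.locus_id for l in passed} == expect
        assert len(passed) + len(dropped) == 200


def panel_with_thetas(thetas):
    """thetas: dict locus_id -> (basin, migratory, ecotype)."""
    loci = [Locus(lid, f"c_{lid}", 45, "A", "G", 90) for lid in sorted(thetas)]
    tables = {
        cat: {lid: thetas[lid][k] for lid in thetas}
        for k, cat in enumerate(("basin", "migratory", "ecotype"))
    }
    return PanelSpec.from_candidates(loci, tables)


class TestRankAndSelect:
    def test_disjoint_top_lists_sum_without_overlap(self, rng):
        # 30 loci: 10 strong per category, disjoint
        thetas = {}
        for j in range(30):
            vals = [0.01, 0.01, 0.01]
            vals[j // 10] = 0.5 + j * 1e-3
            thetas[f"L{j:03d}"] = tuple(vals)
        panel = rank_and_select(panel_with_thetas(thetas),
                                {"basin": 10, "migratory": 10, "ecotype": 10})
        assert panel.report["panel_size"] == 30
        assert panel.report["overlap"] == 0
        assert all(len(panel.tags_of(l)) == 1 for l in panel.selected_ids)

    def test_shared_top_locus_counted_once_with_all_tags(self):
        # one locus ranked #1 in all three categories; each category then has
        # its own distinct runners-up, so 15 slots yield 13 unique loci
        thetas = {"L000": (0.9, 0.9, 0.9)}
        for cat in range(3):
            for m in range(4):
                vals = [0.0, 0.0, 0.0]
                vals[cat] = 0.5 - 0.01 * m
                thetas[f"L{cat + 1}{m:02d}"] = tuple(vals)
        panel = rank_and_select(panel_with_thetas(thetas),
                                {"basin": 5, "migratory": 5, "ecotype": 5})
        assert panel.tags_of("L000") == {"basin", "migratory", "ecotype"}
        assert panel.report["panel_size"] == 13
        assert panel.report["overlap"] == 2

    def test_selection_equals_sort_and_take_oracle(self, rng):
        thetas = {
            f"L{j:03d}": tuple(np.round(rng.random(3), 6)) for j in range(100)
        }
        targets = {"basin": 20, "migratory": 10, "ecotype": 25}
        panel = rank_and_select(panel_with_thetas(thetas), targets)
        expect = set()
        for k, (cat, t) in enumerate(
            (("basin", 20), ("migratory", 10), ("ecotype", 25))
        ):
            ranked = sorted(thetas, key=lambda l: (-thetas[l][k], l))
            expect |= set(ranked[:t])
        assert set(panel.selected_ids) == expect

    def test_target_exceeding_pool_selects_all_with_warning(self):
        thetas = {f"L{j}": (0.1, 0.1, 0.1) for j in range(3)}
        with pytest.warns(UserWarning, match="exceeds pool"):
            panel = rank_and_select(panel_with_thetas(thetas), {"basin": 10})
        assert len(panel.selected_ids) == 3

    def test_flank_dropped_loci_not_selectable(self):
        loci = loci_at([10, 50])
        panel = PanelSpec.from_candidates(
            loci, {"basin": {"L000": 0.9, "L001": 0.1}})
        apply_flanking_filter(panel)
        rank_and_select(panel, {"basin": 1})
        assert panel.selected_ids == ["L001"]


class TestLdPrune:
    def test_no_significant_pairs_leaves_panel(self):
        thetas = {f"L{j}": (0.5, 0.1, 0.1) for j in range(4)}
        panel = rank_and_select(panel_with_thetas(thetas), {"basin": 4})
        ld = pd.DataFrame({"locus_i": ["L0"], "locus_j": ["L1"], "p": [0.9]})
        ld_prune(panel, ld)
        assert len(panel.selected_ids) == 4

    def test_less_informative_member_dropped(self):
        panel = rank_and_select(
            panel_with_thetas({"L0": (0.4, 0, 0), "L1": (0.1, 0, 0)}), {"basin": 2})
        ld = pd.DataFrame({"locus_i": ["L0"], "locus_j": ["L1"], "p": [1e-9]})
        ld_prune(panel, ld)
        assert panel.table.loc["L1", "status"] == STATUS_DROPPED_LD
        assert panel.table.loc["L0", "status"] == STATUS_SELECTED

    def test_one_survivor_per_planted_cluster(self, rng):
        # three clusters of mutually associated loci
        thetas, ld_rows = {}, []
        for c in range(3):
            members = [f"C{c}_{m}" for m in range(4)]
            for m, lid in enumerate(members):
                thetas[lid] = (0.2 + 0.1 * m, 0.0, 0.0)
            for i in range(4):
                for j in range(i + 1, 4):
                    ld_rows.append(
                        {"locus_i": members[i], "locus_j": members[j], "p": 1e-8})
        panel = rank_and_select(panel_with_thetas(thetas), {"basin": 12})
        ld_prune(panel, pd.DataFrame(ld_rows))
        survivors = panel.selected_ids
        assert len(survivors) == 3
        # the max-theta member of each cluster survives
        assert set(survivors) == {"C0_3", "C1_3", "C2_3"}

    def test_never_drops_both_members_of_isolated_pair(self):
        panel = rank_and_select(
            panel_with_thetas({"L0": (0.3, 0, 0), "L1": (0.3, 0, 0)}), {"basin": 2})
        ld = pd.DataFrame({"locus_i": ["L0"], "locus_j": ["L1"], "p": [1e-9]})
        ld_prune(panel, ld)
        assert len(panel.selected_ids) == 1


class TestPrimerQc:
    def make_counts(self, locus_totals, n_samples=4, library_total=None):
        loci = sorted(locus_totals)
        ref = np.zeros((n_samples, len(loci)), dtype=np.int64)
        for j, l in enumerate(loci):
            per = locus_totals[l] // n_samples
            ref[:, j] = per
            ref[0, j] += locus_totals[l] - per * n_samples
        return ReadCountTable([f"S{i}" for i in range(n_samples)], loci, ref,
                              np.zeros_like(ref), library_total)

    def selected_panel(self, locus_ids):
        thetas = {l: (0.5, 0.1, 0.1) for l in locus_ids}
        return rank_and_select(panel_with_thetas(thetas),
                               {"basin": len(locus_ids)})

    def test_zero_count_locus_dropped(self):
        panel = self.selected_panel(["L0", "L1"])
        counts = self.make_counts({"L0": 0, "L1": 400})
        panel, qc = primer_qc(panel, counts)
        assert panel.table.loc["L0", "status"] == STATUS_DROPPED_QC
        assert "no reads" in panel.table.loc["L0", "drop_reason"]

    def test_overamplifying_locus_dropped_by_read_share(self):
        # 60 even loci sit under 2% of the library; the 400-read locus does not
        totals = {f"L{j:02d}": 100 for j in range(60)}
        totals["L03"] = 400
        panel = self.selected_panel(list(totals))
        panel, qc = primer_qc(panel, self.make_counts(totals))
        assert panel.table.loc["L03", "status"] == STATUS_DROPPED_QC
        kept = [l for l in totals if l != "L03"]
        assert all(panel.table.loc[l, "status"] == STATUS_SELECTED for l in kept)

    def test_low_probe_ratio_dropped(self):
        panel = self.selected_panel(["L0", "L1"])
        counts = self.make_counts({"L0": 1000, "L1": 1000})
        panel, _ = primer_qc(panel, counts, probe_counts={"L0": 500, "L1": 990},
                             max_read_share=0.9)
        assert panel.table.loc["L0", "status"] == STATUS_DROPPED_QC
        assert panel.table.loc["L1", "status"] == STATUS_SELECTED

    def test_external_flags_respected(self):
        panel = self.selected_panel(["L0", "L1", "L2"])
        counts = self.make_counts({"L0": 100, "L1": 100, "L2": 100})
        panel, _ = primer_qc(panel, counts, artefact_flags={"L1": True},
                             dimer_flags={"L2": True}, max_read_share=0.9)
        assert panel.table.loc["L1", "status"] == STATUS_DROPPED_QC
        assert panel.table.loc["L2", "status"] == STATUS_DROPPED_QC

    def test_missing_locus_treated_as_zero_with_warning(self):
        panel = self.selected_panel(["L0", "L1"])
        counts = self.make_counts({"L1": 100})
        with pytest.warns(UserWarning, match="L0"):
            panel, _ = primer_qc(panel, counts)
        assert panel.table.loc["L0", "status"] == STATUS_DROPPED_QC

    def test_planted_failure_modes_and_only_those_dropped(self, rng):
        ids = [f"L{j:02d}" for j in range(20)]
        totals = {l: int(rng.integers(80, 120)) for l in ids}
        totals["L02"] = 0
        totals["L07"] = 50 * 120
        panel = self.selected_panel(ids)
        panel, qc = primer_qc(panel, self.make_counts(totals))
        dropped = set(panel.table.index[panel.table["status"] == STATUS_DROPPED_QC])
        assert dropped == {"L02", "L07"}
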