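"""Design a multi-scale SNP panel from a candidate pool.

Theta is computed per comparison category (basin, migratory form, ecotype),
loci outside the primer-design flanking window are dropped, the top loci per
category are taken from theta-descending ranks (overlaps tagged, not double
counted), significantly associated pairs are pruned, and a simulated test
library drives primer QC.
"""

import gsikit as gk
from gsikit.panel import apply_flanking_filter, ld_prune
from gsikit.popgen import ld_test_pairs

cfg = gk.SimulationConfig(seed=1)
baseline, _ = gk.simulate_baseline(cfg)
gm = baseline.genotypes

theta_tables = {}
for cat, field in (("basin", "basin"), ("migratory", "form"), ("ecotype", "ecotype")):
    res = gk.wc_theta(gm, baseline.groups(field), comparison=cat)
    theta_tables[cat] = dict(zip(res.locus_ids, res.theta))

panel = gk.PanelSpec.from_candidates(gm.loci, theta_tables)
apply_flanking_filter(panel)          # SNP must sit at bp 40-70 of its contig
gk.rank_and_select(panel, {"basin": 40, "migratory": 20, "ecotype": 50})
print(f"flanking filter dropped {panel.report['n_dropped_flank']} loci")
print(f"selected {panel.report['panel_size']} unique loci for "
      f"{panel.report['slots']} slots (overlap {panel.report['overlap']})")
print(f"tag multiplicity: {panel.report['multi_tag_counts']}")

pairs = [tuple(panel.selected_ids[k:k + 2]) for k in range(0, 20, 2)]
ld = ld_test_pairs(gm, pairs, baseline.groups("population"), mc_reps=1000, seed=7)
ld_prune(panel, ld)
print(f"LD screen over {len(pairs)} pairs removed {panel.report['n_dropped_ld']} loci")

counts = gk.simulate_readcounts(gm, seed=3, zero_loci=[panel.selected_ids[0]])
panel, qc = gk.primer_qc(panel, counts)
print(f"primer QC dropped {panel.report['n_dropped_qc']} locus/loci "
      f"(planted zero-count primer)")
print(f"final panel size: {len(panel.selected_ids)}")
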