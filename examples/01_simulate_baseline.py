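"""Build the default synthetic baseline and look at its divergence structure.

The world is a 3-basin, 14-population hierarchy with 228 neutral and 60
ecotype-shifted loci. The printed multilocus theta values show the intended
ordering: basins diverge most, lakes within basins less, and co-occurring
ecotypes in the same lake mainly through the planted ecotype loci.
"""

import gsikit as gk

cfg = gk.SimulationConfig(seed=1)
baseline, true_freqs = gk.simulate_baseline(cfg)
gm = baseline.genotypes
print(f"baseline: {gm.n_samples} samples x {gm.n_loci} loci, "
      f"{baseline.strata['population'].nunique()} populations")

basins = baseline.groups("basin")
theta_basin = gk.wc_theta(gm, basins, comparison="basin")
print(f"multilocus theta among basins:          {theta_basin.multilocus_theta:.3f}")

pops = baseline.groups("population")
lakes = {k: pops[k] for k in ("WoodLake_shore", "Okanagan_shore")}
theta_lakes = gk.wc_theta(gm, lakes, comparison="between lakes")
print(f"theta between two shore pops (2 lakes): {theta_lakes.multilocus_theta:.3f}")

eco = {k: pops[k] for k in ("WoodLake_shore", "WoodLake_stream")}
theta_eco = gk.wc_theta(gm, eco, comparison="within lake")
neutral = theta_eco.to_frame().iloc[:cfg.n_loci_neutral]["theta"].mean()
shifted = theta_eco.to_frame().iloc[cfg.n_loci_neutral:]["theta"].mean()
print(f"co-occurring ecotypes, mean per-locus theta: "
      f"neutral loci {neutral:.3f} vs ecotype loci {shifted:.3f}")
print("-> the ecotype signal is concentrated in the planted outlier loci,")
print("   which is what lets one panel separate ecotypes in every lake.")
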