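"""Mixed-stock proportion estimation for a two-ecotype fishery.

A mixture sample of unknown-origin fish is scored against the two reference
stocks; the EM holds baseline frequencies fixed and estimates the mixing
proportions, with percentile bootstrap confidence intervals. The hard-
assignment proportion is printed alongside as the cross-check managers use.
"""

import gsikit as gk

cfg = gk.SimulationConfig(seed=1)
baseline, freqs = gk.simulate_baseline(cfg)

stocks = dict(cfg.mixture_proportions)          # truth: shore 0.39, stream 0.61
mix, truth = gk.simulate_mixture(freqs, stocks, cfg.mixture_n, seed=4,
                                 loci=baseline.genotypes.loci)
wood = baseline.subset_samples(
    [s for s in baseline.genotypes.sample_ids if s.startswith("WoodLake")])

est = gk.bootstrap_ci(mix, wood, "population", B=1000, seed=0)
print(f"EM converged in {est.iterations} iterations "
      f"(log-likelihood {est.log_likelihood_trace[-1]:.1f})")
for _, row in est.to_frame().iterrows():
    print(f"  {row['stock']:17s} {row['proportion']:.4f} "
          f"(95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f})")

ar = gk.assign_novel(mix, wood, "population")
prop = gk.proportion_from_assignment(ar)
shore = [s for s in est.stocks if "shore" in s][0]
print(f"proportion of shore-spawners by individual assignment: "
      f"{prop[shore]:.3f}")
print(f"planted truth: {stocks[shore]:.2f}; EM and hard assignment agree "
      f"closely when stocks are well separated.")
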