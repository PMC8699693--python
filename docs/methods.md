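# Methods

This note records the models `gsikit` implements, the defaults it ships, and
the choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Genotype model and containers

Genotypes are diploid biallelic dosages {0, 1, 2} with a missing sentinel.
PED/MAP allele pairs are normalized to dosages against the declared ref/alt
on read (allele order in PED carries no information); `0 0` is missing. VCF
support covers the biallelic-SNP subset of v4.2 (`0/0, 0/1, 1/1, ./.`),
reading through cyvcf2 and writing a minimal GT-only file. SNP positions are
1-based inclusive throughout.

**Missing-data filter.** Loci first, then samples re-evaluated on the
surviving loci, strictly-greater-than thresholds (default 0.30/0.30; the
mixed-stock case study uses 0.50). Single pass each, matching common
PLINK-style practice; `order="samples_first"` reproduces the other order.
Exact idempotence cannot be guaranteed by any single-pass rule — removing a
heavily missing sample can lift a surviving locus back over the threshold —
but holds in the sparse-missingness regime the filter is meant for, and the
property test asserts it there.

**Replicate merging.** Agreeing calls are kept; a disagreement defaults to
the replicate with fewer missing calls overall (a library-quality proxy),
ties and the `strict` policy giving missing.

## Weir–Cockerham θ

The two-allele variance-component estimator: components a (among groups),
b (among individuals within groups), c (within individuals), per-locus
θ = a/(a+b+c), multilocus θ as the ratio of sums over defined loci. Per-locus
estimates may legitimately be negative and are retained (panel ranking
simply places them low). A locus is undefined when any group has fewer than
two called individuals or when a+b+c = 0 (monomorphic everywhere); undefined
loci are excluded from the ratio of sums. Basin-level θ defaults to a single
three-group estimate; pairwise estimates are available via
`pairwise_theta` (the source tool for the original workflow reports pairwise
values, and both conventions are in use).

## Linkage disequilibrium and FDR

The genotypic exact test builds, per population, the 3×3 genotype-by-
genotype table (missing pairs dropped) and computes a Monte-Carlo exact
p-value: tables with the observed margins are sampled (Patefield algorithm
via `scipy.stats.random_table`) and the p-value is the share with
multivariate-hypergeometric probability no larger than the observed table's,
with an add-one correction so p > 0. This replaces a Markov-chain exact test
with an equivalent null that is simple and seedable. Per-pair p-values are
combined across populations by Fisher's method (the cross-population
handling is not specified by the original workflow; Fisher is the standard
choice for independent per-population nulls). FDR control is
Benjamini–Hochberg step-up, delegated to statsmodels behind the module
surface; the test oracle is an independent brute-force scan over all ranks.

## Panel design

Pipeline order: flanking filter → θ-ranked selection → LD prune → primer QC;
the order is deterministic and reproducible byte-for-byte given inputs and
seeds.

- *Flanking filter*: the SNP must sit within bp 40–70 (1-based, inclusive)
  of its contig so both primer-design flanks exist.
- *Selection*: per category (basin / migratory / ecotype; default slot
  targets 200/100/250), loci are ranked by descending θ, undefined θ last,
  ties broken lexicographically for determinism; the union of the top slots
  forms the panel, with loci taken by several categories appearing once and
  carrying all their tags. The report exposes slots, unique panel size and
  overlap separately (the published 550-slot/547-unique arithmetic mixes
  overlap and LD removal; keeping the counts separate avoids guessing the
  split).
- *LD prune*: BH-significant pairs processed in descending significance;
  the member with the lower maximum θ across its tagged categories is
  dropped ("less informative" is not defined by the source workflow; max-θ
  preserves the locus most useful at any scale). A pair with an
  already-dropped member is skipped, so an isolated significant pair never
  loses both members.
- *Primer QC* on a test library: drop on (a) probe/primer count ratio below
  0.8 when probe counts are supplied (non-specific primers; the original
  criterion gives no number, so the threshold is a config knob), (b) locus
  read share above 2% of the whole library's raw read count
  (overamplifier), (c) zero reads, (d/e) externally supplied PCR-artefact
  and primer-dimer flags (identified by inspection upstream, so accepted as
  booleans rather than detected).

## Amplicon genotype calling

Per cell with total depth `ref+alt`: below `min_depth` (10) → missing;
otherwise `ratio = (ref+0.1)/(alt+0.1)`; ratio ≥ 10 → hom ref, ≤ 0.1 → hom
alt, within [0.2, 5] → het, otherwise missing (ambiguous band, never forced
to the nearest class). The +0.1 pseudocount and the four thresholds follow
the public GT-seq genotyper convention; all are configurable because the
upstream pipeline version is not pinned. The constraint
`het_low < 1 < het_high < hom_ratio` keeps the classes disjoint, which is
what makes calls exactly symmetric under allele swap.

## Individual assignment

Rannala–Mountain genotype probabilities (compound-Dirichlet with uniform
1/k prior, k = 2) with uniform prior over candidate units and ties broken
lexicographically with an explicit flag. Leave-one-out subtracts the
individual's own two alleles from its unit's counts (only its own unit).
Loci monomorphic across the whole baseline are dropped (prior-only noise);
individuals sharing no called locus with the baseline are "unassigned".

Coarser identifications (basin, migratory form, ecotype) are produced by
`map_assignment`: the assignment targets reference units and the coarser
label is read off the winning unit. Scoring directly against pooled
basin/form baselines is also supported (`grouping=` a strata field), but a
pooled 12-population "kokanee" baseline is a poor panmictic model and is
not the operational procedure.

Monte-Carlo cross-validated classification mirrors assignPOP's design:
stratified random train/test splits, θ recomputed on the training split only
(avoiding high-grading bias) to rank loci, top fraction retained,
standardized dosage features with missing imputed to training means, linear
SVM by default (`classifier_factory` accepts any sklearn-style estimator).
Grid defaults: training fractions {0.5, 0.7, 0.9}, loci fractions
{0.5, 0.75, 1.0}, 30 iterations.

## Mixture estimation

Conditional maximum likelihood: baseline allele frequencies fixed, EM from
the uniform simplex point, tolerance 1e-6 on the log-likelihood gain,
10,000-iteration cap, monotonicity asserted on every run. A flat likelihood
surface leaves the uniform start untouched (any simplex point is an MLE;
documented behaviour). Bootstrap CIs are percentile intervals (the simplest
defensible reading of "bootstrap replicates"), default B = 10,000 at the
95% level, resampling mixture individuals; optional within-stock baseline
resampling sits behind `resample_baseline` because the reference
implementation's exact scheme is not described. The companion
hard-assignment proportion (`proportion_from_assignment`) reports
unassigned fish separately.

## Clustering

The admixture likelihood (each allele copy alt with probability
Σ_k q_ik f_kl) is maximized by alternating closed-form EM updates of Q and
cluster frequencies, best of `n_restarts` by final log-likelihood,
deterministic given a seed. This replaces MCMC samplers of the same
likelihood family: no correlated-frequency prior and no sampling-location
prior, so burn-in/chain-length settings have no analogue here. Frequencies
are clamped to [1e-9, 1−1e-9] to keep the likelihood finite.

Replicate alignment permutes each replicate's columns to minimize total
squared distance to the first replicate. Because that cost separates by
column pair it is an assignment problem and is solved exactly for every K
with the Hungarian algorithm (`linear_sum_assignment`) — equivalent to the
exhaustive K! search for small K (verified in tests) without the greedy
fallback a brute-force implementation needs beyond K ≈ 6.

ΔK is the Evanno statistic |mean L(K+1) − 2 mean L(K) + mean L(K−1)| /
sd(L(K)), undefined at range endpoints and flagged (not ε-patched) where the
replicate dispersion is zero. Hard labels use the strict >0.80 membership
rule, otherwise "ambiguous".

## Concordance

Replicate discordance divides mismatching non-missing calls by loci called
in both members; the all-panel-loci denominator is emitted alongside since
either reading of the published denominator is possible. Note the expected
mismatch rate between two independently error-prone replicates is the
collision probability (~4e for small per-allele error e), not e itself; the
simulation tests assert against that expectation. Assignment concordance
excludes "ambiguous"/"unassigned" labels from the denominator by default and
counts them separately.

## Synthetic world

The generator is a pure function of (config, seed). Ancestral frequency per
locus ~ U(0.05, 0.95); basin then population frequencies follow the
Balding–Nichols Beta construction with F_basin and F_pop; ecotype loci add a
parallel ±δ/2 shift between co-occurring ecotypes, identical in direction
across systems (so one panel separates ecotypes in every lake); genotypes
are Binomial(2, freq) under linkage equilibrium. Frequencies are clamped to
[0.01, 0.99].

Defaults are standing choices, fixed a priori:

| parameter | default | rationale |
|---|---|---|
| populations | 14, in 3 basins | the published baseline structure and reference sample sizes, encoded verbatim |
| novel fish | 4 per population (56) | the retained novel-individual count |
| loci | 228 neutral + 60 ecotype | optimized panel size; 60 is the published ecotype-outlier count |
| F_basin / F_pop | 0.15 / 0.08 | basin ≫ lake ≫ within-lake ordering typical of RADseq surveys of this species |
| δ | 0.5 | ecotype outliers are strongly shifted relative to neutral background |
| depth | NB(mean 118, dispersion 3) | the reported mean amplicon depth, with realistic overdispersion |
| per-allele error | 0.005 | consistent with ~1–2% replicate genotype discordance |
| missing rate | 0.10 | ~90% genotyping rate |

A strong-divergence preset (F_basin 0.30, F_pop 0.15, δ 0.8) represents the
regime where novel-individual assignment is expected to be perfect.

What the generator does **not** emulate: linkage between loci, correlated
(phylogenetically structured) drift beyond the two-level hierarchy,
within-lake substructure, locus-specific amplification biases beyond the
planted QC failure modes, and genotyping error that depends on depth. A
green end-to-end test therefore establishes that the estimators and the
workflow behave correctly under the stated hierarchical model — not that
real-data accuracies would match.

Two modelling notes. (i) Co-occurring ecotype populations here drift
independently from their basin value (plus δ), so they are as neutrally
diverged as any two lake populations; in real systems same-lake ecotypes
are often the *least* neutrally diverged pair, which is exactly why the
ecotype loci carry the shift. (ii) Direct migratory-form separation rests
on population-level divergence only; the generator plants no form-specific
loci.

## Pipeline and reproducibility

`gsikit.pipeline` exposes one runner per stage (simulate, genotype,
design-panel, self-assign, assign, cv-assign, mixture, cluster,
concordance) over a YAML config merged onto defaults; every stochastic stage
derives its seed from the config seed by fixed offsets. Logs carry the stage
name, a config hash and input checksums but no timestamps, so identical
config + seed reproduce every artifact byte for byte. The pipeline's panel
stage scales the slot targets to its 288-locus synthetic pool (40/20/50) and
screens a seeded sample of locus pairs for LD rather than all ~41k pairs;
the full-pool targets remain the library defaults. The package is a library
with `examples/` scripts as its public face; there is no command-line
entry point.
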