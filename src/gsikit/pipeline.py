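"""Config-driven stage runners wiring the stages into reproducible runs.

Each runner reads standard-format inputs from / writes artifacts into a run
directory, appends a deterministic log line (stage, config hash, seed, input
checksums — no timestamps, so identical config + seed reproduce artifacts
byte for byte), and returns the paths it wrote. The YAML config mirrors the
stage parameters; anything omitted falls back to the package defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import assign as _assign
from . import calling as _calling
from . import cluster as _cluster
from . import concord as _concord
from . import io as _io
from . import mixture as _mixture
from . import panel as _panel
from . import popgen as _popgen
from . import simulate as _sim
from .core import StratifiedBaseline

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulation": {},              # overrides for SimulationConfig fields
    "filter": {"max_locus_missing": 0.3, "max_sample_missing": 0.3,
               "order": "loci_first"},
    "calling": {"min_depth": 10, "hom_ratio": 10.0, "het_low": 0.2,
                "het_high": 5.0},
    # panel targets scaled ~1:5 to the 288-locus synthetic pool (the full-pool
    # slot targets are 200/100/250 over thousands of candidates)
    "panel": {"targets": {"basin": 40, "migratory": 20, "ecotype": 50},
              "window": [40, 70], "alpha": 0.05, "mc_reps": 1000,
              "max_ld_pairs": 60, "max_read_share": 0.02,
              "on_target_threshold": 0.8},
    "assignment": {"grouping": "population", "pooled": True},
    "cv": {"train_props": [0.5, 0.9], "loci_props": [0.5, 1.0],
           "iterations": 3, "grouping": "basin"},
    "mixture": {"missing_threshold": 0.5, "bootstrap_b": 200, "level": 0.95,
                "tol": 1e-6},
    "cluster": {"k_values": [1, 2, 3], "replicates": 3, "n_restarts": 1,
                "max_iter": 200, "threshold": 0.80},
    "concordance": {"per_allele_error": 0.005, "n_pairs": 5},
}


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict:
    """Merge a YAML config (and/or an override mapping) over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for src in (yaml.safe_load(Path(path).read_text()) if path else None, overrides):
        if not src:
            continue
        for key, val in src.items():
            if key not in cfg and key != "seed":
                raise KeyError(f"unknown config section {key!r}")
            if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _log(outdir: Path, cfg: Mapping, stage: str, seed: int,
         inputs: list[Path], outputs: list[Path]) -> None:
    sums = ",".join(
        f"{p.name}:{hashlib.sha256(p.read_bytes()).hexdigest()[:8]}" for p in inputs
    )
    with open(outdir / "log.txt", "a") as fh:
        fh.write(f"stage={stage} config={config_hash(cfg)} seed={seed} "
                 f"inputs=[{sums}]\n")


def _sim_config(cfg: Mapping) -> _sim.SimulationConfig:
    over = dict(cfg.get("simulation", {}))
    if "populations" in over:
        over["populations"] = tuple(_sim.PopulationDef(**p) for p in over["populations"])
    if "mixture_proportions" in over:
        over["mixture_proportions"] = tuple(
            (k, v) for k, v in over["mixture_proportions"]
        )
    return _sim.SimulationConfig(seed=int(cfg["seed"]), **over)


def _read_baseline(outdir: Path) -> StratifiedBaseline:
    return _io.read_baseline(outdir / "baseline.ped", outdir / "baseline.map",
                             outdir / "strata.csv")


def _grouping(cfg: Mapping, baseline: StratifiedBaseline):
    acfg = cfg["assignment"]
    if acfg.get("pooled") and acfg["grouping"] == "population":
        return _sim.pooled_labels(baseline.strata)
    return acfg["grouping"]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: Mapping, outdir: str | Path) -> dict[str, Path]:
    """Generate every synthetic input downstream stages read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = _sim_config(cfg)
    baseline, freqs = _sim.simulate_baseline(scfg)
    observed = _sim.inject_missing(baseline.genotypes, scfg.missing_rate,
                                   seed=scfg.seed + 10)
    baseline = StratifiedBaseline(observed, baseline.strata)

    novel, novel_truth = _sim.simulate_novel(scfg, freqs, seed=scfg.seed + 1,
                                             loci=baseline.genotypes.loci)
    counts = _sim.simulate_readcounts(novel, scfg.depth_mean,
                                      scfg.depth_dispersion, scfg.error_rate,
                                      seed=scfg.seed + 2)
    mix, mix_truth = _sim.simulate_mixture(
        freqs, dict(scfg.mixture_proportions), scfg.mixture_n,
        seed=scfg.seed + 3, loci=baseline.genotypes.loci,
    )
    mix = _sim.inject_missing(mix, scfg.missing_rate, seed=scfg.seed + 11)

    paths = {k: outdir / v for k, v in {
        "ped": "baseline.ped", "map": "baseline.map", "strata": "strata.csv",
        "freqs": "true_freqs.csv", "novel_ped": "novel.ped",
        "novel_map": "novel.map", "novel_truth": "novel_truth.csv",
        "counts": "readcounts.csv", "mix_ped": "mixture.ped",
        "mix_map": "mixture.map", "mix_truth": "mixture_truth.csv",
    }.items()}
    _io.write_ped(baseline.genotypes, paths["ped"], paths["map"])
    _io.write_strata(baseline.strata, paths["strata"])
    freqs.round(10).to_csv(paths["freqs"])
    _io.write_ped(novel, paths["novel_ped"], paths["novel_map"])
    pd.DataFrame({"sample": novel.sample_ids, "true_group": novel_truth}).to_csv(
        paths["novel_truth"], index=False)
    counts.write_csv(paths["counts"])
    _io.write_ped(mix, paths["mix_ped"], paths["mix_map"])
    pd.DataFrame({"sample": mix.sample_ids, "true_group": mix_truth}).to_csv(
        paths["mix_truth"], index=False)
    _log(outdir, cfg, "simulate", scfg.seed, [], list(paths.values()))
    return paths


def run_genotype(cfg: Mapping, outdir: str | Path) -> dict[str, Path]:
    """Call genotypes from the simulated amplicon read counts."""
    outdir = Path(outdir)
    counts = _calling.ReadCountTable.read_csv(outdir / "readcounts.csv")
    ccfg = cfg["calling"]
    report = _calling.call_genotypes(counts, **ccfg)
    fcfg = cfg["filter"]
    filtered, frep = _io.filter_missing(report.genotypes, **fcfg)
    _io.write_ped(filtered, outdir / "calls.ped", outdir / "calls.map")
    summary = {
        **_calling.summarize(report),
        "removed_loci": sorted(frep.removed_loci),
        "removed_samples": sorted(frep.removed_samples),
    }
    (outdir / "genotype_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    _log(outdir, cfg, "genotype", int(cfg["seed"]),
         [outdir / "readcounts.csv"], [outdir / "calls.ped"])
    return {"calls_ped": outdir / "calls.ped", "calls_map": outdir / "calls.map",
            "summary": outdir / "genotype_summary.json"}


def _category_groups(baseline: StratifiedBaseline) -> dict[str, dict]:
    strata = baseline.strata
    out = {}
    for cat, field in (("basin", "basin"), ("migratory", "form"),
                       ("ecotype", "ecotype")):
        lab = strata[field]
        out[cat] = {g: list(lab.index[lab == g]) for g in sorted(set(lab))}
    return out


def run_design_panel(cfg: Mapping, outdir: str | Path) -> dict[str, Path]:
    """Theta tables, flanking filter, ranked selection, LD prune, primer QC."""
    outdir = Path(outdir)
    baseline = _read_baseline(outdir)
    pcfg = cfg["panel"]
    gm = baseline.genotypes
    theta_tables = {}
    theta_frames = []
    for cat, groups in _category_groups(baseline).items():
        res = _popgen.wc_theta(gm, groups, comparison=cat)
        theta_tables[cat] = dict(zip(res.locus_ids, res.theta))
        theta_frames.append(res.to_frame())
    pd.concat(theta_frames).to_csv(outdir / "theta.csv", index=False,
                                   float_format="%.10g")

    panel = _panel.PanelSpec.from_candidates(gm.loci, theta_tables)
    _panel.apply_flanking_filter(panel, *pcfg["window"])
    _panel.rank_and_select(panel, pcfg["targets"])

    # LD screen over a deterministic sample of within-panel pairs
    rng = np.random.default_rng(int(cfg["seed"]) + 20)
    sel = panel.selected_ids
    pairs = [tuple(sorted(rng.choice(sel, 2, replace=False)))
             for _ in range(min(pcfg["max_ld_pairs"],
                                len(sel) * (len(sel) - 1) // 2))]
    pairs = sorted(set(pairs))
    pops = baseline.groups("population")
    ld = _popgen.ld_test_pairs(gm, pairs, pops, mc_reps=pcfg["mc_reps"],
                               seed=int(cfg["seed"]) + 21, alpha=pcfg["alpha"])
    ld.to_csv(outdir / "ld.csv", index=False, float_format="%.10g")
    _panel.ld_prune(panel, ld, alpha=pcfg["alpha"])

    counts = _calling.ReadCountTable.read_csv(outdir / "readcounts.csv")
    panel, qc = _panel.primer_qc(
        panel, counts, on_target_threshold=pcfg["on_target_threshold"],
        max_read_share=pcfg["max_read_share"],
    )
    panel.write_csv(outdir / "panel.csv")
    qc.to_csv(outdir / "panel_qc.csv", index=False, float_format="%.10g")
    (outdir / "panel_report.json").write_text(
        json.dumps(panel.report, indent=2, sort_keys=True, default=str))
    _log(outdir, cfg, "design-panel", int(cfg["seed"]),
         [outdir / "baseline.ped", outdir / "readcounts.csv"],
         [outdir / "panel.csv"])
    return {"panel": outdir / "panel.csv", "theta": outdir / "theta.csv",
            "ld": outdir / "ld.csv", "qc": outdir / "panel_qc.csv"}


def run_self_assign(cfg: Mapping, outdir: str | Path) -> dict[str, Path]:
    """Leave-one-out self-assignment over the configured grouping."""
    outdir = Path(outdir)
    baseline = _read_baseline(outdir)
    res = _assign.self_assign_loo(baseline, _grouping(cfg, baseline))
    res.write_csv(outdir / "self_assignment.csv")
    acc = {"overall_accuracy": res.accuracy,
           "per_group": {k: float(v) for k, v in
                         res.per_group_accuracy.sort_index().items()}}
    (outdir / "self_assignment_accuracy.json").write_text(
        json.dumps(acc, indent=2, sort_keys=True))
    _log(outdir, cfg, "self-assign", int(cfg["seed"]),
         [outdir / "baseline.ped"], [outdir / "self_assignment.csv"])
    return {"table": outdir / "self_assignment.csv",
            "accuracy": outdir / "self_assignment_accuracy.json"}


def run_assign(cfg: Mapping, outdir: str | Path) -> dict[str, Path]:
    """Assign the novel individuals against the baseline."""
    outdir = Path(outdir)
    baseline = _read_baseline(outdir)
    novel = _io.read_ped(outdir / "novel.ped", outdir / "novel.map")
    truth_df = pd.read_csv(outdir / "novel_truth.csv").set_index("sample")
    grouping = _grouping(cfg, baseline)
    truth = truth_df.loc[novel.sample_ids, "true_group"]
    if not isinstance(grouping, str):
        pool = dict(zip(baseline.strata["population"], grouping))
        truth = truth.map(lambda p: pool.get(p, p))
    res = _assign.assign_novel(novel, baseline, grouping, truth=list(truth))
    res.write_csv(outdir / "novel_assignment.csv")
    (outdir / "novel_assignment_accuracy.json").write_text(
        json.dumps({"accuracy": res.accuracy}, sort_keys=True))
    _log(outdir, cfg, "assign", int(cfg["seed"]),
         [outdir / "novel.ped"], [outdir / "novel_assignment.csv"])
    return {"table": outdir / "novel_assignment.csv"}


def run_cv_assign(cfg: Mapping, outdir: str | Path) -> dict[str, Path]:
    """Monte-Carlo cross-validated SVM assignment over the grid."""
    outdir = Path(outdir)
    baseline = _read_baseline(outdir)
    ccfg = cfg["cv"]
    grid = _assign.CVGrid(tuple(ccfg["train_props"]), tuple(ccfg["loci_props"]),
                          int(ccfg["iterations"]))
    grid = _assign.mc_cv_assign(baseline, grid, seed=int(cfg["seed"]) + 30,
                                grouping=ccfg["grouping"])
    grid.results.to_csv(outdir / "cv_accuracy.csv", index=False,
                        float_format="%.10g")
    _log(outdir, cfg, "cv-assign", int(cfg["seed"]),
         [outdir / "baseline.ped"], [outdir / "cv_accuracy.csv"])
    return {"table": outdir / "cv_accuracy.csv"}


def run_mixture(cfg: Mapping, outdir: str | Path) -> dict[str, Path]:
    """The mixed-stock case study: filter, EM + bootstrap, assignment and
    cluster-label concordance on the mixture sample."""
    outdir = Path(outdir)
    baseline = _read_baseline(outdir)
    mcfg = cfg["mixture"]
    mix = _io.read_ped(outdir / "mixture.ped", outdir / "mixture.map")
    mix, _ = _io.filter_missing(mix, mcfg["missing_threshold"],
                                mcfg["missing_threshold"])
    stocks = sorted(dict(_sim_config(cfg).mixture_proportions))
    stock_baseline = baseline.subset_samples(
        [s for s in baseline.genotypes.sample_ids
         if baseline.strata.loc[s, "population"] in stocks]
    )
    groups = {s: stock_baseline.groups("population")[s] for s in stocks}
    est = _mixture.bootstrap_ci(
        mix, stock_baseline, groups, B=int(mcfg["bootstrap_b"]),
        level=mcfg["level"], seed=int(cfg["seed"]) + 40, tol=mcfg["tol"],
    )
    ar = _assign.assign_novel(mix, stock_baseline, "population")
    est.assignment_proportions = _mixture.proportion_from_assignment(ar)

    kcfg = cfg["cluster"]
    fit = _cluster.admixture_fit(mix, K=len(stocks),
                                 seed=int(cfg["seed"]) + 41,
                                 n_restarts=int(kcfg["n_restarts"]),
                                 max_iter=int(kcfg["max_iter"]))
    labels = _cluster.threshold_assign(fit.Q, kcfg["threshold"])
    conc = _concord.assignment_concordance(
        _cluster_labels_to_stocks(labels, ar), dict(zip(ar.table["sample"],
                                                        ar.table["assigned_group"]))
    )
    est.to_frame().to_csv(outdir / "mixture_proportions.csv", index=False,
                          float_format="%.10g")
    summary = {
        "proportions": dict(zip(est.stocks, map(float, est.proportions))),
        "assignment_proportions": {k: float(v) for k, v in
                                   est.assignment_proportions.items()},
        "converged": bool(est.converged),
        "iterations": est.iterations,
        "log_likelihood": est.log_likelihood_trace[-1],
        "cluster_concordance_pct": conc["percent_agreement"],
    }
    (outdir / "mixture_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    _log(outdir, cfg, "mixture", int(cfg["seed"]),
         [outdir / "mixture.ped"], [outdir / "mixture_proportions.csv"])
    return {"proportions": outdir / "mixture_proportions.csv",
            "summary": outdir / "mixture_summary.json"}


def _cluster_labels_to_stocks(labels: pd.Series, ar) -> dict[str, str]:
    """Map anonymous cluster labels onto stock names by majority vote of the
    likelihood-based assignments (ambiguous stays ambiguous)."""
    assigned = dict(zip(ar.table["sample"], ar.table["assigned_group"]))
    vote: dict[str, dict[str, int]] = {}
    for s, c in labels.items():
        if c == "ambiguous":
            continue
        vote.setdefault(c, {}).setdefault(assigned.get(s, ""), 0)
        vote[c][assigned.get(s, "")] += 1
    mapping = {c: max(v, key=lambda k: (v[k], k)) for c, v in vote.items()}
    return {s: mapping.get(c, "ambiguous") if c != "ambiguous" else "ambiguous"
            for s, c in labels.items()}


def run_cluster(cfg: Mapping, outdir: str | Path) -> dict[str, Path]:
    """Admixture fits across K with replicate averaging and the Evanno table."""
    outdir = Path(outdir)
    baseline = _read_baseline(outdir)
    kcfg = cfg["cluster"]
    logliks: dict[int, list[float]] = {}
    best_qs: dict[int, pd.DataFrame] = {}
    for K in kcfg["k_values"]:
        qs, lls = [], []
        for rep in range(int(kcfg["replicates"])):
            fit = _cluster.admixture_fit(
                baseline.genotypes, K, seed=int(cfg["seed"]) + 50 + 100 * K + rep,
                n_restarts=int(kcfg["n_restarts"]), max_iter=int(kcfg["max_iter"]),
            )
            qs.append(fit.Q)
            lls.append(fit.log_likelihood)
        logliks[K] = lls
        best_qs[K] = _cluster.align_replicates(qs)
        best_qs[K].round(10).to_csv(outdir / f"q_matrix_K{K}.csv")
    dk = _cluster.delta_k(logliks) if len(logliks) >= 3 else None
    if dk is not None:
        dk.to_csv(outdir / "delta_k.csv", index=False, float_format="%.10g")
    _log(outdir, cfg, "cluster", int(cfg["seed"]), [outdir / "baseline.ped"],
         [outdir / f"q_matrix_K{K}.csv" for K in kcfg["k_values"]])
    return {"delta_k": outdir / "delta_k.csv"}


def run_concordance(cfg: Mapping, outdir: str | Path) -> dict[str, Path]:
    """Replicate-pair genotype discordance on a planted-error re-measurement."""
    outdir = Path(outdir)
    baseline = _read_baseline(outdir)
    ccfg = cfg["concordance"]
    n = int(ccfg["n_pairs"])
    sub = baseline.genotypes.take_samples(list(range(n)))
    rep = _sim.simulate_replicates(sub, ccfg["per_allele_error"],
                                   seed=int(cfg["seed"]) + 60)
    report = _concord.genotype_discordance(
        sub, rep, {s: (s, s) for s in sub.sample_ids}
    )
    report.pairs.to_csv(outdir / "discordance.csv", index=False,
                        float_format="%.10g")
    (outdir / "discordance_summary.json").write_text(json.dumps(
        {"mean_discordance_pct": report.mean_discordance_pct}, sort_keys=True))
    _log(outdir, cfg, "concordance", int(cfg["seed"]),
         [outdir / "baseline.ped"], [outdir / "discordance.csv"])
    return {"pairs": outdir / "discordance.csv"}


STAGES = {
    "simulate": run_simulate,
    "design-panel": run_design_panel,
    "genotype": run_genotype,
    "self-assign": run_self_assign,
    "assign": run_assign,
    "cv-assign": run_cv_assign,
    "mixture": run_mixture,
    "cluster": run_cluster,
    "concordance": run_concordance,
}


def run_all(cfg: Mapping, outdir: str | Path) -> None:
    """Run every stage in dependency order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(dict(cfg), sort_keys=True))
    for name in ("simulate", "genotype", "design-panel", "self-assign",
                 "assign", "cv-assign", "mixture", "cluster", "concordance"):
        STAGES[name](cfg, outdir)
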