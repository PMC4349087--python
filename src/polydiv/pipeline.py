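"""End-to-end analysis pipeline: per-locus statistics → group comparisons →
multilocus MK → multilocus HKA → clade/balanced-polymorphism diagnostics.

The pipeline consumes a locus manifest plus per-locus FASTA alignments (or a
dataset produced by :mod:`polydiv.simulate`), writes one TSV per report
table (per-locus summaries, group means, rank-test battery, MK model
comparison, HKA tests, clade tables, window scans) and a single
machine-readable JSON bundle, and logs the master seed so any run can be
reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clades as clades_mod
from . import hka as hka_mod
from . import mk as mk_mod
from . import popstats, ranktests
from .seqdata import classify_sites, load_dataset
from .simulate import (
    BalancedConfig,
    DatasetConfig,
    simulate_balanced_locus,
    simulate_dataset,
    write_dataset,
)

log = logging.getLogger("polydiv")


@dataclass
class RunConfig:
    """Settings for a full pipeline run; defaults follow the study settings
    (200 bp / 25 bp windows, 1000 bootstrap replicates, all three MK models)."""

    manifest: str
    outdir: str
    window: int = 200
    step: int = 25
    min_window_S: int = 3
    bootstrap_replicates: int = 1000
    mk_models: tuple[str, ...] = ("M0", "M1", "M2")
    hka_candidates: dict[str, list[str]] = field(default_factory=dict)
    clade_loci: list[str] = field(default_factory=list)
    pathways: tuple[str, ...] = ("Imd", "Toll")
    seed: int = 0
    verbosity: int = 1


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def _pathway_controls(summaries: pd.DataFrame, pathway: str) -> list[str]:
    """Controls for a pathway-level comparison: the position-matched controls
    of that pathway's immune genes (a shared control re-enters each pathway)."""
    imm = summaries[(summaries["group"] == "immune") & (summaries["pathway"] == pathway)]
    ctrls = [c for c in imm["paired_control"].tolist() if isinstance(c, str) and c]
    return sorted(set(ctrls))


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Stage failures are logged and isolated; the returned dict maps stage
    names to results and carries a ``failed_stages`` list.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO if config.verbosity else logging.WARNING)
    alns = load_dataset(config.manifest)
    if len(alns) < 2:
        raise ValueError("pipeline requires at least 2 loci")
    tables = {a.locus_id: classify_sites(a) for a in alns}
    by_id = {a.locus_id: a for a in alns}
    results: dict = {"seed": config.seed, "n_loci": len(alns), "failed_stages": []}
    log.info("loaded %d loci; master seed %d", len(alns), config.seed)

    # --- per-locus statistics -------------------------------------------------
    summaries = pd.DataFrame(
        [popstats.locus_summary(a, tables[a.locus_id]).as_dict() for a in alns]
    )
    summaries.to_csv(outdir / "per_locus_stats.tsv", sep="\t", index=False)
    results["per_locus"] = summaries
    summaries[["locus_id", "tajima_d"]].to_csv(
        outdir / "tajima_d_by_locus.tsv", sep="\t", index=False
    )

    # --- group means + rank tests --------------------------------------------
    try:
        means = popstats.group_means(summaries)
        comparisons = [ranktests.compare_groups(summaries).assign(set="all")]
        mean_tables = [means.assign(set="all")]
        for pw in config.pathways:
            ctrl = _pathway_controls(summaries, pw)
            if not ctrl:
                continue
            sub = summaries[
                ((summaries["group"] == "immune") & (summaries["pathway"] == pw))
                | summaries["locus_id"].isin(ctrl)
            ]
            mean_tables.append(popstats.group_means(sub).assign(set=pw))
            comparisons.append(
                ranktests.compare_groups(summaries, pathway=pw, control_loci=ctrl).assign(set=pw)
            )
        group_means = pd.concat(mean_tables, ignore_index=True)
        group_tests = pd.concat(comparisons, ignore_index=True)
        group_means.to_csv(outdir / "group_means.tsv", sep="\t", index=False)
        group_tests.to_csv(outdir / "group_tests.tsv", sep="\t", index=False)
        results["group_means"] = group_means
        results["group_tests"] = group_tests
    except Exception:
        log.exception("group comparison stage failed")
        results["failed_stages"].append("group_comparison")

    # --- multilocus MK --------------------------------------------------------
    try:
        coding = [a for a in alns if tables[a.locus_id].syn_sites > 0]
        mk_tables = {a.locus_id: mk_mod.build_mk_table(a, tables[a.locus_id]) for a in coding}
        mk_reports = []
        sets: dict[str, list[str]] = {"all": list(mk_tables)}
        for pw in config.pathways:
            ctrl = _pathway_controls(summaries, pw)
            imm = summaries[
                (summaries["group"] == "immune") & (summaries["pathway"] == pw)
            ]["locus_id"].tolist()
            loci = [l for l in imm + ctrl if l in mk_tables]
            if len(loci) >= 2:
                sets[pw] = loci
        mk_fits = {}
        for name, loci in sets.items():
            subset = [mk_tables[l] for l in loci]
            fits, report = mk_mod.compare_mk_models(subset, seed=config.seed)
            mk_fits[name] = fits
            mk_reports.append(report.assign(set=name))
        mk_report = pd.concat(mk_reports, ignore_index=True)
        mk_report.to_csv(outdir / "mk_model_comparison.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(t) for t in mk_tables.values()]).to_csv(
            outdir / "mk_counts.tsv", sep="\t", index=False
        )
        results["mk"] = mk_report
    except Exception:
        log.exception("multilocus MK stage failed")
        results["failed_stages"].append("mk")

    # --- multilocus HKA -------------------------------------------------------
    try:
        hka_counts = [hka_mod.hka_counts_from_alignment(a, tables[a.locus_id]) for a in alns]
        hka_rows = []
        for name, cand in (config.hka_candidates or {}).items():
            stat, df, p, fit0, fit1 = hka_mod.hka_lrt(hka_counts, cand, seed=config.seed)
            hka_rows.append(
                {
                    "candidate_set": name, "stat": stat, "df": df, "p": p,
                    "logL_null": fit0.logL, "logL_alt": fit1.logL, "T_null": fit0.T,
                    **{f"k_{c}": fit1.k[c] for c in fit1.candidates},
                }
            )
        hka_report = pd.DataFrame(hka_rows)
        if not hka_report.empty:
            hka_report.to_csv(outdir / "hka_tests.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(c) for c in hka_counts]).to_csv(
            outdir / "hka_counts.tsv", sep="\t", index=False
        )
        results["hka"] = hka_report
    except Exception:
        log.exception("HKA stage failed")
        results["failed_stages"].append("hka")

    # --- clade diagnostics ----------------------------------------------------
    clade_loci = list(config.clade_loci)
    if not clade_loci and "tajima_d" in summaries:
        top = summaries.dropna(subset=["tajima_d"]).sort_values("tajima_d")
        if not top.empty and top.iloc[-1]["tajima_d"] > 1.0:
            clade_loci = [top.iloc[-1]["locus_id"]]  # flag strongly positive-D loci
    clade_results = {}
    for locus in clade_loci:
        try:
            aln = by_id[locus]
            part = clades_mod.call_clades(aln)
            part.support = clades_mod.bootstrap_support(
                aln, part, replicates=config.bootstrap_replicates, seed=config.seed
            )
            diffs, span = clades_mod.fixed_differences(aln, part)
            part.fixed_differences = diffs
            csum = clades_mod.clade_summary(aln, part)
            groups = {lab: [aln.ingroup_seqs[aln.ingroup_ids.index(i)]
                            for i in part.members(lab)] for lab in part.labels}
            dxy_tab = clades_mod.dxy_table(groups)
            scan = popstats.sliding_tajimas_d(
                aln, config.window, config.step, config.min_window_S,
                table=tables[locus],
            )
            scan.to_dataframe().to_csv(outdir / f"window_scan_{locus}.tsv", sep="\t", index=False)
            clade_rows = pd.DataFrame([s.as_dict() for s in csum.values()])
            clade_rows.to_csv(outdir / f"clade_stats_{locus}.tsv", sep="\t", index=False)
            dxy_tab.to_csv(outdir / f"clade_dxy_{locus}.tsv", sep="\t", index=False)
            clade_results[locus] = {
                "assignments": part.assignments,
                "support": part.support,
                "n_fixed_differences": len(diffs),
                "fixed_span": span,
                "clade_stats": clade_rows,
                "dxy": dxy_tab,
            }
        except Exception:
            log.exception("clade stage failed for %s", locus)
            results["failed_stages"].append(f"clades:{locus}")
    results["clades"] = clade_results

    bundle = _jsonify(
        {k: v for k, v in results.items() if k != "per_locus"}
        | {"per_locus": results["per_locus"]}
    )
    (outdir / "results.json").write_text(json.dumps(bundle, indent=1, sort_keys=True) + "\n")
    (outdir / "run.log").write_text(
        f"seed={config.seed}\nn_loci={len(alns)}\nfailed_stages={results['failed_stages']}\n"
    )
    return results


def generate_fixtures(scenario: str, outdir: str | Path, seed: int = 0) -> Path:
    """Write a named synthetic dataset directory; returns the manifest path.

    Scenarios: ``minimal`` (3 small loci), ``paper-shape`` (the 20+17-locus
    study-scale dataset), ``balanced`` (study-scale dataset plus a
    balanced-polymorphism locus for the focal species).
    """
    outdir = Path(outdir)
    if scenario == "minimal":
        cfg = DatasetConfig(n_immune=2, n_control=1, n_alleles=6, length=600, seed=seed)
        alns, truths = simulate_dataset(cfg)
        return write_dataset(outdir, alns, truths)
    if scenario == "paper-shape":
        alns, truths = simulate_dataset(DatasetConfig(seed=seed))
        return write_dataset(outdir, alns, truths)
    if scenario == "balanced":
        alns, truths = simulate_dataset(DatasetConfig(seed=seed))
        bal, btruth = simulate_balanced_locus(BalancedConfig(seed=seed + 1))
        focal = bal["sp1"]
        focal.locus_id = "BAL01"
        alns.append(focal)
        truths.append(btruth)
        return write_dataset(outdir, alns, truths)
    raise ValueError(f"unknown scenario {scenario!r}")
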