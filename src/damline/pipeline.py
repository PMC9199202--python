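"""End-to-end study pipelines.

``run_scenario`` executes one simulated replicate: simulate, estimate
with every method (BOA from the tracked origins, LR, supervised
admixture on an LD-pruned panel, both grandparent-relationship
variants), post-process, and evaluate against the tracked truth and
against BOA.  ``run_simulation_study`` repeats this over scenarios and
replicates and aggregates replicate means into the familiar
method x scenario x metric tables.  ``run_real_data`` applies the same
stages to data read from disk, with BOA (when supplied) as the
reference instead of the unavailable truth.

All randomness flows from a single seed through named child streams; a
JSON manifest records the run.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from .datatypes import (CROSSBRED, MISSING_PARENT, DamlineError, GenotypePanel,
                        OriginMatrix, Pedigree, ProportionEstimates)
from .estimators import (admixture_supervised_em, boa_proportions, lr_estimate,
                         rel_gp_estimate)
from .evaluation import evaluate, fst_wc, method_correlation_table
from .freqs import purebred_line_freqs, regression_line_freqs
from .io import maf_filter
from .ldprune import prune_panel
from .postprocess import postprocess_estimates
from .sim import SimulationConfig, preset_config, simulate_scenario

__all__ = ["run_scenario", "run_simulation_study", "run_real_data"]

log = logging.getLogger(__name__)

METHODS = ("BOA", "LR", "ADM", "REL_GP", "REL_GP_noF")


def estimate_all(panel: GenotypePanel, pedigree: Pedigree,
                 origins: OriginMatrix | None,
                 prune_threshold: float = 0.5,
                 prune_window: int = 50, prune_step: int = 10,
                 restrict_common: bool = True,
                 postprocess: bool = True) -> dict[str, ProportionEstimates]:
    """Run every applicable estimator on one dataset.

    By default all methods are restricted to the crossbreds that have
    both maternal grandparents genotyped, so that the methods are
    compared on a common cohort; post-processing is applied per method
    on that cohort.
    """
    freqs_count = purebred_line_freqs(panel)
    freqs_reg = regression_line_freqs(panel)

    out: dict[str, ProportionEstimates] = {}
    rel, _, _, n_excluded = rel_gp_estimate(panel, pedigree, freqs_reg,
                                            adjust_inbreeding=False)
    rel_nof, _, _, _ = rel_gp_estimate(panel, pedigree, freqs_reg,
                                       adjust_inbreeding=True)
    if n_excluded:
        log.info("%d crossbred(s) lack a genotyped maternal grandparent", n_excluded)
    cohort = rel.ids if restrict_common else panel.ids_of(CROSSBRED)
    keep = np.isin(panel.ids, np.concatenate(
        [panel.ids[panel.lines != CROSSBRED], cohort]))
    sub = panel.subset_animals(keep)

    out["LR"] = lr_estimate(sub, freqs_count)
    pruned = prune_panel(sub, window=prune_window, step=prune_step,
                         threshold=prune_threshold)
    out["ADM"] = admixture_supervised_em(pruned, freqs_count.subset_snps(
        _kept_indices(sub, pruned)))
    out["REL_GP"] = rel.restrict(cohort)
    out["REL_GP_noF"] = rel_nof.restrict(cohort)
    if origins is not None:
        out["BOA"] = boa_proportions(origins).restrict(cohort)
    if postprocess:
        out = {k: postprocess_estimates(v) for k, v in out.items()}
    return out


def _kept_indices(panel: GenotypePanel, pruned: GenotypePanel) -> np.ndarray:
    pos = {s: j for j, s in enumerate(panel.markers.table["snp"])}
    return np.array([pos[s] for s in pruned.markers.table["snp"]], dtype=int)


def adm_pruning_table(result, thresholds=(0.1, 0.3, 0.5, 0.7, 0.9, None),
                      postprocess: bool = True) -> pd.DataFrame:
    """Sensitivity of the supervised-admixture estimates to LD pruning.

    Runs ADM on the panel pruned at each r2 threshold (``None`` = no
    pruning) over *all* crossbreds, and reports SNP counts plus the
    quality metrics against the tracked truth.
    """
    panel = result.panel
    freqs = purebred_line_freqs(panel)
    rows = []
    for thr in thresholds:
        if thr is None:
            sub, fsub = panel, freqs
        else:
            kept = prune_panel(panel, threshold=thr)
            sub = kept
            fsub = freqs.subset_snps(_kept_indices(panel, kept))
        est = admixture_supervised_em(sub, fsub)
        if postprocess:
            est = postprocess_estimates(est)
        report = evaluate(est, result.truth.restrict(est.ids))
        rows.append({"r2_threshold": "none" if thr is None else thr,
                     "n_snps": sub.n_snps, **report.to_dict()})
    return pd.DataFrame(rows)


def run_scenario(config: SimulationConfig, prune_threshold: float = 0.5,
                 postprocess: bool = True):
    """Simulate one replicate and estimate with every method.

    Returns ``(result, estimates, truth)`` where ``estimates`` maps
    method name to (post-processed) :class:`ProportionEstimates` and
    ``truth`` is restricted to the same cohort.
    """
    result = simulate_scenario(config)
    estimates = estimate_all(result.panel, result.pedigree, result.origins,
                             prune_threshold=prune_threshold,
                             postprocess=postprocess)
    truth = result.truth.restrict(estimates["LR"].ids)
    return result, estimates, truth


def run_simulation_study(scenarios=("close", "distant", "unrelated"),
                         replicates: int = 1, seed: int = 1,
                         outdir=None, prune_threshold: float = 0.5,
                         postprocess: bool = True, config_overrides=None):
    """The full simulation experiment; returns (quality table, correlation table).

    The quality table is shaped method x scenario x metric with columns
    for both references (truth and BOA), averaged across replicates; the
    correlation table holds between-method correlations of line-B
    proportions per scenario.
    """
    config_overrides = dict(config_overrides or {})
    rows, corr_rows = [], []
    fst_rows = []
    root = np.random.SeedSequence(seed)
    for scenario in scenarios:
        for rep in range(replicates):
            child_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            config = preset_config(scenario, seed=child_seed, **config_overrides)
            result, estimates, truth = run_scenario(
                config, prune_threshold=prune_threshold, postprocess=postprocess)
            purebreds = result.panel.subset_animals(result.panel.lines != CROSSBRED)
            pw = fst_wc(purebreds, pairwise=True)
            fst_rows.append({"scenario": scenario, "replicate": rep,
                             "fst_mean_pairwise": float(np.mean(list(pw.values())))})
            refs = {"TRUE": truth}
            if "BOA" in estimates:
                refs["BOA"] = estimates["BOA"]
            for method, est in estimates.items():
                for ref_name, ref in refs.items():
                    if method == ref_name or (method == "BOA" and ref_name == "BOA"):
                        continue
                    rep_report = evaluate(est, ref)
                    rows.append({"scenario": scenario, "replicate": rep,
                                 "reference": ref_name, **rep_report.to_dict()})
            corr = method_correlation_table(list(estimates.values()))
            corr_rows.append(corr.assign(scenario=scenario, replicate=rep,
                                         method=corr.index))
    quality = pd.DataFrame(rows)
    agg = (quality.drop(columns="replicate")
           .groupby(["scenario", "reference", "method"], sort=False)
           .mean(numeric_only=True).reset_index())
    corr_all = pd.concat(corr_rows, ignore_index=True)
    corr_agg = (corr_all.groupby(["scenario", "method"], sort=False)
                .mean(numeric_only=True).drop(columns="replicate").reset_index())
    fst = pd.DataFrame(fst_rows)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        agg.to_csv(os.path.join(outdir, "quality_by_method.tsv"), sep="\t", index=False)
        corr_agg.to_csv(os.path.join(outdir, "method_correlations.tsv"),
                        sep="\t", index=False)
        fst.to_csv(os.path.join(outdir, "fst.tsv"), sep="\t", index=False)
        manifest = {"seed": seed, "scenarios": list(scenarios),
                    "replicates": replicates, "prune_threshold": prune_threshold,
                    "postprocess": postprocess, "config_overrides": config_overrides}
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return agg, corr_agg, fst


def run_real_data(ped_path, map_path, line_table_path, pedigree_path,
                  origins_path=None, outdir=None, maf_threshold: float = 0.1,
                  prune_threshold: float = 0.5, postprocess: bool = True):
    """Run the estimation pipeline on data read from disk.

    Without an origins table only the between-method correlation table
    is produced; with one, BOA serves as the evaluation reference.
    """
    from .io import read_line_table, read_origins, read_pedigree, read_pedmap

    lines = read_line_table(line_table_path)
    panel = read_pedmap(ped_path, map_path, lines)
    pedigree = read_pedigree(pedigree_path)
    missing = set(pedigree.crossbreds["id"]) - set(panel.ids)
    if missing:
        raise DamlineError(f"pedigree ids absent from panel: {sorted(missing)[:5]}")
    origins = None
    if origins_path is not None:
        origins = read_origins(origins_path)
        if origins.n_snps != panel.n_snps:
            raise DamlineError("origins SNP count does not match the panel")
    panel_f = maf_filter(panel, maf_threshold)
    if origins is not None:
        surviving = set(panel_f.markers.table["snp"])
        kept = [j for j, s in enumerate(panel.markers.table["snp"]) if s in surviving]
        origins = origins.subset_snps(np.array(kept, dtype=int))
    estimates = estimate_all(panel_f, pedigree, origins,
                             prune_threshold=prune_threshold,
                             postprocess=postprocess)
    corr = method_correlation_table(list(estimates.values()))
    quality = None
    if origins is not None:
        ref = estimates["BOA"]
        rows = [evaluate(est, ref).to_dict()
                for method, est in estimates.items() if method != "BOA"]
        quality = pd.DataFrame(rows)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        corr.to_csv(os.path.join(outdir, "method_correlations.tsv"), sep="\t")
        if quality is not None:
            quality.to_csv(os.path.join(outdir, "quality_by_method.tsv"),
                           sep="\t", index=False)
        for method, est in estimates.items():
            est.to_frame().to_csv(os.path.join(outdir, f"estimates_{method}.tsv"),
                                  sep="\t", index=False)
    return estimates, corr, quality
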