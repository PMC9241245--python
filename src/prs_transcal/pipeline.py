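"""End-to-end orchestration: simulate -> score -> ancestry -> adjust ->
evaluate -> meta/concordance.

``run_pipeline`` drives the whole analysis on a synthetic multi-ancestry
study and writes plain-text artifacts (TSV/JSON) plus a manifest with
input hashes so reruns can be verified bit-for-bit for the deterministic
stages.  Each stage logs one structured line with its input/output
sample and variant counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjustment import adjust, fit_adjustment
from .ancestry import (AncestryCoordinates, assign_population, fit_pca,
                       ld_prune, project)
from .evaluation import (DEFAULT_PREVALENCE, EvaluationInput, logistic_fit,
                         calibration_by_decile, metrics_report)
from .meta_concordance import (effect_concordance, extract_lead_variants,
                               fixed_effect_meta, ivw_meta)
from .scoring_io import filter_maf, score_pipeline
from .synthetic_cohorts import (SimulationConfig, simulate_cohort,
                                simulate_gwas_summary,
                                simulate_reference_panel,
                                weight_table_from_effects, write_cohort)

logger = logging.getLogger("prs_transcal")


@dataclass
class PipelineConfig:
    """Run-level settings; every toggle defaults to the documented choice.

    ``simulation`` holds keyword overrides for
    :class:`~prs_transcal.synthetic_cohorts.SimulationConfig`.  The
    synthetic genome is compact (variants ~1 kb apart), so the demo locus
    window is much smaller than the 500 kb used on real coordinates.
    """

    seed: int = 0
    simulation: dict = field(default_factory=dict)
    cutoffs: tuple = (2.0, 5.0, 10.0)
    maf_threshold: float = 0.01
    prune_window: int = 100
    prune_step: int = 50
    prune_r2: float = 0.1
    k_pc: int = 10
    n_pcs_assignment: int = 6
    n_pcs_adjustment: int = 5
    n_pcs_covariates: int = 10
    assignment_prob_threshold: float = 0.8
    lead_p_threshold: float = 5e-8
    locus_window_bp: int = 5000
    prevalence_registry: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(raw["cutoffs"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis; returns the results dict written to
    ``outdir/metrics.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
    panel, panel_labels = simulate_reference_panel(sim_cfg)
    cohort = simulate_cohort(sim_cfg)
    gwas = simulate_gwas_summary(sim_cfg)
    weights = weight_table_from_effects(sim_cfg)
    logger.info("simulate: panel %d x %d, cohort %d x %d",
                panel.n_samples, panel.n_variants,
                cohort.dosages.n_samples, cohort.dosages.n_variants)

    inputs = outdir / "inputs"
    paths = write_cohort(cohort, inputs)
    from .scoring_io import write_weights_pgs
    paths["weights"] = inputs / "weights.pgs.tsv"
    write_weights_pgs(weights, paths["weights"])

    genotypes = filter_maf(cohort.dosages, config.maf_threshold,
                           groups=cohort.population_label)
    raw = score_pipeline(weights, genotypes)
    logger.info("score: %d samples scored over %d variants",
                len(raw.scores), raw.n_variants_used)

    kept = ld_prune(panel, config.prune_window, config.prune_step,
                    config.prune_r2)
    pca = fit_pca(panel.subset_variants(kept), k_pc=config.k_pc,
                  ref_labels=panel_labels)
    coords = project(pca, genotypes)
    assigned = assign_population(coords, pca, config.n_pcs_assignment,
                                 config.assignment_prob_threshold)
    logger.info("ancestry: pruned to %d variants, %d/%d samples assigned",
                len(kept), int((assigned.labels != "unassigned").sum()),
                len(assigned.labels))

    panel_scores = score_pipeline(weights, panel)
    ref_coords = AncestryCoordinates(
        sample_ids=panel.sample_ids, pcs=pca.ref_scores,
        model_fingerprint=pca.fingerprint)
    adj_model = fit_adjustment(panel_scores, ref_coords,
                               n_pcs=config.n_pcs_adjustment)
    adjusted = adjust(adj_model, raw, coords)
    logger.info("adjust: fitted on %d reference samples, %d floored",
                panel.n_samples, adj_model.n_floored_fit)

    # per-population evaluation on the raw score
    pc_cov = pd.DataFrame(
        coords.pcs[:, : config.n_pcs_covariates],
        columns=[f"PC{k + 1}" for k in range(config.n_pcs_covariates)])
    covariates = pd.concat(
        [cohort.covariates.reset_index(drop=True), pc_cov], axis=1)
    prev_list = list(sim_cfg.prevalence) + [sim_cfg.admixed_prevalence]
    pop_prev = dict(zip(sim_cfg.population_names + ["admixed"], prev_list))
    reports, tail_logors = {}, []
    for pop in np.unique(cohort.population_label):
        mask = cohort.population_label == pop
        status = cohort.status[mask]
        if status.min() == status.max() or mask.sum() < 50:
            continue
        inp = EvaluationInput(status, raw.values[mask],
                              covariates.loc[mask].reset_index(drop=True),
                              prevalence=pop_prev[pop])
        rep = metrics_report(inp, cutoffs=config.cutoffs)
        reports[pop] = rep.to_dict()
        top10 = [t for t in rep.tail if t.cutoff_percent == 10.0]
        if top10 and not top10[0].unstable:
            t = top10[0]
            se = (np.log(t.ci_high) - np.log(t.ci_low)) / (2 * 1.959964)
            tail_logors.append((np.log(t.or_estimate), se))
    logger.info("evaluate: %d population reports", len(reports))

    meta_or = None
    if len(tail_logors) >= 2:
        m = ivw_meta([x for x, _ in tail_logors], [s for _, s in tail_logors])
        meta_or = {"or": float(np.exp(m.estimate)),
                   "ci": [float(np.exp(c)) for c in m.ci95],
                   "p": m.p_value, "n_studies": len(tail_logors),
                   "i2": m.i2}

    meta_sum = fixed_effect_meta(list(gwas.values()))
    leads = extract_lead_variants(meta_sum, config.lead_p_threshold,
                                  config.locus_window_bp)
    concordance = None
    names = sim_cfg.population_names
    if len(leads) >= 3 and len(names) >= 2:
        try:
            c = effect_concordance(gwas[names[0]], gwas[names[-1]], leads,
                                   panel=panel,
                                   locus_window_bp=config.locus_window_bp)
            concordance = {"r_abs_beta": c.r, "n_variants": c.n_variants,
                           "n_tag_substitutions": len(c.substitutions)}
        except ValueError as e:
            logger.warning("concordance skipped: %s", e)
    logger.info("meta: %d leads from %d meta-analyzed variants",
                len(leads), len(meta_sum))

    # pooled calibration of the adjusted score
    pooled_prev = float(np.mean([pop_prev[p] for p in
                                 np.unique(cohort.population_label)]))
    joint = logistic_fit(
        cohort.status,
        np.column_stack([adjusted.values,
                         EvaluationInput(cohort.status, adjusted.values,
                                         covariates,
                                         pooled_prev).covariate_matrix()]))
    calib = calibration_by_decile(cohort.status, joint.fitted,
                                  score=adjusted.values)

    results = {
        "config": dataclasses.asdict(config),
        "per_population": reports,
        "meta_or_top10": meta_or,
        "concordance": concordance,
        "n_lead_variants": int(len(leads)),
        "adjusted_score_sd_by_population": {
            p: float(adjusted.values[cohort.population_label == p].std())
            for p in np.unique(cohort.population_label)
        },
    }

    # artifacts
    scores_df = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "prs_raw": raw.values,
        "prs_adjusted": adjusted.values,
        "variance_floored": adjusted.floored.astype(int),
        "population_true": cohort.population_label,
        "population_assigned": assigned.labels,
        "assignment_probability": assigned.probabilities,
    })
    scores_df.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    calib.to_csv(outdir / "calibration.tsv", sep="\t", index=False)
    pca.save(outdir / "pc_model.json")
    adj_model.save(outdir / "adjustment_model.json")
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(results, fh, indent=1, default=_jsonable)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
        "inputs": {p.name: _sha256(Path(p)) for p in sorted(inputs.glob("*"))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("run_pipeline: wrote %d artifacts to %s",
                len(manifest["outputs"]), outdir)
    return results


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="list")
    raise TypeError(f"not JSON serializable: {type(o)}")
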