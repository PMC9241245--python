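# prs-transcal

Trans-ancestry polygenic risk score (PRS) evaluation and calibration.

A PRS compresses genome-wide risk into one number per person,
`PRS_i = Σ_j w_j · d_ij`, where `w_j` is a per-allele weight from GWAS
and `d_ij` the effect-allele dosage.  Deploying one score across
ancestrally diverse patients runs into two problems this package
addresses end to end:

1. **Evaluation.**  How well does the score discriminate cases from
   controls in each population?  The package computes the full metrics
   suite used in trans-ancestry PRS studies: liability-scale R² with
   ascertainment correction `C = K²(1−K)² / (z² P(1−P))`, four AUC
   variants (covariates-only, score-only, covariate-adjusted score,
   combined), odds ratio per SD of the score, tail odds ratios at the
   top 2/5/10% of the distribution, sensitivity/specificity, and
   prevalence-adjusted predictive values
   `PPV = sens·prev / [sens·prev + (1−spec)(1−prev)]`,
   `NPV = spec·(1−prev) / [spec·(1−prev) + (1−sens)·prev]`,
   plus decile calibration of predicted vs observed risk.
2. **Calibration across ancestries.**  Raw PRS distributions shift by
   population because allele frequencies differ, so one clinical cutoff
   cannot be shared.  The package fits the post hoc ancestry adjustment:
   regress the score's mean and its squared residuals (variance) on the
   top 5 reference-panel principal components, then standardize any
   individual as
   `PRS_adj = (PRS_raw − (α̂₀+Σα̂_k·PC_k)) / sqrt(β̂₀+Σβ̂_k·PC_k)`.

Around these sit the supporting stages a real analysis needs: PGS
Catalog scoring-file and VCF/dosage-TSV readers with allele
harmonization, greedy windowed LD pruning, reference-panel PCA with
projection and probabilistic population assignment (with abstention),
inverse-variance-weighted meta-analysis of per-cohort ORs, per-variant
fixed-effect meta-analysis of GWAS summaries, lead-variant extraction,
LD tag-variant substitution, and cross-population effect-size
concordance.  A synthetic-data module generates multi-ancestry cohorts
(Balding–Nichols allele-frequency divergence, liability-threshold
disease, admixed samples, noisy GWAS summaries) so the whole pipeline is
testable without restricted genotype data.

Intended users: statistical geneticists and genomic-medicine teams who
have a weight table and cohort genotypes/phenotypes and want
reproducible cross-ancestry performance reports and a calibrated score.

## Worked example

Simulate a three-population study with the default settings (population
prevalences 10.0/12.5/13.7%, score explaining 10% of liability
variance), score it, adjust for ancestry against the simulated reference
panel, and evaluate per population:

```python
import numpy as np
from prs_transcal import (
    AncestryCoordinates, EvaluationInput, SimulationConfig, adjust,
    fit_adjustment, fit_pca, metrics_report, project, score_pipeline,
    simulate_cohort, simulate_reference_panel, weight_table_from_effects)

cfg = SimulationConfig(seed=42)           # three populations, defaults
panel, labels = simulate_reference_panel(cfg)
cohort = simulate_cohort(cfg)
weights = weight_table_from_effects(cfg)

raw = score_pipeline(weights, cohort.dosages)
pca = fit_pca(panel, k_pc=6, ref_labels=labels)
coords = project(pca, cohort.dosages)
ref_coords = AncestryCoordinates(panel.sample_ids, pca.ref_scores,
                                 model_fingerprint=pca.fingerprint)
model = fit_adjustment(score_pipeline(weights, panel), ref_coords, n_pcs=5)
adjusted = adjust(model, raw, coords)

for pop, prev in zip(cfg.population_names, cfg.prevalence):
    mask = cohort.population_label == pop
    rep = metrics_report(EvaluationInput(
        cohort.status[mask], raw.values[mask],
        cohort.covariates[mask], prevalence=prev))
    print(f"{pop}: liability R2 = {rep.liability_r2:.3f}, "
          f"OR/SD = {rep.or_per_sd:.2f}, "
          f"top-2% OR = {rep.tail[0].or_estimate:.2f}, "
          f"adjusted NPV = {rep.tail[0].adjusted_npv:.2f}")
    print(f"  raw PRS mean {raw.values[mask].mean():+.2f} -> "
          f"adjusted {adjusted.values[mask].mean():+.2f} "
          f"(SD {adjusted.values[mask].std():.2f})")
```

prints

```
pop0: liability R2 = 0.112, OR/SD = 2.02, top-2% OR = 6.35, adjusted NPV = 0.91
  raw PRS mean +2.89 -> adjusted -0.01 (SD 1.04)
pop1: liability R2 = 0.136, OR/SD = 2.07, top-2% OR = 2.93, adjusted NPV = 0.88
  raw PRS mean -3.08 -> adjusted -0.06 (SD 0.98)
pop2: liability R2 = 0.105, OR/SD = 1.87, top-2% OR = 2.55, adjusted NPV = 0.87
  raw PRS mean -0.28 -> adjusted +0.01 (SD 0.99)
```

Each population's liability R² recovers the generative 10% (to sampling
noise), individuals in the top 2% of the score carry a several-fold
increased disease odds, the prevalence-adjusted NPVs sit near 0.9, and
the ancestry adjustment collapses raw between-population mean shifts of
±3 score units onto a common mean-0/SD-1 scale.

The same workflow is available from the shell:

```bash
prs-transcal simulate --out study/ --seed 1
prs-transcal score --weights study/weights.pgs.tsv \
    --genotypes study/cohort.vcf --format vcf --out study/scores.tsv
prs-transcal run --out study/run --seed 1       # full pipeline + report
```

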