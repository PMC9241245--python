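# Methods

This note documents the models, numerical conventions and design choices
behind `prs_transcal`, in the order the pipeline runs.

## Synthetic multi-ancestry studies

The generator (`synthetic_cohorts`) produces every input the analysis
consumes — a labeled reference panel, evaluation cohorts, a weight
table, and per-population GWAS summary statistics — from one seeded
configuration, so panel, cohorts and summaries share the same underlying
population frequencies and true effects.

**Allele frequencies.**  Divergence follows the Balding–Nichols model:
an ancestral frequency `p ~ Uniform(0.05, 0.5)` per variant, and each
population's frequency drawn from `Beta(p(1−F)/F, (1−p)(1−F)/F)` with
per-population drift parameter `F` (its FST against the ancestor;
`F ∈ {0, 1}` is rejected as degenerate).  For two populations with
drift `F₁, F₂` the expected pairwise Hudson FST is `(F₁+F₂)/2`, which
the tests verify against an independent Hudson estimator.  The
ancestral-frequency floor of 0.05 keeps a 1% MAF filter from binding on
most variants; both bounds are configurable.  Genotypes are two
Bernoulli allele draws per sample (Binomial(2, p) marginally); there is
no linkage disequilibrium except an optional knob that appends "tag"
variants — allele-level copies of random source variants retained with
probability `ρ`, giving dosage correlation ≈ ρ (so r² ≈ ρ²) — to
exercise LD pruning and tag-variant search.  Coalescent simulation and
realistic LD blocks are out of scope.

**Admixture** is modeled at the allele-frequency level: an admixed
sample's per-variant frequency is the admixture-weighted mixture of
parental population frequencies.  This places admixed samples between
parental PC centroids (what projection and adjustment need) without
local-ancestry tracts.

**Disease** follows the liability-threshold model.  The genetic score
`g = Σ w_j d_j` is standardized *within population*, scaled to variance
`h² = liability_h2`, and Gaussian noise of variance `1 − h²` is added;
a sample is a case iff liability exceeds `Φ⁻¹(1−K)` for its population's
prevalence `K`.  Within-population standardization makes the realized
case fraction converge to the configured `K` in every population even
when allele-frequency divergence shifts the raw score.  Defaults encode
the study conditions the package targets: three continental populations
(European-, African- and East-Asian-like) with prevalences 10.0%, 12.5%
and 13.7%, admixed (Hispanic/Latino-like) samples at 13.1%, drift
parameters (0.05, 0.15, 0.10) chosen as realistic continental-scale
divergence, and `h² = 0.10`, the order of liability variance a current
type 2 diabetes score explains in its best-matched population.

**True effects** are Normal(0, 1) on `n_causal` variants.  Across
populations, effects correlate at `cross_pop_effect_corr` (default 1:
shared effects) via a shared-plus-independent decomposition; the
parameter exists because cross-ancestry effect architecture is an
empirical question the generator should not hard-code.  **GWAS
summaries** add noise with the analytic standard error
`SE = 1/sqrt(2·N·p(1−p))` of a per-allele regression coefficient on a
standardized trait, and a Wald p-value; monomorphic variants (undefined
SE) are dropped with a recorded count.  Default discovery sizes mirror
the scale imbalance of real multi-ancestry GWAS (≈900k European-like,
≈24k African-like, ≈177k East-Asian-like effective N).

**Covariates** (age, sex, 3 sites) are generated independent of genotype
by default; `confound_site_with_population` ties site to population to
stress covariate adjustment.

What passing tests on these data do *not* show: robustness to real LD
structure, imputation error, phenotyping misclassification, relatedness,
or ascertainment quirks of clinical cohorts — none of which the
generator emulates.

## Scoring

Variants are keyed by `(chrom, 1-based pos, unordered allele pair)`;
rsIDs are only a fallback.  When the weight file's effect allele is the
genotype's other allele, the effect dosage is `2 − d` with the weight
kept — so flipping a file's allele columns (and negating its weights)
changes every score by the same constant, preserving ranks.
Strand-ambiguous SNPs (A/T, C/G) are dropped by default because their
orientation cannot be verified without strand metadata; a `keep` policy
exists for pre-harmonized data.  Missing dosages are imputed as
`2 × effect-allele frequency` (the default of the standard scoring
tools); `mean_impute=False` drops them instead.  Multi-allelic VCF
records are skipped with a count.  MAF filtering (default 1%) is applied
within each population when labels are provided, removing a variant that
fails in any group.

## Ancestry inference

**LD pruning** is the greedy windowed algorithm: within each window of
`window` variants advanced by `step` (per chromosome), while any pair of
survivors has squared Pearson dosage correlation above `r2_max`, the
member of the worst pair with the lower MAF is removed (ties: later
position).  Defaults (500/50/0.05) match common reference-panel
practice; the compact synthetic genome uses smaller windows.

**PCA** standardizes each variant by mean `2p` and scale
`sqrt(2p(1−p))`, excludes zero-variance variants, mean-imputes missing
entries, and takes the top-K SVD.  Component signs are fixed by making
the largest-magnitude loading positive, so downstream regression
coefficients are reproducible.  `K` must be below the matrix rank.
**Projection** uses the reference standardization constants and
loadings; model variants absent from the target (or missing entries)
contribute the standardized mean, i.e. zero, and an overlap below 50%
(configurable) is an error — heavy missingness shrinks projected
coordinates toward the origin, which the adjustment would misread as
admixture.

**Population assignment** is a probabilistic classifier over the top
`n_pcs` (default 6) reference PC scores with an abstention threshold
(default 0.8).  The default model is a seeded extremely-randomized tree
ensemble.  This was a deliberate choice over a Gaussian class-conditional
model: with well-separated reference clusters, likelihood-ratio
posteriors are essentially 0/1 even for samples lying in the empty PC
space *between* clusters, so admixed individuals get confidently — and
wrongly — assigned.  Randomized-threshold trees draw split points
uniformly within the feature range, so their vote fractions decay
smoothly across the between-cluster gap: in the two-population F=0.1
simulation, 100% of admixed samples abstain at threshold 0.8 while 100%
of single-population samples are assigned.  The Gaussian model remains
available (`classifier="gaussian"`).  Both are deterministic.
Intersecting genetic assignments with self-reported labels is supported
as an optional downstream filter on the assignment table, not inferred.

## Post hoc ancestry adjustment

Two ordinary least squares regressions on the top 5 PCs of a scored
reference panel: the score itself (coefficients α), then the per-sample
*squared residuals* of that fit (coefficients β) — the linear-variance
reading of "residual variance"; a log-link variant would guarantee
positivity but departs from the linear form, so it is not the default.
The adjusted score is `(raw − fitted mean)/sqrt(fitted variance)`.
Fitted variances can be negative at extreme PC coordinates, so they are
floored at `1e-6 × Var(reference scores)` and floored samples are
flagged.  Scores are fitted raw (uncentered, unscaled); the convention
is written into the saved model file.  The whole reference panel is used
for fitting, not per-population subsets — the point is one model that
interpolates across (and between) populations.  A fingerprint of the PC
space travels with both the projected coordinates and the adjustment
model, and `adjust` refuses mismatched spaces.  The adjustment
standardizes the score scale only; it does not recalibrate absolute risk
probabilities.

On the F=0.1 two-population simulation the adjustment removes at least
80% of the between-population mean gap (typically well above 90%),
leaves each population's SD within 15% of 1, and a single pooled
top-10% cutoff reproduces the within-population raw-score tail OR
(inside its 95% CI) — distributional differences removed without
compromising tail discrimination, verified in
`tests/test_acceptance.py`.  Because the raw gap depends on how the
random weights align with the frequency divergence, the acceptance
script pools gaps over three replicate weight draws before forming the
shrinkage ratio.

## Evaluation metrics

Logistic regressions are maximum-likelihood fits with Wald standard
errors and symmetric Wald 95% intervals (matching how PRS ORs are
conventionally printed); quasi-separation is flagged and the interval
marked unreliable rather than raising.  The AUC is the rank-statistic
concordance probability with ties counted half (cross-checked against
scikit-learn's ROC integral in the tests).  The four-AUC suite reads
"score adjusting for covariates" as the AUC of the score residualized on
the covariates by least squares — the most common reading; it is
isolated in `auc_suite` so an alternative covariate-adjusted ROC could
be swapped in.  With constant or absent covariates the residualized AUC
equals the score-only AUC exactly.

Liability-scale R² multiplies the *incremental* observed-scale R² (linear
0/1 regression, covariates+score over covariates) by
`C = K²(1−K)² / (z²·P(1−P))`, `z` the standard-normal density at
`Φ⁻¹(1−K)`; at `K = P` this reduces to `K(1−K)/z²`, and at
`K = P = 0.5` to π/2.  The linear-model observed-scale estimator is the
conventional pairing with this transformation.  The result is clipped to
[0, 1].

Tail metrics define the high-risk group as `score ≥` the empirical
`(100−c)`-th percentile, with all tied values entering the top group and
the realized group size reported.  The OR comes from a
covariate-adjusted logistic fit on the indicator; sensitivity and
specificity from the raw cross-tabulation (computed before covariate
adjustment); PPV/NPV from the exact prevalence-adjusted formulas with
the population prevalence from the shipped registry
(`data/prevalence.yaml`: european 0.100, african 0.125, hispanic 0.131,
asian 0.137), overridable per call.  Decile calibration ranks samples by
the score, splits them into 10 groups differing in size by at most one,
and compares mean predicted probability with observed case fraction.

## Meta-analysis and concordance

Inverse-variance weighting throughout: weights `1/se²`, combined
standard error `1/sqrt(Σw)`; the per-variant fixed-effect meta-analysis
applies the same formula after harmonizing each study to a canonical
effect allele (matched on chrom/pos/unordered pair; swapped-allele
studies get `−β` and `1−freq`).  The variant-level weighting scheme is
assumed inverse-variance, consistent with the cohort-level OR
meta-analysis.  Cochran's Q and I² are reported, never filtered on.
Lead variants are extracted greedily: smallest p below 5e-8, remove
everything within the locus window on the same chromosome, repeat; the
result is order-invariant and matches brute-force enumeration in the
tests.  The locus window defaults to 500 kb each side — no standard
definition of "locus" exists, so the value is prominently configurable
(the synthetic pipeline uses 5 kb because its variants sit ~1 kb apart).
Tag-variant search maximizes squared dosage correlation with the lead in
a genotype panel, restricted to the locus window for tractability, and
requires r² ≥ 0.6.  Effect concordance is the Pearson correlation of
|β| pairs at leads (or their tags); tag substitution attenuates the
correlation in expectation, which the tests assert as a property.

## Pipeline and problem sizes

`run_pipeline` chains the stages on one seeded configuration and writes
plain-text artifacts (TSV/JSON) plus a manifest of SHA-256 hashes;
reruns with the same seed are bit-identical.  Defaults for the packaged
demo — ~1000–2000 variants, a few hundred reference samples per
population, 1000–4000 cohort samples per population, 20,000 samples for
direct metric-recovery simulations — were chosen so the full test suite
and acceptance script each complete in well under a minute of compute on
one core while leaving all recovery tolerances comfortably met;
`SimulationConfig` scales to larger studies unchanged.

## Known limitations

* No real LD structure; pruning and tag-search are exercised via the
  duplicated/correlated-variant knob only.
* Incident-case (survival) evaluation is out of scope; only prevalent
  case-control status is analyzed.
* Percentile cutoffs are treated as fixed; their sampling uncertainty is
  not propagated into tail-metric intervals.
* The adjustment's linear variance model can predict negative variances
  far outside the reference PC hull; flooring keeps the output finite
  but extrapolation that far should not be trusted.
* Indels, multi-allelic weights, BGEN/PLINK-binary input, phasing,
  relatedness and imputation are out of scope (upstream tools).
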