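"""Synthetic multi-ancestry cohorts for end-to-end pipeline testing.

Generates everything the downstream analysis consumes: a labeled
reference panel, evaluation cohorts with a liability-threshold binary
disease, and per-population GWAS summary statistics.

Model
-----
* **Allele-frequency divergence** follows the Balding–Nichols model: an
  ancestral frequency ``p`` is drawn uniformly (default 0.05–0.5) and each
  population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with drift
  parameter ``F`` (the per-population FST).  Genotypes are two Bernoulli
  allele draws per sample (equivalently Binomial(2, p_pop)).
* **Admixture** acts at the allele-frequency level: an admixed sample's
  per-variant frequency is the mixture of parental population frequencies
  weighted by the admixture proportions.
* **Disease** follows the liability-threshold model: liability is the
  within-population standardized genetic score scaled to variance
  ``liability_h2`` plus independent Gaussian noise of variance
  ``1 - liability_h2``; a sample is a case iff its liability exceeds
  ``Phi^{-1}(1 - K)`` for its population's prevalence ``K``.
* **GWAS summaries** add sampling noise to the population-specific true
  effects with SE = 1/sqrt(2 N p (1-p)), the standard-error of a
  per-allele regression coefficient on a standardized trait.

Every generator is a pure function of the configuration's ``seed``;
independent seed streams keep the panel, cohorts and summaries mutually
consistent (they share the same underlying population frequencies and
true effects).

Optional knobs: correlated "tag" variants (allele-level copies of random
source variants with a configurable correlation) to exercise LD pruning
and tag-variant search, and a cross-population effect-size correlation
for concordance experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring_io import DosageMatrix, WeightTable

_NONAMBIGUOUS_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-ancestry study.

    Defaults emulate the evaluation setting of a trans-ancestry type 2
    diabetes score: three continental populations with realistic
    continental-scale divergence, population-specific disease prevalence
    of 10.0%, 12.5% and 13.7% (European-, African- and East-Asian-like),
    admixed samples at 13.1% (Hispanic/Latino-like), and a score
    explaining ~10% of liability variance.
    """

    n_populations: int = 3
    fst: Sequence[float] = (0.05, 0.15, 0.10)
    n_variants: int = 1000
    n_causal: int = 200
    liability_h2: float = 0.10
    prevalence: Sequence[float] = (0.100, 0.125, 0.137)
    n_samples: Sequence[int] = (1000, 1000, 1000)
    n_reference: Sequence[int] = (500, 500, 500)
    n_admixed: int = 0
    admixture_proportions: Sequence[float] = (0.5, 0.5)
    admixed_parents: Sequence[int] = (0, 1)
    admixed_prevalence: float = 0.131
    gwas_n: Sequence[int] = (898130, 23827, 177415)
    cross_pop_effect_corr: float = 1.0
    maf_range: tuple = (0.05, 0.5)
    n_tag_variants: int = 0
    tag_correlation: float = 0.8
    confound_site_with_population: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        P = self.n_populations
        for name in ("fst", "prevalence", "n_samples", "n_reference", "gwas_n"):
            if len(getattr(self, name)) != P:
                raise ValueError(f"{name} must have length n_populations={P}")
        if not all(0.0 < f < 1.0 for f in self.fst):
            raise ValueError("each FST must lie strictly in (0, 1)")
        if not all(0.0 < k < 1.0 for k in self.prevalence):
            raise ValueError("prevalence values must lie in (0, 1)")
        if not 0.0 <= self.liability_h2 < 1.0:
            raise ValueError("liability_h2 must lie in [0, 1)")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if abs(sum(self.admixture_proportions) - 1.0) > 1e-9:
            raise ValueError("admixture_proportions must sum to 1")
        if not 0.0 <= self.cross_pop_effect_corr <= 1.0:
            raise ValueError("cross_pop_effect_corr must lie in [0, 1]")

    @property
    def population_names(self) -> list[str]:
        return [f"pop{k}" for k in range(self.n_populations)]


@dataclass
class SyntheticCohort:
    """A generated evaluation cohort with full generative truth."""

    dosages: DosageMatrix
    status: np.ndarray
    covariates: pd.DataFrame
    population_label: np.ndarray
    true_weights: np.ndarray
    true_liability: np.ndarray


# ---------------------------------------------------------------------------
# Shared generative state (frequencies, effects, variant metadata)
# ---------------------------------------------------------------------------

def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _variant_table(config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config, 10)
    m = config.n_variants + config.n_tag_variants
    pairs = [_NONAMBIGUOUS_PAIRS[i]
             for i in rng.integers(0, len(_NONAMBIGUOUS_PAIRS), m)]
    return pd.DataFrame({
        "variant_id": [f"rs{j + 1}" for j in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "a1": [p[0] for p in pairs],
        "a2": [p[1] for p in pairs],
    })


def _tag_sources(config: SimulationConfig) -> np.ndarray:
    """Source index of each appended tag variant (deterministic)."""
    if config.n_tag_variants == 0:
        return np.empty(0, dtype=int)
    rng = _rng(config, 11)
    return rng.choice(config.n_variants, size=config.n_tag_variants,
                      replace=False)


def population_frequencies(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-population allele frequencies (Balding–Nichols).

    Returns ``(p_anc of shape (m,), freqs of shape (n_populations, m))``
    where ``m = n_variants + n_tag_variants``; a tag variant shares its
    source's frequencies.
    """
    rng = _rng(config, 0)
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, config.n_variants)
    freqs = np.empty((config.n_populations, config.n_variants))
    for k, F in enumerate(config.fst):
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        freqs[k] = rng.beta(a, b)
    srcs = _tag_sources(config)
    if len(srcs):
        p_anc = np.concatenate([p_anc, p_anc[srcs]])
        freqs = np.concatenate([freqs, freqs[:, srcs]], axis=1)
    return p_anc, freqs


def true_effects(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-population causal liability effects and the shared mean vector.

    Returns ``(per_pop of shape (n_populations, m), mean of shape (m,))``.
    Effects are nonzero on ``n_causal`` variants; across populations they
    correlate at ``cross_pop_effect_corr`` via a shared component.  Tag
    variants carry zero direct effect.
    """
    rng = _rng(config, 1)
    m = config.n_variants + config.n_tag_variants
    causal = rng.choice(config.n_variants, size=config.n_causal, replace=False)
    rho = config.cross_pop_effect_corr
    shared = rng.standard_normal(config.n_causal)
    per_pop = np.zeros((config.n_populations, m))
    for k in range(config.n_populations):
        own = rng.standard_normal(config.n_causal)
        per_pop[k, causal] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
    return per_pop, per_pop.mean(axis=0)


def _draw_genotypes(freq_row: np.ndarray, n: int, rng: np.random.Generator,
                    tag_sources: np.ndarray, tag_corr: float) -> np.ndarray:
    """Allele-level genotype draws; tag variants copy source alleles with
    probability ``tag_corr`` (giving dosage correlation ~= tag_corr)."""
    m = len(freq_row)
    alleles = (rng.random((n, m, 2)) < freq_row[None, :, None]).astype(float)
    n_base = m - len(tag_sources)
    for t, s in enumerate(tag_sources):
        j = n_base + t
        keep = rng.random((n, 2)) < tag_corr
        alleles[:, j, :] = np.where(keep, alleles[:, s, :], alleles[:, j, :])
    return alleles.sum(axis=2)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_reference_panel(
    config: SimulationConfig,
) -> tuple[DosageMatrix, np.ndarray]:
    """Generate a labeled multi-population reference panel.

    Stands in for an external labeled panel (e.g. a 1000 Genomes-style
    dataset) used for PCA, population assignment and score adjustment.
    """
    _, freqs = population_frequencies(config)
    rng = _rng(config, 2)
    srcs = _tag_sources(config)
    blocks, labels = [], []
    for k, n in enumerate(config.n_reference):
        blocks.append(_draw_genotypes(freqs[k], n, rng, srcs,
                                      config.tag_correlation))
        labels += [config.population_names[k]] * n
    dosages = np.concatenate(blocks, axis=0)
    sample_ids = np.array([f"ref{i + 1}" for i in range(len(labels))])
    dm = DosageMatrix(dosages, _variant_table(config), sample_ids)
    return dm, np.asarray(labels)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate an evaluation cohort under the liability-threshold model.

    Includes ``n_admixed`` two-way admixed samples (label ``"admixed"``)
    whose per-variant frequency is the admixture-weighted mixture of the
    parental population frequencies.
    """
    _, freqs = population_frequencies(config)
    per_pop_eff, mean_eff = true_effects(config)
    rng = _rng(config, 3)
    srcs = _tag_sources(config)

    blocks, labels, effs, prevs = [], [], [], []
    for k, n in enumerate(config.n_samples):
        blocks.append(_draw_genotypes(freqs[k], n, rng, srcs,
                                      config.tag_correlation))
        labels += [config.population_names[k]] * n
        effs.append(np.repeat(per_pop_eff[[k]], n, axis=0))
        prevs += [config.prevalence[k]] * n
    if config.n_admixed > 0:
        w = np.asarray(config.admixture_proportions)
        parents = list(config.admixed_parents)
        p_adm = w @ freqs[parents]
        blocks.append(_draw_genotypes(p_adm, config.n_admixed, rng, srcs,
                                      config.tag_correlation))
        labels += ["admixed"] * config.n_admixed
        adm_eff = w @ per_pop_eff[parents]
        effs.append(np.repeat(adm_eff[None, :], config.n_admixed, axis=0))
        prevs += [config.admixed_prevalence] * config.n_admixed

    dosages = np.concatenate(blocks, axis=0)
    labels = np.asarray(labels)
    prevs = np.asarray(prevs)
    eff = np.concatenate(effs, axis=0)
    n_total = len(labels)

    # within-population standardized genetic score -> liability
    g = (dosages * eff).sum(axis=1)
    h2 = config.liability_h2
    liability = np.empty(n_total)
    noise = rng.standard_normal(n_total)
    for lab in np.unique(labels):
        i = labels == lab
        sd = g[i].std()
        gs = (g[i] - g[i].mean()) / sd if sd > 0 else np.zeros(i.sum())
        liability[i] = np.sqrt(h2) * gs + np.sqrt(1.0 - h2) * noise[i]
    status = (liability > stats.norm.isf(prevs)).astype(int)

    site = (
        pd.factorize(labels)[0] % 3
        if config.confound_site_with_population
        else rng.integers(0, 3, n_total)
    )
    covariates = pd.DataFrame({
        "age": np.round(rng.normal(55.0, 10.0, n_total), 1),
        "sex": rng.integers(0, 2, n_total),
        "site": site,
    })
    sample_ids = np.array([f"s{i + 1}" for i in range(n_total)])
    dm = DosageMatrix(dosages, _variant_table(config), sample_ids)
    return SyntheticCohort(
        dosages=dm,
        status=status,
        covariates=covariates,
        population_label=labels,
        true_weights=mean_eff,
        true_liability=liability,
    )


def simulate_gwas_summary(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Per-population GWAS summary statistics with sampling noise.

    For each population the estimate is the population's true effect plus
    Normal noise with SE = 1/sqrt(2 N p (1-p)); the p-value is the Wald
    two-sided normal tail.  Monomorphic variants (undefined SE) are
    dropped with a recorded count in ``DataFrame.attrs['n_dropped']``.
    """
    _, freqs = population_frequencies(config)
    per_pop_eff, _ = true_effects(config)
    rng = _rng(config, 4)
    variants = _variant_table(config)
    out: dict[str, pd.DataFrame] = {}
    for k, name in enumerate(config.population_names):
        p = freqs[k]
        N = config.gwas_n[k]
        with np.errstate(divide="ignore"):
            se = 1.0 / np.sqrt(2.0 * N * p * (1.0 - p))
        ok = np.isfinite(se) & (p > 0.0) & (p < 1.0)
        beta = per_pop_eff[k] + rng.standard_normal(len(p)) * np.where(ok, se, 0.0)
        z = np.where(ok, beta / np.where(ok, se, 1.0), np.nan)
        pval = 2.0 * stats.norm.sf(np.abs(z))
        df = pd.DataFrame({
            "variant_id": variants["variant_id"],
            "chrom": variants["chrom"],
            "pos": variants["pos"],
            "effect_allele": variants["a1"],
            "other_allele": variants["a2"],
            "beta": beta,
            "se": se,
            "p": np.clip(pval, np.finfo(float).tiny, 1.0),
            "freq": p,
            "n": N,
        })[ok].reset_index(drop=True)
        df.attrs["n_dropped"] = int((~ok).sum())
        out[name] = df
    return out


def weight_table_from_effects(
    config: SimulationConfig, effects: np.ndarray | None = None
) -> WeightTable:
    """Package effect sizes as a WeightTable (effect allele = a1)."""
    variants = _variant_table(config)
    if effects is None:
        _, effects = true_effects(config)
    df = variants.rename(columns={"a1": "effect_allele", "a2": "other_allele"})
    df["weight"] = effects
    return WeightTable(df[["variant_id", "chrom", "pos", "effect_allele",
                           "other_allele", "weight"]])


def write_cohort(cohort: SyntheticCohort, outdir, prefix: str = "cohort") -> dict:
    """Write a cohort in the pipeline's input formats; returns the paths."""
    from pathlib import Path

    from . import scoring_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / f"{prefix}.vcf",
        "dosages": outdir / f"{prefix}.dosages.tsv",
        "variants": outdir / f"{prefix}.variants.tsv",
        "pheno": outdir / f"{prefix}.pheno.tsv",
    }
    scoring_io.write_vcf(cohort.dosages, paths["vcf"])
    scoring_io.write_dosage_tsv(cohort.dosages, paths["dosages"],
                                paths["variants"])
    pheno = cohort.covariates.copy()
    pheno.insert(0, "sample_id", cohort.dosages.sample_ids)
    pheno["status"] = cohort.status
    pheno["population"] = cohort.population_label
    pheno.to_csv(paths["pheno"], sep="\t", index=False)
    return paths
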