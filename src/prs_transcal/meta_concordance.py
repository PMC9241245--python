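"""Meta-analysis and cross-population effect-size concordance.

Summary statistics are plain pandas DataFrames with columns
``variant_id, chrom, pos, effect_allele, other_allele, beta, se, p,
freq, n`` (the schema written by the synthetic generator and accepted
from TSV).

Provides inverse-variance-weighted (IVW) combination of study estimates
(e.g. per-cohort tail log-ORs), per-variant fixed-effect meta-analysis
across population GWAS with allele harmonization, greedy extraction of
lead variants from genome-wide significant loci, LD tag-variant
substitution for leads absent from a dataset, and the Pearson
correlation of absolute effect sizes between populations at lead (or
tag) variants.

Heterogeneity statistics (Cochran's Q, I²) are reported for the IVW
combination but never used for filtering.  The locus window defaults to
500 kb each side of a lead variant and is configurable everywhere it
appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring_io import DosageMatrix

logger = logging.getLogger("prs_transcal")

LOCUS_WINDOW_BP = 500_000
GENOME_WIDE_P = 5e-8


@dataclass
class MetaResult:
    """Inverse-variance-weighted combined estimate."""

    estimate: float
    se: float
    p_value: float
    weights: np.ndarray          # normalized, sum to 1
    q_statistic: float = np.nan  # Cochran's Q (reported, not filtered on)
    i2: float = np.nan

    @property
    def ci95(self) -> tuple[float, float]:
        z = stats.norm.ppf(0.975)
        return (self.estimate - z * self.se, self.estimate + z * self.se)


@dataclass
class ConcordanceResult:
    """Cross-population correlation of absolute effect sizes."""

    r: float
    n_variants: int
    substitutions: list = field(default_factory=list)  # (lead, tag, pop)


def ivw_meta(estimates, ses) -> MetaResult:
    """Combine study estimates with weights 1/se²."""
    x = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(x) == 0:
        raise ValueError("need at least one study")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(s))):
        raise ValueError("non-finite estimate or SE")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s ** 2
    est = float(np.sum(w * x) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(est / se)))
    q = float(np.sum(w * (x - est) ** 2))
    dof = len(x) - 1
    i2 = float(max(0.0, (q - dof) / q)) if dof > 0 and q > 0 else 0.0
    return MetaResult(est, se, p, w / w.sum(), q, i2)


# ---------------------------------------------------------------------------
# Variant-level fixed-effect meta-analysis
# ---------------------------------------------------------------------------

def _keys(df: pd.DataFrame) -> pd.Series:
    pair = [
        "/".join(sorted((a, b)))
        for a, b in zip(df["effect_allele"], df["other_allele"])
    ]
    return (df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":"
            + pd.Series(pair, index=df.index))


def fixed_effect_meta(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-variant IVW meta-analysis across population summary tables.

    Variants are matched on (chrom, pos, unordered allele pair); a study
    whose effect allele is the canonical other allele has its beta
    negated and frequency complemented.  Variants present in a subset of
    studies are combined over the available ones; ``n_studies`` records
    how many.  Allele-pair mismatches at a shared locus key cannot occur
    by construction of the key; rows with non-positive SE are dropped
    with a logged count.
    """
    if len(tables) == 0:
        raise ValueError("need at least one summary table")
    canon: dict[str, dict] = {}
    n_bad_se = 0
    for t in tables:
        keys = _keys(t)
        for i, key in enumerate(keys):
            se = t["se"].iat[i]
            if not np.isfinite(se) or se <= 0:
                n_bad_se += 1
                continue
            row = canon.get(key)
            if row is None:
                row = canon[key] = {
                    "variant_id": t["variant_id"].iat[i],
                    "chrom": str(t["chrom"].iat[i]),
                    "pos": int(t["pos"].iat[i]),
                    "effect_allele": t["effect_allele"].iat[i],
                    "other_allele": t["other_allele"].iat[i],
                    "betas": [], "ses": [], "freqs": [], "ns": [],
                }
            flip = t["effect_allele"].iat[i] != row["effect_allele"]
            row["betas"].append(-t["beta"].iat[i] if flip else t["beta"].iat[i])
            row["freqs"].append(1.0 - t["freq"].iat[i] if flip
                                else t["freq"].iat[i])
            row["ses"].append(se)
            row["ns"].append(t["n"].iat[i])
    if n_bad_se:
        logger.info("fixed_effect_meta: dropped %d rows with invalid SE",
                    n_bad_se)
    out = []
    for row in canon.values():
        m = ivw_meta(row["betas"], row["ses"])
        out.append({
            "variant_id": row["variant_id"],
            "chrom": row["chrom"],
            "pos": row["pos"],
            "effect_allele": row["effect_allele"],
            "other_allele": row["other_allele"],
            "beta": m.estimate,
            "se": m.se,
            "p": m.p_value,
            "freq": float(np.mean(row["freqs"])),
            "n": int(np.sum(row["ns"])),
            "n_studies": len(row["betas"]),
        })
    df = pd.DataFrame(out).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return df


def extract_lead_variants(
    meta: pd.DataFrame,
    p_threshold: float = GENOME_WIDE_P,
    locus_window_bp: int = LOCUS_WINDOW_BP,
) -> pd.DataFrame:
    """Greedy lead-variant extraction from significant loci.

    Repeatedly take the smallest-p variant below the threshold, emit it,
    and remove every variant within ``locus_window_bp`` on the same
    chromosome; repeat until no significant variant remains.  The result
    does not depend on the input row order.
    """
    work = meta.sort_values(["p", "chrom", "pos"]).reset_index(drop=True)
    alive = np.ones(len(work), dtype=bool)
    chroms = work["chrom"].astype(str).to_numpy()
    pos = work["pos"].to_numpy()
    pvals = work["p"].to_numpy()
    leads = []
    for i in range(len(work)):
        if not alive[i] or pvals[i] >= p_threshold:
            continue
        leads.append(i)
        near = (chroms == chroms[i]) & (np.abs(pos - pos[i]) <= locus_window_bp)
        alive[near] = False
    if not leads:
        logger.info("extract_lead_variants: no variant below p=%g", p_threshold)
    return work.iloc[leads].sort_values(["chrom", "pos"]).reset_index(drop=True)


def find_tag_variant(
    lead: pd.Series,
    target_summary: pd.DataFrame,
    panel: DosageMatrix,
    r2_min: float = 0.6,
    locus_window_bp: int = LOCUS_WINDOW_BP,
) -> tuple[str, float] | None:
    """Best LD proxy for a lead variant absent from a target dataset.

    Among target-summary variants within the locus window, returns the
    ``(variant_id, r²)`` maximizing squared dosage correlation with the
    lead in ``panel``, provided r² >= ``r2_min``; otherwise None.  A lead
    that is monomorphic (or absent) in the panel yields None.
    """
    pv = panel.variants
    lead_idx = np.flatnonzero(pv["variant_id"].to_numpy() == lead["variant_id"])
    if len(lead_idx) == 0:
        logger.info("find_tag_variant: lead %s absent from LD panel",
                    lead["variant_id"])
        return None
    d_lead = panel.dosages[:, lead_idx[0]]
    if np.nanstd(d_lead) == 0:
        logger.info("find_tag_variant: lead %s monomorphic in panel",
                    lead["variant_id"])
        return None
    window = target_summary[
        (target_summary["chrom"].astype(str) == str(lead["chrom"]))
        & (np.abs(target_summary["pos"] - lead["pos"]) <= locus_window_bp)
        & (target_summary["variant_id"] != lead["variant_id"])
    ]
    best, best_r2 = None, -1.0
    panel_lookup = {vid: i for i, vid in enumerate(pv["variant_id"])}
    for vid in window["variant_id"]:
        i = panel_lookup.get(vid)
        if i is None:
            continue
        d = panel.dosages[:, i]
        if np.nanstd(d) == 0:
            continue
        r2 = float(np.corrcoef(d_lead, d)[0, 1] ** 2)
        if r2 > best_r2:
            best, best_r2 = vid, r2
    if best is None or best_r2 < r2_min:
        return None
    return best, best_r2


def effect_concordance(
    pop1: pd.DataFrame,
    pop2: pd.DataFrame,
    leads: pd.DataFrame,
    panel: DosageMatrix | None = None,
    r2_min: float = 0.6,
    locus_window_bp: int = LOCUS_WINDOW_BP,
) -> ConcordanceResult:
    """Pearson correlation of |beta| between two populations at lead
    variants, substituting LD tags (r² >= ``r2_min``) for leads missing
    from either table when a panel is supplied.
    """
    substitutions = []

    def lookup(table: pd.DataFrame, lead: pd.Series, pop: str):
        hit = table[table["variant_id"] == lead["variant_id"]]
        if len(hit):
            return abs(float(hit["beta"].iloc[0]))
        if panel is None:
            return None
        tag = find_tag_variant(lead, table, panel, r2_min, locus_window_bp)
        if tag is None:
            return None
        substitutions.append((lead["variant_id"], tag[0], pop))
        return abs(float(
            table.loc[table["variant_id"] == tag[0], "beta"].iloc[0]
        ))

    pairs = []
    for _, lead in leads.iterrows():
        b1 = lookup(pop1, lead, "pop1")
        b2 = lookup(pop2, lead, "pop2")
        if b1 is not None and b2 is not None:
            pairs.append((b1, b2))
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} lead/tag pairs shared; need >= 3")
    a = np.asarray(pairs)
    r, _ = stats.pearsonr(a[:, 0], a[:, 1])
    return ConcordanceResult(float(r), len(pairs), substitutions)
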