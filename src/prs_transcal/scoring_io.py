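"""Weight tables, dosage matrices, allele alignment and PRS computation.

A polygenic risk score (PRS) is the weighted sum of effect-allele dosages
across the variants of a scoring file.  This module reads scoring files
(PGS Catalog format or plain TSV), reads genotypes (VCF with GT/DS, or a
plain dosage TSV), harmonizes the effect allele of each weight with the
allele counted in the genotype data, and computes per-sample scores with
mean imputation of missing dosages.

Conventions
-----------
* Variants are keyed by ``(chrom, pos, unordered allele pair)``; positions
  are 1-based.  rsID matching is a fallback when positions are absent.
* When the scoring file's effect allele is the genotype's *other* allele,
  the effect-allele dosage is ``2 - d`` (the weight is kept as is).
* Strand-ambiguous SNPs (A/T and C/G pairs) are dropped by default because
  their orientation cannot be verified without strand metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("prs_transcal")

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

#: Column synonyms accepted in PGS Catalog scoring files.
PGS_COLUMNS = {
    "rsID": "variant_id",
    "chr_name": "chrom",
    "chr_position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "reference_allele": "other_allele",
    "effect_weight": "weight",
}


class FormatError(ValueError):
    """A required column or field is missing or malformed."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class WeightTable:
    """Per-variant effect alleles and weights defining a score.

    ``table`` has columns ``variant_id, chrom, pos, effect_allele,
    other_allele, weight``; ``n_dropped`` counts rows removed during
    loading (non-ACGT alleles or non-finite weights).
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        t = self.table
        bad = t["effect_allele"] == t["other_allele"]
        if bad.any():
            raise FormatError(
                f"effect_allele equals other_allele for {int(bad.sum())} rows"
            )
        key = _variant_keys(t)
        dup = key[key.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate variant keys: {sorted(set(dup))[:5]}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DosageMatrix:
    """Samples x variants effect-allele dosages with variant metadata.

    ``dosages`` is float with NaN marking missing entries; values are in
    [0, 2].  ``variants`` has columns ``variant_id, chrom, pos, a1, a2``
    where ``a1`` is the counted (dosage) allele.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(
                self.dosages, initial=0
            ) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_frequency(self) -> np.ndarray:
        """Counted-allele (a1) frequency per variant from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_variants(self, index: np.ndarray) -> "DosageMatrix":
        return DosageMatrix(
            self.dosages[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            self.sample_ids,
        )

    def subset_samples(self, index: np.ndarray) -> "DosageMatrix":
        return DosageMatrix(
            self.dosages[index, :], self.variants, self.sample_ids[index]
        )


@dataclass
class ScoreVector:
    """Raw per-sample PRS plus bookkeeping on variants used and imputed."""

    scores: pd.Series  # index: sample_id
    n_variants_used: int
    n_missing_imputed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError("scores must be finite")

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


@dataclass
class MatchedWeights:
    """Weights aligned to genotype variants.

    ``variant_index`` indexes into the DosageMatrix columns; ``flipped``
    marks variants where the effect allele is the genotype's a2, i.e. the
    effect dosage is ``2 - d``.
    """

    variant_index: np.ndarray
    weights: np.ndarray
    flipped: np.ndarray
    report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variant_index)


# ---------------------------------------------------------------------------
# Weight-table loading
# ---------------------------------------------------------------------------

def _variant_keys(df: pd.DataFrame, a1: str = "effect_allele",
                  a2: str = "other_allele") -> pd.Series:
    pair = [
        "/".join(sorted((x, y)))
        for x, y in zip(df[a1].astype(str), df[a2].astype(str))
    ]
    return (
        df["chrom"].astype(str) + ":" + df["pos"].astype("Int64").astype(str)
        + ":" + pd.Series(pair, index=df.index)
    )


def load_weights(path, format: str = "pgs_catalog") -> WeightTable:
    """Load a scoring file into a :class:`WeightTable`.

    ``pgs_catalog`` expects the PGS Catalog header vocabulary
    (``rsID/chr_name/chr_position/effect_allele/other_allele/effect_weight``,
    ``#``-prefixed metadata lines allowed); ``tsv`` expects the internal
    column names directly.  Rows with non-ACGT alleles or non-finite
    weights are dropped and counted in ``n_dropped``.
    """
    if format not in ("pgs_catalog", "tsv"):
        raise ValueError(f"unknown weight format {format!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chr_name": str, "chrom": str})
    if format == "pgs_catalog":
        df = df.rename(columns=PGS_COLUMNS)
    required = ["chrom", "pos", "effect_allele", "other_allele", "weight"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"scoring file missing mandatory column(s): {missing}")
    if "variant_id" not in df.columns:
        df["variant_id"] = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    df = df[["variant_id"] + required].copy()
    df["weight"] = pd.to_numeric(df["weight"], errors="coerce")
    ok = (
        df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & np.isfinite(df["weight"])
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("load_weights: dropped %d malformed rows", n_dropped)
    df = df[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    return WeightTable(df, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Allele alignment and scoring
# ---------------------------------------------------------------------------

def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in _AMBIGUOUS_PAIRS


def align_alleles(
    weights: WeightTable,
    genotypes: DosageMatrix,
    ambiguous_policy: str = "drop",
) -> MatchedWeights:
    """Harmonize weight-table effect alleles with genotype counted alleles.

    Exact (effect, other) == (a1, a2) matches keep the weight; swapped
    matches flag the variant so that scoring uses dosage ``2 - d``;
    allele-pair mismatches are dropped.  Strand-ambiguous variants follow
    ``ambiguous_policy`` ('drop' or 'keep').  Raises if nothing matches.
    """
    if ambiguous_policy not in ("drop", "keep"):
        raise ValueError(f"ambiguous_policy must be 'drop' or 'keep'")
    gv = genotypes.variants
    gkey = _variant_keys(gv, "a1", "a2")
    glookup = {k: i for i, k in enumerate(gkey)}
    wt = weights.table

    idx, w_out, flip = [], [], []
    report = {"matched": 0, "flipped": 0, "mismatch": 0,
              "ambiguous_dropped": 0, "absent": 0}
    wkeys = _variant_keys(wt)
    for j, key in enumerate(wkeys):
        gi = glookup.get(key)
        if gi is None:
            # allele-pair mismatch at same locus vs truly absent
            locus = key.rsplit(":", 1)[0]
            same_locus = any(k.startswith(locus + ":") for k in glookup)
            report["mismatch" if same_locus else "absent"] += 1
            continue
        ea, oa = wt["effect_allele"].iat[j], wt["other_allele"].iat[j]
        if _is_ambiguous(ea, oa) and ambiguous_policy == "drop":
            report["ambiguous_dropped"] += 1
            continue
        a1 = gv["a1"].iat[gi]
        flipped = ea != a1
        idx.append(gi)
        w_out.append(wt["weight"].iat[j])
        flip.append(flipped)
        report["matched"] += 1
        report["flipped"] += int(flipped)
    if not idx:
        raise ValueError(f"no weight-table variants matched genotypes ({report})")
    logger.info("align_alleles: %s", report)
    return MatchedWeights(
        np.asarray(idx, dtype=int),
        np.asarray(w_out, dtype=float),
        np.asarray(flip, dtype=bool),
        report,
    )


def compute_prs(
    genotypes: DosageMatrix,
    matched: MatchedWeights,
    mean_impute: bool = True,
) -> ScoreVector:
    """Score samples: ``score_i = sum_j w_j * d_ij`` over matched variants.

    Missing dosages are imputed as twice the effect-allele frequency
    (estimated from non-missing samples) unless ``mean_impute`` is False,
    in which case they contribute zero.  A variant that is missing in all
    samples cannot be imputed and raises.
    """
    d = genotypes.dosages[:, matched.variant_index].copy()
    d[:, matched.flipped] = 2.0 - d[:, matched.flipped]
    miss = np.isnan(d)
    n_missing = int(miss.sum())
    if n_missing:
        if mean_impute:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                eaf = np.nanmean(d, axis=0) / 2.0
            if np.isnan(eaf).any():
                bad = genotypes.variants["variant_id"].iloc[
                    matched.variant_index[np.isnan(eaf)]
                ].tolist()
                raise ValueError(
                    f"cannot impute variants missing in all samples: {bad[:5]}"
                )
            d = np.where(miss, (2.0 * eaf)[None, :], d)
        else:
            d = np.where(miss, 0.0, d)
            n_missing = 0
    scores = d @ matched.weights
    return ScoreVector(
        pd.Series(scores, index=pd.Index(genotypes.sample_ids, name="sample_id")),
        n_variants_used=len(matched),
        n_missing_imputed=n_missing,
    )


def score_pipeline(
    weights: WeightTable, genotypes: DosageMatrix, **kwargs
) -> ScoreVector:
    """Convenience wrapper: align alleles then compute the PRS."""
    return compute_prs(genotypes, align_alleles(weights, genotypes), **kwargs)


def filter_maf(
    genotypes: DosageMatrix,
    threshold: float = 0.01,
    groups: np.ndarray | None = None,
) -> DosageMatrix:
    """Remove variants with minor allele frequency below ``threshold``.

    With ``groups`` (per-sample population labels), the MAF filter is
    applied within each group and a variant is removed if it fails in any
    group — matching per-population QC of multi-ancestry cohorts.
    """
    if not 0 <= threshold < 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5), got {threshold}")
    if groups is None:
        freqs = [genotypes.allele_frequency()]
    else:
        groups = np.asarray(groups)
        freqs = [
            genotypes.subset_samples(np.flatnonzero(groups == g)).allele_frequency()
            for g in np.unique(groups)
        ]
    keep = np.ones(genotypes.n_variants, dtype=bool)
    for f in freqs:
        maf = np.minimum(f, 1.0 - f)
        keep &= maf >= threshold
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_maf: removed %d variants below MAF %g",
                    n_removed, threshold)
    return genotypes.subset_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Genotype readers / writers
# ---------------------------------------------------------------------------

def read_vcf(path) -> DosageMatrix:
    """Read genotypes from a VCF into a :class:`DosageMatrix`.

    The DS (dosage) FORMAT field is used when present; otherwise dosage is
    the GT alternate-allele count.  The counted allele (a1) is ALT.
    Multi-allelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    rows, meta = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ds = rec.format("DS")
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d[d < 0] = np.nan  # cyvcf2 encodes missing as negative sentinel
        else:
            gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            d = gt.sum(axis=1)
        rows.append(d)
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS,
                     rec.ALT[0], rec.REF))
    if n_multi:
        logger.info("read_vcf: skipped %d multi-allelic records", n_multi)
    variants = pd.DataFrame(meta, columns=["variant_id", "chrom", "pos", "a1", "a2"])
    dosages = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return DosageMatrix(dosages, variants, samples)


def write_vcf(genotypes: DosageMatrix, path) -> None:
    """Write a minimal VCF (DS FORMAT field) for a dosage matrix."""
    v, d = genotypes.variants, genotypes.dosages
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        chroms = v["chrom"].astype(str).unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genotypes.sample_ids)) + "\n")
        for j in range(len(v)):
            vals = ["." if np.isnan(x) else f"{x:g}" for x in d[:, j]]
            fh.write(
                f"{v['chrom'].iat[j]}\t{v['pos'].iat[j]}\t{v['variant_id'].iat[j]}"
                f"\t{v['a2'].iat[j]}\t{v['a1'].iat[j]}\t.\t.\t.\tDS\t"
                + "\t".join(vals) + "\n"
            )


def read_dosage_tsv(path, variants_path=None) -> DosageMatrix:
    """Read a samples x variants dosage TSV (first column sample_id).

    ``variants_path`` optionally supplies variant metadata columns
    ``variant_id, chrom, pos, a1, a2``; without it, placeholder metadata
    is constructed from the header variant IDs.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if variants_path is not None:
        variants = pd.read_csv(
            variants_path, sep="\t", dtype={"chrom": str, "a1": str, "a2": str}
        )
        variants = variants.set_index("variant_id").loc[df.columns].reset_index()
    else:
        variants = pd.DataFrame({
            "variant_id": df.columns,
            "chrom": "0",
            "pos": np.arange(1, df.shape[1] + 1),
            "a1": "A",
            "a2": "G",
        })
    return DosageMatrix(df.to_numpy(dtype=float), variants,
                        df.index.to_numpy(dtype=str))


def write_dosage_tsv(genotypes: DosageMatrix, path, variants_path=None) -> None:
    pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
        columns=genotypes.variants["variant_id"],
    ).to_csv(path, sep="\t")
    if variants_path is not None:
        genotypes.variants.to_csv(variants_path, sep="\t", index=False)


def write_weights_pgs(weights: WeightTable, path) -> None:
    """Write a weight table in PGS Catalog scoring-file format."""
    out = weights.table[
        ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "weight"]
    ].copy()
    out.columns = ["rsID", "chr_name", "chr_position", "effect_allele",
                   "other_allele", "effect_weight"]
    out.to_csv(path, sep="\t", index=False)
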