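"""Reference-panel PCA ancestry inference.

Implements the ancestry workflow used when evaluating a score in a
multi-ancestry cohort: greedy windowed LD pruning, PCA of a labeled
reference panel with allele-frequency standardization, projection of
target samples into the reference PC space, and probabilistic population
assignment with an abstention threshold.

Numerical conventions
---------------------
* Variants are standardized by mean ``2p`` and scale ``sqrt(2p(1-p))``
  with ``p`` the reference counted-allele frequency; missing dosages (and
  model variants absent from a target dataset) contribute the
  standardized mean, i.e. zero.
* PC signs are fixed deterministically: the largest-magnitude loading of
  each component is made positive, so downstream regression coefficients
  are reproducible across runs.
* The default assignment model is a Gaussian class-conditional classifier
  (quadratic discriminant) on the top PCs; a sample is labeled only when
  its maximum posterior probability exceeds the threshold, otherwise it
  is "unassigned".
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring_io import DosageMatrix, _variant_keys

logger = logging.getLogger("prs_transcal")

UNASSIGNED = "unassigned"


@dataclass
class PCModel:
    """Reference-panel PCA enabling projection of new samples."""

    variants: pd.DataFrame        # variant_id, chrom, pos, a1, a2
    mean: np.ndarray              # 2p per variant
    scale: np.ndarray             # sqrt(2p(1-p)) per variant
    loadings: np.ndarray          # (n_variants, K_pc)
    ref_scores: np.ndarray        # (n_reference, K_pc)
    ref_labels: np.ndarray
    n_excluded_zero_variance: int = 0

    @property
    def k_pc(self) -> int:
        return self.loadings.shape[1]

    @property
    def fingerprint(self) -> str:
        """Stable digest of the PC space (variants + loadings)."""
        h = hashlib.sha256()
        h.update("".join(self.variants["variant_id"]).encode())
        h.update(np.round(self.loadings, 10).tobytes())
        return h.hexdigest()[:16]

    def save(self, path) -> None:
        payload = {
            "variants": self.variants.to_dict(orient="list"),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "ref_scores": self.ref_scores.tolist(),
            "ref_labels": self.ref_labels.tolist(),
            "n_excluded_zero_variance": self.n_excluded_zero_variance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PCModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            variants=pd.DataFrame(d["variants"]),
            mean=np.asarray(d["mean"]),
            scale=np.asarray(d["scale"]),
            loadings=np.asarray(d["loadings"]),
            ref_scores=np.asarray(d["ref_scores"]),
            ref_labels=np.asarray(d["ref_labels"]),
            n_excluded_zero_variance=d["n_excluded_zero_variance"],
        )


@dataclass
class AncestryCoordinates:
    """Per-sample PC coordinates with (optional) population assignment."""

    sample_ids: np.ndarray
    pcs: np.ndarray                       # (n_samples, K)
    labels: np.ndarray = None             # populated by assign_population
    probabilities: np.ndarray = None
    model_fingerprint: str | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.labels is None:
            self.labels = np.full(n, UNASSIGNED, dtype=object)
        if self.probabilities is None:
            self.probabilities = np.full(n, np.nan)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.pcs,
            columns=[f"PC{k + 1}" for k in range(self.pcs.shape[1])],
            index=pd.Index(self.sample_ids, name="sample_id"),
        )
        df["label"] = self.labels
        df["probability"] = self.probabilities
        return df


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _mean_imputed(d: np.ndarray) -> np.ndarray:
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), col_mean[None, :], d)
    return d


def ld_prune(
    genotypes: DosageMatrix,
    window: int = 500,
    step: int = 50,
    r2_max: float = 0.05,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns kept variant indices in
    position order.

    Within each window of ``window`` variants (advanced by ``step``,
    restarted per chromosome), while any surviving pair has squared
    Pearson dosage correlation exceeding ``r2_max``, the member of the
    worst pair with the lower MAF is removed (ties remove the variant at
    the later position).  Sample order does not affect the result.
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    if not 0.0 < r2_max < 1.0:
        raise ValueError("r2_max must lie in (0, 1)")
    m = genotypes.n_variants
    if m < 2:
        warnings.warn("fewer than 2 variants: nothing to prune")
        return np.arange(m)

    v = genotypes.variants
    order = np.lexsort((v["pos"].to_numpy(), v["chrom"].astype(str).to_numpy()))
    freq = genotypes.allele_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    d = _mean_imputed(genotypes.dosages)
    keep = np.ones(m, dtype=bool)

    for chrom in v["chrom"].astype(str).unique():
        chrom_idx = order[v["chrom"].astype(str).to_numpy()[order] == chrom]
        for start in range(0, len(chrom_idx), step):
            win = chrom_idx[start:start + window]
            while True:
                live = win[keep[win]]
                if len(live) < 2:
                    break
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.corrcoef(d[:, live], rowvar=False)
                r2 = np.nan_to_num(r ** 2, nan=0.0)
                np.fill_diagonal(r2, 0.0)
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_max:
                    break
                a, b = live[i], live[j]
                if maf[a] < maf[b]:
                    drop = a
                elif maf[b] < maf[a]:
                    drop = b
                else:  # tie -> later position
                    drop = a if v["pos"].iat[a] > v["pos"].iat[b] else b
                keep[drop] = False
            if start + window >= len(chrom_idx):
                break
    kept = order[keep[order]]
    logger.info("ld_prune: kept %d of %d variants", len(kept), m)
    return np.sort(kept)


# ---------------------------------------------------------------------------
# PCA fit / project / assign
# ---------------------------------------------------------------------------

def fit_pca(
    reference: DosageMatrix,
    k_pc: int = 10,
    ref_labels: np.ndarray | None = None,
) -> PCModel:
    """Fit reference-panel PCA on (pruned, MAF-filtered) dosages.

    Variants are standardized by 2p and sqrt(2p(1-p)); zero-variance
    variants are excluded with a count; missing dosages are mean-imputed.
    """
    p = reference.allele_frequency()
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("fit_pca: excluded %d zero-variance variants", n_excluded)
    d = _mean_imputed(reference.dosages[:, ok])
    mean = 2.0 * p[ok]
    z = (d - mean[None, :]) / scale[ok][None, :]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum())
    if k_pc >= rank:
        raise ValueError(f"k_pc={k_pc} must be below matrix rank {rank}")
    loadings = vt[:k_pc].T
    scores = u[:, :k_pc] * s[:k_pc]
    # deterministic sign: largest-magnitude loading positive
    for k in range(k_pc):
        jmax = np.argmax(np.abs(loadings[:, k]))
        if loadings[jmax, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    if ref_labels is None:
        ref_labels = np.full(reference.n_samples, "reference", dtype=object)
    return PCModel(
        variants=reference.variants.iloc[np.flatnonzero(ok)].reset_index(drop=True),
        mean=mean,
        scale=scale[ok],
        loadings=loadings,
        ref_scores=scores,
        ref_labels=np.asarray(ref_labels),
        n_excluded_zero_variance=n_excluded,
    )


def project(
    model: PCModel,
    genotypes: DosageMatrix,
    min_overlap: float = 0.5,
) -> AncestryCoordinates:
    """Project target samples into the reference PC space.

    Model variants are matched to targets on (chrom, pos, allele pair);
    swapped counted alleles use dosage 2-d.  Absent model variants and
    missing dosages contribute the standardized mean (zero).  Raises when
    fewer than ``min_overlap`` of the model variants are found.
    """
    gkeys = _variant_keys(genotypes.variants, "a1", "a2")
    glookup = {k: i for i, k in enumerate(gkeys)}
    mkeys = _variant_keys(model.variants, "a1", "a2")
    m = len(model.variants)
    z = np.zeros((genotypes.n_samples, m))
    n_matched = 0
    for j, key in enumerate(mkeys):
        gi = glookup.get(key)
        if gi is None:
            continue
        n_matched += 1
        d = genotypes.dosages[:, gi]
        if genotypes.variants["a1"].iat[gi] != model.variants["a1"].iat[j]:
            d = 2.0 - d
        zj = (d - model.mean[j]) / model.scale[j]
        z[:, j] = np.where(np.isnan(zj), 0.0, zj)
    overlap = n_matched / m
    if overlap < min_overlap:
        raise ValueError(
            f"only {overlap:.1%} of model variants present in target "
            f"(minimum {min_overlap:.0%})"
        )
    return AncestryCoordinates(
        sample_ids=genotypes.sample_ids,
        pcs=z @ model.loadings,
        model_fingerprint=model.fingerprint,
    )


def assign_population(
    coords: AncestryCoordinates,
    model: PCModel,
    n_pcs: int = 6,
    prob_threshold: float = 0.8,
    classifier: str = "extra_trees",
) -> AncestryCoordinates:
    """Assign each sample a reference population or "unassigned".

    The default classifier is a seeded extremely-randomized tree ensemble
    on the top PCs: its class probabilities (vote fractions) decay
    smoothly across the empty PC-space between reference clusters, so
    admixed or intermediate samples fall below the threshold and abstain,
    while samples inside a reference cluster are assigned with
    probability near 1.  ``classifier="gaussian"`` selects a Gaussian
    class-conditional model instead; its likelihood-ratio posteriors are
    sharp even between clusters, so it abstains far less on admixed
    samples.  Both are deterministic.
    """
    if n_pcs > model.k_pc:
        raise ValueError(f"n_pcs={n_pcs} exceeds model K_pc={model.k_pc}")
    if classifier == "extra_trees":
        from sklearn.ensemble import ExtraTreesClassifier

        clf = ExtraTreesClassifier(n_estimators=500, random_state=0)
    elif classifier == "gaussian":
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        clf = QuadraticDiscriminantAnalysis(reg_param=1e-6)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    clf.fit(model.ref_scores[:, :n_pcs], model.ref_labels)
    prob = clf.predict_proba(coords.pcs[:, :n_pcs])
    best = prob.argmax(axis=1)
    best_p = prob[np.arange(len(best)), best]
    labels = np.asarray(clf.classes_)[best].astype(object)
    labels[~(best_p > prob_threshold)] = UNASSIGNED
    return AncestryCoordinates(
        sample_ids=coords.sample_ids,
        pcs=coords.pcs,
        labels=labels,
        probabilities=best_p,
        model_fingerprint=coords.model_fingerprint,
    )
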