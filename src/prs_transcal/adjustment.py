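"""Post hoc ancestry adjustment of polygenic scores.

Raw polygenic scores have population-specific means and variances driven
by allele-frequency differences, so a single clinical cutoff cannot be
applied across ancestries.  The adjustment models both moments as linear
functions of the top principal components of a labeled reference panel:

    PRS   ~ alpha_0 + sum_k alpha_k * PC_k        (mean regression)
    delta ~ beta_0  + sum_k beta_k  * PC_k        (variance regression)

where ``delta`` is the per-sample squared residual of the mean
regression.  Any individual projected into the same PC space is then
standardized as

    PRS_adj = (PRS_raw - fitted mean) / sqrt(fitted variance).

Both regressions are ordinary least squares; the default number of PCs
is five.  Fitted variances can be negative for extreme PC
coordinates, so they are floored at a small positive value (default
1e-6 times the variance of the reference scores) and floored samples are
flagged.  Scores are fitted raw (not centered or scaled); the convention
is recorded in the saved model file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry import AncestryCoordinates
from .scoring_io import ScoreVector

logger = logging.getLogger("prs_transcal")


@dataclass
class AdjustmentModel:
    """Coefficients of the mean and variance regressions on top PCs."""

    alpha: np.ndarray          # (n_pcs + 1,): intercept first
    beta: np.ndarray           # (n_pcs + 1,)
    n_pcs: int = 5
    variance_floor: float = 1e-12
    fingerprint: str | None = None
    n_floored_fit: int = 0

    def fitted_mean(self, pcs: np.ndarray) -> np.ndarray:
        return self.alpha[0] + pcs[:, : self.n_pcs] @ self.alpha[1:]

    def fitted_variance(self, pcs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Floored fitted variance and the floored-sample mask."""
        v = self.beta[0] + pcs[:, : self.n_pcs] @ self.beta[1:]
        floored = v < self.variance_floor
        return np.where(floored, self.variance_floor, v), floored

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "alpha": self.alpha.tolist(),
                "beta": self.beta.tolist(),
                "n_pcs": self.n_pcs,
                "variance_floor": self.variance_floor,
                "fingerprint": self.fingerprint,
                "n_floored_fit": self.n_floored_fit,
                "score_convention": "raw (uncentered, unscaled) reference scores",
            }, fh, indent=1)

    @classmethod
    def load(cls, path) -> "AdjustmentModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            alpha=np.asarray(d["alpha"]),
            beta=np.asarray(d["beta"]),
            n_pcs=d["n_pcs"],
            variance_floor=d["variance_floor"],
            fingerprint=d.get("fingerprint"),
            n_floored_fit=d.get("n_floored_fit", 0),
        )


@dataclass
class AdjustedScores:
    """Ancestry-adjusted scores with flags for variance-floored samples."""

    scores: pd.Series
    floored: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


def _as_scores(raw) -> np.ndarray:
    return raw.values if isinstance(raw, ScoreVector) else np.asarray(raw, float)


def _as_pcs(pcs) -> np.ndarray:
    return pcs.pcs if isinstance(pcs, AncestryCoordinates) else np.asarray(pcs, float)


def fit_adjustment(
    reference_scores,
    reference_pcs,
    n_pcs: int = 5,
    variance_floor: float | None = None,
) -> AdjustmentModel:
    """Fit the mean and variance regressions on a scored reference panel.

    ``reference_scores`` and ``reference_pcs`` must cover the same
    samples in the same order.  ``variance_floor`` defaults to 1e-6 times
    the variance of the reference scores.
    """
    y = _as_scores(reference_scores)
    pcs = _as_pcs(reference_pcs)
    if len(y) != len(pcs):
        raise ValueError("scores and PCs cover different numbers of samples")
    if len(y) < n_pcs + 2:
        raise ValueError(f"need at least {n_pcs + 2} reference samples")
    if pcs.shape[1] < n_pcs:
        raise ValueError(f"PC matrix has {pcs.shape[1]} columns, need {n_pcs}")
    if np.var(y) == 0:
        raise ValueError("constant reference scores: variance regression degenerate")

    x = np.column_stack([np.ones(len(y)), pcs[:, :n_pcs]])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient PC design matrix")
    alpha, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ alpha
    delta = resid ** 2
    beta, *_ = np.linalg.lstsq(x, delta, rcond=None)

    if variance_floor is None:
        variance_floor = 1e-6 * float(np.var(y))
    fitted_var = x @ beta
    n_floored = int((fitted_var < variance_floor).sum())
    if n_floored:
        logger.info("fit_adjustment: floored fitted variance for %d reference "
                    "samples", n_floored)
    fingerprint = getattr(reference_pcs, "model_fingerprint", None)
    return AdjustmentModel(
        alpha=alpha, beta=beta, n_pcs=n_pcs,
        variance_floor=float(variance_floor),
        fingerprint=fingerprint, n_floored_fit=n_floored,
    )


def adjust(model: AdjustmentModel, raw, pcs) -> AdjustedScores:
    """Standardize raw scores by PC-predicted mean and variance.

    The PCs must come from the same PC space the model was fitted in;
    when both carry a PC-model fingerprint the match is enforced.
    """
    fp = getattr(pcs, "model_fingerprint", None)
    if model.fingerprint is not None and fp is not None and fp != model.fingerprint:
        raise ValueError(
            "PC-space fingerprint mismatch between adjustment model and "
            "coordinates: scores would be standardized in the wrong space"
        )
    y = _as_scores(raw)
    p = _as_pcs(pcs)
    if not np.all(np.isfinite(p[:, : model.n_pcs])):
        raise ValueError("non-finite PC coordinates")
    if len(y) != len(p):
        raise ValueError("scores and PCs cover different numbers of samples")
    mu = model.fitted_mean(p)
    var, floored = model.fitted_variance(p)
    adjusted = (y - mu) / np.sqrt(var)
    index = (raw.scores.index if isinstance(raw, ScoreVector)
             else pd.RangeIndex(len(y)))
    return AdjustedScores(pd.Series(adjusted, index=index, name="prs_adj"),
                          floored)
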