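"""Predictive-performance metrics for case-control polygenic scores.

Implements the full evaluation suite used for a disease PRS in a
case-control cohort:

* liability-scale R² with ascertainment correction (population
  prevalence K, sample case fraction P),
* four AUCs (covariates-only, PRS-only, covariate-adjusted PRS,
  PRS + covariates combined),
* odds ratio per standard deviation of the score from covariate-adjusted
  logistic regression,
* tail discrimination: OR / sensitivity / specificity and
  prevalence-adjusted PPV/NPV for the top 2/5/10% of the score
  distribution,
* decile calibration of predicted versus observed risk.

The liability-scale transformation multiplies the incremental
observed-scale (linear 0/1) R² by

    C = K^2 (1-K)^2 / (z^2 P (1-P)),

with ``z`` the standard-normal density at the liability threshold
``Phi^{-1}(1-K)`` — the standard ascertainment-corrected conversion for
case-control data.  Prevalence-adjusted predictive values follow

    PPV = sens*prev / [sens*prev + (1-spec)(1-prev)]
    NPV = spec*(1-prev) / [spec*(1-prev) + (1-sens)*prev].

Wald 95% intervals are reported throughout, matching the symmetric
intervals conventionally printed for ORs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("prs_transcal")

#: Population-specific prevalence of diagnosed type 2 diabetes used for
#: prevalence-adjusted PPV/NPV (overridable; see data/prevalence.yaml).
DEFAULT_PREVALENCE = {
    "european": 0.100,
    "african": 0.125,
    "hispanic": 0.131,
    "asian": 0.137,
}

Z95 = stats.norm.ppf(0.975)


def load_prevalence_registry(path=None) -> dict[str, float]:
    """Load the population->prevalence registry (packaged default file)."""
    import yaml
    from importlib import resources

    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("prs_transcal").joinpath("data/prevalence.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass
class EvaluationInput:
    """Status, score, covariates and assumed population prevalence."""

    status: np.ndarray
    score: np.ndarray
    covariates: pd.DataFrame | None = None
    prevalence: float = 0.10

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int)
        self.score = np.asarray(self.score, dtype=float)
        if len(self.status) != len(self.score):
            raise ValueError("status and score lengths differ")
        if np.isnan(self.status).any():
            raise ValueError("missing status not allowed")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")

    def covariate_matrix(self) -> np.ndarray:
        """Covariates as a float matrix with constant columns dropped."""
        if self.covariates is None or self.covariates.shape[1] == 0:
            return np.empty((len(self.status), 0))
        x = pd.get_dummies(self.covariates, drop_first=True).to_numpy(float)
        keep = x.std(axis=0) > 0
        return x[:, keep]


@dataclass
class LogisticFit:
    params: np.ndarray        # intercept first
    bse: np.ndarray
    fitted: np.ndarray
    converged: bool
    separation_flag: bool


@dataclass
class TailMetrics:
    cutoff_percent: float
    n_top: int
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    sensitivity: float
    specificity: float
    adjusted_ppv: float
    adjusted_npv: float
    unstable: bool = False


@dataclass
class MetricsReport:
    """Per-cohort performance statistics in the layout of a results table."""

    n_samples: int
    n_cases: int
    prevalence: float
    liability_r2: float
    auc_covariates_only: float
    auc_prs_only: float
    auc_prs_covariate_adjusted: float
    auc_combined: float
    or_per_sd: float
    or_per_sd_ci: tuple
    tail: list[TailMetrics] = field(default_factory=list)
    calibration: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.calibration is not None:
            d["calibration"] = self.calibration.to_dict(orient="list")
        return d


# ---------------------------------------------------------------------------
# Core fits
# ---------------------------------------------------------------------------

def logistic_fit(status: np.ndarray, predictors: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald standard errors.

    Raises when only one class is present; quasi-separation (diverging
    coefficients) is flagged rather than raised so callers can mark the
    interval unreliable.
    """
    status = np.asarray(status, dtype=float)
    if len(np.unique(status)) < 2:
        raise ValueError("both classes must be present")
    x = sm.add_constant(np.asarray(predictors, dtype=float), has_constant="add")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("predictor matrix is rank deficient")
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation is flagged, not raised
        try:
            res = sm.Logit(status, x).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # perfect separation raises inside statsmodels
            res = sm.Logit(status, x).fit_regularized(disp=0, alpha=1e-8)
            converged = False
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(getattr(res, "bse", np.full_like(params, np.nan)), float)
    separation = (not converged) or bool(np.any(np.abs(params) > 15))
    if separation:
        logger.warning("logistic_fit: possible separation; CIs unreliable")
    fitted = 1.0 / (1.0 + np.exp(-(x @ params)))
    return LogisticFit(params, bse, fitted, converged, separation)


def or_per_sd(inp: EvaluationInput) -> tuple[float, tuple[float, float]]:
    """Odds ratio per SD of the score, adjusting for the covariates."""
    sd = inp.score.std()
    if sd == 0:
        raise ValueError("constant score has zero SD")
    z = (inp.score - inp.score.mean()) / sd
    fit = logistic_fit(inp.status, np.column_stack([z, inp.covariate_matrix()]))
    b, se = fit.params[1], fit.bse[1]
    return float(np.exp(b)), (float(np.exp(b - Z95 * se)),
                              float(np.exp(b + Z95 * se)))


def auc(status: np.ndarray, score: np.ndarray) -> float:
    """Concordance probability (rank-statistic AUC), ties counted half."""
    status = np.asarray(status, dtype=int)
    score = np.asarray(score, dtype=float)
    n1 = int(status.sum())
    n0 = len(status) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(score)
    return float((ranks[status == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_suite(inp: EvaluationInput) -> dict[str, float]:
    """The four AUCs: covariates-only, PRS-only, covariate-adjusted PRS,
    and PRS combined with covariates.

    The covariate-adjusted AUC uses the score residualized on the
    covariates by least squares; with constant (or no) covariates it
    equals the PRS-only AUC exactly.
    """
    cov = inp.covariate_matrix()
    out = {"auc_prs_only": auc(inp.status, inp.score)}
    xc = np.column_stack([np.ones(len(inp.status)), cov])
    coef, *_ = np.linalg.lstsq(xc, inp.score, rcond=None)
    out["auc_prs_covariate_adjusted"] = auc(inp.status, inp.score - xc @ coef)
    if cov.shape[1] == 0:
        out["auc_covariates_only"] = 0.5
        out["auc_combined"] = out["auc_prs_only"]
        return out
    out["auc_covariates_only"] = auc(inp.status, logistic_fit(inp.status, cov).fitted)
    joint = logistic_fit(inp.status, np.column_stack([inp.score, cov]))
    out["auc_combined"] = auc(inp.status, joint.fitted)
    return out


def _incremental_r2(status, score, cov) -> float:
    """Observed-scale (linear 0/1) R² of the score over the covariates."""
    y = status - status.mean()
    sst = float(y @ y)
    xc = np.column_stack([np.ones(len(y)), cov])
    rc = y - xc @ np.linalg.lstsq(xc, y, rcond=None)[0]
    xf = np.column_stack([xc, score])
    rf = y - xf @ np.linalg.lstsq(xf, y, rcond=None)[0]
    return float((rc @ rc - rf @ rf) / sst)


def liability_r2(inp: EvaluationInput) -> float:
    """Liability-scale variance explained by the score over the covariates.

    The incremental observed-scale R² is multiplied by the
    ascertainment-corrected factor C = K²(1-K)² / (z² P(1-P)).
    """
    k = inp.prevalence
    p_case = inp.status.mean()
    if not 0.0 < p_case < 1.0:
        raise ValueError("sample case fraction must lie strictly in (0, 1)")
    r2_obs = _incremental_r2(inp.status, inp.score, inp.covariate_matrix())
    z = stats.norm.pdf(stats.norm.isf(k))
    c = (k ** 2 * (1 - k) ** 2) / (z ** 2 * p_case * (1 - p_case))
    return float(np.clip(r2_obs * c, 0.0, 1.0))


def liability_factor(k: float, p_case: float) -> float:
    """The conversion factor C = K²(1-K)² / (z² P(1-P))."""
    if not (0.0 < k < 1.0 and 0.0 < p_case < 1.0):
        raise ValueError("K and P must lie in (0, 1)")
    z = stats.norm.pdf(stats.norm.isf(k))
    return float((k ** 2 * (1 - k) ** 2) / (z ** 2 * p_case * (1 - p_case)))


# ---------------------------------------------------------------------------
# Tail discrimination and predictive values
# ---------------------------------------------------------------------------

def ppv_npv(sensitivity: float, specificity: float, prev: float
            ) -> tuple[float, float]:
    """Prevalence-adjusted positive and negative predictive values."""
    for name, v in (("sensitivity", sensitivity),
                    ("specificity", specificity), ("prev", prev)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    ppv_den = sensitivity * prev + (1.0 - specificity) * (1.0 - prev)
    npv_den = specificity * (1.0 - prev) + (1.0 - sensitivity) * prev
    if ppv_den == 0 or npv_den == 0:
        raise ZeroDivisionError("degenerate sensitivity/specificity/prevalence "
                                "combination: zero denominator")
    return (sensitivity * prev / ppv_den,
            specificity * (1.0 - prev) / npv_den)


def tail_metrics(inp: EvaluationInput, cutoff_percent: float) -> TailMetrics:
    """Discrimination of the top ``cutoff_percent`` of the score.

    The high-risk indicator is score >= the empirical (100-cutoff)
    percentile (ties all enter the top group; the realized group size is
    reported).  The OR comes from a covariate-adjusted logistic fit on
    the indicator; sensitivity/specificity from the raw cross-tabulation;
    PPV/NPV from the configured population prevalence.
    """
    if not 0.0 < cutoff_percent < 50.0:
        raise ValueError("cutoff_percent must lie in (0, 50)")
    threshold = np.quantile(inp.score, 1.0 - cutoff_percent / 100.0)
    top = inp.score >= threshold
    n_top = int(top.sum())
    if n_top == 0 or n_top == len(top):
        raise ValueError("empty or full top group at this cutoff")

    cases, controls = inp.status == 1, inp.status == 0
    sens = float(top[cases].mean())
    spec = float((~top)[controls].mean())
    ppv, npv = ppv_npv(sens, spec, inp.prevalence)

    unstable = top[cases].sum() == 0 or top[controls].sum() == 0
    fit = logistic_fit(
        inp.status,
        np.column_stack([top.astype(float), inp.covariate_matrix()]),
    )
    b, se = fit.params[1], fit.bse[1]
    unstable = bool(unstable or fit.separation_flag)
    wald_p = 2.0 * stats.norm.sf(abs(b / se)) if se > 0 else np.nan
    return TailMetrics(
        cutoff_percent=cutoff_percent,
        n_top=n_top,
        or_estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - Z95 * se)),
        ci_high=float(np.exp(b + Z95 * se)),
        p_value=float(wald_p),
        sensitivity=sens,
        specificity=spec,
        adjusted_ppv=float(ppv),
        adjusted_npv=float(npv),
        unstable=unstable,
    )


def calibration_by_decile(
    status: np.ndarray,
    predicted_probabilities: np.ndarray,
    score: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predicted vs observed risk within score deciles.

    Samples are ranked by ``score`` (default: the predicted probability)
    and split into 10 near-equal groups (sizes differ by at most 1); each
    row reports the mean predicted probability and observed case fraction.
    """
    status = np.asarray(status, dtype=int)
    pred = np.asarray(predicted_probabilities, dtype=float)
    if np.any((pred < 0) | (pred > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if len(status) < 10:
        raise ValueError("need at least 10 samples for decile calibration")
    rank_on = pred if score is None else np.asarray(score, dtype=float)
    order = np.argsort(rank_on, kind="mergesort")
    rows = []
    for dec, grp in enumerate(np.array_split(order, 10), start=1):
        rows.append({
            "decile": dec,
            "n": len(grp),
            "predicted_risk": float(pred[grp].mean()),
            "observed_risk": float(status[grp].mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def metrics_report(
    inp: EvaluationInput,
    cutoffs: tuple = (2.0, 5.0, 10.0),
    calibration: bool = True,
) -> MetricsReport:
    """Assemble the full per-cohort performance report."""
    aucs = auc_suite(inp)
    orsd, ci = or_per_sd(inp)
    tails = [tail_metrics(inp, c) for c in cutoffs]
    calib = None
    if calibration:
        joint = logistic_fit(
            inp.status, np.column_stack([inp.score, inp.covariate_matrix()])
        )
        calib = calibration_by_decile(inp.status, joint.fitted, score=inp.score)
    return MetricsReport(
        n_samples=len(inp.status),
        n_cases=int(inp.status.sum()),
        prevalence=inp.prevalence,
        liability_r2=liability_r2(inp),
        auc_covariates_only=aucs["auc_covariates_only"],
        auc_prs_only=aucs["auc_prs_only"],
        auc_prs_covariate_adjusted=aucs["auc_prs_covariate_adjusted"],
        auc_combined=aucs["auc_combined"],
        or_per_sd=orsd,
        or_per_sd_ci=ci,
        tail=tails,
        calibration=calib,
    )
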