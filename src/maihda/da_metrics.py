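"""Discriminatory accuracy and intersectionality metrics.

Given the two fitted models, this module computes the quantities the MAIHDA
framework is read through:

* **VPC** (variance partition coefficient), the share of latent-scale
  variance lying between intersectional strata. For a logistic model the
  individual-level latent residual variance is fixed at pi^2/3, so
  VPC = sigma2_u / (sigma2_u + pi^2/3). A null-model VPC above 5% is
  conventionally read as acceptable discriminatory accuracy.
* **PCV** (proportional change in variance), (V1 - V2)/V1: how much of the
  null model's stratum variance the main effects explain. A PCV of 100%
  means purely additive effects; a shortfall signals interaction effects.
* **AUC-ROC** of each model's posterior-mean predicted probabilities
  (stratum effects included in both models, so the null model's AUC reflects
  strata alone); 0.5 is absence of discrimination, 1 perfect.
* **Stratum-level residuals** u_j with 95% credible intervals, ranked for
  caterpillar plots; positive residuals mark disadvantaged strata (higher
  risk than their covariates predict), negative residuals privileged ones.

VPC and PCV are each computed two ways: from posterior-summary variances
(the tabular convention) and per posterior draw summarised by the median
(the package default, which respects the nonlinearity of the VPC
transform); the Jensen gap between the two is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .bayes_mlogit import ModelFit
from .survey_io import SurveyDataset

__all__ = [
    "LOGISTIC_LEVEL1_VARIANCE",
    "DAResult",
    "vpc",
    "pcv",
    "auc_roc",
    "predicted_probabilities",
    "stratum_effects",
    "significance_summary",
    "evaluate_da",
]

LOGISTIC_LEVEL1_VARIANCE = np.pi**2 / 3.0
DA_VPC_THRESHOLD = 5.0  # percent; the conventional "acceptable DA" cutoff


def vpc(sigma2_u: float | np.ndarray) -> float | np.ndarray:
    """Variance partition coefficient, in percent.

    ``100 * sigma2_u / (sigma2_u + pi^2/3)`` — the latent-variable form for
    a logistic model. Accepts scalars or draw arrays.
    """
    sigma2_u = np.asarray(sigma2_u, dtype=np.float64)
    if (sigma2_u < 0).any():
        raise ValueError("sigma2_u must be non-negative")
    out = 100.0 * sigma2_u / (sigma2_u + LOGISTIC_LEVEL1_VARIANCE)
    return float(out) if out.ndim == 0 else out


def pcv(v1: float, v2: float) -> float:
    """Proportional change in variance, in percent: ``100 * (v1 - v2)/v1``."""
    if v1 <= 0:
        raise ValueError("null-model variance v1 must be strictly positive")
    if v2 < 0:
        raise ValueError("v2 must be non-negative")
    return 100.0 * (v1 - v2) / v1


def auc_roc(predicted: Sequence[float], outcome: Sequence[int]) -> float:
    """AUC-ROC in percent, rank-sum form with half credit for ties.

    The probability that a uniformly random case receives a higher predicted
    probability than a uniformly random non-case, ties counted 1/2 —
    identical to the brute-force all-pairs concordance count.
    """
    p = np.asarray(predicted, dtype=np.float64)
    y = np.asarray(outcome)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predicted and outcome must be equal-length vectors")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(p, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(100.0 * u / (n1 * n0))


def predicted_probabilities(
    fit: ModelFit, dataset: SurveyDataset | None = None, *, chunk: int = 1000
) -> np.ndarray:
    """Posterior-mean outcome probability per record.

    For each record, the mean over posterior draws of
    ``invlogit(beta0 + x'beta + u_j)`` — stratum effects included, so the
    null model's predictions vary across strata even without covariates.
    Computed against the data the model was fitted to; passing a dataset
    only validates that it is the same size.
    """
    if dataset is not None and dataset.n_records != fit.n_records:
        raise ValueError("dataset does not match the fitted model's records")
    b0 = fit.pooled("beta0")  # (D,)
    beta = fit.pooled("beta")  # (D, p)
    u = fit.pooled("u")  # (D, J)
    D = b0.shape[0]
    acc = np.zeros(fit.n_records)
    for start in range(0, D, chunk):
        sl = slice(start, min(start + chunk, D))
        eta = b0[sl][None, :] + fit.X @ beta[sl].T + u[sl].T[fit.s, :]
        acc += expit(eta).sum(axis=1)
    return acc / D


def stratum_effects(fit: ModelFit) -> pd.DataFrame:
    """Per-stratum posterior residual summaries, ranked for caterpillar plots.

    Columns: stratum ordinal, label, posterior mean, 95% equal-tailed
    credible interval, ascending rank by mean, and a crossing-zero flag
    (interval containing zero = not significantly different from the model's
    expectation).
    """
    u = fit.pooled("u")  # (D, J)
    mean = u.mean(axis=0)
    lo, hi = np.percentile(u, [2.5, 97.5], axis=0)
    order = np.argsort(mean, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    return pd.DataFrame(
        {
            "ordinal": np.arange(1, fit.n_strata + 1),
            "label": fit.spec.strata.labels,
            "mean": mean,
            "ci_lower": lo,
            "ci_upper": hi,
            "rank": rank,
            "crosses_zero": (lo <= 0) & (0 <= hi),
        }
    )


def significance_summary(effects: pd.DataFrame) -> str:
    """One-line count of strata whose 95% interval excludes zero, e.g.
    ``"only 4 (2.7%) of 147 intersectional strata's 95% CI not crossing
    zero"``."""
    total = len(effects)
    k = int((~effects["crosses_zero"]).sum())
    pct = 100.0 * k / total
    return (
        f"only {k} ({pct:.1f}%) of {total} intersectional strata's "
        "95% CI not crossing zero"
    )


@dataclass
class DAResult:
    """Discriminatory-accuracy summary of a Model 1 / Model 2 pair.

    Default VPC/PCV fields use the per-draw posterior-median method;
    ``*_summary`` fields use posterior-mean variances (the tabular
    convention). ``jensen_gap_*`` is the difference between the mean
    per-draw VPC and the VPC of the posterior-mean variance, quantifying the
    nonlinearity of the VPC transform.
    """

    vpc_model1: float
    vpc_model2: float
    pcv: float
    auc_model1: float
    auc_model2: float
    vpc_model1_summary: float
    vpc_model2_summary: float
    pcv_summary: float
    sigma2_model1: float
    sigma2_model2: float
    jensen_gap_model1: float
    jensen_gap_model2: float
    n_strata: int
    n_records: int
    da_verdicts: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "vpc_model1": self.vpc_model1,
            "vpc_model2": self.vpc_model2,
            "pcv": self.pcv,
            "auc_model1": self.auc_model1,
            "auc_model2": self.auc_model2,
            "vpc_model1_summary": self.vpc_model1_summary,
            "vpc_model2_summary": self.vpc_model2_summary,
            "pcv_summary": self.pcv_summary,
            "sigma2_model1": self.sigma2_model1,
            "sigma2_model2": self.sigma2_model2,
            "jensen_gap_model1": self.jensen_gap_model1,
            "jensen_gap_model2": self.jensen_gap_model2,
            "n_strata": self.n_strata,
            "n_records": self.n_records,
            "da_verdicts": self.da_verdicts,
        }


# Model 2 VPCs at or below this are read as "additive effects": posterior
# stratum-variance estimates are bounded away from zero by the positive
# prior support, so exact zero never occurs.
ADDITIVE_VPC_TOLERANCE = 1.0  # percent


def evaluate_da(
    fit1: ModelFit, fit2: ModelFit, dataset: SurveyDataset | None = None
) -> DAResult:
    """Assemble VPC (both models), PCV, AUC (both models) and verdicts.

    ``fit1`` is the null model, ``fit2`` the main-effects model; they must
    share the strata index and outcome.
    """
    if fit1.spec.strata is not fit2.spec.strata and (
        fit1.n_strata != fit2.n_strata
        or fit1.spec.strata.keys != fit2.spec.strata.keys
    ):
        raise ValueError("fits do not share a strata index")
    if fit1.spec.outcome != fit2.spec.outcome:
        raise ValueError("fits model different outcomes")

    s2_1 = fit1.pooled("sigma2")
    s2_2 = fit2.pooled("sigma2")
    v1_med, v2_med = float(np.median(s2_1)), float(np.median(s2_2))
    v1_mean, v2_mean = float(s2_1.mean()), float(s2_2.mean())

    vpc1 = float(np.median(vpc(s2_1)))
    vpc2 = float(np.median(vpc(s2_2)))
    vpc1_sum = vpc(v1_mean)
    vpc2_sum = vpc(v2_mean)

    y = fit1.y.astype(int)
    auc1 = auc_roc(predicted_probabilities(fit1, dataset), y)
    auc2 = auc_roc(predicted_probabilities(fit2, dataset), y)

    verdicts = []
    verdicts.append(
        "acceptable DA" if vpc1 > DA_VPC_THRESHOLD else "low DA"
    )
    if vpc2 <= ADDITIVE_VPC_TOLERANCE:
        verdicts.append("additive effects")
    else:
        verdicts.append("presence of interactional effects")

    return DAResult(
        vpc_model1=vpc1,
        vpc_model2=vpc2,
        pcv=pcv(v1_med, v2_med),
        auc_model1=auc1,
        auc_model2=auc2,
        vpc_model1_summary=vpc1_sum,
        vpc_model2_summary=vpc2_sum,
        pcv_summary=pcv(v1_mean, v2_mean),
        sigma2_model1=v1_med,
        sigma2_model2=v2_med,
        jensen_gap_model1=float(np.mean(vpc(s2_1)) - vpc1_sum),
        jensen_gap_model2=float(np.mean(vpc(s2_2)) - vpc2_sum),
        n_strata=fit1.n_strata,
        n_records=fit1.n_records,
        da_verdicts=verdicts,
    )
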