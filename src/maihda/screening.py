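"""Univariate screening of candidate social determinants.

Each candidate determinant is cross-tabulated against the binary outcome and
tested for independence; candidates significant at level ``alpha`` are the
ones that go on to define the intersectional strata. The default test is the
Pearson chi-square without continuity correction, the test conventionally
reported in DHS-style univariate tables; a likelihood-ratio test from a
univariate logistic regression is available as a sensitivity switch. No
multiple-testing correction is applied: screening selects variables one at a
time at the nominal level, and users who want a corrected rule should adjust
``alpha`` themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survey_io import SurveyDataset

__all__ = [
    "ContingencyTable",
    "ScreeningResult",
    "DegenerateTableError",
    "chisq_independence",
    "select_determinants",
    "screening_frame",
]

DEFAULT_ALPHA = 0.05


class DegenerateTableError(ValueError):
    """A margin of the contingency table is zero (expected counts undefined)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of a determinant (rows) against an outcome (columns)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # shape (rows, cols), non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if (counts < 0).any():
            raise ValueError("negative cell count")
        if counts.sum() <= 0:
            raise ValueError("empty contingency table")


@dataclass(frozen=True)
class ScreeningResult:
    variable: str
    statistic: float
    df: int
    p_value: float
    selected: bool
    note: str = ""


def chisq_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns ``(statistic, df, p_value)`` with ``df = (rows-1)(cols-1)``.
    A zero row or column margin makes expected counts degenerate and raises
    :class:`DegenerateTableError` naming the offending level.
    """
    counts = table.counts
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    if (row_m == 0).any():
        lvl = table.row_labels[int(np.argmin(row_m))]
        raise DegenerateTableError(f"row margin zero for level {lvl!r}")
    if (col_m == 0).any():
        lvl = table.col_labels[int(np.argmin(col_m))]
        raise DegenerateTableError(f"column margin zero for level {lvl!r}")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def crosstab(
    dataset: SurveyDataset, variable: str, outcome: str
) -> ContingencyTable:
    """Observed-level cross-tabulation of ``variable`` against ``outcome``.

    Levels never observed in the data are omitted (they would produce zero
    margins); level order follows the codebook.
    """
    spec = dataset.codebook[variable]
    ospec = dataset.codebook[outcome]
    sub = dataset.records[[variable, outcome]].dropna()
    ct = pd.crosstab(sub[variable], sub[outcome])
    rows = [l for l in spec.levels if l in ct.index]
    cols = [l for l in ospec.levels if l in ct.columns]
    ct = ct.loc[rows, cols]
    return ContingencyTable(tuple(rows), tuple(cols), ct.to_numpy())


def _logistic_lrt(table: ContingencyTable) -> tuple[float, int, float]:
    # LR test for a saturated-vs-null binomial model per determinant level;
    # equivalent to the univariate logistic model's likelihood-ratio test.
    counts = table.counts.astype(float)
    n_r = counts.sum(axis=1)
    k_r = counts[:, 1]
    p_r = k_r / n_r
    p0 = k_r.sum() / n_r.sum()

    def llf(k, n, p):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = k * np.log(p) + (n - k) * np.log(1 - p)
        return np.where((p > 0) & (p < 1), t,
                        np.where((k == 0) | (k == n), 0.0, -np.inf)).sum()

    g2 = 2.0 * (llf(k_r, n_r, p_r) - llf(k_r, n_r, p0))
    df = counts.shape[0] - 1
    return float(g2), int(df), float(stats.chi2.sf(g2, df))


def select_determinants(
    dataset: SurveyDataset,
    outcome: str,
    candidates: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    *,
    method: str = "chi2",
) -> list[ScreeningResult]:
    """Screen candidate determinants against one binary outcome.

    One :class:`ScreeningResult` per candidate, in input order, with
    ``selected = (p_value < alpha)``. Candidates with a single observed level
    are excluded with a warning (``selected=False``, ``p_value=nan``).
    ``method`` is ``"chi2"`` (Pearson, default) or ``"logistic"``
    (likelihood-ratio test of the univariate logistic model).
    """
    if method not in ("chi2", "logistic"):
        raise ValueError(f"unknown screening method {method!r}")
    results: list[ScreeningResult] = []
    for cand in candidates:
        sub = dataset.records[[cand, outcome]].dropna()
        observed = sub[cand].unique()
        if len(observed) < 2:
            warnings.warn(
                f"candidate {cand!r} has a single observed level; excluded",
                stacklevel=2,
            )
            results.append(
                ScreeningResult(cand, float("nan"), 0, float("nan"), False,
                                note="single observed level")
            )
            continue
        table = crosstab(dataset, cand, outcome)
        if method == "chi2":
            stat, df, p = chisq_independence(table)
        else:
            stat, df, p = _logistic_lrt(table)
        results.append(ScreeningResult(cand, stat, df, p, bool(p < alpha)))
    return results


def screening_frame(results: Sequence[ScreeningResult]) -> pd.DataFrame:
    """Results as a DataFrame, exportable as a univariate-analysis CSV."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "selected": [r.selected for r in results],
            "note": [r.note for r in results],
        }
    )
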