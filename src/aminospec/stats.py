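"""Aggregate per-pair accuracy values into library summaries, chemical-space
correlations, threshold classifications and group comparisons.

Conventions: library summaries are unweighted arithmetic means over pairs;
correlations are squared Pearson coefficients (R^2); the derivatized-vs-free
comparison is a two-sided Welch (unequal-variance) t-test, chosen because
group sizes and variances differ between derivatized and free subsets; raw
p-values are reported without multiple-testing correction, with the number
of tests recorded alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import SimilarityResult

__all__ = [
    "LibrarySummary",
    "ThresholdConfig",
    "summarize_library",
    "correlate",
    "correlation_table",
    "welch_ttest",
    "group_comparison_table",
    "classify_similarity",
]

METRIC_COLUMNS = ("rmse", "sca_deg", "wcs", "sen")


@dataclass(frozen=True)
class LibrarySummary:
    library_name: str
    n_pairs: int
    mean_rmse: float
    mean_sca_deg: float
    mean_wcs: float
    mean_sen: float


@dataclass(frozen=True)
class ThresholdConfig:
    """Classification thresholds for the bounded metrics.

    A contrast angle below ~26 degrees is typically adequate for library
    search; weighted-cosine scores above 0.7 are generally called "similar";
    entropy-similarity scores of 0.75 or greater are called "similar".
    SCA and WCS use strict comparisons, SEN is inclusive by default; the
    comparators are part of the config and are recorded in every report.
    """

    sca_adequate_deg: float = 26.0
    wcs_similar: float = 0.7
    sen_similar: float = 0.75
    sen_inclusive: bool = True

    def as_dict(self) -> dict:
        return {
            "sca_adequate_deg": self.sca_adequate_deg,
            "wcs_similar": self.wcs_similar,
            "sen_similar": self.sen_similar,
            "sen_comparator": ">=" if self.sen_inclusive else ">",
        }


def summarize_library(
    results: Sequence[SimilarityResult], library_name: str
) -> LibrarySummary:
    """Unweighted arithmetic means of each metric over all pairs."""
    if not results:
        raise ValueError("cannot summarize an empty result list")
    return LibrarySummary(
        library_name=library_name,
        n_pairs=len(results),
        mean_rmse=float(np.mean([r.rmse for r in results])),
        mean_sca_deg=float(np.mean([r.sca_deg for r in results])),
        mean_wcs=float(np.mean([r.wcs for r in results])),
        mean_sen=float(np.mean([r.sen for r in results])),
    )


def correlate(property_values: Sequence[float], metric_values: Sequence[float]) -> float:
    """Coefficient of determination: squared Pearson correlation."""
    x = np.asarray(property_values, dtype=float)
    y = np.asarray(metric_values, dtype=float)
    if x.size != y.size:
        raise ValueError("property and metric vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points to correlate")
    if _near_constant(x) or _near_constant(y):
        raise ValueError("zero variance in property or metric values")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


def _near_constant(x: np.ndarray) -> bool:
    # constant to within fp round-off of the values' own magnitude
    return float(np.ptp(x)) <= 1e-12 * max(1.0, abs(float(np.mean(x))))


def correlation_table(
    pairs_df: pd.DataFrame,
    library_name: str,
    properties: Sequence[str] = ("molecular_weight", "logp"),
    metrics: Sequence[str] = METRIC_COLUMNS,
) -> pd.DataFrame:
    """R^2 of every (property, metric) combination in a joined pair table.

    Degenerate combinations (zero variance) yield NaN with a note rather
    than aborting the whole report.
    """
    rows = []
    for prop in properties:
        for metric in metrics:
            note = ""
            try:
                r2 = correlate(pairs_df[prop], pairs_df[metric])
            except ValueError as exc:
                r2 = float("nan")
                note = str(exc)
            rows.append(
                {
                    "library": library_name,
                    "property": prop,
                    "metric": metric,
                    "r_squared": r2,
                    "n": len(pairs_df),
                    "note": note,
                }
            )
    return pd.DataFrame(rows)


def welch_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided unequal-variance t-test (Welch–Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if _near_constant(a) and _near_constant(b):
        # no within-group spread: identical groups are indistinguishable,
        # otherwise the test statistic is undefined
        if abs(float(a.mean()) - float(b.mean())) <= 1e-12 * max(1.0, abs(float(a.mean()))):
            return 0.0, 1.0
        raise ValueError("both groups constant; Welch statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def group_comparison_table(
    pairs_df: pd.DataFrame,
    library_name: str,
    group_column: str = "derivatized",
    metrics: Sequence[str] = METRIC_COLUMNS,
) -> pd.DataFrame:
    """Welch t-test per metric between derivatized (Deriv) and free (Free) pairs."""
    deriv = pairs_df[pairs_df[group_column].astype(bool)]
    free = pairs_df[~pairs_df[group_column].astype(bool)]
    rows = []
    for metric in metrics:
        note = ""
        try:
            t, p = welch_ttest(deriv[metric], free[metric])
        except ValueError as exc:
            t, p, note = float("nan"), float("nan"), str(exc)
        rows.append(
            {
                "library": library_name,
                "metric": metric,
                "group_a": "Deriv",
                "group_b": "Free",
                "t_statistic": t,
                "p_value": p,
                "n_a": len(deriv),
                "n_b": len(free),
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def classify_similarity(
    result: SimilarityResult, thresholds: ThresholdConfig | None = None
) -> dict[str, str]:
    """Label one pair against the adequacy/similarity thresholds.

    RMSE has no published threshold and is left unclassified.
    """
    thr = thresholds or ThresholdConfig()
    sen_pass = result.sen >= thr.sen_similar if thr.sen_inclusive else result.sen > thr.sen_similar
    return {
        "sca": "adequate" if result.sca_deg < thr.sca_adequate_deg else "not_adequate",
        "wcs": "similar" if result.wcs > thr.wcs_similar else "not_similar",
        "sen": "similar" if sen_pass else "not_similar",
    }
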