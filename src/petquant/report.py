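"""Agreement statistics between quantification sources and cohort summaries.

Regression pools organ × animal points with unweighted OLS (scatter plots
of in vivo vs ex vivo uptake pool organs the same way); paired comparisons
use the two-sided paired Student's t-test with no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import tnt_ratio

__all__ = [
    "PairedSeries",
    "linear_regression",
    "paired_t_test",
    "summarize_cohort",
    "method_agreement_report",
]


@dataclass(frozen=True)
class PairedSeries:
    """Matched measurements of the same items by two methods."""

    labels: tuple
    x: np.ndarray
    y: np.ndarray
    x_source: str = "x"
    y_source: str = "y"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "labels", tuple(self.labels))
        if not (len(self.labels) == x.size == y.size) or x.size < 2:
            raise ValueError("need >= 2 complete pairs with matching labels")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("missing values are not allowed in a paired series")

    def swapped(self) -> "PairedSeries":
        return PairedSeries(self.labels, self.y, self.x, self.y_source, self.x_source)


def linear_regression(s: PairedSeries) -> tuple[float, float, float]:
    """Unweighted OLS of y on x; returns (slope, intercept, r²)."""
    if s.x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(s.x) == 0:
        raise ValueError("regression undefined for constant x")
    res = stats.linregress(s.x, s.y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def paired_t_test(s: PairedSeries) -> tuple[float, float]:
    """Two-sided paired Student's t-test on d = y − x; returns (t, p).

    Identical series give (0, 1) by convention; non-zero differences with
    zero variance have no finite t statistic and raise.
    """
    d = s.y - s.x
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        raise ValueError("paired t-test undefined for zero-variance, non-zero differences")
    res = stats.ttest_rel(s.y, s.x)
    return float(res.statistic), float(res.pvalue)


def summarize_cohort(rows: pd.DataFrame, metrics=("pid_g", "suv_max", "snr")) -> pd.DataFrame:
    """Mean ± sample-SD per organ × source for each metric.

    Returns a tidy frame with mean, sd (NaN for singletons), n, and a
    2-decimal ``formatted`` column like ``"22.01 ± 9.64"``.
    """
    if rows.empty:
        return pd.DataFrame(columns=["organ", "source", "metric", "mean", "sd", "n", "formatted"])
    out = []
    for (organ, source), grp in rows.groupby(["organ", "source"], sort=True):
        for metric in metrics:
            if metric not in grp:
                continue
            vals = grp[metric].dropna().to_numpy()
            if vals.size == 0:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            out.append(
                {
                    "organ": organ,
                    "source": source,
                    "metric": metric,
                    "mean": mean,
                    "sd": sd,
                    "n": int(vals.size),
                    "formatted": f"{mean:.2f} ± {sd:.2f}" if np.isfinite(sd) else f"{mean:.2f} ± NA",
                }
            )
    return pd.DataFrame(out)


def method_agreement_report(rows: pd.DataFrame, metric: str = "pid_g") -> dict:
    """All pairwise source agreement on a quantified cohort.

    For every pair of sources sharing the cohort: pooled organ × animal
    OLS regression, paired t-test, and per-source cohort T/NT (mean of
    per-animal tumor/muscle ratios).  Input is the tidy frame produced by
    :func:`petquant.quantify.quant_table` (possibly concatenated across
    sources).
    """
    if rows.empty or rows["source"].nunique() < 2:
        raise ValueError("need at least two quantification sources on the same cohort")
    wide = rows.pivot_table(index=["animal", "organ"], columns="source", values=metric)
    if wide.isna().any().any():
        raise ValueError("cohorts are mismatched across sources")
    sources = sorted(wide.columns)
    report: dict = {"metric": metric, "sources": sources, "pairs": {}, "tnt": {}}
    for a, b in combinations(sources, 2):
        s = PairedSeries(tuple(wide.index), wide[a].to_numpy(), wide[b].to_numpy(), a, b)
        slope, intercept, r2 = linear_regression(s)
        t, p = paired_t_test(s)
        report["pairs"][f"{b}~{a}"] = {
            "slope": slope,
            "intercept": intercept,
            "r2": r2,
            "t": t,
            "p": p,
            "n": int(s.x.size),
        }
    if {"tumor", "muscle"} <= set(rows["organ"].unique()):
        by_src = rows.pivot_table(index=["animal", "source"], columns="organ", values=metric)
        for src in sources:
            sub = by_src.xs(src, level="source")
            ratios = [tnt_ratio(t_, m_) for t_, m_ in zip(sub["tumor"], sub["muscle"])]
            ratios = np.asarray(ratios)
            report["tnt"][src] = {
                "mean": float(ratios.mean()),
                "sd": float(ratios.std(ddof=1)) if ratios.size > 1 else float("nan"),
                "n": int(ratios.size),
            }
    return report
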