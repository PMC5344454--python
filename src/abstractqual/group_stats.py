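"""Classical between-group tests: Welch's t and Pearson correlation.

Produces the feature-by-feature comparison table: overall mean, per-group
means, correlation of each feature with the yes-item count, and the Welch
p-value between low- and high-quality groups.  Two-sided throughout; no
multiple-testing correction (matching the reference analysis plan).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WelchResult",
    "PearsonResult",
    "GroupComparisonRow",
    "welch_test",
    "pearson_test",
    "comparison_table",
    "ALPHA",
]

ALPHA = 0.05


class DegenerateSampleError(ValueError):
    pass


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


class PearsonResult(NamedTuple):
    r: float
    t: float
    p: float


def welch_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's two-sample t test (unequal variances), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateSampleError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateSampleError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def pearson_test(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson correlation with the t-based two-sided test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or n != len(y):
        raise DegenerateSampleError("need aligned samples with n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise DegenerateSampleError("zero-variance sample")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0 - 1e-15:
        warnings.warn("|r| = 1: p-value at boundary", RuntimeWarning)
        return PearsonResult(r=r, t=np.inf if r > 0 else -np.inf, p=0.0)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return PearsonResult(r=r, t=float(t), p=float(p))


@dataclass
class GroupComparisonRow:
    feature: str
    mean_all: float
    mean_low: float
    mean_high: float
    pearson_r: float
    p_corr: float
    p_welch: float

    @property
    def significant(self) -> bool:
        return self.p_welch < ALPHA


def comparison_table(
    features: pd.DataFrame,
    labels: Sequence[int],
    yes_counts: Sequence[int],
) -> pd.DataFrame:
    """One row per feature column: group means + correlation/Welch tests.

    ``labels`` are binary quality labels (1 = high), ``yes_counts`` the raw
    yes-item counts used for the correlation.  NaN feature values are dropped
    per feature (with their labels).
    """
    labels = np.asarray(labels, dtype=int)
    yes_counts = np.asarray(yes_counts, dtype=float)
    if len(features) != len(labels) or len(labels) != len(yes_counts):
        raise ValueError("features, labels and yes_counts must align")
    for grp, name in ((0, "low"), (1, "high")):
        if not np.any(labels == grp):
            raise ValueError(f"{name}-quality group is empty")

    rows = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        v, lab, yc = vals[ok], labels[ok], yes_counts[ok]
        try:
            corr = pearson_test(v, yc)
            welch = welch_test(v[lab == 0], v[lab == 1])
        except DegenerateSampleError:
            # constant feature: report means, flag tests as undefined
            rows.append(
                GroupComparisonRow(
                    feature=col,
                    mean_all=float(v.mean()),
                    mean_low=float(v[lab == 0].mean()),
                    mean_high=float(v[lab == 1].mean()),
                    pearson_r=np.nan, p_corr=np.nan, p_welch=np.nan,
                )
            )
            continue
        rows.append(
            GroupComparisonRow(
                feature=col,
                mean_all=float(v.mean()),
                mean_low=float(v[lab == 0].mean()),
                mean_high=float(v[lab == 1].mean()),
                pearson_r=corr.r,
                p_corr=corr.p,
                p_welch=welch.p,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("feature")
    df["significant"] = df["p_welch"] < ALPHA
    return df
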