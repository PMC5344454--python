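"""Discrimination and calibration metrics for the quality classifier.

AUC (Mann-Whitney formulation), Brier score, the Hosmer-Lemeshow decile
calibration test, and PPV/NPV with an explicit positive class and threshold.
Report values are also expressed on the x100 percent scale used in the
published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationReport",
    "auc",
    "brier_score",
    "hosmer_lemeshow",
    "ppv_npv",
    "evaluate",
]


def _check_binary(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if not np.all(np.isin(u, [0, 1])):
        raise ValueError("labels must be binary 0/1")
    if len(u) < 2:
        raise ValueError("both classes must be present")


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative (ties 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must align")
    _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(scores)  # midranks handle ties as 0.5 credit
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def brier_score(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Mean squared error of predicted probabilities."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(probs) != len(labels):
        raise ValueError("probs and labels must align")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((probs - labels) ** 2))


class HosmerLemeshowResult(NamedTuple):
    stat: float
    df: int
    p: float
    n_groups: int
    merged: bool


def _decile_groups(order: np.ndarray, probs: np.ndarray, groups: int) -> list[np.ndarray]:
    """Quantile-based groups over sorted order; tied probs stay together."""
    n = len(order)
    boundaries = [int(round(n * g / groups)) for g in range(1, groups + 1)]
    out = []
    start = 0
    for b in boundaries:
        end = b
        # extend so equal predicted probabilities fall in one group
        while 0 < end < n and probs[order[end]] == probs[order[end - 1]]:
            end += 1
        if end > start:
            out.append(order[start:end])
        start = max(start, end)
    return out


def hosmer_lemeshow(
    probs: Sequence[float],
    labels: Sequence[int],
    groups: int = 10,
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow chi-square test over predicted-probability deciles.

    Groups whose expected event count is 0 or the full group size are merged
    with their neighbour (flagged in the result).  df = n_groups - 2.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(probs) < groups:
        raise ValueError("need at least one observation per group")
    _check_binary(labels)
    order = np.argsort(probs, kind="stable")
    cells = _decile_groups(order, probs, groups)

    # (n_g, O_g, E_g) with degenerate cells merged into the next one
    merged = False
    agg: list[list[float]] = []
    for idx in cells:
        n_g = float(len(idx))
        o_g = float(labels[idx].sum())
        e_g = float(probs[idx].sum())
        if agg and (agg[-1][2] <= 0.0 or agg[-1][2] >= agg[-1][0]):
            agg[-1][0] += n_g
            agg[-1][1] += o_g
            agg[-1][2] += e_g
            merged = True
        else:
            agg.append([n_g, o_g, e_g])
    if len(agg) > 1 and (agg[-1][2] <= 0.0 or agg[-1][2] >= agg[-1][0]):
        last = agg.pop()
        agg[-1] = [a + b for a, b in zip(agg[-1], last)]
        merged = True

    stat = 0.0
    for n_g, o_g, e_g in agg:
        denom = e_g * (1.0 - e_g / n_g)
        stat += (o_g - e_g) ** 2 / denom
    df = max(len(agg) - 2, 1)
    p = float(stats.chi2.sf(stat, df))
    return HosmerLemeshowResult(stat=float(stat), df=df, p=p, n_groups=len(agg), merged=merged)


class PpvNpvResult(NamedTuple):
    ppv: float | None
    npv: float | None
    tp: int
    fp: int
    tn: int
    fn: int


def ppv_npv(
    probs: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    positive_class: int = 0,
) -> PpvNpvResult:
    """Predictive values at a probability threshold.

    ``probs`` are probabilities of label 1 (high quality); the predicted
    label is 1 iff prob > threshold.  With ``positive_class=0`` (default) a
    positive call is a predicted low-quality article — the rare class a
    screener wants to catch.  Undefined values are returned as None, never
    fabricated.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if positive_class not in (0, 1):
        raise ValueError("positive_class must be 0 or 1")
    pred1 = probs > threshold
    if positive_class == 1:
        pred_pos, actual_pos = pred1, labels == 1
    else:
        pred_pos, actual_pos = ~pred1, labels == 0
    tp = int(np.sum(pred_pos & actual_pos))
    fp = int(np.sum(pred_pos & ~actual_pos))
    tn = int(np.sum(~pred_pos & ~actual_pos))
    fn = int(np.sum(~pred_pos & actual_pos))
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    return PpvNpvResult(ppv=ppv, npv=npv, tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class EvaluationReport:
    auc: float
    auc_pct: float
    brier: float
    brier_pct: float
    hl_stat: float
    hl_df: int
    hl_p: float
    ppv_pct: float | None
    npv_pct: float | None
    threshold: float
    positive_class: str
    confusion: dict

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(
    probs: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    positive_class: str = "low_quality",
    hl_groups: int = 10,
) -> EvaluationReport:
    """Full evaluation: AUC, Brier, Hosmer-Lemeshow, PPV/NPV."""
    if positive_class not in ("low_quality", "high_quality"):
        raise ValueError("positive_class must be low_quality or high_quality")
    a = auc(probs, labels)
    b = brier_score(probs, labels)
    hl = hosmer_lemeshow(probs, labels, groups=hl_groups)
    pv = ppv_npv(
        probs, labels, threshold=threshold,
        positive_class=0 if positive_class == "low_quality" else 1,
    )
    return EvaluationReport(
        auc=a,
        auc_pct=100.0 * a,
        brier=b,
        brier_pct=100.0 * b,
        hl_stat=hl.stat,
        hl_df=hl.df,
        hl_p=hl.p,
        ppv_pct=None if pv.ppv is None else 100.0 * pv.ppv,
        npv_pct=None if pv.npv is None else 100.0 * pv.npv,
        threshold=threshold,
        positive_class=positive_class,
        confusion={"tp": pv.tp, "fp": pv.fp, "tn": pv.tn, "fn": pv.fn},
    )
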