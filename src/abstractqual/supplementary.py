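"""Loader for the published per-article risk-of-bias score table.

The deposited CSV is not redistributable with this package and its exact
header layout is not documented, so the loader detects the 12 per-criterion
score columns by content: columns whose non-empty values all parse as
yes/no/unsure (case-insensitive, with y/n/u and "unclear" aliases).  Exactly
12 such columns are required.
"""

from __future__ import annotations

import pandas as pd

from .corpus import N_ROB_ITEMS, RiskOfBiasRecord, Score

__all__ = ["load_supplementary_records"]


def _is_score_column(series: pd.Series) -> bool:
    values = [v for v in series.astype(str).str.strip() if v and v.lower() != "nan"]
    if not values:
        return False
    for v in values:
        try:
            Score.parse(v)
        except ValueError:
            return False
    return True


def load_supplementary_records(path: str) -> list[RiskOfBiasRecord]:
    """Parse the supplementary score table into risk-of-bias records."""
    df = pd.read_csv(path, dtype=str)
    score_cols = [c for c in df.columns if _is_score_column(df[c])]
    if len(score_cols) != N_ROB_ITEMS:
        raise ValueError(
            f"expected {N_ROB_ITEMS} per-criterion score columns, "
            f"detected {len(score_cols)}: {score_cols}"
        )
    records = []
    for _, row in df.iterrows():
        values = [row[c] for c in score_cols]
        if any(pd.isna(v) for v in values):
            continue
        records.append(RiskOfBiasRecord.from_strings(values))
    return records
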