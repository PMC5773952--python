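"""Cohort summary tables and printed-value rounding conventions."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, PhenotypeLabels

__all__ = ["CohortSummary", "summarize_cohort", "round_half_up", "printed_round"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal rounding with halves rounded away from zero (0.5 -> 1, -0.5 -> -1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def printed_round(x: float, ndigits: int = 2, start: int = 6) -> float:
    """Successive half-up rounding, one decimal place at a time.

    Mirrors the way hand-reported table values are often produced: the value
    is rounded half-up at ``start`` decimals, then repeatedly at one fewer
    decimal until ``ndigits``. This differs from single-step rounding exactly
    when an intermediate digit is promoted to 5 (e.g. 1.58496 -> 1.585 ->
    1.59, whereas a single half-up round gives 1.58).
    """
    v = float(x)
    for d in range(start, ndigits - 1, -1):
        v = round_half_up(v, d)
    return v


@dataclass(frozen=True)
class CohortSummary:
    """Per-category case/control counts with integer percentages.

    ``table`` columns: category, control_n, control_pct, case_n, case_pct.
    Percentages are round-half-up integers of 100 * count / arm size;
    categories need not be exhaustive.
    """

    table: pd.DataFrame
    n_cases: int
    n_controls: int


def summarize_cohort(labels: PhenotypeLabels, categories: pd.DataFrame) -> CohortSummary:
    """Tabulate per-arm counts and percentages for each category column.

    ``categories`` must have a ``sample_id`` column; every further column is a
    categorical characteristic whose levels become summary rows. Every
    categorized sample must carry a phenotype label.
    """
    if "sample_id" not in categories.columns:
        raise ValueError("categories table needs a 'sample_id' column")
    lookup = {s: l for s, l in zip(labels.sample_ids, labels.labels)}
    unknown = [s for s in categories["sample_id"] if s not in lookup]
    if unknown:
        raise ValueError(f"categorized samples without phenotype label: {unknown[:5]}")
    n_cases, n_controls = labels.n_cases, labels.n_controls

    rows = []
    for col in categories.columns:
        if col == "sample_id":
            continue
        for level in pd.unique(categories[col].dropna()):
            in_level = categories.loc[categories[col] == level, "sample_id"]
            arm = np.array([lookup[s] for s in in_level])
            c_ctrl = int((arm == CONTROL).sum())
            c_case = int((arm == CASE).sum())
            rows.append(
                {
                    "category": f"{col}: {level}" if len(categories.columns) > 2 else str(level),
                    "control_n": c_ctrl,
                    "control_pct": int(round_half_up(100.0 * c_ctrl / n_controls)),
                    "case_n": c_case,
                    "case_pct": int(round_half_up(100.0 * c_case / n_cases)),
                }
            )
    return CohortSummary(table=pd.DataFrame(rows), n_cases=n_cases, n_controls=n_controls)
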