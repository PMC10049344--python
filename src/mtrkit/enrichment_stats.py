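"""Case/control enrichment statistics over per-variant scores.

This module produces the machine form of a cohort-comparison results
table: percentile rank scores with a common damaging orientation,
fractions of each cohort falling beyond an intolerance threshold,
rank-based two-group tests, and pairwise predictor correlation matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, wilcoxon

logger = logging.getLogger(__name__)

#: predictors whose raw scale runs low = damaging; inverted before ranking
LOW_IS_DAMAGING = frozenset(
    {"MTR", "MTR_v1", "MTR_v2", "MTR3D", "SIFT", "FATHMM", "PROVEAN", "LRT"}
)

BELOW = "below"
ABOVE = "above"


@dataclass
class ScoreTable:
    """Per-variant predictor scores keyed by variant key.

    ``frame`` is indexed by variant key tuples; predictor columns hold raw
    values.  :meth:`add_rank_scores` appends ``<name>_rank`` columns in
    [0, 1] oriented so higher = more likely damaging.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("variant keys must be unique")

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.frame.columns if not c.endswith("_rank")]

    def add_rank_scores(self, orientation: dict[str, bool] | None = None) -> None:
        for name in self.predictors:
            invert = (
                orientation[name]
                if orientation and name in orientation
                else name in LOW_IS_DAMAGING
            )
            raw = self.frame[name]
            values = -raw if invert else raw
            self.frame[f"{name}_rank"] = rank_scores(values.to_numpy(dtype=float))


@dataclass
class EnrichmentResult:
    """One cohort's intolerant-variant tally at one threshold."""

    group: str
    score_name: str
    threshold: float
    direction: str  # below | above
    n_scored: int
    n_intolerant: int
    fraction_pct: int | None  # rounded integer percent; None when nothing scored

    @classmethod
    def from_counts(
        cls,
        n_intolerant: int,
        n_scored: int,
        group: str = "",
        score_name: str = "",
        threshold: float = float("nan"),
        direction: str = BELOW,
    ) -> "EnrichmentResult":
        return cls(
            group=group,
            score_name=score_name,
            threshold=threshold,
            direction=direction,
            n_scored=n_scored,
            n_intolerant=n_intolerant,
            fraction_pct=percentage(n_intolerant, n_scored),
        )


@dataclass
class GroupComparison:
    score_name: str
    case_n: int
    control_n: int
    statistic: float
    p_value: float
    test_kind: str


def percentage(n_intolerant: int, n_scored: int) -> int | None:
    """Integer percent, rounded half away from zero; None for an empty group."""
    if n_scored == 0:
        return None
    pct = Decimal(100 * n_intolerant) / Decimal(n_scored)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def rank_scores(values: np.ndarray) -> np.ndarray:
    """Percentile rank of each non-missing value, mapped to [0, 1].

    Ties receive their average rank; the minimum maps to 0 and the maximum
    to 1 (an all-tied column maps to 0.5).  Missing values stay missing.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("all values missing")
    out = np.full(values.shape, np.nan)
    if n == 1:
        out[mask] = 0.5
        return out
    ranks = rankdata(values[mask], method="average")
    out[mask] = (ranks - 1.0) / (n - 1.0)
    return out


def fraction_intolerant(
    scores: np.ndarray,
    threshold: float,
    direction: str = BELOW,
    group: str = "",
    score_name: str = "",
) -> EnrichmentResult:
    """Count scores strictly beyond ``threshold`` in the damaging direction.

    ``direction="below"`` suits MTR-family scores (low = intolerant);
    ``"above"`` suits MTRX-style scores (high = deleterious).  The
    fraction is reported as a rounded integer percent of non-missing
    scores; an empty column is flagged with ``fraction_pct=None``.
    """
    scores = np.asarray(scores, dtype=float)
    valid = scores[~np.isnan(scores)]
    if direction == BELOW:
        n_intolerant = int((valid < threshold).sum())
    elif direction == ABOVE:
        n_intolerant = int((valid > threshold).sum())
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if valid.size == 0:
        logger.warning("fraction_intolerant: no scored variants in %s", group or "group")
    return EnrichmentResult(
        group=group,
        score_name=score_name,
        threshold=threshold,
        direction=direction,
        n_scored=int(valid.size),
        n_intolerant=n_intolerant,
        fraction_pct=percentage(n_intolerant, int(valid.size)),
    )


def compare_groups(
    case: np.ndarray,
    control: np.ndarray,
    test: str = "ranksum",
    alternative: str = "two-sided",
    score_name: str = "",
) -> GroupComparison:
    """Rank-based two-group comparison of score distributions.

    The default is the two-sample Wilcoxon rank-sum (Mann-Whitney U),
    appropriate for independent case and control cohorts of unequal size;
    ``test="signed_rank"`` is available for genuinely paired samples.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    case = case[~np.isnan(case)]
    control = control[~np.isnan(control)]
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups need at least one non-missing value")
    if test == "ranksum":
        res = mannwhitneyu(case, control, alternative=alternative)
    elif test == "signed_rank":
        if case.size != control.size:
            raise ValueError("signed-rank requires paired samples of equal size")
        res = wilcoxon(case, control, alternative=alternative)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        score_name=score_name,
        case_n=int(case.size),
        control_n=int(control.size),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_kind=test,
    )


def pairwise_correlations(
    table: ScoreTable | pd.DataFrame,
    method: str = "spearman",
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise predictor correlation matrix over pairwise-complete rows.

    Returns ``(correlations, pair_counts)``: a symmetric matrix with unit
    diagonal and, per cell, the number of jointly non-missing rows.
    Columns with fewer than ``min_pairs`` complete pairs against every
    other column are excluded with a warning.
    """
    df = table.frame if isinstance(table, ScoreTable) else table
    numeric = df.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise ValueError("need at least two predictor columns")
    notna = numeric.notna().to_numpy().astype(int)
    counts = pd.DataFrame(
        notna.T @ notna, index=numeric.columns, columns=numeric.columns
    )
    keep = []
    for col in numeric.columns:
        others = counts.loc[col].drop(col)
        if (others >= min_pairs).any():
            keep.append(col)
        else:
            logger.warning(
                "pairwise_correlations: excluding %r (<%d complete pairs)",
                col,
                min_pairs,
            )
    numeric = numeric[keep]
    corr = numeric.corr(method=method, min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr, counts.loc[keep, keep]


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional companion column)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running_min = min(running_min, p[idx] * n / rank)
        adjusted[idx] = running_min
    return adjusted
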