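"""Inflammation calling and the grade–inflammation association tests.

High-grade urothelial tumors tend to carry lymphocytes and neutrophils
infiltrating between the tumor cells; these inflammatory nuclei are small,
so an image is called *inflamed* when the fraction of its segmented nuclei
below an area threshold exceeds a fraction threshold.  The association
between grade class (high / low) and inflammation presence is tested on a
2×2 contingency table with the closed-form Pearson chi-square,

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),

optionally Yates-corrected, plus a two-sided Fisher exact test by
hypergeometric enumeration as the robust alternative for tables with a
zero cell (the training cohort has one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "InflammationCall",
    "MarginError",
    "aggregate_case_calls",
    "call_inflammation",
    "chi_square_2x2",
    "contingency_from_calls",
    "fisher_exact_2x2",
]

logger = logging.getLogger(__name__)

DEFAULT_AREA_THRESHOLD_UM2 = 80.0
DEFAULT_FRACTION_THRESHOLD = 0.10


class MarginError(ValueError):
    """Raised when a contingency margin is zero (chi-square undefined)."""


@dataclass(frozen=True)
class InflammationCall:
    """Small-nucleus content of one image and the resulting binary call."""

    image_id: str
    n_nuclei: int
    small_nucleus_fraction: float
    has_inflammation: bool | None

    def __post_init__(self):
        if self.n_nuclei and not 0.0 <= self.small_nucleus_fraction <= 1.0:
            raise ValueError("small_nucleus_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: rows = grade class (high, low), cols = inflammation
    (present, absent)."""

    high_inflamed: int
    high_clean: int
    low_inflamed: int
    low_clean: int

    def __post_init__(self):
        if min(self.high_inflamed, self.high_clean, self.low_inflamed, self.low_clean) < 0:
            raise ValueError("counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.high_inflamed, self.high_clean], [self.low_inflamed, self.low_clean]],
            dtype=float,
        )

    @property
    def n(self) -> int:
        return self.high_inflamed + self.high_clean + self.low_inflamed + self.low_clean


def call_inflammation(
    records: pd.DataFrame,
    area_threshold_um2: float = DEFAULT_AREA_THRESHOLD_UM2,
    fraction_threshold: float = DEFAULT_FRACTION_THRESHOLD,
    image_id: str | None = None,
) -> InflammationCall:
    """Deterministic inflammation call from one image's nucleus records.

    The call is positive when the proportion of nuclei with
    ``area_um2 < area_threshold_um2`` is at least ``fraction_threshold``.
    An empty record list yields an undefined call (``has_inflammation``
    None) with a logged warning.
    """
    if image_id is None:
        image_id = (
            str(records["image_id"].iloc[0])
            if "image_id" in records.columns and len(records)
            else "image"
        )
    n = len(records)
    if n == 0:
        logger.warning("%s: no nuclei; inflammation call undefined", image_id)
        return InflammationCall(image_id, 0, np.nan, None)
    frac = float((records["area_um2"] < area_threshold_um2).mean())
    return InflammationCall(image_id, n, frac, frac >= fraction_threshold)


def aggregate_case_calls(
    image_calls: pd.DataFrame, rule: str = "majority"
) -> pd.Series:
    """Case-level inflammation from image-level calls.

    ``image_calls`` needs columns ``case_id`` and ``has_inflammation``.
    Under ``majority`` (default) a case is inflamed when more than half of
    its called images are; ``any`` flags a case on a single inflamed image.
    """
    if rule not in ("majority", "any"):
        raise ValueError("rule must be 'majority' or 'any'")
    df = image_calls.dropna(subset=["has_inflammation"])
    grouped = df.groupby("case_id")["has_inflammation"]
    if rule == "majority":
        return (grouped.mean() > 0.5).rename("has_inflammation")
    return grouped.any().rename("has_inflammation")


def contingency_from_calls(
    calls: pd.Series, grade_class: pd.Series
) -> ContingencyTable:
    """Build the 2×2 table from boolean calls and 'high'/'low' grade labels."""
    joined = pd.concat([calls.rename("inflamed"), grade_class.rename("grade")], axis=1)
    joined = joined.dropna()
    bad = set(joined["grade"]) - {"high", "low"}
    if bad:
        raise ValueError(f"grade classes must be 'high'/'low', got {sorted(bad)}")
    inflamed = joined["inflamed"].astype(bool)
    high = joined["grade"] == "high"
    return ContingencyTable(
        high_inflamed=int((high & inflamed).sum()),
        high_clean=int((high & ~inflamed).sum()),
        low_inflamed=int((~high & inflamed).sum()),
        low_clean=int((~high & ~inflamed).sum()),
    )


def chi_square_2x2(
    table: ContingencyTable, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square for a 2×2 table; returns (statistic, p-value).

    Uses the closed-form 2×2 expression (df = 1); ``correction`` applies
    Yates' continuity correction.  A zero margin raises
    :class:`MarginError` suggesting the exact test.
    """
    a, b = table.high_inflamed, table.high_clean
    c, d = table.low_inflamed, table.low_clean
    n = table.n
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise MarginError(
            "a contingency margin is zero; chi-square is undefined — "
            "use fisher_exact_2x2 instead"
        )
    if correction:
        num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    else:
        num = n * float(a * d - b * c) ** 2
    statistic = num / float(np.prod([float(m) for m in margins]))
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def fisher_exact_2x2(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    With margins fixed, the first cell ``a`` follows a hypergeometric law;
    the two-sided p-value sums the probabilities of every table at most as
    probable as the observed one.
    """
    a, b = table.high_inflamed, table.high_clean
    c, d = table.low_inflamed, table.low_clean
    n = table.n
    row1 = a + b
    col1 = a + c
    if n == 0:
        return 1.0
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return min(p, 1.0)
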