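"""Grade-group assignment, feature selection and two-point linear grading.

The grading analysis proceeds from a five-pathologist score panel (1 =
lowest grade .. 5 = highest), plus two expert raters:

* images scored 1 by at least four of the five raters form *group 1*;
  scored 5 by at least four form *group 5*; images whose five-rater mean
  lies in [2.5, 3.5] form *group 3*; everything else is unassigned.  The
  three rules are mutually exclusive (provable by enumerating all 5^5
  panels: four 1s force a mean ≤ 1.8 and four 5s a mean ≥ 4.2).
* each per-image summary statistic is tested group 1 vs group 5 with a
  Welch two-sample t-test; parameters with p < 0.01 are selected.
* a selected parameter's grader is the two-point linear map sending the
  group-1 mean to score 1 and the group-5 mean to score 5, clipped to
  [1, 5].  It is monotone in either direction, which matters because the
  strongest grade predictor (the 10th percentile of nuclear area) moves
  *down* with grade.
* two gradings of an image agree when their absolute difference is
  strictly below 2 points; an agreement report carries the rate (%) and
  the integer-binned delta histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "DegenerateGraderError",
    "LinearGrader",
    "agreement_rate",
    "assign_group",
    "assign_groups",
    "fit_linear_grader",
    "pivot_scores",
    "select_features",
    "validate_score_table",
]

GROUPS = ("group1", "group3", "group5", "unassigned")


class DegenerateGraderError(ValueError):
    """Raised when the two anchor means coincide."""


def validate_score_table(scores: pd.DataFrame, n_general: int = 5) -> pd.DataFrame:
    """Check a long-format score table (image_id, rater_id, role, score)."""
    required = {"image_id", "rater_id", "role", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    s = scores["score"]
    if not np.issubdtype(s.dtype, np.integer):
        if not np.allclose(s, s.astype(int)):
            raise ValueError("scores must be integers")
    if ((s < 1) | (s > 5)).any():
        raise ValueError("scores must lie in [1, 5]")
    bad_roles = set(scores["role"]) - {"general", "expert"}
    if bad_roles:
        raise ValueError(f"unknown rater roles: {sorted(bad_roles)}")
    general = scores[scores["role"] == "general"]
    counts = general.groupby("image_id")["rater_id"].nunique()
    if (counts != n_general).any():
        raise ValueError(f"every image must be scored by all {n_general} general raters")
    return scores


def pivot_scores(scores: pd.DataFrame, role: str | None = None) -> pd.DataFrame:
    """image × rater score matrix, optionally restricted to one role."""
    df = scores if role is None else scores[scores["role"] == role]
    return df.pivot(index="image_id", columns="rater_id", values="score")


def assign_group(panel_scores) -> str:
    """Group label from one image's five general-rater scores."""
    arr = np.asarray(panel_scores)
    if arr.shape != (5,):
        raise ValueError("expected exactly five general-rater scores")
    if np.any((arr < 1) | (arr > 5)) or not np.all(arr == arr.astype(int)):
        raise ValueError("scores must be integers in [1, 5]")
    if np.sum(arr == 1) >= 4:
        return "group1"
    if np.sum(arr == 5) >= 4:
        return "group5"
    if 2.5 <= arr.mean() <= 3.5:
        return "group3"
    return "unassigned"


def assign_groups(scores: pd.DataFrame) -> pd.Series:
    """Apply :func:`assign_group` to every image of a score table."""
    validate_score_table(scores)
    mat = pivot_scores(scores, role="general")
    return pd.Series(
        {img: assign_group(row.to_numpy()) for img, row in mat.iterrows()},
        name="group",
    ).rename_axis("image_id")


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def select_features(
    summaries: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.01,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Welch t-test of every summary parameter, group 1 vs group 5.

    Returns one row per parameter with the p-value, selected flag
    (p < ``alpha``) and the three descriptive group means.  The group-1 vs
    group-5 contrast is the selection gate because the linear grader is
    anchored on those two groups; group-3 means are reported alongside.
    ``bh_correction`` optionally applies Benjamini–Hochberg across
    parameters before gating.
    """
    joined = summaries.join(groups, how="inner")
    g1 = joined[joined["group"] == "group1"]
    g5 = joined[joined["group"] == "group5"]
    g3 = joined[joined["group"] == "group3"]
    if len(g1) < 2 or len(g5) < 2:
        raise ValueError("need at least two images in each of group1 and group5")

    params = [c for c in summaries.columns if c != "n_nuclei"]
    rows = []
    for p in params:
        pval = _welch_p(g1[p].to_numpy(dtype=float), g5[p].to_numpy(dtype=float))
        rows.append(
            {
                "parameter": p,
                "p_value": pval,
                "m1": float(np.nanmean(g1[p])) if len(g1) else np.nan,
                "m3": float(np.nanmean(g3[p])) if len(g3) else np.nan,
                "m5": float(np.nanmean(g5[p])) if len(g5) else np.nan,
            }
        )
    result = pd.DataFrame(rows).set_index("parameter")
    pvals = result["p_value"].to_numpy()
    if bh_correction:
        order = np.argsort(pvals)
        ranked = np.empty_like(pvals)
        m = np.sum(~np.isnan(pvals))
        adj = pvals.copy()
        sorted_p = pvals[order]
        q = sorted_p * m / (np.arange(len(sorted_p)) + 1)
        q = np.minimum.accumulate(q[::-1])[::-1]
        adj[order] = q
        ranked = adj
        result["p_adjusted"] = ranked
        result["selected"] = result["p_adjusted"] < alpha
    else:
        result["selected"] = result["p_value"] < alpha
    return result


@dataclass(frozen=True)
class LinearGrader:
    """Two-point linear grading function for one parameter.

    ``score(x) = 1 + 4 * (x - m1) / (m5 - m1)``, clipped to [1, 5]; the
    group-1 mean maps to score 1 and the group-5 mean to score 5 exactly.
    """

    feature: str
    m1: float
    m5: float

    def __post_init__(self):
        if self.m1 == self.m5:
            raise DegenerateGraderError(
                f"{self.feature!r}: group means coincide ({self.m1}); "
                "no two-point line exists"
            )

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        raw = 1.0 + 4.0 * (x - self.m1) / (self.m5 - self.m1)
        return np.clip(raw, 1.0, 5.0)

    def __call__(self, x):
        return self.predict(x)


def fit_linear_grader(m1: float, m5: float, feature: str = "") -> LinearGrader:
    """Construct the two-point grader from the group-1 and group-5 means."""
    return LinearGrader(feature=feature, m1=float(m1), m5=float(m5))


@dataclass
class AgreementReport:
    """Agreement rate (%) and integer-binned delta histogram of a − b."""

    rate_percent: float
    n: int
    delta_histogram: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.rate_percent <= 100.0:
            raise ValueError("rate must lie in [0, 100]")
        if sum(self.delta_histogram.values()) != self.n:
            raise ValueError("delta histogram must sum to the number of images")


def agreement_rate(a, b) -> AgreementReport:
    """Agreement of two gradings of the same images: agree iff |a − b| < 2.

    ``a`` may be continuous (a grader's output) and ``b`` integer rater
    scores, or both integer.  Accepts aligned arrays, or two pandas Series
    indexed by image id covering the same image set.  The delta histogram
    bins a − b rounded to the nearest integer (display convention); the
    rate itself uses the unrounded deltas.
    """
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        if set(a.index) != set(b.index):
            raise ValueError("gradings cover different image sets")
        b = b.reindex(a.index)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("gradings must be aligned 1-d collections")
    if a.size == 0:
        raise ValueError("cannot compute agreement on zero images")
    delta = a - b
    agree = np.abs(delta) < 2.0
    rounded = np.round(delta).astype(int)
    hist = {int(k): int(v) for k, v in zip(*np.unique(rounded, return_counts=True))}
    return AgreementReport(
        rate_percent=float(100.0 * agree.mean()),
        n=int(a.size),
        delta_histogram=hist,
    )
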